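"""Cause-group splitting of all-cause incidence.

Counts per cause within a stratum follow a Dirichlet-multinomial whose mean
is a multinomial-logit function of year, age group, sex and province and
whose concentration ``phi`` captures overdispersion (phi -> infinity recovers
the plain multinomial).  Estimation is maximum a posteriori with a weak
normal prior on the coefficients — no sampling.  Predicted fractions are then
applied multiplicatively to the all-cause rate surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .types import INDEX_COLS, CaseCountCube, CauseTaxonomy, RateSurface

#: Design terms the multinomial-logit mean may include.
DESIGN_TERMS = ("year", "age", "sex", "province")


@dataclass
class CauseModel:
    """Fitted multinomial-logit mean with Dirichlet-multinomial dispersion.

    ``coef`` has one column per non-reference cause and one row per design
    column; the reference cause carries implicit zeros.
    """

    causes: list[str]              # reference last
    reference: str
    coef: pd.DataFrame
    phi: float
    design_spec: tuple[str, ...]
    year_center: float
    province_levels: list[int]

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("concentration phi must be positive")
        if self.causes[-1] != self.reference:
            raise ValueError("reference cause must be ordered last")


def dirichlet_multinomial_loglik(counts: np.ndarray, probs: np.ndarray, phi: float) -> float:
    """Log likelihood of count rows given mean probabilities and concentration.

    Omits the multinomial coefficient (constant in the parameters), exactly
    as the fitting objective does.
    """
    counts = np.atleast_2d(counts)
    probs = np.atleast_2d(probs)
    n = counts.sum(axis=1)
    alpha = phi * probs
    ll = gammaln(phi) - gammaln(n + phi) + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1)
    return float(ll.sum())


def multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log likelihood without the combinatorial constant."""
    counts = np.atleast_2d(counts)
    probs = np.atleast_2d(probs)
    return float((counts * np.log(probs)).sum())


def _strata_counts(cube: CaseCountCube, causes: list[str]):
    df = cube.data
    if "cause" not in df.columns:
        raise ValueError("cause model needs a cube with a cause dimension")
    wide = (
        df.pivot_table(index=INDEX_COLS, columns="cause", values="count", aggfunc="sum")
        .fillna(0.0)
        .reset_index()
    )
    missing = [c for c in causes if c not in wide.columns]
    for c in missing:
        wide[c] = 0.0
    zero_causes = [c for c in causes if wide[c].sum() == 0]
    if zero_causes:
        raise ValueError(
            f"cause(s) with zero count everywhere: {zero_causes}; collapse into the reference first"
        )
    return wide[INDEX_COLS].copy(), wide[causes].to_numpy(dtype=float)


def _build_design(
    strata: pd.DataFrame,
    design_spec: tuple[str, ...],
    year_center: float,
    province_levels: list[int],
) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(strata))}
    if "year" in design_spec:
        cols["year_c"] = strata["year"].to_numpy(dtype=float) - year_center
    if "age" in design_spec:
        for a in (1, 2, 3):
            cols[f"age_{a}"] = (strata["age_code"] == a).to_numpy(dtype=float)
    if "sex" in design_spec:
        cols["sex_male"] = (strata["sex"] == "male").to_numpy(dtype=float)
    if "province" in design_spec:
        for pid in province_levels[1:]:  # first level is the baseline
            cols[f"prov_{pid}"] = (strata["province_id"] == pid).to_numpy(dtype=float)
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def _softmax_eta(Z: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mean probabilities from design Z (S x D) and coefficients B (D x K-1);
    the reference cause's linear predictor is pinned at zero (last column)."""
    eta = np.concatenate([Z @ B, np.zeros((Z.shape[0], 1))], axis=1)
    return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))


def fit_cause_model(
    cause_cube: CaseCountCube,
    design_spec: tuple[str, ...] = DESIGN_TERMS,
    prior_sd: float = 5.0,
    taxonomy: CauseTaxonomy | None = None,
) -> CauseModel:
    """MAP fit of the overdispersed multinomial cause model.

    Strata with zero total count contribute nothing to the likelihood and
    are skipped.  ``prior_sd`` is the scale of the mean-zero normal prior on
    every coefficient; the concentration is estimated jointly on the log
    scale.
    """
    unknown = set(design_spec) - set(DESIGN_TERMS)
    if unknown:
        raise ValueError(f"unknown design terms: {sorted(unknown)}")
    if taxonomy is not None:
        causes = [c for c in taxonomy.codes if c != taxonomy.reference] + [taxonomy.reference]
        reference = taxonomy.reference
    else:
        observed = sorted(cause_cube.data["cause"].unique())
        reference = "other" if "other" in observed else observed[-1]
        causes = [c for c in observed if c != reference] + [reference]
    if len(causes) < 2:
        raise ValueError("need at least two cause groups")

    strata, counts = _strata_counts(cause_cube, causes)
    keep = counts.sum(axis=1) > 0
    strata, counts = strata.loc[keep].reset_index(drop=True), counts[keep]
    year_center = float(strata["year"].mean()) if "year" in design_spec else 0.0
    province_levels = (
        sorted(strata["province_id"].unique()) if "province" in design_spec else []
    )
    Z, design_cols = _build_design(strata, design_spec, year_center, province_levels)
    S, D = Z.shape
    K = len(causes)
    n = counts.sum(axis=1)

    def unpack(theta):
        return theta[:-1].reshape(D, K - 1), np.exp(theta[-1])

    def neg_log_posterior(theta):
        B, phi = unpack(theta)
        pi = _softmax_eta(Z, B)
        alpha = phi * pi
        ll = (
            gammaln(phi) * S
            - gammaln(n + phi).sum()
            + (gammaln(counts + alpha) - gammaln(alpha)).sum()
        )
        lp = -0.5 * (B**2).sum() / prior_sd**2
        # gradient
        g_pi = phi * (digamma(counts + alpha) - digamma(alpha))  # S x K
        dl_deta = pi * (g_pi - (pi * g_pi).sum(axis=1, keepdims=True))
        grad_B = Z.T @ dl_deta[:, : K - 1] - B / prior_sd**2
        dl_dphi = (
            digamma(phi) * S
            - digamma(n + phi).sum()
            + (pi * (digamma(counts + alpha) - digamma(alpha))).sum()
        )
        grad_logphi = phi * dl_dphi
        grad = np.concatenate([grad_B.reshape(-1), [grad_logphi]])
        return -(ll + lp), -grad

    theta0 = np.concatenate([np.zeros(D * (K - 1)), [np.log(10.0)]])
    bounds = [(None, None)] * (D * (K - 1)) + [(-5.0, 20.0)]
    res = minimize(
        neg_log_posterior,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500},
    )
    B_hat, phi_hat = unpack(res.x)
    coef = pd.DataFrame(B_hat, index=design_cols, columns=causes[:-1])
    return CauseModel(
        causes=causes,
        reference=reference,
        coef=coef,
        phi=float(phi_hat),
        design_spec=tuple(design_spec),
        year_center=year_center,
        province_levels=province_levels,
    )


@dataclass
class CauseFractionTable:
    """Per-stratum simplex over causes (wide: one column per cause)."""

    data: pd.DataFrame
    causes: list[str]

    def __post_init__(self) -> None:
        frac = self.data[self.causes].to_numpy()
        if (frac < -1e-12).any() or (frac > 1 + 1e-12).any():
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(frac.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1 within 1e-9 per stratum")

    @property
    def stratum_cols(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.causes]


def predict_fractions(model: CauseModel, strata: pd.DataFrame) -> CauseFractionTable:
    """Softmax fractions for each requested stratum row."""
    Z, _ = _build_design(strata, model.design_spec, model.year_center, model.province_levels)
    pi = _softmax_eta(Z, model.coef.to_numpy())
    out = strata.reset_index(drop=True).copy()
    for k, cause in enumerate(model.causes):
        out[cause] = pi[:, k]
    return CauseFractionTable(data=out, causes=list(model.causes))


def apply_fractions(
    all_cause_surface: RateSurface, fractions: CauseFractionTable
) -> dict[str, RateSurface]:
    """Cause-specific surfaces: rate_cause = all-cause rate x fraction.

    Fractions may be defined on any subset of the stratum key; they are
    joined on the columns they carry.  Summing the outputs over causes
    restores the all-cause surface.
    """
    join_cols = [c for c in INDEX_COLS if c in fractions.stratum_cols]
    if not join_cols:
        raise ValueError("fraction table shares no stratum columns with the surface")
    merged = all_cause_surface.data.merge(
        fractions.data[join_cols + fractions.causes], on=join_cols, how="left",
        validate="many_to_one",
    )
    if merged[fractions.causes].isna().any().any():
        raise ValueError("fraction table does not cover all surface strata")
    out = {}
    for cause in fractions.causes:
        df = merged[INDEX_COLS].copy()
        df["rate"] = np.maximum(merged["rate"] * merged[cause], 1e-12)
        out[cause] = RateSurface(df)
    return out
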