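"""Two-stage age-spatiotemporal incidence estimator.

Stage 1 fits a random-intercept mixed model to log incidence rates,

    ln(rate + floor) = b0 + b.X(p,t) + d*t + alpha_age + gamma_sex + u_p + e,

by restricted maximum likelihood (province random intercepts).  Stage 2
remodels the residuals: every cell's residual is replaced by a weighted
average of all residuals, with weights separable into a spatial factor
(1 for the same province, ``zeta`` for first-order neighbours, 0 otherwise),
an exponential time kernel exp(-|dt|/lamda) and an exponential age kernel
exp(-omega*|da|) on age-group midpoints.  Sexes never share information.
Uncertainty comes from a Poisson parametric bootstrap of the aggregated
counts through the whole two-stage estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import (
    AGE_MIDPOINTS,
    INDEX_COLS,
    AdjacencyGraph,
    CaseCountCube,
    PopulationCube,
    RateSurface,
    SmoothingParams,
)

#: Fixed rate floor (per 100,000) added inside the log so zero cells stay
#: finite; the default is the count-adaptive rule instead (see ``fit_stage1``).
FIXED_FLOOR = 0.01

_COVARIATE_COLS = ("wealth_index", "education_years", "urbanization")


@dataclass
class Stage1Fit:
    """Fitted stage-1 mixed model plus the per-cell linear predictor.

    ``linear_predictor`` carries one row per modelled cell with the linear
    predictor ``eta`` (fixed effects plus the province intercept) and the
    per-cell rate floor used inside the log transform.
    """

    params: pd.Series              # fixed effects, named
    bse: pd.Series                 # standard errors of the fixed effects
    random_intercepts: dict[int, float]
    var_random: float              # random-intercept variance
    var_resid: float               # residual variance
    floor: float | str             # configured floor rule
    year_center: float
    linear_predictor: pd.DataFrame  # INDEX_COLS + eta + floor

    def __post_init__(self) -> None:
        if self.var_random < 0 or self.var_resid < 0:
            raise ValueError("variance components must be non-negative")


def _cell_floors(df: pd.DataFrame, floor: float | str) -> np.ndarray:
    """Per-cell rate floor (per 100,000).

    A numeric ``floor`` is used as-is for every cell.  ``"adaptive"`` uses
    half of the year's count quantum per person-year: completeness-corrected
    counts are integer multiples of 1/completeness, so the smallest positive
    count in a year recovers that quantum and the floor corresponds to half
    an uncorrected case — the continuity correction ln(count + q/2) on the
    rate scale.  This keeps zero cells from dominating the log-scale fit
    when expected counts are small.
    """
    if isinstance(floor, (int, float)):
        if floor <= 0:
            raise ValueError("fixed floor must be positive")
        return np.full(len(df), float(floor))
    if floor != "adaptive":
        raise ValueError(f"unknown floor rule {floor!r}")
    positive = df[df["count"] > 0]
    if positive.empty:
        raise ValueError("all-zero cube: nothing to model")
    quantum = positive.groupby("year")["count"].min()
    qy = df["year"].map(quantum).fillna(quantum.min()).to_numpy()
    return 0.5 * qy / df["person_years"].to_numpy() * 1e5


def _log_rate(
    cube: CaseCountCube, population: PopulationCube, floor: float | str
) -> pd.DataFrame:
    df = cube.all_cause().data.merge(population.data, on=INDEX_COLS, validate="one_to_one")
    if (df["person_years"] <= 0).any():
        raise ValueError("person-years must be strictly positive in modelled cells")
    df["rate"] = df["count"] / df["person_years"] * 1e5
    df["floor"] = _cell_floors(df, floor)
    df["y"] = np.log(df["rate"] + df["floor"])
    return df


def _design(df: pd.DataFrame, covariates: pd.DataFrame | None, year_center: float):
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    if covariates is not None:
        merged = df[["province_id", "year"]].merge(
            covariates, on=["province_id", "year"], how="left", validate="many_to_one"
        )
        if merged[list(_COVARIATE_COLS)].isna().any().any():
            raise ValueError("covariate table does not cover all modelled cells")
        for c in _COVARIATE_COLS:
            X[c] = merged[c].to_numpy()
    X["year_c"] = df["year"].to_numpy() - year_center
    for a in (1, 2, 3):
        X[f"age_{a}"] = (df["age_code"] == a).astype(float).to_numpy()
    X["sex_male"] = (df["sex"] == "male").astype(float).to_numpy()
    return X


def fit_stage1(
    cube: CaseCountCube,
    population: PopulationCube,
    covariates: pd.DataFrame | None = None,
    floor: float | str = "adaptive",
) -> Stage1Fit:
    """REML random-intercept mixed model on log incidence rates.

    ``floor`` is either a fixed rate floor per 100,000 or ``"adaptive"``
    (half the year's count quantum; see :func:`_cell_floors`).  A
    single-province input (no random-effect information) degenerates to
    ordinary least squares with a zero random intercept.
    """
    df = _log_rate(cube, population, floor)
    if (df["count"] == 0).all():
        raise ValueError("all-zero cube: nothing to model")
    year_center = float(df["year"].mean())
    X = _design(df, covariates, year_center)
    if len(df) <= X.shape[1]:
        raise ValueError("fewer strata than model parameters")
    y = df["y"].to_numpy()
    groups = df["province_id"].to_numpy()

    if df["province_id"].nunique() < 2:
        ols = sm.OLS(y, X).fit()
        params, bse = ols.params, ols.bse
        u = {int(df["province_id"].iloc[0]): 0.0}
        var_random, var_resid = 0.0, float(ols.mse_resid)
        fitted = ols.fittedvalues.to_numpy()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
        params, bse = res.params[X.columns], res.bse[X.columns]
        u = {int(g): float(re.iloc[0]) for g, re in res.random_effects.items()}
        var_random = float(res.cov_re.iloc[0, 0])
        var_resid = float(res.scale)
        fitted = X.to_numpy() @ params.to_numpy() + df["province_id"].map(u).to_numpy()

    lp = df[INDEX_COLS + ["floor"]].copy()
    lp["eta"] = fitted
    return Stage1Fit(
        params=pd.Series(params, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        random_intercepts=u,
        var_random=max(var_random, 0.0),
        var_resid=max(var_resid, 0.0),
        floor=floor,
        year_center=year_center,
        linear_predictor=lp,
    )


def compute_residuals(
    fit: Stage1Fit, cube: CaseCountCube, population: PopulationCube
) -> pd.DataFrame:
    """Observed log rate minus the stage-1 linear predictor, per cell."""
    df = cube.all_cause().data.merge(population.data, on=INDEX_COLS, validate="one_to_one")
    merged = df.merge(fit.linear_predictor, on=INDEX_COLS, validate="one_to_one")
    if len(merged) != len(df):
        raise ValueError("stage-1 fit does not cover all cube cells")
    y = np.log(merged["count"] / merged["person_years"] * 1e5 + merged["floor"])
    out = merged[INDEX_COLS].copy()
    out["residual"] = y - merged["eta"]
    return out


def st_weight(
    delta_t: float,
    spatial_relation: str,
    delta_age: float,
    params: SmoothingParams,
) -> float:
    """Separable space x time x age weight between two cells, in [0, 1]."""
    if delta_t < 0 or delta_age < 0:
        raise ValueError("time and age distances must be non-negative")
    if spatial_relation == "same":
        w_space = 1.0
    elif spatial_relation == "neighbor":
        w_space = params.zeta
    elif spatial_relation == "other":
        w_space = 0.0
    else:
        raise ValueError(f"unknown spatial relation {spatial_relation!r}")
    w_time = np.exp(-abs(delta_t) / params.lamda)
    w_age = np.exp(-params.omega * abs(delta_age))
    return float(w_space * w_time * w_age)


def _kernel_matrices(
    provinces: np.ndarray, years: np.ndarray, ages: np.ndarray,
    adjacency: AdjacencyGraph, params: SmoothingParams,
):
    P = len(provinces)
    Wp = np.eye(P)
    for i in range(P):
        for j in range(P):
            if i != j and adjacency.are_neighbors(int(provinces[i]), int(provinces[j])):
                Wp[i, j] = params.zeta
    dt = np.abs(years[:, None] - years[None, :])
    Kt = np.exp(-dt / params.lamda)
    mids = np.array([AGE_MIDPOINTS[int(a)] for a in ages])
    Ka = np.exp(-params.omega * np.abs(mids[:, None] - mids[None, :]))
    return Wp, Kt, Ka


def smooth_residuals(
    residuals: pd.DataFrame, adjacency: AdjacencyGraph, params: SmoothingParams
) -> pd.DataFrame:
    """Weighted-average residual smoothing; sexes are never mixed.

    Each output cell is the convex combination of every same-sex residual
    with positive weight (the cell itself always has weight 1, so the
    normaliser never vanishes).
    """
    out_frames = []
    for sex, sub in residuals.groupby("sex"):
        provinces = np.sort(sub["province_id"].unique())
        years = np.sort(sub["year"].unique())
        ages = np.sort(sub["age_code"].unique())
        expected = len(provinces) * len(years) * len(ages)
        if len(sub) != expected:
            raise ValueError(f"residual cube incomplete for sex={sex!r}")
        R = (
            sub.set_index(["province_id", "year", "age_code"])["residual"]
            .unstack(["year", "age_code"])  # rows: province
            .loc[provinces]
            .to_numpy()
            .reshape(len(provinces), len(years), len(ages))
        )
        Wp, Kt, Ka = _kernel_matrices(provinces, years, ages, adjacency, params)
        num = np.einsum("pq,tu,av,quv->pta", Wp, Kt, Ka, R, optimize=True)
        den = np.einsum("pq,tu,av->pta", Wp, Kt, Ka, optimize=True)
        S = num / den
        frame = pd.MultiIndex.from_product(
            [provinces, years, ages], names=["province_id", "year", "age_code"]
        ).to_frame(index=False)
        frame["sex"] = sex
        frame["residual"] = S.reshape(-1)
        out_frames.append(frame)
    out = pd.concat(out_frames, ignore_index=True)[INDEX_COLS + ["residual"]]
    return out.sort_values(INDEX_COLS, ignore_index=True)


def predict_rates(fit: Stage1Fit, smoothed: pd.DataFrame) -> RateSurface:
    """Compose stage 1 and stage 2: rate = exp(eta + smoothed) - floor."""
    merged = fit.linear_predictor.merge(smoothed, on=INDEX_COLS, validate="one_to_one")
    if len(merged) != len(fit.linear_predictor):
        raise ValueError("smoothed residuals do not cover the fitted cells")
    out = merged[INDEX_COLS].copy()
    out["rate"] = np.maximum(
        np.exp(merged["eta"] + merged["residual"]) - merged["floor"], 1e-6
    )
    return RateSurface(out)


def make_two_stage_estimator(
    population: PopulationCube,
    covariates: pd.DataFrame | None,
    adjacency: AdjacencyGraph,
    smoothing: SmoothingParams | None = None,
    floor: float | str = "adaptive",
) -> Callable[[CaseCountCube], RateSurface]:
    """Bind everything but the counts, for repeated bootstrap refits."""
    params = smoothing or SmoothingParams()

    def estimator(cube: CaseCountCube) -> RateSurface:
        fit = fit_stage1(cube, population, covariates, floor=floor)
        res = compute_residuals(fit, cube, population)
        smoothed = smooth_residuals(res, adjacency, params)
        return predict_rates(fit, smoothed)

    return estimator


def simulate_uncertainty(
    cube: CaseCountCube,
    population: PopulationCube,
    estimator: Callable[[CaseCountCube], RateSurface],
    n_draws: int = 200,
    seed: int = 0,
) -> RateSurface:
    """Parametric bootstrap 95% uncertainty intervals.

    Each draw resamples every cell count as Poisson(observed corrected
    count), reruns the full estimator and stores the resulting rates; the
    interval is the 2.5th-97.5th percentile band of the draws, widened if
    necessary to bracket the point estimate from the unresampled data.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    point = estimator(cube)
    rng = np.random.default_rng(seed)
    base = cube.all_cause().data
    means = base["count"].to_numpy(dtype=float)
    draws = np.empty((len(point.data), n_draws))
    for d in range(n_draws):
        resampled = base.copy()
        resampled["count"] = rng.poisson(means)
        surf = estimator(CaseCountCube(resampled, kind="corrected"))
        aligned = point.data[INDEX_COLS].merge(surf.data, on=INDEX_COLS, validate="one_to_one")
        draws[:, d] = aligned["rate"].to_numpy()
    lower = np.percentile(draws, 2.5, axis=1)
    upper = np.percentile(draws, 97.5, axis=1)
    data = point.data.copy()
    data["lower"] = np.minimum(lower, data["rate"])
    data["upper"] = np.maximum(upper, data["rate"])
    return RateSurface(data, draws=draws)


def select_smoothing_loyo(
    residuals: pd.DataFrame,
    adjacency: AdjacencyGraph,
    grid: list[SmoothingParams],
) -> tuple[SmoothingParams, pd.DataFrame]:
    """Leave-one-year-out selection of the smoothing hyperparameters.

    For each candidate, every year's residuals are predicted using only the
    other years' cells (the held-out year's column of the time kernel is
    zeroed); the candidate with the lowest mean squared prediction error
    wins.  A convenience, not part of the default pipeline.
    """
    scores = []
    for params in grid:
        sq_errs = []
        for sex, sub in residuals.groupby("sex"):
            provinces = np.sort(sub["province_id"].unique())
            years = np.sort(sub["year"].unique())
            ages = np.sort(sub["age_code"].unique())
            R = (
                sub.set_index(["province_id", "year", "age_code"])["residual"]
                .unstack(["year", "age_code"])
                .loc[provinces]
                .to_numpy()
                .reshape(len(provinces), len(years), len(ages))
            )
            Wp, Kt, Ka = _kernel_matrices(provinces, years, ages, adjacency, params)
            for ti in range(len(years)):
                Kt_holdout = Kt.copy()
                Kt_holdout[:, ti] = 0.0
                num = np.einsum("pq,tu,av,quv->pta", Wp, Kt_holdout, Ka, R, optimize=True)
                den = np.einsum("pq,tu,av->pta", Wp, Kt_holdout, Ka, optimize=True)
                with np.errstate(invalid="ignore", divide="ignore"):
                    pred = num[:, ti, :] / den[:, ti, :]
                sq = (pred - R[:, ti, :]) ** 2
                # a candidate that cannot predict a held-out year at all
                # (zero total weight) is infinitely bad there
                sq[~np.isfinite(sq)] = np.inf
                sq_errs.append(sq)
        scores.append(float(np.mean([e.mean() for e in sq_errs])))
    table = pd.DataFrame(
        {
            "zeta": [p.zeta for p in grid],
            "lamda": [p.lamda for p in grid],
            "omega": [p.omega for p in grid],
            "loyo_mse": scores,
        }
    )
    best = grid[int(np.argmin(scores))]
    return best, table
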