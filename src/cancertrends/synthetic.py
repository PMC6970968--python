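"""Synthetic registry generator with a known ground truth.

The real national childhood-cancer registry is confidential, so every
downstream stage is exercised against data generated here: a population cube
with a declining under-15 population, a log-linear incidence surface with
spatially correlated province effects and a fixed male:female rate ratio,
individual records thinned by year-varying registration completeness and
contaminated with near-duplicate records and missing fields, cause labels
drawn from drifting multinomial fractions, and a paired mortality series with
a declining mortality-to-incidence ratio.  Every injection is logged in a
:class:`~cancertrends.types.TruthBundle` so recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AGE_BOUNDS,
    AGE_GROUPS,
    INDEX_COLS,
    SEXES,
    STUDY_YEARS,
    AdjacencyGraph,
    CaseCountCube,
    PopulationCube,
    RateSurface,
    RegistryRecord,
    TruthBundle,
    load_default_adjacency,
    load_default_provinces,
)

# ---------------------------------------------------------------------------
# Parameter blocks (defaults are the study conditions)
# ---------------------------------------------------------------------------


def _default_province_shares() -> dict[int, float]:
    return {p.id: p.population_share for p in load_default_provinces()}


@dataclass(frozen=True)
class DemographicParams:
    """National under-15 person-years and how they split across strata.

    Endpoint totals reflect the documented decline of the Iranian under-15
    population (roughly 23.7M around 1990 to 19.2M in 2016); interior years
    are log-linear between them.  Shares are held constant over time.
    """

    total_first: float = 23_700_000.0
    total_last: float = 19_190_000.0
    years: tuple[int, ...] = STUDY_YEARS
    province_shares: dict[int, float] = field(default_factory=_default_province_shares)
    age_shares: dict[int, float] = field(
        default_factory=lambda: {0: 1 / 15, 1: 4 / 15, 2: 5 / 15, 3: 5 / 15}
    )
    male_fraction: float = 0.512

    def national_total(self, year: int) -> float:
        """The configured national total for ``year`` (log-linear endpoints)."""
        y0, y1 = self.years[0], self.years[-1]
        if y1 == y0:
            return self.total_first
        frac = (year - y0) / (y1 - y0)
        return float(self.total_first * (self.total_last / self.total_first) ** frac)


@dataclass(frozen=True)
class RateParams:
    """True incidence surface: rate(p,t,a,s) = base * e^(slope*(t-t0))
    * age_mult(a) * sex_mult(s) * e^(u_p).

    ``base_rate`` is per 100,000 for the reference cell (female, <1 year,
    year ``t0``).  Age multipliers rise with age order and, together with the
    base, put the national ASR near 10 per 100,000 at ``t0``; the male:female
    ratio is the constant 1.3 reported for the study population.
    """

    base_rate: float = 6.5
    annual_slope: float = 0.0065
    age_multipliers: tuple[float, float, float, float] = (1.0, 1.09, 1.36, 1.67)
    male_female_ratio: float = 1.3
    province_sd: float = 0.25
    spatial_rho: float = 0.5
    t0: int = STUDY_YEARS[0]


@dataclass(frozen=True)
class CauseParams:
    """Drifting multinomial cause fractions on the log-odds scale.

    ``intercepts``/``slopes`` are log-odds versus the reference cause at
    ``t0`` and per year; the reference cause carries an implicit zero.
    Defaults emulate the observed shift from a residual-dominated mix toward
    leukemia and CNS tumours over 1990-2016.
    """

    reference: str = "other"
    intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "leukemia": -1.568,
            "cns": -3.381,
            "lymphoma": -1.931,
            "endocrine": -3.705,
            "digestive": -2.381,
            "urinary": -2.769,
        }
    )
    slopes: dict[str, float] = field(
        default_factory=lambda: {
            "leukemia": 0.094,
            "cns": 0.138,
            "lymphoma": 0.042,
            "endocrine": 0.111,
            "digestive": 0.050,
            "urinary": 0.048,
        }
    )
    t0: int = STUDY_YEARS[0]

    def fractions(self, years) -> pd.DataFrame:
        """One row per year, one simplex column per cause code."""
        causes = list(self.intercepts) + [self.reference]
        rows = []
        for y in years:
            eta = np.array(
                [
                    self.intercepts[c] + self.slopes.get(c, 0.0) * (y - self.t0)
                    for c in self.intercepts
                ]
                + [0.0]
            )
            p = np.exp(eta - eta.max())
            p /= p.sum()
            rows.append(dict(zip(causes, p), year=y))
        return pd.DataFrame(rows)[["year"] + causes]


#: Small plausible name pool; realism is a non-goal, recoverability is not.
DEFAULT_NAME_POOL = {
    "first": [
        "Ali", "Reza", "Hossein", "Mehdi", "Amir", "Hassan", "Mohammad",
        "Abbas", "Javad", "Saeed", "Hamid", "Majid", "Omid", "Babak",
        "Fatemeh", "Zahra", "Maryam", "Narges", "Sara", "Leila", "Niloofar",
        "Shirin", "Parisa", "Elham", "Azadeh", "Mina", "Roya", "Samaneh",
    ],
    "last": [
        "Ahmadi", "Mohammadi", "Hosseini", "Rezaei", "Moradi", "Karimi",
        "Jafari", "Rahimi", "Sadeghi", "Ebrahimi", "Ghasemi", "Heidari",
        "Kazemi", "Akbari", "Naderi", "Salehi", "Mousavi", "Bagheri",
        "Tehrani", "Shirazi", "Esfahani", "Yazdani", "Rashidi", "Farahani",
    ],
    "street": ["Azadi", "Enghelab", "Ferdowsi", "Hafez", "Saadi", "Valiasr"],
}


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def generate_population_cube(
    demo_params: DemographicParams | None = None, seed: int = 0
) -> PopulationCube:
    """Person-years per stratum, log-linear in time between endpoint totals.

    Deterministic given the parameters; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    p = demo_params or DemographicParams()
    if p.total_first <= 0 or p.total_last <= 0:
        raise ValueError("national totals must be positive")
    for name, shares in (("province", p.province_shares), ("age", p.age_shares)):
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} shares must sum to 1 within 1e-9")
    if not 0 < p.male_fraction < 1:
        raise ValueError("male_fraction must lie in (0, 1)")

    sex_share = {"female": 1.0 - p.male_fraction, "male": p.male_fraction}
    rows = []
    for year in p.years:
        total = p.national_total(year)
        for pid, ps in p.province_shares.items():
            for age, ash in p.age_shares.items():
                for sex, ss in sex_share.items():
                    rows.append(
                        {
                            "province_id": pid,
                            "year": year,
                            "age_code": age,
                            "sex": sex,
                            "person_years": total * ps * ash * ss,
                        }
                    )
    return PopulationCube(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# True rates
# ---------------------------------------------------------------------------


def generate_true_rates(
    rate_params: RateParams | None = None,
    adjacency: AdjacencyGraph | None = None,
    seed: int = 0,
    years: tuple[int, ...] = STUDY_YEARS,
) -> RateSurface:
    """Noise-free structural incidence surface with spatially correlated
    province effects.

    Province effects start i.i.d. N(0, province_sd^2) and are mixed one step
    along the adjacency graph: u_p <- (1-rho) u_p + rho * mean(u_neighbours),
    the simplest mechanism giving adjacency-structured correlation.
    """
    rp = rate_params or RateParams()
    if rp.base_rate <= 0 or any(m <= 0 for m in rp.age_multipliers):
        raise ValueError("base rate and age multipliers must be positive")
    if rp.male_female_ratio <= 0:
        raise ValueError("male:female ratio must be positive")
    graph = adjacency or load_default_adjacency()
    pids = sorted(p.id for p in graph.provinces)

    rng = np.random.default_rng(seed)
    u_raw = {pid: rng.normal(0.0, rp.province_sd) for pid in pids}
    u = {}
    for pid in pids:
        nbrs = graph.neighbors(pid)
        if nbrs and rp.spatial_rho > 0:
            nbr_mean = float(np.mean([u_raw[n] for n in nbrs]))
            u[pid] = (1 - rp.spatial_rho) * u_raw[pid] + rp.spatial_rho * nbr_mean
        else:
            u[pid] = u_raw[pid]

    sex_mult = {"female": 1.0, "male": rp.male_female_ratio}
    rows = []
    for pid in pids:
        for year in years:
            trend = np.exp(rp.annual_slope * (year - rp.t0))
            for g in AGE_GROUPS:
                for sex in SEXES:
                    rows.append(
                        {
                            "province_id": pid,
                            "year": year,
                            "age_code": g.code,
                            "sex": sex,
                            "rate": rp.base_rate
                            * trend
                            * rp.age_multipliers[g.code]
                            * sex_mult[sex]
                            * np.exp(u[pid]),
                        }
                    )
    return RateSurface(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Individual records
# ---------------------------------------------------------------------------

#: Analytic/identity fields that the generator may blank at random.
MASKABLE_FIELDS = ("parent_name", "address", "sex", "province_id")

_SOURCES = ("pathology", "hospital", "chemotherapy", "surgery", "radiotherapy")


def _perturb_name(name: str, rng: np.random.Generator) -> str:
    """Single-character edit or case/spacing change, never emptying the name."""
    kind = rng.integers(0, 4)
    i = int(rng.integers(0, len(name)))
    if kind == 0:  # case flip
        return name[:i] + name[i].swapcase() + name[i + 1 :]
    if kind == 1 and len(name) > 2:  # deletion
        return name[:i] + name[i + 1 :]
    if kind == 2:  # substitution
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        return name[:i] + alphabet[int(rng.integers(0, 26))] + name[i + 1 :]
    return name[:i] + " " + name[i:]  # inserted space


def sample_registry(
    true_rates: RateSurface,
    population: PopulationCube,
    completeness_by_year: dict[int, float],
    dup_rate: float = 0.02,
    missing_rate: float = 0.03,
    name_pool: dict[str, list[str]] | None = None,
    seed: int = 0,
    cause_params: CauseParams | None = None,
) -> tuple[list[RegistryRecord], TruthBundle]:
    """Draw an individual-level registry from the true surface.

    Cell counts are Poisson(rate * PY / 1e5), thinned binomially by the
    year's completeness.  With probability ``dup_rate`` an observed record
    spawns a near-duplicate (perturbed name spelling); each maskable field is
    blanked independently with probability ``missing_rate``.  All injections
    are logged in the returned :class:`TruthBundle`.
    """
    for y, c in completeness_by_year.items():
        if not 0 < c <= 1:
            raise ValueError(f"completeness for {y} must lie in (0, 1], got {c}")
    if not 0 <= dup_rate < 1 or not 0 <= missing_rate < 1:
        raise ValueError("dup_rate and missing_rate must lie in [0, 1)")
    pool = name_pool or DEFAULT_NAME_POOL
    if dup_rate > 0 and (not pool.get("first") or not pool.get("last")):
        raise ValueError("name pool must be non-empty when dup_rate > 0")
    cp = cause_params or CauseParams()

    merged = true_rates.data.merge(population.data, on=INDEX_COLS, validate="one_to_one")
    years = sorted(merged["year"].unique())
    missing_years = [y for y in years if y not in completeness_by_year]
    if missing_years:
        raise ValueError(f"completeness missing for years {missing_years}")

    frac_table = cp.fractions(years)
    causes = [c for c in frac_table.columns if c != "year"]
    frac_by_year = {
        int(r.year): np.array([getattr(r, c) for c in causes]) for r in frac_table.itertuples()
    }

    rng = np.random.default_rng(seed)
    mean_counts = merged["rate"].to_numpy() * merged["person_years"].to_numpy() / 1e5
    true_counts = rng.poisson(mean_counts)

    records: list[RegistryRecord] = []
    duplicate_pairs: list[tuple[int, int]] = []
    missing_mask: list[tuple[int, str]] = []
    next_id = 1
    firsts, lasts, streets = pool["first"], pool["last"], pool.get("street", ["Main"])

    for row, n_true in zip(merged.itertuples(), true_counts):
        if n_true == 0:
            continue
        comp = completeness_by_year[int(row.year)]
        n_obs = rng.binomial(int(n_true), comp)
        if n_obs == 0:
            continue
        lo, hi = AGE_BOUNDS[int(row.age_code)]
        cause_p = frac_by_year[int(row.year)]
        for _ in range(int(n_obs)):
            rec = RegistryRecord(
                record_id=next_id,
                diagnosis_year=int(row.year),
                first_name=firsts[int(rng.integers(0, len(firsts)))],
                surname=lasts[int(rng.integers(0, len(lasts)))],
                parent_name=firsts[int(rng.integers(0, len(firsts)))],
                address=(
                    f"No {int(rng.integers(1, 200))}, "
                    f"{streets[int(rng.integers(0, len(streets)))]} St"
                ),
                sex=str(row.sex),
                age_years=int(rng.integers(lo, hi + 1)),
                province_id=int(row.province_id),
                cause_code=causes[int(rng.choice(len(causes), p=cause_p))],
                source=_SOURCES[int(rng.integers(0, len(_SOURCES)))],
            )
            next_id += 1
            records.append(rec)

    # Near-duplicates: perturbed-name copies of already-observed records.
    n_base = len(records)
    for i in range(n_base):
        if dup_rate > 0 and rng.random() < dup_rate:
            orig = records[i]
            dup = RegistryRecord(
                record_id=next_id,
                diagnosis_year=orig.diagnosis_year,
                first_name=_perturb_name(orig.first_name, rng),
                surname=_perturb_name(orig.surname, rng),
                parent_name=orig.parent_name,
                address=orig.address,
                sex=orig.sex,
                age_years=orig.age_years,
                province_id=orig.province_id,
                cause_code=orig.cause_code,
                source=_SOURCES[int(rng.integers(0, len(_SOURCES)))],
            )
            next_id += 1
            records.append(dup)
            duplicate_pairs.append((orig.record_id, dup.record_id))

    # Missing fields, blanked independently.
    if missing_rate > 0:
        for rec in records:
            for fname in MASKABLE_FIELDS:
                if rng.random() < missing_rate:
                    setattr(rec, fname, None)
                    missing_mask.append((rec.record_id, fname))

    bundle = TruthBundle(
        true_rates=true_rates,
        duplicate_pairs=duplicate_pairs,
        missing_mask=missing_mask,
        true_cause_fractions=frac_table,
        completeness_by_year={int(y): float(completeness_by_year[y]) for y in years},
    )
    return records, bundle


# ---------------------------------------------------------------------------
# Covariates and mortality
# ---------------------------------------------------------------------------


def generate_covariates(
    provinces=None, years: tuple[int, ...] = STUDY_YEARS, seed: int = 0
) -> pd.DataFrame:
    """Province-year covariate table: wealth index, education years,
    urbanization fraction, each with a smooth secular trend plus province
    offsets."""
    provs = provinces or load_default_provinces()
    rng = np.random.default_rng(seed)
    base = {
        p.id: (
            rng.normal(0.0, 1.0),        # wealth offset
            rng.normal(6.0, 1.0),        # education level
            rng.uniform(0.4, 0.8),       # urbanization level
        )
        for p in provs
    }
    y0, y1 = years[0], years[-1]
    rows = []
    for p in provs:
        w0, e0, u0 = base[p.id]
        for y in years:
            f = (y - y0) / max(y1 - y0, 1)
            rows.append(
                {
                    "province_id": p.id,
                    "year": y,
                    "wealth_index": w0 + 0.8 * f,
                    "education_years": e0 + 3.0 * f,
                    "urbanization": min(0.95, u0 + 0.15 * f),
                }
            )
    return pd.DataFrame(rows)


def default_mir_schedule(
    years: tuple[int, ...] = STUDY_YEARS, start: float = 0.8, end: float = 0.2
) -> dict[int, float]:
    """Log-linear MIR schedule; the default end/start ratio is 0.25,
    i.e. a 75% decline across the window."""
    y0, y1 = years[0], years[-1]
    return {
        y: float(start * (end / start) ** ((y - y0) / max(y1 - y0, 1))) for y in years
    }


def generate_mortality(
    true_rates: RateSurface,
    population: PopulationCube,
    mir_schedule: dict[int, float],
    seed: int = 0,
    noise_free: bool = False,
) -> CaseCountCube:
    """Mortality counts, Poisson around incidence mean x MIR(year).

    ``noise_free`` returns the expected counts exactly (corrected-real kind),
    which makes downstream MIR identities exact.
    """
    for y, r in mir_schedule.items():
        if r < 0:
            raise ValueError(f"MIR for {y} must be >= 0, got {r}")
    merged = true_rates.data.merge(population.data, on=INDEX_COLS, validate="one_to_one")
    missing = sorted(set(merged["year"].unique()) - set(mir_schedule))
    if missing:
        raise ValueError(f"MIR schedule missing years {missing}")
    mir = merged["year"].map(mir_schedule).to_numpy()
    mean = merged["rate"].to_numpy() * merged["person_years"].to_numpy() / 1e5 * mir
    out = merged[INDEX_COLS].copy()
    if noise_free:
        out["count"] = mean
        return CaseCountCube(out, kind="corrected")
    rng = np.random.default_rng(seed)
    out["count"] = rng.poisson(mean)
    return CaseCountCube(out, kind="raw")
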