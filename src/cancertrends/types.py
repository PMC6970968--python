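"""Shared domain containers for the incidence-estimation pipeline.

Cubes (case counts, person-years, rates) are thin wrappers around long-format
pandas DataFrames keyed by ``(province_id, year, age_code, sex)`` and, where a
cause dimension exists, ``cause``.  Keeping the tabular layout explicit makes
every stage's input and output directly writable as delimited text.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Canonical stratum key of every cube, in column order.
INDEX_COLS = ["province_id", "year", "age_code", "sex"]

SEXES = ("female", "male")

FIRST_YEAR = 1990
LAST_YEAR = 2016
STUDY_YEARS = tuple(range(FIRST_YEAR, LAST_YEAR + 1))


@dataclass(frozen=True)
class AgeGroup:
    """One of the four paediatric age bands used throughout."""

    code: int
    label: str
    midpoint: float  # years

    def contains(self, age_years: int) -> bool:
        lo, hi = AGE_BOUNDS[self.code]
        return lo <= age_years <= hi


#: Inclusive integer-age bounds per age-group code.
AGE_BOUNDS = {0: (0, 0), 1: (1, 4), 2: (5, 9), 3: (10, 14)}

AGE_GROUPS = (
    AgeGroup(0, "<1", 0.5),
    AgeGroup(1, "1-4", 3.0),
    AgeGroup(2, "5-9", 7.5),
    AgeGroup(3, "10-14", 12.5),
)

AGE_MIDPOINTS = {g.code: g.midpoint for g in AGE_GROUPS}


def age_group_of(age_years: int) -> int:
    """Map an integer age in [0, 14] to its age-group code."""
    for code, (lo, hi) in AGE_BOUNDS.items():
        if lo <= age_years <= hi:
            return code
    raise ValueError(f"age {age_years} outside the 0-14 study range")


@dataclass(frozen=True)
class Province:
    id: int
    name: str
    hasc: str  # two-letter Hierarchical Administrative Subdivision Code
    population_share: float


def load_default_provinces() -> list[Province]:
    """The 31 Iranian provinces shipped with the package.

    Shares are approximate census fractions and are normalised to sum to 1.
    """
    ref = importlib.resources.files("cancertrends.data") / "iran_provinces.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    total = df["population_share"].sum()
    return [
        Province(int(r.id), str(r.name), str(r.hasc), float(r.population_share) / total)
        for r in df.itertuples()
    ]


@dataclass
class AdjacencyGraph:
    """Undirected province-neighbourhood graph used for spatial borrowing."""

    provinces: list[Province]
    edges: set[frozenset[int]]

    def __post_init__(self) -> None:
        ids = {p.id for p in self.provinces}
        if len(ids) != len(self.provinces):
            raise ValueError("province ids must be unique")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= ids:
                raise ValueError(f"edge {set(e)} references unknown province id")

    @classmethod
    def from_pairs(cls, provinces: list[Province], pairs) -> "AdjacencyGraph":
        return cls(provinces, {frozenset(p) for p in pairs})

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(p.id for p in self.provinces)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def neighbors(self, province_id: int) -> set[int]:
        return {next(iter(e - {province_id})) for e in self.edges if province_id in e}

    def are_neighbors(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.edges


def load_default_adjacency() -> AdjacencyGraph:
    """The packaged first-order neighbour graph of the 31 provinces."""
    provinces = load_default_provinces()
    by_hasc = {p.hasc: p.id for p in provinces}
    ref = importlib.resources.files("cancertrends.data") / "iran_adjacency.txt"
    pairs = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()
        pairs.append((by_hasc[a], by_hasc[b]))
    return AdjacencyGraph.from_pairs(provinces, pairs)


def _check_long_frame(df: pd.DataFrame, value_col: str, extra: tuple[str, ...] = ()) -> None:
    required = set(INDEX_COLS) | {value_col} | set(extra)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cube frame missing columns: {sorted(missing)}")
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    bad_age = set(df["age_code"].unique()) - set(AGE_BOUNDS)
    if bad_age:
        raise ValueError(f"unknown age codes: {sorted(bad_age)}")


@dataclass
class PopulationCube:
    """Person-years per (province, year, age group, sex)."""

    data: pd.DataFrame  # INDEX_COLS + person_years

    def __post_init__(self) -> None:
        _check_long_frame(self.data, "person_years")
        if (self.data["person_years"] < 0).any():
            raise ValueError("person_years must be non-negative")
        self.data = self.data.sort_values(INDEX_COLS, ignore_index=True)

    def total(self, year: int | None = None) -> float:
        df = self.data if year is None else self.data[self.data["year"] == year]
        return float(df["person_years"].sum())


@dataclass
class CaseCountCube:
    """Case counts per stratum; ``kind`` tracks completeness correction.

    ``raw`` cubes hold non-negative integers straight from aggregation;
    ``corrected`` cubes hold real-valued counts scaled up by the completeness
    schedule.
    """

    data: pd.DataFrame  # INDEX_COLS [+ cause] + count
    kind: str = "raw"  # raw | corrected

    def __post_init__(self) -> None:
        extra = ("cause",) if "cause" in self.data.columns else ()
        _check_long_frame(self.data, "count", extra)
        if self.kind not in ("raw", "corrected"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if self.kind == "raw":
            counts = self.data["count"].to_numpy()
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("raw cube must hold integer counts")
        order = INDEX_COLS + (["cause"] if extra else [])
        self.data = self.data.sort_values(order, ignore_index=True)

    @property
    def has_cause(self) -> bool:
        return "cause" in self.data.columns

    def all_cause(self) -> "CaseCountCube":
        """Collapse the cause dimension (no-op if absent)."""
        if not self.has_cause:
            return self
        df = self.data.groupby(INDEX_COLS, as_index=False)["count"].sum()
        return CaseCountCube(df, kind=self.kind)

    def total(self) -> float:
        return float(self.data["count"].sum())


@dataclass
class RateSurface:
    """Incidence (or mortality) rates per 100,000 person-years per stratum.

    ``draws`` is an optional (n_cells, n_draws) array of bootstrap rates whose
    rows align with ``data``; ``data`` optionally carries ``lower``/``upper``
    95% uncertainty-interval columns.
    """

    data: pd.DataFrame  # INDEX_COLS + rate [+ lower + upper]
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_long_frame(self.data, "rate")
        if (self.data["rate"] <= 0).any():
            raise ValueError("rates must be strictly positive")
        if {"lower", "upper"} <= set(self.data.columns):
            bad = (self.data["lower"] > self.data["rate"] + 1e-12) | (
                self.data["upper"] < self.data["rate"] - 1e-12
            )
            if bad.any():
                raise ValueError("uncertainty interval does not bracket the point rate")
        self.data = self.data.sort_values(INDEX_COLS, ignore_index=True)
        if self.draws is not None and self.draws.shape[0] != len(self.data):
            raise ValueError("draws rows must align with data rows")

    @property
    def has_ui(self) -> bool:
        return {"lower", "upper"} <= set(self.data.columns)


@dataclass(frozen=True)
class SmoothingParams:
    """Hyperparameters of the age-spatiotemporal residual smoother.

    zeta   — weight given to first-order neighbour provinces, in [0, 1];
             0 disables spatial borrowing entirely.
    lamda  — temporal bandwidth in years (> 0); the time kernel is
             exp(-|dt| / lamda).
    omega  — age bandwidth per year of age-midpoint distance (>= 0); the age
             kernel is exp(-omega * |da|).
    """

    zeta: float = 0.5
    lamda: float = 5.0
    omega: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        if self.lamda <= 0:
            raise ValueError("lamda (temporal bandwidth) must be > 0")
        if self.omega < 0:
            raise ValueError("omega (age bandwidth) must be >= 0")


@dataclass
class CauseTaxonomy:
    """Ordered cause groups with a designated reference group."""

    groups: list[tuple[str, str]]  # (code, label)
    reference: str

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.groups]
        if len(codes) < 2:
            raise ValueError("taxonomy needs at least two cause groups")
        if len(set(codes)) != len(codes):
            raise ValueError("cause codes must be unique")
        labels = [l for _, l in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("cause labels must be unique")
        if self.reference not in codes:
            raise ValueError(f"reference cause {self.reference!r} not in taxonomy")

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.groups]


#: Default grouping: the six leading childhood-cancer groups plus a residual.
DEFAULT_TAXONOMY = CauseTaxonomy(
    groups=[
        ("leukemia", "Leukemia"),
        ("cns", "Central nervous system"),
        ("lymphoma", "Lymphoma"),
        ("endocrine", "Endocrine glands"),
        ("digestive", "Digestive organs"),
        ("urinary", "Urinary tract"),
        ("other", "Other neoplasms"),
    ],
    reference="other",
)


@dataclass
class TruthBundle:
    """Ground-truth ledger emitted next to every synthetic registry."""

    true_rates: RateSurface
    duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)
    missing_mask: list[tuple[int, str]] = field(default_factory=list)
    true_cause_fractions: pd.DataFrame | None = None  # year + one column per cause
    completeness_by_year: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for y, c in self.completeness_by_year.items():
            if not 0 < c <= 1:
                raise ValueError(f"completeness for {y} outside (0, 1]: {c}")


#: Registration sources a record may originate from.
RECORD_SOURCES = (
    "pathology",
    "radiotherapy",
    "chemotherapy",
    "surgery",
    "hospital",
    "death_registry",
)

#: Free-text identity fields used for duplicate detection, never for analysis.
IDENTITY_FIELDS = ("first_name", "surname", "parent_name", "address")

#: Categorical analytic fields that imputation may fill.
ANALYTIC_FIELDS = ("sex", "age_years", "province_id", "cause_code")


@dataclass
class RegistryRecord:
    """One diagnosed case as it arrives from a registration source.

    Identity fields (names, address) exist only to support duplicate
    detection; analytic fields feed aggregation.  ``None`` marks a missing
    value (empty string on disk).
    """

    record_id: int
    diagnosis_year: int
    first_name: str | None = None
    surname: str | None = None
    parent_name: str | None = None
    address: str | None = None
    sex: str | None = None
    age_years: int | None = None
    province_id: int | None = None
    cause_code: str | None = None
    source: str = "hospital"

    def __post_init__(self) -> None:
        if not FIRST_YEAR <= self.diagnosis_year <= LAST_YEAR:
            raise ValueError(
                f"diagnosis_year {self.diagnosis_year} outside study window "
                f"{FIRST_YEAR}-{LAST_YEAR}"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_years is not None:
            age_group_of(self.age_years)  # raises if outside 0-14
        if self.source not in RECORD_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def age_code(self) -> int | None:
        return None if self.age_years is None else age_group_of(self.age_years)

    def is_complete(self) -> bool:
        return all(getattr(self, f) is not None for f in ANALYTIC_FIELDS)


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights for direct standardisation; normalised on construction."""

    weights: dict[int, float]  # age_code -> weight
    label: str = "Iran 2016"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("standard-population weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("standard-population weights must sum to a positive value")
        object.__setattr__(
            self, "weights", {a: w / total for a, w in self.weights.items()}
        )
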