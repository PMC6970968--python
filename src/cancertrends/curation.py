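"""Registry curation: from raw records to completeness-corrected cubes.

Order of operations mirrors a registry's cleaning funnel: normalise
identities, remove near-duplicate records (same analytic block, small
name edit distance), impute residual missing analytic fields, aggregate to a
raw count cube, and scale counts up by the year's registration completeness.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .types import (
    ANALYTIC_FIELDS,
    IDENTITY_FIELDS,
    INDEX_COLS,
    SEXES,
    CaseCountCube,
    CauseTaxonomy,
    RegistryRecord,
)

_PUNCT = re.compile(f"[{re.escape(string.punctuation)}]")
_WS = re.compile(r"\s+")

#: Fields other than names that enter the identity key.
_KEY_ANALYTIC = ("diagnosis_year", "province_id", "cause_code")


def _norm_text(value: str | None) -> str:
    if value is None:
        return ""
    return _WS.sub(" ", _PUNCT.sub(" ", value.lower())).strip()


@dataclass(frozen=True)
class IdentityKey:
    """Normalised identity of a record.

    ``name`` is the whitespace-collapsed, punctuation-stripped, lowercased
    concatenation of the name fields; ``key`` appends year, province and
    cause.  ``partial`` flags a missing name field, ``unlinkable`` flags a
    record with no identity information at all (excluded from dedup).
    """

    name: str
    key: str
    partial: bool
    unlinkable: bool


def normalize_identity(record: RegistryRecord) -> IdentityKey:
    """Build the record's dedup identity key, stable under formatting noise."""
    parts = [_norm_text(getattr(record, f)) for f in ("first_name", "surname", "parent_name")]
    unlinkable = all(
        getattr(record, f) is None for f in IDENTITY_FIELDS
    )
    partial = any(getattr(record, f) is None for f in ("first_name", "surname", "parent_name"))
    name = " ".join(p for p in parts if p)
    tail = "|".join(str(getattr(record, f)) for f in _KEY_ANALYTIC)
    return IdentityKey(name=name, key=f"{name}|{tail}", partial=partial, unlinkable=unlinkable)


@dataclass
class DedupReport:
    merged_pairs: list[tuple[int, int, float]]  # (kept_id, dropped_id, similarity)
    n_input: int
    n_output: int

    def __post_init__(self) -> None:
        dropped = {d for _, d, _ in self.merged_pairs}
        kept = {k for k, _, _ in self.merged_pairs}
        if kept & dropped:
            raise ValueError("a record id appears both kept and dropped")
        if self.n_output != self.n_input - len(dropped):
            raise ValueError("dedup report counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merged_pairs, columns=["kept_id", "dropped_id", "similarity"]
        )


def _block_key(record: RegistryRecord):
    # Analytic fields only: names carry the noise, so they stay out of the
    # block and the within-block comparison stays cheap.
    return (
        record.diagnosis_year,
        record.province_id,
        record.sex,
        record.age_code,
        record.cause_code,
    )


def _name_string(record: RegistryRecord) -> str:
    return normalize_identity(record).name


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (edlib's C implementation)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def records_match(a: RegistryRecord, b: RegistryRecord, max_edit_fraction: float) -> bool:
    """The pairwise merge rule: same analytic block and name edit distance
    at most ``max_edit_fraction`` of the longer name."""
    if _block_key(a) != _block_key(b):
        return False
    na, nb = _name_string(a), _name_string(b)
    if not na and not nb:
        return False
    return edit_distance(na, nb) <= max_edit_fraction * max(len(na), len(nb))


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def deduplicate(
    records: list[RegistryRecord], max_edit_fraction: float = 0.2
) -> tuple[list[RegistryRecord], DedupReport]:
    """Merge near-duplicate records within analytic blocks.

    Within each (year, province, sex, age group, cause) block, records whose
    normalised name strings differ by at most ``max_edit_fraction`` of the
    longer length are merged transitively; the earliest ``record_id``
    survives.  Records with no identity information are never merged.
    """
    if not 0 <= max_edit_fraction < 1:
        raise ValueError("max_edit_fraction must lie in [0, 1)")
    ids = [r.record_id for r in records]
    uf = _UnionFind(ids)
    by_id = {r.record_id: r for r in records}
    similarity: dict[tuple[int, int], float] = {}

    blocks: dict[tuple, list[RegistryRecord]] = {}
    for r in records:
        if normalize_identity(r).unlinkable:
            continue
        blocks.setdefault(_block_key(r), []).append(r)

    for block in blocks.values():
        names = [_name_string(r) for r in block]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                na, nb = names[i], names[j]
                if not na and not nb:
                    continue
                longer = max(len(na), len(nb))
                dist = edit_distance(na, nb)
                if dist <= max_edit_fraction * longer:
                    uf.union(block[i].record_id, block[j].record_id)
                    similarity[(block[i].record_id, block[j].record_id)] = 1 - dist / longer

    clusters: dict[int, list[int]] = {}
    for rid in ids:
        clusters.setdefault(uf.find(rid), []).append(rid)

    unique_records = []
    merged_pairs = []
    for root, members in sorted(clusters.items()):
        keep = min(members)
        unique_records.append(by_id[keep])
        for dropped in sorted(m for m in members if m != keep):
            score = similarity.get((keep, dropped)) or similarity.get((dropped, keep))
            if score is None:
                # transitive merge: similarity via the name strings directly
                na, nb = _name_string(by_id[keep]), _name_string(by_id[dropped])
                longer = max(len(na), len(nb))
                score = 1 - edit_distance(na, nb) / longer if longer else 0.0
            merged_pairs.append((keep, dropped, float(score)))

    report = DedupReport(merged_pairs=merged_pairs, n_input=len(records), n_output=len(unique_records))
    return unique_records, report


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def _conditioners(records: list[RegistryRecord], target: str):
    """Conditioning fields for hot-deck draws of ``target``: always year,
    plus sex and province when they are not the target."""
    conds = ["diagnosis_year"]
    if target != "sex":
        conds.append("sex")
    if target != "province_id":
        conds.append("province_id")
    return conds


def impute_missing(
    records: list[RegistryRecord], m: int = 5, seed: int = 0
) -> list[list[RegistryRecord]]:
    """Multiple imputation of missing categorical analytic fields.

    Deterministic recovery happens first (nothing to recover in the default
    schema beyond derived fields); residual missing values are drawn from the
    empirical conditional distribution of complete records given year and,
    when present, sex and province — independently per imputation.  Observed
    values are never touched.
    """
    if m < 1:
        raise ValueError("m (number of imputations) must be >= 1")
    for fname in ANALYTIC_FIELDS:
        if records and all(getattr(r, fname) is None for r in records):
            raise ValueError(f"field {fname!r} is missing in every record; cannot impute")

    # Empirical donor pools per target field, keyed by progressively coarser
    # conditioning sets (full -> year only -> marginal).
    pools: dict[str, list[tuple[tuple[str, ...], dict]]] = {}
    for target in ANALYTIC_FIELDS:
        conds_full = tuple(_conditioners(records, target))
        levels = [conds_full, ("diagnosis_year",), ()]
        level_pools = []
        for conds in levels:
            table: dict[tuple, Counter] = {}
            for r in records:
                val = getattr(r, target)
                if val is None:
                    continue
                if any(getattr(r, c) is None for c in conds):
                    continue
                key = tuple(getattr(r, c) for c in conds)
                table.setdefault(key, Counter())[val] += 1
            level_pools.append((conds, table))
        pools[target] = level_pools

    rng = np.random.default_rng(seed)
    out: list[list[RegistryRecord]] = []
    for _ in range(m):
        completed = []
        for r in records:
            filled = RegistryRecord(**{
                fld: getattr(r, fld)
                for fld in (
                    "record_id", "diagnosis_year", "first_name", "surname",
                    "parent_name", "address", "sex", "age_years",
                    "province_id", "cause_code", "source",
                )
            })
            for target in ANALYTIC_FIELDS:
                if getattr(filled, target) is not None:
                    continue
                drawn = None
                for conds, table in pools[target]:
                    key = tuple(getattr(filled, c) for c in conds)
                    if any(k is None for k in key):
                        continue
                    counter = table.get(key)
                    if counter:
                        values = list(counter)
                        probs = np.array(list(counter.values()), dtype=float)
                        probs /= probs.sum()
                        drawn = values[int(rng.choice(len(values), p=probs))]
                        break
                if drawn is None:  # cannot happen: marginal pool is non-empty
                    raise RuntimeError(f"no donor found for field {target!r}")
                setattr(filled, target, drawn)
            completed.append(filled)
        out.append(completed)
    return out


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------


@dataclass
class CompletenessSchedule:
    """Registration completeness per study year, interpolated from anchors.

    Interpolation is linear on the logit scale (keeps values inside (0, 1])
    with flat extrapolation outside the anchor range; anchor years are
    reproduced exactly.
    """

    anchors: dict[int, float]
    values: dict[int, float] = field(default_factory=dict)

    def __call__(self, year: int) -> float:
        if year not in self.values:
            raise KeyError(f"no completeness value for year {year}")
        return self.values[year]


def build_completeness_schedule(anchors: dict[int, float], years) -> CompletenessSchedule:
    if not anchors:
        raise ValueError("at least one completeness anchor is required")
    for y, c in anchors.items():
        if not 0 < c <= 1:
            raise ValueError(f"anchor completeness for {y} outside (0, 1]: {c}")
    ay = np.array(sorted(anchors))
    # logit(1) is +inf; cap so a perfect anchor survives the round trip.
    av = np.clip([anchors[int(y)] for y in ay], 1e-12, 1 - 1e-12)
    alog = logit(av)
    values = {}
    for y in years:
        interp = np.interp(y, ay, alog)  # flat outside the anchor range
        values[int(y)] = float(expit(interp))
    for y, c in anchors.items():
        if int(y) in values:
            values[int(y)] = float(c)
    return CompletenessSchedule(anchors=dict(anchors), values=values)


# ---------------------------------------------------------------------------
# Aggregation and correction
# ---------------------------------------------------------------------------


def aggregate(
    records: list[RegistryRecord],
    taxonomy: CauseTaxonomy,
    provinces: list[int] | None = None,
    years: list[int] | None = None,
) -> CaseCountCube:
    """Count completed records per (province, year, age group, sex, cause),
    zero-filling the full index cross."""
    known = set(taxonomy.codes)
    for r in records:
        if not r.is_complete():
            raise ValueError(f"record {r.record_id} has missing analytic fields; impute first")
        if r.cause_code not in known:
            raise ValueError(f"cause code {r.cause_code!r} absent from taxonomy")

    rows = [
        {
            "province_id": r.province_id,
            "year": r.diagnosis_year,
            "age_code": r.age_code,
            "sex": r.sex,
            "cause": r.cause_code,
        }
        for r in records
    ]
    observed = (
        pd.DataFrame(rows, columns=INDEX_COLS + ["cause"])
        .groupby(INDEX_COLS + ["cause"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    prov_list = provinces or sorted({r.province_id for r in records})
    year_list = years or sorted({r.diagnosis_year for r in records})
    if not prov_list or not year_list:
        prov_list = prov_list or [1]
        year_list = year_list or [1990]
    full = pd.MultiIndex.from_product(
        [prov_list, year_list, [0, 1, 2, 3], list(SEXES), taxonomy.codes],
        names=INDEX_COLS + ["cause"],
    ).to_frame(index=False)
    cube = full.merge(observed, on=INDEX_COLS + ["cause"], how="left").fillna({"count": 0})
    cube["count"] = cube["count"].astype(int)
    return CaseCountCube(cube, kind="raw")


def correct_completeness(cube: CaseCountCube, schedule: CompletenessSchedule) -> CaseCountCube:
    """Scale raw counts by 1/completeness(year); linear in the counts."""
    if cube.kind != "raw":
        raise ValueError("completeness correction expects a raw cube")
    missing = sorted(set(cube.data["year"].unique()) - set(schedule.values))
    if missing:
        raise ValueError(f"completeness schedule missing years {missing}")
    df = cube.data.copy()
    df["count"] = df["count"] / df["year"].map(schedule.values)
    return CaseCountCube(df, kind="corrected")
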