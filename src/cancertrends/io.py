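"""Delimited-text readers and writers for every pipeline artefact.

All tabular files are UTF-8 CSV with a header row; an empty string encodes a
missing value in record files.  Cubes travel in long format with the stratum
key columns first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .types import (
    INDEX_COLS,
    CaseCountCube,
    CauseTaxonomy,
    PopulationCube,
    Province,
    AdjacencyGraph,
    RateSurface,
    RegistryRecord,
    StandardPopulation,
    TruthBundle,
)

RECORD_COLUMNS = [
    "record_id",
    "diagnosis_year",
    "first_name",
    "surname",
    "parent_name",
    "address",
    "sex",
    "age_years",
    "province_id",
    "cause_code",
    "source",
]


def write_records(records: list[RegistryRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({c: ("" if d[c] is None else d[c]) for c in RECORD_COLUMNS})
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path) -> list[RegistryRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            RegistryRecord(
                record_id=int(d["record_id"]),
                diagnosis_year=int(d["diagnosis_year"]),
                first_name=d["first_name"] or None,
                surname=d["surname"] or None,
                parent_name=d["parent_name"] or None,
                address=d["address"] or None,
                sex=d["sex"] or None,
                age_years=int(d["age_years"]) if d["age_years"] != "" else None,
                province_id=int(d["province_id"]) if d["province_id"] != "" else None,
                cause_code=d["cause_code"] or None,
                source=d["source"] or "hospital",
            )
        )
    return records


def write_population(cube: PopulationCube, path: str | Path) -> None:
    cube.data.to_csv(path, index=False)


def read_population(path: str | Path) -> PopulationCube:
    return PopulationCube(pd.read_csv(path))


def write_case_cube(cube: CaseCountCube, path: str | Path) -> None:
    df = cube.data.copy()
    df["kind"] = cube.kind
    df.to_csv(path, index=False)


def read_case_cube(path: str | Path) -> CaseCountCube:
    df = pd.read_csv(path)
    kind = "raw"
    if "kind" in df.columns:
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"mixed cube kinds in {path}: {sorted(kinds)}")
        kind = str(kinds[0])
        df = df.drop(columns="kind")
    return CaseCountCube(df, kind=kind)


def write_rate_surface(surface: RateSurface, path: str | Path, draws_path: str | Path | None = None) -> None:
    surface.data.to_csv(path, index=False)
    if draws_path is not None and surface.draws is not None:
        wide = pd.concat(
            [
                surface.data[INDEX_COLS].reset_index(drop=True),
                pd.DataFrame(
                    surface.draws,
                    columns=[f"draw_{i}" for i in range(surface.draws.shape[1])],
                ),
            ],
            axis=1,
        )
        wide.to_csv(draws_path, index=False)


def read_rate_surface(path: str | Path, draws_path: str | Path | None = None) -> RateSurface:
    data = pd.read_csv(path)
    draws = None
    if draws_path is not None and Path(draws_path).exists():
        wide = pd.read_csv(draws_path)
        draw_cols = [c for c in wide.columns if c.startswith("draw_")]
        merged = data[INDEX_COLS].merge(wide, on=INDEX_COLS, how="left")
        draws = merged[draw_cols].to_numpy()
    return RateSurface(data, draws=draws)


def write_adjacency(graph: AdjacencyGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{e[0]} {e[1]}\n")


def read_adjacency(path: str | Path, provinces: list[Province]) -> AdjacencyGraph:
    pairs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()
        pairs.append((int(a), int(b)))
    return AdjacencyGraph.from_pairs(provinces, pairs)


def write_taxonomy(taxonomy: CauseTaxonomy, path: str | Path) -> None:
    rows = [
        {"code": c, "label": l, "reference": int(c == taxonomy.reference)}
        for c, l in taxonomy.groups
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_taxonomy(path: str | Path) -> CauseTaxonomy:
    df = pd.read_csv(path)
    refs = df.loc[df["reference"] == 1, "code"]
    if len(refs) != 1:
        raise ValueError("taxonomy file must mark exactly one reference cause")
    return CauseTaxonomy(
        groups=[(str(r.code), str(r.label)) for r in df.itertuples()],
        reference=str(refs.iloc[0]),
    )


def write_standard_population(standard: StandardPopulation, path: str | Path) -> None:
    pd.DataFrame(
        {"age_code": list(standard.weights), "weight": list(standard.weights.values())}
    ).to_csv(path, index=False)


def read_standard_population(path: str | Path, label: str = "custom") -> StandardPopulation:
    df = pd.read_csv(path)
    return StandardPopulation(
        weights={int(r.age_code): float(r.weight) for r in df.itertuples()}, label=label
    )


def write_truth_bundle(bundle: TruthBundle, path: str | Path, rates_path: str | Path | None = None) -> None:
    """JSON sidecar; true rates go to their own CSV when a path is given."""
    payload = {
        "duplicate_pairs": [list(p) for p in bundle.duplicate_pairs],
        "missing_mask": [list(m) for m in bundle.missing_mask],
        "completeness_by_year": {str(y): c for y, c in bundle.completeness_by_year.items()},
        "true_cause_fractions": (
            None
            if bundle.true_cause_fractions is None
            else bundle.true_cause_fractions.to_dict(orient="list")
        ),
        "true_rates_file": str(rates_path) if rates_path is not None else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    if rates_path is not None:
        write_rate_surface(bundle.true_rates, rates_path)


def read_truth_bundle(path: str | Path) -> TruthBundle:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    rates_file = payload.get("true_rates_file")
    if rates_file is None:
        raise ValueError("truth bundle was written without a true-rates file")
    fractions = payload.get("true_cause_fractions")
    return TruthBundle(
        true_rates=read_rate_surface(rates_file),
        duplicate_pairs=[tuple(p) for p in payload["duplicate_pairs"]],
        missing_mask=[(int(r), str(f)) for r, f in payload["missing_mask"]],
        true_cause_fractions=None if fractions is None else pd.DataFrame(fractions),
        completeness_by_year={int(y): float(c) for y, c in payload["completeness_by_year"].items()},
    )
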