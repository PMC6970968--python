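"""Configuration-driven orchestration of the full estimation pipeline.

Stages run in the order simulate -> curate -> estimate -> split-causes ->
measures -> report; each stage reads its predecessor's delimited files from
the output directory (or explicit ``paths`` overrides) and writes its own.
A manifest with the config snapshot, seeds, and per-stage row counts is
written atomically at the end of every run.
"""

from __future__ import annotations

import copy
import json
import logging
import os
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .causes import apply_fractions, fit_cause_model, predict_fractions
from .curation import (
    aggregate,
    build_completeness_schedule,
    correct_completeness,
    deduplicate,
    impute_missing,
)
from .measures import (
    apc,
    asr_table,
    decompose,
    mir,
    national_rates,
    provincial_disparity,
    standard_from_population,
)
from .model import make_two_stage_estimator, simulate_uncertainty
from .synthetic import (
    CauseParams,
    DemographicParams,
    RateParams,
    default_mir_schedule,
    generate_covariates,
    generate_mortality,
    generate_population_cube,
    generate_true_rates,
    sample_registry,
)
from .types import (
    DEFAULT_TAXONOMY,
    INDEX_COLS,
    AGE_GROUPS,
    CaseCountCube,
    RateSurface,
    SmoothingParams,
    load_default_adjacency,
    load_default_provinces,
)

__version__ = "0.1.0"

logger = logging.getLogger("cancertrends")

ALL_STAGES = ("simulate", "curate", "estimate", "split_causes", "measures", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "stages": {s: True for s in ALL_STAGES},
    "synthetic": {
        "population_scale": 1.0,
        "first_year": 1990,
        "last_year": 2016,
        "dup_rate": 0.02,
        "missing_rate": 0.03,
        "base_rate": 6.5,
        "annual_slope": 0.0065,
        "male_female_ratio": 1.3,
        "province_sd": 0.25,
        "spatial_rho": 0.5,
        "mir_start": 0.8,
        "mir_end": 0.2,
    },
    "curation": {
        "max_edit_fraction": 0.2,
        "n_imputations": 5,
        "completeness_anchors": {2000: 0.22, 2010: 0.75},
    },
    "model": {
        "floor": "adaptive",
        "zeta": 0.5,
        "lamda": 5.0,
        "omega": 0.3,
        "n_draws": 0,
        "seed": None,
    },
    "causes": {
        "design": ["year", "age", "sex", "province"],
        "prior_sd": 5.0,
    },
    "measures": {
        "standard_year": None,   # None = last year in the population cube
        "decomposition_first": None,  # None = first/last year of the window
        "decomposition_last": None,
    },
    "paths": {
        "taxonomy": None,
        "standard_population": None,
        "records": None,
        "cube": None,
        "mortality": None,
        "adjacency": None,
        "population": None,
        "covariates": None,
    },
}

#: Nested keys whose values are open mappings, not fixed schema nodes.
_OPEN_MAPPINGS = {("curation", "completeness_anchors")}


def _merge_config(defaults: dict, override: dict, path: tuple = ()) -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {'.'.join(map(str, path + (key,)))!r}")
        if (
            isinstance(defaults[key], dict)
            and path + (key,) not in _OPEN_MAPPINGS
        ):
            if not isinstance(value, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            merged[key] = _merge_config(defaults[key], value, path + (key,))
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(source: str | Path | dict | None = None) -> dict:
    """Resolve a config mapping (or YAML file) against the defaults,
    rejecting unknown keys by name."""
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            source = yaml.safe_load(fh) or {}
    return _merge_config(DEFAULT_CONFIG, source)


def _derive_seed(base: int, offset: int) -> int:
    return int((int(base) * 1_000_003 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, out: Path, manifest: dict) -> None:
    sc = cfg["synthetic"]
    seed = _derive_seed(cfg["seed"], 1)
    years = tuple(range(sc["first_year"], sc["last_year"] + 1))
    demo = DemographicParams(
        total_first=DemographicParams.total_first * sc["population_scale"],
        total_last=DemographicParams.total_last * sc["population_scale"],
        years=years,
    )
    rp = RateParams(
        base_rate=sc["base_rate"],
        annual_slope=sc["annual_slope"],
        male_female_ratio=sc["male_female_ratio"],
        province_sd=sc["province_sd"],
        spatial_rho=sc["spatial_rho"],
        t0=years[0],
    )
    adjacency = load_default_adjacency()
    population = generate_population_cube(demo, seed)
    covariates = generate_covariates(years=years, seed=_derive_seed(seed, 2))
    true_rates = generate_true_rates(rp, adjacency, seed=_derive_seed(seed, 3), years=years)
    anchors = cfg["curation"]["completeness_anchors"]
    schedule = build_completeness_schedule(
        {int(y): float(c) for y, c in anchors.items()}, years
    )
    records, truth = sample_registry(
        true_rates,
        population,
        schedule.values,
        dup_rate=sc["dup_rate"],
        missing_rate=sc["missing_rate"],
        seed=_derive_seed(seed, 4),
        cause_params=CauseParams(t0=years[0]),
    )
    mortality = generate_mortality(
        true_rates,
        population,
        default_mir_schedule(years, sc["mir_start"], sc["mir_end"]),
        seed=_derive_seed(seed, 5),
    )
    ctio.write_population(population, out / "population.csv")
    covariates.to_csv(out / "covariates.csv", index=False)
    ctio.write_records(records, out / "records.csv")
    ctio.write_truth_bundle(truth, out / "truth.json", out / "true_rates.csv")
    ctio.write_case_cube(mortality, out / "mortality.csv")
    ctio.write_adjacency(adjacency, out / "adjacency.txt")
    logger.info("simulate: %d records, %d strata", len(records), len(population.data))
    manifest["stages"]["simulate"] = {
        "records_out": len(records),
        "duplicate_pairs_injected": len(truth.duplicate_pairs),
        "missing_values_injected": len(truth.missing_mask),
        "seed": seed,
    }


def _resolve(cfg: dict, out: Path, key: str, default_name: str) -> Path:
    override = cfg["paths"][key]
    path = Path(override) if override else out / default_name
    if not path.exists():
        raise FileNotFoundError(f"input for stage not found: {path} (paths.{key})")
    return path


def _load_taxonomy(cfg: dict):
    path = cfg["paths"]["taxonomy"]
    return ctio.read_taxonomy(path) if path else DEFAULT_TAXONOMY


def _stage_curate(cfg: dict, out: Path, manifest: dict) -> None:
    cc = cfg["curation"]
    records = ctio.read_records(_resolve(cfg, out, "records", "records.csv"))
    population = ctio.read_population(_resolve(cfg, out, "population", "population.csv"))
    unique, report = deduplicate(records, cc["max_edit_fraction"])
    report.to_frame().to_csv(out / "dedup_report.csv", index=False)
    imputations = impute_missing(
        unique, m=cc["n_imputations"], seed=_derive_seed(cfg["seed"], 11)
    )
    taxonomy = _load_taxonomy(cfg)
    provinces = sorted(population.data["province_id"].unique())
    years = sorted(population.data["year"].unique())
    cubes = []
    for k, completed in enumerate(imputations):
        ctio.write_records(completed, out / f"imputed_{k}.csv")
        cubes.append(aggregate(completed, taxonomy, provinces, years).data["count"].to_numpy())
    pooled = aggregate(imputations[0], taxonomy, provinces, years)
    pooled_counts = np.rint(np.mean(cubes, axis=0)).astype(int)
    raw = CaseCountCube(pooled.data.assign(count=pooled_counts), kind="raw")
    schedule = build_completeness_schedule(
        {int(y): float(c) for y, c in cc["completeness_anchors"].items()}, years
    )
    corrected = correct_completeness(raw, schedule)
    ctio.write_case_cube(raw, out / "cube_raw.csv")
    ctio.write_case_cube(corrected, out / "cube_corrected.csv")
    pd.DataFrame(
        {"year": list(schedule.values), "completeness": list(schedule.values.values())}
    ).to_csv(out / "completeness.csv", index=False)
    logger.info(
        "curate: %d -> %d records after dedup; raw total %d, corrected total %.1f",
        report.n_input, report.n_output, raw.total(), corrected.total(),
    )
    manifest["stages"]["curate"] = {
        "records_in": report.n_input,
        "records_out": report.n_output,
        "merged_pairs": len(report.merged_pairs),
        "raw_count_total": int(raw.total()),
        "corrected_count_total": float(corrected.total()),
    }


def _stage_estimate(cfg: dict, out: Path, manifest: dict) -> None:
    mc = cfg["model"]
    cube = ctio.read_case_cube(_resolve(cfg, out, "cube", "cube_corrected.csv")).all_cause()
    population = ctio.read_population(_resolve(cfg, out, "population", "population.csv"))
    cov_path = cfg["paths"]["covariates"] or (out / "covariates.csv")
    covariates = pd.read_csv(cov_path) if Path(cov_path).exists() else None
    adj_path = cfg["paths"]["adjacency"] or (out / "adjacency.txt")
    if Path(adj_path).exists():
        adjacency = ctio.read_adjacency(adj_path, load_default_provinces())
    else:
        adjacency = load_default_adjacency()
    smoothing = SmoothingParams(zeta=mc["zeta"], lamda=mc["lamda"], omega=mc["omega"])
    estimator = make_two_stage_estimator(
        population, covariates, adjacency, smoothing, floor=mc["floor"]
    )
    if mc["n_draws"] and mc["n_draws"] >= 2:
        seed = mc["seed"] if mc["seed"] is not None else _derive_seed(cfg["seed"], 21)
        surface = simulate_uncertainty(cube, population, estimator, mc["n_draws"], seed)
        ctio.write_rate_surface(surface, out / "rates.csv", out / "rate_draws.csv")
    else:
        surface = estimator(cube)
        ctio.write_rate_surface(surface, out / "rates.csv")
    logger.info("estimate: %d cells, %s draws", len(surface.data), mc["n_draws"])
    manifest["stages"]["estimate"] = {
        "cells": len(surface.data),
        "n_draws": int(mc["n_draws"]),
    }


def _stage_split_causes(cfg: dict, out: Path, manifest: dict) -> None:
    cause_cube = ctio.read_case_cube(_resolve(cfg, out, "cube", "cube_corrected.csv"))
    if not cause_cube.has_cause:
        raise ValueError("split_causes needs a cube with a cause dimension")
    surface = ctio.read_rate_surface(out / "rates.csv")
    taxonomy = _load_taxonomy(cfg)
    rounded = cause_cube.data.copy()
    rounded["count"] = np.rint(rounded["count"]).astype(int)
    model = fit_cause_model(
        CaseCountCube(rounded, kind="raw"),
        design_spec=tuple(cfg["causes"]["design"]),
        prior_sd=cfg["causes"]["prior_sd"],
        taxonomy=taxonomy,
    )
    strata = surface.data[INDEX_COLS].drop_duplicates().reset_index(drop=True)
    fractions = predict_fractions(model, strata)
    fractions.data.to_csv(out / "cause_fractions.csv", index=False)
    per_cause = apply_fractions(surface, fractions)
    long = pd.concat(
        [s.data.assign(cause=c) for c, s in per_cause.items()], ignore_index=True
    )
    long.to_csv(out / "cause_rates.csv", index=False)
    logger.info("split_causes: %d causes, phi=%.1f", len(model.causes), model.phi)
    manifest["stages"]["split_causes"] = {
        "causes": len(model.causes),
        "phi": float(model.phi),
        "strata": len(fractions.data),
    }


def _national_asr_series(surface: RateSurface, population, standard) -> pd.DataFrame:
    """ASR per (year, sex) plus a pooled 'both' series, population-weighted."""
    nat = national_rates(surface, population)
    rows = []
    for (year, sex), sub in nat.groupby(["year", "sex"]):
        from .measures import age_standardize

        rows.append(
            {
                "year": int(year),
                "sex": sex,
                "asr": age_standardize(dict(zip(sub["age_code"], sub["rate"])), standard),
                "cases": float(sub["cases"].sum()),
            }
        )
    both = (
        nat.groupby(["year", "age_code"], as_index=False)[["cases", "person_years"]].sum()
    )
    both["rate"] = both["cases"] / both["person_years"] * 1e5
    for year, sub in both.groupby("year"):
        from .measures import age_standardize

        rows.append(
            {
                "year": int(year),
                "sex": "both",
                "asr": age_standardize(dict(zip(sub["age_code"], sub["rate"])), standard),
                "cases": float(sub["cases"].sum()),
            }
        )
    return pd.DataFrame(rows).sort_values(["sex", "year"], ignore_index=True)


def _measures_years(cfg: dict, population) -> tuple[int, int, int]:
    years = sorted(population.data["year"].unique())
    mc = cfg["measures"]
    std_year = mc["standard_year"] if mc["standard_year"] is not None else years[-1]
    y0 = mc["decomposition_first"] if mc["decomposition_first"] is not None else years[0]
    y1 = mc["decomposition_last"] if mc["decomposition_last"] is not None else years[-1]
    return int(std_year), int(y0), int(y1)


def _stage_measures(cfg: dict, out: Path, manifest: dict) -> None:
    surface = ctio.read_rate_surface(out / "rates.csv", out / "rate_draws.csv")
    population = ctio.read_population(_resolve(cfg, out, "population", "population.csv"))
    std_year, y0, y1 = _measures_years(cfg, population)
    std_path = cfg["paths"]["standard_population"]
    standard = (
        ctio.read_standard_population(std_path)
        if std_path
        else standard_from_population(population, std_year)
    )
    asr = _national_asr_series(surface, population, standard)
    asr.to_csv(out / "asr_national.csv", index=False)

    apc_rows = []
    for sex, sub in asr.groupby("sex"):
        r = apc(dict(zip(sub["year"], sub["asr"])))
        c = apc(dict(zip(sub["year"], sub["cases"])))
        apc_rows.append(
            {"sex": sex, "apc_asr": r.apc_percent, "apc_cases": c.apc_percent}
        )
    pd.DataFrame(apc_rows).to_csv(out / "apc_national.csv", index=False)

    nat = national_rates(surface, population)
    pops = population.data.groupby(["year", "age_code", "sex"], as_index=False)["person_years"].sum()

    def _maps(year):
        r = nat[nat["year"] == year]
        p = pops[pops["year"] == year]
        return (
            {(int(a), s): float(v) for a, s, v in zip(r["age_code"], r["sex"], r["rate"])},
            {(int(a), s): float(v) for a, s, v in zip(p["age_code"], p["sex"], p["person_years"])},
        )

    rates0, pop0 = _maps(y0)
    rates1, pop1 = _maps(y1)
    dec = decompose(rates0, pop0, pop1, rates1)
    pd.DataFrame(
        [
            {
                "first_year": y0,
                "last_year": y1,
                "growth_pct": dec.growth,
                "aging_pct": dec.aging,
                "rate_change_pct": dec.rate_change,
                "total_pct": dec.total,
            }
        ]
    ).to_csv(out / "decomposition.csv", index=False)

    # MIR on age-standardised series when the mortality cube is available.
    mort_path = cfg["paths"]["mortality"] or (out / "mortality.csv")
    if Path(mort_path).exists():
        mort_cube = ctio.read_case_cube(mort_path)
        md = mort_cube.data.merge(population.data, on=INDEX_COLS, validate="one_to_one")
        md["rate"] = np.maximum(md["count"] / md["person_years"] * 1e5, 1e-9)
        mort_surface = RateSurface(md[INDEX_COLS + ["rate"]])
        mort_asr = _national_asr_series(mort_surface, population, standard)
        inc_both = asr[asr["sex"] == "both"].set_index("year")["asr"]
        mor_both = mort_asr[mort_asr["sex"] == "both"].set_index("year")["asr"]
        series = mir(mor_both.to_dict(), inc_both.to_dict(), mode="age-standardized")
        pd.DataFrame(
            {"year": list(series.ratios), "mir": list(series.ratios.values()), "mode": series.mode}
        ).to_csv(out / "mir_national.csv", index=False)

    prov_rows = []
    for year in (y0, y1):
        sub = RateSurface(surface.data[surface.data["year"] == year].copy())
        prov_asr = asr_table(sub, standard, by=("province_id",))
        disp = provincial_disparity(dict(zip(prov_asr["province_id"], prov_asr["asr"])))
        prov_rows.append(
            {
                "year": year,
                "max_asr": disp.max_asr,
                "min_asr": disp.min_asr,
                "range": disp.range,
                "ratio": disp.ratio,
                "province_max": disp.argmax,
                "province_min": disp.argmin,
            }
        )
        prov_asr.assign(year=year).to_csv(out / f"asr_province_{year}.csv", index=False)
    pd.DataFrame(prov_rows).to_csv(out / "disparity.csv", index=False)
    logger.info("measures: ASR/APC/decomposition/MIR/disparity written")
    manifest["stages"]["measures"] = {
        "asr_rows": len(asr),
        "decomposition_total_pct": float(dec.total),
    }


def _stage_report(cfg: dict, out: Path, manifest: dict) -> None:
    surface = ctio.read_rate_surface(out / "rates.csv", out / "rate_draws.csv")
    population = ctio.read_population(_resolve(cfg, out, "population", "population.csv"))
    std_year, y0, y1 = _measures_years(cfg, population)
    std_path = cfg["paths"]["standard_population"]
    standard = (
        ctio.read_standard_population(std_path)
        if std_path
        else standard_from_population(population, std_year)
    )
    nat = national_rates(surface, population)

    # ----- Table 1 shape: age x sex new cases and rates with APC -----
    rows = []
    age_labels = {g.code: g.label for g in AGE_GROUPS}
    sexes = ["both", "female", "male"]

    def _series(sub: pd.DataFrame, value: str) -> dict[int, float]:
        return dict(zip(sub["year"].astype(int), sub[value]))

    for age in [None] + [g.code for g in AGE_GROUPS]:
        for sex in sexes:
            sub = nat.copy()
            if age is not None:
                sub = sub[sub["age_code"] == age]
            if sex != "both":
                sub = sub[sub["sex"] == sex]
            cases = sub.groupby("year", as_index=False)[["cases", "person_years"]].sum()
            cases["rate"] = cases["cases"] / cases["person_years"] * 1e5
            case_series = _series(cases, "cases")
            if age is None:
                # all ages: direct standardisation over the age dimension
                by_age = sub.groupby(["year", "age_code"], as_index=False)[
                    ["cases", "person_years"]
                ].sum()
                by_age["rate"] = by_age["cases"] / by_age["person_years"] * 1e5
                from .measures import age_standardize

                rate_series = {
                    int(y): age_standardize(dict(zip(g["age_code"], g["rate"])), standard)
                    for y, g in by_age.groupby("year")
                }
            else:
                rate_series = _series(cases, "rate")
            rows.append(
                {
                    "age": "Under 15" if age is None else age_labels[age],
                    "sex": sex,
                    "new_cases_first": case_series[y0],
                    "new_cases_last": case_series[y1],
                    "apc_cases": apc(case_series).apc_percent,
                    "rate_first": rate_series[y0],
                    "rate_last": rate_series[y1],
                    "apc_rate": apc(rate_series).apc_percent,
                }
            )
    table1 = pd.DataFrame(rows)
    table1.to_csv(out / "table1_national.csv", index=False)

    # ----- Table 2 shape: cause x sex ASR with APC -----
    cause_path = out / "cause_rates.csv"
    t2_rows = []
    if cause_path.exists():
        cause_rates = pd.read_csv(cause_path)
        for cause, csub in cause_rates.groupby("cause"):
            csurf = RateSurface(csub[INDEX_COLS + ["rate"]].copy())
            series = _national_asr_series(csurf, population, standard)
            for sex in sexes:
                ssub = series[series["sex"] == sex]
                asr_series = dict(zip(ssub["year"], ssub["asr"]))
                t2_rows.append(
                    {
                        "cause": cause,
                        "sex": sex,
                        "asr_first": asr_series[y0],
                        "asr_last": asr_series[y1],
                        "apc": apc(asr_series).apc_percent,
                    }
                )
    pd.DataFrame(
        t2_rows, columns=["cause", "sex", "asr_first", "asr_last", "apc"]
    ).to_csv(out / "table2_causes.csv", index=False)

    # ----- Table 3 shape: lowest/highest province per age x sex -----
    t3_rows = []
    has_draws = surface.draws is not None
    for year in (y0, y1):
        ysub = surface.data[surface.data["year"] == year]
        ymask = (surface.data["year"] == year).to_numpy()
        for age in [None] + [g.code for g in AGE_GROUPS]:
            for sex in ("both", "female", "male"):
                sub = ysub if age is None else ysub[ysub["age_code"] == age]
                sub = sub if sex == "both" else sub[sub["sex"] == sex]
                if age is None:
                    prov = asr_table(RateSurface(sub.copy()), standard, by=("province_id",))
                    prov = prov.rename(columns={"asr": "value"})
                else:
                    prov = sub.groupby("province_id", as_index=False)["rate"].mean().rename(
                        columns={"rate": "value"}
                    )
                disp = provincial_disparity(dict(zip(prov["province_id"], prov["value"])))
                row = {
                    "year": year,
                    "age": "Under 15" if age is None else age_labels[age],
                    "sex": sex,
                    "lowest_province": disp.argmin,
                    "lowest_asr": disp.min_asr,
                    "highest_province": disp.argmax,
                    "highest_asr": disp.max_asr,
                }
                if has_draws:
                    # draw-based width, recentred on the point estimate
                    # (sparse-count draws are biased low relative to the
                    # unresampled point, so raw percentiles can miss it)
                    for tag, pid, point in (
                        ("lowest", disp.argmin, disp.min_asr),
                        ("highest", disp.argmax, disp.max_asr),
                    ):
                        cell_mask = ymask & (surface.data["province_id"] == pid).to_numpy()
                        if age is not None:
                            cell_mask &= (surface.data["age_code"] == age).to_numpy()
                        if sex != "both":
                            cell_mask &= (surface.data["sex"] == sex).to_numpy()
                        cell_draws = surface.draws[cell_mask].mean(axis=0)
                        shift = point - float(cell_draws.mean())
                        row[f"{tag}_ui_lower"] = float(np.percentile(cell_draws, 2.5) + shift)
                        row[f"{tag}_ui_upper"] = float(np.percentile(cell_draws, 97.5) + shift)
                t3_rows.append(row)
    pd.DataFrame(t3_rows).to_csv(out / "table3_provinces.csv", index=False)
    logger.info("report: table1 (%d rows), table2 (%d), table3 (%d)",
                len(table1), len(t2_rows), len(t3_rows))
    manifest["stages"]["report"] = {
        "table1_rows": len(table1),
        "table2_rows": len(t2_rows),
        "table3_rows": len(t3_rows),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "curate": _stage_curate,
    "estimate": _stage_estimate,
    "split_causes": _stage_split_causes,
    "measures": _stage_measures,
    "report": _stage_report,
}


def run_pipeline(config: str | Path | dict | None = None, out_dir: str | Path | None = None) -> Path:
    """Run the enabled stages in order and write the run manifest.

    Returns the output directory.  Identical config and seed give
    byte-identical output tables.
    """
    cfg = load_config(config)
    out = Path(out_dir) if out_dir is not None else Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": cfg,
        "seed": cfg["seed"],
        "stages": {},
        "started_unix": time.time(),
    }
    for stage in ALL_STAGES:
        if cfg["stages"].get(stage):
            t0 = time.time()
            logger.info("stage %s: start", stage)
            _STAGE_FUNCS[stage](cfg, out, manifest)
            manifest["stages"].setdefault(stage, {})["wall_seconds"] = time.time() - t0
    manifest["finished_unix"] = time.time()
    # atomic write: tmp file in the same directory, then rename
    fd, tmp = tempfile.mkstemp(dir=out, suffix=".manifest.tmp")
    with os.fdopen(fd, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    os.replace(tmp, out / "manifest.json")
    return out


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def _full_cross_missing(df: pd.DataFrame, cols: list[str]) -> list[tuple]:
    levels = [sorted(df[c].unique()) for c in cols]
    expected = pd.MultiIndex.from_product(levels, names=cols)
    present = pd.MultiIndex.from_frame(df[cols].drop_duplicates())
    return list(expected.difference(present)[:5])


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema checks per input kind; returns machine-readable results.

    ``paths`` maps a kind in {records, population, cube, rates, adjacency}
    to a file path.  Each returned entry carries ``passed`` and, on failure,
    the first offending row or missing index.
    """
    results = []

    def add(kind, path, check, passed, detail=""):
        results.append(
            {"kind": kind, "path": str(path), "check": check, "passed": bool(passed), "detail": detail}
        )

    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            add(kind, path, "readable", False, "file not found")
            continue
        try:
            if kind == "records":
                records = ctio.read_records(path)
                add(kind, path, "parse", True, f"{len(records)} records")
            elif kind == "population":
                df = pd.read_csv(path)
                need = set(INDEX_COLS) | {"person_years"}
                missing_cols = need - set(df.columns)
                add(kind, path, "columns", not missing_cols, f"missing {sorted(missing_cols)}" if missing_cols else "")
                if not missing_cols:
                    neg = df[df["person_years"] < 0]
                    add(kind, path, "non_negative", neg.empty,
                        "" if neg.empty else f"first offending row index {neg.index[0]}")
                    gaps = _full_cross_missing(df, INDEX_COLS)
                    add(kind, path, "index_complete", not gaps,
                        "" if not gaps else f"missing strata (first 5): {gaps}")
            elif kind == "cube":
                df = pd.read_csv(path)
                need = set(INDEX_COLS) | {"count"}
                missing_cols = need - set(df.columns)
                add(kind, path, "columns", not missing_cols,
                    f"missing {sorted(missing_cols)}" if missing_cols else "")
                if not missing_cols:
                    neg = df[df["count"] < 0]
                    add(kind, path, "non_negative", neg.empty,
                        "" if neg.empty else f"first offending cell: {neg.iloc[0][INDEX_COLS].to_dict()}")
                    key = INDEX_COLS + (["cause"] if "cause" in df.columns else [])
                    gaps = _full_cross_missing(df, key)
                    add(kind, path, "index_complete", not gaps,
                        "" if not gaps else f"missing strata (first 5): {gaps}")
            elif kind == "rates":
                surf = ctio.read_rate_surface(path)
                add(kind, path, "parse", True, f"{len(surf.data)} cells")
            elif kind == "adjacency":
                ctio.read_adjacency(path, load_default_provinces())
                add(kind, path, "parse", True)
            else:
                add(kind, path, "known_kind", False, f"unknown input kind {kind!r}")
        except Exception as exc:  # validation must report, not raise
            add(kind, path, "parse", False, str(exc))
    return results
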