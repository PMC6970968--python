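"""Derived epidemiological measures.

Direct age-standardisation, annual percent change from a log-linear trend,
three-component decomposition of case-count change (population growth,
population aging, rate change), mortality-to-incidence ratio, and
between-province disparity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import INDEX_COLS, PopulationCube, RateSurface, StandardPopulation


def age_standardize(age_rates: Mapping[int, float], standard: StandardPopulation) -> float:
    """Directly standardised rate: sum of age-specific rates times the
    standard population's (normalised) age weights."""
    missing = set(standard.weights) - set(age_rates)
    if missing:
        raise ValueError(f"missing age groups {sorted(missing)} in rate input")
    if any(age_rates[a] < 0 for a in standard.weights):
        raise ValueError("age-specific rates must be non-negative")
    return float(sum(standard.weights[a] * age_rates[a] for a in standard.weights))


def standard_from_population(population: PopulationCube, year: int) -> StandardPopulation:
    """Standard age weights taken from a population cube's age structure in
    one year (conventionally the national population of 2016)."""
    df = population.data[population.data["year"] == year]
    if df.empty:
        raise ValueError(f"population cube has no year {year}")
    weights = df.groupby("age_code")["person_years"].sum().to_dict()
    return StandardPopulation(weights={int(a): float(w) for a, w in weights.items()},
                              label=f"population {year}")


def asr_table(
    surface: RateSurface,
    standard: StandardPopulation,
    by: tuple[str, ...] = ("year", "sex"),
) -> pd.DataFrame:
    """ASR per requested stratum (e.g. per year and sex, or per province).

    Age-specific rates are first averaged over the remaining dimensions with
    person-year-free equal weights within each (by, age) cell, then
    standardised.  For national series pass a surface already aggregated to
    the national level, or group by province explicitly.
    """
    df = surface.data
    group_cols = list(by) + ["age_code"]
    age_rates = df.groupby(group_cols, as_index=False)["rate"].mean()
    rows = []
    for key, sub in age_rates.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        rates = dict(zip(sub["age_code"], sub["rate"]))
        rows.append(dict(zip(by, key), asr=age_standardize(rates, standard)))
    return pd.DataFrame(rows)


def national_rates(surface: RateSurface, population: PopulationCube) -> pd.DataFrame:
    """Population-weighted national age-specific rates per (year, age, sex)."""
    df = surface.data.merge(population.data, on=INDEX_COLS, validate="one_to_one")
    df["cases"] = df["rate"] * df["person_years"] / 1e5
    nat = df.groupby(["year", "age_code", "sex"], as_index=False)[["cases", "person_years"]].sum()
    nat["rate"] = nat["cases"] / nat["person_years"] * 1e5
    return nat


@dataclass(frozen=True)
class APCResult:
    """Annual percent change from a log-linear trend fit."""

    apc_percent: float
    slope: float
    n_years: int


def apc(series: Mapping[int, float]) -> APCResult:
    """APC = 100*(e^slope - 1), slope from OLS of ln(value) on calendar year."""
    years = np.array(sorted(series), dtype=float)
    values = np.array([series[int(y)] for y in years], dtype=float)
    if len(years) < 2:
        raise ValueError("APC needs at least two distinct years")
    if (values <= 0).any():
        raise ValueError("APC requires strictly positive values")
    X = sm.add_constant(years)
    slope = float(sm.OLS(np.log(values), X).fit().params[1])
    return APCResult(apc_percent=100.0 * (np.exp(slope) - 1.0), slope=slope, n_years=len(years))


@dataclass(frozen=True)
class DecompositionResult:
    """Contributions to the change in new cases, each as % of baseline cases.

    growth + aging + rate_change telescopes exactly to total.
    """

    growth: float
    aging: float
    rate_change: float
    total: float

    def __post_init__(self) -> None:
        if abs(self.growth + self.aging + self.rate_change - self.total) > 1e-9:
            raise ValueError("decomposition components must sum to the total")


def decompose(
    rates_base: Mapping[tuple, float],
    pop_base: Mapping[tuple, float],
    pop_final: Mapping[tuple, float],
    rates_final: Mapping[tuple, float],
) -> DecompositionResult:
    """Three-component decomposition of the change in new cases.

    Rates are per 100,000; populations are person-years; strata (e.g.
    (age, sex) pairs) must match across the four inputs.  Two hypothetical
    datasets bridge baseline and final year: H1 applies baseline rates and
    baseline age/sex structure to the final year's total population
    (difference from baseline cases = population growth); H2 applies
    baseline rates to the final year's structure and population (H2 - H1 =
    population aging); the remainder to the final year's actual cases is the
    change in age-specific rates.
    """
    strata = set(rates_base)
    if not (strata == set(pop_base) == set(pop_final) == set(rates_final)):
        raise ValueError("stratum keys must match across all four inputs")
    c_base = sum(rates_base[s] * pop_base[s] for s in strata) / 1e5
    c_final = sum(rates_final[s] * pop_final[s] for s in strata) / 1e5
    if c_base <= 0:
        raise ValueError("baseline case total must be positive")
    total_base = sum(pop_base.values())
    total_final = sum(pop_final.values())
    # H1: baseline rates and structure, final total population.
    h1 = sum(rates_base[s] * pop_base[s] / total_base * total_final for s in strata) / 1e5
    # H2: baseline rates, final structure and population.
    h2 = sum(rates_base[s] * pop_final[s] for s in strata) / 1e5
    growth = (h1 - c_base) / c_base
    aging = (h2 - h1) / c_base
    rate_change = (c_final - h2) / c_base
    total = (c_final - c_base) / c_base
    # close the telescoping identity to machine precision
    rate_change = total - growth - aging
    return DecompositionResult(
        growth=100.0 * growth,
        aging=100.0 * aging,
        rate_change=100.0 * rate_change,
        total=100.0 * total,
    )


@dataclass
class MIRSeries:
    """Mortality-to-incidence ratio per year; lower means better outcomes."""

    ratios: dict[int, float]
    mode: str  # crude | age-standardized

    def __post_init__(self) -> None:
        if self.mode not in ("crude", "age-standardized"):
            raise ValueError(f"unknown MIR mode {self.mode!r}")
        if any(r < 0 for r in self.ratios.values()):
            raise ValueError("MIR must be non-negative")


def mir(
    mortality_series: Mapping[int, float],
    incidence_series: Mapping[int, float],
    mode: str = "age-standardized",
) -> MIRSeries:
    """Ratio of mortality to incidence per year, on matching series.

    Pass crude rates (or counts over the same person-years) for ``crude``,
    ASR series for ``age-standardized``.
    """
    years = sorted(incidence_series)
    if sorted(mortality_series) != years:
        raise ValueError("mortality and incidence series must cover the same years")
    ratios = {}
    for y in years:
        inc = incidence_series[y]
        if inc is None or inc <= 0:
            raise ValueError(f"incidence must be positive in {y}")
        ratios[int(y)] = float(mortality_series[y] / inc)
    return MIRSeries(ratios=ratios, mode=mode)


@dataclass(frozen=True)
class DisparityResult:
    max_asr: float
    min_asr: float
    range: float
    ratio: float
    argmax: int
    argmin: int


def provincial_disparity(asr_by_province: Mapping[int, float]) -> DisparityResult:
    """Extremes of the provincial ASR distribution; ties go to the lowest id."""
    if len(asr_by_province) < 2:
        raise ValueError("disparity needs at least two provinces")
    items = sorted(asr_by_province.items())
    argmax = max(items, key=lambda kv: (kv[1], -kv[0]))[0]
    argmin = min(items, key=lambda kv: (kv[1], kv[0]))[0]
    hi, lo = asr_by_province[argmax], asr_by_province[argmin]
    if lo <= 0:
        raise ValueError("ASR values must be positive for the max/min ratio")
    return DisparityResult(
        max_asr=float(hi),
        min_asr=float(lo),
        range=float(hi - lo),
        ratio=float(hi / lo),
        argmax=int(argmax),
        argmin=int(argmin),
    )
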