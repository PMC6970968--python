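"""Shared fixtures: small graphs, populations and registries built in-memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cancertrends as ct
from cancertrends.types import INDEX_COLS, AdjacencyGraph, Province


def make_provinces(n: int) -> list[Province]:
    return [Province(i, f"Province {i}", f"P{i}", 1.0 / n) for i in range(1, n + 1)]


def make_path_graph(n: int) -> AdjacencyGraph:
    provs = make_provinces(n)
    return AdjacencyGraph.from_pairs(provs, [(i, i + 1) for i in range(1, n)])


@pytest.fixture(scope="session")
def small_graph() -> AdjacencyGraph:
    """Four provinces on a path: 1-2-3-4."""
    return make_path_graph(4)


@pytest.fixture(scope="session")
def small_population(small_graph) -> ct.PopulationCube:
    """Equal-share population, four provinces, 2000-2007, constant totals."""
    demo = ct.DemographicParams(
        total_first=8e6,
        total_last=8e6,
        years=tuple(range(2000, 2008)),
        province_shares={p.id: 0.25 for p in small_graph.provinces},
    )
    return ct.generate_population_cube(demo, 0)


@pytest.fixture(scope="session")
def small_truth(small_graph) -> ct.RateSurface:
    return ct.generate_true_rates(
        ct.RateParams(province_sd=0.2, spatial_rho=0.4),
        small_graph,
        seed=5,
        years=tuple(range(2000, 2008)),
    )


def poisson_cube(
    truth: ct.RateSurface, population: ct.PopulationCube, seed: int
) -> ct.CaseCountCube:
    """Counts drawn Poisson around the truth, on the corrected scale."""
    merged = truth.data.merge(population.data, on=INDEX_COLS)
    mu = merged["rate"].to_numpy() * merged["person_years"].to_numpy() / 1e5
    rng = np.random.default_rng(seed)
    return ct.CaseCountCube(
        merged[INDEX_COLS].assign(count=rng.poisson(mu)), kind="corrected"
    )


def expected_cube(truth: ct.RateSurface, population: ct.PopulationCube) -> ct.CaseCountCube:
    """Noise-free counts: exactly the Poisson means."""
    merged = truth.data.merge(population.data, on=INDEX_COLS)
    mu = merged["rate"].to_numpy() * merged["person_years"].to_numpy() / 1e5
    return ct.CaseCountCube(merged[INDEX_COLS].assign(count=mu), kind="corrected")


def make_record(record_id: int, **kwargs) -> ct.RegistryRecord:
    defaults = dict(
        diagnosis_year=2005,
        first_name="Ali",
        surname="Ahmadi",
        parent_name="Reza",
        address="No 1, Azadi St",
        sex="male",
        age_years=7,
        province_id=1,
        cause_code="leukemia",
        source="hospital",
    )
    defaults.update(kwargs)
    return ct.RegistryRecord(record_id=record_id, **defaults)
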