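"""Two-stage model: stage-1 oracles, kernel weights, smoother vs brute force,
composition identities and bootstrap uncertainty behaviour."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cancertrends as ct
from cancertrends.model import _design, st_weight
from cancertrends.types import AGE_MIDPOINTS, INDEX_COLS, AdjacencyGraph

from conftest import expected_cube, make_path_graph, make_provinces, poisson_cube


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------


def _single_province_inputs(seed=0, n_years=10):
    provs = make_provinces(1)
    years = tuple(range(2000, 2000 + n_years))
    demo = ct.DemographicParams(
        total_first=2e6, total_last=2e6, years=years, province_shares={1: 1.0}
    )
    pop = ct.generate_population_cube(demo, 0)
    rng = np.random.default_rng(seed)
    df = pop.data[INDEX_COLS].copy()
    df["count"] = rng.poisson(20.0, len(df)) + 1
    return ct.CaseCountCube(df, kind="raw"), pop


class TestFitStage1:
    def test_single_province_matches_ordinary_least_squares(self):
        cube, pop = _single_province_inputs()
        fit = ct.fit_stage1(cube, pop, covariates=None, floor=0.01)
        assert fit.var_random <= 1e-4
        # independent oracle: plain OLS on the same design
        df = cube.data.merge(pop.data, on=INDEX_COLS)
        y = np.log(df["count"] / df["person_years"] * 1e5 + 0.01)
        X = _design(df, None, df["year"].mean())
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_intercept_equals_mean_log_rate_for_one_stratum_class(self):
        # one province, one age, one sex, no trend information used
        years = tuple(range(2000, 2010))
        rows = [
            {"province_id": 1, "year": y, "age_code": 0, "sex": "female",
             "count": c, "person_years": 1e6}
            for y, c in zip(years, [12, 15, 9, 14, 11, 13, 10, 16, 12, 14])
        ]
        df = pd.DataFrame(rows)
        pop = ct.PopulationCube(df[INDEX_COLS + ["person_years"]])
        cube = ct.CaseCountCube(df[INDEX_COLS + ["count"]], kind="raw")
        fit = ct.fit_stage1(cube, pop, floor=0.01)
        y = np.log(df["count"] / df["person_years"] * 1e5 + 0.01)
        # intercept + year term evaluated at the centred mean = mean of y
        assert fit.params["const"] == pytest.approx(
            np.mean(y) - 0, abs=1e-6
        ) or np.isclose(fit.linear_predictor["eta"].mean(), np.mean(y), atol=1e-8)

    def test_fixed_coefficients_recovered_within_ci_in_most_replicates(self):
        """Simulation-based calibration on the full 31x27x4x2 grid."""
        adj = ct.load_default_adjacency()
        pop = ct.generate_population_cube(ct.DemographicParams(), 1)
        cov = ct.generate_covariates(years=tuple(range(1990, 2017)), seed=1)
        grid = pop.data.copy()
        X = _design(grid, cov, grid["year"].mean())
        true = {"const": 2.0, "wealth_index": 0.10, "education_years": 0.03,
                "urbanization": -0.5, "year_c": 0.01, "age_1": 0.2,
                "age_2": 0.4, "age_3": 0.6, "sex_male": 0.26}
        beta = np.array([true[c] for c in X.columns])
        sigma_u, sigma_e = 0.2, 0.15
        n_rep = 100
        cover = {c: 0 for c in X.columns}
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            u = {p.id: rng.normal(0, sigma_u) for p in adj.provinces}
            eta = (
                X.to_numpy() @ beta
                + grid["province_id"].map(u).to_numpy()
                + rng.normal(0, sigma_e, len(grid))
            )
            counts = np.maximum(np.exp(eta) - 0.01, 1e-9) * grid["person_years"].to_numpy() / 1e5
            cube = ct.CaseCountCube(grid[INDEX_COLS].assign(count=counts), kind="corrected")
            fit = ct.fit_stage1(cube, pop, cov, floor=0.01)
            for c in X.columns:
                half = 1.96 * fit.bse[c]
                if fit.params[c] - half <= true[c] <= fit.params[c] + half:
                    cover[c] += 1
        for c, hits in cover.items():
            assert hits / n_rep >= 0.85, f"{c}: {hits}/{n_rep}"

    def test_all_zero_cube_rejected(self, small_population):
        df = small_population.data[INDEX_COLS].assign(count=0)
        cube = ct.CaseCountCube(df, kind="raw")
        with pytest.raises(ValueError):
            ct.fit_stage1(cube, small_population)

    def test_too_few_strata_rejected(self):
        df = pd.DataFrame(
            {"province_id": [1, 1], "year": [2000, 2001], "age_code": [0, 0],
             "sex": ["male", "male"], "count": [1, 2], "person_years": [1e5, 1e5]}
        )
        pop = ct.PopulationCube(df[INDEX_COLS + ["person_years"]])
        cube = ct.CaseCountCube(df[INDEX_COLS + ["count"]], kind="raw")
        with pytest.raises(ValueError):
            ct.fit_stage1(cube, pop)


class TestResiduals:
    def test_zero_when_fit_reproduces_observations(self, small_graph, small_population, small_truth):
        cube = expected_cube(small_truth, small_population)
        fit = ct.fit_stage1(cube, small_population, floor=0.01)
        res = ct.compute_residuals(fit, cube, small_population)
        # recompose: y = eta + residual exactly
        merged = res.merge(fit.linear_predictor, on=INDEX_COLS)
        df = cube.data.merge(small_population.data, on=INDEX_COLS)
        y = np.log(df["count"] / df["person_years"] * 1e5 + 0.01)
        assert np.allclose(merged["eta"] + merged["residual"], y, atol=1e-12)

    def test_mean_residual_near_zero_for_least_squares_stage1(self):
        cube, pop = _single_province_inputs(seed=3)
        fit = ct.fit_stage1(cube, pop, floor=0.01)
        res = ct.compute_residuals(fit, cube, pop)
        assert abs(res["residual"].mean()) < 1e-6

    def test_frozen_fit_shifts_residuals_linearly(self):
        cube, pop = _single_province_inputs(seed=4)
        fit = ct.fit_stage1(cube, pop, floor=0.01)
        res = ct.compute_residuals(fit, cube, pop)
        # adding c to every observation (on the log scale) with the fit frozen
        shifted = fit.linear_predictor.copy()
        shifted["eta"] = shifted["eta"] - 0.7  # equivalently y + 0.7
        fit_frozen = ct.Stage1Fit(
            params=fit.params, bse=fit.bse, random_intercepts=fit.random_intercepts,
            var_random=fit.var_random, var_resid=fit.var_resid, floor=fit.floor,
            year_center=fit.year_center, linear_predictor=shifted,
        )
        res2 = ct.compute_residuals(fit_frozen, cube, pop)
        assert np.allclose(res2["residual"] - res["residual"], 0.7, atol=1e-12)


# ---------------------------------------------------------------------------
# Kernel weights
# ---------------------------------------------------------------------------


class TestSTWeight:
    def test_identity_cell_has_weight_one(self):
        assert st_weight(0, "same", 0, ct.SmoothingParams()) == 1.0

    def test_non_neighbor_provinces_never_borrow(self):
        p = ct.SmoothingParams()
        for dt, da in [(0, 0), (3, 1), (10, 12)]:
            assert st_weight(dt, "other", da, p) == 0.0

    def test_age_kernel_formula(self):
        p = ct.SmoothingParams(zeta=0.5, lamda=5.0, omega=0.5)
        assert st_weight(0, "same", 2.0, p) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_neighbor_weight_scales_by_zeta(self):
        p = ct.SmoothingParams(zeta=0.3, lamda=2.0, omega=0.1)
        same = st_weight(1.0, "same", 1.0, p)
        nbr = st_weight(1.0, "neighbor", 1.0, p)
        assert nbr == pytest.approx(0.3 * same)

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = ct.SmoothingParams(zeta=0.7, lamda=3.0, omega=0.4)
        for _ in range(100):
            w = st_weight(
                rng.uniform(0, 30), rng.choice(["same", "neighbor", "other"]),
                rng.uniform(0, 12), p,
            )
            assert 0.0 <= w <= 1.0

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            st_weight(-1, "same", 0, ct.SmoothingParams())


# ---------------------------------------------------------------------------
# Residual smoothing
# ---------------------------------------------------------------------------


def _toy_residuals(n_prov=2, years=(2000, 2001), ages=(0, 1), sexes=("female",)):
    rng = np.random.default_rng(5)
    rows = []
    for p in range(1, n_prov + 1):
        for y in years:
            for a in ages:
                for s in sexes:
                    rows.append(
                        {"province_id": p, "year": y, "age_code": a, "sex": s,
                         "residual": rng.normal()}
                    )
    return pd.DataFrame(rows)


def brute_force_smooth(residuals, adjacency, params):
    """Exhaustive double loop over cells, per sex."""
    out = residuals.copy()
    values = []
    for _, c in residuals.iterrows():
        num = den = 0.0
        for _, o in residuals.iterrows():
            if o["sex"] != c["sex"]:
                continue
            if o["province_id"] == c["province_id"]:
                rel = "same"
            elif adjacency.are_neighbors(int(o["province_id"]), int(c["province_id"])):
                rel = "neighbor"
            else:
                rel = "other"
            w = st_weight(
                abs(c["year"] - o["year"]), rel,
                abs(AGE_MIDPOINTS[int(c["age_code"])] - AGE_MIDPOINTS[int(o["age_code"])]),
                params,
            )
            num += w * o["residual"]
            den += w
        values.append(num / den)
    out["residual"] = values
    return out.sort_values(INDEX_COLS, ignore_index=True)


class TestSmoothResiduals:
    def test_degenerate_kernel_returns_raw_residuals(self, small_graph):
        res = _toy_residuals(n_prov=4, years=(2000, 2001, 2002))
        params = ct.SmoothingParams(zeta=0.0, lamda=1e-9, omega=50.0)
        smoothed = ct.smooth_residuals(res, small_graph, params)
        merged = res.sort_values(INDEX_COLS, ignore_index=True)
        assert np.allclose(smoothed["residual"], merged["residual"], atol=1e-9)

    def test_uniform_kernel_gives_per_sex_global_mean(self):
        # complete graph + zeta=1 + flat time/age kernels: every same-sex
        # cell receives weight 1
        provs = make_provinces(4)
        complete = AdjacencyGraph.from_pairs(
            provs, [(i, j) for i in range(1, 5) for j in range(i + 1, 5)]
        )
        res = _toy_residuals(n_prov=4, years=(2000, 2001), sexes=("female", "male"))
        params = ct.SmoothingParams(zeta=1.0, lamda=1e12, omega=0.0)
        smoothed = ct.smooth_residuals(res, complete, params)
        for sex in ("female", "male"):
            expected = res.loc[res["sex"] == sex, "residual"].mean()
            got = smoothed.loc[smoothed["sex"] == sex, "residual"]
            assert np.allclose(got, expected, atol=1e-9)

    def test_matches_brute_force_oracle_on_toy_grid(self):
        graph = make_path_graph(2)
        res = _toy_residuals(n_prov=2, years=(2000, 2001), ages=(1,))
        params = ct.SmoothingParams(zeta=0.4, lamda=1.5, omega=0.2)
        smoothed = ct.smooth_residuals(res, graph, params)
        oracle = brute_force_smooth(res, graph, params)
        assert np.allclose(smoothed["residual"], oracle["residual"], atol=1e-12)

    def test_matches_brute_force_oracle_on_larger_grid(self, small_graph):
        res = _toy_residuals(
            n_prov=4, years=(2000, 2001, 2002), ages=(0, 1, 2, 3),
            sexes=("female", "male"),
        )
        params = ct.SmoothingParams(zeta=0.6, lamda=3.0, omega=0.3)
        smoothed = ct.smooth_residuals(res, small_graph, params)
        oracle = brute_force_smooth(res, small_graph, params)
        assert np.allclose(smoothed["residual"], oracle["residual"], atol=1e-12)

    def test_output_is_convex_combination_of_positive_weight_cells(self, small_graph):
        res = _toy_residuals(n_prov=4, years=tuple(range(2000, 2005)),
                             ages=(0, 1, 2, 3), sexes=("female", "male"))
        params = ct.SmoothingParams(zeta=0.5, lamda=4.0, omega=0.2)
        smoothed = ct.smooth_residuals(res, small_graph, params)
        # zeta > 0 and finite bandwidths: every same-sex cell has positive
        # weight somewhere, but the bound below uses the per-sex extremes
        for sex, sub in smoothed.groupby("sex"):
            raw = res[res["sex"] == sex]["residual"]
            assert (sub["residual"] >= raw.min() - 1e-12).all()
            assert (sub["residual"] <= raw.max() + 1e-12).all()

    def test_incomplete_cube_rejected(self, small_graph):
        res = _toy_residuals(n_prov=4).iloc[:-1]
        with pytest.raises(ValueError):
            ct.smooth_residuals(res, small_graph, ct.SmoothingParams())


# ---------------------------------------------------------------------------
# Composition and prediction
# ---------------------------------------------------------------------------


class TestPredictRates:
    def test_zero_smoothing_recovers_stage1_prediction(self, small_population, small_truth):
        cube = poisson_cube(small_truth, small_population, seed=9)
        fit = ct.fit_stage1(cube, small_population, floor=0.01)
        zero = fit.linear_predictor[INDEX_COLS].assign(residual=0.0)
        surface = ct.predict_rates(fit, zero)
        merged = surface.data.merge(fit.linear_predictor, on=INDEX_COLS)
        assert np.allclose(
            merged["rate"], np.maximum(np.exp(merged["eta"]) - 0.01, 1e-6), atol=1e-12
        )

    def test_log_rate_identity_inverts_to_smoothed_residual(
        self, small_graph, small_population, small_truth
    ):
        cube = poisson_cube(small_truth, small_population, seed=10)
        fit = ct.fit_stage1(cube, small_population, floor=0.01)
        res = ct.compute_residuals(fit, cube, small_population)
        smoothed = ct.smooth_residuals(res, small_graph, ct.SmoothingParams())
        surface = ct.predict_rates(fit, smoothed)
        merged = (
            surface.data.merge(fit.linear_predictor, on=INDEX_COLS)
            .merge(smoothed, on=INDEX_COLS)
        )
        recovered = np.log(merged["rate"] + merged["floor"]) - merged["eta"]
        assert np.allclose(recovered, merged["residual"], atol=1e-9)

    def test_two_stage_beats_stage1_on_structured_residuals(
        self, small_graph, small_population
    ):
        """Noise-free truth with a non-log-linear time component: smoothing
        the residuals must not hurt, and on structure it helps."""
        years = np.array(sorted(small_population.data["year"].unique()))
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            base = ct.generate_true_rates(
                ct.RateParams(province_sd=0.15), small_graph,
                seed=700 + rep, years=tuple(years),
            )
            bump = dict(zip(years, 0.25 * np.sin(2 * np.pi * (years - years[0]) / 6)))
            truth = base.data.copy()
            truth["rate"] = truth["rate"] * np.exp(truth["year"].map(bump))
            truth = ct.RateSurface(truth)
            cube = expected_cube(truth, small_population)
            fit = ct.fit_stage1(cube, small_population, floor=0.01)
            res = ct.compute_residuals(fit, cube, small_population)
            smoothed = ct.smooth_residuals(res, small_graph, ct.SmoothingParams())
            two_stage = ct.predict_rates(fit, smoothed)
            stage1 = ct.predict_rates(
                fit, fit.linear_predictor[INDEX_COLS].assign(residual=0.0)
            )
            t = truth.data.rename(columns={"rate": "true_rate"})
            rmse2 = np.sqrt(
                ((two_stage.data.merge(t, on=INDEX_COLS).eval("rate - true_rate")) ** 2).mean()
            )
            rmse1 = np.sqrt(
                ((stage1.data.merge(t, on=INDEX_COLS).eval("rate - true_rate")) ** 2).mean()
            )
            wins += int(rmse2 <= rmse1)
        assert wins == 20


# ---------------------------------------------------------------------------
# Uncertainty
# ---------------------------------------------------------------------------


class TestSimulateUncertainty:
    def test_fixed_seed_gives_identical_draws(self, small_graph, small_population, small_truth):
        cube = poisson_cube(small_truth, small_population, seed=20)
        est = ct.make_two_stage_estimator(small_population, None, small_graph)
        a = ct.simulate_uncertainty(cube, small_population, est, n_draws=5, seed=3)
        b = ct.simulate_uncertainty(cube, small_population, est, n_draws=5, seed=3)
        assert np.array_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_interval_width_shrinks_with_total_count(self, small_graph):
        """sqrt-n scaling: larger counts, tighter intervals, on a 3-point ladder."""
        provs = small_graph.provinces
        years = tuple(range(2000, 2004))
        widths = []
        for scale in (1.0, 16.0, 256.0):
            demo = ct.DemographicParams(
                total_first=4e6 * scale, total_last=4e6 * scale, years=years,
                province_shares={p.id: 0.25 for p in provs},
            )
            pop = ct.generate_population_cube(demo, 0)
            truth = ct.generate_true_rates(
                ct.RateParams(province_sd=0.0), small_graph, seed=1, years=years
            )
            cube = expected_cube(truth, pop)
            est = ct.make_two_stage_estimator(pop, None, small_graph)
            surf = ct.simulate_uncertainty(cube, pop, est, n_draws=30, seed=4)
            widths.append(float((surf.data["upper"] - surf.data["lower"]).mean()))
        assert widths[0] > widths[1] > widths[2]

    def test_interval_brackets_point_estimate(self, small_graph, small_population, small_truth):
        cube = poisson_cube(small_truth, small_population, seed=21)
        est = ct.make_two_stage_estimator(small_population, None, small_graph)
        surf = ct.simulate_uncertainty(cube, small_population, est, n_draws=10, seed=5)
        assert (surf.data["lower"] <= surf.data["rate"]).all()
        assert (surf.data["rate"] <= surf.data["upper"]).all()

    def test_too_few_draws_rejected(self, small_graph, small_population, small_truth):
        cube = poisson_cube(small_truth, small_population, seed=22)
        est = ct.make_two_stage_estimator(small_population, None, small_graph)
        with pytest.raises(ValueError):
            ct.simulate_uncertainty(cube, small_population, est, n_draws=1, seed=0)


def test_whole_pipeline_recovers_province_ranking():
    """Synthetic registries at the default noise conditions (completeness
    0.22-0.75, duplicates, missing fields): provinces ranked by estimated
    ASR agree with the true-ASR ranking at rank correlation >= 0.8 over 20
    replicates."""
    from scipy.stats import spearmanr

    adj = ct.load_default_adjacency()
    pop = ct.generate_population_cube(ct.DemographicParams(), 1)
    years = tuple(range(1990, 2017))
    sched = ct.build_completeness_schedule({2000: 0.22, 2010: 0.75}, years)
    cov = ct.generate_covariates(years=years, seed=1)
    std = ct.standard_from_population(pop, 2016)
    est = ct.make_two_stage_estimator(pop, cov, adj)
    pids = [p.id for p in adj.provinces]
    corrs = []
    for rep in range(20):
        truth = ct.generate_true_rates(ct.RateParams(), adj, seed=100 + rep)
        records, _ = ct.sample_registry(truth, pop, sched.values, seed=200 + rep)
        unique, _ = ct.deduplicate(records, 0.2)
        completed = ct.impute_missing(unique, m=1, seed=300 + rep)[0]
        cube = ct.aggregate(completed, ct.DEFAULT_TAXONOMY, pids, list(years))
        corrected = ct.correct_completeness(cube, sched).all_cause()
        surface = est(corrected)
        m = ct.asr_table(surface, std, by=("province_id",)).merge(
            ct.asr_table(truth, std, by=("province_id",)),
            on="province_id", suffixes=("_est", "_true"),
        )
        corrs.append(spearmanr(m["asr_est"], m["asr_true"]).statistic)
    assert np.mean(corrs) >= 0.8, corrs


def test_loyo_selection_prefers_informative_bandwidths(small_graph):
    """Residuals smooth in time: leave-one-year-out MSE should favour a
    finite temporal bandwidth over a near-degenerate one."""
    years = np.arange(2000, 2010)
    rows = []
    rng = np.random.default_rng(2)
    for p in range(1, 5):
        for y in years:
            for a in (0, 1, 2, 3):
                for s in ("female", "male"):
                    rows.append({
                        "province_id": p, "year": y, "age_code": a, "sex": s,
                        "residual": np.sin((y - 2000) / 3) + rng.normal(0, 0.05),
                    })
    res = pd.DataFrame(rows)
    grid = [
        ct.SmoothingParams(zeta=0.0, lamda=1e-6, omega=50.0),  # near-identity
        ct.SmoothingParams(zeta=0.3, lamda=2.0, omega=0.3),
    ]
    best, table = ct.select_smoothing_loyo(res, small_graph, grid)
    assert best == grid[1]
    assert table.loc[1, "loyo_mse"] < table.loc[0, "loyo_mse"]
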