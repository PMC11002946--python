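"""PK metrics, cohort statistics, fold changes and result tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lapbpk import (ConcentrationProfile, PKMetrics, cohort_summary,
                    compute_pk_metrics, fold_change, fraction_below,
                    geometric_cv_percent, geometric_mean)
from lapbpk.analysis import build_result_tables


def profile_from(times, concs):
    return ConcentrationProfile(times=np.asarray(times, float),
                                plasma_concentration=np.asarray(concs, float))


def metrics_map(cmins, cmaxs=None, aucs=None):
    cmaxs = cmaxs or [2 * c for c in cmins]
    aucs = aucs or [24 * c for c in cmins]
    return {f"s{i}": PKMetrics(cmax=cx, auc_tau=a, cmin=cn, interval=(0, 24))
            for i, (cx, a, cn) in enumerate(zip(cmaxs, aucs, cmins))}


class TestComputePKMetrics:
    def test_constant_profile_exact(self):
        t = np.arange(0.0, 48.1, 6.0)
        prof = profile_from(t, np.full_like(t, 5.0))
        m = compute_pk_metrics(prof, (0.0, 24.0))
        assert (m.cmax, m.cmin) == (5.0, 5.0)
        assert m.auc_tau == pytest.approx(5.0 * 24.0, rel=1e-12)

    def test_single_exponential_auc_vs_closed_form(self):
        """Trapezoid on a 6 h grid within 0.1% of C0/k (1 - e^-ktau)."""
        k, c0, tau = 0.01, 100.0, 672.0
        t = np.arange(0.0, tau + 0.1, 6.0)
        prof = profile_from(t, c0 * np.exp(-k * t))
        analytic = c0 / k * (1.0 - np.exp(-k * tau))
        m = compute_pk_metrics(prof, (0.0, tau))
        assert m.auc_tau == pytest.approx(analytic, rel=1e-3)

    def test_trapezoid_error_shrinks_at_second_order(self):
        """Halving the grid step cuts the AUC error ~4x on a smooth profile."""
        k, c0, tau = 0.05, 100.0, 96.0
        analytic = c0 / k * (1.0 - np.exp(-k * tau))
        errors = []
        for step in (6.0, 3.0):
            t = np.arange(0.0, tau + 0.01, step)
            m = compute_pk_metrics(profile_from(t, c0 * np.exp(-k * t)),
                                   (0.0, tau))
            errors.append(abs(m.auc_tau - analytic))
        assert errors[0] / errors[1] > 3.0

    def test_interval_outside_grid_rejected(self):
        prof = profile_from([0.0, 6.0, 12.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            compute_pk_metrics(prof, (0.0, 24.0))

    def test_cmin_is_interval_end_value(self):
        t = np.arange(0.0, 24.1, 1.0)
        c = 100.0 * np.exp(-0.1 * t)
        m = compute_pk_metrics(profile_from(t, c), (0.0, 24.0))
        assert m.cmin == pytest.approx(c[-1])
        assert m.cmax == pytest.approx(100.0)


class TestCohortSummary:
    def test_identical_individuals_have_zero_cv(self):
        res = cohort_summary(metrics_map([100.0, 100.0, 100.0]))
        assert res.geomean.cmin == pytest.approx(100.0)
        assert res.cv_percent["cmin"] == pytest.approx(0.0, abs=1e-9)

    def test_two_point_geometric_mean(self):
        res = cohort_summary(metrics_map([100.0, 400.0]))
        assert res.geomean.cmin == pytest.approx(200.0, rel=1e-12)

    def test_geomean_dual_formula_oracle(self):
        """exp(mean(log x)) equals the n-th root of the product."""
        rng = np.random.default_rng(12)
        values = rng.lognormal(3.0, 0.5, size=1000)
        direct = np.prod(values ** (1.0 / len(values)))
        assert geometric_mean(values) == pytest.approx(direct, rel=1e-9)

    def test_stored_geomean_reproduces_per_individual_values(self):
        rng = np.random.default_rng(3)
        res = cohort_summary(metrics_map(list(rng.lognormal(4, 0.6, 50))))
        recomputed = geometric_mean(res.metric_values("cmin"))
        assert res.geomean.cmin == pytest.approx(recomputed, rel=1e-9)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            cohort_summary(metrics_map([100.0]))


class TestFoldChange:
    def test_self_ratio_is_exactly_one(self):
        res = cohort_summary(metrics_map([50.0, 80.0, 120.0]))
        for metric in ("cmax", "auc_tau", "cmin"):
            assert fold_change(res, res, metric, n_boot=0).ratio == 1.0

    def test_reciprocal_property(self):
        a = cohort_summary(metrics_map([55.0, 70.0, 130.0]))
        b = cohort_summary(metrics_map([40.0, 90.0, 100.0]))
        fwd = fold_change(a, b, "cmin", n_boot=0).ratio
        rev = fold_change(b, a, "cmin", n_boot=0).ratio
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_three_versus_three(self):
        a = cohort_summary(metrics_map([100.0, 200.0, 400.0]))  # geomean 200
        b = cohort_summary(metrics_map([50.0, 100.0, 200.0]))   # geomean 100
        fc = fold_change(a, b, "cmin", n_boot=0)
        assert fc.ratio == pytest.approx(2.0, rel=1e-12)

    def test_bootstrap_band_brackets_ratio_and_is_seeded(self):
        rng = np.random.default_rng(5)
        a = cohort_summary(metrics_map(list(rng.lognormal(4.2, 0.4, 60))))
        b = cohort_summary(metrics_map(list(rng.lognormal(4.0, 0.4, 60))))
        f1 = fold_change(a, b, "cmin", seed=7)
        f2 = fold_change(a, b, "cmin", seed=7)
        assert f1.band == f2.band
        assert f1.band[0] < f1.ratio < f1.band[1]

    def test_unknown_metric_rejected(self):
        res = cohort_summary(metrics_map([50.0, 80.0]))
        with pytest.raises(KeyError):
            fold_change(res, res, "thalf")


class TestFractionBelow:
    def test_hand_counted_toy_set(self):
        troughs = {8: np.array([100.0, 200.0, 700.0])}
        assert fraction_below(troughs, 8, 664.0) == pytest.approx(200.0 / 3)

    def test_all_above_gives_zero(self):
        assert fraction_below({48: np.array([700.0, 800.0])}, 48, 664.0) == 0.0

    def test_strict_inequality_on_ties(self):
        troughs = {8: np.array([50.0, 49.999, 50.001])}
        assert fraction_below(troughs, 8, 50.0) == pytest.approx(100.0 / 3)

    def test_unsampled_week_rejected(self):
        with pytest.raises(KeyError):
            fraction_below({8: np.array([1.0])}, 48, 50.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(1.0, 1e4), min_size=1, max_size=50),
           st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    def test_monotone_in_threshold(self, concs, thr_a, thr_b):
        troughs = {8: np.array(concs)}
        lo, hi = sorted((thr_a, thr_b))
        assert fraction_below(troughs, 8, lo) <= fraction_below(troughs, 8, hi)


@pytest.fixture(scope="module")
def results_grid():
    rng = np.random.default_rng(10)
    grid = {}
    for drug in ("cabotegravir", "rilpivirine"):
        for regimen in ("Q4W", "Q8W"):
            for group in ("young", "middle", "older"):
                shift = {"young": 0.0, "middle": 0.1, "older": 0.25}[group]
                vals = list(rng.lognormal(4 + shift, 0.3, 20))
                cr = cohort_summary(
                    metrics_map(vals),
                    threshold_fractions={(8, 664.0): 4.0})
                grid[(drug, regimen, group)] = cr
    return grid


class TestResultTables:

    def test_summary_row_combinatorics(self, results_grid):
        tables = build_result_tables(results_grid, fold_seed=0)
        # drugs x regimens x groups x metrics
        assert len(tables["cohort_summary"]) == 2 * 2 * 3 * 3
        assert len(tables["threshold_fractions"]) == 2 * 2 * 3
        # fold rows: (middle, older) vs young per drug/regimen/metric
        assert len(tables["fold_changes"]) == 2 * 2 * 2 * 3

    def test_sex_stratified_rows_appear(self, results_grid):
        rng = np.random.default_rng(11)
        grid = dict(results_grid)
        for group in ("older_female", "older_male"):
            grid[("cabotegravir", "Q4W", group)] = cohort_summary(
                metrics_map(list(rng.lognormal(4, 0.3, 20))))
        tables = build_result_tables(grid, fold_seed=0)
        sex_rows = tables["fold_changes"].query(
            "numerator == 'older_female' and denominator == 'older_male'")
        assert len(sex_rows) == 3

    def test_aging_direction_in_toy_grid(self, results_grid):
        tables = build_result_tables(results_grid, fold_seed=0)
        older = tables["fold_changes"].query("numerator == 'older'")
        assert (older["ratio"] > 1.0).all()

    def test_csv_round_trip(self, results_grid, tmp_path):
        tables = build_result_tables(results_grid, fold_seed=0)
        for name, frame in tables.items():
            path = tmp_path / f"{name}.csv"
            frame.to_csv(path, index=False)
            back = pd.read_csv(path, float_precision="round_trip")
            pd.testing.assert_frame_equal(back, frame)
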