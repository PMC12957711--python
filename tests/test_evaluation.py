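"""DVH metrics, acceptance thresholds, robustness report, posture statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posture4d._grid import Grid
from posture4d.dose import DoseDistribution
from posture4d.evaluation import (
    AcceptanceRule,
    DVHMetrics,
    compare_postures,
    dose_percentile,
    dvh,
    dvh_metrics,
    robustness_report,
)
from posture4d.planning import Prescription, scenario_set


def _dose_on(grid, values):
    return DoseDistribution(np.asarray(values, float), grid)


@pytest.fixture
def toy_grid():
    return Grid((10, 10, 10), (2.0, 2.0, 2.0))


def sorting_oracle_dp(values, p):
    """Independent oracle: largest dose d with >= p% of voxels at >= d."""
    vals = sorted(values, reverse=True)
    k = int(np.ceil(p / 100.0 * len(vals)))
    return vals[max(k, 1) - 1]


class TestDVHCurve:
    def test_uniform_dose_step_curve(self, toy_grid, rx):
        mask = np.ones(toy_grid.shape, bool)
        d = _dose_on(toy_grid, np.full(toy_grid.shape, 2.0))
        edges, vol = dvh(d, mask, bin_width_gy=0.1)
        assert vol[0] == 100.0
        assert np.all(vol[edges <= 2.0] == 100.0)
        assert np.all(vol[edges > 2.0 + 1e-9] == 0.0)

    def test_monotone_non_increasing(self, toy_grid):
        rng = np.random.default_rng(0)
        d = _dose_on(toy_grid, rng.random(toy_grid.shape) * 3)
        mask = np.ones(toy_grid.shape, bool)
        _, vol = dvh(d, mask)
        assert np.all(np.diff(vol) <= 1e-12)

    def test_random_field_matches_sorting_oracle_at_bins(self, toy_grid):
        rng = np.random.default_rng(42)
        vals = rng.random(toy_grid.shape) * 5
        mask = rng.random(toy_grid.shape) > 0.4
        edges, vol = dvh(_dose_on(toy_grid, vals), mask, bin_width_gy=0.25)
        sel = np.sort(vals[mask])
        for e, v in zip(edges, vol):
            assert v == pytest.approx((sel >= e).mean() * 100.0)

    def test_empty_mask_fails(self, toy_grid):
        with pytest.raises(ValueError):
            dvh(_dose_on(toy_grid, np.zeros(toy_grid.shape)), np.zeros(toy_grid.shape, bool))


class TestDVHMetrics:
    def test_uniform_prescription_dose(self, toy_grid, rx):
        target = np.ones(toy_grid.shape, bool)
        d = _dose_on(toy_grid, np.full(toy_grid.shape, rx.dose_per_fraction_gy))
        m = dvh_metrics(d, {"target": target}, rx)
        assert m.d95_pct == pytest.approx(100.0)
        assert m.v95_pct == 100.0
        assert m.hi_pp == pytest.approx(0.0)

    def test_half_hot_half_cold(self, toy_grid, rx):
        target = np.zeros(toy_grid.shape, bool)
        target[:, :, :] = True
        vals = np.zeros(toy_grid.shape)
        vals[:5] = 2.0 * rx.dose_per_fraction_gy
        m = dvh_metrics(_dose_on(toy_grid, vals), {"target": target}, rx)
        assert m.v95_pct == pytest.approx(50.0)
        assert m.d95_pct == pytest.approx(0.0)

    def test_oar_threshold_fraction(self, toy_grid, rx):
        target = np.ones(toy_grid.shape, bool)
        lung = np.ones(toy_grid.shape, bool)
        vals = np.zeros(toy_grid.shape)
        flat = vals.reshape(-1)
        flat[: int(0.3 * flat.size)] = 17.0 / rx.n_fractions  # 17 Gy at course scale
        vals[:] = flat.reshape(vals.shape)
        vals += 0.0
        d = _dose_on(toy_grid, vals)
        m = dvh_metrics(d, {"target": target, "lung": lung}, rx)
        assert m.vx_gy_pct["lung"] == pytest.approx(30.0)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_percentiles_match_sorting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(rng.integers(5, 200)) * 10
        for p in (5.0, 50.0, 95.0):
            assert dose_percentile(vals, p) == pytest.approx(
                sorting_oracle_dp(vals, p)
            )

    def test_zero_prescription_fails(self, toy_grid):
        rx0 = Prescription(dose_per_fraction_gy=0.0)
        target = np.ones(toy_grid.shape, bool)
        with pytest.raises(ValueError):
            dvh_metrics(_dose_on(toy_grid, np.ones(toy_grid.shape)), {"target": target}, rx0)

    def test_d5_below_d95_rejected(self):
        with pytest.raises(ValueError):
            DVHMetrics(d95_pct=100.0, d5_pct=90.0, v95_pct=100.0, hi_pp=-10.0)


class TestAcceptanceRule:
    def test_threshold_function_pure_and_idempotent(self):
        rule = AcceptanceRule()
        m = DVHMetrics(97.0, 101.0, 99.0, 4.0, {"lung": 10.0, "heart": 4.0})
        first = rule.check(m)
        assert first["all"]
        assert rule.check(m) == first

    def test_failing_metric_flags(self):
        rule = AcceptanceRule()
        m = DVHMetrics(93.0, 101.0, 99.0, 8.0, {"lung": 35.0, "heart": 12.0})
        out = rule.check(m)
        assert not out["d95"] and not out["hi"]
        assert not out["v16_lung"] and not out["v20_heart"]
        assert not out["all"]


class TestRobustnessReport:
    def test_nine_rows_per_setting_and_nominal_matches_static(
        self, small_phantom, small_plan, table
    ):
        settings_list = [scenario_set(3.0, 0.035), scenario_set(5.0, 0.05)]
        df = robustness_report(small_plan, small_phantom, table, settings_list,
                               mode="static")
        assert len(df) == 18
        assert (df.groupby("setting").size() == 9).all()

        from posture4d.dose4d import dose_4d_average

        nominal = df[(df["setting"] == "setting_0") & (df["scenario"] == "nominal")].iloc[0]
        dd = dose_4d_average(small_plan, small_phantom, table, static=True)
        m = dvh_metrics(
            dd,
            {"target": small_phantom.masks["itv"], "lung": small_phantom.lungs,
             "heart": small_phantom.masks["heart"]},
            small_plan.prescription,
        )
        assert nominal["d95_pct"] == pytest.approx(m.d95_pct)
        assert nominal["hi_pp"] == pytest.approx(m.hi_pp)

    def test_zero_uncertainty_single_nominal_row(self, small_phantom, small_plan, table):
        df = robustness_report(small_plan, small_phantom, table,
                               [scenario_set(0.0, 0.0)], mode="static")
        assert len(df) == 1
        assert df.iloc[0]["scenario"] == "nominal"


def exact_wilcoxon_oracle(diff):
    """Exhaustive sign-enumeration null for the Wilcoxon signed-rank test."""
    diff = np.asarray(diff, float)
    diff = diff[diff != 0]
    n = len(diff)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    w_plus = ranks[diff > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append((ranks * np.asarray(signs)).sum())
    stats = np.asarray(stats)
    w = min(w_plus, n * (n + 1) / 2 - w_plus)
    p = np.mean(np.minimum(stats, n * (n + 1) / 2 - stats) <= w + 1e-12)
    return w, min(1.0, p)


class TestComparePostures:
    def test_identical_samples_degenerate(self):
        a = np.array([95.0, 96.0, 97.0, 96.5])
        out = compare_postures(a, a.copy())
        assert out.degenerate and not out.significant and out.p_value == 1.0

    def test_small_sample_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        a = rng.normal(96.0, 1.0, size=6)
        b = a + rng.normal(0.8, 0.3, size=6)
        out = compare_postures(a, b)
        w_oracle, p_oracle = exact_wilcoxon_oracle(a - b)
        assert out.statistic == pytest.approx(w_oracle)
        assert out.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_significance_threshold_at_p05(self):
        a = np.arange(10, dtype=float)
        b = a + 1.0  # strictly one-sided differences: smallest possible p
        out = compare_postures(a, b)
        assert out.p_value < 0.05 and out.significant

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert compare_postures(a, b).p_value == pytest.approx(
            compare_postures(b, a).p_value
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_postures(np.ones(3), np.ones(4))
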