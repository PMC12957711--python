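"""Scenario generation, spot placement, robust optimization, angle selection."""

import numpy as np
import pytest

from posture4d._grid import Grid
from posture4d.dose import FieldDoseCalculator, SpotSet
from posture4d.evaluation import dose_percentile
from posture4d.planning import (
    AngleCatalog,
    OptimizationSettings,
    Prescription,
    Scenario,
    _best_pair,
    _stack_influence,
    optimize_robust,
    place_spots,
    scenario_set,
)


class TestScenarioSet:
    @pytest.mark.parametrize("setup,rng", [(3.0, 0.035), (5.0, 0.05)])
    def test_nine_scenarios_for_standard_settings(self, setup, rng):
        scenarios = scenario_set(setup, rng)
        assert len(scenarios) == 9
        assert sum(s.is_nominal for s in scenarios) == 1
        shifts = {s.shift_mm for s in scenarios if any(v != 0 for v in s.shift_mm)}
        assert len(shifts) == 6  # one per cardinal direction
        scales = sorted(s.rsp_scale for s in scenarios if s.rsp_scale != 1.0)
        assert scales == pytest.approx([1.0 - rng, 1.0 + rng])

    def test_degenerate_setting_collapses_to_nominal(self):
        scenarios = scenario_set(0.0, 0.0)
        assert len(scenarios) == 1 and scenarios[0].is_nominal

    def test_negative_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            scenario_set(-1.0, 0.035)


class TestPlaceSpots:
    def test_single_voxel_target(self, table):
        grid = Grid((48, 24, 24), (2.5, 2.5, 2.5))
        img = np.zeros(grid.shape, np.float32)
        target = np.zeros(grid.shape, bool)
        target[24, 12, 12] = True
        ss = place_spots(target, img, grid, 0.0, table)
        assert ss.n_spots >= 1
        assert len(np.unique(ss.energy_idx)) >= 1

    def test_spot_count_scales_with_lateral_spacing(self, table):
        grid = Grid((48, 32, 32), (2.5, 2.5, 2.5))
        img = np.zeros(grid.shape, np.float32)
        target = np.zeros(grid.shape, bool)
        target[20:30, 10:22, 10:22] = True  # box target
        n = {}
        for sp in (3.0, 6.0):
            sets = OptimizationSettings(lateral_spacing_mm=sp)
            n[sp] = place_spots(target, img, grid, 0.0, table, sets).n_spots
        ratio = n[3.0] / n[6.0]
        assert 2.5 <= ratio <= 6.0  # ~4x within grid rounding

    def test_rotational_symmetry_of_sphere_target(self, table):
        grid = Grid((48, 48, 24), (2.5, 2.5, 2.5))
        img = np.zeros(grid.shape, np.float32)
        x, y, z = grid.coords()
        target = (x**2 + y**2 + (z + 5) ** 2) <= 15.0**2
        n0 = place_spots(target, img, grid, 0.0, table).n_spots
        n90 = place_spots(target, img, grid, 90.0, table).n_spots
        assert abs(n0 - n90) / max(n0, n90) < 0.1

    def test_empty_target_fails(self, table):
        grid = Grid((16, 16, 16), (2.5, 2.5, 2.5))
        with pytest.raises(ValueError):
            place_spots(np.zeros(grid.shape, bool), np.zeros(grid.shape, np.float32),
                        grid, 0.0, table)


class TestOptimizeRobust:
    def _water_setup(self, table):
        grid = Grid((48, 16, 16), (2.5, 2.5, 2.5))
        img = np.zeros(grid.shape, np.float32)
        target = np.zeros(grid.shape, bool)
        target[28, 7, 7] = True
        return grid, img, target

    def test_single_spot_single_voxel_closed_form(self, table, rx):
        grid, img, target = self._water_setup(table)
        calc = FieldDoseCalculator(img, grid, 0.0, table, roi_mask=target,
                                   overrides=[(target, 70.0)])
        wepl = calc.wepl_at_voxels()[0]
        e = int(np.argmin(np.abs(table.ranges - wepl)))
        pos = grid.index_to_phys(np.array([28, 7, 7]))
        ss = SpotSet(0.0, np.array([e]), np.array([-pos[0] * 0 + pos[1] * 0]),
                     np.array([pos[2]]), None)
        # beam along +x: u = y = 0 at this voxel, v = z
        ss = SpotSet(0.0, np.array([e]), np.array([0.0]), np.array([pos[2]]), None)
        out, info = optimize_robust(
            [ss], img, grid, table, target, {}, [Scenario("nominal")], rx,
            OptimizationSettings(), max_iter=400, strict=False,
        )
        unit_dose = calc.influence(ss)[0, 0]
        expected = rx.dose_per_fraction_gy / unit_dose
        assert out[0].weights[0] == pytest.approx(expected, rel=0.01)

    def test_zero_prescription_gives_zero_weights(self, table):
        grid, img, target = self._water_setup(table)
        ss = place_spots(target, img, grid, 0.0, table)
        rx0 = Prescription(dose_per_fraction_gy=0.0)
        out, _ = optimize_robust([ss], img, grid, table, target, {},
                                 [Scenario("nominal")], rx0, OptimizationSettings())
        assert np.all(out[0].weights == 0.0)

    def test_objective_monotone_descent(self, small_robust_plan):
        hist = small_robust_plan.info["objective_history"]
        assert all(hist[i + 1] <= hist[i] + 1e-12 for i in range(len(hist) - 1))

    def test_robust_beats_nominal_on_worst_case_coverage(
        self, small_phantom, small_plan, small_robust_plan, table, rx
    ):
        """The robust plan's worst-case-scenario D95 must not be worse than
        the nominal-only plan's (the point of robust optimization)."""
        ph = small_phantom
        scenarios = scenario_set(3.0, 0.035)
        target = ph.masks["itv"]
        overrides = [(target, 70.0)]

        def worst_d95(plan):
            vals = []
            for sc in scenarios:
                A = _stack_influence(plan.spotsets, ph.reference, ph.grid, table,
                                     target, overrides, sc)
                w = np.concatenate([s.weights for s in plan.spotsets])
                d = A @ w.astype(np.float32)
                vals.append(dose_percentile(d, 95.0) / rx.dose_per_fraction_gy * 100)
            return min(vals)

        assert worst_d95(small_robust_plan) >= worst_d95(small_plan) - 0.5

    def test_infeasible_when_no_spot_reaches_target(self, table, rx):
        grid, img, target = self._water_setup(table)
        # spot laterally far from the target: effectively zero influence
        ss = SpotSet(0.0, np.array([5]), np.array([1e4]), np.array([1e4]), None)
        from posture4d.planning import OptimizationError

        with pytest.raises(OptimizationError):
            optimize_robust([ss], img, grid, table, target, {},
                            [Scenario("nominal")], rx, OptimizationSettings())


class TestAngleSelection:
    def test_catalog_inclination_filter(self):
        cat = AngleCatalog()
        allowed = cat.within_vertical_inclination(45.0)
        assert set(allowed) == {45.0, 90.0, 135.0, 225.0, 270.0, 315.0}
        assert 0.0 not in allowed and 180.0 not in allowed

    def test_best_pair_dominance(self):
        rows = [
            {"angle1": 90.0, "angle2": 270.0, "d95_pct": 97.0,
             "v16_lung_pct": 5.0, "v20_heart_pct": 1.0},
            {"angle1": 45.0, "angle2": 135.0, "d95_pct": 97.5,
             "v16_lung_pct": 9.0, "v20_heart_pct": 4.0},
        ]
        pair, ok = _best_pair(rows)
        assert pair == (90.0, 270.0) and ok

    def test_best_pair_tie_break_lower_angle_sum(self):
        rows = [
            {"angle1": 225.0, "angle2": 315.0, "d95_pct": 96.0,
             "v16_lung_pct": 5.0, "v20_heart_pct": 2.0},
            {"angle1": 90.0, "angle2": 270.0, "d95_pct": 96.0,
             "v16_lung_pct": 5.0, "v20_heart_pct": 2.0},
        ]
        pair, ok = _best_pair(rows)
        assert pair == (90.0, 270.0) and ok

    def test_best_pair_flags_no_coverage(self):
        rows = [
            {"angle1": 90.0, "angle2": 270.0, "d95_pct": 80.0,
             "v16_lung_pct": 5.0, "v20_heart_pct": 1.0},
            {"angle1": 45.0, "angle2": 135.0, "d95_pct": 88.0,
             "v16_lung_pct": 2.0, "v20_heart_pct": 0.0},
        ]
        pair, ok = _best_pair(rows)
        assert not ok
        assert pair == (45.0, 135.0)  # best coverage, flagged non-acceptable

    def test_protocol_runs_and_audits_all_pairs(self, small_pair, table, rx):
        from posture4d.planning import select_angles

        pairs = [(225.0, 315.0), (90.0, 270.0)]
        fixed = [(0.0, 90.0), (225.0, 315.0), (90.0, 270.0)]
        sel = select_angles(
            small_pair, table, rx, candidate_pairs=pairs, fixed_pairs=fixed,
            settings=OptimizationSettings(quick_iter=60),
        )
        # both candidate pairs evaluated for supine and upright 360 steps
        for step in ("supine_360", "upright_360"):
            sub = sel.audit[sel.audit["step"] == step]
            assert len(sub) == len(pairs)
        assert sel.supine_pair in pairs
        assert sel.upright_pair in pairs
        fb = sel.audit[sel.audit["step"] == "supine_fixed_beamline"]
        assert len(fb) == len(fixed)
        assert sel.fixed_beamline_pair in fixed
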