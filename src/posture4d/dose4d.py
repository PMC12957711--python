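"""4D dose computation: motion-averaged (interplay-free) doses, D4D
(interplay-considering) doses, fraction-course sampling and convergence.

The "4D dose" is the phase-weighted average of the full plan's dose computed
on each breathing phase and accumulated on the reference phase via the
phantom's ground-truth deformation fields (uniform 1/10 weights: phases are
equal time bins under time-based sorting).  The "D4D dose" additionally
models the interplay between the scanning delivery timeline and the motion:
each spot is assigned the breathing phase active at its delivery start time,
per-phase partial plans are computed on that phase's geometry, warped to the
reference, and summed.

Dose warping is pull-back trilinear interpolation: with the ground-truth
field in the synthesis convention ``phase(x) = ref(x + w(x))``, the dose on
the reference grid is ``dose_ref(y) = dose_phase(y + w^{-1}(y))`` with the
inverse obtained by fixed-point iteration (cached per phantom and phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .breathing import BreathingTrajectory, phase_at_time
from .dose import DepthDoseTable, DoseDistribution, FieldDoseCalculator, SpotSet
from .phantom import Phantom4D, apply_deformation, invert_dvf, warp_mask
from .planning import ITV_OVERRIDE_HU, Plan, Scenario

__all__ = [
    "dose_4d_average",
    "interplay_dose",
    "D4DEngine",
    "CourseSample",
    "sample_course",
    "convergence_speed",
]


def _eval_roi(phantom: Phantom4D) -> np.ndarray:
    """Evaluation region: body dilated to keep warped dose inside."""
    return ndimage.binary_dilation(phantom.masks["body"], iterations=3)


def _inverse_dvf(phantom: Phantom4D, phase: int) -> np.ndarray:
    cache = getattr(phantom, "_inv_dvf_cache", None)
    if cache is None:
        cache = {}
        phantom._inv_dvf_cache = cache
    if phase not in cache:
        if phantom.phase_scale[phase] == 0.0:
            cache[phase] = np.zeros(tuple(phantom.grid.shape) + (3,), dtype=np.float32)
        else:
            cache[phase] = invert_dvf(phantom.dvf(phase), phantom.grid, n_iter=5)
    return cache[phase]


def accumulate_to_reference(dose_phase: np.ndarray, phantom: Phantom4D, phase: int) -> np.ndarray:
    """Warp a phase dose onto the reference phase geometry."""
    if phantom.phase_scale[phase] == 0.0:
        return dose_phase
    inv = _inverse_dvf(phantom, phase)
    return apply_deformation(dose_phase.astype(np.float32), inv, phantom.grid, cval=0.0)


class D4DEngine:
    """Caching 4D dose engine for one plan on one phantom.

    Precomputes per (phase, field) dose calculators (beam-frame WEPL volumes
    and voxel beam coordinates) lazily and reuses them across the 10 starting
    phases x 2 periods sweep, so a delivery sweep costs little more than one
    full 4D dose computation.  The ITV density override follows the anatomy:
    on each phase the override is applied to the ITV mask warped into that
    phase's geometry.
    """

    def __init__(
        self,
        plan: Plan,
        phantom: Phantom4D,
        table: DepthDoseTable,
        scenario: Scenario | None = None,
        roi_mask: np.ndarray | None = None,
    ) -> None:
        self.plan = plan
        self.phantom = phantom
        self.table = table
        self.scenario = scenario or Scenario("nominal")
        self.roi = _eval_roi(phantom) if roi_mask is None else roi_mask
        self._calcs: dict[tuple[int, int], FieldDoseCalculator] = {}

    def _calc(self, phase: int, field_idx: int) -> FieldDoseCalculator:
        key = (phase, field_idx)
        if key not in self._calcs:
            ph = self.phantom
            itv_phase = (
                ph.masks["itv"]
                if ph.phase_scale[phase] == 0.0
                else warp_mask(ph.masks["itv"], ph.dvf(phase), ph.grid)
            )
            self._calcs[key] = FieldDoseCalculator(
                ph.phase_image(phase),
                ph.grid,
                self.plan.spotsets[field_idx].angle_deg,
                self.table,
                overrides=[(itv_phase, ITV_OVERRIDE_HU)],
                roi_mask=self.roi,
                setup_shift_mm=np.asarray(self.scenario.shift_mm),
                rsp_scale=self.scenario.rsp_scale,
            )
        return self._calcs[key]

    def phase_dose(self, phase: int, spot_subsets: list[np.ndarray] | None = None) -> np.ndarray:
        """Dose of (a subset of) the plan on one phase geometry."""
        dose = np.zeros(self.phantom.grid.shape, dtype=np.float64)
        for fi, ss in enumerate(self.plan.spotsets):
            if spot_subsets is not None:
                sel = spot_subsets[fi]
                if sel.size == 0:
                    continue
                sub = SpotSet(ss.angle_deg, ss.energy_idx[sel], ss.u_mm[sel], ss.v_mm[sel],
                              ss.weights[sel])
            else:
                sub = ss
            dose += self._calc(phase, fi).dose_volume(sub)
        return dose

    def dose_4d_average(self, phase_weights: np.ndarray | None = None) -> DoseDistribution:
        ph = self.phantom
        n = ph.n_phases
        if phase_weights is None:
            phase_weights = np.full(n, 1.0 / n)
        phase_weights = np.asarray(phase_weights, dtype=float)
        if len(phase_weights) != n:
            raise ValueError("need one weight per phase")
        total = np.zeros(ph.grid.shape, dtype=np.float64)
        for p in range(n):
            if phase_weights[p] == 0.0:
                continue
            total += phase_weights[p] * accumulate_to_reference(self.phase_dose(p), ph, p)
        return DoseDistribution(
            total, ph.grid, geometry=f"{ph.posture}/reference",
            provenance={"kind": "4d_average", "scenario": self.scenario.label},
        )

    def interplay_dose(self, timeline, traj: BreathingTrajectory) -> DoseDistribution:
        ph = self.phantom
        spot_phase = phase_at_time(timeline.spots["start_s"].to_numpy(), traj, ph.n_phases)
        field_arr = timeline.spots["field"].to_numpy()
        index_arr = timeline.spots["spot_index"].to_numpy()
        total = np.zeros(ph.grid.shape, dtype=np.float64)
        for p in np.unique(spot_phase):
            subsets = [
                index_arr[(field_arr == fi) & (spot_phase == p)]
                for fi in range(len(self.plan.spotsets))
            ]
            total += accumulate_to_reference(self.phase_dose(int(p), subsets), ph, int(p))
        return DoseDistribution(
            total, ph.grid, geometry=f"{ph.posture}/reference",
            provenance={
                "kind": "d4d", "scenario": self.scenario.label,
                "start_phase": float(traj.start_phase), "period_s": traj.period_s,
            },
        )


def dose_4d_average(
    plan: Plan,
    phantom: Phantom4D,
    table: DepthDoseTable,
    scenario: Scenario | None = None,
    phase_weights: np.ndarray | None = None,
    static: bool = False,
) -> DoseDistribution:
    """Motion-averaged 4D dose accumulated on the reference phase.

    With ``static=True`` only the reference phase is evaluated (a plain 3D
    dose under the given scenario).
    """
    eng = D4DEngine(plan, phantom, table, scenario=scenario)
    if static:
        dose = eng.phase_dose(phantom.reference_phase)
        return DoseDistribution(
            dose, phantom.grid, geometry=f"{phantom.posture}/reference",
            provenance={"kind": "static", "scenario": eng.scenario.label},
        )
    return eng.dose_4d_average(phase_weights)


def interplay_dose(
    plan: Plan,
    timeline,
    traj: BreathingTrajectory,
    phantom: Phantom4D,
    table: DepthDoseTable,
    scenario: Scenario | None = None,
) -> DoseDistribution:
    """One-shot D4D dose (see :class:`D4DEngine` for the sweeping API)."""
    return D4DEngine(plan, phantom, table, scenario=scenario).interplay_dose(timeline, traj)


# ---------------------------------------------------------------------------
# fraction-course sampling and convergence
# ---------------------------------------------------------------------------


@dataclass
class CourseSample:
    """A sampled treatment course: fraction indices into a pool of
    per-fraction D4D doses.  Cumulative doses are exact partial sums."""

    course_id: int
    seed: int
    fraction_indices: np.ndarray
    pool: list[DoseDistribution]

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_indices)

    def cumulative_dose(self, k: int | None = None) -> np.ndarray:
        """Sum of the first k fraction doses (all fractions if k is None)."""
        k = self.n_fractions if k is None else k
        if not 1 <= k <= self.n_fractions:
            raise ValueError(f"k must be in [1, {self.n_fractions}]")
        out = np.zeros_like(self.pool[0].dose)
        for i in self.fraction_indices[:k]:
            out = out + self.pool[i].dose
        return out

    def metric_series(self, metric_fn) -> np.ndarray:
        """metric_fn(cumulative_dose, k) evaluated for k = 1..n (incremental)."""
        acc = np.zeros_like(self.pool[0].dose)
        vals = []
        for k, i in enumerate(self.fraction_indices, start=1):
            acc = acc + self.pool[i].dose
            vals.append(metric_fn(acc, k))
        return np.asarray(vals)


def sample_course(
    pool: list[DoseDistribution],
    n_fractions: int = 20,
    n_courses: int = 4,
    seed: int = 0,
) -> list[CourseSample]:
    """Sample treatment courses by drawing fractions from the delivery pool
    with replacement (default: 4 courses of 20 fractions from the pool of
    20 = 10 starting phases x 2 periods single-fraction D4D doses)."""
    if len(pool) == 0:
        raise ValueError("empty delivery pool")
    rng = np.random.default_rng(seed)
    courses = []
    for c in range(n_courses):
        idx = rng.integers(0, len(pool), size=n_fractions)
        courses.append(CourseSample(c, seed, np.asarray(idx), pool))
    return courses


def convergence_speed(metric_by_fraction: np.ndarray, tol_pp: float = 1.0) -> int:
    """Number of fractions to reach the metric plateau: the smallest k
    (1-based) such that every value from fraction k onward lies within
    +/- ``tol_pp`` of the final value.  A series whose tail leaves its own
    band returns the series length (the plateau only begins at the end)."""
    series = np.asarray(metric_by_fraction, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("need a 1-D series of at least 2 values")
    final = series[-1]
    inside = np.abs(series - final) <= tol_pp
    k = len(series)
    for i in range(len(series) - 1, -1, -1):
        if inside[i]:
            k = i + 1
        else:
            break
    return k
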