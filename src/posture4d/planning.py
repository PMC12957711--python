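"""Treatment planning: spot placement, robustness scenarios, voxel-wise
robust spot-weight optimization, and the posture/angle-selection protocol.

Plans use two coplanar scanned-ion fields (clinical thoracic practice at the
emulated centre), optimized to deliver 3 GyRBE per fraction to the geometrical
ITV after a 70 HU density override, with voxel-wise robust optimization over
nine scenarios (nominal, +/-3 mm cardinal setup shifts, +/-3.5% range).
Target coverage is prioritized over lung and heart dose (the target penalty
outweighs the organ-at-risk penalties by two orders of magnitude).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import Grid
from .dose import DepthDoseTable, FieldDoseCalculator, SpotSet

__all__ = [
    "Prescription",
    "Scenario",
    "Plan",
    "AngleCatalog",
    "OptimizationSettings",
    "scenario_set",
    "place_spots",
    "optimize_robust",
    "select_angles",
    "make_plan",
]

ITV_OVERRIDE_HU = 70.0


@dataclass(frozen=True)
class Prescription:
    """Prescribed dose: 3 GyRBE/fraction x 20 fractions = 60 GyRBE by default."""

    dose_per_fraction_gy: float = 3.0
    n_fractions: int = 20
    target: str = "itv"

    def __post_init__(self) -> None:
        if self.dose_per_fraction_gy <= 0 and self.dose_per_fraction_gy != 0.0:
            raise ValueError("dose per fraction must be non-negative")
        if self.n_fractions < 1:
            raise ValueError("need at least one fraction")

    @property
    def total_gy(self) -> float:
        return self.dose_per_fraction_gy * self.n_fractions


@dataclass(frozen=True)
class Scenario:
    """One robustness scenario: rigid setup shift + global range (RSP) scaling."""

    label: str
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rsp_scale: float = 1.0

    @property
    def is_nominal(self) -> bool:
        return all(s == 0 for s in self.shift_mm) and self.rsp_scale == 1.0


def scenario_set(setup_mm: float = 3.0, range_pct: float = 0.035) -> list[Scenario]:
    """Nominal + cardinal setup shifts + range under/overshoot scenarios.

    The default (3 mm, 3.5%) yields the standard nine scenarios; (5 mm, 5%)
    is the conservative setting probed for upright positioning.  Degenerate
    settings collapse duplicates: (0, 0) returns the nominal scenario only.
    """
    if setup_mm < 0 or range_pct < 0:
        raise ValueError("uncertainty magnitudes must be non-negative")
    scenarios = [Scenario("nominal")]
    if setup_mm > 0:
        for axis, name in enumerate("xyz"):
            for sign, tag in ((1.0, "+"), (-1.0, "-")):
                shift = [0.0, 0.0, 0.0]
                shift[axis] = sign * setup_mm
                scenarios.append(Scenario(f"shift{tag}{name}", tuple(shift)))
    if range_pct > 0:
        # undershoot: denser tissue, beam stops short (RSP scaled up)
        scenarios.append(Scenario("undershoot", rsp_scale=1.0 + range_pct))
        scenarios.append(Scenario("overshoot", rsp_scale=1.0 - range_pct))
    return scenarios


@dataclass(frozen=True)
class OptimizationSettings:
    """Spot grid and optimizer parameters (deterministic, dependency-light)."""

    lateral_spacing_mm: float = 4.5
    lateral_margin_mm: float = 5.0
    #: extra proximal/distal range coverage so range scenarios stay compensable
    range_margin_mm: float = 6.0
    layer_halfwidth_mm: float = 3.0
    max_iter: int = 800
    tol: float = 1e-4
    target_weight: float = 1.0
    oar_weight: float = 0.01
    max_target_voxels: int = 4500
    max_oar_voxels: int = 2000
    quick_iter: int = 120


@dataclass
class Plan:
    """An optimized two-field plan for one posture."""

    posture: str
    spotsets: list[SpotSet]
    prescription: Prescription
    robust_setting: str = "3.5%/3mm"
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spotsets) == 0:
            raise ValueError("plan needs at least one field")

    @property
    def angles(self) -> tuple[float, ...]:
        return tuple(ss.angle_deg for ss in self.spotsets)

    @property
    def n_spots(self) -> int:
        return sum(ss.n_spots for ss in self.spotsets)

    @property
    def total_particles(self) -> float:
        return float(sum(ss.weights.sum() for ss in self.spotsets))

    def to_dict(self) -> dict:
        return {
            "posture": self.posture,
            "robust_setting": self.robust_setting,
            "prescription": {
                "dose_per_fraction_gy": self.prescription.dose_per_fraction_gy,
                "n_fractions": self.prescription.n_fractions,
                "target": self.prescription.target,
            },
            "fields": [
                {
                    "angle_deg": ss.angle_deg,
                    "energy_idx": ss.energy_idx.tolist(),
                    "u_mm": ss.u_mm.tolist(),
                    "v_mm": ss.v_mm.tolist(),
                    "weights": ss.weights.tolist(),
                }
                for ss in self.spotsets
            ],
        }


@dataclass(frozen=True)
class AngleCatalog:
    """Named beam angles (patient coordinate system, degrees)."""

    angles: dict = field(
        default_factory=lambda: {
            "vertical_ap": 90.0,
            "vertical_pa": 270.0,
            "horizontal_left": 0.0,
            "horizontal_right": 180.0,
            "oblique_ap_45": 45.0,
            "oblique_ap_135": 135.0,
            "oblique_pa_225": 225.0,
            "oblique_pa_315": 315.0,
        }
    )

    def __post_init__(self) -> None:
        for name, a in self.angles.items():
            if not 0 <= a < 360:
                raise ValueError(f"angle {name}={a} outside [0, 360)")

    def values(self) -> list[float]:
        return sorted(self.angles.values())

    def within_vertical_inclination(self, max_deg: float = 45.0) -> list[float]:
        """Angles within ``max_deg`` of a vertical (AP/PA) direction; steeper
        inclinations risk arms/shoulders in the beam path and are excluded."""
        out = []
        for a in self.values():
            d = min(abs(((a - v + 180) % 360) - 180) for v in (90.0, 270.0))
            if d <= max_deg + 1e-9:
                out.append(a)
        return out


# ---------------------------------------------------------------------------
# spot placement
# ---------------------------------------------------------------------------


def place_spots(
    target_mask: np.ndarray,
    image_hu: np.ndarray,
    grid: Grid,
    angle_deg: float,
    table: DepthDoseTable,
    settings: OptimizationSettings = OptimizationSettings(),
    overrides: list | None = None,
) -> SpotSet:
    """Raster-spot grid covering the target's beam's-eye-view footprint.

    Energy layers are chosen from the table's range ladder so their peaks span
    the target's WEPL interval; per layer, spots sit on a regular lateral grid
    (fixed lattice through the isocenter) covering the footprint of the target
    voxels belonging to that layer, expanded by the lateral margin.
    """
    from scipy.spatial import cKDTree

    if not target_mask.any():
        raise ValueError("cannot place spots on an empty target")
    if overrides is None:
        overrides = [(target_mask, ITV_OVERRIDE_HU)]
    calc = FieldDoseCalculator(
        image_hu, grid, angle_deg, table, overrides=overrides, roi_mask=target_mask
    )
    wepl = calc.wepl_at_voxels()
    u, v = calc._u, calc._v
    layers = table.layers_covering(
        max(float(wepl.min()) - settings.range_margin_mm, float(table.ranges[0])),
        float(wepl.max()) + settings.range_margin_mm,
    )

    sp = settings.lateral_spacing_mm
    margin = settings.lateral_margin_mm
    energy_out, u_out, v_out = [], [], []
    half_gap = max(settings.layer_halfwidth_mm, np.diff(table.ranges).max() / 2 + 0.5)
    for e in layers:
        R = table.peak_depth(int(e))
        sel = np.abs(wepl - R) <= half_gap
        if not sel.any():
            # range-margin layer beyond the target's WEPL span: reuse the
            # footprint of the nearest target voxels in depth
            sel = np.abs(wepl - np.clip(R, float(wepl.min()), float(wepl.max()))) <= half_gap
        if not sel.any():
            continue
        us, vs = u[sel], v[sel]
        tree = cKDTree(np.column_stack([us, vs]))
        gu = np.arange(np.floor((us.min() - margin) / sp), np.ceil((us.max() + margin) / sp) + 1) * sp
        gv = np.arange(np.floor((vs.min() - margin) / sp), np.ceil((vs.max() + margin) / sp) + 1) * sp
        uu, vv = np.meshgrid(gu, gv, indexing="ij")
        pts = np.column_stack([uu.ravel(), vv.ravel()])
        d, _ = tree.query(pts, k=1)
        keep = d <= margin
        for p in pts[keep]:
            energy_out.append(int(e))
            u_out.append(p[0])
            v_out.append(p[1])
    if not energy_out:
        raise ValueError("target outside beam reach: no spots placed")
    return SpotSet(angle_deg, np.array(energy_out), np.array(u_out), np.array(v_out))


# ---------------------------------------------------------------------------
# robust optimization
# ---------------------------------------------------------------------------


class OptimizationError(RuntimeError):
    pass


def _subsample(idx: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic stride subsampling of voxel indices."""
    if len(idx) <= cap:
        return idx
    stride = int(np.ceil(len(idx) / cap))
    return idx[::stride]


def _stack_influence(
    spotsets: list[SpotSet],
    image_hu: np.ndarray,
    grid: Grid,
    table: DepthDoseTable,
    roi: np.ndarray,
    overrides: list,
    scenario: Scenario,
) -> np.ndarray:
    cols = []
    for ss in spotsets:
        calc = FieldDoseCalculator(
            image_hu, grid, ss.angle_deg, table, overrides=overrides, roi_mask=roi,
            setup_shift_mm=np.asarray(scenario.shift_mm), rsp_scale=scenario.rsp_scale,
        )
        cols.append(calc.influence(ss))
    return np.concatenate(cols, axis=1)


def optimize_robust(
    spotsets: list[SpotSet],
    image_hu: np.ndarray,
    grid: Grid,
    table: DepthDoseTable,
    target_mask: np.ndarray,
    oar_masks: dict[str, np.ndarray],
    scenarios: list[Scenario],
    rx: Prescription,
    settings: OptimizationSettings = OptimizationSettings(),
    overrides: list | None = None,
    max_iter: int | None = None,
    strict: bool = True,
) -> tuple[list[SpotSet], dict]:
    """Voxel-wise worst-case robust spot-weight optimization.

    Minimizes, over non-negative weights ``w``::

        f(w) = wt/|T| * sum_{v in T} max_s (d_s(v; w) - p)^2
             + sum_O wo/|O| * sum_{v in O} d_nom(v; w)^2

    i.e. the per-voxel worst case over scenarios of the quadratic deviation
    from prescription in the target, plus quadratic organ-at-risk penalties on
    the nominal scenario, with the target weighted 100x over the OARs.
    Projected gradient descent with an adaptive step (monotone descent),
    deterministic given inputs.
    """
    if max_iter is None:
        max_iter = settings.max_iter
    if overrides is None:
        overrides = [(target_mask, ITV_OVERRIDE_HU)]
    p = rx.dose_per_fraction_gy
    n_spots = sum(ss.n_spots for ss in spotsets)

    t_idx = _subsample(np.argwhere(target_mask), settings.max_target_voxels)
    t_roi = np.zeros(grid.shape, dtype=bool)
    t_roi[tuple(t_idx.T)] = True

    A_scen = [
        _stack_influence(spotsets, image_hu, grid, table, t_roi, overrides, sc)
        for sc in scenarios
    ]
    A_nom = A_scen[next(i for i, sc in enumerate(scenarios) if sc.is_nominal)]
    if float(A_nom.sum()) <= 0:
        raise OptimizationError("infeasible: no spot reaches the target")

    A_oars = []
    for name, m in oar_masks.items():
        o_idx = _subsample(np.argwhere(m & ~target_mask), settings.max_oar_voxels)
        if len(o_idx) == 0:
            continue
        o_roi = np.zeros(grid.shape, dtype=bool)
        o_roi[tuple(o_idx.T)] = True
        A_oars.append(
            _stack_influence(spotsets, image_hu, grid, table, o_roi, overrides, Scenario("nominal"))
        )

    wt = settings.target_weight
    wo = settings.oar_weight
    p32 = np.float32(p)

    def objective_grad(w):
        w32 = w.astype(np.float32)
        resid = np.stack([A @ w32 - p32 for A in A_scen])  # (S, n_t)
        sq = resid**2
        s_star = np.argmax(sq, axis=0)
        n_t = sq.shape[1]
        f = wt * float(sq[s_star, np.arange(n_t)].mean())
        g = np.zeros(n_spots, dtype=np.float64)
        for s, A in enumerate(A_scen):
            sel = s_star == s
            if sel.any():
                g += (2.0 * wt / n_t) * (A[sel].T @ resid[s, sel]).astype(np.float64)
        for A in A_oars:
            d = A @ w32
            f += wo * float(np.mean(d**2))
            g += (2.0 * wo / A.shape[0]) * (A.T @ d).astype(np.float64)
        return f, g

    if p == 0.0:
        w = np.zeros(n_spots)
        history = [0.0]
    else:
        # initial guess: uniform weights scaled to the prescription (nominal scenario)
        from scipy import optimize as sopt

        ones = np.ones(n_spots)
        d1 = A_nom @ ones.astype(np.float32)
        denom = float(d1 @ d1)
        scale = p * float(d1.sum()) / denom if denom > 0 else 1.0
        scale = max(scale, 1e-12)
        # optimize in normalized units (x = w / scale, x0 = 1) so gradients
        # are O(1) regardless of the physical particle-number magnitude
        A_scen = [A * np.float32(scale) for A in A_scen]
        A_oars = [A * np.float32(scale) for A in A_oars]
        history = []
        last = {}

        def fg_cached(x):
            f, g = objective_grad(x)
            last["key"], last["f"] = x.tobytes(), f
            return f, g

        def on_iter(xk):
            history.append(last["f"] if last.get("key") == xk.tobytes() else objective_grad(xk)[0])

        res = sopt.minimize(
            fg_cached, ones, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * n_spots, callback=on_iter,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-14},
        )
        w = np.maximum(res.x, 0.0) * scale
        history = history or [float(res.fun)]
        # per-iteration relative decrease, averaged over the last iterations
        k = min(len(history) - 1, 10)
        rel = (
            abs(history[-1 - k] - history[-1]) / (k * max(abs(history[-1 - k]), 1e-30))
            if k > 0
            else 0.0
        )
        if not (res.success or res.status == 1):
            raise OptimizationError(f"optimizer failed (status {res.status}: {res.message})")
        if strict and res.status == 1 and rel > settings.tol:
            raise OptimizationError(
                f"no convergence within {max_iter} iterations "
                f"(mean relative change {rel:.2e} > {settings.tol:g})"
            )
    converged = True

    out, k = [], 0
    for ss in spotsets:
        out.append(ss.with_weights(w[k : k + ss.n_spots]))
        k += ss.n_spots
    info = {"objective_history": history, "iterations": len(history) - 1, "converged": converged}
    return out, info


def make_plan(
    posture: str,
    image_hu: np.ndarray,
    grid: Grid,
    table: DepthDoseTable,
    target_mask: np.ndarray,
    oar_masks: dict[str, np.ndarray],
    angles: tuple[float, float],
    rx: Prescription = Prescription(),
    scenarios: list[Scenario] | None = None,
    settings: OptimizationSettings = OptimizationSettings(),
    robust_setting: str = "3.5%/3mm",
    max_iter: int | None = None,
    strict: bool = True,
) -> Plan:
    """Place spots for each field and run the robust optimization."""
    overrides = [(target_mask, ITV_OVERRIDE_HU)]
    if scenarios is None:
        scenarios = scenario_set(3.0, 0.035)
    spotsets = [
        place_spots(target_mask, image_hu, grid, a, table, settings, overrides) for a in angles
    ]
    spotsets, info = optimize_robust(
        spotsets, image_hu, grid, table, target_mask, oar_masks, scenarios, rx,
        settings, overrides, max_iter=max_iter, strict=strict,
    )
    return Plan(posture, spotsets, rx, robust_setting=robust_setting, info=info)


# ---------------------------------------------------------------------------
# beam-angle selection protocol
# ---------------------------------------------------------------------------


@dataclass
class AngleSelection:
    """Outcome of the four-step posture/angle-selection protocol."""

    supine_pair: tuple[float, float]
    upright_supine_pair: tuple[float, float]
    upright_pair: tuple[float, float]
    fixed_beamline_pair: tuple[float, float]
    audit: pd.DataFrame
    acceptable: dict


def _pair_metrics(phantom, pair_angles, table, rx, settings) -> dict:
    """Quick nominal plan + coverage/OAR metrics for one candidate pair."""
    from .evaluation import dvh_metrics

    grid = phantom.grid
    img = phantom.reference
    target = phantom.masks["itv"]
    oars = {"lung": phantom.lungs, "heart": phantom.masks["heart"]}
    plan = make_plan(
        phantom.posture, img, grid, table, target, oars, pair_angles, rx,
        scenarios=[Scenario("nominal")], settings=settings,
        max_iter=settings.quick_iter, robust_setting="nominal-quick", strict=False,
    )
    from .dose import compute_dose

    roi = target | phantom.lungs | phantom.masks["heart"]
    dd = compute_dose(img, grid, plan.spotsets, table,
                      overrides=[(target, ITV_OVERRIDE_HU)], roi_mask=roi)
    m = dvh_metrics(dd, {"target": target, "lung": phantom.lungs, "heart": phantom.masks["heart"]}, rx)
    return {
        "angle1": pair_angles[0], "angle2": pair_angles[1],
        "d95_pct": m.d95_pct, "v95_pct": m.v95_pct,
        "v16_lung_pct": m.vx_gy_pct["lung"], "v20_heart_pct": m.vx_gy_pct["heart"],
    }


def _best_pair(rows: list[dict], coverage_pct: float = 95.0):
    """Pair minimizing V16Gy(lung), then V20Gy(heart), among pairs meeting the
    coverage requirement; ties broken by the lower angle sum.  If no pair
    meets coverage, the best-coverage pair is returned flagged non-acceptable."""
    ok = [r for r in rows if r["d95_pct"] >= coverage_pct]
    flag = len(ok) > 0
    pool = ok if flag else sorted(rows, key=lambda r: -r["d95_pct"])[:1]
    best = min(pool, key=lambda r: (round(r["v16_lung_pct"], 6), round(r["v20_heart_pct"], 6),
                                    r["angle1"] + r["angle2"]))
    return (best["angle1"], best["angle2"]), flag


def select_angles(
    pair,
    table: DepthDoseTable,
    rx: Prescription = Prescription(),
    catalog: AngleCatalog = AngleCatalog(),
    settings: OptimizationSettings = OptimizationSettings(),
    candidate_pairs: list[tuple[float, float]] | None = None,
    fixed_pairs: list[tuple[float, float]] | None = None,
    max_inclination_deg: float = 45.0,
) -> AngleSelection:
    """Four-step protocol: (1) optimal supine pair under gantry-like 360
    flexibility (within the vertical-inclination limit), (2) the same pair
    re-evaluated on the upright phantom, (3) upright-specific re-selection,
    (4) a fixed-beamline supine selection restricted to the
    vertical/horizontal/45-degree set.  Every evaluated pair and its metrics
    are returned for audit."""
    if candidate_pairs is None:
        allowed = catalog.within_vertical_inclination(max_inclination_deg)
        candidate_pairs = list(itertools.combinations(allowed, 2))
    if len(candidate_pairs) == 0:
        raise ValueError("no candidate angle pairs")

    rows = []

    def evaluate(phantom, pairs, step):
        out = []
        for pa in pairs:
            r = _pair_metrics(phantom, pa, table, rx, settings)
            r["step"] = step
            r["posture"] = phantom.posture
            rows.append(r)
            out.append(r)
        return out

    sup_rows = evaluate(pair.supine, candidate_pairs, "supine_360")
    supine_pair, sup_ok = _best_pair(sup_rows)

    up_same = evaluate(pair.upright, [supine_pair], "upright_supine_angles")
    _, up_same_ok = _best_pair(up_same)

    up_rows = evaluate(pair.upright, candidate_pairs, "upright_360")
    upright_pair, up_ok = _best_pair(up_rows)

    if fixed_pairs is None:
        fixed_angles = sorted({0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0})
        fixed_pairs = list(itertools.combinations(fixed_angles, 2))
    fixed_rows = evaluate(pair.supine, fixed_pairs, "supine_fixed_beamline")
    fixed_pair, fixed_ok = _best_pair(fixed_rows)

    return AngleSelection(
        supine_pair=supine_pair,
        upright_supine_pair=supine_pair,
        upright_pair=upright_pair,
        fixed_beamline_pair=fixed_pair,
        audit=pd.DataFrame(rows),
        acceptable={
            "supine_360": sup_ok,
            "upright_supine_angles": up_same_ok,
            "upright_360": up_ok,
            "supine_fixed_beamline": fixed_ok,
        },
    )
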