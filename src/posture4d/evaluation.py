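"""Plan-quality evaluation: DVHs, DVH metrics, robustness reporting and the
paired posture comparison statistic.

Metric conventions (all relative quantities in percent):

* ``D95`` — dose exceeded by 95% of the target volume, as % of prescription;
* ``V95`` — % of the target volume receiving >= 95% of prescription;
* ``HI = D5 - D95`` in percentage points of prescription (0 = homogeneous);
* ``VxGy`` — % of an organ-at-risk volume receiving >= x GyRBE *at full
  course scale* (V16Gy for whole lung, V20Gy for heart).

Dose-percentile metrics are computed by exact order statistics on the voxel
doses (no histogram interpolation), so acceptance checks carry no bin-width
sensitivity.  A plan is clinically acceptable when D95 > 95%, V95 > 95%,
HI < 5 pp, V20Gy(heart) < 10% and V16Gy(lung) < 30%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseDistribution
from .planning import Plan, Prescription, Scenario

__all__ = [
    "DVHMetrics",
    "AcceptanceRule",
    "dvh",
    "dose_percentile",
    "dvh_metrics",
    "robustness_report",
    "compare_postures",
    "PostureComparison",
]

DEFAULT_OAR_THRESHOLDS_GY = {"lung": 16.0, "heart": 20.0}


@dataclass(frozen=True)
class DVHMetrics:
    d95_pct: float
    d5_pct: float
    v95_pct: float
    hi_pp: float
    vx_gy_pct: dict = field(default_factory=dict)
    target_volume_cc: float = float("nan")

    def __post_init__(self) -> None:
        if self.d5_pct + 1e-9 < self.d95_pct:
            raise ValueError("D5 must be >= D95")


@dataclass(frozen=True)
class AcceptanceRule:
    """Clinical plan-acceptance thresholds (fixed constants)."""

    d95_min_pct: float = 95.0
    v95_min_pct: float = 95.0
    hi_max_pp: float = 5.0
    v20_heart_max_pct: float = 10.0
    v16_lung_max_pct: float = 30.0

    def check(self, m: DVHMetrics) -> dict:
        out = {
            "d95": m.d95_pct > self.d95_min_pct,
            "v95": m.v95_pct > self.v95_min_pct,
            "hi": m.hi_pp < self.hi_max_pp,
        }
        if "heart" in m.vx_gy_pct:
            out["v20_heart"] = m.vx_gy_pct["heart"] < self.v20_heart_max_pct
        if "lung" in m.vx_gy_pct:
            out["v16_lung"] = m.vx_gy_pct["lung"] < self.v16_lung_max_pct
        out["all"] = all(out.values())
        return out


def dvh(dose: DoseDistribution | np.ndarray, mask: np.ndarray, bin_width_gy: float = 0.05):
    """Cumulative DVH: (dose edges in GyRBE, % volume receiving >= edge)."""
    d = dose.dose if isinstance(dose, DoseDistribution) else dose
    if not mask.any():
        raise ValueError("empty structure mask")
    vals = np.asarray(d[mask], dtype=float)
    edges = np.arange(0.0, vals.max() + 2 * bin_width_gy, bin_width_gy)
    vol = np.array([(vals >= e).mean() * 100.0 for e in edges])
    return edges, vol


def dose_percentile(voxel_doses: np.ndarray, p: float) -> float:
    """D_p: the largest dose received by at least p% of the voxels (exact
    order statistic: with n voxels, the ceil(p/100 * n)-th highest dose)."""
    vals = np.sort(np.asarray(voxel_doses, dtype=float))[::-1]
    n = len(vals)
    if n == 0:
        raise ValueError("no voxels")
    k = int(np.ceil(p / 100.0 * n))
    k = min(max(k, 1), n)
    return float(vals[k - 1])


def dvh_metrics(
    dose: DoseDistribution,
    structures: dict[str, np.ndarray],
    rx: Prescription,
    dose_scale: str = "fraction",
    oar_thresholds_gy: dict[str, float] | None = None,
) -> DVHMetrics:
    """DVH metrics of a dose distribution.

    ``dose_scale`` names the scale the dose array is on: "fraction" doses are
    compared to the per-fraction prescription and linearly scaled to the full
    course for the VxGy organ thresholds; "course" doses are used as-is.
    """
    if "target" not in structures or not structures["target"].any():
        raise ValueError("a non-empty 'target' structure is required")
    if dose_scale not in ("fraction", "course"):
        raise ValueError("dose_scale must be 'fraction' or 'course'")
    p_ref = rx.dose_per_fraction_gy if dose_scale == "fraction" else rx.total_gy
    if p_ref <= 0:
        raise ValueError("prescription must be positive for relative metrics")
    course_factor = rx.n_fractions if dose_scale == "fraction" else 1.0
    thresholds = dict(DEFAULT_OAR_THRESHOLDS_GY)
    if oar_thresholds_gy:
        thresholds.update(oar_thresholds_gy)

    tvals = dose.dose[structures["target"]]
    d95 = dose_percentile(tvals, 95.0) / p_ref * 100.0
    d5 = dose_percentile(tvals, 5.0) / p_ref * 100.0
    v95 = float((tvals >= 0.95 * p_ref).mean() * 100.0)
    vx = {}
    for name, m in structures.items():
        if name == "target":
            continue
        if not m.any():
            raise ValueError(f"empty structure mask: {name}")
        thr = thresholds.get(name)
        if thr is None:
            continue
        vx[name] = float((dose.dose[m] * course_factor >= thr).mean() * 100.0)
    vol_cc = float(structures["target"].sum()) * dose.grid.voxel_volume_cc
    return DVHMetrics(d95, d5, v95, d5 - d95, vx, vol_cc)


def robustness_report(
    plan: Plan,
    phantom,
    table,
    settings: list[list[Scenario]],
    mode: str = "4d",
):
    """Per-scenario DVH metrics and pass/fail for one or more scenario sets.

    Scenario doses are the motion-averaged ("interplay-free") 4D doses by
    default, recomputed under each scenario's setup shift / range scaling;
    ``mode="static"`` evaluates on the reference phase only (faster).
    Pass requires D95 and V95 above 95%.
    """
    import pandas as pd

    from .dose4d import dose_4d_average

    rows = []
    structures = {
        "target": phantom.masks["itv"],
        "lung": phantom.lungs,
        "heart": phantom.masks["heart"],
    }
    for si, scenario_list in enumerate(settings):
        setting_label = f"setting_{si}"
        for sc in scenario_list:
            dd = dose_4d_average(plan, phantom, table, scenario=sc, static=(mode == "static"))
            m = dvh_metrics(dd, structures, plan.prescription)
            rows.append(
                {
                    "setting": setting_label,
                    "scenario": sc.label,
                    "d95_pct": m.d95_pct,
                    "d5_pct": m.d5_pct,
                    "v95_pct": m.v95_pct,
                    "hi_pp": m.hi_pp,
                    "v16_lung_pct": m.vx_gy_pct.get("lung", np.nan),
                    "v20_heart_pct": m.vx_gy_pct.get("heart", np.nan),
                    "pass": bool(m.d95_pct > 95.0 and m.v95_pct > 95.0),
                }
            )
    return pd.DataFrame(rows)


def plot_dvh(
    dose: DoseDistribution,
    structures: dict[str, np.ndarray],
    path: str | None = None,
    bin_width_gy: float = 0.05,
):
    """Cumulative DVH plot, one curve per structure (optional output file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, mask in structures.items():
        edges, vol = dvh(dose, mask, bin_width_gy)
        ax.plot(edges, vol, label=name)
    ax.set_xlabel("dose (GyRBE)")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass(frozen=True)
class PostureComparison:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool
    summary: dict


def compare_postures(metric_a: np.ndarray, metric_b: np.ndarray, alpha: float = 0.05) -> PostureComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-delivery metrics.

    Pairs must share the delivery condition (starting phase, period).
    Zero-difference pairs are dropped, as in the classic Wilcoxon procedure;
    if every pair is identical the data are degenerate and p is reported as 1.
    The exact null distribution is used for n <= 25 (no ties), the normal
    approximation above.
    """
    from scipy import stats

    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    diff = a - b
    nz = diff[diff != 0.0]
    summary = {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        "n_pairs": int(len(a)), "n_nonzero": int(len(nz)),
    }
    if len(nz) == 0:
        return PostureComparison(0.0, 1.0, False, True, summary)
    method = "exact" if len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return PostureComparison(
        float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha), False, summary
    )
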