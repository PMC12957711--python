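"""End-to-end upright/supine comparison pipeline.

Orchestrates the full study on a synthetic phantom pair: phantom generation,
ROI-restricted registration with contour-propagation QA, per-posture robust
planning (including the angle-selection protocol and a fixed-beamline
variant), robustness analysis at the standard and conservative uncertainty
settings, the interplay (D4D) delivery sweep over 10 starting phases x 2
breathing periods, fraction-course sampling with convergence analysis, and
the paired statistical posture comparison.

Every stage is a pure function of the run configuration and the master seed;
stage sub-seeds are derived by hashing the stage name, so reruns are
bit-identical and stages remain independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breathing import BreathingTrajectory
from .delivery import AcceleratorModel, simulate_timeline
from .dose import DepthDoseTable, compute_dose
from .dose4d import D4DEngine, convergence_speed, sample_course
from .evaluation import (
    AcceptanceRule,
    compare_postures,
    dose_percentile,
    dvh_metrics,
    robustness_report,
)
from .phantom import PhantomConfig, generate_phantom_pair
from .planning import (
    ITV_OVERRIDE_HU,
    OptimizationSettings,
    Prescription,
    make_plan,
    scenario_set,
    select_angles,
)
from .registration import (
    RegistrationParams,
    build_ribcage_roi,
    contour_qa,
    propagate_contour,
    register_roi_restricted,
)

__all__ = ["RunConfig", "run_comparison", "stage_seed"]

log = logging.getLogger("posture4d")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Full study configuration; the master seed fixes every stochastic choice."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    optimization: OptimizationSettings = field(default_factory=OptimizationSettings)
    accelerator: AcceleratorModel = field(default_factory=AcceleratorModel)
    prescription: Prescription = field(default_factory=Prescription)
    #: explicit two-field angles per posture; None runs the selection protocol
    angles_supine: tuple[float, float] | None = (225.0, 315.0)
    angles_upright: tuple[float, float] | None = (225.0, 315.0)
    run_angle_protocol: bool = False
    robust_setup_mm: float = 3.0
    robust_range_pct: float = 0.035
    conservative_setup_mm: float = 5.0
    conservative_range_pct: float = 0.05
    robustness_mode: str = "4d"  # or "static"
    periods_s: tuple[float, ...] = (5.0, 10.0)
    n_start_phases: int = 10
    n_fractions: int = 20
    n_courses: int = 4
    master_seed: int = 1234
    out_dir: str = "posture4d_run"

    def __post_init__(self) -> None:
        if isinstance(self.phantom, dict):
            self.phantom = PhantomConfig(**self.phantom)
        if isinstance(self.registration, dict):
            self.registration = RegistrationParams(**self.registration)
        if isinstance(self.optimization, dict):
            self.optimization = OptimizationSettings(**self.optimization)
        if isinstance(self.accelerator, dict):
            self.accelerator = AcceleratorModel(**self.accelerator)
        if isinstance(self.prescription, dict):
            self.prescription = Prescription(**self.prescription)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("angles_supine", "angles_upright", "periods_s"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key, sub in (("phantom", PhantomConfig),):
            if key in d and isinstance(d[key], dict):
                for tup in ("shape", "spacing_supine", "spacing_upright",
                            "target_offset_frac", "heart_shift_upright_mm"):
                    if tup in d[key] and d[key][tup] is not None:
                        d[key][tup] = tuple(d[key][tup])
        for tupkey in ("shrink_factors", "smoothing_sigmas_mm", "iterations"):
            if isinstance(d.get("registration"), dict) and tupkey in d["registration"]:
                d["registration"][tupkey] = tuple(d["registration"][tupkey])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _timer(name):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *a):
            log.info("stage %s: done in %.1f s", name, time.time() - self.t0)

    return _T()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_phantom(cfg: RunConfig):
    with _timer("phantom"):
        pcfg = dataclasses.replace(cfg.phantom, seed=stage_seed(cfg.master_seed, "phantom"))
        return generate_phantom_pair(pcfg)


def stage_registration(cfg: RunConfig, pair):
    """Supine -> upright DIR restricted to the ribcage ROI, with QA."""
    with _timer("registration"):
        sup, up = pair.supine, pair.upright
        roi_up = build_ribcage_roi(up.masks, up.grid)
        roi_sup = build_ribcage_roi(sup.masks, sup.grid)
        dvf = register_roi_restricted(
            up.reference, up.grid, sup.reference, sup.grid, roi_up, roi_sup,
            cfg.registration,
        )
        rows = []
        for name in ("lung_left", "lung_right", "heart", "itv"):
            prop = propagate_contour(sup.masks[name], dvf, sup.grid, up.grid)
            qa = contour_qa(prop, up.masks[name], up.grid)
            rows.append({"structure": name, "dsc": qa.dsc, "ahd_mm": qa.ahd_mm,
                         "com_distance_mm": qa.com_distance_mm,
                         "volume_diff_pct": qa.volume_diff_pct})
        lung_prop = propagate_contour(sup.lungs, dvf, sup.grid, up.grid)
        qa_lung = contour_qa(lung_prop, up.lungs, up.grid)
        rows.append({"structure": "lung_total", "dsc": qa_lung.dsc, "ahd_mm": qa_lung.ahd_mm,
                     "com_distance_mm": qa_lung.com_distance_mm,
                     "volume_diff_pct": qa_lung.volume_diff_pct})
        # ground-truth endpoint error inside the ROI
        epe = np.linalg.norm(dvf - pair.inter_posture_dvf, axis=-1)[roi_up]
        return {"dvf": dvf, "qa": pd.DataFrame(rows), "mean_epe_mm": float(epe.mean()),
                "roi_upright": roi_up, "roi_supine": roi_sup}


def stage_planning(cfg: RunConfig, pair, table: DepthDoseTable):
    """Per-posture robust plans (+ optional angle protocol, + fixed-beamline
    supine variant)."""
    with _timer("planning"):
        scenarios = scenario_set(cfg.robust_setup_mm, cfg.robust_range_pct)
        out = {}
        if cfg.run_angle_protocol:
            sel = select_angles(pair, table, cfg.prescription, settings=cfg.optimization)
            angles = {"supine": sel.supine_pair, "upright": sel.upright_pair}
            out["angle_selection"] = sel
            fixed_pair_angles = sel.fixed_beamline_pair
        else:
            angles = {"supine": cfg.angles_supine, "upright": cfg.angles_upright}
            fixed_pair_angles = cfg.angles_supine
        for ph in (pair.supine, pair.upright):
            out[ph.posture] = make_plan(
                ph.posture, ph.reference, ph.grid, table, ph.masks["itv"],
                {"lung": ph.lungs, "heart": ph.masks["heart"]},
                angles[ph.posture], cfg.prescription, scenarios, cfg.optimization,
                robust_setting=f"{cfg.robust_range_pct:.1%}/{cfg.robust_setup_mm:g}mm",
            )
        out["supine_fixed_beamline"] = dataclasses.replace(
            out["supine"]) if fixed_pair_angles == angles["supine"] else make_plan(
            "supine", pair.supine.reference, pair.supine.grid, table,
            pair.supine.masks["itv"],
            {"lung": pair.supine.lungs, "heart": pair.supine.masks["heart"]},
            fixed_pair_angles, cfg.prescription, scenarios, cfg.optimization,
            robust_setting="fixed-beamline",
        )
        return out


def _static_metrics(plan, phantom, table, rx):
    dd = compute_dose(
        phantom.reference, phantom.grid, plan.spotsets, table,
        overrides=[(phantom.masks["itv"], ITV_OVERRIDE_HU)], roi_mask=phantom.masks["body"],
        geometry=f"{phantom.posture}/reference", provenance={"kind": "static-nominal"},
    )
    return dvh_metrics(
        dd, {"target": phantom.masks["itv"], "lung": phantom.lungs,
             "heart": phantom.masks["heart"]}, rx,
    )


def stage_robustness(cfg: RunConfig, pair, plans, table):
    with _timer("robustness"):
        settings = [
            scenario_set(cfg.robust_setup_mm, cfg.robust_range_pct),
            scenario_set(cfg.conservative_setup_mm, cfg.conservative_range_pct),
        ]
        frames = []
        for ph in (pair.supine, pair.upright):
            df = robustness_report(plans[ph.posture], ph, table, settings,
                                   mode=cfg.robustness_mode)
            df.insert(0, "posture", ph.posture)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def stage_delivery_sweep(cfg: RunConfig, pair, plans, table):
    """20 D4D doses per posture (10 starting phases x 2 periods) plus the
    motion-averaged 4D dose, with per-delivery DVH metrics."""
    with _timer("d4d_sweep"):
        rx = cfg.prescription
        results = {}
        for ph in (pair.supine, pair.upright):
            plan = plans[ph.posture]
            timeline = simulate_timeline(plan, cfg.accelerator)
            engine = D4DEngine(plan, ph, table)
            structures = {"target": ph.masks["itv"], "lung": ph.lungs,
                          "heart": ph.masks["heart"]}
            pool, rows = [], []
            for period in cfg.periods_s:
                for sp in range(cfg.n_start_phases):
                    traj = BreathingTrajectory(period_s=period, start_phase=sp)
                    dd = engine.interplay_dose(timeline, traj)
                    dd.dose = dd.dose.astype(np.float32)
                    pool.append(dd)
                    m = dvh_metrics(dd, structures, rx)
                    rows.append({
                        "posture": ph.posture, "period_s": period, "start_phase": sp,
                        "d95_pct": m.d95_pct, "hi_pp": m.hi_pp, "v95_pct": m.v95_pct,
                        "v16_lung_pct": m.vx_gy_pct["lung"],
                        "v20_heart_pct": m.vx_gy_pct["heart"],
                    })
            avg = engine.dose_4d_average()
            m4d = dvh_metrics(avg, structures, rx)
            results[ph.posture] = {
                "pool": pool, "metrics": pd.DataFrame(rows), "dose_4d": avg,
                "metrics_4d": m4d, "timeline": timeline,
                "delivery_time_s": timeline.total_time_s,
            }
        return results


def stage_courses(cfg: RunConfig, pair, sweep, table):
    with _timer("courses"):
        rx = cfg.prescription
        out = {}
        for ph in (pair.supine, pair.upright):
            pool = sweep[ph.posture]["pool"]
            courses = sample_course(
                pool, cfg.n_fractions, cfg.n_courses,
                seed=stage_seed(cfg.master_seed, f"courses/{ph.posture}"),
            )
            itv = ph.masks["itv"]
            rows = []
            for c in courses:
                def d95_series(acc, k):
                    return dose_percentile(acc[itv], 95.0) / (k * rx.dose_per_fraction_gy) * 100.0

                def hi_series(acc, k):
                    ref = k * rx.dose_per_fraction_gy
                    return (dose_percentile(acc[itv], 5.0) - dose_percentile(acc[itv], 95.0)) / ref * 100.0

                s_d95 = c.metric_series(d95_series)
                s_hi = c.metric_series(hi_series)
                rows.append({
                    "posture": ph.posture, "course": c.course_id,
                    "final_d95_pct": s_d95[-1], "final_hi_pp": s_hi[-1],
                    "conv_d95_fractions": convergence_speed(s_d95),
                    "conv_hi_fractions": convergence_speed(s_hi),
                    "total_dose_gy": float(np.max(c.cumulative_dose()[itv])),
                    "d95_series": s_d95.tolist(), "hi_series": s_hi.tolist(),
                })
            out[ph.posture] = pd.DataFrame(rows)
        return out


def stage_compare(cfg: RunConfig, sweep):
    with _timer("compare"):
        sup = sweep["supine"]["metrics"].sort_values(["period_s", "start_phase"])
        up = sweep["upright"]["metrics"].sort_values(["period_s", "start_phase"])
        report = {}
        for metric in ("d95_pct", "hi_pp", "v95_pct", "v16_lung_pct", "v20_heart_pct"):
            cmp = compare_postures(sup[metric].to_numpy(), up[metric].to_numpy())
            report[metric] = {
                "statistic": cmp.statistic, "p_value": cmp.p_value,
                "significant": cmp.significant, "degenerate": cmp.degenerate,
                **cmp.summary,
            }
        return report


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_comparison(cfg: RunConfig, table: DepthDoseTable | None = None) -> dict:
    """Execute the full comparison pipeline and write all artifacts.

    Returns a report bundle (also serialized under ``cfg.out_dir``):
    registration QA, per-posture static/4D/D4D metrics, robustness tables,
    course convergence and the paired posture statistics.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        table = table or DepthDoseTable.default()
        cfg.save(out / "config.yaml")

        pair = stage_phantom(cfg)
        reg = stage_registration(cfg, pair)
        reg["qa"].to_csv(out / "registration_qa.csv", index=False)

        plans = stage_planning(cfg, pair, table)
        for key in ("supine", "upright", "supine_fixed_beamline"):
            (out / f"plan_{key}.json").write_text(json.dumps(plans[key].to_dict()))

        rule = AcceptanceRule()
        static = {}
        for ph in (pair.supine, pair.upright):
            m = _static_metrics(plans[ph.posture], ph, table, cfg.prescription)
            static[ph.posture] = {
                "d95_pct": m.d95_pct, "hi_pp": m.hi_pp, "v95_pct": m.v95_pct,
                "v16_lung_pct": m.vx_gy_pct["lung"], "v20_heart_pct": m.vx_gy_pct["heart"],
                "acceptance": rule.check(m),
            }

        robust = stage_robustness(cfg, pair, plans, table)
        robust.to_csv(out / "robustness.csv", index=False)

        sweep = stage_delivery_sweep(cfg, pair, plans, table)
        d4d_rows = pd.concat(
            [sweep[p]["metrics"] for p in ("supine", "upright")], ignore_index=True
        )
        d4d_rows.to_csv(out / "d4d_metrics.csv", index=False)

        courses = stage_courses(cfg, pair, sweep, table)
        pd.concat([courses[p] for p in ("supine", "upright")], ignore_index=True).drop(
            columns=["d95_series", "hi_series"]
        ).to_csv(out / "courses.csv", index=False)

        comparison = stage_compare(cfg, sweep)

        report = {
            "config": cfg.to_dict(),
            "registration": {
                "qa": reg["qa"].to_dict(orient="records"),
                "mean_epe_mm": reg["mean_epe_mm"],
            },
            "static_metrics": static,
            "robustness_pass_rate": {
                posture: float(robust[robust["posture"] == posture]["pass"].mean())
                for posture in ("supine", "upright")
            },
            "d4d_summary": {
                posture: {
                    "n_deliveries": int(len(sweep[posture]["metrics"])),
                    "delivery_time_s": sweep[posture]["delivery_time_s"],
                    "d95_mean_pct": float(sweep[posture]["metrics"]["d95_pct"].mean()),
                    "d95_sd_pp": float(sweep[posture]["metrics"]["d95_pct"].std(ddof=1)),
                    "hi_mean_pp": float(sweep[posture]["metrics"]["hi_pp"].mean()),
                }
                for posture in ("supine", "upright")
            },
            "courses": {
                posture: courses[posture].drop(columns=["d95_series", "hi_series"]).to_dict(
                    orient="records"
                )
                for posture in ("supine", "upright")
            },
            "posture_comparison": comparison,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        return report
    finally:
        log.removeHandler(fh)
        fh.close()
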