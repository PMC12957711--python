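"""Voxel-wise robust two-field carbon-ion plan and its robustness analysis.

Optimizes a plan on the phantom's ITV (3 GyRBE/fraction, 70 HU density
override, nine 3.5%/3 mm scenarios), prints the clinical DVH metrics of the
nominal dose, and re-evaluates the plan under both uncertainty settings.
"""

from posture4d import (
    AcceptanceRule,
    DepthDoseTable,
    PhantomConfig,
    Prescription,
    compute_dose,
    dvh_metrics,
    generate_phantom_pair,
    make_plan,
    robustness_report,
    scenario_set,
)
from posture4d.planning import OptimizationSettings

cfg = PhantomConfig(shape=(48, 48, 48), spacing_supine=(4, 4, 4),
                    spacing_upright=(4, 4, 4.8), target_volume_cc=12.0, seed=7)
ph = generate_phantom_pair(cfg).supine
table = DepthDoseTable.default()
rx = Prescription()

plan = make_plan(
    ph.posture, ph.reference, ph.grid, table, ph.masks["itv"],
    {"lung": ph.lungs, "heart": ph.masks["heart"]}, (225.0, 315.0), rx,
    scenarios=scenario_set(3.0, 0.035), settings=OptimizationSettings(),
    max_iter=400, strict=False,
)
dose = compute_dose(ph.reference, ph.grid, plan.spotsets, table,
                    overrides=[(ph.masks["itv"], 70.0)], roi_mask=ph.masks["body"])
m = dvh_metrics(dose, {"target": ph.masks["itv"], "lung": ph.lungs,
                       "heart": ph.masks["heart"]}, rx)
print(f"nominal static plan ({plan.n_spots} spots, angles {plan.angles}):")
print(f"  D95 = {m.d95_pct:.1f}%  V95 = {m.v95_pct:.1f}%  HI = {m.hi_pp:.2f} pp")
print(f"  V16Gy(lung) = {m.vx_gy_pct['lung']:.1f}%  "
      f"V20Gy(heart) = {m.vx_gy_pct['heart']:.1f}%")
print("  clinical acceptance:", AcceptanceRule().check(m))

report = robustness_report(
    plan, ph, table, [scenario_set(3.0, 0.035), scenario_set(5.0, 0.05)],
    mode="static",
)
print("\nrobustness analysis (static doses, both settings):")
print(report[["setting", "scenario", "d95_pct", "v95_pct", "hi_pp", "pass"]]
      .to_string(index=False))
# D95/V95 > 95% in every scenario means the plan survives the modelled setup
# and range uncertainties; the 5%/5 mm setting probes the larger positioning
# uncertainty an upright posture may entail.
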