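"""End-to-end upright vs supine comparison on a reduced phantom.

Runs the whole pipeline — phantom pair, ROI-restricted registration,
per-posture robust planning, robustness analysis, the D4D delivery sweep,
course sampling and the paired Wilcoxon comparison — and prints the summary.
Expect a few minutes of runtime.
"""

import json
import tempfile

from posture4d import PhantomConfig, RunConfig, run_comparison
from posture4d.planning import OptimizationSettings

cfg = RunConfig(
    phantom=PhantomConfig(
        shape=(48, 48, 48),
        spacing_supine=(4.0, 4.0, 4.0),
        spacing_upright=(4.0, 4.0, 4.8),
        target_volume_cc=12.0,
    ),
    optimization=OptimizationSettings(max_iter=300, tol=2e-3),
    robustness_mode="static",
    periods_s=(5.0, 10.0),
    master_seed=7,
    out_dir=tempfile.mkdtemp(prefix="posture4d_demo_"),
)
report = run_comparison(cfg)

print("\nregistration QA:", json.dumps(report["registration"]["qa"], indent=2))
print("\nstatic plan metrics:", json.dumps(report["static_metrics"], indent=2))
print("\nD4D summary:", json.dumps(report["d4d_summary"], indent=2))
print("\npaired posture comparison (Wilcoxon, 20 deliveries):")
for metric, row in report["posture_comparison"].items():
    print(f"  {metric:14s} supine {row['mean_a']:6.2f} +/- {row['sd_a']:5.2f}  "
          f"upright {row['mean_b']:6.2f} +/- {row['sd_b']:5.2f}  "
          f"p = {row['p_value']:.3f}{' *' if row['significant'] else ''}")
print(f"\nartifacts under: {cfg.out_dir}")
# With the default 6 mm supine / 3 mm upright tumour motion, the upright
# deliveries show a higher, tighter D95 distribution - the interplay
# advantage of the posture with the smaller breathing excursion.
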