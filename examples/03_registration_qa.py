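"""Ribcage-ROI-restricted registration between postures with contour QA.

Registers the supine reference image onto the upright one inside the
ribcage region of interest, propagates the lung contours, and prints the
QA metrics together with the ground-truth endpoint error that only a
synthetic pair can provide.
"""

import numpy as np

from posture4d import PhantomConfig, generate_phantom_pair
from posture4d.registration import (
    build_ribcage_roi,
    contour_qa,
    propagate_contour,
    register_roi_restricted,
)

cfg = PhantomConfig(shape=(64, 64, 64), spacing_supine=(3.5, 3.5, 3.5),
                    spacing_upright=(3.5, 3.5, 4.2), target_volume_cc=25.0, seed=7)
pair = generate_phantom_pair(cfg)
sup, up = pair.supine, pair.upright

roi_up = build_ribcage_roi(up.masks, up.grid)
roi_sup = build_ribcage_roi(sup.masks, sup.grid)
dvf = register_roi_restricted(up.reference, up.grid, sup.reference, sup.grid,
                              roi_up, roi_sup)

print(f"{'structure':12s} {'DSC':>6s} {'AHD mm':>7s} {'COM mm':>7s} {'dV %':>6s}")
for name in ("lung_left", "lung_right", "heart", "itv"):
    prop = propagate_contour(sup.masks[name], dvf, sup.grid, up.grid)
    qa = contour_qa(prop, up.masks[name], up.grid)
    print(f"{name:12s} {qa.dsc:6.3f} {qa.ahd_mm:7.2f} {qa.com_distance_mm:7.2f} "
          f"{qa.volume_diff_pct:6.1f}")

epe = np.linalg.norm(dvf - pair.inter_posture_dvf, axis=-1)[roi_up]
print(f"\nmean ground-truth endpoint error in ROI: {epe.mean():.2f} mm "
      f"(voxel: {max(up.grid.spacing):.1f} mm)")
# DSC above 0.9 and AHD below the slice distance indicate a propagation good
# enough to transfer target contours between postures.
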