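# Methods

This note documents the models, defaults and numerical choices behind
`posture4d`, and what its synthetic testbed can and cannot say about real
paired upright/supine studies.

## Synthetic phantom pair

**Anatomy.** The thorax is analytic: an elliptic body column, two lung
ellipsoids, a heart ellipsoid (anterior-inferior, disjoint from the lungs),
a bony shell between 1.08 and 1.30 scaled lung radii standing in for the
ribcage, and a spherical tumour of configurable volume placed fractionally
inside a chosen lung. Shapes scale with the grid's physical extent, so
reduced grids carry a proportionally smaller thorax. Tissue classes are
painted as HU (air −1000, lung −700, soft tissue 40, heart 60, bone 700,
tumour 40) and lightly smoothed (σ = 0.6 voxel) to avoid voxel-edge
gradients. The default grid is 96³ voxels at 2.5 mm isotropic (supine) and
2.5/2.5/3.0 mm (upright) — the slice-distance asymmetry of typical paired
scan protocols. A seeded sub-voxel jitter of the tumour position makes the
seed the single source of randomness.

**Posture differences.** The upright anatomy is the supine anatomy pulled
through an analytic, invertible displacement field: a per-lung radial
scaling about each lung centre (exact out to 1.35 scaled radii, smoothly
blended to identity by 1.9) and a blended heart translation (default
(0, 3, −6) mm). The linear lung-scaling factor is calibrated by a damped
fixed-point iteration until the voxelized upright/supine total lung volume
ratio matches the configured value (default 1.13, a typical posture-induced
inflation) to better than the 2% contract. Upright lung HU rises toward air
by the same factor (more air per voxel). Arms — the posture-specific content
that defeats unrestricted registration — are added in upright only, outside
the ribcage region. Because upright masks are the supine masks pulled
through this field, a ground-truth inter-posture mapping exists and
registration accuracy can be asserted, which is impossible on real data.
The upright backrest is treated as vertical; an incline is a config hook
deliberately left unimplemented.

**Breathing.** Motion is a separable field `u(x, p) = s_p · A · g(z) ·
e(x, y) · d̂` with `d̂` SI-dominant (AP component 25% of SI), `g(z)` a
logistic profile strongest caudally and decaying cranially, and `e(x, y)` a
lateral envelope confined to the lungs' axial footprint so the chest wall
and ribcage stay quasi-static, as on real 4DCT. `s_p` follows the Lujan
trajectory (exponent n = 2, longer exhale dwell) sampled at the ten
time-based phase bins: phase 0 (end-inhale) is the motion-free reference,
phase 5 (end-exhale) carries full amplitude. The field is normalized so the
mean displacement magnitude over the tumour equals the configured amplitude
(defaults: 6 mm supine, 3 mm upright — a lower-lobe tumour whose excursion
halves when seated, the regime where posture matters most for interplay).
Phase images are pull-back warps of the reference; the stored fields are
therefore exactly the synthesis ground truth. The ITV is the union of the
warped tumour masks over all phases.

**Optional lung texture.** A seeded, smoothed random field can emulate
vascular contrast inside the lungs (`lung_texture_hu`). It is off by
default: the posture-dependent HU dilution makes the two postures'
textures differ by a linear intensity map that the demons similarity
(intensity difference after global histogram matching) does not fully
absorb, which measurably degrades rather than improves the ground-truth
endpoint error. The hook remains for experiments with
intensity-robust registration variants.

## Registration

Supine→upright registration is restricted to a ribcage region of interest:
the union of lungs, heart and ITV dilated by 10 mm (metric dilation via a
Euclidean distance transform, so anisotropic spacing is honoured),
intersected with the body. Both images are masked to their ROI with air
outside, rigidly pre-aligned on the ROI centres of mass, histogram-matched,
and registered with SimpleITK's fast symmetric-forces demons inside a
3-level pyramid (shrink 4/2/1, field smoothing 8/5/3 mm, 150/120/80
iterations). The returned displacement field lives on the upright grid, in
physical mm, composed with the rigid pre-alignment and zeroed outside the
ROI. Contours propagate by pull-back warping of the indicator, re-binarized
at 0.5.

QA follows contour-propagation practice: Dice coefficient, average
Hausdorff distance (defined here as the symmetric mean of the two directed
average boundary-voxel surface distances — the common variant, consistent
with the rule that AHD should stay below the CT slice distance), COM
distance and relative volume difference. On the synthetic pair the mean
ground-truth endpoint error inside the ROI is also reported; the package's
registration-quality contract is DSC ≥ 0.9, AHD ≤ 3 mm and mean endpoint
error within one (upright) voxel on the default pair.

## Dose engine

HU→relative stopping power is a declared piecewise-linear calibration with
water (0 HU) at 1.0 and air at 0.001. Fields are coplanar (beams in the
axial plane, rotation about the slice axis; 90° = vertical
anterior-posterior, 270° = vertical PA, 0/180° horizontal). For each field
the RSP volume is resampled into the beam frame and integrated
cumulatively to a WEPL volume; each evaluation voxel's dose is

`d(v) = Σ_s w_s · DD(E_s, wepl(v)) · G(u(v) − u_s, z(v) − z_s; σ(wepl(v)))`

with `DD` an analytic RBE-weighted Bragg parameterization per energy
(entrance plateau 18% of peak with a mild rise, Gaussian peak of width
1.5 + 0.02·R mm, 1.2 mm distal falloff) tabulated in a versioned CSV on a
3 mm range ladder (21–255 mm), and a lateral Gaussian of width
`σ(d) = sqrt(4² + (0.025·d)²)` mm. This parameterization deliberately
carries carbon's sharp peak and high peak-to-entrance contrast — the
features every coverage/sparing trade-off in the comparison depends on —
without claiming a radiobiological model; a biological dose model is out of
scope, and the α/β ratio consequently has no computational role here.
Setup-shift scenarios counter-shift the patient image and report dose in
the patient frame; range scenarios scale the RSP map globally. Lateral
kernels are cut off at 3.5 σ (≤ 0.2% mass). Dose grids equal the phantom
grid.

## Planning

Spots sit on a fixed lateral lattice (4.5 mm spacing) covering each energy
layer's beam's-eye-view target footprint plus a 5 mm margin; layers cover
the ITV's WEPL span extended by a 6 mm range margin so range scenarios
remain compensable (without that margin the robust optimum is forced into
nominal inhomogeneity). The optimization objective is a per-voxel worst
case over scenarios of the quadratic deviation from prescription on the
target, plus quadratic organ-at-risk penalties on the nominal scenario,
with target weight 100× the OAR weight (target coverage prioritized). It is
minimized by bound-constrained L-BFGS-B on weights normalized by the
uniform-weight solution (the raw problem is badly scaled: particle numbers
~10³–10⁴ against influence values ~10⁻⁴), with an 800-iteration cap and a
smoothed relative-change convergence test at 1e−4; the iterate history is
monotone, deterministic, and a non-converged strict run raises. Target
voxels are subsampled deterministically (stride) to ≤ 4500, OARs to ≤ 2000
per organ. The defaults reach, on the default phantom, D95 ≈ 98%,
HI ≈ 4.3 pp, V16Gy(lung) ≈ 6%, V20Gy(heart) ≈ 7% — inside the clinical
acceptance surface (D95/V95 > 95%, HI < 5 pp, V16 < 30%, V20 < 10%).

The angle-selection protocol scores candidate two-field pairs with quick
nominal-only optimizations (120 iterations) and picks, among pairs with
D95 ≥ 95%, the one minimizing V16Gy(lung), then V20Gy(heart), ties broken
by the lower angle sum; steps: supine under 360° flexibility (within 45° of
vertical — steeper beams risk arms/shoulders in the path), the same pair
re-evaluated upright, an upright-specific re-selection, and a supine
fixed-beamline selection over the vertical/horizontal/45° set.

## Delivery and 4D dose

The synchrotron model delivers spots per field, energy layers deepest
first, raster order (v, then u) within a layer. Spot duration is
weight/extraction-rate floored at the 2 ms minimum dwell; a spill ends at
4 s or at layer completion, whichever is first; pauses are 4 s (layer
switches happen during them); spots are not split across spills. With one
spill per layer and ~44 layers for two fields, a default fraction delivers
in ≈ 180 s — dominated by spill pauses and spanning dozens of breathing
cycles, the regime in which starting-phase sampling of interplay is
meaningful.

The 4D (interplay-free) dose is the uniform 1/10 phase-weighted average of
the full plan computed on each phase geometry and accumulated on the
reference. The D4D (interplay) dose assigns each spot the phase active at
its delivery start time, computes per-phase partial doses on that phase's
geometry (with the density override following the warped ITV), and
accumulates. Accumulation is pull-back trilinear interpolation through the
fixed-point-inverted ground-truth field (5 iterations; exact for the
separable fields used). A caching engine shares per-(phase, field) WEPL
volumes across the 10-starting-phase × {5, 10} s sweep. Courses draw 20
fractions with replacement from the 20-delivery pool (4 courses by
default, seeded); convergence speed is the first fraction index from which
the cumulative metric stays within ±1 pp of its final value. Posture
comparison uses the two-sided Wilcoxon signed-rank test on paired
deliveries (exact null for n ≤ 25 without ties, zero differences dropped;
all-identical pairs are flagged degenerate), significance at p < 0.05.

## Problem sizes

Default study size is the 96³ phantom; the bundled test suite exercises the
clinical-acceptance and registration contracts at that size and runs unit
and property tests on 48³ phantoms (4 mm voxels, 12 cc tumour), where all
mechanisms — interplay degeneracies, amplitude dependence, course
convergence — are already expressed. The acceptance script
(`scripts/acceptance.py`) recomputes the headline quantities at the default
size in a few minutes on one CPU.

## Limitations

* Analytic anatomy: no CT texture or noise by default, no cardiac motion,
  single-lobe spherical tumours; DSC/AHD values on such clean shapes are
  optimistic relative to clinical contours.
* Breathing is strictly periodic and identical in waveform across postures
  (only amplitude and period vary); no drift, baseline shift or
  irregularity.
* The depth-dose stand-in has no nuclear fragmentation tail and a fixed
  RBE-weighted shape per energy; absolute particle numbers are internally
  consistent but not machine-calibrated.
* Posture comparison outcomes on the phantom demonstrate mechanisms (e.g.,
  interplay spread scaling with motion amplitude), not patient statistics;
  passing tests show the pipeline's correctness and the mechanisms'
  reproduction, not clinical equivalence of postures.
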