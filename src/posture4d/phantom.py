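"""Paired supine/upright synthetic 4D thorax phantoms with known ground truth.

The phantom emulates, at desk scale, a paired 4DCT study of a thoracic tumour
patient scanned both lying (supine) and seated (upright):

* an analytic thorax anatomy (elliptic body, two lung ellipsoids, a heart, a
  bony ribcage shell, a spherical tumour with an ITV) voxelized onto an
  anisotropic grid (slice spacing differs between postures, 2.5 vs 3.0 mm by
  default, as typical supine/upright scan protocols do);
* 10 breathing phases per posture synthesized by warping the end-inhale
  reference image with a known, smooth, SI-dominant motion field whose
  per-phase scaling follows a Lujan-type trajectory (phase 0 = end-inhale =
  reference, phase 5 = end-exhale = full amplitude);
* posture differences realized as an analytic, invertible inter-posture
  displacement field (lung inflation about each lung centre, a heart shift,
  plus arms added outside the ribcage region in upright), so that a
  ground-truth mapping between the postures exists and registration accuracy
  can be asserted — something impossible on real paired scans.

The upright total lung volume is calibrated to exceed the supine volume by a
configurable factor (default 1.13, a typical posture-induced inflation), and
the target motion amplitude is posture specific (default 6 mm supine vs 3 mm
upright, emulating a lower-lobe tumour whose excursion halves when seated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._grid import Grid, mask_volume_cc, sample_at_physical
from .breathing import phase_fractions

__all__ = [
    "PhantomConfig",
    "Phantom4D",
    "PhantomPair",
    "generate_phantom",
    "generate_phantom_pair",
    "apply_deformation",
    "invert_dvf",
    "target_delta_motion",
    "write_phantom",
    "read_phantom",
]

N_PHASES = 10

DEFAULT_HU = {
    "air": -1000.0,
    "lung": -700.0,
    "soft": 40.0,
    "bone": 700.0,
    "heart": 60.0,
    "target": 40.0,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the paired phantom; the seed fixes all stochastic choices."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_supine: tuple[float, float, float] = (2.5, 2.5, 2.5)
    spacing_upright: tuple[float, float, float] = (2.5, 2.5, 3.0)
    target_volume_cc: float = 60.0
    target_lung: str = "left"
    #: target centre as a fraction of the host-lung semi-axes
    target_offset_frac: tuple[float, float, float] = (0.30, 0.35, -0.60)
    amplitude_supine_mm: float = 6.0
    amplitude_upright_mm: float = 3.0
    #: AP motion component as a fraction of the SI component
    ap_motion_fraction: float = 0.25
    lung_scale_upright: float = 1.13
    heart_shift_upright_mm: tuple[float, float, float] = (0.0, 3.0, -6.0)
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    #: std (HU) and correlation length (mm) of an optional vessel-like lung
    #: texture (0 disables it; see the methods note for its registration
    #: intensity-consistency caveat)
    lung_texture_hu: float = 0.0
    lung_texture_scale_mm: float = 6.0
    lujan_exponent: int = 2
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.amplitude_supine_mm < 0 or self.amplitude_upright_mm < 0:
            raise ValueError("motion amplitudes must be non-negative")
        if self.lung_scale_upright <= 0:
            raise ValueError("lung scale must be positive")
        if not 10.0 <= self.target_volume_cc <= 500.0:
            raise ValueError(
                f"target volume {self.target_volume_cc} cc outside supported [10, 500] cc"
            )
        if self.target_lung not in ("left", "right"):
            raise ValueError("target_lung must be 'left' or 'right'")
        if self.lujan_exponent < 1:
            raise ValueError("Lujan exponent must be >= 1")

    @property
    def grid_supine(self) -> Grid:
        return Grid(self.shape, self.spacing_supine)

    @property
    def grid_upright(self) -> Grid:
        return Grid(self.shape, self.spacing_upright)


class Phantom4D:
    """One posture's 4D phantom: phases, structure masks and ground-truth motion.

    The reference phase is end-inhale (phase 0).  The per-phase ground-truth
    deformation field (pull-back convention: ``phase_p(x) = ref(x + dvf_p(x))``)
    is separable into a static base field times a Lujan phase fraction, so
    ``dvf(0)`` is identically zero and ``dvf(5)`` carries full amplitude.
    """

    def __init__(
        self,
        posture: str,
        grid: Grid,
        reference: np.ndarray,
        phases: list[np.ndarray],
        masks: dict[str, np.ndarray],
        motion_base: np.ndarray,
        phase_scale: np.ndarray,
        air_hu: float = -1000.0,
    ) -> None:
        self.posture = posture
        self.grid = grid
        self.reference = reference
        self.phases = phases
        self.masks = masks
        self.motion_base = motion_base
        self.phase_scale = np.asarray(phase_scale, dtype=float)
        self.air_hu = float(air_hu)
        self.reference_phase = 0
        self._validate()

    def _validate(self) -> None:
        body = self.masks["body"]
        for name, m in self.masks.items():
            if m.shape != tuple(self.grid.shape):
                raise ValueError(f"mask {name} shape mismatch")
            if name != "body" and np.any(m & ~body):
                raise ValueError(f"mask {name} is not a subset of the body")
        if np.any(self.masks["heart"] & (self.masks["lung_left"] | self.masks["lung_right"])):
            raise ValueError("heart and lung masks overlap")
        if abs(self.phase_scale[0]) > 1e-12:
            raise ValueError("reference-phase motion scaling must be zero")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def lungs(self) -> np.ndarray:
        return self.masks["lung_left"] | self.masks["lung_right"]

    def dvf(self, phase: int) -> np.ndarray:
        """Ground-truth displacement field (mm, shape ``(*grid, 3)``) of ``phase``."""
        return (self.phase_scale[phase] * self.motion_base).astype(np.float32)

    def phase_image(self, phase: int) -> np.ndarray:
        return self.phases[phase]


@dataclass
class PhantomPair:
    """Supine and upright phantoms derived from one configuration.

    ``inter_posture_dvf`` maps upright physical points onto the corresponding
    supine points (pull-back convention on the upright grid); it is exact on
    the thorax core and is intended to be evaluated inside the ribcage
    surrogate region, where it is smooth and invertible.
    """

    config: PhantomConfig
    supine: Phantom4D
    upright: Phantom4D
    inter_posture_dvf: np.ndarray  # (*upright grid, 3), mm, upright -> supine


# ---------------------------------------------------------------------------
# deformation primitives
# ---------------------------------------------------------------------------


def apply_deformation(
    image: np.ndarray,
    dvf_mm: np.ndarray,
    grid: Grid,
    cval: float = DEFAULT_HU["air"],
    order: int = 1,
) -> np.ndarray:
    """Pull-back resampling: ``out(x) = image(x + dvf(x))``.

    The displacement field is in mm on the same grid as the image; samples
    falling outside the grid take ``cval`` (air, for CT-like volumes).
    """
    if image.shape != tuple(grid.shape):
        raise ValueError(f"image shape {image.shape} does not match grid {grid.shape}")
    if dvf_mm.shape != tuple(grid.shape) + (3,):
        raise ValueError(f"dvf shape {dvf_mm.shape} does not match grid {grid.shape}")
    idx = np.indices(grid.shape, dtype=np.float32)
    coords = idx + np.moveaxis(dvf_mm, -1, 0) / grid.spacing_arr[:, None, None, None]
    return ndimage.map_coordinates(
        image.astype(np.float32, copy=False),
        coords.astype(np.float32),
        order=order,
        mode="constant",
        cval=cval,
    )


def warp_mask(mask: np.ndarray, dvf_mm: np.ndarray, grid: Grid) -> np.ndarray:
    """Warp a binary mask (pull-back of the indicator, re-binarized at 0.5)."""
    if not mask.any():
        return mask.copy()
    warped = apply_deformation(mask.astype(np.float32), dvf_mm, grid, cval=0.0)
    return warped >= 0.5


def invert_dvf(dvf_mm: np.ndarray, grid: Grid, n_iter: int = 8) -> np.ndarray:
    """Fixed-point inverse of a displacement field.

    Finds ``m`` with ``(id + dvf) o (id + m) ~ id`` by iterating
    ``m(x) <- -dvf(x + m(x))``; converges for the smooth, moderate-amplitude
    fields the phantom produces.
    """
    inv = np.zeros_like(dvf_mm, dtype=np.float32)
    idx = np.indices(grid.shape, dtype=np.float32)
    spacing = grid.spacing_arr[:, None, None, None]
    for _ in range(n_iter):
        coords = idx + np.moveaxis(inv, -1, 0) / spacing
        for c in range(3):
            inv[..., c] = -ndimage.map_coordinates(
                dvf_mm[..., c].astype(np.float32, copy=False),
                coords,
                order=1,
                mode="nearest",
            )
    return inv


def resample_through_mapping(
    values: np.ndarray,
    source_grid: Grid,
    target_grid: Grid,
    displacement_mm: np.ndarray,
    cval: float = DEFAULT_HU["air"],
) -> np.ndarray:
    """Sample ``values`` (on source grid) at ``x + disp(x)`` for target-grid voxels."""
    idx = np.indices(target_grid.shape, dtype=np.float64)
    pts = np.stack(
        [
            (idx[c] - (target_grid.shape[c] - 1) / 2.0) * target_grid.spacing[c]
            for c in range(3)
        ],
        axis=-1,
    )
    pts = pts + displacement_mm
    return sample_at_physical(values, source_grid, pts, cval=cval).astype(np.float32)


def target_delta_motion(phantom: Phantom4D) -> float:
    """Target motion amplitude (mm): mean magnitude of the end-inhale to
    end-exhale deformation field over the ITV voxels."""
    itv = phantom.masks["itv"]
    if not itv.any():
        raise ValueError("ITV mask is empty")
    mid = phantom.n_phases // 2
    dvf = phantom.dvf(mid)
    mag = np.linalg.norm(dvf[itv], axis=-1)
    return float(mag.mean())


# ---------------------------------------------------------------------------
# analytic anatomy
# ---------------------------------------------------------------------------


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _elliptic_radius(x, y, z, center, semi) -> np.ndarray:
    return np.sqrt(
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )


class _Anatomy:
    """Supine anatomy parameters in mm, proportional to the grid half-extent."""

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator) -> None:
        hx, hy, hz = cfg.grid_supine.half_extent
        self.body_semi = (0.74 * hx, 0.62 * hy)
        self.lung_center = {
            "left": np.array([0.38 * hx, -0.04 * hy, 0.0]),
            "right": np.array([-0.38 * hx, -0.04 * hy, 0.0]),
        }
        self.lung_semi = np.array([0.32 * hx, 0.46 * hy, 0.67 * hz])
        # heart sits anterior (negative y) of the spine/lung centre line
        self.heart_center = np.array([0.125 * hx, -0.16 * hy, -0.25 * hz])
        self.heart_semi = np.array([0.40 * hx, 0.33 * hy, 0.38 * hz])
        self.rib_inner, self.rib_outer = 1.08, 1.30
        # small seeded jitter on the tumour position (sub-voxel scale)
        jitter = rng.uniform(-0.02, 0.02, size=3)
        off = np.asarray(cfg.target_offset_frac) + jitter
        self.target_center = self.lung_center[cfg.target_lung] + off * self.lung_semi
        self.target_radius = (3.0 * cfg.target_volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        self.arm_radius = 0.10 * hx
        self.arm_center_x = self.body_semi[0] + self.arm_radius
        self.arm_center_y = 0.05 * hy

    def validate(self, cfg: PhantomConfig) -> None:
        grid = cfg.grid_supine
        margin = np.max(grid.spacing_arr)
        room = grid.half_extent - margin
        if np.any(np.abs(self.target_center) + self.target_radius > room):
            raise ValueError(
                f"target of {cfg.target_volume_cc} cc at {self.target_center} "
                "does not fit on the grid"
            )
        if self.target_radius < np.min(grid.spacing_arr):
            raise ValueError("target smaller than one voxel")
        # sample the sphere surface against the axial body ellipse
        phi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        px = self.target_center[0] + self.target_radius * np.cos(phi)
        py = self.target_center[1] + self.target_radius * np.sin(phi)
        # tolerate sub-voxel protrusion: the mask is trimmed to the body anyway
        if np.any((px / self.body_semi[0]) ** 2 + (py / self.body_semi[1]) ** 2 > 1.05):
            raise ValueError("target sphere falls outside the body outline")


def _build_supine_masks(cfg: PhantomConfig, anat: _Anatomy) -> dict[str, np.ndarray]:
    grid = cfg.grid_supine
    x, y, z = grid.coords()
    body = ((x / anat.body_semi[0]) ** 2 + (y / anat.body_semi[1]) ** 2) <= 1.0
    body = np.broadcast_to(body, grid.shape).copy()

    r_lung = {
        side: _elliptic_radius(x, y, z, anat.lung_center[side], anat.lung_semi)
        for side in ("left", "right")
    }
    r_heart = _elliptic_radius(x, y, z, anat.heart_center, anat.heart_semi)
    heart = (r_heart <= 1.0) & body
    lung_left = (r_lung["left"] <= 1.0) & body & ~heart
    lung_right = (r_lung["right"] <= 1.0) & body & ~heart

    rib = np.zeros(grid.shape, dtype=bool)
    for side in ("left", "right"):
        rib |= (r_lung[side] >= anat.rib_inner) & (r_lung[side] <= anat.rib_outer)
    rib &= body & ~heart & ~lung_left & ~lung_right

    r_t = np.sqrt(
        (x - anat.target_center[0]) ** 2
        + (y - anat.target_center[1]) ** 2
        + (z - anat.target_center[2]) ** 2
    )
    target = (r_t <= anat.target_radius) & body

    masks = {
        "body": body,
        "lung_left": lung_left & ~target,
        "lung_right": lung_right & ~target,
        "heart": heart & ~target,
        "ribcage": rib & ~target,
        "target": target,
    }
    if not target.any():
        raise ValueError("target voxelization produced an empty mask")
    return masks


def _paint_image(
    masks: dict[str, np.ndarray],
    hu: dict,
    texture: np.ndarray | None = None,
    smooth_vox: float = 0.6,
) -> np.ndarray:
    img = np.full(masks["body"].shape, hu["air"], dtype=np.float32)
    img[masks["body"]] = hu["soft"]
    img[masks["ribcage"]] = hu["bone"]
    lungs = masks["lung_left"] | masks["lung_right"]
    img[lungs] = hu["lung"]
    if texture is not None:
        # vessel-like intra-lung structure; anchors registration inside the
        # otherwise homogeneous parenchyma, as vasculature does on real CT
        img[lungs] += texture[lungs]
    img[masks["heart"]] = hu["heart"]
    img[masks["target"]] = hu["target"]
    if smooth_vox > 0:
        img = ndimage.gaussian_filter(img, smooth_vox)
    return img


def _lung_texture(cfg: PhantomConfig, grid: Grid, rng: np.random.Generator) -> np.ndarray:
    """Smooth seeded random field emulating pulmonary vessel contrast (HU)."""
    if cfg.lung_texture_hu == 0.0:
        return None
    raw = rng.standard_normal(grid.shape).astype(np.float32)
    sigma_vox = [cfg.lung_texture_scale_mm / s for s in grid.spacing]
    tex = ndimage.gaussian_filter(raw, sigma_vox)
    std = float(tex.std())
    if std > 0:
        tex *= cfg.lung_texture_hu / std
    return tex


def _motion_base(cfg: PhantomConfig, grid: Grid, anat: _Anatomy, amplitude: float) -> np.ndarray:
    """Static motion field (mm): SI-dominant diaphragm-like displacement,
    strongest caudally and decaying cranially (smooth logistic profile),
    confined laterally to the lung/diaphragm column so the chest wall and
    ribcage stay quasi-static as on real 4DCT.  Normalized so the magnitude
    at the tumour equals the configured amplitude."""
    base = np.zeros(tuple(grid.shape) + (3,), dtype=np.float32)
    if amplitude == 0.0:
        return base
    x, y, z1 = grid.coords()
    z = grid.axis_coords(2)
    tau = 0.25 * grid.half_extent[2]
    g = 1.0 / (1.0 + np.exp((z - 0.0) / tau))
    g = g / (1.0 / (1.0 + np.exp(anat.target_center[2] / tau)))
    # lateral envelope: 1 inside each lung's axial footprint, 0 at the ribcage
    env = np.zeros(grid.shape[:2], dtype=np.float32)
    for side in ("left", "right"):
        c, s = anat.lung_center[side], anat.lung_semi
        r2d = np.sqrt(((x[:, :, 0] - c[0]) / s[0]) ** 2 + ((y[:, :, 0] - c[1]) / s[1]) ** 2)
        env = np.maximum(env, 1.0 - _smoothstep((r2d - 0.80) / (1.05 - 0.80)))
    # re-normalize at the tumour position so the configured amplitude is met
    ct = anat.target_center
    r_t = min(
        np.sqrt(((ct[0] - anat.lung_center[s2][0]) / anat.lung_semi[0]) ** 2
                + ((ct[1] - anat.lung_center[s2][1]) / anat.lung_semi[1]) ** 2)
        for s2 in ("left", "right")
    )
    env_t = float(1.0 - _smoothstep((r_t - 0.80) / (1.05 - 0.80)))
    if env_t <= 0:
        raise ValueError("target lies outside the moving lung column")
    weight = g[None, None, :] * env[:, :, None] / env_t
    direction = np.array([0.0, cfg.ap_motion_fraction, -1.0])
    direction /= np.linalg.norm(direction)
    for c in range(3):
        base[..., c] = amplitude * weight * direction[c]
    return base


def _build_itv(target: np.ndarray, motion_base: np.ndarray, scale: np.ndarray, grid: Grid) -> np.ndarray:
    itv = target.copy()
    for s in np.unique(scale):
        if s == 0.0:
            continue
        itv |= warp_mask(target, (s * motion_base).astype(np.float32), grid)
    return itv


def generate_phantom(cfg: PhantomConfig, posture: str = "supine") -> Phantom4D:
    """Generate a single-posture phantom (supine path of the pair)."""
    if posture != "supine":
        raise ValueError("single-posture generation supports 'supine'; use generate_phantom_pair")
    rng = np.random.default_rng(cfg.seed)
    anat = _Anatomy(cfg, rng)
    anat.validate(cfg)
    texture = _lung_texture(cfg, cfg.grid_supine, rng)
    return _assemble(cfg, cfg.grid_supine, _build_supine_masks(cfg, anat), anat,
                     cfg.amplitude_supine_mm, cfg.hu, "supine", texture)


def _assemble(
    cfg: PhantomConfig,
    grid: Grid,
    masks: dict[str, np.ndarray],
    anat: _Anatomy,
    amplitude: float,
    hu: dict,
    posture: str,
    texture: np.ndarray | None = None,
) -> Phantom4D:
    scale = phase_fractions(N_PHASES, cfg.lujan_exponent)
    base = _motion_base(cfg, grid, anat, amplitude)
    masks = dict(masks)
    masks["itv"] = _build_itv(masks["target"], base, scale, grid) & masks["body"]
    ref = _paint_image(masks, hu, texture)
    phases = [ref.copy()]
    for p in range(1, N_PHASES):
        if scale[p] == 0.0 or amplitude == 0.0:
            phases.append(ref.copy())
        else:
            phases.append(apply_deformation(ref, (scale[p] * base).astype(np.float32), grid, cval=hu["air"]))
    return Phantom4D(posture, grid, ref, phases, masks, base, scale, air_hu=hu["air"])


# ---------------------------------------------------------------------------
# inter-posture mapping and pair generation
# ---------------------------------------------------------------------------


def _inter_posture_field(
    cfg: PhantomConfig, anat: _Anatomy, grid_up: Grid, lam: float
) -> np.ndarray:
    """Upright->supine displacement (mm) on the upright grid.

    Lung inflation: the upright lung ellipsoids are the supine ones scaled by
    ``lam`` per axis about each lung centre; the map contracts them back
    (exact out to 1.35 scaled radii, blended to identity by 1.9).  Heart: a
    blended translation undoing the configured upright heart shift.
    """
    x, y, z = grid_up.coords()
    disp = np.zeros(tuple(grid_up.shape) + (3,), dtype=np.float32)
    for side in ("left", "right"):
        c = anat.lung_center[side]
        semi_up = anat.lung_semi * lam
        r = _elliptic_radius(x, y, z, c, semi_up)
        beta = 1.0 - _smoothstep((r - 1.35) / (1.9 - 1.35))
        f = (1.0 / lam - 1.0) * beta
        disp[..., 0] += f * (x - c[0])
        disp[..., 1] += f * (y - c[1])
        disp[..., 2] += f * (z - c[2])
    shift = np.asarray(cfg.heart_shift_upright_mm, dtype=float)
    if np.any(shift != 0):
        c_up = anat.heart_center + shift
        r_h = _elliptic_radius(x, y, z, c_up, anat.heart_semi)
        beta_h = 1.0 - _smoothstep((r_h - 1.15) / (1.7 - 1.15))
        for k in range(3):
            disp[..., k] += -shift[k] * beta_h
    return disp


def _arm_mask(grid: Grid, anat: _Anatomy) -> np.ndarray:
    x, y, z = grid.coords()
    arms = np.zeros(grid.shape, dtype=bool)
    for sx in (-1.0, 1.0):
        r = ((x - sx * anat.arm_center_x) / anat.arm_radius) ** 2 + (
            (y - anat.arm_center_y) / (1.6 * anat.arm_radius)
        ) ** 2
        arms |= np.broadcast_to(r <= 1.0, grid.shape)
    return arms


def generate_phantom_pair(cfg: PhantomConfig) -> PhantomPair:
    """Generate the paired supine/upright phantoms (deterministic per seed).

    The upright anatomy is the supine anatomy pulled through an analytic
    inter-posture field (lung inflation calibrated so the upright/supine total
    lung volume ratio matches the configured scale within 2%, heart shift),
    with arms added outside the ribcage region — the posture-specific content
    that defeats unrestricted registration.
    """
    rng = np.random.default_rng(cfg.seed)
    anat = _Anatomy(cfg, rng)
    anat.validate(cfg)
    grid_sup, grid_up = cfg.grid_supine, cfg.grid_upright

    masks_sup = _build_supine_masks(cfg, anat)
    texture = _lung_texture(cfg, grid_sup, rng)
    supine = _assemble(
        cfg, grid_sup, masks_sup, anat, cfg.amplitude_supine_mm, cfg.hu, "supine", texture
    )

    lung_sup_cc = mask_volume_cc(masks_sup["lung_left"], grid_sup) + mask_volume_cc(
        masks_sup["lung_right"], grid_sup
    )

    # calibrate the linear inflation factor so the realized (voxelized, warped)
    # lung volume ratio hits the configured scale
    lam = cfg.lung_scale_upright ** (1.0 / 3.0)
    best = None
    for _ in range(6):
        disp = _inter_posture_field(cfg, anat, grid_up, lam)
        masks_up = {
            name: resample_through_mapping(
                masks_sup[name].astype(np.float32), grid_sup, grid_up, disp, cval=0.0
            )
            >= 0.5
            for name in masks_sup
        }
        lung_up_cc = mask_volume_cc(masks_up["lung_left"], grid_up) + mask_volume_cc(
            masks_up["lung_right"], grid_up
        )
        ratio = lung_up_cc / lung_sup_cc
        err = abs(ratio - cfg.lung_scale_upright) / cfg.lung_scale_upright
        if best is None or err < best[0]:
            best = (err, disp, masks_up)
        if err < 0.005:
            break
        # damped fixed-point update: voxelization quantizes the measured
        # ratio, so an undamped update oscillates on coarse grids
        lam *= (cfg.lung_scale_upright / ratio) ** (1.0 / 6.0)
    _, disp, masks_up = best

    arms = _arm_mask(grid_up, anat)
    masks_up["body"] = masks_up["body"] | arms

    hu_up = dict(cfg.hu)
    # upright inflation means more air per lung voxel: HU scales with tissue density
    hu_up["lung"] = hu_up["air"] + (cfg.hu["lung"] - hu_up["air"]) / cfg.lung_scale_upright

    # the vascular texture follows the anatomy through the inter-posture map,
    # diluted by the same inflation factor as the parenchyma
    if texture is not None:
        texture_up = resample_through_mapping(texture, grid_sup, grid_up, disp, cval=0.0)
        texture_up /= cfg.lung_scale_upright
    else:
        texture_up = None

    upright = _assemble(
        cfg, grid_up, masks_up, anat, cfg.amplitude_upright_mm, hu_up, "upright", texture_up
    )
    return PhantomPair(cfg, supine, upright, disp)


# ---------------------------------------------------------------------------
# I/O (NRRD volumes + JSON sidecar)
# ---------------------------------------------------------------------------


def _to_sitk(arr: np.ndarray, grid: Grid, vector: bool = False):
    import SimpleITK as sitk

    data = np.moveaxis(arr, (0, 1, 2), (2, 1, 0))  # sitk expects (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data), isVector=vector)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    origin = -grid.half_extent
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img) -> np.ndarray:
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4:
        return np.moveaxis(arr, (0, 1, 2), (2, 1, 0))
    return np.moveaxis(arr, (0, 1, 2), (2, 1, 0))


def write_phantom(phantom: Phantom4D, out_dir: str | Path) -> None:
    """Write one image per phase, one per mask, and the motion base field as
    NRRD volumes, with grid/phase metadata in a JSON sidecar."""
    import SimpleITK as sitk

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p, img in enumerate(phantom.phases):
        sitk.WriteImage(_to_sitk(img, phantom.grid), str(out / f"phase_{p:02d}.nrrd"))
    for name, m in phantom.masks.items():
        sitk.WriteImage(
            _to_sitk(m.astype(np.uint8), phantom.grid), str(out / f"mask_{name}.nrrd")
        )
    sitk.WriteImage(
        _to_sitk(phantom.motion_base.astype(np.float32), phantom.grid, vector=True),
        str(out / "motion_base.nrrd"),
    )
    sidecar = {
        "posture": phantom.posture,
        "format": "nrrd",
        "shape": list(phantom.grid.shape),
        "spacing_mm": list(phantom.grid.spacing),
        "origin_mm": [float(v) for v in -phantom.grid.half_extent],
        "n_phases": phantom.n_phases,
        "reference_phase": phantom.reference_phase,
        "phase_scale": [float(s) for s in phantom.phase_scale],
        "air_hu": phantom.air_hu,
        "masks": sorted(phantom.masks),
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def read_phantom(in_dir: str | Path) -> Phantom4D:
    import SimpleITK as sitk

    src = Path(in_dir)
    meta = json.loads((src / "phantom.json").read_text())
    grid = Grid(tuple(meta["shape"]), tuple(meta["spacing_mm"]))
    phases = [
        _from_sitk(sitk.ReadImage(str(src / f"phase_{p:02d}.nrrd"))).astype(np.float32)
        for p in range(meta["n_phases"])
    ]
    masks = {
        name: _from_sitk(sitk.ReadImage(str(src / f"mask_{name}.nrrd"))).astype(bool)
        for name in meta["masks"]
    }
    base = _from_sitk(sitk.ReadImage(str(src / "motion_base.nrrd"))).astype(np.float32)
    return Phantom4D(
        meta["posture"], grid, phases[meta["reference_phase"]], phases, masks, base,
        np.asarray(meta["phase_scale"]), air_hu=meta["air_hu"],
    )
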