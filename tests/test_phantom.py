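"""Synthetic phantom pair: anatomy, motion ground truth, deformation primitives."""

import numpy as np
import pytest
from scipy import ndimage

from posture4d._grid import Grid, mask_com_mm, mask_volume_cc
from posture4d.phantom import (
    Phantom4D,
    PhantomConfig,
    apply_deformation,
    generate_phantom_pair,
    invert_dvf,
    read_phantom,
    target_delta_motion,
    warp_mask,
    write_phantom,
)

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_volume_cc": 5.0},
            {"target_volume_cc": 600.0},
            {"amplitude_supine_mm": -1.0},
            {"lung_scale_upright": 0.0},
            {"target_lung": "middle"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs)

    def test_unachievable_target_fails_explicitly(self):
        # a near-maximal tumour cannot fit on a small grid
        cfg = small_config(target_volume_cc=480.0)
        with pytest.raises(ValueError):
            generate_phantom_pair(cfg)


class TestGeneration:
    def test_determinism_same_seed(self):
        cfg = small_config()
        a = generate_phantom_pair(cfg)
        b = generate_phantom_pair(cfg)
        np.testing.assert_array_equal(a.supine.reference, b.supine.reference)
        np.testing.assert_array_equal(a.upright.reference, b.upright.reference)
        np.testing.assert_array_equal(a.supine.motion_base, b.supine.motion_base)
        for name in a.supine.masks:
            np.testing.assert_array_equal(a.supine.masks[name], b.supine.masks[name])
        np.testing.assert_array_equal(a.inter_posture_dvf, b.inter_posture_dvf)

    def test_lung_volume_ratio_matches_configured_scale(self, small_pair):
        cfg = small_pair.config
        sup = mask_volume_cc(small_pair.supine.lungs, small_pair.supine.grid)
        up = mask_volume_cc(small_pair.upright.lungs, small_pair.upright.grid)
        assert up / sup == pytest.approx(cfg.lung_scale_upright, rel=0.02)

    def test_delta_motion_recovers_configured_amplitudes(self, small_pair):
        cfg = small_pair.config
        assert target_delta_motion(small_pair.supine) == pytest.approx(
            cfg.amplitude_supine_mm, rel=0.2
        )
        assert target_delta_motion(small_pair.upright) == pytest.approx(
            cfg.amplitude_upright_mm, rel=0.2
        )

    def test_target_volume_on_grid(self, small_pair):
        vol = mask_volume_cc(small_pair.supine.masks["target"], small_pair.supine.grid)
        assert vol == pytest.approx(small_pair.config.target_volume_cc, rel=0.1)

    def test_body_outline_differs_between_postures(self, small_pair):
        # upright adds arms outside the ribcage region
        sup_body = small_pair.supine.masks["body"]
        up_body = small_pair.upright.masks["body"]
        assert up_body.sum() != sup_body.sum()

    def test_masks_are_subsets_of_body_and_disjoint(self, small_pair):
        for ph in (small_pair.supine, small_pair.upright):
            body = ph.masks["body"]
            for name, m in ph.masks.items():
                assert not np.any(m & ~body), name
            assert not np.any(ph.masks["heart"] & ph.lungs)

    def test_reference_phase_dvf_is_zero(self, small_phantom):
        assert np.all(small_phantom.dvf(0) == 0.0)

    def test_phase5_image_is_reference_warped_by_ground_truth(self, small_phantom):
        ph = small_phantom
        expected = apply_deformation(ph.reference, ph.dvf(5), ph.grid, cval=ph.air_hu)
        np.testing.assert_allclose(ph.phase_image(5), expected, atol=1e-4)

    def test_itv_contains_target_at_every_phase(self, small_phantom):
        ph = small_phantom
        for p in range(ph.n_phases):
            tp = warp_mask(ph.masks["target"], ph.dvf(p), ph.grid)
            assert not np.any(tp & ~ph.masks["itv"])

    def test_lung_texture_hook(self):
        cfg = small_config(lung_texture_hu=50.0)
        pair = generate_phantom_pair(cfg)
        lungs = ndimage.binary_erosion(pair.supine.lungs, iterations=2)
        assert pair.supine.reference[lungs].std() > 10.0


class TestDeformationPrimitives:
    def test_identity_dvf_leaves_image_unchanged(self, small_phantom):
        ph = small_phantom
        zero = np.zeros(tuple(ph.grid.shape) + (3,), dtype=np.float32)
        out = apply_deformation(ph.reference, zero, ph.grid)
        np.testing.assert_allclose(out, ph.reference, atol=1e-5)

    def test_uniform_translation_shifts_com_by_oracle(self, small_phantom):
        # continuous-intensity oracle: the centroid of a warped Gaussian blob
        # shifts by exactly the (negated pull-back) translation
        ph = small_phantom
        g = ph.grid
        x, y, z = g.coords()
        blob = np.exp(-((x - 10) ** 2 + y**2 + (z + 20) ** 2) / (2 * 15.0**2)).astype(
            np.float32
        )
        dvf = np.zeros(tuple(g.shape) + (3,), dtype=np.float32)
        dvf[..., 2] = 3.0  # pull-back by +3 mm: content moves 3 mm inferior
        moved = apply_deformation(blob, dvf, g, cval=0.0)

        def com(img):
            w = img / img.sum()
            return np.array([(w * c).sum() for c in (x + 0 * img, y + 0 * img, z + 0 * img)])

        shift = com(moved) - com(blob)
        assert shift[2] == pytest.approx(-3.0, abs=0.2)
        assert abs(shift[0]) < 0.2 and abs(shift[1]) < 0.2

    def test_round_trip_through_inverse_recovers_image(self, small_phantom):
        ph = small_phantom
        dvf = ph.dvf(5)
        inv = invert_dvf(dvf, ph.grid)
        warped = apply_deformation(ph.reference, dvf, ph.grid, cval=ph.air_hu)
        back = apply_deformation(warped, inv, ph.grid, cval=ph.air_hu)
        interior = ndimage.binary_erosion(ph.masks["body"], iterations=3)
        err = np.abs(back - ph.reference)[interior]
        # double interpolation across sharp bone/soft interfaces dominates the
        # tail; the bulk must be recovered
        assert np.median(err) < 10.0
        assert np.percentile(err, 95) < 120.0

    def test_grid_mismatch_fails(self, small_phantom):
        ph = small_phantom
        bad = np.zeros((8, 8, 8, 3), dtype=np.float32)
        with pytest.raises(ValueError):
            apply_deformation(ph.reference, bad, ph.grid)


class TestDeltaMotion:
    def _toy(self, base_value):
        grid = Grid((12, 12, 12), (2.0, 2.0, 2.0))
        masks = {
            "body": np.ones(grid.shape, bool),
            "lung_left": np.zeros(grid.shape, bool),
            "lung_right": np.zeros(grid.shape, bool),
            "heart": np.zeros(grid.shape, bool),
            "ribcage": np.zeros(grid.shape, bool),
            "target": np.zeros(grid.shape, bool),
            "itv": np.zeros(grid.shape, bool),
        }
        masks["itv"][4:8, 4:8, 4:8] = True
        base = np.zeros(tuple(grid.shape) + (3,), np.float32)
        base[..., 2] = base_value
        img = np.zeros(grid.shape, np.float32)
        scale = np.array([0.0, 0.5, 0.8, 0.9, 0.95, 1.0, 0.95, 0.9, 0.8, 0.5])
        return Phantom4D("supine", grid, img, [img] * 10, masks, base, scale)

    def test_zero_field_gives_zero(self):
        assert target_delta_motion(self._toy(0.0)) == 0.0

    def test_uniform_3mm_gives_3mm(self):
        # phase 5 carries full amplitude in the toy scale vector
        assert target_delta_motion(self._toy(3.0)) == pytest.approx(3.0, abs=1e-6)

    def test_empty_itv_fails(self):
        ph = self._toy(1.0)
        ph.masks["itv"][:] = False
        with pytest.raises(ValueError):
            target_delta_motion(ph)

    def test_invariant_under_rigid_translation(self, small_phantom):
        ph = small_phantom
        shift = (2, 1, 3)
        rolled_masks = {k: np.roll(v, shift, axis=(0, 1, 2)) for k, v in ph.masks.items()}
        rolled = Phantom4D(
            ph.posture, ph.grid, np.roll(ph.reference, shift, axis=(0, 1, 2)),
            ph.phases, rolled_masks, np.roll(ph.motion_base, shift, axis=(0, 1, 2)),
            ph.phase_scale,
        )
        assert target_delta_motion(rolled) == pytest.approx(
            target_delta_motion(ph), rel=0.02
        )


def test_io_round_trip(tmp_path, small_phantom):
    write_phantom(small_phantom, tmp_path / "ph")
    back = read_phantom(tmp_path / "ph")
    assert back.posture == small_phantom.posture
    assert back.grid == small_phantom.grid
    np.testing.assert_allclose(back.reference, small_phantom.reference, atol=1e-3)
    np.testing.assert_array_equal(back.masks["itv"], small_phantom.masks["itv"])
    np.testing.assert_allclose(back.motion_base, small_phantom.motion_base, atol=1e-4)
    np.testing.assert_allclose(back.phase_scale, small_phantom.phase_scale)
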