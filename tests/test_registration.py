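"""ROI construction, demons registration, contour propagation and QA metrics."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from posture4d._grid import Grid, mask_com_mm
from posture4d.registration import (
    RegistrationParams,
    build_ribcage_roi,
    contour_qa,
    propagate_contour,
    register_roi_restricted,
)


class TestRibcageRoi:
    def test_margin_zero_is_union_in_body(self, small_phantom):
        masks = small_phantom.masks
        roi = build_ribcage_roi(masks, small_phantom.grid, margin_mm=0.0)
        union = (masks["lung_left"] | masks["lung_right"] | masks["heart"] | masks["itv"])
        np.testing.assert_array_equal(roi, union & masks["body"])

    def test_monotone_in_margin(self, small_phantom):
        g = small_phantom.grid
        a = build_ribcage_roi(small_phantom.masks, g, margin_mm=4.0)
        b = build_ribcage_roi(small_phantom.masks, g, margin_mm=10.0)
        assert not np.any(a & ~b)
        assert b.sum() > a.sum()

    def test_voxel_count_matches_brute_force_dilation_oracle(self):
        grid = Grid((16, 16, 16), (2.0, 2.0, 3.0))
        masks = {
            "lung_left": np.zeros(grid.shape, bool),
            "lung_right": np.zeros(grid.shape, bool),
            "heart": np.zeros(grid.shape, bool),
            "body": np.ones(grid.shape, bool),
        }
        masks["lung_left"][4:7, 5:8, 6:9] = True
        masks["heart"][9:11, 9:11, 4:6] = True
        margin = 5.0
        roi = build_ribcage_roi(masks, grid, margin_mm=margin)
        union = masks["lung_left"] | masks["heart"]
        pts_union = grid.index_to_phys(np.argwhere(union))
        pts_all = grid.index_to_phys(np.argwhere(np.ones(grid.shape, bool)))
        d = cdist(pts_all, pts_union).min(axis=1)
        oracle = (d <= margin).reshape(grid.shape)
        np.testing.assert_array_equal(roi, oracle)

    def test_empty_union_fails(self, small_phantom):
        masks = {k: np.zeros(small_phantom.grid.shape, bool) for k in
                 ("lung_left", "lung_right", "heart", "body")}
        with pytest.raises(ValueError):
            build_ribcage_roi(masks, small_phantom.grid)


class TestContourQA:
    def test_identical_masks(self, small_phantom):
        m = small_phantom.masks["lung_left"]
        qa = contour_qa(m, m, small_phantom.grid)
        assert qa.dsc == 1.0 and qa.ahd_mm == 0.0
        assert qa.com_distance_mm == 0.0 and qa.volume_diff_pct == 0.0

    def test_disjoint_masks_dsc_zero(self):
        grid = Grid((12, 12, 12), (2.0, 2.0, 2.0))
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[2:4, 2:4, 2:4] = True
        b[8:10, 8:10, 8:10] = True
        assert contour_qa(a, b, grid).dsc == 0.0

    def test_half_overlapping_boxes_dsc(self):
        # two 10-voxel boxes sharing 5 voxels: DSC = 2*5/(10+10) = 0.5
        grid = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[1:11, 2, 2] = True
        b[6:11, 2, 2] = True  # 5 shared voxels
        b[0, 3:8, 4] = True  # 5 voxels elsewhere
        assert a.sum() == 10 and b.sum() == 10 and (a & b).sum() == 5
        assert contour_qa(a, b, grid).dsc == pytest.approx(0.5)

    def test_symmetry(self, small_phantom):
        g = small_phantom.grid
        a = small_phantom.masks["lung_left"]
        b = ndimage.binary_dilation(a, iterations=2)
        qa_ab = contour_qa(a, b, g)
        qa_ba = contour_qa(b, a, g)
        assert qa_ab.dsc == pytest.approx(qa_ba.dsc)
        assert qa_ab.ahd_mm == pytest.approx(qa_ba.ahd_mm)

    def test_ahd_below_max_directed_hausdorff(self):
        grid = Grid((14, 14, 14), (1.5, 1.5, 1.5))
        rng = np.random.default_rng(7)
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[3:8, 3:8, 3:8] = True
        b[5:11, 4:9, 3:9] = True
        qa = contour_qa(a, b, grid)

        def boundary_pts(m):
            bd = m & ~ndimage.binary_erosion(m)
            return grid.index_to_phys(np.argwhere(bd))

        d = cdist(boundary_pts(a), boundary_pts(b))
        hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert qa.ahd_mm <= hausdorff + 1e-9

    def test_both_empty_fails(self):
        grid = Grid((8, 8, 8), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            contour_qa(np.zeros(grid.shape, bool), np.zeros(grid.shape, bool), grid)


class TestPropagation:
    def test_identity_field(self, small_phantom):
        g = small_phantom.grid
        zero = np.zeros(tuple(g.shape) + (3,), np.float32)
        m = small_phantom.masks["heart"]
        np.testing.assert_array_equal(propagate_contour(m, zero, g), m)

    def test_uniform_translation_com_oracle(self, small_phantom):
        g = small_phantom.grid
        dvf = np.zeros(tuple(g.shape) + (3,), np.float32)
        dvf[..., 0] = 8.0
        m = small_phantom.masks["heart"]
        out = propagate_contour(m, dvf, g)
        shift = mask_com_mm(out, g) - mask_com_mm(m, g)
        assert shift[0] == pytest.approx(-8.0, abs=float(g.spacing[0]))

    def test_empty_input_empty_output(self, small_phantom):
        g = small_phantom.grid
        zero = np.zeros(tuple(g.shape) + (3,), np.float32)
        out = propagate_contour(np.zeros(g.shape, bool), zero, g)
        assert not out.any()

    def test_ground_truth_field_propagates_lungs_consistently(self, small_pair):
        # by construction the upright masks are the supine masks pulled
        # through the inter-posture field
        out = propagate_contour(
            small_pair.supine.lungs, small_pair.inter_posture_dvf,
            small_pair.supine.grid, small_pair.upright.grid,
        )
        qa = contour_qa(out, small_pair.upright.lungs, small_pair.upright.grid)
        assert qa.dsc >= 0.95


class TestDemonsRegistration:
    def test_identity_registration_near_zero_field(self, small_phantom):
        ph = small_phantom
        roi = build_ribcage_roi(ph.masks, ph.grid)
        params = RegistrationParams(shrink_factors=(2, 1), smoothing_sigmas_mm=(6.0, 4.0),
                                    iterations=(30, 20))
        dvf = register_roi_restricted(
            ph.reference, ph.grid, ph.reference, ph.grid, roi, roi, params
        )
        mean_mag = np.linalg.norm(dvf, axis=-1)[roi].mean()
        assert mean_mag <= 0.1 * float(min(ph.grid.spacing))

    def test_known_translation_recovered(self, small_phantom):
        ph = small_phantom
        g = ph.grid
        t_mm = 8.0  # two voxels along y
        shift_vox = t_mm / g.spacing[1]
        moving = ndimage.shift(ph.reference, (0, -shift_vox, 0), order=1, cval=-1000.0)
        roi = build_ribcage_roi(ph.masks, g)
        roi_moving = ndimage.shift(roi.astype(float), (0, -shift_vox, 0), order=0) > 0.5
        dvf = register_roi_restricted(ph.reference, g, moving, g, roi, roi_moving)
        inner = ndimage.binary_erosion(roi, iterations=2)
        mean_dy = dvf[..., 1][inner].mean()
        # fixed(x) = moving(x + d): content moved -y, so d ~ -t
        assert mean_dy == pytest.approx(-t_mm, abs=float(g.spacing[1]))

    def test_posture_pair_registration_quality(self, small_pair):
        sup, up = small_pair.supine, small_pair.upright
        roi_up = build_ribcage_roi(up.masks, up.grid)
        roi_sup = build_ribcage_roi(sup.masks, sup.grid)
        dvf = register_roi_restricted(
            up.reference, up.grid, sup.reference, sup.grid, roi_up, roi_sup
        )
        prop = propagate_contour(sup.lungs, dvf, sup.grid, up.grid)
        qa = contour_qa(prop, up.lungs, up.grid)
        assert qa.dsc >= 0.9  # excellent-agreement bound, reduced grid
        assert np.all(dvf[~roi_up] == 0.0)

    def test_empty_roi_fails(self, small_phantom):
        ph = small_phantom
        empty = np.zeros(ph.grid.shape, bool)
        with pytest.raises(ValueError):
            register_roi_restricted(ph.reference, ph.grid, ph.reference, ph.grid,
                                    empty, empty)
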