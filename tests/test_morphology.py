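import numpy as np
import pytest

from uterseg.core import BinaryMask
from uterseg.morphology import (
    SEShape,
    StructuringElement,
    closing,
    fill_holes,
    largest_central_component,
    opening,
)

from .conftest import random_mask


def mask_from(arr2d):
    return BinaryMask(np.asarray(arr2d, bool)[:, :, None], (1.0, 1.0, 1.0))


SE_DISK = StructuringElement(SEShape.DISK, 1)
SE_BALL = StructuringElement(SEShape.BALL, 1)


class TestFillHoles:
    def test_interior_hole_filled(self):
        sq = np.zeros((9, 9), bool)
        sq[1:8, 1:8] = True
        sq[3:6, 3:6] = False
        out = fill_holes(mask_from(sq))
        expect = np.zeros((9, 9), bool)
        expect[1:8, 1:8] = True
        assert np.array_equal(out.data[:, :, 0], expect)

    def test_no_holes_unchanged_and_idempotent(self, rng):
        m = random_mask(rng)
        once = fill_holes(m)
        assert np.array_equal(fill_holes(once).data, once.data)
        assert np.all(once.data >= m.data)  # extensive

    def test_per_slice_mode_fills_through_slice_tunnels(self):
        # cavity open only through the neighbouring slice
        data = np.zeros((9, 9, 3), bool)
        data[1:8, 1:8, 1] = True
        data[3:6, 3:6, 1] = False  # hole in middle slice, open in 3D via z
        out3d = fill_holes(BinaryMask(data, (1, 1, 1)), mode="volume")
        out2d = fill_holes(BinaryMask(data, (1, 1, 1)), mode="per-slice")
        assert not out3d.data[4, 4, 1]
        assert out2d.data[4, 4, 1]

    def test_phantom_fibroid_holes_restore_solid_uterus(self, fast_config):
        from uterseg.fcm import fcm_cluster, select_enhanced_class
        from uterseg.phantom import generate, preset

        spec = preset("default")
        _, t1c, _ = generate(spec)
        U, model = fcm_cluster(t1c, fast_config)
        sel = select_enhanced_class(U, model, t1c.spacing)
        filled = fill_holes(sel)
        expected = (spec.uterus_mask() | spec.colon_mask())
        assert np.array_equal(filled.data, expected)


class TestOpeningClosing:
    def test_opening_removes_isolated_voxel(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        assert opening(mask_from(m), SE_DISK).voxel_count == 0

    def test_opening_leaves_large_block_mostly_intact(self):
        m = np.zeros((20, 20), bool)
        m[2:18, 2:18] = True
        out = opening(mask_from(m), SE_DISK)
        assert out.voxel_count >= 0.98 * m.sum()

    def test_opening_severs_one_voxel_bridge(self):
        from scipy import ndimage

        m = np.zeros((9, 21), bool)
        m[2:7, 2:7] = True
        m[2:7, 14:19] = True
        m[4, 7:14] = True  # 1-voxel bridge
        out = opening(mask_from(m), SE_DISK)
        labels, n = ndimage.label(out.data[:, :, 0])
        assert n == 2

    def test_closing_seals_thin_crack(self):
        m = np.ones((11, 11), bool)
        m[:, 5] = False
        out = closing(mask_from(m), SE_DISK)
        # interior of the crack is sealed; the mouths stay open to the
        # outside (true closing with background beyond the border)
        assert out.data[1:-1, :, 0].all()
        assert not out.data[0, 5, 0]

    def test_empty_mask_maps_to_empty(self):
        empty = mask_from(np.zeros((6, 6), bool))
        assert closing(empty, SE_DISK).voxel_count == 0
        assert opening(empty, SE_DISK).voxel_count == 0

    @pytest.mark.parametrize("se", [SE_DISK, SE_BALL, StructuringElement(SEShape.SQUARE, 1)])
    def test_algebraic_laws_on_random_masks(self, rng, se):
        for _ in range(5):
            m = random_mask(rng, shape=(14, 14, 6), p=0.45)
            opened = opening(m, se)
            closed = closing(m, se)
            assert np.all(opened.data <= m.data)  # anti-extensive
            assert np.all(closed.data >= m.data)  # extensive
            assert np.array_equal(opening(opened, se).data, opened.data)  # idempotent
            assert np.array_equal(closing(closed, se).data, closed.data)

    def test_duality_opening_is_complement_of_closing(self, rng):
        # away from the border: embed in a padded field and compare the core
        m = np.zeros((20, 20, 8), bool)
        m[6:14, 6:14, 2:6] = random_mask(rng, (8, 8, 4), p=0.5).data
        mask = BinaryMask(m, (1, 1, 1))
        comp = BinaryMask(~m, (1, 1, 1))
        lhs = opening(mask, SE_BALL).data
        rhs = ~closing(comp, SE_BALL).data
        core = (slice(4, 16), slice(4, 16), slice(1, 7))
        assert np.array_equal(lhs[core], rhs[core])

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            StructuringElement(SEShape.DISK, 0)


class TestLargestCentralComponent:
    def test_single_component_returned_unchanged(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        out, empty = largest_central_component(mask_from(m))
        assert not empty
        assert np.array_equal(out.data, mask_from(m).data)

    def test_central_blob_beats_larger_corner_blob(self):
        m = np.zeros((64, 64), bool)
        m[27:37, 27:37] = True  # 100 voxels at the centre
        m[0:12, 0:10] = True  # 120 voxels in the corner
        out, _ = largest_central_component(mask_from(m), mode="per-slice")
        assert out.data[31, 31, 0] and not out.data[2, 2, 0]
        # size/(1+d_c) confirms: 100/(1+~0.7) > 120/(1+~38)
        assert out.voxel_count == 100

    def test_pure_largest_mode_prefers_corner_blob(self):
        m = np.zeros((64, 64), bool)
        m[27:37, 27:37] = True
        m[0:12, 0:10] = True
        out, _ = largest_central_component(mask_from(m), mode="per-slice", score="largest")
        assert out.voxel_count == 120

    def test_empty_mask_warns_and_flags(self):
        with pytest.warns(UserWarning):
            out, empty = largest_central_component(mask_from(np.zeros((5, 5), bool)))
        assert empty and out.voxel_count == 0

    def test_output_is_single_component(self, rng):
        from scipy import ndimage

        for _ in range(5):
            m = random_mask(rng, shape=(20, 20, 6), p=0.35)
            if not m.data.any():
                continue
            out, _ = largest_central_component(m, mode="volume")
            _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
            assert n == 1

    def test_per_slice_mode_single_component_per_slice(self, rng):
        from scipy import ndimage

        m = random_mask(rng, shape=(20, 20, 6), p=0.3)
        out, _ = largest_central_component(m, mode="per-slice")
        for k in range(6):
            sl = out.data[:, :, k]
            _, n = ndimage.label(sl, structure=np.ones((3, 3)))
            assert n <= 1
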