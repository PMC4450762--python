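import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from phasesnake import fill_holes, grayscale_reconstruct, open_close, remove_small_components

from helpers import geodesic_dilation_fixpoint

img8 = arrays(
    dtype=np.uint8, shape=(12, 12), elements=st.integers(0, 255)
)


class TestGrayscaleReconstruct:
    def test_marker_equal_to_mask_is_identity(self):
        mask = np.arange(36, dtype=float).reshape(6, 6)
        assert np.array_equal(grayscale_reconstruct(mask, mask), mask)

    def test_flat_marker_under_flat_mask_stays_flat(self):
        out = grayscale_reconstruct(np.full((5, 5), 3.0), np.full((5, 5), 9.0))
        assert np.array_equal(out, np.full((5, 5), 3.0))

    def test_ring_well_matches_geodesic_dilation_oracle(self):
        # bright ring (200) enclosing a dark well (50) on background 100;
        # marker equals the mask on the border, 0 inside
        mask = np.full((7, 7), 100.0)
        mask[1:6, 1:6] = 200.0
        mask[2:5, 2:5] = 200.0
        mask[3, 3] = 50.0
        marker = np.zeros_like(mask)
        marker[0, :] = mask[0, :]
        marker[-1, :] = mask[-1, :]
        marker[:, 0] = mask[:, 0]
        marker[:, -1] = mask[:, -1]
        expected = geodesic_dilation_fixpoint(marker, mask)
        assert np.array_equal(grayscale_reconstruct(marker, mask), expected)

    @given(marker=img8, mask=img8)
    def test_matches_brute_force_fixpoint_on_random_images(self, marker, mask):
        marker = np.minimum(marker, mask).astype(float)
        mask = mask.astype(float)
        out = grayscale_reconstruct(marker, mask)
        assert np.array_equal(out, geodesic_dilation_fixpoint(marker, mask))

    @given(marker=img8, mask=img8)
    def test_bounded_between_marker_and_mask(self, marker, mask):
        marker = np.minimum(marker, mask).astype(float)
        out = grayscale_reconstruct(marker, mask.astype(float))
        assert np.all(out >= marker) and np.all(out <= mask)

    def test_idempotent_as_marker(self, rng):
        mask = rng.uniform(0, 255, (12, 12))
        marker = np.minimum(rng.uniform(0, 255, (12, 12)), mask)
        once = grayscale_reconstruct(marker, mask)
        assert np.array_equal(grayscale_reconstruct(once, mask), once)

    def test_marker_above_mask_clamped_with_warning(self):
        mask = np.full((4, 4), 5.0)
        marker = np.full((4, 4), 7.0)
        with pytest.warns(UserWarning, match="clamp"):
            out = grayscale_reconstruct(marker, mask)
        assert np.array_equal(out, mask)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            grayscale_reconstruct(np.zeros((3, 3)), np.zeros((4, 4)))


class TestFillHoles:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 42.0)
        assert np.array_equal(fill_holes(img), img)

    def test_dark_pit_in_bright_disk_raised_to_disk_level(self):
        img = np.full((15, 15), 100.0)
        yy, xx = np.mgrid[0:15, 0:15]
        disk = (yy - 7) ** 2 + (xx - 7) ** 2 <= 25
        img[disk] = 200.0
        img[7, 7] = 50.0
        out = fill_holes(img)
        assert out[7, 7] == 200.0
        assert np.array_equal(out[~disk], img[~disk])

    def test_idempotent(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        once = fill_holes(img)
        assert np.allclose(fill_holes(once), once)

    @given(img=img8)
    def test_never_decreases_any_pixel_and_keeps_border(self, img):
        img = img.astype(float)
        out = fill_holes(img)
        assert np.all(out >= img)
        assert np.array_equal(out[0, :], img[0, :])
        assert np.array_equal(out[:, 0], img[:, 0])


class TestRemoveSmallComponents:
    def test_empty_image_stays_empty(self):
        out = remove_small_components(np.zeros((10, 10), bool), 15)
        assert not out.any()

    def test_component_below_threshold_removed(self):
        b = np.zeros((10, 10), bool)
        b[2:4, 2:7] = True  # 10 pixels < P=15
        assert not remove_small_components(b, 15).any()

    def test_size_threshold_is_strict(self):
        b = np.zeros((20, 20), bool)
        b[1:3, 1:8] = True  # 14 px -> removed at P=15
        b[10:14, 10:15] = True  # 20 px -> kept
        out = remove_small_components(b, 15)
        assert not out[1:3, 1:8].any()
        assert out[10:14, 10:15].all()

    def test_exact_size_kept(self):
        b = np.zeros((10, 10), bool)
        b[2:5, 2:7] = True  # exactly 15 px
        assert remove_small_components(b, 15).sum() == 15

    @given(b=arrays(dtype=bool, shape=(16, 16)))
    def test_never_adds_pixels_and_survivors_large_enough(self, b):
        from skimage.measure import label, regionprops

        out = remove_small_components(b, 5)
        assert not (out & ~b).any()
        for region in regionprops(label(out, connectivity=2)):
            assert region.area >= 5


class TestOpenClose:
    def test_large_disk_nearly_unchanged(self):
        from skimage.morphology import disk

        b = np.zeros((41, 41), bool)
        b[4:37, 4:37] = disk(16)
        out = open_close(b, 3)
        assert (b ^ out).sum() <= 0.05 * b.sum()

    def test_isolated_pixel_removed(self):
        b = np.zeros((11, 11), bool)
        b[5, 5] = True
        assert not open_close(b, 3).any()

    def test_idempotent(self, rng):
        b = rng.uniform(size=(40, 40)) > 0.45
        once = open_close(b, 3)
        assert np.array_equal(open_close(once, 3), once)
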