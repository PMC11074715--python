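import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from contourtl import phantoms, prep
from contourtl.errors import NoContourFound, ValidationError
from contourtl.prep import (
    BoundingBox,
    MorphParams,
    binarize,
    crop,
    extract_brain,
    find_external_contours,
    gaussian_smooth,
    largest_contour_bbox,
    morph_clean,
    to_grayscale,
)

EIGHT = np.ones((3, 3), dtype=bool)


class TestGrayscale:
    def test_equal_channels_identity(self):
        img = np.full((4, 4, 3), 137, dtype=np.uint8)
        assert (to_grayscale(img) == 137).all()

    def test_pure_red_bt601(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0, 0] = 255
        assert to_grayscale(img)[0, 0] == 76  # 0.299 * 255 = 76.245

    def test_black_stays_black_and_single_channel_passthrough(self):
        assert (to_grayscale(np.zeros((3, 3, 3), np.uint8)) == 0).all()
        gray = np.arange(9, dtype=np.uint8).reshape(3, 3)
        assert np.array_equal(to_grayscale(gray), gray)

    def test_bad_channel_count_rejected(self):
        with pytest.raises(ValidationError):
            to_grayscale(np.zeros((3, 3, 4), np.uint8))


class TestGaussian:
    def test_constant_image_unchanged(self):
        img = np.full((10, 12), 99, dtype=np.uint8)
        assert np.array_equal(gaussian_smooth(img, 5), img)

    def test_kernel_normalized(self):
        k = prep._gaussian_kernel1d(7, 1.5)
        assert abs(k.sum() - 1.0) < 1e-9

    def test_impulse_response_symmetric_max_at_center(self):
        img = np.zeros((11, 11))
        img[5, 5] = 255
        out = gaussian_smooth(img.astype(np.uint8), 5).astype(int)
        assert out[5, 5] == out.max()
        assert np.array_equal(out, out[::-1, :])
        assert np.array_equal(out, out[:, ::-1])
        # independent direct-convolution oracle
        k1 = prep._gaussian_kernel1d(5, 0)
        oracle = np.clip(np.rint(np.outer(k1, k1) * 255), 0, 255).astype(int)
        assert np.array_equal(out[3:8, 3:8], oracle)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(np.zeros((4, 4), np.uint8), 4)


class TestBinarize:
    def test_threshold_boundary(self):
        img = np.array([[44, 45]], dtype=np.uint8)
        assert list(binarize(img, 45)[0]) == [0, 255]

    def test_all_zero_stays_zero(self):
        assert (binarize(np.zeros((5, 5), np.uint8), 1) == 0).all()

    def test_half_and_half_count(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 255
        assert (binarize(img, 128) == 255).sum() == 32

    @given(
        img=hnp.arrays(np.uint8, (6, 6), elements=st.integers(0, 255)),
        t1=st.integers(0, 255),
        t2=st.integers(0, 255),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, img, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        fg_lo = binarize(img, lo) > 0
        fg_hi = binarize(img, hi) > 0
        assert (fg_hi <= fg_lo).all()
        assert set(np.unique(binarize(img, lo))) <= {0, 255}


class TestMorphology:
    def test_isolated_pixel_eroded_away(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[3, 3] = 255
        params = MorphParams(erode_iterations=1, dilate_iterations=0)
        assert (morph_clean(mask, params) == 0).all()

    def test_solid_square_restored_by_open(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5:25, 5:25] = 255
        out = morph_clean(mask, MorphParams(erode_iterations=2, dilate_iterations=2))
        # set-algebra oracle: erosion then dilation of a large solid square
        # with a square structuring element restores the square exactly
        assert np.array_equal(out, mask)

    def test_empty_mask_fixed_point(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        assert (morph_clean(mask, MorphParams()) == 0).all()

    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((9, 9)) > 0.5).astype(np.uint8) * 255
        out = morph_clean(mask, MorphParams(erode_iterations=0, dilate_iterations=0))
        assert np.array_equal(out, mask)

    @given(mask=hnp.arrays(np.uint8, (8, 8), elements=st.sampled_from([0, 255])))
    @settings(max_examples=50, deadline=None)
    def test_erosion_shrinks_dilation_grows(self, mask):
        fg = mask > 0
        er = morph_clean(mask, MorphParams(erode_iterations=1, dilate_iterations=0)) > 0
        di = morph_clean(mask, MorphParams(erode_iterations=0, dilate_iterations=1)) > 0
        assert (er <= fg).all()
        assert (di >= fg).all()


class TestContours:
    def test_solid_square_one_contour_area(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:14, 6:16] = 255
        cs = find_external_contours(mask)
        assert len(cs) == 1
        assert cs[0].area == 100

    def test_ring_reports_only_outer_contour(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[2:18, 2:18] = 255
        mask[6:14, 6:14] = 0  # hole
        cs = find_external_contours(mask)
        assert len(cs) == 1
        assert cs[0].area == 16 * 16  # filled interior, hole ignored
        assert cs[0].bbox() == BoundingBox(2, 2, 17, 17)

    def test_empty_mask_gives_empty_list(self):
        assert find_external_contours(np.zeros((5, 5), np.uint8)) == []

    def test_single_pixel_component(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 3] = 255
        cs = find_external_contours(mask)
        assert len(cs) == 1
        assert cs[0].points == ((2, 3),)
        assert cs[0].area == 1

    def test_chain_approximation_compresses_straight_runs(self):
        mask = np.zeros((10, 30), dtype=np.uint8)
        mask[3:7, 5:25] = 255  # 4x20 rectangle: 4 corners after compression
        cs = find_external_contours(mask)
        assert len(cs[0].points) == 4
        assert set(cs[0].points) == {(3, 5), (3, 24), (6, 24), (6, 5)}

    @given(
        mask=hnp.arrays(np.uint8, (16, 16), elements=st.sampled_from([0, 0, 0, 255]))
    )
    @settings(max_examples=60, deadline=None)
    def test_contour_count_matches_flood_fill_oracle(self, mask):
        n_components = ndimage.label(mask > 0, structure=EIGHT)[1]
        assert len(find_external_contours(mask)) == n_components

    @given(mask=hnp.arrays(np.uint8, (12, 12), elements=st.sampled_from([0, 0, 255])))
    @settings(max_examples=60, deadline=None)
    def test_every_component_pixel_inside_some_bbox(self, mask):
        cs = find_external_contours(mask)
        covered = np.zeros_like(mask, dtype=bool)
        for c in cs:
            b = c.bbox()
            covered[b.row_min : b.row_max + 1, b.col_min : b.col_max + 1] = True
        assert covered[mask > 0].all()


class TestLargestAndCrop:
    def _mask_with_two_blobs(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[10:20, 30:40] = 255  # area 100
        mask[25:30, 5:10] = 255  # area 25
        return mask

    def test_largest_blob_selected(self):
        cs = find_external_contours(self._mask_with_two_blobs())
        box = largest_contour_bbox(cs)
        assert box == BoundingBox(10, 30, 19, 39)

    def test_bbox_extent_matches_component_pixels(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[10:21, 30:51] = 255  # rows 10-20, cols 30-50
        box = largest_contour_bbox(find_external_contours(mask))
        assert (box.row_min, box.col_min, box.row_max, box.col_max) == (10, 30, 20, 50)

    def test_empty_list_raises(self):
        with pytest.raises(NoContourFound):
            largest_contour_bbox([])

    def test_crop_shapes(self):
        img = np.arange(100, dtype=np.uint8).reshape(10, 10)
        assert np.array_equal(crop(img, BoundingBox(0, 0, 9, 9)), img)
        one = crop(img, BoundingBox(0, 0, 0, 0))
        assert one.shape == (1, 1) and one[0, 0] == img[0, 0]
        assert crop(np.zeros((40, 60), np.uint8), BoundingBox(10, 30, 20, 50)).shape == (11, 21)

    def test_crop_out_of_bounds(self):
        with pytest.raises(ValidationError):
            crop(np.zeros((5, 5), np.uint8), BoundingBox(0, 0, 5, 4))


class TestExtractBrain:
    def test_crop_tightly_bounds_the_ellipse(self):
        spec = phantoms.tumor_spec(noise_sd=0.0)
        li = phantoms.generate_phantom(spec, seed=3)
        cropped = extract_brain(li.image)
        ay, ax = spec.brain_axes
        assert cropped.size <= li.image.size
        # at least as large as the inscribed ellipse bounding box, at most
        # slightly larger (morphology can move the boundary a pixel or two)
        assert 2 * ay - 4 <= cropped.shape[0] <= 2 * ay + 5
        assert 2 * ax - 4 <= cropped.shape[1] <= 2 * ax + 5

    def test_all_black_image_raises(self):
        with pytest.raises(NoContourFound):
            extract_brain(np.zeros((64, 64), dtype=np.uint8))

    def test_idempotent_within_two_pixels_per_side(self, normal_image):
        once = extract_brain(normal_image.image)
        twice = extract_brain(once)
        assert abs(once.shape[0] - twice.shape[0]) <= 4
        assert abs(once.shape[1] - twice.shape[1]) <= 4

    def test_three_channel_input_accepted(self, tumor_image):
        rgb = np.repeat(tumor_image.image[..., None], 3, axis=2)
        out = extract_brain(rgb)
        assert out.ndim == 3 and out.shape[2] == 3
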