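"""ROI geometry, noise model, resizing and augmentation."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from sijbme import phantom, preprocess
from sijbme.phantom import Box
from sijbme.preprocess import NoiseParams


class TestRoiGeometry:
    def test_hand_computed_left_roi(self):
        # left box cols [10,50): width 40, center 30; 0.8*40 = 32 -> [30, 62)
        left = Box(20, 80, 10, 50)
        right = Box(20, 80, 150, 190)
        rb = preprocess.compute_roi_boxes(left, right, 0.8)
        assert rb.left_roi.as_tuple() == (20, 80, 30, 62)
        assert rb.left_roi.height == left.height

    def test_zero_shift_fraction_rejected(self):
        left, right = Box(0, 10, 0, 10), Box(0, 10, 20, 30)
        with pytest.raises(ValueError):
            preprocess.compute_roi_boxes(left, right, 0.0)

    def test_order_violation_rejected(self):
        with pytest.raises(ValueError):
            preprocess.compute_roi_boxes(Box(0, 10, 20, 30), Box(0, 10, 0, 25), 0.8)

    @given(
        c0=st.integers(2, 30),
        width=st.integers(4, 30),
        rows=st.tuples(st.integers(0, 20), st.integers(30, 60)),
        img_w=st.integers(100, 140),
        frac=st.floats(0.3, 1.0),
    )
    def test_mirror_symmetry(self, c0, width, rows, img_w, frac):
        """Symmetric iliac boxes about the midline give mirror-image ROIs."""
        assume(2 * (c0 + width) <= img_w)  # boxes must not overlap
        left = Box(rows[0], rows[1], c0, c0 + width)
        right = Box(rows[0], rows[1], img_w - (c0 + width), img_w - c0)
        rb = preprocess.compute_roi_boxes(left, right, frac)
        lr, rr = rb.left_roi, rb.right_roi
        # reflect the left ROI: col c -> img_w - 1 - c
        assert (img_w - lr.c1, img_w - lr.c0) == (rr.c0, rr.c1)
        assert (lr.r0, lr.r1) == (rr.r0, rr.r1)

    def test_translation_equivariance(self, phantom_params):
        exam = phantom.generate_subject(phantom_params, positive=True, seed=5)
        s = next(sl for sl in exam.slices if sl.lesion_masks)
        rb = preprocess.compute_roi_boxes(s.left_box, s.right_box, 0.8)
        patch = preprocess.extract_roi_patch(s.image, rb)
        dr, dc = 3, -2
        shifted = np.roll(np.roll(s.image, dr, axis=0), dc, axis=1)
        shift_box = lambda b: Box(b.r0 + dr, b.r1 + dr, b.c0 + dc, b.c1 + dc)
        rb2 = preprocess.compute_roi_boxes(shift_box(s.left_box), shift_box(s.right_box), 0.8)
        patch2 = preprocess.extract_roi_patch(shifted, rb2)
        np.testing.assert_array_equal(patch.image, patch2.image)

    def test_lesions_covered_by_rois(self, phantom_params):
        """>=95% of lesion pixels fall inside the union of the two ROIs."""
        rng = np.random.default_rng(0)
        covered = total = 0
        checked = 0
        while checked < 50:
            exam = phantom.generate_subject(phantom_params, True, int(rng.integers(1, 10**6)))
            for s in exam.slices:
                if not s.lesion_masks:
                    continue
                rb = preprocess.compute_roi_boxes(
                    s.left_box, s.right_box, 0.8, image_shape=s.image.shape
                )
                union = np.any(np.stack(s.lesion_masks), axis=0)
                inroi = np.zeros_like(union)
                for b in (rb.left_roi, rb.right_roi):
                    inroi[b.r0 : b.r1, b.c0 : b.c1] = True
                covered += (union & inroi).sum()
                total += union.sum()
                checked += 1
        assert covered / total >= 0.95


class TestPatchExtraction:
    def test_equal_height_concatenation(self):
        img = np.random.default_rng(1).random((100, 200))
        rb = preprocess.RoiBoxes(Box(10, 70, 20, 52), Box(10, 70, 120, 152))
        patch = preprocess.extract_roi_patch(img, rb)
        assert patch.image.shape == (60, 64)

    def test_height_matching_extends_shorter_side(self):
        img = np.random.default_rng(2).random((100, 200))
        rb = preprocess.RoiBoxes(Box(10, 70, 20, 50), Box(15, 65, 120, 150))
        patch = preprocess.extract_roi_patch(img, rb)
        assert patch.image.shape[0] == 60  # right crop grown from 50 to 60 rows
        assert patch.right_roi.height == 60

    def test_pixels_copied_not_interpolated(self):
        img = np.random.default_rng(3).random((80, 160))
        rb = preprocess.RoiBoxes(Box(5, 45, 10, 40), Box(5, 45, 100, 130))
        patch = preprocess.extract_roi_patch(img, rb)
        np.testing.assert_array_equal(patch.image[:, :30], img[5:45, 10:40])
        np.testing.assert_array_equal(patch.image[:, 30:], img[5:45, 100:130])

    def test_roi_outside_image_rejected(self):
        img = np.zeros((50, 50))
        rb = preprocess.RoiBoxes(Box(0, 10, 60, 70), Box(0, 10, 80, 90))
        with pytest.raises(ValueError):
            preprocess.extract_roi_patch(img, rb)


class TestScannerNoise:
    def test_disabled_noise_is_identity(self):
        img = np.random.default_rng(4).random((32, 32))
        params = NoiseParams(gaussian_variance=0.0, poisson_rule="disabled", seed=1)
        np.testing.assert_array_equal(preprocess.add_scanner_noise(img, params), img)

    def test_deterministic_for_fixed_seed(self):
        img = np.full((64, 64), 0.4)
        params = NoiseParams(gaussian_variance=0.01, poisson_rule="single_pixel", seed=5)
        a = preprocess.add_scanner_noise(img, params)
        b = preprocess.add_scanner_noise(img, params)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_gaussian_component_variance(self):
        """Empirical variance of the Gaussian component ~ configured value."""
        img = np.full((1000, 1000), 0.5)
        params = NoiseParams(gaussian_variance=0.01, poisson_rule="disabled", seed=6)
        out = preprocess.add_scanner_noise(img, params)
        # 0.5 +/- 5 sigma stays inside [0,1]: clipping is negligible
        var = (out - img).var()
        assert abs(var - 0.01) <= 0.001

    def test_poisson_component_mean(self):
        """Mean added intensity ~ lambda/255 with lambda = ln(255 p + 1)^4."""
        value = 0.01  # constant image -> the sampled pixel is deterministic
        img = np.full((1000, 1000), value)
        lam = preprocess.poisson_mean(value)
        params = NoiseParams(gaussian_variance=0.0, poisson_rule="single_pixel", seed=7)
        out = preprocess.add_scanner_noise(img, params)
        mean_shift = (out - img).mean()
        stderr = np.sqrt(lam / img.size) / 255.0
        assert abs(mean_shift - lam / 255.0) <= 3 * stderr

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(poisson_rule="bogus")
        with pytest.raises(ValueError):
            NoiseParams(gaussian_variance=-1.0)


class TestResize:
    def test_identity_resize(self):
        img = np.random.default_rng(8).random((224, 224))
        out = preprocess.resize_patch(img, (224, 224)).image
        np.testing.assert_allclose(out, img, atol=1e-7)

    def test_constant_image_stays_constant(self):
        out = preprocess.resize_patch(np.full((50, 70), 0.37), (224, 224)).image
        assert out.shape == (224, 224)
        np.testing.assert_allclose(out, 0.37, atol=1e-7)

    def test_downscale_preserves_mean(self):
        checker = np.indices((64, 64)).sum(axis=0) % 2
        out = preprocess.resize_patch(checker.astype(float), (32, 32)).image
        assert abs(out.mean() - checker.mean()) <= 0.01 * max(checker.mean(), 1e-9)

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            preprocess.resize_patch(np.zeros((0, 10)), (32, 32))


class TestAugment:
    def test_zero_rotation_no_flip_is_identity(self):
        img = np.random.default_rng(9).random((40, 40))
        out = preprocess.augment(img, rng=0, rotation_range=0.0, flip_probability=0.0)
        np.testing.assert_allclose(out, img)

    def test_flip_is_involution(self):
        img = np.random.default_rng(10).random((40, 40))
        once = preprocess.augment(img, rng=1, rotation_range=0.0, flip_probability=1.0)
        twice = preprocess.augment(once, rng=2, rotation_range=0.0, flip_probability=1.0)
        np.testing.assert_allclose(twice, img)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25)
    def test_dimensions_preserved_for_any_angle(self, seed):
        img = np.random.default_rng(11).random((48, 32))
        out = preprocess.augment(img, rng=seed, rotation_range=180.0)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
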