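"""Preprocessing: body mask, crop round-trips, normalization, resampling
and histogram matching, including independent-oracle cross-checks."""

import numpy as np
import pytest
from skimage import exposure, measure

from dfuseg import (EmptyBodyError, Volume, compute_body_mask, crop_to_body,
                    histogram_match, preprocess_case, resample,
                    zscore_normalize)


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data), spacing_mm=spacing)


class TestBodyMask:
    def test_largest_component_wins(self):
        data = np.zeros((6, 20, 20), dtype=np.float32)
        data[1:5, 2:7, 2:7] = 100.0          # 4*5*5 = 100 voxels
        data[1:3, 12:14, 12:14] = 100.0      # small distractor blob
        mask = compute_body_mask(_vol(data), 60.0).data.astype(bool)
        # oracle: connected-component labeling from scikit-image
        lab = measure.label(data > 60)
        sizes = np.bincount(lab.ravel())[1:]
        big = lab == (np.argmax(sizes) + 1)
        assert mask[big].all()
        assert not mask[lab == (np.argmin(sizes) + 1)].any()

    def test_all_background_raises(self):
        with pytest.raises(EmptyBodyError):
            compute_body_mask(_vol(np.zeros((4, 4, 4))), 60.0)

    def test_interior_hole_is_filled(self):
        data = np.zeros((8, 16, 16), dtype=np.float32)
        data[2:6, 3:13, 3:13] = 100.0
        data[4, 8, 8] = 0.0
        mask = compute_body_mask(_vol(data), 60.0).data
        assert mask[4, 8, 8] == 1

    def test_result_is_single_component(self):
        rng = np.random.default_rng(0)
        data = (rng.uniform(0, 1, (8, 24, 24)) > 0.5) * 100.0
        data[2:6, 4:20, 4:20] = 100.0
        mask = compute_body_mask(_vol(data.astype(np.float32)), 60.0).data
        assert measure.label(mask).max() == 1


class TestCrop:
    def test_tight_bounding_box_along_requested_axes(self):
        body = np.zeros((5, 30, 30), dtype=np.uint8)
        body[:, 10:20, 5:25] = 1
        vol = _vol(np.arange(5 * 30 * 30, dtype=np.float32).reshape(5, 30, 30))
        out, rec = crop_to_body(vol, _vol(body))
        assert out.shape == (5, 10, 20)
        assert rec.lower == (0, 10, 5) and rec.upper == (5, 20, 25)

    def test_no_axes_is_identity(self):
        body = np.zeros((4, 6, 6), dtype=np.uint8)
        body[1, 2, 2] = 1
        vol = _vol(np.ones((4, 6, 6), dtype=np.float32))
        out, rec = crop_to_body(vol, _vol(body), axes=())
        assert out.shape == vol.shape
        assert rec.lower == (0, 0, 0) and rec.upper == vol.shape

    def test_crop_paste_back_roundtrip(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 12, 14)).astype(np.float32)
        body = (data > 0.5).astype(np.uint8)
        body[3, 6, 7] = 1
        out, rec = crop_to_body(_vol(data), _vol(body), axes=(0, 1, 2))
        restored = rec.paste_back(out.data)
        assert np.array_equal(restored[rec.slices], data[rec.slices])
        outside = np.ones_like(data, dtype=bool)
        outside[rec.slices] = False
        assert (restored[outside] == 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            crop_to_body(_vol(np.ones((2, 2, 2))), _vol(np.zeros((2, 2, 2))))


class TestZScore:
    def test_standardizes_mean_and_sd(self, rng):
        vol = _vol(rng.uniform(0, 200, (5, 8, 8)).astype(np.float32))
        out = zscore_normalize(vol)
        assert abs(out.data.mean()) < 1e-5
        assert abs(out.data.std() - 1.0) < 1e-5

    def test_hand_computed_example(self):
        out = zscore_normalize(_vol(np.array([0, 0, 10, 10], dtype=np.float32
                                             ).reshape(1, 1, 4)))
        assert np.allclose(out.data.ravel(), [-1, -1, 1, 1], atol=1e-6)

    def test_idempotent(self, rng):
        vol = _vol(rng.standard_normal((4, 6, 6)).astype(np.float32))
        once = zscore_normalize(vol)
        twice = zscore_normalize(once)
        assert np.allclose(once.data, twice.data, atol=1e-5)

    def test_masked_region(self, rng):
        data = rng.uniform(0, 100, (4, 6, 6)).astype(np.float32)
        mask = np.zeros_like(data, dtype=np.uint8)
        mask[:, 2:5, 2:5] = 1
        out = zscore_normalize(_vol(data), _vol(mask))
        inside = out.data[mask.astype(bool)]
        assert abs(inside.mean()) < 1e-5 and abs(inside.std() - 1) < 1e-4

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(_vol(np.full((3, 3, 3), 7.0)))


class TestResample:
    def test_identity_spacing_preserves_shape_and_data(self, rng):
        vol = _vol(rng.standard_normal((10, 12, 12)).astype(np.float32),
                   spacing=(1.2, 0.5, 0.5))
        out = resample(vol, (1.2, 0.5, 0.5))
        assert out.shape == vol.shape
        assert np.allclose(out.data, vol.data, atol=1e-3)

    def test_shape_formula(self):
        vol = _vol(np.zeros((40, 40, 40), dtype=np.float32),
                   spacing=(1.2, 1.2, 1.2))
        out = resample(vol, (0.6, 0.6, 0.6))
        assert out.shape == (80, 80, 80)
        assert out.spacing_mm == (0.6, 0.6, 0.6)

    def test_label_mode_preserves_value_set(self, rng):
        lab = rng.integers(0, 3, (12, 12, 12)).astype(np.int16)
        out = resample(_vol(lab, spacing=(1.0, 1.0, 1.0)), (0.7, 0.7, 0.7),
                       "label")
        assert set(np.unique(out.data)) <= {0, 1, 2}

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resample(_vol(np.zeros((4, 4, 4))), (0.0, 1.0, 1.0))


class TestHistogramMatch:
    def test_self_match_is_identity(self, rng):
        vol = _vol(rng.uniform(0, 100, (6, 10, 10)).astype(np.float32))
        out = histogram_match(vol, vol)
        assert np.allclose(out.data, vol.data, atol=0.5)

    def test_reduces_ks_distance(self, rng):
        src = _vol(rng.normal(50, 10, (8, 12, 12)).astype(np.float32))
        ref = _vol(rng.normal(200, 40, (8, 12, 12)).astype(np.float32))
        out = histogram_match(src, ref)

        def ks(a, b):
            allv = np.sort(np.concatenate([a, b]))
            ca = np.searchsorted(np.sort(a), allv, side="right") / a.size
            cb = np.searchsorted(np.sort(b), allv, side="right") / b.size
            return np.abs(ca - cb).max()

        before = ks(src.data.ravel(), ref.data.ravel())
        after = ks(out.data.ravel(), ref.data.ravel())
        assert after <= before

    def test_preserves_rank_order(self, rng):
        src = _vol(rng.uniform(0, 1, (5, 8, 8)).astype(np.float32))
        ref = _vol(rng.normal(10, 2, (5, 8, 8)).astype(np.float32))
        out = histogram_match(src, ref)
        flat_in = src.data.ravel()
        flat_out = out.data.ravel()
        pairs = np.random.default_rng(0).integers(0, flat_in.size, (200, 2))
        for i, j in pairs:
            if flat_in[i] < flat_in[j]:
                assert flat_out[i] <= flat_out[j]

    def test_agrees_with_skimage_oracle(self, rng):
        src = rng.normal(30, 5, (6, 10, 10)).astype(np.float32)
        ref = rng.normal(100, 20, (6, 10, 10)).astype(np.float32)
        ours = histogram_match(_vol(src), _vol(ref), n_levels=4096).data
        theirs = exposure.match_histograms(src, ref)
        # both are quantile mappings; agreement up to quantization
        assert np.abs(ours - theirs).mean() < 2.0

    def test_constant_source_rejected(self):
        with pytest.raises(ValueError):
            histogram_match(_vol(np.full((3, 3, 3), 5.0)),
                            _vol(np.arange(27, dtype=np.float32).reshape(3, 3, 3)))


class TestFullPipeline:
    def _case(self):
        data = np.full((16, 40, 40), 10.0, dtype=np.float32)
        data[4:12, 8:32, 10:34] = 150.0
        data[7:10, 15:21, 15:21] = 260.0
        lab = np.zeros_like(data, dtype=np.int16)
        lab[7:10, 15:21, 15:21] = 1
        spacing = (1.2, 0.5, 0.5)
        return _vol(data, spacing), Volume(lab, spacing_mm=spacing)

    def test_image_and_labels_stay_aligned(self):
        img, lab = self._case()
        pp = preprocess_case(img, lab, target_spacing=(1.2, 0.5, 0.5))
        assert pp.image.shape == pp.labels.shape
        # the lesion's bright voxels and label-1 voxels coincide closely
        lesion_mask = pp.labels.data == 1
        assert lesion_mask.any()
        assert pp.image.data[lesion_mask].mean() > pp.image.data.mean() + 1.0

    def test_deterministic(self):
        img, lab = self._case()
        a = preprocess_case(img, lab)
        b = preprocess_case(img, lab)
        assert np.array_equal(a.image.data, b.image.data)
        assert np.array_equal(a.labels.data, b.labels.data)

    def test_pretraining_branch_applies_histogram_match(self):
        img, lab = self._case()
        ref = _vol(np.random.default_rng(0).normal(400, 50, (8, 8, 8)
                                                   ).astype(np.float32))
        plain = preprocess_case(img, lab)
        matched = preprocess_case(img, lab, match_reference=ref)
        # Z-scoring follows the match, so shapes agree but intensities differ
        assert matched.image.shape == plain.image.shape
        assert not np.allclose(matched.image.data, plain.image.data)
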