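"""Sliding-window prediction, flip TTA, ensembling and grid restoration."""

import itertools

import numpy as np
import pytest

from dfuseg import (BasicSegNet, InferenceConfig, NetworkSpec, Volume,
                    ensemble_predict, nn, probabilities_to_labels,
                    restore_to_original_grid, sliding_window_predict,
                    tta_predict)
from dfuseg.inference import compute_window_starts, gaussian_window
from dfuseg.preprocessing import CropRecord


class _ConstNet:
    """Emits fixed logits everywhere — exposes weighting/TTA invariances."""

    def __init__(self, logits=(0.3, -0.1, 1.2), spec=None):
        self.logit_values = np.asarray(logits, dtype=np.float32)
        self.spec = spec or NetworkSpec(
            n_stages=3, channels_per_stage=(2, 2, 2),
            pooling_pattern=((1, 2, 2), (2, 2, 2)),
            deep_supervision_heads=1, n_classes=len(logits))
        self.in_channels = 1

    def __call__(self, x):
        x = np.asarray(x.data if hasattr(x, "data") else x)
        shape = (x.shape[0], len(self.logit_values)) + x.shape[2:]
        out = np.broadcast_to(
            self.logit_values.reshape(1, -1, 1, 1, 1), shape).copy()
        return [nn.Tensor(out)]


def _small_cfg(**kw):
    base = dict(patch_size=(4, 8, 8), window_step_fraction=0.5,
                gaussian_weighting=True, tta_flip_axes=())
    base.update(kw)
    return InferenceConfig(**base)


class TestWindowing:
    def test_single_window_equals_direct_forward(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=0)
        img = rng.standard_normal((1, 8, 32, 32)).astype(np.float32)
        cfg = InferenceConfig(patch_size=(8, 32, 32), window_step_fraction=1.0,
                              gaussian_weighting=True, tta_flip_axes=())
        probs = sliding_window_predict(net, img, cfg)
        with nn.no_grad():
            logits = net(img[None])[0].data[0]
        e = np.exp(logits - logits.max(axis=0, keepdims=True))
        direct = e / e.sum(axis=0, keepdims=True)
        assert np.allclose(probs, direct, atol=1e-5)

    @pytest.mark.parametrize("gaussian", [True, False])
    def test_constant_network_invariant_to_overlap(self, gaussian):
        net = _ConstNet()
        img = np.zeros((1, 8, 16, 16), dtype=np.float32)
        cfg = _small_cfg(window_step_fraction=0.5, gaussian_weighting=gaussian)
        probs = sliding_window_predict(net, img, cfg)
        e = np.exp(net.logit_values - net.logit_values.max())
        expected = e / e.sum()
        assert np.allclose(probs, expected.reshape(-1, 1, 1, 1), atol=1e-5)

    def test_probabilities_sum_to_one(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=1)
        img = rng.standard_normal((1, 12, 48, 40)).astype(np.float32)
        cfg = InferenceConfig(patch_size=(8, 32, 32),
                              window_step_fraction=0.5, tta_flip_axes=())
        probs = sliding_window_predict(net, img, cfg)
        assert probs.shape == (3, 12, 48, 40)
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_small_volume_padded_and_unpadded(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=1)
        img = rng.standard_normal((1, 4, 20, 20)).astype(np.float32)
        probs = sliding_window_predict(
            net, img, InferenceConfig(patch_size=(8, 32, 32),
                                      tta_flip_axes=()))
        assert probs.shape == (3, 4, 20, 20)

    def test_coverage_against_enumeration_oracle(self):
        for size, patch, frac in [(20, 8, 0.5), (16, 8, 1.0), (23, 8, 0.5),
                                  (8, 8, 0.5)]:
            starts = compute_window_starts(size, patch, frac)
            covered = np.zeros(size, dtype=int)
            for s in starts:
                covered[s:s + patch] += 1
            assert covered.min() >= 1
            assert starts == sorted(set(starts))
            assert starts[-1] + patch == max(size, patch)

    def test_gaussian_window_peaks_at_center(self):
        w = gaussian_window((5, 9, 9))
        assert w.max() == w[2, 4, 4] == 1.0


class TestTTA:
    def test_empty_tta_equals_sliding_window(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=0)
        img = rng.standard_normal((1, 8, 32, 32)).astype(np.float32)
        cfg = InferenceConfig(patch_size=(8, 32, 32), tta_flip_axes=())
        assert np.array_equal(tta_predict(net, img, cfg),
                              sliding_window_predict(net, img, cfg))

    def test_symmetric_input_gives_symmetric_output(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=0)
        half = rng.standard_normal((1, 8, 32, 16)).astype(np.float32)
        img = np.concatenate([half, np.flip(half, axis=3)], axis=3)
        cfg = InferenceConfig(patch_size=(8, 32, 32), tta_flip_axes=(2,))
        probs = tta_predict(net, img, cfg)
        assert np.allclose(probs, np.flip(probs, axis=3), atol=1e-4)

    def test_constant_network_unchanged_by_tta(self):
        net = _ConstNet()
        img = np.zeros((1, 8, 16, 16), dtype=np.float32)
        a = tta_predict(net, img, _small_cfg(tta_flip_axes=(0, 1, 2)))
        b = sliding_window_predict(net, img, _small_cfg())
        assert np.allclose(a, b, atol=1e-6)


class TestEnsemble:
    def test_single_model_equals_tta(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=0)
        img = rng.standard_normal((1, 8, 32, 32)).astype(np.float32)
        cfg = InferenceConfig(patch_size=(8, 32, 32), tta_flip_axes=(0,))
        assert np.allclose(ensemble_predict([net], img, cfg),
                           tta_predict(net, img, cfg), atol=1e-7)

    def test_identical_models_idempotent(self, tiny_spec, rng):
        net = BasicSegNet(tiny_spec, seed=0)
        img = rng.standard_normal((1, 8, 32, 32)).astype(np.float32)
        cfg = InferenceConfig(patch_size=(8, 32, 32), tta_flip_axes=())
        one = ensemble_predict([net], img, cfg)
        two = ensemble_predict([net, net], img, cfg)
        assert np.allclose(one, two, atol=1e-6)

    def test_mean_of_two_constant_models(self):
        a = _ConstNet((2.0, 0.0, 0.0))
        b = _ConstNet((0.0, 2.0, 0.0))
        img = np.zeros((1, 4, 8, 8), dtype=np.float32)
        cfg = _small_cfg()
        pa = tta_predict(a, img, cfg)
        pb = tta_predict(b, img, cfg)
        pe = ensemble_predict([a, b], img, cfg)
        assert np.allclose(pe, (pa + pb) / 2, atol=1e-6)
        assert np.allclose(pe.sum(axis=0), 1.0, atol=1e-5)

    def test_incompatible_class_counts_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([_ConstNet((1, 0, 0)), _ConstNet((1, 0))],
                             np.zeros((1, 4, 8, 8), np.float32), _small_cfg())


class TestArgmax:
    def test_one_hot_recovery(self, rng):
        lab = rng.integers(0, 3, (4, 5, 5))
        probs = np.zeros((3, 4, 5, 5), dtype=np.float32)
        for c in range(3):
            probs[c][lab == c] = 1.0
        assert np.array_equal(probabilities_to_labels(probs), lab)

    def test_exact_tie_favors_background(self):
        probs = np.full((3, 1, 1, 1), 1 / 3, dtype=np.float32)
        assert probabilities_to_labels(probs)[0, 0, 0] == 0
        probs = np.array([0.5, 0.5, 0.0], dtype=np.float32).reshape(3, 1, 1, 1)
        assert probabilities_to_labels(probs)[0, 0, 0] == 0

    def test_matches_per_voxel_scan_oracle(self, rng):
        probs = rng.dirichlet([1, 1, 1], size=(4, 4, 4)).transpose(3, 0, 1, 2)
        labels = probabilities_to_labels(probs.astype(np.float32))
        for idx in itertools.product(range(4), repeat=3):
            vals = probs[(slice(None),) + idx]
            best = max(range(3), key=lambda c: (vals[c], -c))
            assert labels[idx] == best


class TestRestore:
    def test_noop_preprocessing_is_identity(self, rng):
        lab = rng.integers(0, 3, (6, 10, 10)).astype(np.int16)
        vol = Volume(lab, spacing_mm=(1.0, 1.0, 1.0))
        rec = CropRecord((0, 0, 0), (6, 10, 10), (6, 10, 10))
        out = restore_to_original_grid(vol, rec, (1.0, 1.0, 1.0))
        assert np.array_equal(out.data, lab)

    def test_roundtrip_preserves_foreground_volume(self):
        full = np.zeros((12, 24, 24), dtype=np.int16)
        full[3:9, 6:18, 6:18] = 1
        rec = CropRecord((0, 4, 4), (12, 22, 22), (12, 24, 24))
        cropped = Volume(full[rec.slices].copy(), spacing_mm=(1.0, 1.0, 1.0))
        resampled = Volume(cropped.data.repeat(2, 1).repeat(2, 2),
                           spacing_mm=(1.0, 0.5, 0.5))
        out = restore_to_original_grid(resampled, rec, (1.0, 1.0, 1.0))
        vol_in = int((full == 1).sum())
        vol_out = int((out.data == 1).sum())
        assert abs(vol_out - vol_in) / vol_in < 0.05
        assert set(np.unique(out.data)) <= {0, 1, 2}
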