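import numpy as np
import pytest

from mispeed.conformer import Conformer, ConformerConfig, TrainedModel
from mispeed.preprocess import EpochSet
from mispeed.xai import (
    CAMResult,
    _bin_cam,
    _upsample_tokens,
    cat,
    gradcam,
    kernel_frequency_response,
    spatial_pattern,
)

CFG = ConformerConfig(
    n_temporal_filters=4,
    temporal_kernel_len=5,
    pool_len=4,
    pool_stride=2,
    embed_dim=4,
    n_attention_layers=1,
    n_heads=2,
    dropout=0.0,
)


def _trained(n_channels=4, n_samples=40, seed=0, fs=10.0):
    m = Conformer(CFG, n_channels, n_samples, seed=seed)
    return TrainedModel(
        model=m, config=CFG, training_log=[], seed=seed,
        channel_names=tuple(f"ch{i}" for i in range(n_channels)), fs=fs, t_min=-1.0,
    )


class TestKernelSpectra:
    def test_delta_kernel_flat_spectrum(self):
        tm = _trained()
        K = np.zeros_like(tm.kernels)
        K[:, 0] = 1.0
        tm.model.params["K"] = K
        spec = kernel_frequency_response(tm)
        assert np.allclose(spec.magnitude, 1.0, atol=1e-9)

    def test_boxcar_matches_brute_force_dft(self):
        """Boxcar kernel spectrum equals the Dirichlet kernel computed by
        direct summation."""
        tm = _trained()
        L = tm.kernels.shape[1]
        tm.model.params["K"] = np.ones_like(tm.kernels)
        spec = kernel_frequency_response(tm)
        # brute-force DFT oracle at each grid frequency
        n = np.arange(L)
        fs = tm.fs
        oracle = np.array(
            [np.abs(np.sum(np.exp(-2j * np.pi * f * n / fs))) for f in spec.freq_grid]
        )
        np.testing.assert_allclose(spec.magnitude[0], oracle, atol=1e-9)
        assert spec.magnitude[0, 0] == pytest.approx(L)

    def test_time_reversal_same_magnitude(self):
        tm = _trained()
        spec1 = kernel_frequency_response(tm)
        tm.model.params["K"] = tm.kernels[:, ::-1].copy()
        spec2 = kernel_frequency_response(tm)
        np.testing.assert_allclose(spec1.magnitude, spec2.magnitude, atol=1e-12)

    def test_invalid_savgol_params(self):
        tm = _trained()
        with pytest.raises(ValueError):
            kernel_frequency_response(tm, smooth=(4, 3))
        with pytest.raises(ValueError):
            kernel_frequency_response(tm, smooth=(3, 3))


class TestSpatialPattern:
    def test_identity_w(self):
        tm = _trained()
        tm.model.params["W"] = np.eye(4)
        pat = spatial_pattern(tm)
        np.testing.assert_allclose(pat.pattern_matrix, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(pat.normalized_abs, np.eye(4), atol=1e-12)
        assert not pat.used_pseudo_inverse

    def test_orthonormal_w_gives_transpose(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        tm = _trained()
        tm.model.params["W"] = q
        pat = spatial_pattern(tm)
        np.testing.assert_allclose(pat.pattern_matrix, q.T, atol=1e-9)

    def test_scale_invariance_of_normalization(self):
        tm = _trained()
        tm.model.params["W"] = 2.0 * np.eye(4)
        pat = spatial_pattern(tm)
        np.testing.assert_allclose(pat.normalized_abs, np.eye(4), atol=1e-12)

    def test_nonsquare_uses_pseudo_inverse(self):
        cfg = ConformerConfig(
            n_temporal_filters=5, temporal_kernel_len=5, pool_len=4, pool_stride=2,
            embed_dim=5, n_attention_layers=1, n_heads=1, dropout=0.0,
        )
        m = Conformer(cfg, 3, 40, seed=0)
        tm = TrainedModel(model=m, config=cfg, training_log=[], seed=0,
                          channel_names=("a", "b", "c"), fs=10.0, t_min=-1.0)
        pat = spatial_pattern(tm)
        assert pat.used_pseudo_inverse
        assert pat.pattern_matrix.shape == (3, 5)


def _epochs_for(tm, n=6, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    t = tm.model.n_samples
    return EpochSet(
        data=rng.standard_normal((n, tm.model.n_channels, t)),
        labels=rng.integers(0, 4, n) if labels is None else np.asarray(labels),
        time_axis=-1.0 + np.arange(t) / tm.fs,
        fs=tm.fs,
        channel_names=tm.channel_names,
    )


class TestGradCAM:
    def test_binned_length_for_six_second_epoch(self):
        cfg = ConformerConfig(
            n_temporal_filters=4, temporal_kernel_len=25, pool_len=75, pool_stride=15,
            embed_dim=4, n_attention_layers=1, n_heads=2, dropout=0.0,
        )
        m = Conformer(cfg, 3, 1500, seed=0)
        tm = TrainedModel(model=m, config=cfg, training_log=[], seed=0,
                          channel_names=("a", "b", "c"), fs=250.0, t_min=-1.0)
        eps = EpochSet(
            data=np.random.default_rng(0).standard_normal((4, 3, 1500)),
            labels=[0, 1, 2, 3],
            time_axis=-1.0 + np.arange(1500) / 250.0,
            fs=250.0,
            channel_names=("a", "b", "c"),
        )
        cam = gradcam(tm, eps, 2)
        assert len(cam.binned) == 12
        assert cam.bin_starts[0] == pytest.approx(-1.0)

    def test_bin_mean_conservation(self):
        tm = _trained()
        eps = _epochs_for(tm, labels=[0, 1, 2, 3, 1, 2])
        cam = gradcam(tm, eps, 1)
        assert cam.binned.mean() == pytest.approx(cam.activation.mean(), abs=1e-12)

    def test_missing_class_error(self):
        tm = _trained()
        eps = _epochs_for(tm, labels=[0, 0, 1, 1, 2, 2])
        with pytest.raises(ValueError, match="fast"):
            gradcam(tm, eps, 3)

    def test_linear_in_feature_maps_for_fixed_gradients(self):
        """CAM = sum_k alpha_k A_k is linear in A for frozen alpha."""
        rng = np.random.default_rng(4)
        tokens_a = rng.standard_normal((2, 7, 4))
        tokens_b = rng.standard_normal((2, 7, 4))
        alpha = rng.standard_normal((2, 1, 4))
        cam = lambda tk: (alpha * tk).sum(axis=-1)
        np.testing.assert_allclose(
            cam(2.0 * tokens_a + tokens_b), 2.0 * cam(tokens_a) + cam(tokens_b), atol=1e-12
        )

    def test_upsampling_nearest_token(self):
        centers = np.array([2.0, 6.0, 10.0])
        vals = np.array([1.0, 2.0, 3.0])
        up = _upsample_tokens(vals, centers, 12)
        # midpoint ties (sample 4 between centers 2 and 6) go to the earlier token
        assert up[4] == 1.0
        np.testing.assert_array_equal(up[:4], 1.0)
        np.testing.assert_array_equal(up[5:8], 2.0)
        np.testing.assert_array_equal(up[9:], 3.0)


class TestCAT:
    def _cam_like(self, eps, value):
        act = np.full(len(eps.time_axis), value)
        starts, binned = _bin_cam(act, eps.time_axis)
        return CAMResult(
            class_label="slow", time_axis=eps.time_axis.copy(), activation=act,
            bin_starts=starts, binned=binned,
        )

    def test_unit_cam_gives_time_mean(self):
        from mispeed.preprocess import normalize

        tm = _trained()
        eps = normalize(_epochs_for(tm, labels=[1, 1, 1, 0, 0, 0]))
        topo = cat(self._cam_like(eps, 1.0), eps, 1)
        np.testing.assert_allclose(topo.values, 0.0, atol=1e-12)

    def test_zero_cam_gives_zero(self):
        tm = _trained()
        eps = _epochs_for(tm, labels=[1, 1, 0, 0, 2, 3])
        topo = cat(self._cam_like(eps, 0.0), eps, 1)
        np.testing.assert_array_equal(topo.values, 0.0)

    def test_misaligned_axes_error(self):
        tm = _trained()
        eps = _epochs_for(tm, labels=[1, 1, 0, 0, 2, 3])
        cam = self._cam_like(eps, 1.0)
        cam.time_axis = cam.time_axis + 0.3
        with pytest.raises(ValueError, match="misaligned"):
            cat(cam, eps, 1)

    def test_recovers_occipital_injection(self):
        """When class information is injected only on occipital channels, the
        CAT of a trained decoder concentrates there."""
        from mispeed.conformer import predict, train
        from mispeed.montage import SSMRP_CHANNELS, SSVEP_CHANNELS, gaussian_topography
        from mispeed.preprocess import bandpass, epoch, iter_folds, normalize
        from mispeed.simulate import (
            HARMONIC_PROFILE,
            ConditionSpec,
            NoiseSpec,
            SessionDesign,
            generate_session,
        )

        design = SessionDesign(n_runs=2)
        ch = design.channel_names
        occ = gaussian_topography(ch, SSVEP_CHANNELS)
        conds = {}
        for lab, f0 in (("rest", 0.0), ("slow", 0.9), ("medium", 2.1), ("fast", 2.6)):
            conds[lab] = ConditionSpec(
                f0=f0,
                harmonic_amps=tuple(2.5 * a for a in HARMONIC_PROFILE) if f0 > 0 else (),
                ssvep_amp=3.0 if f0 > 0 else 0.0,
                ssmrp_topography=np.zeros(len(ch)),
                ssvep_topography=occ,
            )
        sess = generate_session(design, conds, NoiseSpec(noise_scale=0.5), seed=7)
        eps = normalize(epoch(bandpass(sess, 4, 40), -1, 5))
        from mispeed.conformer import ConformerConfig

        cfg = ConformerConfig(
            n_temporal_filters=16, embed_dim=16, n_attention_layers=1, n_heads=4,
            max_epochs=40, patience=10,
        )
        tr, te = next(iter_folds(eps, "leave-one-run-out"))
        tm = train(cfg, tr, te, seed=0)
        assert float((predict(tm, te) == te.labels).mean()) > 0.35  # learned something
        occ_idx = [ch.index(c) for c in SSVEP_CHANNELS]
        motor_idx = [ch.index(c) for c in SSMRP_CHANNELS]
        other_idx = [ch.index(c) for c in ("T7", "Fz")]
        topo = cat(gradcam(tm, eps, "medium"), eps, "medium")
        a = np.abs(topo.values)
        assert a[occ_idx].mean() > a[motor_idx].mean()
        assert a[occ_idx].mean() > a[other_idx].mean()
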