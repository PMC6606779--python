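"""Spectrograms, silence trimming, segmentation, patches, PCA whitening."""

import numpy as np
import pytest

from sparsestruct import preprocess as pp
from sparsestruct import synth


class TestLogSpectrogram:
    def test_pure_tone_peaks_at_nearest_bin(self):
        """Every frame's argmax frequency is the log-spaced bin nearest 1 kHz,
        cross-checked against a direct DFT of one Hamming-windowed frame."""
        sr = 16000
        t = np.arange(sr) / sr
        wav = np.sin(2 * np.pi * 1000.0 * t)
        cfg = pp.SpectrogramConfig()
        spec = pp.compute_log_spectrogram(wav, sr, cfg)
        targets = np.geomspace(cfg.freq_min, cfg.freq_max, cfg.n_freqs)
        # oracle: direct DFT of the first frame
        frame = wav[:cfg.window_samples] * np.hamming(cfg.window_samples)
        dft_freqs = np.fft.rfftfreq(cfg.window_samples, 1 / sr)
        oracle_peak = dft_freqs[np.argmax(np.abs(np.fft.rfft(frame)))]
        peaks = np.argmax(spec, axis=0)
        # several adjacent log-spaced targets can share the same nearest DFT
        # bin; require the peak frequency to sit within half a DFT bin width
        dft_bin_width = sr / cfg.window_samples
        assert np.all(np.abs(targets[peaks] - oracle_peak) <= dft_bin_width)

    def test_all_zero_waveform_is_finite_floor(self):
        cfg = pp.SpectrogramConfig(log_floor=1e-12)
        spec = pp.compute_log_spectrogram(np.zeros(1000), 8000, cfg)
        assert np.all(spec == np.log(1e-12))

    def test_frame_count_arithmetic(self):
        wav = np.random.default_rng(0).standard_normal(32000)
        spec = pp.compute_log_spectrogram(wav, 16000)
        assert spec.shape == (256, (32000 - 256) // 128 + 1)
        assert spec.shape[1] == 249

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            pp.compute_log_spectrogram(np.zeros(100), 8000)

    def test_hop_shift_equivariance(self):
        """Shifting the waveform by an exact hop multiple shifts frames."""
        rng = np.random.default_rng(1)
        wav = rng.standard_normal(8000)
        cfg = pp.SpectrogramConfig(log_floor=1e-10)
        s1 = pp.compute_log_spectrogram(wav, 8000, cfg)
        s2 = pp.compute_log_spectrogram(wav[2 * cfg.hop_samples:], 8000, cfg)
        assert np.allclose(s1[:, 2:2 + s2.shape[1]], s2)


class TestTrimSilence:
    def test_silent_first_half_removed(self):
        sr = 8000
        wav = synth.make_test_waveform([(400.0, 2, 0.5, 1.0)], 1.0, sr,
                                       decay_time=1.0)
        spec = pp.compute_log_spectrogram(wav, sr)
        trimmed = pp.trim_silence(spec, threshold=0.5)
        n_frames = spec.shape[1]
        # surviving frames must come from the loud second half
        power = np.exp(spec).sum(axis=0)
        kept = power >= 0.5 * np.median(power)
        assert np.all(np.nonzero(kept)[0] >= n_frames // 2 - 1)
        assert trimmed.shape[1] == kept.sum()

    def test_zero_threshold_identity(self, rng):
        spec = rng.standard_normal((16, 30))
        assert np.array_equal(pp.trim_silence(spec, 0.0), spec)

    def test_constructed_frame_count(self):
        # 7 frames of power e, 3 frames at a much lower floor
        spec = np.full((4, 10), -30.0)
        spec[:, :7] = 1.0
        out = pp.trim_silence(spec, threshold=0.5)
        assert out.shape == (4, 7)

    def test_all_removed_raises(self):
        spec = np.zeros((4, 5))
        with pytest.raises(ValueError, match="every frame"):
            pp.trim_silence(spec, threshold=2.0)


class TestSegmentation:
    def test_default_segment_is_6400_dim(self, rng):
        spec = rng.standard_normal((256, 25))
        seg = pp.segment_spectrogram(spec, segment_len=25, segment_hop=5)
        assert seg.shape == (1, 6400)

    def test_segment_count(self, rng):
        spec = rng.standard_normal((8, 100))
        seg = pp.segment_spectrogram(spec, segment_len=25, segment_hop=5)
        assert seg.shape[0] == (100 - 25) // 5 + 1 == 16

    def test_flatten_roundtrip(self, rng):
        spec = rng.standard_normal((8, 40))
        seg = pp.segment_spectrogram(spec, segment_len=10, segment_hop=10)
        blocks = pp.segments_to_blocks(seg, n_freqs=8)
        for i in range(blocks.shape[0]):
            assert np.array_equal(blocks[i], spec[:, i * 10:(i + 1) * 10])

    def test_too_few_frames_raises(self, rng):
        with pytest.raises(ValueError):
            pp.segment_spectrogram(rng.standard_normal((8, 10)), segment_len=25)


class TestPatches:
    def test_patch_dimensions_and_centering(self, rng):
        img = rng.random((120, 150)) + 0.5
        patches = pp.extract_patches(img, side=80, n_patches=10, seed=0)
        assert patches.shape == (10, 6400)
        assert np.abs(patches.mean(axis=1)).max() < 1e-12

    def test_constant_image_gives_zero_patches(self):
        img = np.full((50, 50), 7.0)
        patches = pp.extract_patches(img, side=16, n_patches=5, seed=1)
        assert np.all(patches == 0)

    def test_log_of_nonpositive_raises(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="positive"):
            pp.extract_patches(img, side=8, n_patches=2, seed=0, take_log=True)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    # anisotropic Gaussian data with known variance profile
    scales = np.array([10.0, 5.0, 2.0, 1.0, 0.5, 0.1])
    x = rng.standard_normal((5000, 6)) * scales
    return x, pp.fit_whitener(x, n_components=4), scales


class TestWhitening:
    def test_whitened_covariance_is_identity(self, fitted):
        x, w, _ = fitted
        z = pp.whiten(x, w)
        cov = np.cov(z.T, bias=True)
        assert np.abs(cov - np.eye(4)).max() < 1e-8
        assert np.allclose(z.var(axis=0), 1.0, atol=1e-8)

    def test_variance_retained_matches_profile(self, fitted):
        x, w, scales = fitted
        eig = np.sort(np.linalg.eigvalsh(np.cov(x.T, bias=True)))[::-1]
        expected = eig[:4].sum() / eig.sum()
        assert w.variance_retained == pytest.approx(expected, abs=1e-9)

    def test_roundtrip_is_subspace_projection(self, fitted):
        x, w, _ = fitted
        back = pp.unwhiten(pp.whiten(x, w), w)
        resid = x - back
        # residual orthogonal to every retained component
        assert np.abs(resid @ w.components.T).max() < 1e-8

    def test_point_in_subspace_roundtrips_exactly(self, fitted):
        x, w, _ = fitted
        pt = w.mean_vector + 3.0 * w.components[1]
        assert np.allclose(pp.unwhiten(pp.whiten(pt, w), w), pt, atol=1e-9)

    def test_linearity(self, fitted):
        x, w, _ = fitted
        a, b = x[:3], x[3:6]
        lhs = pp.whiten(2 * a + 3 * b, w)
        # affine mean handling: whiten(2a+3b) = 2 w(a) + 3 w(b) - 4 w(0)
        rhs = (2 * pp.whiten(a, w) + 3 * pp.whiten(b, w)
               - 4 * pp.whiten(np.zeros_like(a), w))
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_isotropic_full_rank_retains_all_variance(self, rng):
        x = rng.standard_normal((2000, 5))
        w = pp.fit_whitener(x, n_components=5)
        assert w.variance_retained == pytest.approx(1.0)

    def test_rank_deficiency_raises(self, rng):
        base = rng.standard_normal((200, 2))
        x = np.column_stack([base, base @ np.ones((2, 2))])  # rank 2 in R^4
        with pytest.raises(ValueError, match="zero-variance"):
            pp.fit_whitener(x, n_components=4)

    def test_dimension_mismatch_raises(self, fitted):
        _, w, _ = fitted
        with pytest.raises(ValueError):
            pp.whiten(np.zeros((3, 9)), w)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        x, w, _ = fitted
        w.save(tmp_path / "w.npz")
        w2 = pp.PCAWhitener.load(tmp_path / "w.npz")
        assert np.allclose(pp.whiten(x[:5], w), pp.whiten(x[:5], w2))


def test_wav_roundtrip(tmp_path):
    wav = synth.make_test_waveform([(440.0, 2, 0.0, 1.0)], 0.25, 8000)
    path = tmp_path / "t.wav"
    pp.write_wav(path, wav, 8000)
    back, rate = pp.read_wav(path)
    assert rate == 8000
    # 16-bit quantization plus peak rescaling: shapes agree up to scale
    scale = np.dot(back, wav) / np.dot(wav, wav)
    assert np.allclose(back, scale * wav, atol=2e-3)


def test_normalize_waveform_removes_dc():
    wav = np.sin(np.linspace(0, 20, 2000)) + 5.0
    out = pp.normalize_waveform(wav)
    assert abs(out.mean()) < 1e-12
    assert np.allclose(out, (wav - wav.mean()) / (10 * wav.var()))
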