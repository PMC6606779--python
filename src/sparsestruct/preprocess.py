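"""Preprocessing: log spectrograms, patch extraction, and PCA whitening.

Waveforms become log-power spectrograms (Hamming-windowed 16 ms frames with
half-overlap, power sampled at frequencies logarithmically spaced between
100 Hz and 4 kHz), silence is trimmed, and the spectrograms are cut into
overlapping fixed-length segments.  Images become mean-subtracted
(log-)intensity patches.  Both paths then pass through the same PCA whitener,
which keeps the top ``n_components`` principal components and scales each to
unit variance so the empirical covariance of the whitened fitting set is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import default_rng
from scipy.io import wavfile

__all__ = [
    "SpectrogramConfig",
    "PCAWhitener",
    "compute_log_spectrogram",
    "trim_silence",
    "segment_spectrogram",
    "segments_to_blocks",
    "extract_patches",
    "fit_whitener",
    "whiten",
    "unwhiten",
    "normalize_waveform",
    "read_wav",
    "write_wav",
]


@dataclass
class SpectrogramConfig:
    window_samples: int = 256
    hop_samples: int = 128
    n_freqs: int = 256
    freq_min: float = 100.0
    freq_max: float = 4000.0
    segment_len: int = 25
    log_floor: float | None = None  # None -> 1e-12 x median frame power

    def __post_init__(self):
        if self.hop_samples > self.window_samples:
            raise ValueError("hop_samples must not exceed window_samples")
        if not self.freq_min < self.freq_max:
            raise ValueError("freq_min must be below freq_max")


def normalize_waveform(wav: np.ndarray, by: str = "variance") -> np.ndarray:
    """Remove DC and divide by 10x the variance (or std) of the waveform.

    The divisor only sets an overall scale that whitening later removes; both
    conventions are exposed because either reading of "10 times its variance"
    yields the same downstream statistics.
    """
    w = np.asarray(wav, dtype=float)
    w = w - w.mean()
    denom = w.var() if by == "variance" else w.std()
    if denom == 0:
        return w
    return w / (10.0 * denom)


def compute_log_spectrogram(waveform, sample_rate: float,
                            config: SpectrogramConfig | None = None) -> np.ndarray:
    """Log power at log-spaced frequencies for each Hamming-windowed frame.

    Returns an n_freqs x n_frames array with
    n_frames = floor((len - window) / hop) + 1.  Power at each of the
    ``n_freqs`` logarithmically spaced target frequencies is taken from the
    nearest DFT bin.  A small power floor keeps silent frames finite.
    """
    if config is None:
        config = SpectrogramConfig()
    w = np.asarray(waveform, dtype=float)
    if w.size < config.window_samples:
        raise ValueError(
            f"waveform of {w.size} samples is shorter than one "
            f"{config.window_samples}-sample window"
        )
    if config.freq_max > sample_rate / 2:
        raise ValueError("freq_max exceeds the Nyquist frequency")
    n_frames = (w.size - config.window_samples) // config.hop_samples + 1
    window = np.hamming(config.window_samples)
    idx = (
        np.arange(config.window_samples)[None, :]
        + config.hop_samples * np.arange(n_frames)[:, None]
    )
    frames = w[idx] * window
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # n_frames x (win//2+1)
    dft_freqs = np.fft.rfftfreq(config.window_samples, d=1.0 / sample_rate)
    targets = np.geomspace(config.freq_min, config.freq_max, config.n_freqs)
    nearest = np.argmin(np.abs(dft_freqs[None, :] - targets[:, None]), axis=1)
    sampled = power[:, nearest].T  # n_freqs x n_frames
    if config.log_floor is not None:
        floor = config.log_floor
    else:
        med = np.median(power.sum(axis=1))
        floor = 1e-12 * med if med > 0 else 1e-30
    return np.log(sampled + floor)


def trim_silence(spectrogram: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Drop frames whose total power is below threshold x median frame power.

    Operates on a log-power spectrogram; frame power is recovered by
    exponentiation.  Frame order is preserved.
    """
    s = np.asarray(spectrogram, dtype=float)
    if s.size == 0:
        raise ValueError("empty spectrogram")
    frame_power = np.exp(s).sum(axis=0)
    keep = frame_power >= threshold * np.median(frame_power)
    if not np.any(keep):
        raise ValueError("silence trimming removed every frame")
    return s[:, keep]


def segment_spectrogram(spectrogram: np.ndarray, segment_len: int = 25,
                        segment_hop: int = 5) -> np.ndarray:
    """Cut the spectrogram into overlapping segments, one flattened per row.

    Each row is an (n_freqs x segment_len) block flattened in C order; with
    the default 256 frequencies and 25 frames, rows are 6400-dimensional.
    """
    s = np.asarray(spectrogram, dtype=float)
    n_freqs, n_frames = s.shape
    if n_frames < segment_len:
        raise ValueError(
            f"{n_frames} frames < segment length {segment_len}"
        )
    n_segments = (n_frames - segment_len) // segment_hop + 1
    out = np.empty((n_segments, n_freqs * segment_len))
    for i in range(n_segments):
        out[i] = s[:, i * segment_hop:i * segment_hop + segment_len].ravel()
    return out


def segments_to_blocks(segments: np.ndarray, n_freqs: int) -> np.ndarray:
    """Inverse of the flattening in segment_spectrogram (for display)."""
    seg = np.atleast_2d(segments)
    seg_len = seg.shape[1] // n_freqs
    return seg.reshape(seg.shape[0], n_freqs, seg_len)


def extract_patches(image: np.ndarray, side: int = 80, n_patches: int = 1000,
                    seed: int = 0, take_log: bool = False) -> np.ndarray:
    """Random square patches of (log-)intensity with per-patch mean removed."""
    img = np.asarray(image, dtype=float)
    if img.shape[0] < side or img.shape[1] < side:
        raise ValueError(f"image smaller than {side}x{side}")
    if take_log:
        if np.any(img <= 0):
            raise ValueError("log intensity requires strictly positive pixels")
        img = np.log(img)
    rng = default_rng(seed)
    rows = rng.integers(0, img.shape[0] - side + 1, n_patches)
    cols = rng.integers(0, img.shape[1] - side + 1, n_patches)
    out = np.empty((n_patches, side * side))
    for i, (r, c) in enumerate(zip(rows, cols)):
        patch = img[r:r + side, c:c + side]
        out[i] = (patch - patch.mean()).ravel()
    return out


@dataclass
class PCAWhitener:
    """Fitted PCA whitening transform.

    ``components`` has orthonormal rows (principal axes); ``component_scales``
    are the per-component standard deviations on the fitting set, so whitened
    data have unit variance along every retained axis.
    """

    mean_vector: np.ndarray
    components: np.ndarray
    component_scales: np.ndarray
    variance_retained: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path) -> None:
        np.savez(path, mean_vector=self.mean_vector, components=self.components,
                 component_scales=self.component_scales,
                 variance_retained=self.variance_retained)

    @classmethod
    def load(cls, path) -> "PCAWhitener":
        with np.load(path) as f:
            return cls(f["mean_vector"], f["components"],
                       f["component_scales"], float(f["variance_retained"]))


def fit_whitener(data: np.ndarray, n_components: int = 200) -> PCAWhitener:
    """Fit the PCA whitener on a batch (rows are samples).

    Raises if any retained component has zero variance — that indicates a
    degenerate fitting set, not something to clamp silently.
    """
    x = np.asarray(data, dtype=float)
    n_samples, n_dims = x.shape
    if n_samples <= n_components:
        raise ValueError("need more samples than components to fit the whitener")
    if n_components > n_dims:
        raise ValueError("cannot retain more components than data dimensions")
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD; principal axes are rows of vt
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    variances = svals**2 / n_samples
    kept = variances[:n_components]
    if np.any(kept <= 1e-12 * max(variances[0], 1e-300)):
        raise ValueError(
            "zero-variance principal component within the retained set"
        )
    total = variances.sum()
    return PCAWhitener(
        mean_vector=mean,
        components=vt[:n_components],
        component_scales=np.sqrt(kept),
        variance_retained=float(kept.sum() / total),
    )


def whiten(data: np.ndarray, whitener: PCAWhitener) -> np.ndarray:
    """Project onto the retained axes and scale each to unit variance."""
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[1] != whitener.mean_vector.size:
        raise ValueError(
            f"data dimension {x.shape[1]} != whitener dimension "
            f"{whitener.mean_vector.size}"
        )
    return (x - whitener.mean_vector) @ whitener.components.T / whitener.component_scales


def unwhiten(whitened: np.ndarray, whitener: PCAWhitener) -> np.ndarray:
    """Map whitened coordinates back; composes with whiten to the projection
    of the input onto the retained principal subspace (plus the mean)."""
    z = np.atleast_2d(np.asarray(whitened, dtype=float))
    if z.shape[1] != whitener.n_components:
        raise ValueError(
            f"whitened dimension {z.shape[1]} != {whitener.n_components}"
        )
    return z * whitener.component_scales @ whitener.components + whitener.mean_vector


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file to float64 in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(rate)


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a waveform as 16-bit PCM, rescaled to near full range."""
    w = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak * 0.95
    wavfile.write(path, sample_rate, (w * 32767).astype(np.int16))
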