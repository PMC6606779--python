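"""Synthetic ensembles with controlled sparse structure.

Data are drawn from the linear generative model

    x = sum_m a_m Phi_m + noise,

with a factorial coefficient prior configurable per element.  Symmetric
(Laplace) coefficients emulate the sign-symmetric statistics of natural image
patches; skewed (exponential) and spike-and-slab coefficients emulate the
asymmetric, intermittent structure of speech features such as harmonic stacks
and broadband onsets.  Raw waveform and image-patch surrogates are provided so
the spectrogram and patch pipelines can be exercised without external corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng

__all__ = [
    "CoeffDist",
    "GenerativeSpec",
    "make_dictionary",
    "random_orthonormal_dictionary",
    "generate_ensemble",
    "symmetric_ensemble",
    "skewed_ensemble",
    "make_test_waveform",
    "make_image_like_patches",
    "save_ensemble",
    "load_ensemble",
]

DICTIONARY_KINDS = ("random_gaussian", "oriented_edge", "harmonic_stack", "onset")


@dataclass(frozen=True)
class CoeffDist:
    """Coefficient distribution for one dictionary element.

    ``kind`` is one of ``laplace`` (symmetric, scale b), ``exponential``
    (non-negative, skewness 2, scale b), or ``spike_and_slab`` (zero with
    probability 1 - p_active, otherwise drawn from ``slab``).
    """

    kind: str
    scale: float = 1.0
    p_active: float = 1.0
    slab: "CoeffDist | None" = None

    def __post_init__(self):
        if self.kind not in ("laplace", "exponential", "spike_and_slab"):
            raise ValueError(f"unknown coefficient distribution {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if not 0.0 <= self.p_active <= 1.0:
            raise ValueError("p_active must lie in [0, 1]")
        if self.kind == "spike_and_slab" and self.slab is None:
            object.__setattr__(self, "slab", CoeffDist("laplace", self.scale))

    def sample(self, n: int, rng: Generator) -> np.ndarray:
        if self.kind == "laplace":
            return rng.laplace(0.0, self.scale, n)
        if self.kind == "exponential":
            return rng.exponential(self.scale, n)
        draw = self.slab.sample(n, rng)
        active = rng.random(n) < self.p_active
        return np.where(active, draw, 0.0)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "scale": self.scale, "p_active": self.p_active}
        if self.kind == "spike_and_slab":
            d["slab"] = self.slab.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CoeffDist":
        slab = cls.from_dict(d["slab"]) if "slab" in d else None
        return cls(d["kind"], d.get("scale", 1.0), d.get("p_active", 1.0), slab)


@dataclass
class GenerativeSpec:
    """Ground-truth dictionary plus per-element coefficient distributions."""

    dictionary: np.ndarray  # K x D, unit-norm rows
    coeff_dists: list[CoeffDist]
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.dictionary = np.asarray(self.dictionary, dtype=float)
        if self.dictionary.ndim != 2:
            raise ValueError("dictionary must be a K x D matrix")
        norms = np.linalg.norm(self.dictionary, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("dictionary rows must have unit norm")
        if isinstance(self.coeff_dists, CoeffDist):
            self.coeff_dists = [self.coeff_dists] * self.n_elements
        if len(self.coeff_dists) != self.n_elements:
            raise ValueError("need one coefficient distribution per element")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_elements(self) -> int:
        return self.dictionary.shape[0]

    @property
    def n_dims(self) -> int:
        return self.dictionary.shape[1]


def _harmonic_stack_element(n_dims: int, f0: int, n_harmonics: int, rng: Generator):
    el = np.zeros(n_dims)
    for k in range(1, n_harmonics + 1):
        idx = k * f0
        if idx >= n_dims:
            break
        el[idx] = 1.0 / k * (0.75 + 0.5 * rng.random())
    return el


def _oriented_edge_element(side: int, rng: Generator) -> np.ndarray:
    # Gabor-like oriented edge: odd-symmetric sinusoid under a Gaussian envelope
    theta = rng.uniform(0, np.pi)
    freq = rng.uniform(1.5, 4.0) / side
    cx, cy = rng.uniform(side * 0.25, side * 0.75, 2)
    sigma = side / rng.uniform(4.0, 8.0)
    yy, xx = np.mgrid[0:side, 0:side]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    env = np.exp(-(u**2 + v**2) / (2 * sigma**2))
    return (env * np.sin(2 * np.pi * freq * u)).ravel()


def make_dictionary(kind: str, n_dims: int, n_elements: int, seed: int) -> np.ndarray:
    """Build a K x D dictionary of unit-norm elements of the given kind.

    ``random_gaussian``: iid normal directions (the null model).
    ``oriented_edge``: Gabor-like edges on a sqrt(D) x sqrt(D) grid.
    ``harmonic_stack``: non-negative energy at integer multiples of a base
    frequency index, amplitude falling off with harmonic number.
    ``onset``: zero left of a step index, then an abrupt rise with slow decay.
    """
    if n_dims < 1 or n_elements < 1:
        raise ValueError("n_dims and n_elements must be >= 1")
    if kind not in DICTIONARY_KINDS:
        raise ValueError(f"unknown dictionary kind {kind!r}; choose from {DICTIONARY_KINDS}")
    rng = default_rng(seed)
    if kind == "random_gaussian":
        d = rng.standard_normal((n_elements, n_dims))
    elif kind == "oriented_edge":
        side = int(round(np.sqrt(n_dims)))
        if side * side != n_dims:
            raise ValueError("oriented_edge requires n_dims to be a perfect square")
        d = np.stack([_oriented_edge_element(side, rng) for _ in range(n_elements)])
    elif kind == "harmonic_stack":
        max_f0 = max(n_dims // 4, 2)
        f0s = rng.integers(1, max_f0, n_elements, endpoint=True)
        d = np.stack(
            [_harmonic_stack_element(n_dims, int(f0), 8, rng) for f0 in f0s]
        )
    else:  # onset
        d = np.zeros((n_elements, n_dims))
        onsets = rng.integers(0, max(n_dims - 2, 1), n_elements)
        decay = n_dims / 4.0
        t = np.arange(n_dims)
        for m, o in enumerate(onsets):
            prof = np.where(t >= o, np.exp(-(t - o) / decay), 0.0)
            d[m] = prof
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate zero-norm element generated")
    return d / norms


def random_orthonormal_dictionary(n_dims: int, n_elements: int, seed: int) -> np.ndarray:
    """Rows of a Haar-random orthogonal matrix (requires K <= D)."""
    if n_elements > n_dims:
        raise ValueError("an orthonormal dictionary needs K <= D")
    rng = default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n_dims, n_dims)))
    q = q * np.sign(np.diag(r))  # make the distribution Haar
    return q[:, :n_elements].T


def generate_ensemble(
    spec: GenerativeSpec, n_samples: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``(data, coefficients)`` from the linear generative model.

    ``data`` is n_samples x D, ``coefficients`` n_samples x K; the latter are
    the ground truth for parameter-recovery experiments.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = default_rng(seed)
    a = np.column_stack(
        [dist.sample(n_samples, rng) for dist in spec.coeff_dists]
    )
    x = a @ spec.dictionary
    if spec.noise_sigma > 0:
        x = x + rng.normal(0.0, spec.noise_sigma, x.shape)
    return x, a


def symmetric_ensemble(
    n_dims: int = 64,
    n_elements: int = 64,
    n_samples: int = 20000,
    seed: int = 0,
    p_active: float = 0.1,
    noise_sigma: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, GenerativeSpec]:
    """The image-like study ensemble: sign-symmetric sparse coefficients.

    Ground truth is a random orthonormal dictionary; coefficients are
    spike-and-slab with a Laplace slab, so each feature appears in a minority
    of samples with either sign equally often — the statistical signature of
    natural image patches in this analysis.
    """
    phi = random_orthonormal_dictionary(n_dims, n_elements, seed)
    dist = CoeffDist("spike_and_slab", scale=1.0, p_active=p_active,
                     slab=CoeffDist("laplace", 1.0))
    spec = GenerativeSpec(phi, [dist] * n_elements, noise_sigma=noise_sigma)
    x, a = generate_ensemble(spec, n_samples, seed + 1)
    return x, a, spec


def skewed_ensemble(
    n_dims: int = 64,
    n_elements: int = 64,
    n_samples: int = 20000,
    seed: int = 0,
    p_active_range: tuple[float, float] = (0.02, 0.3),
    noise_sigma: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, GenerativeSpec]:
    """The speech-like study ensemble: non-negative, skewed, heterogeneous.

    Ground truth mixes harmonic stacks and onset profiles (both non-negative,
    like spectrogram energy); coefficients are spike-and-slab with an
    exponential slab, activation probabilities spread across elements so that
    sparseness and skewness vary widely across features — the signature of
    speech spectrograms in this analysis.
    """
    half = n_elements // 2
    rng = default_rng(seed)
    stacks = make_dictionary("harmonic_stack", n_dims, half, seed)
    onsets = make_dictionary("onset", n_dims, n_elements - half, seed + 1)
    phi = np.vstack([stacks, onsets])
    p_lo, p_hi = p_active_range
    p_actives = np.exp(rng.uniform(np.log(p_lo), np.log(p_hi), n_elements))
    dists = [
        CoeffDist("spike_and_slab", scale=1.0, p_active=float(p),
                  slab=CoeffDist("exponential", 1.0))
        for p in p_actives
    ]
    spec = GenerativeSpec(phi, dists, noise_sigma=noise_sigma)
    x, a = generate_ensemble(spec, n_samples, seed + 1)
    return x, a, spec


def make_test_waveform(
    components: list[tuple[float, int, float, float]],
    duration: float,
    sample_rate: float,
    seed: int = 0,
    decay_time: float = 0.05,
) -> np.ndarray:
    """Sum of harmonic stacks with abrupt onsets and exponential decays.

    Each component is ``(f0_hz, n_harmonics, onset_time_s, amplitude)``: silent
    before its onset, then harmonics ``k*f0`` (k = 1..n_harmonics) with 1/k
    amplitude roll-off under a shared exponential decay envelope (default time
    constant 50 ms, long relative to a 16 ms analysis window).
    """
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    rng = default_rng(seed)
    wav = np.zeros(n)
    for f0, n_harm, onset, amp in components:
        if f0 * n_harm >= sample_rate / 2:
            raise ValueError(
                f"component f0={f0} with {n_harm} harmonics exceeds Nyquist "
                f"({sample_rate / 2} Hz)"
            )
        if onset >= duration:
            raise ValueError("onset_time must precede the end of the waveform")
        tau = np.where(t >= onset, t - onset, np.nan)
        env = np.where(t >= onset, np.exp(-(t - onset) / decay_time), 0.0)
        comp = np.zeros(n)
        for k in range(1, n_harm + 1):
            phase = rng.uniform(0, 2 * np.pi)
            comp += (1.0 / k) * np.sin(2 * np.pi * k * f0 * np.nan_to_num(tau) + phase)
        wav += amp * env * comp
    return wav


def make_image_like_patches(n_patches: int, side: int, seed: int,
                            edge_density: float = 0.3) -> np.ndarray:
    """Zero-mean patches with 1/f^2 power spectra plus sparse oriented edges.

    A surrogate for natural image patches: Gaussian random fields whose power
    falls as 1/f^2 (approximate scale invariance), with a sparse admixture of
    oriented edge components giving non-Gaussian, sign-symmetric structure.
    Each patch has its mean removed.  Rows are flattened side x side patches.
    """
    if side < 4:
        raise ValueError("side must be >= 4")
    rng = default_rng(seed)
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    f[0, 0] = 1.0
    amp = 1.0 / f  # amplitude ~ 1/f -> power ~ 1/f^2
    amp[0, 0] = 0.0  # no DC
    patches = np.empty((n_patches, side * side))
    for i in range(n_patches):
        spec = amp * (rng.standard_normal((side, side)) + 1j * rng.standard_normal((side, side)))
        img = np.fft.ifft2(spec).real
        if rng.random() < edge_density:
            img = img + 2.0 * _oriented_edge_element(side, rng).reshape(side, side)
        img -= img.mean()
        patches[i] = img.ravel()
    return patches


def save_ensemble(path, data, coefficients, dictionary, spec: GenerativeSpec | None = None):
    """Write an ensemble to NPZ with a JSON-serialized spec attribute."""
    meta = ""
    if spec is not None:
        meta = json.dumps(
            {
                "noise_sigma": spec.noise_sigma,
                "coeff_dists": [d.to_dict() for d in spec.coeff_dists],
            }
        )
    np.savez(path, data=data, coefficients=coefficients, dictionary=dictionary,
             spec_json=np.asarray(meta))


def load_ensemble(path):
    with np.load(path, allow_pickle=False) as f:
        spec_json = str(f["spec_json"])
        meta = json.loads(spec_json) if spec_json else None
        return f["data"], f["coefficients"], f["dictionary"], meta
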