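"""L1 sparse coding: locally competitive algorithm (LCA) inference and
stochastic gradient dictionary learning.

Inference solves the MAP problem for the linear generative model with a
Laplace coefficient prior, i.e. minimizes the energy

    E(a) = 1/2 ||x - a Phi||^2 + lambda ||a||_1,

by integrating the LCA dynamical system: auxiliary variables u receive
feedforward drive Phi x, leak toward zero, and are inhibited by the thresholded
activities of competing units,

    du/dt = Phi x - u - (Phi Phi^T - I) a,      a = T_lambda(u),

where T_lambda is the (optionally rectified) soft threshold.  Learning takes
gradient steps on the reconstruction error averaged over minibatches and
renormalizes every dictionary element to unit norm after each step.  The
sparseness parameter lambda is not fixed: a closed-loop controller adjusts it
during training so reconstructions achieve a target signal-to-noise ratio
(15 dB by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng

__all__ = [
    "LCAConfig",
    "soft_threshold",
    "lca_infer",
    "reconstruct",
    "snr_db",
    "adapt_lambda",
    "lca_energy",
    "train_lca",
    "TrainingHistory",
]

SNR_CAP_DB = 300.0  # sentinel for a perfect reconstruction


@dataclass
class LCAConfig:
    """Inference and lambda-controller settings.

    ``lam`` is the soft-threshold level (the Laplace prior width); ``n_steps``
    and ``step_size`` discretize the LCA dynamics by explicit Euler;
    ``rectified`` forbids negative activations; ``snr_target_db`` and
    ``lambda_gain`` parameterize the closed-loop lambda controller used during
    training.
    """

    lam: float = 0.1
    n_steps: int = 200
    step_size: float = 0.1
    rectified: bool = False
    snr_target_db: float = 15.0
    lambda_gain: float = 0.05

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 < self.step_size <= 1:
            raise ValueError("step_size must lie in (0, 1]")


def soft_threshold(u, lam: float, rectified: bool = False) -> np.ndarray:
    """Soft threshold: sign(u) * max(|u| - lam, 0); rectified: max(u - lam, 0)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    u = np.asarray(u, dtype=float)
    if rectified:
        return np.maximum(u - lam, 0.0)
    return np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)


def lca_infer(batch, dictionary, config: LCAConfig) -> np.ndarray:
    """Run LCA dynamics to a sparse code for each stimulus in the batch.

    Returns the n_stimuli x K activation matrix; most entries are exactly
    zero for lam > 0.  Deterministic given its inputs (u starts at zero).
    """
    x = np.atleast_2d(np.asarray(batch, dtype=float))
    phi = np.asarray(dictionary, dtype=float)
    if x.shape[1] != phi.shape[1]:
        raise ValueError(
            f"batch dimension {x.shape[1]} != dictionary dimension {phi.shape[1]}"
        )
    b = x @ phi.T  # feedforward drive
    gram = phi @ phi.T
    inhibit = gram - np.eye(phi.shape[0])
    u = np.zeros_like(b)
    a = soft_threshold(u, config.lam, config.rectified)
    for step in range(config.n_steps):
        du = b - u - a @ inhibit
        u = u + config.step_size * du
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(
                f"LCA dynamics produced non-finite values at step {step}"
            )
        a = soft_threshold(u, config.lam, config.rectified)
    return a


def reconstruct(code, dictionary) -> np.ndarray:
    """Linear reconstruction a Phi of the stimuli from their sparse codes."""
    a = np.atleast_2d(np.asarray(code, dtype=float))
    phi = np.asarray(dictionary, dtype=float)
    if a.shape[1] != phi.shape[0]:
        raise ValueError(
            f"code width {a.shape[1]} != number of dictionary elements {phi.shape[0]}"
        )
    return a @ phi


def snr_db(signal, reconstruction) -> float:
    """Reconstruction SNR: 10 log10(mean signal power / mean residual power).

    A perfect reconstruction is reported as the finite sentinel 300 dB.
    """
    x = np.asarray(signal, dtype=float)
    xhat = np.asarray(reconstruction, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("signal and reconstruction shapes differ")
    sig = np.mean(x * x)
    if sig == 0.0:
        raise ValueError("zero signal power: SNR undefined")
    res = np.mean((x - xhat) ** 2)
    if res == 0.0:
        return SNR_CAP_DB
    return float(min(10.0 * np.log10(sig / res), SNR_CAP_DB))


def adapt_lambda(lam: float, achieved_snr: float, target_snr: float,
                 gain: float = 0.05) -> float:
    """Multiplicative lambda update toward the target reconstruction SNR.

    When the achieved SNR exceeds the target the code can afford to be
    sparser, so lambda rises; below target lambda falls.  Fixed point at
    achieved == target; the result is never negative.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    factor = 1.0 + gain * (achieved_snr - target_snr) / abs(target_snr)
    # clamp the per-step change so a transiently terrible SNR cannot zero
    # lambda out (a multiplicative controller cannot recover from zero)
    factor = min(max(factor, 0.5), 2.0)
    return max(lam * factor, 0.0)


def lca_energy(x, a, phi, lam: float) -> float:
    """The objective LCA descends: 1/2 ||x - a Phi||^2 + lam ||a||_1."""
    resid = np.asarray(x, float) - reconstruct(a, phi)
    return float(0.5 * np.sum(resid**2) + lam * np.sum(np.abs(a)))


@dataclass
class TrainingHistory:
    lam: list = field(default_factory=list)
    snr_db: list = field(default_factory=list)
    mean_l0: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"lam": self.lam, "snr_db": self.snr_db, "mean_l0": self.mean_l0}


def train_lca(
    data: np.ndarray,
    n_elements: int,
    config: LCAConfig | None = None,
    n_epochs: int = 10,
    learning_rate: float = 0.1,
    lr_decay: bool = False,
    minibatch: int = 100,
    seed: int = 0,
    init_dictionary: np.ndarray | None = None,
) -> tuple[np.ndarray, TrainingHistory]:
    """Learn a dictionary by SGD on reconstruction error with LCA inference.

    Per minibatch: infer codes, take the gradient step
    ``Phi += (lr / batch) * a^T (x - a Phi)``, renormalize every element to
    unit norm, then let the closed-loop controller nudge lambda toward the
    reconstruction SNR target.  The history records lambda, SNR, and the mean
    fraction of active units per minibatch.  Deterministic given the seed.
    """
    if config is None:
        config = LCAConfig()
    x = np.asarray(data, dtype=float)
    n_samples, n_dims = x.shape
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    rng = default_rng(seed)
    if init_dictionary is not None:
        phi = np.array(init_dictionary, dtype=float, copy=True)
    else:
        phi = rng.standard_normal((n_elements, n_dims))
    phi /= np.linalg.norm(phi, axis=1, keepdims=True)

    lam = config.lam
    history = TrainingHistory()
    step_idx = 0
    for epoch in range(n_epochs):
        order = rng.permutation(n_samples)
        for start in range(0, n_samples - minibatch + 1, minibatch):
            batch = x[order[start:start + minibatch]]
            cfg = LCAConfig(
                lam=lam, n_steps=config.n_steps, step_size=config.step_size,
                rectified=config.rectified,
                snr_target_db=config.snr_target_db, lambda_gain=config.lambda_gain,
            )
            a = lca_infer(batch, phi, cfg)
            recon = reconstruct(a, phi)
            lr = learning_rate / (1.0 + step_idx / 100.0) if lr_decay else learning_rate
            grad = a.T @ (batch - recon) / batch.shape[0]
            phi = phi + lr * grad
            if not np.all(np.isfinite(phi)):
                raise FloatingPointError(
                    f"dictionary diverged at training step {step_idx}"
                )
            norms = np.linalg.norm(phi, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            phi = phi / norms
            achieved = snr_db(batch, recon)
            lam = adapt_lambda(lam, achieved, config.snr_target_db, config.lambda_gain)
            history.lam.append(lam)
            history.snr_db.append(achieved)
            history.mean_l0.append(float(np.mean(a != 0)))
            step_idx += 1
    return phi, history
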