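"""SAILnet: sparse coding with spiking units and synaptically local plasticity.

The network is a population of leaky integrate-and-fire units with feedforward
weights Phi, firing thresholds theta_m, and non-negative lateral inhibition
W_mn.  Learning performs constrained optimization of the Lagrange function

    L = 1/2 sum_mi (x_i - Phi_mi a_m)^2
        + sum_m theta_m (a_m - p)
        + 1/2 sum_mn W_mn (a_m a_n - p^2),

whose first term approximates the reconstruction error in the limit of sparse,
uncorrelated activities.  Maximizing over the multipliers theta (thresholds)
and W (inhibition) enforces mean rate p << 1 and decorrelation; minimizing
over Phi fits the dictionary.  Crucially, every gradient is *synaptically
local*: the update of W_mn needs only a_m and a_n, of theta_m only a_m, and of
Phi_mi only a_m and x_i.  There is no dictionary renormalization — that would
be a non-local operation — so homeostasis comes entirely from theta and the
decay term in the Phi rule.

A signed-spike variant fires spikes of either sign when the membrane crosses
+theta or -theta, allowing sign-symmetric features to be coded with a single
unit instead of a +/- pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import default_rng

__all__ = [
    "SAILnetParams",
    "SAILnetConfig",
    "sailnet_infer",
    "sailnet_energy",
    "sailnet_update",
    "train_sailnet",
]


@dataclass
class SAILnetParams:
    """Learnable state: feedforward weights, thresholds, lateral inhibition."""

    phi: np.ndarray          # K x D feedforward weights
    thresholds: np.ndarray   # theta_m >= 0, per unit
    inhibition: np.ndarray   # W_mn >= 0, symmetric, zero diagonal
    target_rate: float       # p << 1

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        k = self.phi.shape[0]
        if self.thresholds.shape != (k,):
            raise ValueError("thresholds must be per-unit")
        if self.inhibition.shape != (k, k):
            raise ValueError("inhibition must be K x K")
        if not np.allclose(self.inhibition, self.inhibition.T):
            raise ValueError("inhibition must be symmetric")
        if np.any(np.diag(self.inhibition) != 0):
            raise ValueError("inhibition diagonal must be zero")
        if np.any(self.inhibition < 0):
            raise ValueError("inhibition entries must be >= 0")
        if not 0 < self.target_rate < 1:
            raise ValueError("target_rate must lie in (0, 1)")

    @classmethod
    def init(cls, n_elements: int, n_dims: int, target_rate: float = 0.05,
             seed: int = 0, phi_scale: float | None = None) -> "SAILnetParams":
        rng = default_rng(seed)
        scale = phi_scale if phi_scale is not None else 1.0 / np.sqrt(n_dims)
        return cls(
            phi=rng.standard_normal((n_elements, n_dims)) * scale,
            thresholds=np.full(n_elements, 2.0),
            inhibition=np.zeros((n_elements, n_elements)),
            target_rate=target_rate,
        )


@dataclass
class SAILnetConfig:
    """Simulation and learning-rate settings.

    ``sim_steps`` LIF timesteps per stimulus with integration step ``dt`` and
    membrane decay ``leak`` (the effective time constant dt/leak spans the
    window).  The multiplier rates ``alpha_w`` and ``alpha_theta`` must exceed
    the dictionary rate ``alpha_phi`` so the sparseness and decorrelation
    constraints hold throughout learning.
    """

    sim_steps: int = 50
    dt: float = 0.1
    leak: float = 1.0
    alpha_phi: float = 0.01
    alpha_w: float = 0.1
    alpha_theta: float = 0.02
    signed_spikes: bool = False

    def __post_init__(self):
        if self.sim_steps < 1:
            raise ValueError("sim_steps must be >= 1")
        if not (self.alpha_w > self.alpha_phi and self.alpha_theta > self.alpha_phi):
            raise ValueError(
                "multiplier rates alpha_w, alpha_theta must exceed alpha_phi"
            )


def sailnet_infer(batch, params: SAILnetParams, config: SAILnetConfig,
                  seed: int = 0) -> np.ndarray:
    """Simulate the LIF circuit and return spike counts a_m per stimulus.

    Membranes integrate the feedforward drive Phi x minus W-weighted spikes of
    the other units, with leak; a unit crossing threshold emits a unit spike
    and resets to zero.  In signed mode a crossing of -theta emits a -1 spike.
    Activities are total spike counts over the window (non-negative unless
    signed_spikes).
    """
    x = np.atleast_2d(np.asarray(batch, dtype=float))
    if x.shape[1] != params.phi.shape[1]:
        raise ValueError("stimulus dimension does not match feedforward weights")
    n, k = x.shape[0], params.phi.shape[0]
    b = x @ params.phi.T
    u = np.zeros((n, k))
    counts = np.zeros((n, k))
    for _ in range(config.sim_steps):
        u = (1.0 - config.leak * config.dt) * u + config.dt * b
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite membrane potential in SAILnet")
        fired_pos = u >= params.thresholds
        if config.signed_spikes:
            fired_neg = u <= -params.thresholds
            spikes = fired_pos.astype(float) - fired_neg.astype(float)
            reset = fired_pos | fired_neg
        else:
            spikes = fired_pos.astype(float)
            reset = fired_pos
        counts += spikes
        u = np.where(reset, 0.0, u)
        u = u - spikes @ params.inhibition
    return counts


def sailnet_energy(params: SAILnetParams, x, a) -> float:
    """The Lagrange function L(x, a; Phi, theta, W) the network optimizes.

    The first term is the *per-connection* squared error
    1/2 sum_mi (x_i - Phi_mi a_m)^2 — the approximation to the true
    reconstruction error that is valid for sparse, uncorrelated activities
    and is what makes every gradient synaptically local.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    resid = x[None, :] - params.phi * a[:, None]  # K x D per-connection errors
    recon_term = 0.5 * np.sum(resid**2)
    thresh_term = np.sum(params.thresholds * (a - params.target_rate))
    outer = np.outer(a, a) - params.target_rate**2
    inhib_term = 0.5 * np.sum(params.inhibition * outer)
    return float(recon_term + thresh_term + inhib_term)


def sailnet_update(params: SAILnetParams, x, a,
                   config: SAILnetConfig) -> SAILnetParams:
    """One synaptically local gradient step on the Lagrange function.

    dW_mn ~ a_m a_n - p^2 (off-diagonal, floored at zero),
    dtheta_m ~ a_m - p,
    dPhi_mi ~ a_m (x_i - a_m Phi_mi)  [the diagonal approximation to the
    reconstruction gradient, which keeps the rule local].
    ``x`` and ``a`` may be batches (rows); updates then average over the batch.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a = np.atleast_2d(np.asarray(a, dtype=float))
    n = x.shape[0]
    p = params.target_rate

    # with signed spikes the rate/correlation constraints apply to spike
    # *events*, so the multiplier updates see magnitudes; the Phi rule keeps
    # the signed activities (it must know the direction of drive)
    act = np.abs(a) if config.signed_spikes else a

    dw = (act.T @ act) / n - p**2
    w = params.inhibition + config.alpha_w * dw
    np.fill_diagonal(w, 0.0)
    w = np.maximum(w, 0.0)
    w = 0.5 * (w + w.T)

    theta = params.thresholds + config.alpha_theta * (act.mean(axis=0) - p)

    # local Phi rule: a_m * (x_i - a_m * Phi_mi), averaged over the batch
    hebb = (a.T @ x) / n
    decay = (a**2).mean(axis=0)[:, None] * params.phi
    phi = params.phi + config.alpha_phi * (hebb - decay)

    return SAILnetParams(phi=phi, thresholds=theta, inhibition=w,
                         target_rate=p)


@dataclass
class SAILnetHistory:
    mean_rate: list = field(default_factory=list)
    recon_mse: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"mean_rate": self.mean_rate, "recon_mse": self.recon_mse}


def train_sailnet(
    data: np.ndarray,
    n_elements: int,
    config: SAILnetConfig | None = None,
    target_rate: float = 0.05,
    n_epochs: int = 10,
    minibatch: int = 100,
    seed: int = 0,
) -> tuple[SAILnetParams, SAILnetHistory]:
    """Alternate LIF inference and local updates over minibatches.

    The history records the grand-mean firing rate and reconstruction MSE per
    minibatch; after convergence the long-run mean rate per unit approaches
    the target p.  Deterministic given the seed.
    """
    if config is None:
        config = SAILnetConfig()
    x = np.asarray(data, dtype=float)
    n_samples, n_dims = x.shape
    rng = default_rng(seed)
    params = SAILnetParams.init(n_elements, n_dims, target_rate=target_rate,
                                seed=seed)
    history = SAILnetHistory()
    for epoch in range(n_epochs):
        order = rng.permutation(n_samples)
        for start in range(0, n_samples - minibatch + 1, minibatch):
            batch = x[order[start:start + minibatch]]
            a = sailnet_infer(batch, params, config)
            params = sailnet_update(params, batch, a, config)
            if not np.all(np.isfinite(params.phi)):
                raise FloatingPointError("SAILnet diverged during training")
            history.mean_rate.append(float(np.mean(np.abs(a))))
            history.recon_mse.append(
                float(np.mean((batch - a @ params.phi) ** 2))
            )
    return params, history
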