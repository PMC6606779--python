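"""Canonical study runs for the comparative sparse-structure analysis.

These functions fix the study conditions — ensemble sizes, whitening, model
settings — used by the acceptance checks and the analysis drivers, so every
entry point measures the same experiment.  Ensembles are PCA-whitened before
any coding model sees them, exactly as the preprocessing stage does for real
spectrograms and image patches; all statistics (projections, random-direction
controls) are computed in that whitened space.

Default problem sizes (D = 64 dimensions, K = 64 elements, 2 x 10^4 samples)
keep every run to seconds-to-minutes on one CPU while leaving the qualitative
structure of the full-scale experiment intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lca as lca_mod
from . import preprocess as pp
from . import sailnet as sn
from . import stats as st
from . import synth

__all__ = [
    "WhitenedEnsemble",
    "make_whitened_ensemble",
    "train_study_lca",
    "train_study_sailnet",
    "controller_snr_db",
    "lambda_controller_run",
    "one_active_unit_score",
    "dictionary_recovery",
    "null_separation",
    "modality_contrast",
]


@dataclass
class WhitenedEnsemble:
    """A synthetic ensemble mapped to whitened coordinates.

    ``data`` is n_samples x D in whitened space; ``truth`` holds the
    ground-truth dictionary mapped into the same space and renormalized, for
    recovery comparisons.
    """

    data: np.ndarray
    truth: np.ndarray
    whitener: pp.PCAWhitener
    raw_truth: np.ndarray


def make_whitened_ensemble(kind: str, seed: int, n_dims: int = 64,
                           n_elements: int = 64,
                           n_samples: int = 20000) -> WhitenedEnsemble:
    """Generate the symmetric or skewed study ensemble and whiten it."""
    if kind == "symmetric":
        x, _, spec = synth.symmetric_ensemble(n_dims, n_elements, n_samples,
                                              seed=seed)
    elif kind == "skewed":
        x, _, spec = synth.skewed_ensemble(n_dims, n_elements, n_samples,
                                           seed=seed)
    else:
        raise ValueError(f"unknown ensemble kind {kind!r}")
    whitener = pp.fit_whitener(x, n_dims)
    xw = pp.whiten(x, whitener)
    truth_w = spec.dictionary @ whitener.components.T / whitener.component_scales
    truth_w = truth_w / np.linalg.norm(truth_w, axis=1, keepdims=True)
    return WhitenedEnsemble(data=xw, truth=truth_w, whitener=whitener,
                            raw_truth=spec.dictionary)


def train_study_lca(data: np.ndarray, seed: int, n_elements: int | None = None,
                    n_epochs: int = 15, learning_rate: float = 0.2,
                    rectified: bool = False):
    """The standard LCA training run: 15 dB SNR target, minibatch 100."""
    k = n_elements if n_elements is not None else data.shape[1]
    cfg = lca_mod.LCAConfig(rectified=rectified)
    return lca_mod.train_lca(data, k, cfg, n_epochs=n_epochs,
                             learning_rate=learning_rate, seed=seed)


def train_study_sailnet(data: np.ndarray, seed: int,
                        n_elements: int | None = None, n_epochs: int = 20,
                        target_rate: float = 0.05, signed_spikes: bool = False):
    """The standard SAILnet training run (p = 0.05, 50 LIF steps/stimulus)."""
    k = n_elements if n_elements is not None else data.shape[1]
    cfg = sn.SAILnetConfig(signed_spikes=signed_spikes)
    return sn.train_sailnet(data, k, cfg, target_rate=target_rate,
                            n_epochs=n_epochs, seed=seed)


def controller_snr_db(history: lca_mod.TrainingHistory,
                      n_samples: int = 20000, minibatch: int = 100) -> float:
    """Mean reconstruction SNR over the final training epoch."""
    per_epoch = n_samples // minibatch
    return float(np.mean(history.snr_db[-per_epoch:]))


def lambda_controller_run(seed: int, n_dims: int = 64, n_elements: int = 64,
                          n_samples: int = 20000, n_epochs: int = 5) -> float:
    """Closed-loop LCA training on the Laplace generative ensemble.

    Data follow the linear model with unit-scale Laplace coefficients on a
    random orthonormal dictionary (D = K = 64, 2 x 10^4 samples).  Returns the
    mean reconstruction SNR over the final training epoch, which the dynamic
    sparseness-parameter controller drives to its 15 dB target.
    """
    phi = synth.random_orthonormal_dictionary(n_dims, n_elements, seed)
    spec = synth.GenerativeSpec(phi, synth.CoeffDist("laplace", 1.0))
    x, _ = synth.generate_ensemble(spec, n_samples, seed + 1)
    _, history = lca_mod.train_lca(x, n_elements, lca_mod.LCAConfig(),
                                   n_epochs=n_epochs, seed=seed + 2)
    return controller_snr_db(history, n_samples=n_samples)


def one_active_unit_score(n_units: int = 2000) -> float:
    """Population sparseness when exactly one of ``n_units`` units is active.

    For a single nonzero entry the score is sqrt(2/pi) - 1/sqrt(K),
    approaching the supremum for large dictionaries — the argument for why a
    single high-variance data dimension can fake extreme population
    sparseness on unwhitened data.
    """
    a = np.zeros(n_units)
    a[0] = 1.0  # scale-invariant, any nonzero value gives the same score
    return st.sparseness_score(a)


def dictionary_recovery(seed: int, n_dims: int = 20, n_samples: int = 10000,
                        n_epochs: int = 10) -> float:
    """Mean max |cos| between true and learned elements.

    Data come from a known random orthonormal D x D dictionary with unit-scale
    Laplace coefficients and no noise; LCA-SGD with the 15 dB controller
    should recover every element nearly exactly.
    """
    phi_true = synth.random_orthonormal_dictionary(n_dims, n_dims, seed)
    spec = synth.GenerativeSpec(phi_true, synth.CoeffDist("laplace", 1.0),
                                noise_sigma=0.0)
    x, _ = synth.generate_ensemble(spec, n_samples, seed + 1)
    phi, _ = lca_mod.train_lca(x, n_dims, lca_mod.LCAConfig(),
                               n_epochs=n_epochs, learning_rate=0.2,
                               seed=seed + 2)
    match = st.match_dictionaries(phi_true, phi)
    return float(match["abs_cos"].mean())


def null_separation(data: np.ndarray, dictionary: np.ndarray, seed: int,
                    n_dirs: int = 200) -> dict:
    """Learned-dictionary lifetime sparseness vs the random-direction band.

    Projections of the (whitened) data onto learned elements versus onto
    random unit directions; returns the minimum learned score and the maximum
    of the control band.
    """
    _, rep_learned, _ = st.projection_stats(data, dictionary)
    ctrl = st.random_direction_control(data.shape[1], n_dirs, seed)
    _, rep_ctrl, _ = st.projection_stats(data, ctrl)
    return {
        "learned_min": float(rep_learned.records["sparseness_score"].min()),
        "learned_median": float(rep_learned.records["sparseness_score"].median()),
        "control_max": float(rep_ctrl.records["sparseness_score"].max()),
        "control_median": float(rep_ctrl.records["sparseness_score"].median()),
    }


def modality_contrast(seed: int, n_dims: int = 64, n_samples: int = 20000) -> dict:
    """The headline comparison run on paired synthetic ensembles.

    Trains LCA on both ensembles and SAILnet on both, in whitened space, and
    returns the per-element sparseness/|skewness| ranges, the SAILnet-LCA
    dictionary match on the symmetric ensemble, and the SAILnet skewness
    concentration on the skewed ensemble.
    """
    sym = make_whitened_ensemble("symmetric", seed, n_dims=n_dims,
                                 n_samples=n_samples)
    skw = make_whitened_ensemble("skewed", seed + 10, n_dims=n_dims,
                                 n_samples=n_samples)

    phi_sym, _ = train_study_lca(sym.data, seed + 1)
    phi_skw, _ = train_study_lca(skw.data, seed + 2)
    sail_sym, _ = train_study_sailnet(sym.data, seed + 3)
    sail_skw, _ = train_study_sailnet(skw.data, seed + 4)

    _, rep_sym, _ = st.projection_stats(sym.data, phi_sym)
    _, rep_skw, _ = st.projection_stats(skw.data, phi_skw)

    def ranges(rep):
        r = rep.records
        return (
            float(r["sparseness_score"].max() - r["sparseness_score"].min()),
            float(r["skewness_magnitude"].max() - r["skewness_magnitude"].min()),
        )

    s_range_sym, k_range_sym = ranges(rep_sym)
    s_range_skw, k_range_skw = ranges(rep_skw)

    match = st.match_dictionaries(sail_sym.phi, phi_sym)

    _, rep_sail_skw, _ = st.projection_stats(skw.data, sail_skw.phi)
    ctrl = st.random_direction_control(n_dims, 200, seed + 5)
    _, rep_ctrl_skw, _ = st.projection_stats(skw.data, ctrl)

    sail_skew = rep_sail_skw.records["skewness_magnitude"]
    ctrl_skew = rep_ctrl_skw.records["skewness_magnitude"]
    return {
        "sparseness_range_symmetric": s_range_sym,
        "sparseness_range_skewed": s_range_skw,
        "skewness_range_symmetric": k_range_sym,
        "skewness_range_skewed": k_range_skw,
        "sailnet_lca_median_abs_cos": float(match["abs_cos"].median()),
        "sailnet_skew_median": float(sail_skew.median()),
        "sailnet_skew_frac_above_control": float(
            (sail_skew > ctrl_skew.max()).mean()
        ),
        "control_skew_max": float(ctrl_skew.max()),
    }
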