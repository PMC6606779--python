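"""Sparseness and skewness statistics for comparing learned representations.

The central quantity is the sparseness score

    S[y] = sqrt(2/pi) - <|y|> / sqrt(<y^2>),

which is zero for a normal distribution and grows toward sqrt(2/pi) as the
distribution of ``y`` concentrates mass at zero.  Applied down the columns of
an activation matrix (one unit's responses across stimuli) it measures
*lifetime* sparseness; applied across rows (all units' responses to one
stimulus) it measures *population* sparseness.  The companion statistic is the
magnitude of skewness of mean-centered samples, which separates asymmetric
acoustic features (harmonic stacks, onsets) from sign-symmetric visual ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

SPARSENESS_OFFSET = np.sqrt(2.0 / np.pi)

__all__ = [
    "SPARSENESS_OFFSET",
    "StatReport",
    "sparseness_score",
    "skewness_magnitude",
    "aux_stats",
    "lifetime_report",
    "population_report",
    "random_direction_control",
    "sign_align",
    "match_dictionaries",
    "cluster_elements",
    "effect_sizes",
    "projection_stats",
]


@dataclass
class StatReport:
    """Per-entity sparseness statistics plus mean/median summaries.

    ``axis`` is ``"lifetime"`` (one record per unit, statistics taken over
    stimuli) or ``"population"`` (one record per stimulus, statistics taken
    over units).  ``records`` is a DataFrame with columns ``sparseness_score``,
    ``skewness_magnitude``, ``excess_kurtosis``, ``l0_zero_fraction``,
    ``l0_asymmetry``, ``mean_abs`` and a boolean ``degenerate`` flag marking
    all-zero sample sets.
    """

    axis: str
    records: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index_label="entity")


def _check_samples(samples) -> np.ndarray:
    y = np.asarray(samples, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("sparseness statistics require a non-empty sample set")
    return y


def sparseness_score(samples) -> float:
    """Sparseness score ``sqrt(2/pi) - <|y|>/sqrt(<y^2>)``.

    Zero for normal samples, ~0.091 for a Laplace distribution, approaching
    the supremum sqrt(2/pi) as mass concentrates at zero.  An all-zero sample
    set returns the supremum by convention (the limit of a single vanishing
    active entry); callers that need to distinguish this case should check the
    ``degenerate`` flag in report records.
    """
    y = _check_samples(samples)
    ms = np.mean(y * y)
    if ms == 0.0:
        return float(SPARSENESS_OFFSET)
    return float(SPARSENESS_OFFSET - np.mean(np.abs(y)) / np.sqrt(ms))


def skewness_magnitude(samples) -> float:
    """Absolute standardized third moment of mean-centered samples."""
    y = _check_samples(samples)
    y = y - y.mean()
    var = np.mean(y * y)
    if var == 0.0:
        raise ValueError("skewness magnitude undefined for zero-variance samples")
    return float(abs(np.mean(y**3) / var**1.5))


def aux_stats(samples, zero_tol: float = 0.0) -> tuple[float, float, float, float]:
    """Return (excess_kurtosis, l0_zero_fraction, l0_asymmetry, mean_abs).

    Entries with ``|y| <= zero_tol`` count as zero; the L0 asymmetry is the
    fraction of positive minus the fraction of negative responses.
    """
    y = _check_samples(samples)
    zero = np.abs(y) <= zero_tol
    zero_fraction = float(zero.mean())
    pos = float(np.mean(~zero & (y > 0)))
    neg = float(np.mean(~zero & (y < 0)))
    # biased (population) excess kurtosis; normal -> 0
    kurt = float(sps.kurtosis(y, fisher=True, bias=True)) if np.ptp(y) > 0 else float("nan")
    return kurt, zero_fraction, pos - neg, float(np.mean(np.abs(y)))


def _report(samples_matrix: np.ndarray, axis: str, zero_tol: float) -> StatReport:
    # samples_matrix: one row per entity, columns are that entity's samples
    rows = []
    for y in samples_matrix:
        degenerate = bool(np.all(y == 0.0))
        s = sparseness_score(y)
        skew = float("nan") if np.ptp(y) == 0 else skewness_magnitude(y)
        kurt, zf, asym, mabs = aux_stats(y, zero_tol=zero_tol)
        rows.append(
            {
                "sparseness_score": s,
                "skewness_magnitude": skew,
                "excess_kurtosis": kurt,
                "l0_zero_fraction": zf,
                "l0_asymmetry": asym,
                "mean_abs": mabs,
                "degenerate": degenerate,
            }
        )
    records = pd.DataFrame(rows)
    numeric = records.drop(columns="degenerate")
    summary = {
        "mean": numeric.mean().to_dict(),
        "median": numeric.median().to_dict(),
    }
    return StatReport(axis=axis, records=records, summary=summary)


def lifetime_report(activations, zero_tol: float = 0.0) -> StatReport:
    """Per-unit statistics over stimuli (columns of the stimuli x units matrix)."""
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    if a.size == 0:
        raise ValueError("empty activation matrix")
    return _report(a.T, "lifetime", zero_tol)


def population_report(activations, zero_tol: float = 0.0) -> StatReport:
    """Per-stimulus statistics over units (rows of the stimuli x units matrix)."""
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    if a.size == 0:
        raise ValueError("empty activation matrix")
    return _report(a, "population", zero_tol)


def random_direction_control(n_dims: int, n_dirs: int, seed: int) -> np.ndarray:
    """iid Gaussian unit vectors: the null dictionary for control curves.

    Push whitened data through either plain projections or LCA inference with
    this dictionary to obtain the control band that learned dictionaries are
    compared against.
    """
    rng = default_rng(seed)
    d = rng.standard_normal((n_dirs, n_dims))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def sign_align(dictionary: np.ndarray, samples_per_element: np.ndarray) -> np.ndarray:
    """Flip each element by the sign of the skewness of its activations.

    ``samples_per_element`` is stimuli x elements (activations or projections).
    Elements with exactly zero skewness fall back to the sign of the mean
    activity; if that is also zero they are left unchanged.
    """
    d = np.array(dictionary, dtype=float, copy=True)
    s = np.asarray(samples_per_element, dtype=float)
    if s.shape[1] != d.shape[0]:
        raise ValueError("need one activation column per dictionary element")
    centered = s - s.mean(axis=0)
    third = np.mean(centered**3, axis=0)
    signs = np.sign(third)
    fallback = np.sign(s.mean(axis=0))
    signs = np.where(signs == 0, fallback, signs)
    signs = np.where(signs == 0, 1.0, signs)
    return d * signs[:, None]


def match_dictionaries(dict_a: np.ndarray, dict_b: np.ndarray) -> pd.DataFrame:
    """For each element of ``dict_a``, the ``dict_b`` element of minimal angle.

    Angles use |cos| and are therefore sign-invariant, since sparse coding
    elements are defined only up to sign.  Returns a DataFrame with columns
    ``match_index``, ``abs_cos``, ``angle_deg`` (angle in [0, 90]).
    """
    a = np.asarray(dict_a, dtype=float)
    b = np.asarray(dict_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("dictionaries live in different data spaces")
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    bn = b / np.linalg.norm(b, axis=1, keepdims=True)
    cos = np.abs(an @ bn.T)
    idx = np.argmax(cos, axis=1)
    best = cos[np.arange(a.shape[0]), idx]
    angle = np.degrees(np.arccos(np.clip(best, 0.0, 1.0)))
    return pd.DataFrame({"match_index": idx, "abs_cos": best, "angle_deg": angle})


def cluster_elements(
    sparseness_scores,
    skewness_magnitudes,
    max_components: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Cluster elements in the (sparseness, |skewness|) plane with a GMM.

    The number of components is selected by BIC over 1..max_components.
    Returns hard labels and the chosen k.
    """
    x = np.column_stack(
        [np.asarray(sparseness_scores, float), np.asarray(skewness_magnitudes, float)]
    )
    if x.shape[0] < 2:
        raise ValueError("clustering requires at least two elements")
    best_bic, best_gmm, best_k = np.inf, None, 1
    for k in range(1, min(max_components, x.shape[0]) + 1):
        gmm = GaussianMixture(n_components=k, n_init=3, random_state=seed).fit(x)
        bic = gmm.bic(x)
        if bic < best_bic:
            best_bic, best_gmm, best_k = bic, gmm, k
    return best_gmm.predict(x), best_k


def effect_sizes(dist_a, dist_b) -> tuple[float, float]:
    """Cohen's d and the normalized median difference between two samples.

    Both use the pooled standard deviation in the denominator; the median
    variant replaces means with medians in the numerator.
    """
    a = _check_samples(dist_a)
    b = _check_samples(dist_b)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        raise ValueError("zero pooled standard deviation")
    pooled_sd = np.sqrt(pooled_var)
    d = (a.mean() - b.mean()) / pooled_sd
    nmd = (np.median(a) - np.median(b)) / pooled_sd
    return float(d), float(nmd)


def projection_stats(
    batch: np.ndarray,
    dictionary: np.ndarray,
    activations: np.ndarray | None = None,
    zero_tol: float = 1e-12,
) -> tuple[np.ndarray, StatReport, np.ndarray | None]:
    """Linear projections of the data onto each element, with their statistics.

    Returns ``(projections, report, correlations)`` where ``projections`` is
    stimuli x elements, ``report`` is the per-element lifetime report of the
    projections, and ``correlations`` (when ``activations`` is given) holds
    the per-element Pearson correlation between projections and activations.
    """
    x = np.asarray(batch, dtype=float)
    d = np.asarray(dictionary, dtype=float)
    if x.shape[1] != d.shape[1]:
        raise ValueError(
            f"data dimension {x.shape[1]} != dictionary dimension {d.shape[1]}"
        )
    proj = x @ d.T
    report = lifetime_report(proj, zero_tol=zero_tol)
    corr = None
    if activations is not None:
        a = np.asarray(activations, dtype=float)
        if a.shape != proj.shape:
            raise ValueError("activation matrix shape does not match projections")
        corr = np.empty(proj.shape[1])
        for m in range(proj.shape[1]):
            pm, am = proj[:, m], a[:, m]
            if pm.std() == 0 or am.std() == 0:
                corr[m] = np.nan
            else:
                corr[m] = np.corrcoef(pm, am)[0, 1]
    return proj, report, corr
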