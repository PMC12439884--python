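"""Model-selection and concordance statistics for external clusterings.

The clustering model itself is fit elsewhere; this module scores supplied
fits (log-likelihoods and label assignments) with BIC, the plain Rand
index between random starts, and the label concordance of overlapping
spots treated as technical replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics import rand_score

__all__ = ["ModelFitSummary", "bic", "default_df", "rand_index", "overlap_concordance"]


@dataclass
class ModelFitSummary:
    """Summary of one spatial-clustering fit.

    ``df`` may be supplied directly; otherwise it is derived from the
    model dimensions by ``default_df`` (the exact parameter accounting of
    the upstream clustering tool is not recoverable, so the formula is
    pluggable).
    """

    log_likelihood: float
    n: int
    k: int = 0
    q: int = 0
    p: int = 0
    r_max: int = 0
    cov_structure: str = "diagonal"
    df: float | None = None


def default_df(fit: ModelFitSummary) -> float:
    """Mean/loading/covariance parameter count.

    p*q projection loadings + k*q cluster means + covariance parameters
    (k*q diagonal per cluster; q shared; k*q(q+1)/2 full) + r_max embedding
    dimensions.
    """
    cov = {
        "diagonal": fit.k * fit.q,
        "shared": fit.q,
        "full": fit.k * fit.q * (fit.q + 1) // 2,
    }
    if fit.cov_structure not in cov:
        raise ValueError(f"unknown covariance structure {fit.cov_structure!r}")
    return fit.p * fit.q + fit.k * fit.q + cov[fit.cov_structure] + fit.r_max


def bic(fit: ModelFitSummary, df_fn: Callable[[ModelFitSummary], float] = default_df) -> float:
    """BIC = -2 * log-likelihood + df * ln(n)."""
    if fit.n <= 1:
        raise ValueError("BIC requires n > 1")
    df = fit.df if fit.df is not None else df_fn(fit)
    return -2.0 * fit.log_likelihood + df * math.log(fit.n)


def rand_index(labels_a, labels_b) -> float:
    """Plain (unadjusted) Rand index: the fraction of observation pairs on
    which two partitions agree."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(rand_score(labels_a, labels_b))


def overlap_concordance(labels: dict, overlap_pairs) -> float:
    """Fraction of overlapping spot pairs assigned the same cluster label."""
    pairs = list(overlap_pairs)
    if not pairs:
        raise ValueError("concordance undefined with no overlap pairs")
    agree = sum(1 for a, b in pairs if labels[a] == labels[b])
    return agree / len(pairs)
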