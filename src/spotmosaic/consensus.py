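"""Cross-donor consensus of spatial patterns.

Patterns detected independently in each donor are compared on two axes:
gene-set overlap (Jaccard index) and the correlation of their domain-mean
score profiles. The two similarities are averaged into a consensus matrix,
Ward-clustered, and cut into k groups (consensus patterns). Within each
group, a donor contributes a representative pattern only when it
contributes exactly one pattern, unless the highest-scoring override is
requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusPattern",
    "jaccard_similarity",
    "jaccard_matrix",
    "domain_profile_correlation",
    "consensus_matrix",
    "cluster_patterns",
    "select_representatives",
]


@dataclass
class ConsensusPattern:
    """One cross-donor consensus group of per-donor patterns."""

    mcp_id: int
    members: list[str]
    representatives: dict[str, str] = field(default_factory=dict)  # donor -> pattern
    domain_scores: pd.Series | None = None


def jaccard_similarity(a, b) -> float:
    """|A intersect B| / |A union B|; two empty sets give 0 with a warning."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def jaccard_matrix(gene_sets: dict[str, set]) -> pd.DataFrame:
    names = list(gene_sets)
    J = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            J.loc[a, b] = J.loc[b, a] = jaccard_similarity(gene_sets[a], gene_sets[b])
    return J


def domain_profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of domain-mean score profiles across patterns.

    ``profiles`` is patterns x domains (at least 3 domains for a meaningful
    correlation). Zero-variance profiles correlate 0 with a warning.
    """
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance domain profile(s): correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.nan_to_num(R, nan=0.0)
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=profiles.index, columns=profiles.index)


def consensus_matrix(jaccard: pd.DataFrame, correlation: pd.DataFrame) -> pd.DataFrame:
    """Element-wise mean of the two similarity matrices, unit diagonal.

    The Jaccard lives on [0, 1] and the correlation on [-1, 1]; they are
    averaged as-is (negative consensus similarities are permitted here and
    floored only at the clustering step).
    """
    if jaccard.shape != correlation.shape or list(jaccard.index) != list(correlation.index):
        raise ValueError("similarity matrices must share shape and labels")
    S = (jaccard.to_numpy(dtype=float) + correlation.to_numpy(dtype=float)) / 2.0
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=jaccard.index, columns=jaccard.columns)


def cluster_patterns(
    consensus: pd.DataFrame, k: int = 6, method: str = "ward"
) -> tuple[np.ndarray, pd.Series]:
    """Ward clustering of patterns on distance 1 - similarity.

    Negative similarities are floored to 0 first, capping distances at 1 so
    Ward receives a valid dissimilarity. Returns the linkage matrix and the
    k-cut labels (1-based).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > consensus.shape[0]:
        raise ValueError(f"k={k} exceeds the number of patterns ({consensus.shape[0]})")
    D = 1.0 - np.maximum(consensus.to_numpy(dtype=float), 0.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=consensus.index, name="mcp")


def select_representatives(
    labels: pd.Series,
    donor_of_pattern: pd.Series,
    scores: pd.Series | None = None,
    keep_highest_scoring: bool = False,
) -> list[ConsensusPattern]:
    """Pick at most one representative pattern per donor per consensus group.

    Donors contributing exactly one pattern to a group contribute that
    pattern; donors contributing more than one contribute none by default.
    With ``keep_highest_scoring`` the multi-pattern case keeps the pattern
    with the highest mean domain score (``scores``, indexed by pattern).
    """
    out: list[ConsensusPattern] = []
    for mcp in sorted(labels.unique()):
        members = labels.index[labels == mcp].tolist()
        reps: dict[str, str] = {}
        donors = donor_of_pattern.loc[members]
        for donor, pats in donors.groupby(donors).groups.items():
            pats = list(pats)
            if len(pats) == 1:
                reps[donor] = pats[0]
            elif keep_highest_scoring:
                if scores is None:
                    raise ValueError("keep_highest_scoring requires scores")
                reps[donor] = max(pats, key=lambda p: scores[p])
        out.append(ConsensusPattern(mcp_id=int(mcp), members=members, representatives=reps))
    return out
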