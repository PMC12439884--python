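"""Trait-informed ligand-receptor prioritization and spatial co-occurrence.

Candidate interactions (scored upstream by a multi-method consensus) are
filtered to trait risk genes and high-confidence ranks; spots are
classified by strict positivity of the ligand and receptor in
log-normalized expression; and deconvolution weights are used to measure
which cell-type pairs co-occur preferentially in co-expressing spots:

    C_LR   = W_SLR^T  W_SLR      (co-expressing spots)
    C_ctrl = W_Sctrl^T W_Sctrl   (all other spots)

with the diagonal and strict upper triangle zeroed, each lower triangle
normalized to sum to one, and the enrichment ratio
R = C_LR / (C_ctrl + 1e-6) taken element-wise on the lower triangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CooccurrenceResult",
    "prioritize_trait_lr",
    "classify_spots",
    "domain_class_proportions",
    "cooccurrence_matrix",
    "cooccurrence_enrichment",
]

SPOT_CLASSES = ["coexpressing", "ligand_only", "receptor_only", "neither"]


@dataclass
class CooccurrenceResult:
    C_lr: pd.DataFrame
    C_ctrl: pd.DataFrame
    R: pd.DataFrame
    epsilon: float
    undefined: bool = False


def prioritize_trait_lr(
    candidates: pd.DataFrame,
    trait_evidence: pd.DataFrame,
    evidence_min: float = 0.1,
    rank_max: float = 0.01,
) -> pd.DataFrame:
    """Filter candidate interactions to trait-relevant, confident pairs.

    ``trait_evidence`` is genes x evidence-score columns ("no data" or NaN
    entries count as 0); a gene is a risk gene when its maximum evidence
    exceeds ``evidence_min``. A candidate survives when its ligand or
    receptor is a risk gene, neither symbol starts with "HLA" (MHC
    artifacts), and ``aggregate_rank <= rank_max``.
    """
    ev = trait_evidence.apply(pd.to_numeric, errors="coerce").fillna(0.0)
    max_evidence = ev.max(axis=1)
    risk_genes = set(max_evidence.index[max_evidence > evidence_min])

    def risk(row) -> bool:
        return row["ligand"] in risk_genes or row["receptor"] in risk_genes

    keep = (
        candidates.apply(risk, axis=1)
        & ~candidates["ligand"].str.startswith("HLA")
        & ~candidates["receptor"].str.startswith("HLA")
        & (candidates["aggregate_rank"] <= rank_max)
    )
    return candidates.loc[keep].reset_index(drop=True)


def classify_spots(ligand_expr, receptor_expr) -> np.ndarray:
    """Four-way spot classification from strict positivity.

    A spot "expresses" a gene when its log-normalized value is > 0; the
    classes are coexpressing / ligand_only / receptor_only / neither.
    """
    lig = np.asarray(ligand_expr, dtype=float) > 0
    rec = np.asarray(receptor_expr, dtype=float) > 0
    out = np.where(
        lig & rec,
        "coexpressing",
        np.where(lig, "ligand_only", np.where(rec, "receptor_only", "neither")),
    )
    return out


def domain_class_proportions(classification, domain_labels) -> pd.DataFrame:
    """Per-domain fractions of the four spot classes (rows sum to 1)."""
    df = pd.DataFrame(
        {"cls": np.asarray(classification), "domain": np.asarray(domain_labels)}
    )
    table = (
        df.groupby("domain")["cls"].value_counts(normalize=True).unstack(fill_value=0.0)
    )
    for c in SPOT_CLASSES:
        if c not in table:
            table[c] = 0.0
    return table[SPOT_CLASSES]


def _lower_triangle_normalize(C: np.ndarray) -> np.ndarray:
    """Zero the diagonal and strict upper triangle; normalize the rest to 1."""
    out = np.tril(C, k=-1)
    total = out.sum()
    if total > 0:
        out = out / total
    return out


def cooccurrence_matrix(weights: pd.DataFrame, spot_mask=None) -> pd.DataFrame:
    """W_S^T W_S over a spot set, diagonal/upper zeroed, lower triangle
    normalized to sum to one."""
    W = weights.to_numpy(dtype=float)
    if spot_mask is not None:
        W = W[np.asarray(spot_mask, dtype=bool)]
    C = _lower_triangle_normalize(W.T @ W)
    return pd.DataFrame(C, index=weights.columns, columns=weights.columns)


def cooccurrence_enrichment(
    weights: pd.DataFrame,
    coexpress_mask,
    epsilon: float = 1e-6,
    renormalize_rows: bool = True,
) -> CooccurrenceResult:
    """Cell-type co-occurrence enrichment in co-expressing spots.

    ``weights`` is spots x cell types; ``coexpress_mask`` marks the
    co-expressing spot set S_LR (its complement is the control set). Rows
    are renormalized to sum to one first (disable with
    ``renormalize_rows=False`` when the weights are already proportions).
    If S_LR is empty the result is flagged undefined.
    """
    mask = np.asarray(coexpress_mask, dtype=bool)
    if mask.shape[0] != weights.shape[0]:
        raise ValueError("mask length does not match the number of spots")
    W = weights.to_numpy(dtype=float)
    if renormalize_rows:
        sums = W.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        W = W / sums
    celltypes = list(weights.columns)

    if not mask.any() or mask.all():
        warnings.warn("co-expressing or control spot set is empty; ratios undefined", stacklevel=2)
        empty = pd.DataFrame(
            np.zeros((len(celltypes), len(celltypes))), index=celltypes, columns=celltypes
        )
        return CooccurrenceResult(empty, empty.copy(), empty.copy(), epsilon, undefined=True)

    C_lr = _lower_triangle_normalize(W[mask].T @ W[mask])
    C_ctrl = _lower_triangle_normalize(W[~mask].T @ W[~mask])
    R = np.tril(C_lr / (C_ctrl + epsilon), k=-1)
    wrap = lambda M: pd.DataFrame(M, index=celltypes, columns=celltypes)
    return CooccurrenceResult(wrap(C_lr), wrap(C_ctrl), wrap(R), epsilon)
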