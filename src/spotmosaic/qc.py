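"""Spot- and nucleus-level QC filters, count normalization and gene-rank
aggregation.

Filters return boolean masks (True = flagged/excluded) and never reorder
observations. The spot low-expression rule is a conjunction of low depth
AND proximity to the capture-area edge, because depth is systematically
lower in white matter and a global depth cutoff alone would remove tissue.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import median_abs_deviation

from .io import CountsMatrix

__all__ = [
    "NormalizedMatrix",
    "spot_qc_filter",
    "mad_outlier_filter",
    "fixed_threshold_filters",
    "log_normalize",
    "gene_filters",
    "aggregate_gene_ranks",
]


class NormalizedMatrix(CountsMatrix):
    """Log-normalized genes x observations matrix (same container contract
    as :class:`~spotmosaic.io.CountsMatrix`, float-valued)."""


def spot_qc_filter(
    metrics: pd.DataFrame, umi_min: int = 250, edge_max: float = 6.0
) -> pd.Series:
    """Exclusion mask for low-quality edge spots.

    A spot is excluded iff ``sum_umi < umi_min`` AND
    ``edge_distance < edge_max`` — both conditions must hold.
    """
    excluded = (metrics["sum_umi"] < umi_min) & (metrics["edge_distance"] < edge_max)
    return excluded.rename("excluded")


def mad_outlier_filter(
    values,
    batch_labels,
    n_mads_per_batch: dict,
    log_scale: bool = False,
    direction: str = "lower",
) -> pd.Series:
    """Per-batch median-absolute-deviation outlier flags.

    Within each batch, values beyond ``median +/- n * MAD`` are flagged
    (lower tail only when ``direction="lower"``). The MAD uses the 1.4826
    normal-consistency constant; all-equal batches (MAD 0) flag nothing.
    ``log_scale`` applies log1p first, appropriate for library sizes.
    """
    if direction not in ("lower", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    values = pd.Series(np.asarray(values, dtype=float))
    batches = pd.Series(np.asarray(batch_labels), index=values.index)
    missing = set(batches.unique()) - set(n_mads_per_batch)
    if missing:
        raise ValueError(f"no MAD threshold for batch(es) {sorted(missing)}")

    work = np.log1p(values) if log_scale else values
    flags = pd.Series(False, index=values.index, name="outlier")
    for batch, idx in batches.groupby(batches).groups.items():
        v = work.loc[idx]
        if len(v) < 3:
            warnings.warn(f"batch {batch!r} has < 3 observations; not flagged", stacklevel=2)
            continue
        med = float(np.median(v))
        mad = float(median_abs_deviation(v, scale="normal"))
        if mad == 0:
            continue
        n = n_mads_per_batch[batch]
        low = v < med - n * mad
        flags.loc[idx] = low if direction == "lower" else low | (v > med + n * mad)
    return flags


def fixed_threshold_filters(
    metrics: pd.DataFrame, mito_max: float = 0.05, doublet_max: float = 5.0
) -> pd.Series:
    """Flag nuclei with mitochondrial fraction strictly above ``mito_max``
    or doublet score at or above ``doublet_max``."""
    flagged = pd.Series(False, index=metrics.index, name="excluded")
    if "mito_ratio" in metrics:
        flagged |= metrics["mito_ratio"] > mito_max
    if "doublet_score" in metrics:
        flagged |= metrics["doublet_score"] >= doublet_max
    return flagged


def log_normalize(
    counts: CountsMatrix, method: str = "scale_factor", scale: float = 10000.0
) -> NormalizedMatrix:
    """Library-size normalization followed by a log transform.

    ``scale_factor``: ln(count / libsize * scale + 1) — the Seurat-style
    LogNormalize with a scaling factor of 10,000.
    ``size_factor``: size factor = libsize / mean(libsize),
    value = log2(count / size_factor + 1) — the scuttle-style variant.
    Observations with zero library size are dropped with a warning.
    """
    if method not in ("scale_factor", "size_factor"):
        raise ValueError(f"unknown method {method!r}")
    mat = sp.csc_matrix(counts.matrix, dtype=float)
    libsize = np.asarray(mat.sum(axis=0)).ravel()
    keep = libsize > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} observation(s) with zero library size",
            stacklevel=2,
        )
        mat = mat[:, keep]
        libsize = libsize[keep]
    if method == "scale_factor":
        norm = mat.multiply(scale / libsize).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        size_factors = libsize / libsize.mean()
        norm = mat.multiply(1.0 / size_factors).tocsr()
        norm.data = np.log2(norm.data + 1.0)
    barcodes = [b for b, k in zip(counts.barcodes, keep) if k]
    return NormalizedMatrix(norm.tocsr(), list(counts.genes), barcodes)


def gene_filters(
    counts: CountsMatrix,
    mode: str,
    donor_labels=None,
    min_count: int = 3,
    min_prop: float = 0.005,
) -> pd.Series:
    """Gene keep-mask.

    ``all_donors_nonzero`` keeps genes with a nonzero total in every donor;
    ``min_count_prop`` keeps genes with at least ``min_count`` counts in at
    least ``min_prop`` of observations (both bounds inclusive).
    """
    mat = sp.csr_matrix(counts.matrix)
    if mode == "all_donors_nonzero":
        if donor_labels is None:
            raise ValueError("all_donors_nonzero mode requires donor_labels")
        donors = pd.Series(np.asarray(donor_labels))
        keep = np.ones(mat.shape[0], dtype=bool)
        for _, idx in donors.groupby(donors).groups.items():
            cols = np.asarray(idx, dtype=int)
            keep &= np.asarray(mat[:, cols].sum(axis=1)).ravel() > 0
    elif mode == "min_count_prop":
        n_obs = mat.shape[1]
        n_hits = np.asarray((mat >= min_count).sum(axis=1)).ravel()
        keep = n_hits >= min_prop * n_obs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(keep, index=counts.genes, name="keep")


def aggregate_gene_ranks(
    per_donor_tables: dict[str, pd.DataFrame],
    top_n: int = 2000,
    require_all_significant: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Aggregate per-donor spatially-variable-gene rankings.

    Genes are first restricted to those significant (padj < ``alpha``) in
    every donor, the per-donor ranks are averaged, and genes are re-ranked
    by the mean (ties broken alphabetically). The top ``top_n`` are
    returned with their mean rank.
    """
    universes = [set(t["gene"]) for t in per_donor_tables.values()]
    shared = set.intersection(*universes)
    if any(len(u) != len(shared) for u in universes):
        warnings.warn("gene universes differ across donors; intersecting", stacklevel=2)

    keep = shared
    if require_all_significant:
        for t in per_donor_tables.values():
            sig = set(t.loc[t["padj"] < alpha, "gene"])
            keep &= sig
    rank_sum: dict[str, float] = {g: 0.0 for g in keep}
    for t in per_donor_tables.values():
        sub = t.set_index("gene")["rank"]
        for g in keep:
            rank_sum[g] += float(sub[g])
    n_donors = len(per_donor_tables)
    out = pd.DataFrame(
        {"gene": list(keep), "mean_rank": [rank_sum[g] / n_donors for g in keep]}
    ).sort_values(["mean_rank", "gene"], kind="stable").reset_index(drop=True)
    return out.head(top_n)
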