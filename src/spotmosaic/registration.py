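"""Pseudobulk one-vs-all statistics and cross-dataset registration.

The central statistic is the one-vs-all t for gene g and group c,

    t_{g,c} = (Xbar_{g,c} - Xbar_{g,-c}) / sqrt((s2_{g,c} + s2_{g,-c}) / (2 n_c)),

computed from log-normalized expression with the group's size n_c in the
denominator regardless of the complement's size. This is deliberately not
Welch's statistic — a Welch variant is available behind a flag. Profiles of
these t-statistics are Pearson-correlated across datasets (or species,
after one-to-one ortholog mapping) over a focused gene universe to register
query groups onto reference groups. Fisher over-representation of external
gene lists in group DEG sets and heritability gene-set/BED construction
round out the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BedInterval, CountsMatrix, HomologRecord

__all__ = [
    "GroupExpressionStats",
    "pseudobulk_aggregate",
    "group_expression_stats",
    "one_vs_all_t",
    "select_markers",
    "map_orthologs",
    "registration_correlation",
    "over_representation",
    "heritability_genesets",
]


@dataclass
class GroupExpressionStats:
    """Per-(gene, group) means and variances inside and outside the group."""

    genes: list[str]
    groups: list[str]
    mean_in: np.ndarray  # genes x groups
    mean_out: np.ndarray
    var_in: np.ndarray
    var_out: np.ndarray
    n_in: np.ndarray  # per group


def pseudobulk_aggregate(
    counts: CountsMatrix,
    group_labels,
    unit_labels,
    min_spots: int = 50,
    min_detected_genes: int = 2000,
    min_samples_per_group: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sum counts per (group, unit) and drop under-supported samples.

    Pseudobulk samples aggregating fewer than ``min_spots`` observations
    are dropped, then samples detecting fewer than ``min_detected_genes``
    genes and groups left with fewer than ``min_samples_per_group`` samples.
    Returns (genes x samples matrix, sample metadata).
    """
    mat = sp.csc_matrix(counts.matrix)
    groups = pd.Series(np.asarray(group_labels))
    units = pd.Series(np.asarray(unit_labels))
    key = pd.DataFrame({"group": groups, "unit": units})
    cols, meta = [], []
    for (g, u), idx in key.groupby(["group", "unit"], sort=True).groups.items():
        idx = np.asarray(idx, dtype=int)
        if len(idx) < min_spots:
            continue
        cols.append(np.asarray(mat[:, idx].sum(axis=1)).ravel())
        meta.append((g, u, len(idx)))
    if not cols:
        return np.empty((mat.shape[0], 0)), pd.DataFrame(columns=["group", "unit", "n_obs"])
    pb = np.column_stack(cols)
    meta = pd.DataFrame(meta, columns=["group", "unit", "n_obs"])

    detected = (pb > 0).sum(axis=0)
    keep = detected >= min_detected_genes
    pb, meta = pb[:, keep], meta.loc[keep].reset_index(drop=True)
    sizes = meta.groupby("group")["group"].transform("size")
    keep = (sizes >= min_samples_per_group).to_numpy()
    return pb[:, keep], meta.loc[keep].reset_index(drop=True)


def group_expression_stats(expr: np.ndarray, labels, genes: list[str]) -> GroupExpressionStats:
    """Compute per-group in/out means and (ddof=1) variances.

    ``expr`` is genes x observations of log-normalized expression.
    """
    expr = np.asarray(expr, dtype=float)
    labels = pd.Series(np.asarray(labels))
    groups = sorted(labels.unique())
    n_genes = expr.shape[0]
    mean_in = np.empty((n_genes, len(groups)))
    mean_out = np.empty_like(mean_in)
    var_in = np.empty_like(mean_in)
    var_out = np.empty_like(mean_in)
    n_in = np.empty(len(groups), dtype=int)
    for j, g in enumerate(groups):
        sel = (labels == g).to_numpy()
        if sel.sum() < 2 or (~sel).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations on both sides")
        mean_in[:, j] = expr[:, sel].mean(axis=1)
        mean_out[:, j] = expr[:, ~sel].mean(axis=1)
        var_in[:, j] = expr[:, sel].var(axis=1, ddof=1)
        var_out[:, j] = expr[:, ~sel].var(axis=1, ddof=1)
        n_in[j] = int(sel.sum())
    return GroupExpressionStats(list(genes), groups, mean_in, mean_out, var_in, var_out, n_in)


def one_vs_all_t(stats_in: GroupExpressionStats, welch: bool = False) -> pd.DataFrame:
    """One-vs-all t-statistics, p-values and BH-FDR per group.

    The default denominator pools the in- and out-group variances over
    2 n_c (the group's own size), with a t reference on 2 n_c - 2 degrees
    of freedom. ``welch=True`` uses the Welch statistic and
    Welch-Satterthwaite degrees of freedom instead. ``logFC`` is the
    difference of mean log expression. Zero pooled variance yields t = 0
    when the means agree and an infinite sentinel otherwise.
    """
    rows = []
    s = stats_in
    n_out_total = None
    for j, grp in enumerate(s.groups):
        diff = s.mean_in[:, j] - s.mean_out[:, j]
        n_c = s.n_in[j]
        if welch:
            n_o = int(s.n_in.sum() - n_c) if n_out_total is None else n_out_total
            se2 = s.var_in[:, j] / n_c + s.var_out[:, j] / n_o
            with np.errstate(divide="ignore", invalid="ignore"):
                df = se2**2 / (
                    (s.var_in[:, j] / n_c) ** 2 / (n_c - 1)
                    + (s.var_out[:, j] / n_o) ** 2 / (n_o - 1)
                )
            df = np.nan_to_num(df, nan=1.0)
        else:
            se2 = (s.var_in[:, j] + s.var_out[:, j]) / (2.0 * n_c)
            df = np.full(len(diff), 2 * n_c - 2, dtype=float)
        t = np.empty(len(diff))
        zero_se = se2 == 0
        if np.any(zero_se & (diff != 0)):
            warnings.warn("zero pooled variance with nonzero mean difference", stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero_se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), diff / np.sqrt(se2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isinf(t), 0.0, p)
        fdr = multipletests(p, method="fdr_bh")[1]
        rows.append(
            pd.DataFrame(
                {"gene": s.genes, "group": grp, "t": t, "logFC": diff, "p": p, "fdr": fdr}
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_markers(
    de: pd.DataFrame, top_n: int = 250, fdr_max: float = 0.05
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-group marker lists: FDR < ``fdr_max``, logFC > 0, ranked by
    descending logFC, top ``top_n``; plus their union."""
    per_group: dict[str, list[str]] = {}
    for grp, sub in de.groupby("group"):
        passed = sub[(sub["fdr"] < fdr_max) & (sub["logFC"] > 0)]
        if passed.empty:
            warnings.warn(f"no marker genes pass filters for group {grp!r}", stacklevel=2)
            per_group[grp] = []
            continue
        per_group[grp] = (
            passed.sort_values(["logFC", "gene"], ascending=[False, True], kind="stable")
            .head(top_n)["gene"]
            .tolist()
        )
    union: list[str] = sorted({g for lst in per_group.values() for g in lst})
    return per_group, union


def map_orthologs(
    gene_lists: dict[str, list[str]], homologs: list[HomologRecord]
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Translate gene lists through one-to-one homolog records.

    Genes without a one-to-one match are dropped; a per-list mapping report
    (n mapped / n dropped) is returned alongside.
    """
    mapping = {h.source_symbol: h.target_symbol for h in homologs}
    out: dict[str, list[str]] = {}
    report = []
    for name, genes in gene_lists.items():
        mapped = [mapping[g] for g in genes if g in mapping]
        out[name] = mapped
        report.append((name, len(mapped), len(genes) - len(mapped)))
    return out, pd.DataFrame(report, columns=["list", "n_mapped", "n_dropped"])


def registration_correlation(
    query_t: pd.DataFrame,
    reference_t: pd.DataFrame,
    gene_universe="top100_per_reference_group",
    top_n: int = 100,
) -> pd.DataFrame:
    """Pearson-correlate query and reference t-statistic profiles.

    ``query_t`` and ``reference_t`` are genes x groups tables indexed by
    gene. ``gene_universe`` is either an explicit gene list (e.g. a marker
    union) or ``"top100_per_reference_group"``, which takes the union of
    the ``top_n`` genes by t per reference group. Returns query groups x
    reference groups correlations.
    """
    shared = query_t.index.intersection(reference_t.index)
    if isinstance(gene_universe, str):
        if gene_universe != "top100_per_reference_group":
            raise ValueError(f"unknown gene universe {gene_universe!r}")
        ref = reference_t.loc[shared]
        universe: set[str] = set()
        for col in ref.columns:
            universe |= set(ref[col].nlargest(top_n).index)
        genes = [g for g in shared if g in universe]
    else:
        genes = [g for g in shared if g in set(gene_universe)]
    if len(genes) < 3:
        raise ValueError(f"gene universe too small after intersection ({len(genes)} genes)")
    q = query_t.loc[genes]
    r = reference_t.loc[genes]
    out = np.empty((q.shape[1], r.shape[1]))
    for i, qc in enumerate(q.columns):
        for j, rc in enumerate(r.columns):
            out[i, j] = stats.pearsonr(q[qc], r[rc])[0]
    return pd.DataFrame(out, index=q.columns, columns=r.columns)


def over_representation(
    gene_list,
    de_genes_by_group: dict[str, set],
    universe,
    min_list: int = 25,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of a gene list in group DEG sets.

    The list is intersected with the universe; lists below ``min_list``
    genes are skipped with a warning (a power guard). Returns per group the
    2x2 counts, sample odds ratio (ad/bc) and one-sided (enrichment)
    Fisher exact p.
    """
    universe = set(universe)
    glist = set(gene_list) & universe
    if len(glist) < min_list:
        warnings.warn(
            f"gene list has {len(glist)} genes in the universe (< {min_list}); skipped",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["group", "a", "b", "c", "d", "odds_ratio", "p"])
    rows = []
    for grp, degs in de_genes_by_group.items():
        degs = set(degs) & universe
        a = len(glist & degs)
        b = len(glist - degs)
        c = len(degs - glist)
        d = len(universe) - a - b - c
        table = [[a, b], [c, d]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((grp, a, b, c, d, odds, p))
    return pd.DataFrame(rows, columns=["group", "a", "b", "c", "d", "odds_ratio", "p"])


def heritability_genesets(
    pseudobulk: np.ndarray,
    genes: list[str],
    groups: list[str],
    gene_coords: pd.DataFrame,
    top_fraction: float = 0.10,
    flank: int = 100_000,
    exclude_chroms: set[str] = frozenset({"chrX", "chrY", "chrMT"}),
) -> tuple[dict[str, list[BedInterval]], pd.DataFrame]:
    """Top relative-expression gene intervals per group, BED-ready.

    Relative expression is each gene's CPM over the group's total CPM; the
    top ``ceil(n * top_fraction)`` genes per group are selected. Intervals
    span the gene (``gene_coords``: gene, chrom, start, end; 1-based
    inclusive) extended by ``flank`` on both sides, clipped at zero, with
    the excluded chromosomes dropped. A per-group report counts genes
    dropped for missing coordinates.
    """
    pb = np.asarray(pseudobulk, dtype=float)
    colsum = pb.sum(axis=0)
    cpm = pb / np.where(colsum == 0, 1.0, colsum) * 1e6
    rel = cpm / np.where(cpm.sum(axis=0) == 0, 1.0, cpm.sum(axis=0))
    coords = gene_coords.set_index("gene")

    out: dict[str, list[BedInterval]] = {}
    report = []
    n_top = math.ceil(len(genes) * top_fraction)
    for j, grp in enumerate(groups):
        order = pd.Series(rel[:, j], index=genes).sort_values(ascending=False, kind="stable")
        top = order.head(n_top).index
        intervals, n_missing, n_excluded = [], 0, 0
        for g in top:
            if g not in coords.index:
                n_missing += 1
                continue
            row = coords.loc[g]
            if row["chrom"] in exclude_chroms:
                n_excluded += 1
                continue
            start0 = int(row["start"]) - 1  # 1-based inclusive -> 0-based half-open
            end0 = int(row["end"])
            intervals.append(
                BedInterval(str(row["chrom"]), max(0, start0 - flank), end0 + flank, str(g))
            )
        out[grp] = intervals
        report.append((grp, len(intervals), n_missing, n_excluded))
    return out, pd.DataFrame(
        report, columns=["group", "n_intervals", "n_missing_coords", "n_excluded_chrom"]
    )
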