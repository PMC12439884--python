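"""Non-negative matrix factorization, factor transfer and factor screening.

A genes x observations log-normalized matrix A is decomposed as A ~ W H
with non-negative W (gene loadings) and H (observation scores) by
multiplicative updates minimizing

    0.5 * ||M * (A - W H)||_F^2 + l1_w * ||W||_1,

where M is an optional observation mask (used for held-out-entry
cross-validation; masked entries are excluded from the objective, not
zero-filled). The objective is non-increasing under these updates, which
the tests assert on the recorded trace. After convergence each factor is
rescaled so its W column sums to one, with the scale absorbed into H.

Transfer onto a second dataset uses the literal projection H' = W^T A'
(with an optional non-negative least-squares mode) followed by per-spot
sum-to-one normalization; screening drops factors correlated with donor
sex or detected in too few spots, and a rank-biserial Wilcoxon test flags
condition-responsive factors per cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FactorModel",
    "ProjectionResult",
    "fit_nmf",
    "cross_validate_rank",
    "project_factors",
    "match_factors",
    "exclude_factors",
    "summarize_by_domain",
    "factor_gene_correlation",
    "drug_factor_association",
]

_EPS = 1e-12


@dataclass
class FactorModel:
    W: np.ndarray  # genes x k, columns sum to 1
    H: np.ndarray  # k x observations
    k: int
    scaling: np.ndarray  # per-factor scale absorbed into H
    objective_trace: list[float]
    seed: int
    l1_w: float

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ProjectionResult:
    H: np.ndarray  # k x spots, spot columns sum to 1 unless all-zero
    zero_spots: np.ndarray  # boolean, spots exempt from normalization
    gene_coverage: float  # fraction of model genes found in the target
    normalized: bool = True


def _objective(A, W, H, l1_w, mask=None) -> float:
    R = A - W @ H
    if mask is not None:
        R = R * mask
    return 0.5 * float((R * R).sum()) + l1_w * float(W.sum())


def fit_nmf(
    A: np.ndarray,
    k: int,
    l1_w: float = 0.1,
    tol: float = 1e-6,
    maxit: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> FactorModel:
    """Fit A ~ W H with multiplicative updates.

    ``tol`` is the relative objective change at which iteration stops;
    ``mask`` (True = observed) excludes entries from the fit. Raises on
    non-finite input or k >= min(A.shape).
    """
    A = np.asarray(A, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("input matrix contains non-finite entries")
    if A.min() < 0:
        raise ValueError("input matrix must be non-negative")
    if not 1 <= k < min(A.shape):
        raise ValueError(f"rank k={k} must satisfy 1 <= k < min{A.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), _EPS) / k)
    W = rng.uniform(0.1, 1.0, size=(A.shape[0], k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, A.shape[1])) * scale
    M = None if mask is None else np.asarray(mask, dtype=float)
    Am = A if M is None else A * M

    trace = [_objective(A, W, H, l1_w, M)]
    for _ in range(maxit):
        WH = W @ H if M is None else (W @ H) * M
        H *= (W.T @ Am) / (W.T @ WH + _EPS)
        WH = W @ H if M is None else (W @ H) * M
        W *= (Am @ H.T) / (WH @ H.T + l1_w + _EPS)
        obj = _objective(A, W, H, l1_w, M)
        trace.append(obj)
        denom = abs(trace[-2]) + _EPS
        if abs(trace[-2] - obj) / denom < tol:
            break

    col_sums = W.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    W = W / col_sums
    H = H * col_sums[:, None]
    return FactorModel(
        W=W, H=H, k=k, scaling=col_sums, objective_trace=trace, seed=seed, l1_w=l1_w
    )


def cross_validate_rank(
    A: np.ndarray,
    ranks,
    n_rep: int = 3,
    holdout: float = 0.2,
    seed: int = 0,
    l1_w: float = 0.1,
    tol: float = 1e-4,
    maxit: int = 200,
) -> tuple[pd.DataFrame, int]:
    """Held-out-entry cross-validation over candidate ranks.

    Per rank and replicate a random ``holdout`` fraction of entries is
    masked out of the fit and scored by held-out RMSE. Returns the per-rank
    table and the recommended rank — the smallest rank whose mean error is
    within one standard error of the minimum.
    """
    if not 0 < holdout < 1:
        raise ValueError("holdout must be in (0, 1)")
    A = np.asarray(A, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rank in ranks:
        for rep in range(n_rep):
            mask = rng.random(A.shape) >= holdout  # True = train
            model = fit_nmf(A, rank, l1_w=l1_w, tol=tol, maxit=maxit, seed=seed + rep, mask=mask)
            resid = (A - model.reconstruct())[~mask]
            rows.append((rank, rep, float(np.sqrt(np.mean(resid**2)))))
    table = pd.DataFrame(rows, columns=["rank", "rep", "rmse"])
    summary = table.groupby("rank")["rmse"].agg(["mean", "std", "count"])
    best = summary["mean"].idxmin()
    se = summary.loc[best, "std"] / np.sqrt(summary.loc[best, "count"])
    threshold = summary.loc[best, "mean"] + (0.0 if np.isnan(se) else se)
    recommended = int(min(r for r in summary.index if summary.loc[r, "mean"] <= threshold))
    return table, recommended


def project_factors(
    W: np.ndarray,
    genes_model: list[str],
    A_target: np.ndarray,
    genes_target: list[str],
    mode: str = "dot",
    normalize: bool = True,
) -> ProjectionResult:
    """Transfer factor loadings onto a target expression matrix.

    Genes are intersected (in model order). ``dot`` computes the literal
    projection H' = W^T A'; ``lstsq`` solves min ||A' - W H'|| with
    non-negativity per spot. With ``normalize`` each spot's factor vector
    is scaled to sum to one; all-zero spots are exempt and flagged.
    """
    target_pos = {g: i for i, g in enumerate(genes_target)}
    rows_model, rows_target = [], []
    for i, g in enumerate(genes_model):
        if g in target_pos:
            rows_model.append(i)
            rows_target.append(target_pos[g])
    if not rows_model:
        raise ValueError("no genes shared between the factor model and the target")
    Wm = np.asarray(W, dtype=float)[rows_model]
    At = np.asarray(A_target, dtype=float)[rows_target]

    if mode == "dot":
        Hp = Wm.T @ At
    elif mode == "lstsq":
        Hp = np.column_stack([nnls(Wm, At[:, j])[0] for j in range(At.shape[1])])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    zero = np.abs(Hp).sum(axis=0) == 0
    if normalize:
        sums = Hp.sum(axis=0)
        sums[zero] = 1.0
        Hp = Hp / sums
    return ProjectionResult(
        H=Hp,
        zero_spots=zero,
        gene_coverage=len(rows_model) / len(genes_model),
        normalized=normalize,
    )


def match_factors(W_est: np.ndarray, W_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal factor-to-factor assignment on the cosine-similarity matrix.

    Returns (permutation mapping true factor j to estimated factor perm[j],
    matched cosine similarities).
    """
    from scipy.optimize import linear_sum_assignment

    def _unit(M):
        n = np.linalg.norm(M, axis=0)
        n[n == 0] = 1.0
        return M / n

    C = _unit(np.asarray(W_est, float)).T @ _unit(np.asarray(W_true, float))
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(W_true.shape[1], dtype=int)
    perm[cols] = rows
    return perm, C[rows, cols]


def exclude_factors(
    H: np.ndarray,
    sex_labels,
    r_max: float = 0.3,
    min_spots: int = 200,
    projections: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop factors confounded with sex or detected in too few spots.

    A factor is excluded when |Pearson r| between its scores and the sex
    indicator exceeds ``r_max``, or when its projection (``projections`` if
    given, else ``H``) is nonzero in fewer than ``min_spots`` observations.
    Returns (kept factor indices, per-factor report).
    """
    H = np.asarray(H, dtype=float)
    sex = pd.Series(np.asarray(sex_labels))
    indicator = (sex == sorted(sex.unique())[0]).to_numpy(dtype=float)
    P = H if projections is None else np.asarray(projections, dtype=float)
    rows = []
    for f in range(H.shape[0]):
        if H[f].std() == 0 or indicator.std() == 0:
            r = 0.0
        else:
            r = float(stats.pearsonr(H[f], indicator)[0])
        n_nonzero = int((P[f] > 0).sum())
        rows.append((f, r, n_nonzero, abs(r) > r_max, n_nonzero < min_spots))
    report = pd.DataFrame(
        rows, columns=["factor", "sex_r", "n_nonzero", "excluded_sex", "excluded_sparse"]
    )
    kept = report.loc[~(report["excluded_sex"] | report["excluded_sparse"]), "factor"]
    return kept.to_numpy(), report


def summarize_by_domain(
    projections: np.ndarray,
    domain_labels,
    prevalence_min: float = 0.2,
    scaled_mean_min: float = 0.2,
) -> pd.DataFrame:
    """Per-(factor, domain) prevalence, mean projection and z-scaled mean.

    Prevalence is the fraction of the domain's spots with a nonzero
    projection; the mean projection is z-scaled across domains within each
    factor. A factor is flagged domain-associated when both thresholds are
    exceeded in at least one domain.
    """
    P = np.asarray(projections, dtype=float)
    labels = pd.Series(np.asarray(domain_labels))
    domains = sorted(labels.unique())
    rows = []
    for f in range(P.shape[0]):
        means, prevs = [], []
        for dom in domains:
            sel = (labels == dom).to_numpy()
            means.append(P[f, sel].mean())
            prevs.append(float((P[f, sel] > 0).mean()))
        means = np.array(means)
        sd = means.std(ddof=0)
        scaled = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
        for dom, m, pr, sm in zip(domains, means, prevs, scaled):
            rows.append((f, dom, pr, m, sm, pr > prevalence_min and sm > scaled_mean_min))
    df = pd.DataFrame(
        rows, columns=["factor", "domain", "prevalence", "mean", "scaled_mean", "associated"]
    )
    flag = df.groupby("factor")["associated"].any().rename("factor_associated")
    return df.merge(flag, on="factor")


def factor_gene_correlation(
    H: np.ndarray, expr: np.ndarray, gene_names: list[str], top_n: int = 20
) -> dict[int, pd.DataFrame]:
    """Top genes correlated with each factor's scores.

    ``H`` is factors x observations, ``expr`` genes x observations.
    Constant genes correlate 0 by convention (with a warning).
    """
    H = np.asarray(H, dtype=float)
    X = np.asarray(expr, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = Xc.std(axis=1)
    const = xsd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s): correlation set to 0", stacklevel=2)
    out: dict[int, pd.DataFrame] = {}
    for f in range(H.shape[0]):
        h = H[f] - H[f].mean()
        hsd = h.std()
        if hsd == 0:
            r = np.zeros(X.shape[0])
        else:
            r = (Xc @ h) / (len(h) * np.where(const, 1.0, xsd) * hsd)
            r[const] = 0.0
        table = (
            pd.DataFrame({"gene": gene_names, "r": r})
            .sort_values("r", ascending=False, kind="stable")
            .head(top_n)
            .reset_index(drop=True)
        )
        out[f] = table
    return out


def drug_factor_association(
    H: np.ndarray,
    condition_labels,
    celltype_labels,
    drug_label: str = "drug",
    control_label: str = "control",
    effect_min: float = 0.3,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum screen for condition-responsive factors.

    Within each cell type, factor scores are compared between drug and
    control nuclei (two-sided); the effect size is the rank-biserial
    correlation r = 2 U1 / (n1 n0) - 1, which is +1 under complete
    separation drug > control. BH-FDR is applied across all
    (factor, cell type) tests; a factor is flagged responsive when
    |effect| > ``effect_min`` and FDR < ``fdr_max`` in at least one cell
    type. Strata missing either condition are skipped.
    """
    H = np.asarray(H, dtype=float)
    condition = pd.Series(np.asarray(condition_labels))
    celltype = pd.Series(np.asarray(celltype_labels))
    rows = []
    for ct in sorted(celltype.unique()):
        sel = (celltype == ct).to_numpy()
        drug_sel = sel & (condition == drug_label).to_numpy()
        ctrl_sel = sel & (condition == control_label).to_numpy()
        n1, n0 = int(drug_sel.sum()), int(ctrl_sel.sum())
        if n1 == 0 or n0 == 0:
            continue
        for f in range(H.shape[0]):
            u1, p = stats.mannwhitneyu(
                H[f, drug_sel], H[f, ctrl_sel], alternative="two-sided"
            )
            effect = 2.0 * u1 / (n1 * n0) - 1.0
            rows.append((f, ct, n1, n0, float(u1), float(effect), float(p)))
    df = pd.DataFrame(rows, columns=["factor", "cell_type", "n_drug", "n_control", "U", "effect", "p"])
    if df.empty:
        df["fdr"] = []
        df["responsive"] = []
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = (df["effect"].abs() > effect_min) & (df["fdr"] < fdr_max)
    flag = df.groupby("factor")["significant"].any().rename("responsive")
    return df.merge(flag, on="factor")
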