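"""Synthetic Visium-like and snRNA-seq-like data with planted ground truth.

Every input the downstream stages consume can be generated here: multiple
hexagonal capture areas with known rigid offsets and overlap regions,
landmark pairs with optional jitter, domain-structured negative-binomial
spot counts (medial-lateral gradients or island domains), cell-type-labelled
nuclei counts with optional sex and drug programs, planted non-negative
factor structure, and Dirichlet deconvolution weights centred on
domain-specific mixtures. All generators are pure functions of
(config, seed).

Geometry follows the Visium convention: within an array row, spots sit at
every second ``array_col`` (column parity equals row parity), so the
same-row neighbour two columns over is one pitch away and interior spots
have six equidistant neighbours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountsMatrix, NATIVE_ARRAY_COL_MAX, NATIVE_ARRAY_ROW_MAX

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "LandmarkPairs",
    "hex_lattice",
    "simulate_capture_areas",
    "simulate_domain_counts",
    "simulate_nuclei",
    "simulate_deconv_weights",
    "simulate_factor_data",
    "simulate_lr_colocalization",
]

ROW_SPACING_FACTOR = math.sqrt(3.0) / 2.0  # hex lattice row spacing in pitches


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generators.

    Spot-level defaults mirror a Visium capture array (100 um pitch, native
    array bounds) with strong, recoverable domain structure: negative
    binomial counts with per-gene mean 2.5 and dispersion 5 — so the
    default 120-gene panel yields roughly 300 UMIs per spot, above the
    250-UMI floor real spots are expected to clear — and an 8-fold marker
    enrichment.
    """

    seed: int = 0
    # capture-area geometry
    n_capture_areas: int = 2
    grid_rows: int = 30
    grid_cols: int = 30
    pitch: float = 100.0  # um; synthetic pixel scale is 1 px/um
    overlap_fraction: float = 0.2
    true_transforms: list[tuple[float, tuple[float, float]]] | None = None
    landmark_noise_sd: float = 0.0
    n_landmarks_per_overlap: int = 6
    # spot counts
    n_genes: int = 120
    n_domains: int = 3
    domain_layout: str = "lateral_gradient"  # lateral_gradient | island | uniform
    markers_per_domain: int = 10
    nb_mean: float = 2.5
    nb_dispersion: float = 5.0
    marker_fold_change: float = 8.0
    # nuclei
    n_nuclei: int = 800
    n_celltypes: int = 4
    nuclei_n_genes: int = 200
    nuclei_markers_per_type: int = 10
    sex_program_size: int = 5
    sex_effect: float = 4.0
    drug_program_size: int = 10
    drug_effect: float = 3.0
    drug_celltypes: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ConfigurationError("pitch must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.marker_fold_change < 1:
            raise ConfigurationError("marker_fold_change must be >= 1")
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigurationError("overlap_fraction must be in [0, 1)")
        if self.grid_rows - 1 > NATIVE_ARRAY_ROW_MAX:
            raise ConfigurationError(
                f"grid_rows={self.grid_rows} exceeds the native array_row "
                f"bound of {NATIVE_ARRAY_ROW_MAX}"
            )
        if 2 * (self.grid_cols - 1) + 1 > NATIVE_ARRAY_COL_MAX:
            raise ConfigurationError(
                f"grid_cols={self.grid_cols} exceeds the native array_col "
                f"bound of {NATIVE_ARRAY_COL_MAX}"
            )


@dataclass
class LandmarkPairs:
    """Matched point pairs between two capture areas, (x, y) pixel coords."""

    area_a: str
    area_b: str
    points_a: np.ndarray  # (n, 2)
    points_b: np.ndarray  # (n, 2)

    def __len__(self) -> int:
        return len(self.points_a)


@dataclass
class GroundTruth:
    """Planted structure carried alongside the generated data."""

    spot_domain_labels: pd.Series | None = None
    nuclei_celltype_labels: pd.Series | None = None
    planted_W: np.ndarray | None = None
    planted_H: np.ndarray | None = None
    planted_lr_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_transforms: dict[str, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    true_overlap_pairs: list[tuple[str, str]] = field(default_factory=list)
    domain_celltype_mixtures: pd.DataFrame | None = None
    marker_genes: dict[str, list[str]] = field(default_factory=dict)


def hex_lattice(rows: int, cols: int, pitch: float, origin=(0.0, 0.0)) -> pd.DataFrame:
    """A rows x cols block of Visium-style hexagonal lattice spots.

    Returns a DataFrame with ``array_row``, ``array_col`` (col parity equals
    row parity) and pixel coordinates ``x``, ``y``. Interior spots have six
    neighbours, each exactly one ``pitch`` away.
    """
    r = np.repeat(np.arange(rows), cols)
    j = np.tile(np.arange(cols), rows)
    c = 2 * j + (r % 2)
    x = origin[0] + c * (pitch / 2.0)
    y = origin[1] + r * (pitch * ROW_SPACING_FACTOR)
    return pd.DataFrame({"array_row": r, "array_col": c, "x": x, "y": y})


def _rotate(points: np.ndarray, theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return points @ np.array([[c, -s], [s, c]]).T


def simulate_capture_areas(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], list[LandmarkPairs], GroundTruth]:
    """Generate overlapping capture areas with known rigid placements.

    A single global hexagonal lattice is windowed into ``n_capture_areas``
    column blocks where consecutive blocks share a fraction
    ``overlap_fraction`` of their columns. Each area's native coordinates
    are the global coordinates pulled back through the inverse of its true
    transform, so applying the true transform re-stitches the section
    exactly. Landmark pairs are matched lattice points in the overlap,
    jittered by ``landmark_noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    n_areas = config.n_capture_areas
    overlap_cols = int(round(config.overlap_fraction * config.grid_cols))
    if n_areas > 1 and overlap_cols * config.grid_rows < 4:
        raise ConfigurationError(
            "overlap_fraction too small: fewer than 4 landmarkable spots per overlap"
        )

    step = config.grid_cols - overlap_cols
    total_cols = config.grid_cols + (n_areas - 1) * step
    global_lattice = hex_lattice(config.grid_rows, total_cols, config.pitch)

    transforms = config.true_transforms
    if transforms is None:
        # modest arbitrary placements; the first area is the reference
        transforms = [(0.0, (0.0, 0.0))]
        for i in range(1, n_areas):
            theta = rng.uniform(-0.3, 0.3)
            shift = tuple(rng.uniform(-200.0, 200.0, size=2))
            transforms.append((theta, shift))
    if len(transforms) != n_areas:
        raise ConfigurationError("true_transforms length must equal n_capture_areas")

    area_ids = [f"A{i + 1}" for i in range(n_areas)]
    areas: dict[str, pd.DataFrame] = {}
    gt = GroundTruth()
    barcode_of_global: dict[int, list[str]] = {}

    for i, area in enumerate(area_ids):
        j_lo, j_hi = i * step, i * step + config.grid_cols
        block = global_lattice[
            (global_lattice["array_col"] // 2 >= j_lo) & (global_lattice["array_col"] // 2 < j_hi)
        ].reset_index()
        theta, (tx, ty) = transforms[i]
        # native frame = inverse placement of global coordinates
        native = _rotate(block[["x", "y"]].to_numpy() - np.array([tx, ty]), -theta)
        barcodes = [f"{area}_s{k}" for k in range(len(block))]
        for g_idx, bc in zip(block["index"], barcodes):
            barcode_of_global.setdefault(int(g_idx), []).append(bc)
        areas[area] = pd.DataFrame(
            {
                "barcode": barcodes,
                "in_tissue": 1,
                "array_row": block["array_row"].to_numpy(),
                "array_col": (block["array_col"] - 2 * j_lo).to_numpy(),
                "pxl_col_in_fullres": native[:, 0],
                "pxl_row_in_fullres": native[:, 1],
                "capture_area": area,
                "global_x": block["x"].to_numpy(),
                "global_y": block["y"].to_numpy(),
            }
        )
        gt.true_transforms[area] = (theta, (tx, ty))

    gt.true_overlap_pairs = [
        (bcs[a], bcs[b])
        for bcs in barcode_of_global.values()
        for a in range(len(bcs))
        for b in range(a + 1, len(bcs))
    ]

    landmarks: list[LandmarkPairs] = []
    for i in range(n_areas - 1):
        a, b = area_ids[i], area_ids[i + 1]
        shared = pd.merge(
            areas[a][["barcode", "global_x", "global_y"]],
            areas[b][["barcode", "global_x", "global_y"]],
            on=["global_x", "global_y"],
            suffixes=("_a", "_b"),
        )
        if len(shared) < 4:
            raise ConfigurationError(f"fewer than 4 landmarks derivable for ({a}, {b})")
        n_lm = min(config.n_landmarks_per_overlap, len(shared))
        pick = shared.iloc[
            np.sort(rng.choice(len(shared), size=n_lm, replace=False))
        ]
        glob = pick[["global_x", "global_y"]].to_numpy(dtype=float)
        pa = _rotate(glob - np.array(gt.true_transforms[a][1]), -gt.true_transforms[a][0])
        pb = _rotate(glob - np.array(gt.true_transforms[b][1]), -gt.true_transforms[b][0])
        if config.landmark_noise_sd > 0:
            pa = pa + rng.normal(0, config.landmark_noise_sd, pa.shape)
            pb = pb + rng.normal(0, config.landmark_noise_sd, pb.shape)
        landmarks.append(LandmarkPairs(a, b, pa, pb))

    return areas, landmarks, gt


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + mu^2 / dispersion."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def assign_domains(spots: pd.DataFrame, config: SimulationConfig, rng=None) -> pd.Series:
    """Assign each spot a domain label under the configured layout."""
    x = spots["global_x"].to_numpy() if "global_x" in spots else spots["x"].to_numpy()
    y = spots["global_y"].to_numpy() if "global_y" in spots else spots["y"].to_numpy()
    n = len(spots)
    if config.domain_layout == "uniform":
        labels = np.zeros(n, dtype=int)
    elif config.domain_layout == "lateral_gradient":
        edges = np.quantile(x, np.linspace(0, 1, config.n_domains + 1))
        labels = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, config.n_domains - 1)
    elif config.domain_layout == "island":
        rng = rng or np.random.default_rng(config.seed + 1)
        labels = np.zeros(n, dtype=int)
        span = max(x.max() - x.min(), y.max() - y.min())
        radius = span / (2.0 * config.n_domains)
        for d in range(1, config.n_domains):
            cx = rng.uniform(x.min() + radius, x.max() - radius)
            cy = rng.uniform(y.min() + radius, y.max() - radius)
            inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
            labels[inside] = d
    else:
        raise ConfigurationError(f"unknown domain_layout {config.domain_layout!r}")
    index = spots["barcode"] if "barcode" in spots else spots.index
    return pd.Series([f"domain_{d}" for d in labels], index=index, name="domain")


def simulate_domain_counts(
    spots: pd.DataFrame, config: SimulationConfig, domain_labels: pd.Series | None = None
) -> tuple[CountsMatrix, pd.Series, dict[str, list[str]]]:
    """Negative-binomial spot counts with disjoint per-domain marker sets.

    Under the gradient layout, marker means ramp linearly along the lateral
    (x) axis toward each domain's band centre; under island/uniform layouts
    markers are flatly enriched ``marker_fold_change``-fold in their domain.
    """
    if config.n_genes < config.n_domains * config.markers_per_domain:
        raise ConfigurationError(
            "n_genes must be at least n_domains * markers_per_domain"
        )
    rng = np.random.default_rng(config.seed + 2)
    if domain_labels is None:
        domain_labels = assign_domains(spots, config, rng)
    domains = [f"domain_{d}" for d in range(config.n_domains)]
    genes = [f"gene_{g}" for g in range(config.n_genes)]
    markers = {
        dom: genes[d * config.markers_per_domain : (d + 1) * config.markers_per_domain]
        for d, dom in enumerate(domains)
    }

    x = spots["global_x"].to_numpy() if "global_x" in spots else spots["x"].to_numpy()
    n_spots = len(spots)
    mean = np.full((config.n_genes, n_spots), config.nb_mean)
    fold = config.marker_fold_change
    if config.domain_layout == "lateral_gradient" and fold > 1:
        centers = np.quantile(x, (np.arange(config.n_domains) + 0.5) / config.n_domains)
        spacing = max((x.max() - x.min()) / config.n_domains, 1e-9)
        for d, dom in enumerate(domains):
            ramp = np.clip(1.0 - np.abs(x - centers[d]) / spacing, 0.0, 1.0)
            rows = slice(d * config.markers_per_domain, (d + 1) * config.markers_per_domain)
            mean[rows, :] *= 1.0 + (fold - 1.0) * ramp[None, :]
    elif fold > 1:
        lab = domain_labels.to_numpy()
        for d, dom in enumerate(domains):
            rows = slice(d * config.markers_per_domain, (d + 1) * config.markers_per_domain)
            mean[rows, lab == dom] *= fold

    counts = _nb_sample(rng, mean, config.nb_dispersion)
    import scipy.sparse as sp

    barcodes = spots["barcode"].tolist() if "barcode" in spots else list(map(str, spots.index))
    return (
        CountsMatrix(sp.csr_matrix(counts), genes, barcodes),
        domain_labels,
        markers,
    )


def simulate_nuclei(
    config: SimulationConfig,
) -> tuple[CountsMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Cell-type-labelled nuclei counts with sex and drug covariates.

    Cell types carry disjoint marker programs; a small planted sex program
    is shifted in one sex (to exercise the sex-correlation factor exclusion)
    and a drug program is shifted in ``drug_celltypes`` under the drug
    condition (to exercise the drug-association test).
    """
    rng = np.random.default_rng(config.seed + 3)
    n, g = config.n_nuclei, config.nuclei_n_genes
    n_ct, mpc = config.n_celltypes, config.nuclei_markers_per_type
    if g < n_ct * mpc + config.sex_program_size + config.drug_program_size:
        raise ConfigurationError("nuclei_n_genes too small for the requested programs")

    celltypes = np.array([f"type_{i}" for i in range(n_ct)])
    ct = celltypes[rng.integers(0, n_ct, size=n)]
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    condition = np.where(rng.random(n) < 0.5, "drug", "control")

    genes = [f"ngene_{i}" for i in range(g)]
    mean = np.full((g, n), config.nb_mean)
    markers: dict[str, list[str]] = {}
    for i, t in enumerate(celltypes):
        rows = slice(i * mpc, (i + 1) * mpc)
        markers[t] = genes[i * mpc : (i + 1) * mpc]
        mean[rows, ct == t] *= config.marker_fold_change
    sex_rows = slice(n_ct * mpc, n_ct * mpc + config.sex_program_size)
    markers["sex_program"] = genes[sex_rows]
    mean[sex_rows, sex == "F"] *= config.sex_effect
    drug_lo = n_ct * mpc + config.sex_program_size
    drug_rows = slice(drug_lo, drug_lo + config.drug_program_size)
    markers["drug_program"] = genes[drug_rows]
    drug_types = {f"type_{i}" for i in config.drug_celltypes}
    in_drug = (condition == "drug") & np.isin(ct, list(drug_types))
    mean[drug_rows, in_drug] *= config.drug_effect

    counts = _nb_sample(rng, mean, config.nb_dispersion)
    import scipy.sparse as sp

    barcodes = [f"nucleus_{i}" for i in range(n)]
    labels = pd.DataFrame(
        {"cell_type": ct, "sex": sex, "condition": condition}, index=barcodes
    )
    return CountsMatrix(sp.csr_matrix(counts), genes, barcodes), labels, markers


def simulate_deconv_weights(
    spots: pd.DataFrame,
    ground_truth: GroundTruth,
    dirichlet_concentration: float = 50.0,
    celltypes: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet deconvolution weights centred on per-domain mixtures.

    Each domain gets a distinct dominant cell type; rows sum to one. The
    mixture table is stored on ``ground_truth.domain_celltype_mixtures``.
    """
    if ground_truth.spot_domain_labels is None:
        raise ConfigurationError("ground truth has no spot domain labels")
    rng = np.random.default_rng(seed + 4)
    labels = ground_truth.spot_domain_labels
    domains = sorted(labels.unique())
    if celltypes is None:
        celltypes = [f"type_{i}" for i in range(max(3, len(domains)))]
    k = len(celltypes)
    mixtures = np.full((len(domains), k), 1.0)
    for d in range(len(domains)):
        mixtures[d, d % k] = 4.0  # dominant type per domain
    mixtures /= mixtures.sum(axis=1, keepdims=True)
    ground_truth.domain_celltype_mixtures = pd.DataFrame(
        mixtures, index=domains, columns=celltypes
    )

    barcodes = spots["barcode"].tolist() if "barcode" in spots else list(map(str, spots.index))
    out = np.empty((len(barcodes), k))
    lab = labels.reindex(barcodes)
    if lab.isna().any():
        raise ConfigurationError("spots missing domain labels")
    for d, dom in enumerate(domains):
        idx = np.flatnonzero((lab == dom).to_numpy())
        if len(idx):
            out[idx] = rng.dirichlet(dirichlet_concentration * mixtures[d], size=len(idx))
    return pd.DataFrame(out, index=barcodes, columns=celltypes)


def simulate_factor_data(
    n_genes: int,
    n_obs: int,
    k: int,
    noise_sd: float = 0.0,
    sparsity: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted non-negative factor structure A = W H (+ truncated noise).

    W columns are sparse non-negative loadings scaled to sum to one; H is
    non-negative with blocks of dominant observations per factor so factors
    are identifiable. Returns (A, W, H).
    """
    rng = np.random.default_rng(seed + 5)
    W = rng.uniform(0, 1, size=(n_genes, k)) * (rng.random((n_genes, k)) > sparsity)
    W[rng.integers(0, n_genes, size=k), np.arange(k)] += 1.0  # no all-zero column
    W /= W.sum(axis=0, keepdims=True)
    H = rng.uniform(0, 0.2, size=(k, n_obs))
    block = n_obs // k
    for f in range(k):
        lo = f * block
        hi = (f + 1) * block if f < k - 1 else n_obs
        H[f, lo:hi] += rng.uniform(1.0, 2.0, size=hi - lo)
    A = W @ H
    if noise_sd > 0:
        A = np.maximum(A + rng.normal(0, noise_sd, A.shape), 0.0)
    return A, W, H


def simulate_lr_colocalization(
    n_spots: int,
    celltypes: list[str],
    colocalized_pair: tuple[str, str],
    coexpress_fraction: float = 0.3,
    concentration: float = 30.0,
    enrichment: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Deconvolution weights with a cell-type pair planted to co-occur
    in ligand-receptor co-expressing spots.

    Returns (weights spots x cell types, boolean co-expression mask). In
    co-expressing spots the Dirichlet centre up-weights both members of
    ``colocalized_pair`` by ``enrichment``; other spots use a flat centre.
    """
    rng = np.random.default_rng(seed + 6)
    k = len(celltypes)
    ia, ib = celltypes.index(colocalized_pair[0]), celltypes.index(colocalized_pair[1])
    coexpress = rng.random(n_spots) < coexpress_fraction
    base = np.ones(k)
    enriched = np.ones(k)
    enriched[[ia, ib]] = enrichment
    W = np.empty((n_spots, k))
    W[coexpress] = rng.dirichlet(concentration * enriched / enriched.sum(), size=int(coexpress.sum()))
    W[~coexpress] = rng.dirichlet(concentration * base / base.sum(), size=int((~coexpress).sum()))
    index = [f"spot_{i}" for i in range(n_spots)]
    return pd.DataFrame(W, index=index, columns=celltypes), coexpress
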