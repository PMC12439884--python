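"""Whole-section reconstruction from multiple capture areas.

Stages: refine the coarse (manually derived) affine alignment from landmark
pairs using a weighted-angle rotation estimate and mean-vector translation,
propagate pairwise refinements over a spanning tree of the overlap graph,
lay a donor-level artificial hexagonal grid over the stitched section,
remap spots to their nearest artificial spot, detect cross-area overlapping
spots, and flag the lower-depth side of each overlap for exclusion.

Axis convention: all geometry here works on (x, y) = (pxl_col_in_fullres,
pxl_row_in_fullres) points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import AffineTransform2D, NATIVE_ARRAY_COL_MAX, NATIVE_ARRAY_ROW_MAX
from .simulate import LandmarkPairs, ROW_SPACING_FACTOR

__all__ = [
    "RigidTransform",
    "ArtificialGrid",
    "OverlapAssignment",
    "estimate_rotation",
    "estimate_translation",
    "estimate_pairwise_rigid",
    "refine_alignment",
    "stitch_positions",
    "build_artificial_grid",
    "assign_to_grid",
    "detect_overlaps",
    "resolve_overlaps",
    "edge_distance",
]


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform:
    """Rotation by ``theta`` about ``center`` followed by ``translation``."""

    theta: float
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ _rotation_matrix(self.theta).T + self.center + self.translation

    def as_matrix(self) -> np.ndarray:
        """Equivalent 2x3 affine matrix."""
        R = _rotation_matrix(self.theta)
        t = self.center + self.translation - R @ self.center
        return np.column_stack([R, t])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        theta = math.atan2(matrix[1, 0], matrix[0, 0])
        return cls(theta=theta, translation=matrix[:, 2].copy())

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, np.zeros(2))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        a, b = self.as_matrix(), other.as_matrix()
        R = a[:, :2] @ b[:, :2]
        t = a[:, :2] @ b[:, 2] + a[:, 2]
        return RigidTransform.from_matrix(np.column_stack([R, t]))

    def inverse(self) -> "RigidTransform":
        m = self.as_matrix()
        Rinv = m[:, :2].T
        return RigidTransform.from_matrix(np.column_stack([Rinv, -Rinv @ m[:, 2]]))


@dataclass
class ArtificialGrid:
    """Donor-level hexagonal lattice replacing per-area array coordinates."""

    pitch: float
    origin: np.ndarray  # (x, y) of array (0, 0)
    rows: int
    cols: int  # number of half-step column indices

    def lattice(self) -> pd.DataFrame:
        """All lattice points with array indices and (x, y) centres."""
        r = np.repeat(np.arange(self.rows), self.cols)
        c = np.tile(np.arange(self.cols), self.rows)
        keep = (c % 2) == (r % 2)  # Visium parity
        r, c = r[keep], c[keep]
        x = self.origin[0] + c * (self.pitch / 2.0)
        y = self.origin[1] + r * (self.pitch * ROW_SPACING_FACTOR)
        return pd.DataFrame({"array_row": r, "array_col": c, "x": x, "y": y})


@dataclass
class OverlapAssignment:
    """Cross-area overlapping spot pairs and the spots flagged for exclusion."""

    pairs: list[tuple[str, str, float]]
    excluded_spot_ids: set[str]
    threshold: float


def estimate_rotation(landmarks: LandmarkPairs) -> float:
    """Rotation angle of area B's landmarks relative to area A's.

    For every unordered pair of landmarks the segment between them is formed
    in each area; the signed angle from the A-segment to the B-segment
    (atan2 of cross over dot) contributes to a weighted circular mean, with
    weight the geometric mean of the two segment lengths. The circular mean
    avoids +/- pi wraparound and reduces to the arithmetic mean for small
    angles.
    """
    a, b = np.asarray(landmarks.points_a, float), np.asarray(landmarks.points_b, float)
    if len(a) < 2:
        raise ValueError("need at least 2 landmark pairs to form a segment")
    angles, weights = [], []
    n_zero = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            va, vb = a[j] - a[i], b[j] - b[i]
            la, lb = np.linalg.norm(va), np.linalg.norm(vb)
            if la == 0 or lb == 0:
                n_zero += 1
                continue
            cross = va[0] * vb[1] - va[1] * vb[0]
            angles.append(math.atan2(cross, float(np.dot(va, vb))))
            weights.append(math.sqrt(la * lb))
    if n_zero:
        warnings.warn(f"skipped {n_zero} zero-length landmark segment pair(s)", stacklevel=2)
    if not angles:
        raise ValueError("all landmark segment pairs are zero-length")
    angles, weights = np.array(angles), np.array(weights)
    return float(math.atan2((weights * np.sin(angles)).sum(), (weights * np.cos(angles)).sum()))


def estimate_translation(landmarks: LandmarkPairs, theta: float) -> np.ndarray:
    """Mean A-minus-B displacement after de-rotating B about its centroid."""
    a, b = np.asarray(landmarks.points_a, float), np.asarray(landmarks.points_b, float)
    if len(a) == 0:
        raise ValueError("no landmark pairs")
    center_b = b.mean(axis=0)
    b_rot = (b - center_b) @ _rotation_matrix(-theta).T + center_b
    return (a - b_rot).mean(axis=0)


def estimate_pairwise_rigid(landmarks: LandmarkPairs) -> RigidTransform:
    """Rigid transform carrying area B's landmark frame onto area A's."""
    theta = estimate_rotation(landmarks)
    t = estimate_translation(landmarks, theta)
    center_b = np.asarray(landmarks.points_b, float).mean(axis=0)
    return RigidTransform(theta=-theta, translation=t, center=center_b)


def refine_alignment(
    areas: dict[str, pd.DataFrame],
    coarse: dict[str, AffineTransform2D],
    landmarks: list[LandmarkPairs],
) -> tuple[dict[str, RigidTransform], dict[tuple[str, str], float]]:
    """Refine the coarse alignment of every capture area from landmark pairs.

    Landmark coordinates are given in each area's native frame; they are
    pushed through the coarse transforms, a pairwise rigid refinement is
    estimated per overlapping pair, and refinements are propagated along a
    BFS spanning tree of the overlap graph with the first area (sorted by
    id) held fixed. Returns the per-area refinement (applied after the
    coarse transform) and the mean landmark residual per pair after
    refinement.
    """
    area_ids = sorted(areas)
    edges: dict[tuple[str, str], LandmarkPairs] = {}
    for lm in landmarks:
        edges[(lm.area_a, lm.area_b)] = lm

    adjacency: dict[str, list[str]] = {a: [] for a in area_ids}
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)

    # connectivity check, naming the components on failure
    seen: set[str] = set()
    components = []
    for start in area_ids:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            node = queue.pop()
            for nxt in adjacency[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        components.append(sorted(comp))
    if len(components) > 1:
        raise ValueError(f"overlap graph is disconnected: components {components}")

    def coarse_landmarks(pair: LandmarkPairs) -> LandmarkPairs:
        return LandmarkPairs(
            pair.area_a,
            pair.area_b,
            coarse[pair.area_a].apply(pair.points_a),
            coarse[pair.area_b].apply(pair.points_b),
        )

    refinements: dict[str, RigidTransform] = {area_ids[0]: RigidTransform.identity()}
    queue = [area_ids[0]]
    while queue:
        parent = queue.pop(0)
        for child in adjacency[parent]:
            if child in refinements:
                continue
            if (parent, child) in edges:
                lm = coarse_landmarks(edges[(parent, child)])
            else:
                rev = edges[(child, parent)]
                lm = coarse_landmarks(
                    LandmarkPairs(parent, child, rev.points_b, rev.points_a)
                )
            delta = estimate_pairwise_rigid(lm)  # child coarse frame -> parent coarse frame
            refinements[child] = refinements[parent].compose(delta)
            queue.append(child)

    residuals: dict[tuple[str, str], float] = {}
    for (a, b), lm in edges.items():
        clm = coarse_landmarks(lm)
        pa = refinements[a].apply(clm.points_a)
        pb = refinements[b].apply(clm.points_b)
        residuals[(a, b)] = float(np.linalg.norm(pa - pb, axis=1).mean())
    return refinements, residuals


def stitch_positions(
    areas: dict[str, pd.DataFrame],
    coarse: dict[str, AffineTransform2D],
    refinements: dict[str, RigidTransform],
) -> pd.DataFrame:
    """Concatenate all areas with stitched pixel coordinates.

    Native columns are preserved with an ``_original`` suffix; stitched
    coordinates replace ``pxl_row_in_fullres`` / ``pxl_col_in_fullres``.
    """
    frames = []
    for area in sorted(areas):
        df = areas[area].copy()
        pts = df[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(dtype=float)
        stitched = refinements[area].apply(coarse[area].apply(pts))
        df["pxl_col_in_fullres_original"] = df["pxl_col_in_fullres"]
        df["pxl_row_in_fullres_original"] = df["pxl_row_in_fullres"]
        df["array_row_original"] = df["array_row"]
        df["array_col_original"] = df["array_col"]
        df["pxl_col_in_fullres"] = stitched[:, 0]
        df["pxl_row_in_fullres"] = stitched[:, 1]
        df["capture_area"] = area
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def native_median_nn_distance(points: np.ndarray) -> float:
    """Median nearest-neighbour distance of a point set."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))


def build_artificial_grid(stitched: pd.DataFrame, pitch_px: float | None = None) -> ArtificialGrid:
    """Hexagonal lattice covering the bounding box of the stitched spots.

    ``pitch_px`` defaults to the median nearest-neighbour spacing of the
    first listed capture area, realizing the 100 um physical pitch in pixel
    units. The origin anchors the minimum pixel coordinates at array index
    zero; rows and columns extend as far as needed to cover every spot.
    """
    pts = stitched[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(dtype=float)
    if pitch_px is None:
        first = sorted(stitched["capture_area"].unique())[0]
        sel = stitched["capture_area"] == first
        pitch_px = native_median_nn_distance(pts[sel.to_numpy()])
    if pitch_px <= 0:
        raise ValueError("pitch must be positive")
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    rows = int(math.floor((y_max - y_min) / (pitch_px * ROW_SPACING_FACTOR))) + 2
    cols = int(math.floor((x_max - x_min) / (pitch_px / 2.0))) + 2
    return ArtificialGrid(pitch=pitch_px, origin=np.array([x_min, y_min]), rows=rows, cols=cols)


def assign_to_grid(stitched: pd.DataFrame, grid: ArtificialGrid) -> pd.DataFrame:
    """Map each spot to its nearest artificial spot by Euclidean distance.

    Redefines ``array_row`` / ``array_col`` from the grid; exact distance
    ties are broken toward the lexicographically smallest (row, col).
    Multiple spots may share coordinates in overlap regions.
    """
    lattice = grid.lattice().sort_values(["array_row", "array_col"]).reset_index(drop=True)
    tree = cKDTree(lattice[["x", "y"]].to_numpy())
    pts = stitched[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(dtype=float)
    k = min(4, len(lattice))
    dist, idx = tree.query(pts, k=k)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    chosen = np.empty(len(pts), dtype=int)
    for i in range(len(pts)):
        tied = idx[i][dist[i] <= dist[i, 0] + 1e-9]
        rows_cols = lattice.iloc[tied][["array_row", "array_col"]].to_numpy()
        best = tied[np.lexsort((rows_cols[:, 1], rows_cols[:, 0]))[0]]
        chosen[i] = best
    out = stitched.copy()
    out["array_row"] = lattice["array_row"].to_numpy()[chosen]
    out["array_col"] = lattice["array_col"].to_numpy()[chosen]
    out["grid_distance"] = np.linalg.norm(
        pts - lattice[["x", "y"]].to_numpy()[chosen], axis=1
    )
    return out


def detect_overlaps(stitched: pd.DataFrame) -> OverlapAssignment:
    """Find cross-area spots mapping to the same tissue position.

    The threshold is 1.5x the median nearest-neighbour distance of the
    first listed capture area's spots (its native spacing, preserved by the
    rigid stitch). Each spot is paired with its nearest spot from a
    different capture area when that distance falls within the threshold.
    """
    area_ids = sorted(stitched["capture_area"].unique())
    pts = stitched[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(dtype=float)
    if len(area_ids) < 2:
        return OverlapAssignment(pairs=[], excluded_spot_ids=set(), threshold=float("nan"))
    first_sel = (stitched["capture_area"] == area_ids[0]).to_numpy()
    threshold = 1.5 * native_median_nn_distance(pts[first_sel])

    barcodes = stitched["barcode"].to_numpy()
    area = stitched["capture_area"].to_numpy()
    pairs: dict[tuple[str, str], float] = {}
    for a in area_ids:
        sel = area == a
        other = ~sel
        if not other.any():
            continue
        tree = cKDTree(pts[other])
        d, j = tree.query(pts[sel], k=1)
        other_idx = np.flatnonzero(other)
        for bc, dd, jj in zip(barcodes[sel], d, j):
            if dd <= threshold:
                mate = barcodes[other_idx[jj]]
                key = (bc, mate) if bc < mate else (mate, bc)
                pairs.setdefault(key, float(dd))
    pair_list = [(a, b, d) for (a, b), d in sorted(pairs.items())]
    return OverlapAssignment(pairs=pair_list, excluded_spot_ids=set(), threshold=threshold)


def resolve_overlaps(
    assignment: OverlapAssignment,
    umi_per_spot: pd.Series,
    area_of_spot: pd.Series,
    area_order: list[str],
) -> OverlapAssignment:
    """Flag the lower-depth side of every overlapping area pair.

    For each pair of overlapping capture areas, the side whose overlapping
    spots have the lower minimum UMI count has all its overlapping spots
    flagged for exclusion; on ties the later-listed area is flagged.
    """
    by_area_pair: dict[tuple[str, str], dict[str, set[str]]] = {}
    for a, b, _ in assignment.pairs:
        aa, ab = area_of_spot[a], area_of_spot[b]
        if aa == ab:
            continue
        key = tuple(sorted((aa, ab)))
        bucket = by_area_pair.setdefault(key, {key[0]: set(), key[1]: set()})
        bucket[aa].add(a)
        bucket[ab].add(b)

    excluded: set[str] = set()
    order = {a: i for i, a in enumerate(area_order)}
    for (x, y), spots in by_area_pair.items():
        min_x = min(umi_per_spot[s] for s in spots[x])
        min_y = min(umi_per_spot[s] for s in spots[y])
        if min_x < min_y:
            loser = x
        elif min_y < min_x:
            loser = y
        else:
            loser = x if order[x] > order[y] else y  # tie: later-listed area
        excluded |= spots[loser]
    return OverlapAssignment(
        pairs=assignment.pairs, excluded_spot_ids=excluded, threshold=assignment.threshold
    )


def edge_distance(
    positions: pd.DataFrame,
    row_max: int = NATIVE_ARRAY_ROW_MAX,
    col_max: int = NATIVE_ARRAY_COL_MAX,
    row_col_columns: tuple[str, str] = ("array_row", "array_col"),
) -> pd.Series:
    """Distance (in array units) from each spot's native array coordinates
    to the capture-area boundary rectangle [0, row_max] x [0, col_max]."""
    rcol, ccol = row_col_columns
    if rcol not in positions or ccol not in positions:
        raise ValueError(f"missing native array coordinate columns {row_col_columns}")
    r = positions[rcol].to_numpy(dtype=float)
    c = positions[ccol].to_numpy(dtype=float)
    dist = np.minimum.reduce([r, row_max - r, c, col_max - c])
    return pd.Series(dist, index=positions.index, name="edge_distance")
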