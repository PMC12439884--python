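import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from spotmosaic.io import AffineTransform2D
from spotmosaic.simulate import LandmarkPairs, SimulationConfig, hex_lattice, simulate_capture_areas
from spotmosaic.stitch import (
    ArtificialGrid,
    RigidTransform,
    assign_to_grid,
    build_artificial_grid,
    detect_overlaps,
    edge_distance,
    estimate_pairwise_rigid,
    estimate_rotation,
    estimate_translation,
    refine_alignment,
    resolve_overlaps,
    stitch_positions,
)


def rot(points, theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.asarray(points, float) @ np.array([[c, -s], [s, c]]).T


def kabsch_rigid(a, b):
    """Least-squares rigid (theta, canonical R, t) mapping b onto a."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb).T @ (a - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = ca - R @ cb
    return np.arctan2(R[1, 0], R[0, 0]), R, t


@pytest.fixture
def square_landmarks():
    a = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0], [30.0, 60.0]])
    return a


class TestRotationEstimate:
    def test_pure_rotation_exact(self, square_landmarks):
        theta = np.deg2rad(30)
        b = rot(square_landmarks, theta)
        lm = LandmarkPairs("A", "B", square_landmarks, b)
        assert estimate_rotation(lm) == pytest.approx(theta, abs=1e-12)

    def test_identity_is_zero(self, square_landmarks):
        lm = LandmarkPairs("A", "B", square_landmarks, square_landmarks.copy())
        assert estimate_rotation(lm) == pytest.approx(0.0, abs=1e-12)

    def test_large_angle_no_wraparound(self, square_landmarks):
        theta = np.deg2rad(170)
        b = rot(square_landmarks, theta)
        lm = LandmarkPairs("A", "B", square_landmarks, b)
        assert estimate_rotation(lm) == pytest.approx(theta, abs=1e-9)

    def test_noisy_close_to_least_squares_oracle(self, square_landmarks):
        rng = np.random.default_rng(0)
        theta = np.deg2rad(12)
        b = rot(square_landmarks, theta) + rng.normal(0, 2.0, square_landmarks.shape)
        lm = LandmarkPairs("A", "B", square_landmarks, b)
        est = estimate_rotation(lm)
        oracle_theta, _, _ = kabsch_rigid(b, square_landmarks)  # b = R(a)
        assert abs(est - oracle_theta) < np.deg2rad(1.0)

    def test_zero_length_segments(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="zero-length"):
            estimate_rotation(LandmarkPairs("A", "B", pts, pts))


class TestTranslationEstimate:
    def test_pure_translation(self, square_landmarks):
        b = square_landmarks + np.array([5.0, -2.0])
        lm = LandmarkPairs("A", "B", square_landmarks, b)
        np.testing.assert_allclose(estimate_translation(lm, 0.0), [-5.0, 2.0])

    def test_identity(self, square_landmarks):
        lm = LandmarkPairs("A", "B", square_landmarks, square_landmarks.copy())
        np.testing.assert_allclose(estimate_translation(lm, 0.0), [0.0, 0.0])

    def test_rotate_then_translate_recovered(self, square_landmarks):
        theta = np.deg2rad(25)
        b = rot(square_landmarks, theta) + np.array([40.0, -70.0])
        lm = LandmarkPairs("A", "B", square_landmarks, b)
        tf = estimate_pairwise_rigid(lm)
        np.testing.assert_allclose(tf.apply(b), square_landmarks, atol=1e-9)


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        tf = RigidTransform(theta=0.4, translation=[12.0, -3.0], center=[50.0, 50.0])
        pts = np.random.default_rng(1).uniform(-100, 100, (20, 2))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-9)

    def test_compose_matches_sequential_application(self):
        t1 = RigidTransform(0.3, [5.0, 1.0], [10.0, 0.0])
        t2 = RigidTransform(-0.7, [-2.0, 8.0], [0.0, 4.0])
        pts = np.random.default_rng(2).uniform(-50, 50, (10, 2))
        np.testing.assert_allclose(
            t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-9
        )


class TestRefineAlignment:
    def test_two_areas_exact_recovery(self):
        cfg = SimulationConfig(
            seed=0, n_capture_areas=2, grid_rows=15, grid_cols=15, overlap_fraction=0.25,
            true_transforms=[(0.0, (0.0, 0.0)), (0.3, (120.0, -60.0))],
        )
        areas, landmarks, _ = simulate_capture_areas(cfg)
        coarse = {a: AffineTransform2D.identity() for a in areas}
        refinements, residuals = refine_alignment(areas, coarse, landmarks)
        assert residuals[("A1", "A2")] < 1e-6
        stitched = stitch_positions(areas, coarse, refinements)
        err = np.hypot(
            stitched.pxl_col_in_fullres - stitched.global_x,
            stitched.pxl_row_in_fullres - stitched.global_y,
        )
        assert err.max() < 1e-6

    def test_three_area_chain_composition(self):
        cfg = SimulationConfig(
            seed=1, n_capture_areas=3, grid_rows=15, grid_cols=15, overlap_fraction=0.25,
            true_transforms=[(0.0, (0.0, 0.0)), (0.2, (150.0, -80.0)), (-0.15, (300.0, 40.0))],
        )
        areas, landmarks, gt = simulate_capture_areas(cfg)
        coarse = {a: AffineTransform2D.identity() for a in areas}
        refinements, _ = refine_alignment(areas, coarse, landmarks)
        # the composed transform for A3 must reproduce its planted placement
        theta, (tx, ty) = gt.true_transforms["A3"]
        native = areas["A3"][["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
        expected = rot(native, theta) + np.array([tx, ty])
        np.testing.assert_allclose(refinements["A3"].apply(native), expected, atol=1e-6)

    def test_noisy_refinement_beats_coarse(self):
        cfg = SimulationConfig(
            seed=2, n_capture_areas=2, grid_rows=15, grid_cols=15, overlap_fraction=0.25,
            landmark_noise_sd=2.0, n_landmarks_per_overlap=8,
            true_transforms=[(0.0, (0.0, 0.0)), (0.1, (40.0, 20.0))],
        )
        areas, landmarks, _ = simulate_capture_areas(cfg)
        coarse = {a: AffineTransform2D.identity() for a in areas}
        refinements, residuals = refine_alignment(areas, coarse, landmarks)
        lm = landmarks[0]
        coarse_resid = np.linalg.norm(lm.points_a - lm.points_b, axis=1).mean()
        assert residuals[("A1", "A2")] <= coarse_resid

    def test_disconnected_graph_names_components(self):
        cfg = SimulationConfig(seed=3, n_capture_areas=3, grid_rows=10, grid_cols=10)
        areas, landmarks, _ = simulate_capture_areas(cfg)
        coarse = {a: AffineTransform2D.identity() for a in areas}
        with pytest.raises(ValueError, match="A3"):
            refine_alignment(areas, coarse, landmarks[:1])


class TestArtificialGrid:
    def test_coverage_arithmetic(self):
        spots = pd.DataFrame(
            {
                "barcode": [f"s{i}" for i in range(2)],
                "pxl_col_in_fullres": [0.0, 1000.0],
                "pxl_row_in_fullres": [0.0, 0.0],
                "capture_area": "A1",
            }
        )
        grid = build_artificial_grid(spots, pitch_px=100.0)
        lat = grid.lattice()
        assert lat.array_col.nunique() >= 11

    def test_lattice_min_distance_is_pitch(self):
        grid = ArtificialGrid(pitch=100.0, origin=np.zeros(2), rows=12, cols=24)
        pts = grid.lattice()[["x", "y"]].to_numpy()
        d, _ = cKDTree(pts).query(pts, k=2)
        np.testing.assert_allclose(d[:, 1], 100.0, rtol=1e-6)

    def test_single_spot(self):
        spots = pd.DataFrame(
            {"barcode": ["s0"], "pxl_col_in_fullres": [55.0],
             "pxl_row_in_fullres": [70.0], "capture_area": "A1"}
        )
        grid = build_artificial_grid(spots, pitch_px=100.0)
        assert len(grid.lattice()) >= 1

    def test_nonpositive_pitch_rejected(self):
        spots = pd.DataFrame(
            {"barcode": ["s0"], "pxl_col_in_fullres": [0.0],
             "pxl_row_in_fullres": [0.0], "capture_area": "A1"}
        )
        with pytest.raises(ValueError):
            build_artificial_grid(spots, pitch_px=0.0)


class TestAssignToGrid:
    def _spots(self, xs, ys):
        return pd.DataFrame(
            {
                "barcode": [f"s{i}" for i in range(len(xs))],
                "pxl_col_in_fullres": xs,
                "pxl_row_in_fullres": ys,
                "capture_area": "A1",
            }
        )

    def test_nearest_assignment(self):
        grid = ArtificialGrid(pitch=100.0, origin=np.zeros(2), rows=3, cols=6)
        out = assign_to_grid(self._spots([60.0], [0.0]), grid)
        assert out.loc[0, "array_col"] == 2  # lattice x=100 is index 2 (half steps)

    def test_midpoint_tie_lexicographic(self):
        grid = ArtificialGrid(pitch=100.0, origin=np.zeros(2), rows=3, cols=6)
        out = assign_to_grid(self._spots([50.0], [0.0]), grid)
        assert (out.loc[0, "array_row"], out.loc[0, "array_col"]) == (0, 0)

    def test_idempotent_on_lattice_points(self):
        grid = ArtificialGrid(pitch=100.0, origin=np.zeros(2), rows=5, cols=10)
        lat = grid.lattice()
        spots = self._spots(lat.x.tolist(), lat.y.tolist())
        out = assign_to_grid(spots, grid)
        np.testing.assert_array_equal(out.array_row, lat.array_row)
        np.testing.assert_array_equal(out.array_col, lat.array_col)
        assert out.grid_distance.max() < 1e-9
        again = assign_to_grid(out, grid)
        np.testing.assert_array_equal(again.array_row, out.array_row)


def _two_grid_frame(offset):
    a = hex_lattice(8, 8, 100.0)
    frames = []
    for area, (dx, dy) in (("A1", (0.0, 0.0)), ("A2", offset)):
        df = pd.DataFrame(
            {
                "barcode": [f"{area}_s{i}" for i in range(len(a))],
                "pxl_col_in_fullres": a.x + dx,
                "pxl_row_in_fullres": a.y + dy,
                "capture_area": area,
            }
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestDetectOverlaps:
    def test_threshold_is_1p5_native_nn(self):
        st = _two_grid_frame((10.0, 0.0))
        ov = detect_overlaps(st)
        assert ov.threshold == pytest.approx(150.0)

    def test_identical_grids_offset_pair_one_to_one(self):
        st = _two_grid_frame((10.0, 0.0))
        ov = detect_overlaps(st)
        # brute-force: every spot's nearest cross-area spot is its shifted twin
        assert len(ov.pairs) == 64
        counts = {}
        for a, b, d in ov.pairs:
            assert d == pytest.approx(10.0)
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        assert all(v == 1 for v in counts.values())

    def test_beyond_threshold_not_overlapping(self):
        st = _two_grid_frame((2000.0, 0.0))
        ov = detect_overlaps(st)
        assert ov.pairs == []

    def test_single_area_empty(self):
        st = _two_grid_frame((10.0, 0.0))
        ov = detect_overlaps(st[st.capture_area == "A1"])
        assert ov.pairs == [] and ov.excluded_spot_ids == set()

    def test_invariant_to_global_rigid_motion(self):
        st = _two_grid_frame((10.0, 5.0))
        moved = st.copy()
        pts = moved[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy()
        moved[["pxl_col_in_fullres", "pxl_row_in_fullres"]] = rot(pts, 0.7) + np.array([300.0, -50.0])
        p1 = {(a, b) for a, b, _ in detect_overlaps(st).pairs}
        p2 = {(a, b) for a, b, _ in detect_overlaps(moved).pairs}
        assert p1 == p2


class TestResolveOverlaps:
    def _assignment(self):
        st = _two_grid_frame((10.0, 0.0))
        return detect_overlaps(st), st

    def test_lower_minimum_side_flagged(self):
        ov, st = self._assignment()
        umi = pd.Series(600, index=st.barcode)
        umi[st.barcode[st.capture_area == "A1"].iloc[0]] = 500  # A1 min 500 < A2 min 600
        resolved = resolve_overlaps(
            ov, umi, st.set_index("barcode").capture_area, ["A1", "A2"]
        )
        assert all(b.startswith("A1") for b in resolved.excluded_spot_ids)
        assert len(resolved.excluded_spot_ids) == 64

    def test_tie_flags_later_listed(self):
        ov, st = self._assignment()
        umi = pd.Series(600, index=st.barcode)
        resolved = resolve_overlaps(
            ov, umi, st.set_index("barcode").capture_area, ["A1", "A2"]
        )
        assert all(b.startswith("A2") for b in resolved.excluded_spot_ids)

    def test_no_overlaps_no_flags(self):
        st = _two_grid_frame((2000.0, 0.0))
        ov = detect_overlaps(st)
        umi = pd.Series(600, index=st.barcode)
        resolved = resolve_overlaps(
            ov, umi, st.set_index("barcode").capture_area, ["A1", "A2"]
        )
        assert resolved.excluded_spot_ids == set()


class TestEdgeDistance:
    @pytest.mark.parametrize(
        "row,col,expected",
        [(0, 5, 0.0), (5, 64, 5.0), (39, 64, 38.0), (77, 127, 0.0)],
    )
    def test_distance_to_boundary(self, row, col, expected):
        df = pd.DataFrame({"array_row": [row], "array_col": [col]})
        assert edge_distance(df).iloc[0] == expected

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="array coordinate"):
            edge_distance(pd.DataFrame({"x": [1]}))
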