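"""Feature battery oracles: closed forms, hand computations, invariances."""

import numpy as np
import pytest

from swarmflight import features as F
from swarmflight.segmentation import Segment

from conftest import circle_segment, make_segment


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


class TestKinematics:
    def test_uniform_motion(self):
        t = np.arange(20) * 0.04
        seg = make_segment(np.column_stack([2 * t, np.zeros(20), np.zeros(20)]), t)
        k = F.kinematics(seg)
        np.testing.assert_allclose(k["vx"], 2.0, atol=1e-10)
        np.testing.assert_allclose(k["speed"], 2.0, atol=1e-10)
        for name in ("ax", "ay", "az", "jx", "jy", "jz", "radial_accel", "radial_jerk"):
            np.testing.assert_allclose(k[name], 0.0, atol=1e-8)

    def test_free_fall_acceleration(self):
        t = np.arange(30) * 0.04
        z = -4.905 * t**2
        seg = make_segment(np.column_stack([np.zeros(30), np.zeros(30), z]), t)
        k = F.kinematics(seg)
        # quadratic position is exact under second-order differences
        np.testing.assert_allclose(k["az"], -9.81, atol=1e-8)

    def test_circle_speed_and_radial_accel(self):
        r, omega = 0.5, 2.5
        seg = circle_segment(radius=r, omega=omega, n=41)
        k = F.kinematics(seg)
        # |v| = omega * r, constant; its time derivative vanishes
        interior = slice(2, -2)
        np.testing.assert_allclose(
            k["speed"][interior], omega * r, rtol=2e-3
        )
        np.testing.assert_allclose(k["radial_accel"][interior], 0.0, atol=0.02)

    def test_too_short_segment_raises(self):
        seg = make_segment(np.zeros((4, 3)) + np.arange(4)[:, None])
        with pytest.raises(F.DegenerateSegmentError):
            F.kinematics(seg)


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------


class TestAngleOfFlight:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (1, 0, 0), (2, 0, 0)], 0.0),  # collinear forward
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0)], np.pi / 2),  # right angle
            ([(0, 0, 0), (1, 0, 0), (0, 0, 0)], np.pi),  # exact reversal
        ],
    )
    def test_canonical_turns(self, points, expected):
        seg = make_segment(np.array(points, dtype=float))
        angles = F.angle_of_flight(seg)
        assert angles == pytest.approx([expected], abs=1e-12)

    def test_stationary_step_dropped_not_raised(self):
        pts = np.array([(0, 0, 0), (1, 0, 0), (1, 0, 0), (2, 0, 0)], dtype=float)
        angles = F.angle_of_flight(make_segment(pts))
        # both junctions touch the zero-length step and are dropped
        assert len(angles) == 0

    def test_angles_in_range(self):
        rng = np.random.default_rng(0)
        seg = make_segment(rng.normal(size=(30, 3)))
        angles = F.angle_of_flight(seg)
        assert np.all((angles >= 0) & (angles <= np.pi))


class TestAngularRates:
    def test_circle_angular_velocity(self):
        seg = circle_segment(radius=0.5, omega=2.5, n=41)
        rates = F.angular_rates(seg)
        np.testing.assert_allclose(rates["angvel_XY"], 2.5, rtol=1e-3)
        np.testing.assert_allclose(rates["angvel_3D"], 2.5, rtol=1e-3)
        np.testing.assert_allclose(rates["angacc_XY"], 0.0, atol=1e-6)

    def test_straight_line_all_variants_zero(self):
        t = np.arange(20) * 0.04
        seg = make_segment(np.column_stack([t, 2 * t, 3 * t]), t)
        rates = F.angular_rates(seg)
        for tag in ("XY", "YZ", "XZ", "3D"):
            np.testing.assert_allclose(rates[f"angvel_{tag}"], 0.0, atol=1e-6)

    def test_planar_motion_degenerate_projections(self):
        # motion confined to XY: the YZ and XZ projections still yield
        # well-defined 1D angles (0 or pi) for non-stationary steps
        pts = np.array(
            [(0, 0, 1), (1, 1, 1), (2, 0, 1), (3, 1, 1), (4, 0, 1)], dtype=float
        )
        rates = F.angular_rates(make_segment(pts))
        assert np.all(np.isfinite(rates["angvel_YZ"]))
        # junction time span is 0.04 s at 25 Hz, so a reversal gives pi/0.04
        assert np.all(
            (np.abs(rates["angvel_YZ"]) < 1e-9)
            | (np.abs(rates["angvel_YZ"] * 0.04 - np.pi) < 1e-9)
        )


# ---------------------------------------------------------------------------
# orthogonal velocity components
# ---------------------------------------------------------------------------


def brute_force_orthogonal(pos, t):
    """Step-by-step spherical decomposition, scalar arithmetic only."""
    import math

    d = np.diff(pos, axis=0)
    P, T, I = [], [], []
    rho = [math.sqrt(dx * dx + dy * dy + dz * dz) for dx, dy, dz in d]
    theta = [math.atan2(dy, dx) for dx, dy, dz in d]
    phi = [
        math.acos(max(-1, min(1, dz / r))) if r > 0 else float("nan")
        for (dx, dy, dz), r in zip(d, rho)
    ]
    for i in range(len(d) - 1):
        if rho[i] == 0 or rho[i + 1] == 0:
            continue
        Th = theta[i + 1] - theta[i]
        Ph = phi[i + 1] - phi[i]
        v = rho[i] / (t[i + 1] - t[i])
        P.append(v * math.sin(Ph) * math.cos(Th))
        T.append(v * math.sin(Ph) * math.sin(Th))
        I.append(v * math.cos(Ph))
    return np.array(P), np.array(T), np.array(I)


class TestOrthogonalVelocities:
    def test_straight_line_is_pure_inclination(self):
        t = np.arange(10) * 0.04
        seg = make_segment(np.column_stack([t, np.zeros(10), np.zeros(10)]), t)
        comp = F.orthogonal_velocities(seg)
        np.testing.assert_allclose(comp["persistence"], 0.0, atol=1e-12)
        np.testing.assert_allclose(comp["turning"], 0.0, atol=1e-12)
        np.testing.assert_allclose(comp["inclination"], comp["v"], atol=1e-12)

    def test_energy_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seg = make_segment(rng.normal(size=(25, 3)))
            comp = F.orthogonal_velocities(seg)
            lhs = comp["persistence"] ** 2 + comp["turning"] ** 2 + comp["inclination"] ** 2
            np.testing.assert_allclose(lhs, comp["v"] ** 2, rtol=1e-12)

    def test_matches_brute_force_random_walk(self):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.normal(size=(15, 3)), axis=0)
        t = np.arange(15) * 0.04
        seg = make_segment(pos, t)
        comp = F.orthogonal_velocities(seg)
        P, T, I = brute_force_orthogonal(pos, t)
        np.testing.assert_allclose(comp["persistence"], P, rtol=1e-10)
        np.testing.assert_allclose(comp["turning"], T, rtol=1e-10)
        np.testing.assert_allclose(comp["inclination"], I, rtol=1e-10)


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------


class TestStraightness:
    def test_collinear_monotone_is_one(self):
        n = 50
        x = np.arange(n) * 0.25  # dyadic step: sums are exact
        seg = make_segment(np.column_stack([x, np.zeros(n), np.zeros(n)]))
        assert F.straightness(seg) == 1.0

    def test_semicircle_approaches_half_pi(self):
        theta = np.linspace(0, np.pi, 500)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(500)])
        assert F.straightness(make_segment(pts)) == pytest.approx(np.pi / 2, rel=1e-4)

    def test_out_and_back(self):
        pts = np.array([(0, 0, 0), (1, 0, 0), (0.5, 0, 0)], dtype=float)
        assert F.straightness(make_segment(pts)) == pytest.approx(3.0)

    def test_closed_loop_degenerate(self):
        theta = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(8)])
        pts = np.vstack([pts, pts[0]])
        assert np.isnan(F.straightness(make_segment(pts)))


class TestConvexHull:
    def test_unit_cube(self):
        corners = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
        )
        vol, area = F.convex_hull_metrics(make_segment(corners))
        assert vol == pytest.approx(1.0)
        assert area == pytest.approx(6.0)

    def test_regular_tetrahedron(self):
        # edge length 1
        pts = np.array(
            [
                (0, 0, 0),
                (1, 0, 0),
                (0.5, np.sqrt(3) / 2, 0),
                (0.5, np.sqrt(3) / 6, np.sqrt(6) / 3),
            ]
        )
        vol, area = F.convex_hull_metrics(make_segment(pts))
        assert vol == pytest.approx(1 / (6 * np.sqrt(2)), rel=1e-10)
        assert area == pytest.approx(np.sqrt(3), rel=1e-10)

    def test_coplanar_square_counts_both_faces(self):
        pts = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], dtype=float)
        vol, area = F.convex_hull_metrics(make_segment(pts))
        assert vol == 0.0
        assert area == pytest.approx(2.0)

    def test_identical_points_degenerate(self):
        pts = np.ones((5, 3))
        vol, area = F.convex_hull_metrics(make_segment(pts))
        assert np.isnan(vol) and np.isnan(area)


class TestCentroidDistance:
    def test_full_circle_is_constant_radius(self):
        theta = np.linspace(0, 2 * np.pi, 101)[:-1]  # uniform, no duplicate
        r = 0.7
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(100)])
        c = F.centroid_distance(make_segment(pts))
        np.testing.assert_allclose(c, r, rtol=1e-10)

    def test_two_points(self):
        pts = np.array([(0, 0, 0), (2, 0, 0)], dtype=float)
        np.testing.assert_allclose(
            F.centroid_distance(make_segment(pts)), [1.0, 1.0]
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        expected = [
            float(np.sqrt(np.sum((p - pts.mean(axis=0)) ** 2))) for p in pts
        ]
        np.testing.assert_allclose(
            F.centroid_distance(make_segment(pts)), expected, rtol=1e-12
        )


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        r = 0.5
        seg = circle_segment(radius=r, omega=2.5, n=101)
        out = F.curvature(seg)
        assert abs(out["curv_XY_mean"]) == pytest.approx(1 / r, rel=0.02)
        assert out["curv_XY_std"] == pytest.approx(0.0, abs=0.05)

    def test_straight_line_zero_everywhere(self):
        t = np.arange(20) * 0.04
        seg = make_segment(np.column_stack([t, 2 * t, -t]), t)
        out = F.curvature(seg)
        for tag in ("XY", "YZ", "XZ"):
            assert out[f"curv_{tag}_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_parabola_apex(self):
        x = np.linspace(-0.2, 0.2, 81)
        seg = make_segment(np.column_stack([x, x**2, np.zeros_like(x)]))
        t = seg.times
        # recompute the series directly to inspect the apex value
        dt = np.diff(t)
        dx = np.diff(x) / dt
        dy = np.diff(x**2) / dt
        ddx = np.diff(dx) / dt[:-1]
        ddy = np.diff(dy) / dt[:-1]
        k = (dx[:-1] * ddy - dy[:-1] * ddx) / (dx[:-1] ** 2 + dy[:-1] ** 2) ** 1.5
        apex = k[np.argmin(np.abs(x[:-2]))]
        assert apex == pytest.approx(2.0, rel=0.05)
        out = F.curvature(seg)
        assert out["curv_XY_mean"] > 0


class TestFractalDimension:
    def test_straight_path_is_exactly_one(self):
        x = np.linspace(0.0, 2.0, 100)
        seg = make_segment(np.column_stack([x, np.zeros(100), np.zeros(100)]))
        assert F.fractal_dimension(seg) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_case(self):
        # path of length 8 with bounding-box diagonal 2 -> log8/log2 = 3
        pts = np.array(
            [(0, 0, 0), (2, 0, 0), (0, 0, 0), (2, 0, 0), (0, 0, 0)], dtype=float
        )
        assert F.fractal_dimension(make_segment(pts)) == pytest.approx(3.0)

    def test_unit_diagonal_is_degenerate(self):
        pts = np.array([(0, 0, 0), (1, 0, 0), (0, 0, 0)], dtype=float)
        assert np.isnan(F.fractal_dimension(make_segment(pts)))

    def test_planar_random_walk_near_two(self):
        rng = np.random.default_rng(11)
        ang = rng.uniform(0, 2 * np.pi, 20000)
        steps = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(20000)])
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        seg = make_segment(pos, np.arange(len(pos)) * 0.04)
        assert F.fractal_dimension(seg) == pytest.approx(2.0, abs=0.3)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


class TestSummarise:
    def test_linear_series_hand_values(self):
        s = F.summarise(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert s["mean"] == 3.0
        assert s["median"] == 3.0
        assert s["q1"] == 2.0
        assert s["q3"] == 4.0
        assert s["n_extrema"] == 0
        assert s["n_zero_cross"] == 0
        assert s["std"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def test_alternating_series_zero_crossings(self):
        assert F.summarise(np.array([1.0, -1.0, 1.0, -1.0]))["n_zero_cross"] == 3

    def test_extrema_count_strict_sign_changes(self):
        # 2 maxima + 1 minimum -> 3 sign changes of the first difference
        assert F.summarise(np.array([0.0, 1.0, 0.0, 1.0, 0.0]))["n_extrema"] == 3

    def test_constant_series_convention(self):
        s = F.summarise(np.full(10, 7.0))
        assert s["kurtosis"] == 0.0
        assert s["skewness"] == 0.0
        assert s["std"] == 0.0

    def test_moments_match_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        v = rng.normal(size=200)
        s = F.summarise(v)
        assert s["kurtosis"] == pytest.approx(stats.kurtosis(v, bias=True))
        assert s["skewness"] == pytest.approx(stats.skew(v, bias=True))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class TestExtractFeatures:
    def test_schema_size_and_order(self):
        schema = F.feature_schema()
        assert len(schema) == 25 * 9 + 12  # 25 series x 9 stats + 12 scalars
        assert len(set(schema)) == len(schema)

    def test_straight_line_consistency(self):
        # oblique line so every planar projection moves
        t = np.arange(41) * 0.04
        seg = make_segment(np.column_stack([2 + t, 1 + 2 * t, 3 * t]), t)
        out = F.extract_features(seg)
        assert out["straightness"] == pytest.approx(1.0, rel=1e-12)
        assert out["fractal_d"] == pytest.approx(1.0, abs=1e-9)
        for tag in ("XY", "YZ", "XZ"):
            assert out[f"curv_{tag}_mean"] == pytest.approx(0.0, abs=1e-9)
        assert out["css_mean"] == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(scale=0.05, size=(41, 3)), axis=0)
        seg = make_segment(pts)
        a = F.extract_features(seg)
        b = F.extract_features(make_segment(pts.copy()))
        assert a == b

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        pts = np.cumsum(rng.normal(scale=0.05, size=(41, 3)), axis=0)
        a = F.extract_features(make_segment(pts))
        b = F.extract_features(make_segment(pts + np.array([5.0, -3.0, 11.0])))
        for name in F.feature_schema():
            assert a[name] == pytest.approx(b[name], rel=1e-6, abs=1e-9), name

    def test_z_rotation_invariants(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(scale=0.05, size=(41, 3)), axis=0)
        ang = 0.7
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        a = F.extract_features(make_segment(pts))
        b = F.extract_features(make_segment(pts @ R.T))
        # fractal_d is NOT rotation invariant: its scaling factor comes from
        # the axis-aligned bounding box, whose diagonal turns with the frame
        invariant = (
            ["straightness", "hull_volume", "hull_area"]
            + [f"speed_{s}" for s in F.SUMMARY_STATS]
            + [f"angle_of_flight_{s}" for s in F.SUMMARY_STATS]
            + [f"angvel_3D_{s}" for s in F.SUMMARY_STATS]
        )
        for name in invariant:
            assert a[name] == pytest.approx(b[name], rel=1e-6, abs=1e-9), name

    def test_matrix_schema_and_lineage(self, small_matrix):
        assert list(small_matrix.columns[:4]) == list(F.LINEAGE_COLUMNS)
        assert list(small_matrix.columns[4:]) == F.feature_schema()
        assert small_matrix["segment_id"].is_unique

    def test_imputer_uses_training_medians_only(self):
        import pandas as pd

        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan, 1.0, 1.0]})
        test = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
        med = F.fit_imputer(train)
        out = F.impute(test, med)
        assert out.loc[0, "a"] == 2.0
        assert out.loc[0, "b"] == 1.0
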