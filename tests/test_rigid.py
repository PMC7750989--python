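"""Rigid superposition, relative motion, anatomical frame and plane fit."""

import numpy as np
import pytest

from gulpflow import rigid, simulate
from gulpflow.errors import (
    AlignmentError,
    DegenerateGeometryError,
    InsufficientMarkersError,
    NoIntersectionError,
)
from gulpflow.io import MarkerTrackSet


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestFitRigidTransform:
    def test_identity_on_identical_points(self, rng):
        pts = rng.normal(size=(5, 3)) * 10
        tr = rigid.fit_rigid_transform(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tr.translation, 0, atol=1e-12)

    def test_recovers_known_transform(self):
        ref = np.array([[0.0, 0, 0], [10, 0, 0], [0, 7, 0]])
        # 90 degrees about z plus a translation
        R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        t = np.array([1.0, 2, 3])
        tr = rigid.fit_rigid_transform(ref, ref @ R.T + t)
        np.testing.assert_allclose(tr.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tr.translation, t, atol=1e-9)

    def test_collinear_markers_rejected(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            rigid.fit_rigid_transform(ref, ref)

    def test_too_few_pairs(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [np.nan, 1, 0]])
        with pytest.raises(InsufficientMarkersError):
            rigid.fit_rigid_transform(ref, ref)

    def test_least_squares_optimality_against_random_transforms(self, rng):
        """The Procrustes residual beats 1000 random proper transforms on
        the same noisy point pairs."""
        ref = rng.normal(size=(6, 3)) * 15
        true_R = _random_rotation(rng)
        cur = ref @ true_R.T + rng.normal(size=3) + rng.normal(size=(6, 3)) * 0.2
        fit = rigid.fit_rigid_transform(ref, cur)
        best = np.sum((fit.apply(ref) - cur) ** 2)
        for _ in range(1000):
            R = _random_rotation(rng)
            t = cur.mean(axis=0) - R @ ref.mean(axis=0) + rng.normal(size=3) * 0.1
            res = np.sum((ref @ R.T + t - cur) ** 2)
            assert best <= res + 1e-12


class TestBodyMotion:
    def test_static_markers_give_identity_series(self, rng):
        pts = rng.normal(size=(4, 3)) * 20
        tracks = MarkerTrackSet({f"m{i}": np.tile(pts[i], (6, 1)) for i in range(4)})
        out = rigid.body_motion_from_markers(tracks, {"b": [f"m{i}" for i in range(4)]})
        series = out["b"]
        assert series.valid.all()
        np.testing.assert_allclose(series.R, np.tile(np.eye(3), (6, 1, 1)), atol=1e-9)
        np.testing.assert_allclose(series.t, 0, atol=1e-9)

    def test_translation_ramp_recovered(self, rng):
        pts = rng.normal(size=(3, 3)) * 20
        n = 5
        data = {}
        for i in range(3):
            arr = np.tile(pts[i], (n, 1))
            arr[:, 0] += np.arange(n)  # +1 mm per frame along x
            data[f"m{i}"] = arr
        out = rigid.body_motion_from_markers(MarkerTrackSet(data), {"b": list(data)})
        series = out["b"]
        np.testing.assert_allclose(series.R, np.tile(np.eye(3), (n, 1, 1)), atol=1e-9)
        np.testing.assert_allclose(series.t[:, 0], np.arange(n), atol=1e-9)

    def test_missing_marker_gap_only_at_that_frame(self, rng):
        pts = rng.normal(size=(3, 3)) * 20
        data = {f"m{i}": np.tile(pts[i], (6, 1)) for i in range(3)}
        data["m0"][3] = np.nan
        out = rigid.body_motion_from_markers(MarkerTrackSet(data), {"b": list(data)})
        assert list(out["b"].valid) == [True, True, True, False, True, True]

    def test_fewer_than_three_markers_is_config_error(self, rng):
        from gulpflow.errors import ValidationError

        tracks = MarkerTrackSet({"m0": rng.normal(size=(3, 3))})
        with pytest.raises(ValidationError):
            rigid.body_motion_from_markers(tracks, {"b": ["m0", "m0"]})


class TestExpressRelative:
    def test_body_relative_to_itself_is_identity(self, rng):
        n = 4
        R = np.stack([_random_rotation(rng) for _ in range(n)])
        t = rng.normal(size=(n, 3))
        s = rigid.RigidMotionSeries("b", R, t, np.ones(n, bool))
        rel = rigid.express_relative(s, s)
        np.testing.assert_allclose(rel.R, np.tile(np.eye(3), (n, 1, 1)), atol=1e-12)
        np.testing.assert_allclose(rel.t, 0, atol=1e-12)

    def test_hand_composed_single_frame(self):
        # reference translates by t_ref, body static: relative motion is
        # R_ref^T (0 - t_ref) with identity rotation
        t_ref = np.array([3.0, -1, 2])
        ref = rigid.RigidMotionSeries("n", np.eye(3)[None], t_ref[None], np.ones(1, bool))
        body = rigid.RigidMotionSeries.identity("b", 1)
        rel = rigid.express_relative(body, ref)
        np.testing.assert_allclose(rel.t[0], -t_ref, atol=1e-12)

    def test_reference_gap_propagates(self, rng):
        R = np.tile(np.eye(3), (3, 1, 1))
        t = np.zeros((3, 3))
        ref = rigid.RigidMotionSeries("n", R.copy(), t.copy(), np.array([True, False, True]))
        body = rigid.RigidMotionSeries.identity("b", 3)
        rel = rigid.express_relative(body, ref)
        assert list(rel.valid) == [True, False, True]

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            rigid.express_relative(
                rigid.RigidMotionSeries.identity("a", 3),
                rigid.RigidMotionSeries.identity("b", 4),
            )


class TestAnatomicalFrame:
    def test_food_at_origin_static_skull(self):
        frame = rigid.AnatomicalFrame(np.array([5.0, 0, 0]), np.eye(3))
        neuro = rigid.RigidMotionSeries.identity("n", 3)
        food = np.tile([5.0, 0, 0], (3, 1))
        out = rigid.food_in_anatomical_frame(food, neuro, frame)
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_common_mode_rejection(self, rng):
        """Skull and food translating together leave the food stationary."""
        n = 5
        v = rng.normal(size=3)
        t = np.outer(np.arange(n), v)
        neuro = rigid.RigidMotionSeries("n", np.tile(np.eye(3), (n, 1, 1)), t, np.ones(n, bool))
        food0 = np.array([12.0, 3, -4])
        out = rigid.food_in_anatomical_frame(food0 + t, neuro, rigid.AnatomicalFrame.canonical())
        np.testing.assert_allclose(out, np.tile(food0, (n, 1)), atol=1e-9)

    def test_single_frame_45_degree_rotation_by_hand(self):
        # skull rotated 45 degrees about z; food fixed in world at (1, 0, 0);
        # skull-frame coords are R^T x = (cos45, -sin45, 0)
        c = np.cos(np.pi / 4)
        R = np.array([[c, -c, 0], [c, c, 0], [0, 0, 1]])
        neuro = rigid.RigidMotionSeries("n", R[None], np.zeros((1, 3)), np.ones(1, bool))
        out = rigid.food_in_anatomical_frame(
            np.array([[1.0, 0, 0]]), neuro, rigid.AnatomicalFrame.canonical()
        )
        np.testing.assert_allclose(out[0], [c, -c, 0], atol=1e-12)

    def test_frame_invariance_under_common_world_transform(self, rng):
        """Pre-multiplying both food and skull motion by one rigid
        transform leaves anatomical coordinates unchanged."""
        tracks, motions, _ = simulate.generate_marker_scene(
            simulate.GeneratorConfig(marker_noise=0.0), seed=3, n_frames=20
        )
        neuro = motions["neurocranium"]
        food = tracks.get("food")
        frame = rigid.AnatomicalFrame(np.array([10.0, 0, 0]), np.eye(3))
        base = rigid.food_in_anatomical_frame(food, neuro, frame)
        Q = _random_rotation(rng)
        q = rng.normal(size=3) * 50
        food2 = food @ Q.T + q
        R2 = np.einsum("ij,njk->nik", Q, neuro.R)
        t2 = neuro.t @ Q.T + q
        neuro2 = rigid.RigidMotionSeries("n", R2, t2, neuro.valid)
        out = rigid.food_in_anatomical_frame(food2, neuro2, frame)
        np.testing.assert_allclose(out, base, atol=1e-9)


class TestPlane:
    def test_exact_coplanar_points(self):
        pts = np.array([[0.0, 0, 2], [1, 0, 2], [0, 1, 2], [3, 4, 2]])
        plane = rigid.fit_plane(pts)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(2.0 * np.sign(plane.normal[2]))

    def test_noisy_plane_normal_within_half_degree(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 60)
        pts = np.column_stack([np.full(60, 7.0), 5 * np.sin(theta), 5 * np.cos(theta)])
        pts += rng.normal(scale=0.01, size=pts.shape)
        plane = rigid.fit_plane(pts)
        angle = np.degrees(np.arccos(abs(plane.normal @ [1, 0, 0])))
        assert angle < 0.5

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]])
        with pytest.raises(DegenerateGeometryError):
            rigid.fit_plane(pts)

    def test_plane_fit_matches_normal_grid_search(self, rng):
        """TLS plane equals a brute-force search over normal directions
        (2-degree grid) within grid resolution."""
        pts = rng.normal(size=(12, 3)) * np.array([0.05, 4.0, 4.0]) + np.array([6.0, 0, 0])
        plane = rigid.fit_plane(pts)

        def rms(normal):
            normal = normal / np.linalg.norm(normal)
            d = pts @ normal - (pts.mean(axis=0) @ normal)
            return np.sqrt(np.mean(d**2))

        best = (None, np.inf)
        for az in np.deg2rad(np.arange(0, 180, 2)):
            for el in np.deg2rad(np.arange(-88, 90, 2)):
                nrm = np.array(
                    [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
                )
                v = rms(nrm)
                if v < best[1]:
                    best = (nrm, v)
        assert rms(plane.normal) <= best[1] + 1e-12
        angle = np.degrees(np.arccos(np.clip(abs(best[0] @ plane.normal), 0, 1)))
        assert angle <= 2.5  # within the grid resolution

    def test_esophagus_threshold_perpendicular_plane(self):
        plane = rigid.EsophagusPlane(np.array([1.0, 0, 0]), 70.0)
        d = rigid.esophagus_threshold(plane, rigid.AnatomicalFrame.canonical())
        assert d == pytest.approx(70.0)

    def test_esophagus_threshold_tilted_plane_by_hand(self):
        """Plane tilted 30 degrees from perpendicular with nearest point at
        60 mm pierces the axis at 60 / cos(30)."""
        tilt = np.deg2rad(30)
        normal = np.array([np.cos(tilt), np.sin(tilt), 0.0])
        plane = rigid.EsophagusPlane(normal, 60.0)  # perpendicular distance 60
        d = rigid.esophagus_threshold(plane, rigid.AnatomicalFrame.canonical())
        assert d == pytest.approx(60.0 / np.cos(tilt))
        # perpendicular mode returns the point-to-plane distance instead
        dp = rigid.esophagus_threshold(
            plane, rigid.AnatomicalFrame.canonical(), mode="perpendicular"
        )
        assert dp == pytest.approx(60.0)

    def test_plane_containing_axis_has_no_intersection(self):
        plane = rigid.EsophagusPlane(np.array([0.0, 1, 0]), 5.0)
        with pytest.raises(NoIntersectionError):
            rigid.esophagus_threshold(plane, rigid.AnatomicalFrame.canonical())
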