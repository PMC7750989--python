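"""Differentiation, path complexity, phase statistics, pooling, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gulpflow import trajectory
from gulpflow.changepoint import PhaseSegmentation
from gulpflow.errors import EmptySeriesError, ValidationError
from gulpflow.trajectory import PhaseStats, Trajectory

from conftest import straight_trajectory


def _seg(breakpoint, crossing, n):
    return PhaseSegmentation(breakpoint, crossing, n, 0.5, np.zeros(3))


class TestDifferentiate:
    def test_constant_position_zero_velocity(self):
        pos = np.tile([10.0, 2, 3], (20, 1))
        traj = Trajectory.from_mm(pos, 70, 56, 300)
        vel = trajectory.differentiate(traj)
        np.testing.assert_allclose(vel.velocity, 0, atol=1e-12)

    def test_linear_rc_motion_scales_with_frame_rate(self):
        # 0.01 HL per frame at 300 frames/s -> 3 HL/s rostrocaudal
        pos = np.zeros((30, 3))
        pos[:, 0] = np.arange(30) * 0.01 * 70  # mm
        vel = trajectory.differentiate(Trajectory.from_mm(pos, 70, 56, 300))
        np.testing.assert_allclose(vel.rc_velocity, 3.0, atol=1e-9)
        np.testing.assert_allclose(vel.speed, 3.0, atol=1e-9)

    def test_central_difference_exact_on_quadratics(self):
        # x(t) = t^2 in frame units: central difference equals 2t exactly
        n = 21
        frames = np.arange(n, dtype=float)
        pos = np.zeros((n, 3))
        pos[:, 0] = frames**2 * 70  # HL -> mm
        vel = trajectory.differentiate(Trajectory.from_mm(pos, 70, 56, 300))
        expected = 2 * frames[1:-1] * 300
        np.testing.assert_allclose(vel.rc_velocity[1:-1], expected, rtol=1e-12)

    def test_gaps_split_segments(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10.0)
        pos[4] = np.nan
        vel = trajectory.differentiate(Trajectory.from_mm(pos, 70, 56, 300))
        assert np.isnan(vel.speed[4])
        assert np.isfinite(vel.speed[3]) and np.isfinite(vel.speed[5])

    def test_all_gap_trajectory_raises(self):
        pos = np.full((5, 3), np.nan)
        with pytest.raises(EmptySeriesError):
            trajectory.differentiate(Trajectory.from_mm(pos, 70, 56, 300))

    def test_speed_bounds_rc_component(self, default_trial):
        vel = trajectory.differentiate(default_trial.trajectory)
        ok = np.isfinite(vel.speed)
        assert (vel.speed[ok] + 1e-12 >= np.abs(vel.rc_velocity[ok])).all()


class TestPathComplexity:
    def test_straight_monotone_path_is_one(self):
        pts = np.column_stack([np.linspace(0, 5, 17), np.zeros(17), np.zeros(17)])
        assert trajectory.path_complexity(pts) == pytest.approx(1.0)

    def test_back_and_forth_hand_example(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 0], [2, 0, 0]])
        # traveled 1 + 1 + 2 = 4; net displacement 2
        assert trajectory.path_complexity(pts) == pytest.approx(2.0)

    def test_closed_loop_undefined(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]])
        assert np.isnan(trajectory.path_complexity(pts))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        moved = pts @ R.T + rng.normal(size=3)
        a = trajectory.path_complexity(pts)
        b = trajectory.path_complexity(moved)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert b == pytest.approx(a, rel=1e-9)


class TestPhaseStats:
    def test_duration_from_frame_count(self):
        # 27-frame capture at 300 frames/s is exactly 90 ms
        traj = straight_trajectory(n=100)
        vel = trajectory.differentiate(traj)
        stats = trajectory.phase_stats(traj, vel, _seg(27, None, 100))
        assert stats["capture"].duration_ms == pytest.approx(90.0)

    def test_constant_speed_phase(self):
        # 5 HL/s: 5/300 HL per frame
        pos = np.zeros((60, 3))
        pos[:, 0] = np.arange(60) * 5.0 / 300 * 70
        traj = Trajectory.from_mm(pos, 70, 56, 300)
        vel = trajectory.differentiate(traj)
        stats = trajectory.phase_stats(traj, vel, _seg(30, None, 60))
        assert stats["capture"].mean_speed == pytest.approx(5.0)
        assert stats["handling"].mean_speed == pytest.approx(5.0)

    def test_generator_truth_recovered(self, default_trial, default_velocity):
        """Phase means measured through the pipeline match the generator's
        constructed per-phase speeds within discretization tolerance."""
        truth = default_trial.truth
        seg = _seg(truth["breakpoint"], truth["crossing"], truth["n_frames"])
        stats = trajectory.phase_stats(default_trial.trajectory, default_velocity, seg)
        assert stats["handling"].mean_speed == pytest.approx(
            truth["mean_speed"]["handling"], rel=0.15
        )
        assert stats["swallowing"].mean_speed == pytest.approx(
            truth["mean_speed"]["swallowing"], rel=0.15
        )
        assert stats["capture"].mean_speed == pytest.approx(
            truth["mean_speed"]["capture"], rel=0.15
        )

    def test_empty_phase_omitted(self):
        traj = straight_trajectory(n=50)
        vel = trajectory.differentiate(traj)
        stats = trajectory.phase_stats(traj, vel, _seg(20, None, 50))
        assert "swallowing" not in stats


def _stats(phase, duration, speed, pc):
    return PhaseStats(phase, duration, speed, speed, pc, 0.5, 10, 0.0, False)


class TestPoolStats:
    def test_fold_changes_from_study_phase_means(self):
        """Feeding the pooled phase means reported for the catfish study
        (89 vs 1397 ms, 10.93 vs 0.82 HL/s, 1.13 vs 3.25) reproduces the
        printed fold changes 15.7, 0.07, 2.88."""
        per_trial = [
            {
                "capture": _stats("capture", 89.0, 10.93, 1.13),
                "handling": _stats("handling", 1397.0, 0.82, 3.25),
            }
        ]
        pooled = trajectory.pool_stats(per_trial)
        assert round(pooled.fold_change["duration_ms"], 1) == 15.7
        assert round(pooled.fold_change["path_complexity"], 2) == 2.88
        # the speed ratio of the printed means is 0.0750; the study's table
        # prints 0.07 (rounded from unrounded means), i.e. agreement within
        # one unit in the last printed digit
        assert pooled.fold_change["mean_speed"] == pytest.approx(0.82 / 10.93, rel=1e-12)
        assert abs(pooled.fold_change["mean_speed"] - 0.07) <= 0.01

    def test_identical_trials_zero_sd(self):
        trial = {"capture": _stats("capture", 100.0, 5.0, 1.2)}
        pooled = trajectory.pool_stats([trial, trial, trial])
        assert pooled.sd["capture"]["mean_speed"] == 0.0
        assert pooled.mean["capture"]["mean_speed"] == pytest.approx(5.0)

    def test_unweighted_pooling_differs_from_frame_weighted(self):
        """Grand mean is the mean of per-trial means, not the mean over all
        frames: a long slow trial must not dominate."""
        short_fast = {"capture": _stats("capture", 10.0, 10.0, 1.0)}
        long_slow = {"capture": _stats("capture", 1000.0, 1.0, 1.0)}
        pooled = trajectory.pool_stats([short_fast, long_slow])
        assert pooled.mean["capture"]["mean_speed"] == pytest.approx(5.5)
        frame_weighted = (10 * 10.0 + 1000 * 1.0) / 1010
        assert pooled.mean["capture"]["mean_speed"] != pytest.approx(frame_weighted)

    def test_undefined_complexity_excluded_from_that_parameter_only(self):
        a = {"capture": _stats("capture", 100.0, 5.0, float("nan"))}
        b = {"capture": _stats("capture", 200.0, 3.0, 2.0)}
        pooled = trajectory.pool_stats([a, b])
        assert pooled.mean["capture"]["path_complexity"] == pytest.approx(2.0)
        assert pooled.mean["capture"]["mean_speed"] == pytest.approx(4.0)


class TestBinnedProfiles:
    def test_pure_rostrocaudal_motion(self):
        traj = straight_trajectory(n=60, step_mm=1.0)
        vel = trajectory.differentiate(traj)
        prof = trajectory.binned_profiles(traj, vel)
        occupied = prof.n_steps > 0
        assert occupied.any()
        np.testing.assert_allclose(prof.axis_proportion[occupied, 0], 1.0)
        np.testing.assert_allclose(prof.axis_proportion[occupied, 1:], 0.0)

    def test_hand_computed_axis_proportions(self):
        # two steps with absolute component sums (0.3, 0.4, 0.0) -> (3/7, 4/7, 0)
        pos = np.zeros((3, 3))
        pos[1] = [0.15 * 70, 0.2 * 70, 0]
        pos[2] = [0.3 * 70, 0.4 * 70, 0]
        traj = Trajectory.from_mm(pos, 70.0, 70.0 * 10, 300)  # rc_norm stays in bin 0
        vel = trajectory.differentiate(traj)
        prof = trajectory.binned_profiles(traj, vel)
        np.testing.assert_allclose(prof.axis_proportion[0], [3 / 7, 4 / 7, 0], atol=1e-12)

    def test_peak_speed_scales_to_one(self, default_trial, default_velocity):
        prof = trajectory.binned_profiles(default_trial.trajectory, default_velocity)
        finite = np.isfinite(prof.scaled_speed)
        assert np.nanmax(prof.scaled_speed) <= 1.0 + 1e-12
        assert prof.max_speed == pytest.approx(np.nanmax(default_velocity.speed))

    def test_axis_proportions_sum_to_one(self, default_trial, default_velocity):
        prof = trajectory.binned_profiles(default_trial.trajectory, default_velocity)
        rows = prof.axis_proportion[np.isfinite(prof.axis_proportion).all(axis=1)]
        np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_out_of_span_trajectory_rejected(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = -100.0
        traj = Trajectory.from_mm(pos, 70, 56, 300)
        with pytest.raises(ValidationError):
            trajectory.binned_profiles(traj, trajectory.differentiate(traj))


class TestScaleEquivariance:
    def test_common_rescaling_leaves_all_statistics_unchanged(self, rng):
        """Scaling raw mm coordinates and head length together must not
        change HL-unit positions, rc_norm, speeds or phase statistics."""
        pos = np.cumsum(rng.normal(size=(80, 3)), axis=0) + 30
        a = Trajectory.from_mm(pos, 70.0, 56.0, 300)
        b = Trajectory.from_mm(pos * 2.5, 175.0, 140.0, 300)
        np.testing.assert_allclose(b.positions, a.positions, rtol=1e-12)
        np.testing.assert_allclose(b.rc_norm, a.rc_norm, rtol=1e-12)
        va, vb = trajectory.differentiate(a), trajectory.differentiate(b)
        np.testing.assert_allclose(vb.speed, va.speed, rtol=1e-12)
        seg = _seg(30, None, 80)
        sa = trajectory.phase_stats(a, va, seg)
        sb = trajectory.phase_stats(b, vb, seg)
        assert sb["capture"].mean_speed == pytest.approx(sa["capture"].mean_speed, rel=1e-12)
        assert sb["capture"].path_complexity == pytest.approx(
            sa["capture"].path_complexity, rel=1e-12
        )
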