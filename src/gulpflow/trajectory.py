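"""Normalized food trajectories, velocities, phase statistics and profiles.

This is the single place where raw millimetre coordinates become
head-length (HL) units and where the rostrocaudal coordinate is normalized
to 0 at the oral jaws and 1 at the esophageal sphincter. Speeds are HL/s,
durations milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptySeriesError, ValidationError

PHASES = ("capture", "handling", "swallowing")

#: displacement below which path complexity is undefined (HL)
_PC_EPS = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Food path in the anatomical frame, head-length units.

    ``positions`` is ``(n, 3)`` in HL with axis order (rostrocaudal,
    dorsoventral, mediolateral); ``rc_norm`` is the rostrocaudal coordinate
    divided by the esophagus distance, so 0 is the jaws and 1 the
    esophageal sphincter. ``gaps`` marks missing frames.
    """

    positions: np.ndarray  # (n, 3), HL
    rc_norm: np.ndarray  # (n,)
    frame_rate: float  # frames/s
    gaps: np.ndarray  # (n,) bool
    head_length: float  # mm
    esophagus_distance: float  # mm, along-axis jaws -> sphincter

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        rc = np.asarray(self.rc_norm, dtype=float)
        gaps = np.asarray(self.gaps, dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "rc_norm", rc)
        object.__setattr__(self, "gaps", gaps)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError(f"positions must be (n, 3), got {pos.shape}")
        if len(rc) != len(pos) or len(gaps) != len(pos):
            raise ValidationError("positions, rc_norm and gaps must have equal length")
        if not (self.frame_rate > 0 and self.head_length > 0 and self.esophagus_distance > 0):
            raise ValidationError("frame_rate, head_length, esophagus_distance must be > 0")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_mm(
        cls,
        positions_mm: np.ndarray,
        head_length: float,
        esophagus_distance: float,
        frame_rate: float,
    ) -> "Trajectory":
        """Build from anatomical-frame millimetre coordinates."""
        pos = np.asarray(positions_mm, dtype=float)
        gaps = np.isnan(pos).any(axis=1)
        pos_hl = pos / head_length
        rc_norm = pos[:, 0] / esophagus_distance
        return cls(pos_hl, rc_norm, frame_rate, gaps, head_length, esophagus_distance)


@dataclass(frozen=True)
class VelocitySeries:
    """Per-frame food velocity in HL/s (NaN at gaps)."""

    velocity: np.ndarray  # (n, 3)
    speed: np.ndarray  # (n,), |v|
    rc_velocity: np.ndarray  # (n,), rostrocaudal component
    frame_rate: float

    def __len__(self) -> int:
        return len(self.speed)


def differentiate(traj: Trajectory) -> VelocitySeries:
    """Discrete derivative of the trajectory.

    Central differences on interior frames, one-sided at the ends of each
    contiguous (gap-free) segment; segments are differentiated
    independently so gaps never leak across. The whole series being gaps is
    an error; an isolated single frame gets NaN velocity (no neighbor to
    difference against).
    """
    pos = traj.positions
    n = len(pos)
    ok = ~traj.gaps
    if not ok.any():
        raise EmptySeriesError("trajectory contains no usable frames")
    vel = np.full((n, 3), np.nan)
    for a, b in _segments(ok):
        if b - a < 2:
            continue
        seg = pos[a:b]
        vel[a:b] = np.gradient(seg, axis=0) * traj.frame_rate
    speed = np.linalg.norm(vel, axis=1)
    return VelocitySeries(vel, speed, vel[:, 0], traj.frame_rate)


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    cuts = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[cuts + 1]]
    stops = np.r_[idx[cuts] + 1, idx[-1] + 1]
    return list(zip(starts.tolist(), stops.tolist()))


def path_complexity(points: np.ndarray) -> float:
    """Tortuosity of a path: total distance traveled over net displacement.

    1.0 for a straight monotone path, larger for winding ones; NaN
    (undefined) when the endpoints coincide. Interior missing frames are
    bridged by straight-line omission.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("points must be (n, 3)")
    pts = pts[~np.isnan(pts).any(axis=1)]
    if len(pts) < 2:
        raise ValidationError("path complexity needs >= 2 finite points")
    steps = np.diff(pts, axis=0)
    traveled = float(np.linalg.norm(steps, axis=1).sum())
    displacement = float(np.linalg.norm(pts[-1] - pts[0]))
    if displacement < _PC_EPS:
        return float("nan")
    return traveled / displacement


@dataclass(frozen=True)
class PhaseStats:
    """Kinematic summary of one transport phase in one trial."""

    phase: str
    duration_ms: float
    mean_speed: float  # HL/s, mean of per-frame speeds
    displacement_speed: float  # HL/s, net 3D displacement / duration
    path_complexity: float  # NaN when undefined (closed loop)
    net_rc_progress: float  # change in rc_norm over the phase
    n_frames: int
    gap_fraction: float
    gappy: bool  # True when > 10% of the phase frames are gaps


def phase_stats(
    traj: Trajectory,
    vel: VelocitySeries,
    segmentation,
) -> dict[str, PhaseStats]:
    """Per-phase duration, speeds, path complexity and net progress.

    ``segmentation`` provides half-open frame ranges per phase (see
    :class:`gulpflow.changepoint.PhaseSegmentation`). Empty ranges are
    omitted from the output.
    """
    out = {}
    for phase in PHASES:
        rng = segmentation.range_of(phase)
        if rng is None:
            continue
        a, b = rng
        if not (0 <= a <= b <= len(traj)):
            raise ValidationError(f"{phase} range [{a}, {b}) outside trial of {len(traj)}")
        if b - a < 2:
            continue
        ok = ~traj.gaps[a:b]
        if ok.sum() < 2:
            continue
        n_frames = b - a
        duration_ms = n_frames / traj.frame_rate * 1e3
        speeds = vel.speed[a:b]
        mean_speed = float(np.nanmean(speeds)) if np.isfinite(speeds).any() else float("nan")
        pts = traj.positions[a:b][ok]
        pc = path_complexity(pts)
        disp = float(np.linalg.norm(pts[-1] - pts[0]))
        gap_fraction = 1.0 - ok.sum() / n_frames
        rc = traj.rc_norm[a:b][ok]
        out[phase] = PhaseStats(
            phase=phase,
            duration_ms=duration_ms,
            mean_speed=mean_speed,
            displacement_speed=disp / (duration_ms / 1e3),
            path_complexity=pc,
            net_rc_progress=float(rc[-1] - rc[0]),
            n_frames=n_frames,
            gap_fraction=gap_fraction,
            gappy=gap_fraction > 0.10,
        )
    return out


@dataclass(frozen=True)
class PooledPhaseStats:
    """Across-trial grand means/SDs per phase plus handling/capture ratios.

    Each trial contributes its phase average once, regardless of length
    (unweighted pooling avoids long trials dominating). Fold changes are
    ratios of grand means, handling over capture.
    """

    mean: dict[str, dict[str, float]]  # phase -> parameter -> grand mean
    sd: dict[str, dict[str, float]]  # phase -> parameter -> across-trial SD
    n_trials: dict[str, int]
    fold_change: dict[str, float]  # parameter -> handling / capture


_POOLED_PARAMS = ("duration_ms", "mean_speed", "path_complexity", "net_rc_progress")


def pool_stats(per_trial: Sequence[Mapping[str, PhaseStats]]) -> PooledPhaseStats:
    """Pool per-trial phase statistics into grand means, SDs and fold changes.

    Undefined path complexities (NaN) are excluded from that parameter's
    pooling only. Phases absent from every trial are omitted.
    """
    mean: dict[str, dict[str, float]] = {}
    sd: dict[str, dict[str, float]] = {}
    n_trials: dict[str, int] = {}
    for phase in PHASES:
        stats = [d[phase] for d in per_trial if phase in d]
        if not stats:
            continue
        n_trials[phase] = len(stats)
        mean[phase] = {}
        sd[phase] = {}
        for param in _POOLED_PARAMS:
            vals = np.array([getattr(s, param) for s in stats], dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                mean[phase][param] = float("nan")
                sd[phase][param] = float("nan")
                continue
            mean[phase][param] = float(vals.mean())
            sd[phase][param] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    fold = {}
    if "capture" in mean and "handling" in mean:
        for param in _POOLED_PARAMS:
            cap = mean["capture"].get(param)
            han = mean["handling"].get(param)
            if cap and np.isfinite(cap) and han is not None and np.isfinite(han):
                fold[param] = han / cap
    return PooledPhaseStats(mean=mean, sd=sd, n_trials=n_trials, fold_change=fold)


@dataclass(frozen=True)
class BinProfile:
    """Binned speed and axis-proportion profiles over the head.

    Ten equal bins of normalized rostrocaudal position [0, 1); speeds are
    scaled to the trial's maximum so profiles are comparable across trials,
    and per-bin motion is decomposed into the proportion of summed absolute
    displacement along each anatomical axis.
    """

    bin_edges: np.ndarray  # (11,)
    scaled_speed: np.ndarray  # (10,), NaN for empty bins
    axis_proportion: np.ndarray  # (10, 3), rows sum to 1; NaN rows for empty bins
    n_steps: np.ndarray  # (10,) int
    max_speed: float  # HL/s, the per-trial scaling constant


def binned_profiles(traj: Trajectory, vel: VelocitySeries, n_bins: int = 10) -> BinProfile:
    """Profile speed and axis decomposition across 10% head increments.

    A step from frame i to i+1 is assigned to the bin of ``rc_norm[i]``;
    positions at or past the esophagus (rc_norm >= 1) clip into the last
    bin, and frames rostral of the jaws (rc_norm < 0) are excluded.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ok = ~traj.gaps
    rc = traj.rc_norm
    if not ((rc[ok] >= 0) & (rc[ok] <= 1 + 1e-9)).any():
        raise ValidationError("trajectory never enters the jaws-to-esophagus span")
    max_speed = float(np.nanmax(vel.speed))
    if not max_speed > 0:
        raise ValidationError("per-trial maximum speed must be > 0")

    step_ok = ok[:-1] & ok[1:] & (rc[:-1] >= 0)
    start_bin = np.minimum((rc[:-1] * n_bins).astype(int), n_bins - 1)
    deltas = np.abs(np.diff(traj.positions, axis=0))  # (n-1, 3), HL

    frame_ok = ok & (rc >= 0) & np.isfinite(vel.speed)
    frame_bin = np.minimum((rc * n_bins).astype(int), n_bins - 1)

    scaled = np.full(n_bins, np.nan)
    props = np.full((n_bins, 3), np.nan)
    n_steps = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        fsel = frame_ok & (frame_bin == b)
        if fsel.any():
            scaled[b] = float(np.mean(vel.speed[fsel]) / max_speed)
        ssel = step_ok & (start_bin == b)
        n_steps[b] = int(ssel.sum())
        if n_steps[b]:
            comp = deltas[ssel].sum(axis=0)
            total = comp.sum()
            if total > 0:
                props[b] = comp / total
    return BinProfile(edges, scaled, props, n_steps, max_speed)
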