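"""End-to-end study driver: trajectories -> phases -> statistics -> synchrony.

Per trial: load the anatomical-frame food trajectory and cranial
degree-of-freedom velocities, normalize to head lengths and the
jaws-to-esophagus axis, differentiate, locate the capture-to-handling
breakpoint (sup-F with permutation support), segment the three phases and
compute phase statistics and binned profiles. Across trials: unweighted
pooled phase statistics and fold changes, per-phase common-lag
cross-correlograms, and the regression of breakpoint location on
individual and food type.

Trials that fail a stage are recorded and skipped; the run aborts only
when every trial fails (or none exist). Identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import changepoint, synchrony, trajectory
from .errors import GulpflowError, ValidationError
from .io import StudyConfig, TrialMetadata, read_landmarks_csv, read_points_csv, read_trial_table
from .rigid import AnatomicalFrame, esophagus_threshold, fit_plane

log = logging.getLogger("gulpflow")


@dataclass
class TrialResult:
    metadata: TrialMetadata
    trajectory: trajectory.Trajectory
    velocity: trajectory.VelocitySeries
    breakpoint: changepoint.BreakpointResult
    breakpoint_speed: changepoint.BreakpointResult | None
    segmentation: changepoint.PhaseSegmentation
    phase_stats: dict[str, trajectory.PhaseStats]
    bin_profile: trajectory.BinProfile
    dofs: dict[str, np.ndarray]


@dataclass
class StudySummary:
    """Everything the study computes, one entry per surviving trial."""

    trials: dict[str, TrialResult]
    pooled: trajectory.PooledPhaseStats
    synchrony: dict[str, dict[str, dict[str, synchrony.CrossCorrelogram]]]  # phase -> group -> dof
    regression: synchrony.RegressionResult | None
    esophagus_distance_mm: dict[str, float]
    errors: dict[str, str] = field(default_factory=dict)


def _esophagus_distances(config: StudyConfig, trials: list[TrialMetadata]) -> dict[str, float]:
    """Per-individual jaws-to-sphincter distance (mm), from landmark plane
    fits or direct config values."""
    out = dict(config.esophagus_distance_mm)
    frame = AnatomicalFrame.canonical()
    for ind, path in config.esophagus_landmarks.items():
        if ind in out:
            continue
        plane = fit_plane(read_landmarks_csv(path))
        out[ind] = esophagus_threshold(plane, frame)
    missing = {t.individual_id for t in trials} - set(out)
    if missing:
        raise ValidationError(
            f"no esophageal landmarks or distance for individual(s): {sorted(missing)}"
        )
    return out


def _load_trial(config: StudyConfig, md: TrialMetadata, esoph_mm: float):
    food_path = Path(config.data_dir) / f"{md.trial_id}_food.csv"
    tracks = read_points_csv(food_path, dialect=config.dialect)
    if "food" not in tracks:
        raise ValidationError(f"{food_path}: no 'food' marker found")
    traj = trajectory.Trajectory.from_mm(
        tracks.get("food"), md.head_length, esoph_mm, md.frame_rate
    )
    dof_path = Path(config.data_dir) / f"{md.trial_id}_dofs.csv"
    dofs: dict[str, np.ndarray] = {}
    if dof_path.exists():
        df = pd.read_csv(dof_path)
        for col in df.columns:
            if col.lower() == "frame":
                continue
            dofs[col] = df[col].to_numpy(dtype=float)
    return traj, dofs


def _trial_seed(base_seed: int, index: int) -> int:
    """Stable per-trial permutation seed below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), index]).generate_state(1)[0] % (2**31))


def run_pipeline(config: StudyConfig, out_dir: str | Path | None = None) -> StudySummary:
    """Run the full study described by ``config``.

    When ``out_dir`` is given, per-trial and pooled tables are written as
    CSV plus one JSON summary; repeated runs with the same config and seed
    produce byte-identical files.
    """
    config.validate()
    metadata = read_trial_table(config.trial_table)
    if not metadata:
        raise ValidationError("no trials in the trial table")
    esoph = _esophagus_distances(config, metadata)
    bset = config.breakpoint

    results: dict[str, TrialResult] = {}
    errors: dict[str, str] = {}
    for i, md in enumerate(metadata):
        try:
            traj, dofs = _load_trial(config, md, esoph[md.individual_id])
            vel = trajectory.differentiate(traj)
            series = vel.rc_velocity if bset.series == "rc_velocity" else vel.speed
            finite = np.nonzero(np.isfinite(series))[0]
            bp = changepoint.sup_f_test(
                series[finite], trim=bset.trim, n_perm=bset.n_perm,
                seed=_trial_seed(bset.seed, i), series_used=bset.series,
                early_stop_alpha=bset.alpha,
            )
            if len(finite) != len(series):
                # map the gap-compressed index back to a trial frame
                import dataclasses as _dc

                bp = _dc.replace(bp, breakpoint_index=int(finite[bp.breakpoint_index]))
            other = vel.speed if bset.series == "rc_velocity" else vel.rc_velocity
            other_name = "speed" if bset.series == "rc_velocity" else "rc_velocity"
            try:
                bp_other = changepoint.sup_f_test(
                    other[np.isfinite(other)], trim=bset.trim, n_perm=bset.n_perm,
                    seed=_trial_seed(bset.seed, i) + 1, series_used=other_name,
                    early_stop_alpha=bset.alpha,
                )
            except GulpflowError:
                bp_other = None
            seg = changepoint.segment_trial(traj, bp, alpha=bset.alpha)
            stats = trajectory.phase_stats(traj, vel, seg)
            profile = trajectory.binned_profiles(traj, vel)
            if seg.has_swallowing != md.includes_esophageal:
                log.warning(
                    "trial %s: segmentation %s swallowing but metadata flag is %s",
                    md.trial_id,
                    "found" if seg.has_swallowing else "found no",
                    md.includes_esophageal,
                )
            results[md.trial_id] = TrialResult(
                md, traj, vel, bp, bp_other, seg, stats, profile, dofs
            )
            log.info("trial %s: ok (breakpoint %d, p=%.2g)", md.trial_id,
                     bp.breakpoint_index, bp.p_value)
        except GulpflowError as exc:
            errors[md.trial_id] = f"{type(exc).__name__}: {exc}"
            log.warning("trial %s: skipped (%s)", md.trial_id, errors[md.trial_id])
    if not results:
        raise ValidationError(
            "all trials failed: " + "; ".join(f"{k}: {v}" for k, v in errors.items())
        )

    pooled = trajectory.pool_stats([r.phase_stats for r in results.values()])

    sync_inputs = [
        {
            "rc_velocity": r.velocity.rc_velocity,
            "dofs": r.dofs,
            "segmentation": r.segmentation,
            "frame_rate": r.metadata.frame_rate,
            "individual_id": r.metadata.individual_id,
        }
        for r in results.values()
        if r.dofs
    ]
    sync: dict[str, dict] = {}
    if sync_inputs:
        for phase in trajectory.PHASES:
            try:
                sync[phase] = synchrony.phase_synchrony(
                    sync_inputs, phase,
                    max_lag=config.synchrony.max_lag,
                    spacer=config.synchrony.spacer,
                    min_pairs=config.synchrony.min_pairs,
                )
            except ValidationError:
                log.warning("phase %s: synchrony skipped (absent or degenerate)", phase)

    reg = None
    if len(results) >= 4:
        reg = synchrony.breakpoint_regression(
            [r.segmentation.breakpoint_rc_norm for r in results.values()],
            [r.metadata.individual_id for r in results.values()],
            [r.metadata.food_type for r in results.values()],
        )

    summary = StudySummary(results, pooled, sync, reg, esoph, errors)
    if out_dir is not None:
        write_summary(summary, out_dir)
    return summary


# ---------------------------------------------------------------------------
# tabular export


def phase_stats_table(summary: StudySummary) -> pd.DataFrame:
    rows = []
    for tid, r in summary.trials.items():
        for phase, s in r.phase_stats.items():
            rows.append(
                {
                    "trial_id": tid,
                    "individual_id": r.metadata.individual_id,
                    "food_type": r.metadata.food_type,
                    "phase": phase,
                    "duration_ms": s.duration_ms,
                    "mean_speed_hl_s": s.mean_speed,
                    "displacement_speed_hl_s": s.displacement_speed,
                    "path_complexity": s.path_complexity,
                    "net_rc_progress": s.net_rc_progress,
                    "n_frames": s.n_frames,
                    "gappy": s.gappy,
                }
            )
    return pd.DataFrame(rows)


def pooled_table(summary: StudySummary) -> pd.DataFrame:
    rows = []
    p = summary.pooled
    for phase in p.mean:
        for param in p.mean[phase]:
            rows.append(
                {
                    "phase": phase,
                    "parameter": param,
                    "grand_mean": p.mean[phase][param],
                    "sd": p.sd[phase][param],
                    "n_trials": p.n_trials[phase],
                }
            )
    for param, fc in p.fold_change.items():
        rows.append(
            {"phase": "handling/capture", "parameter": param,
             "grand_mean": fc, "sd": float("nan"), "n_trials": min(p.n_trials.values())}
        )
    return pd.DataFrame(rows)


def breakpoints_table(summary: StudySummary) -> pd.DataFrame:
    rows = []
    for tid, r in summary.trials.items():
        bp = r.breakpoint
        seg = r.segmentation
        rows.append(
            {
                "trial_id": tid,
                "breakpoint_frame": bp.breakpoint_index,
                "breakpoint_time_ms": bp.breakpoint_index / r.metadata.frame_rate * 1e3,
                "sup_f": bp.sup_f,
                "p_value": bp.p_value,
                "method": bp.method,
                "series": bp.series_used,
                "rc_norm": seg.breakpoint_rc_norm,
                "x_hl": seg.breakpoint_position[0],
                "y_hl": seg.breakpoint_position[1],
                "z_hl": seg.breakpoint_position[2],
                "crossing_frame": seg.crossing if seg.crossing is not None else -1,
            }
        )
    return pd.DataFrame(rows)


def correlogram_table(summary: StudySummary) -> pd.DataFrame:
    rows = []
    for phase, groups in summary.synchrony.items():
        for group, dofs in groups.items():
            for dof, cc in dofs.items():
                for lag, r, npair in zip(cc.lags, cc.r, cc.n_pairs):
                    rows.append(
                        {
                            "phase": phase,
                            "group": group,
                            "dof": dof,
                            "lag_frames": int(lag),
                            "lag_ms": lag / cc.frame_rate * 1e3,
                            "r": r,
                            "r2": r**2 if np.isfinite(r) else float("nan"),
                            "n_pairs": int(npair),
                            "is_best": int(lag) == cc.best_lag,
                        }
                    )
    return pd.DataFrame(rows)


def bin_profile_table(summary: StudySummary) -> pd.DataFrame:
    rows = []
    axes = ("rostrocaudal", "dorsoventral", "mediolateral")
    for tid, r in summary.trials.items():
        prof = r.bin_profile
        for b in range(len(prof.scaled_speed)):
            for ai, ax in enumerate(axes):
                rows.append(
                    {
                        "trial_id": tid,
                        "bin_start": prof.bin_edges[b],
                        "bin_end": prof.bin_edges[b + 1],
                        "scaled_speed": prof.scaled_speed[b],
                        "axis": ax,
                        "axis_proportion": prof.axis_proportion[b, ai],
                        "n_steps": int(prof.n_steps[b]),
                    }
                )
    return pd.DataFrame(rows)


def write_summary(summary: StudySummary, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    phase_stats_table(summary).to_csv(out / "phase_stats.csv", index=False, float_format=fmt)
    pooled_table(summary).to_csv(out / "pooled_stats.csv", index=False, float_format=fmt)
    breakpoints_table(summary).to_csv(out / "breakpoints.csv", index=False, float_format=fmt)
    correlogram_table(summary).to_csv(out / "correlograms.csv", index=False, float_format=fmt)
    bin_profile_table(summary).to_csv(out / "bin_profiles.csv", index=False, float_format=fmt)

    best = {}
    for phase, groups in summary.synchrony.items():
        best[phase] = {
            group: {
                dof: {
                    "best_lag_frames": cc.best_lag,
                    "best_lag_ms": round(cc.best_lag_ms, 6),
                    "r": round(cc.best_r, 10),
                    "r2": round(cc.best_r2, 10),
                }
                for dof, cc in dofs.items()
            }
            for group, dofs in groups.items()
        }
    js = {
        "n_trials": len(summary.trials),
        "n_failed": len(summary.errors),
        "errors": summary.errors,
        "esophagus_distance_mm": {k: round(v, 10) for k, v in summary.esophagus_distance_mm.items()},
        "pooled_mean": summary.pooled.mean,
        "pooled_sd": summary.pooled.sd,
        "fold_change": summary.pooled.fold_change,
        "synchrony_best": best,
        "regression": None,
    }
    if summary.regression is not None:
        js["regression"] = {
            "n": summary.regression.n,
            "r_squared": summary.regression.r_squared,
            "term_pvalues": summary.regression.term_pvalues,
            "flags": summary.regression.flags,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(js, fh, indent=1, sort_keys=True, allow_nan=True)
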