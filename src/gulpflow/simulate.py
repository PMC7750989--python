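"""Seeded synthetic feeding trials with ground truth for every stage.

A generated trial emulates the three-phase structure of suction-feeding
food transport in a catfish-like fish at 300 frames/s:

capture
    the food, starting just rostral of the oral jaws, is drawn in at high
    speed (peak ~17 HL/s) along a near-linear, exponentially decelerating
    rostrocaudal path, stopping ~60% of the way to the esophagus after
    ~89 ms;
handling
    a slow (~0.82 HL/s), erratic random walk — Poisson-timed bursts of
    motion in random directions over a weak caudal drift — that winds
    (path complexity ~3.25) the rest of the way to the esophageal plane;
swallowing
    slow (~0.25 HL/s) esophageal transport whose velocity pulses are a
    scaled, lag-shifted copy of the cranial-expansion (hyoid retraction)
    signal, the lag defaulting to 25 ms, so synchrony detection has a
    known truth.

Cranial degree-of-freedom signals carry one large coordinated excursion
during capture, low-amplitude noise during handling and periodic
expansion cycles during swallowing. Everything is driven by one
``numpy.random.Generator``; identical (config, seed) reproduce identical
arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .io import MarkerTrackSet, TrialMetadata
from .rigid import RigidMotionSeries, RigidTransform
from .trajectory import Trajectory

DOF_NAMES = (
    "hyoid_retraction",
    "girdle_retraction",
    "hypaxial_shortening",
    "mouth_opening",
)

#: cranial-excursion amplitudes during capture and swallowing (nominal deg/s)
_CAPTURE_DOF_AMP = {"hyoid_retraction": 40.0, "girdle_retraction": 30.0,
                    "hypaxial_shortening": 25.0, "mouth_opening": 35.0}
_SWALLOW_DOF_AMP = {"hyoid_retraction": 20.0, "girdle_retraction": 15.0,
                    "hypaxial_shortening": 12.0, "mouth_opening": 8.0}
_BODY_NAMES = ("neurocranium", "suspensorium", "operculum",
               "lower_jaw", "hyoid", "pectoral_girdle")


@dataclass(frozen=True)
class CaptureConfig:
    initial_speed_mean: float = 17.0  # HL/s, peak speed at the jaws
    initial_speed_sd: float = 9.0
    duration_mean_ms: float = 89.0
    duration_sd_ms: float = 53.0
    stop_mean: float = 0.605  # rc_norm where handling begins
    stop_sd: float = 0.155
    start_rc: float = -0.4  # rc_norm as the tracked strike begins
    lateral_noise: float = 0.015  # HL amplitude of off-axis wander


@dataclass(frozen=True)
class HandlingConfig:
    mean_speed: float = 0.82  # HL/s, per-frame speed target
    burst_rate: float = 4.0  # bursts per second
    burst_duration_ms: float = 120.0
    path_complexity: float = 3.25  # target tortuosity; sets the caudal drift
    jitter: float = 0.3  # white-noise fraction of the burst field


@dataclass(frozen=True)
class SwallowingConfig:
    mean_speed: float = 0.25  # HL/s
    pulse_period_ms: float = 250.0  # cranial-expansion cycle period
    lag_ms: float = 25.0  # food velocity lags cranial expansion by this
    noise: float = 0.02  # HL/s white noise on food velocity
    duration_mean_ms: float = 1000.0
    duration_sd_ms: float = 250.0


@dataclass(frozen=True)
class GeneratorConfig:
    frame_rate: float = 300.0  # frames/s
    head_length: float = 70.0  # mm
    esophagus_distance: float = 56.0  # mm, jaws to esophageal plane (0.8 HL)
    include_swallowing_p: float = 16 / 25
    marker_noise: float = 0.05  # mm, marker-scene tracking noise
    dof_noise: float = 1.5  # baseline cranial-DOF velocity noise (deg/s)
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    handling: HandlingConfig = field(default_factory=HandlingConfig)
    swallowing: SwallowingConfig = field(default_factory=SwallowingConfig)

    def validate(self) -> None:
        if not (self.frame_rate > 0 and self.head_length > 0 and self.esophagus_distance > 0):
            raise ConfigError("frame_rate, head_length, esophagus_distance must be > 0")
        if not 0 <= self.include_swallowing_p <= 1:
            raise ConfigError("include_swallowing_p must be a probability")
        if self.handling.path_complexity < 1:
            raise ConfigError("target path complexity < 1 is infeasible")
        if self.handling.mean_speed <= 0 or self.swallowing.mean_speed <= 0:
            raise ConfigError("phase mean speeds must be > 0")
        if self.swallowing.lag_ms >= self.swallowing.pulse_period_ms:
            raise ConfigError("lag must be shorter than the pulse period")
        if self.capture.initial_speed_mean <= 0 or self.capture.duration_mean_ms <= 0:
            raise ConfigError("capture speed and duration means must be > 0")


@dataclass
class SyntheticTrial:
    """One generated trial plus its construction truth."""

    trial_id: str
    trajectory: Trajectory
    positions_mm: np.ndarray  # (n, 3) anatomical mm, convenience for writing
    dofs: dict[str, np.ndarray]  # per-frame DOF velocities (nominal deg/s)
    truth: dict
    seed: object


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float = 0.0, high: float = np.inf) -> float:
    """Rejection-sampled truncated normal (open interval)."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if low < v < high:
            return float(v)
    raise ConfigError(f"truncated normal ({mean}, {sd}) on ({low}, {high}) is infeasible")


def _measured_speed(v: np.ndarray) -> float:
    """Mean per-frame speed under the analysis's central-difference
    convention: frame i of a differentiated trajectory sees the average of
    step velocities i-1 and i, which attenuates frame-to-frame jitter.
    Calibrating against this convention makes the generated phases hit
    their speed targets as *measured*, not just as constructed."""
    v = np.asarray(v)
    if len(v) < 2:
        return float(np.linalg.norm(v, axis=1).mean())
    mid = 0.5 * (v[:-1] + v[1:])
    sp = np.concatenate(
        [[np.linalg.norm(v[0])], np.linalg.norm(mid, axis=1), [np.linalg.norm(v[-1])]]
    )
    return float(sp.mean())


def _half_cosine(n: int) -> np.ndarray:
    """Bell pulse of unit peak over n samples: 0.5 (1 - cos(2 pi t / T))."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def generate_trial(
    config: GeneratorConfig | None = None,
    seed: object = 0,
    include_swallowing: bool | None = None,
    trial_id: str = "synthetic",
) -> SyntheticTrial:
    """Generate one seeded synthetic feeding trial.

    ``include_swallowing=None`` samples inclusion with the configured
    probability (16/25 by default, mirroring a study in which 16 of 25
    trials recorded esophageal transport).
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    fr = config.frame_rate
    hl = config.head_length
    e_hl = config.esophagus_distance / hl  # esophagus distance in HL
    cap, han, swa = config.capture, config.handling, config.swallowing

    # --- capture: suction pull decelerating exponentially toward a floor
    #     speed, so handling begins with an abrupt, detectable stop.
    #     The sampled (peak, duration, stop-position) triple is resampled
    #     until internally consistent with that profile: the peak-speed x
    #     duration product must exceed the required displacement but not
    #     overshoot it so far that the floor speed collapses to zero (which
    #     would smear the stop out over the whole capture).
    min_dur_ms = 3.0 / fr * 1e3
    for _ in range(10_000):
        v0 = _truncnorm(rng, cap.initial_speed_mean, cap.initial_speed_sd)
        dur_s = _truncnorm(rng, cap.duration_mean_ms, cap.duration_sd_ms, low=min_dur_ms) / 1e3
        stop = _truncnorm(rng, cap.stop_mean, cap.stop_sd, low=0.05, high=0.95)
        disp = (stop - cap.start_rc) * e_hl  # HL to travel during capture
        if 1.15 * disp < v0 * dur_s < 2.4 * disp:
            break
    else:
        raise ConfigError("capture calibration infeasible for this configuration")
    # v(t) = floor + (v0 - floor) exp(-t / tau); tau = duration/3 and the
    # floor solved so the integral equals the displacement exactly
    tau = dur_s / 3.0
    kdec = 1.0 - np.exp(-3.0)
    floor = (disp - v0 * tau * kdec) / (dur_s - tau * kdec)
    n_cap = max(int(round(dur_s * fr)), 3)
    # midpoint sampling: v_cap[i] is the mean velocity over frame step i,
    # so the discrete integral tracks the analytic displacement closely
    t_cap = (np.arange(n_cap) + 0.5) / fr
    v_cap = np.zeros((n_cap, 3))
    v_cap[:, 0] = floor + (v0 - floor) * np.exp(-t_cap / tau)
    if cap.lateral_noise > 0:
        for ax in (1, 2):  # smooth low-frequency off-axis wander
            f_hz = rng.uniform(2.0, 6.0)
            amp = cap.lateral_noise * rng.uniform(0.5, 1.0)
            v_cap[:, ax] = amp * 2 * np.pi * f_hz * np.cos(2 * np.pi * f_hz * t_cap + rng.uniform(0, 2 * np.pi))
    else:
        rng.uniform(size=6)  # keep the stream aligned across noise settings

    # --- handling: caudal drift + Poisson bursts. Both the drift gain and
    #     the burst/jitter scale are solved numerically on the realized
    #     walk so that the phase hits the target per-frame mean speed and
    #     the target path complexity (lateral wander inflates the net
    #     displacement, so the naive drift = speed / complexity runs short).
    drift0 = han.mean_speed / han.path_complexity  # closed-form starting point
    # discrete sum, so the crossing frame matches the integrated trajectory
    start_rc_hl = cap.start_rc * e_hl + v_cap[:, 0].sum() / fr
    d_han = e_hl - start_rc_hl  # HL left to the esophageal plane
    g_lo = 0.3 * drift0
    n_max = int(np.ceil(d_han / g_lo * fr * 1.5)) + 300
    burst_len = max(int(round(han.burst_duration_ms / 1e3 * fr)), 2)
    u = np.zeros((n_max, 3))
    n_bursts = rng.poisson(han.burst_rate * n_max / fr)
    starts = rng.integers(0, n_max, size=n_bursts)
    pulse = _half_cosine(burst_len)
    for s0 in starts:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        amp = abs(rng.normal(1.0, 0.5))
        stop_i = min(s0 + burst_len, n_max)
        u[s0:stop_i] += amp * pulse[: stop_i - s0, None] * direction[None, :]
    u += han.jitter * rng.standard_normal((n_max, 3))

    def _walk(g: float, c: float) -> np.ndarray:
        """Velocity rows of the walk up to (and including) plane crossing."""
        v = c * u
        rc = start_rc_hl + (g * np.arange(1, n_max + 1) + np.cumsum(v[:, 0])) / fr
        crossed = np.nonzero(rc >= e_hl)[0]
        nh = int(crossed[0]) + 1 if len(crossed) else n_max
        out = v[:nh].copy()
        out[:, 0] += g
        return out

    def _solve_c(g: float) -> float:
        def err(c: float) -> float:
            return _measured_speed(_walk(g, c)) - han.mean_speed

        if err(0.0) > 0:
            raise ConfigError("handling drift alone exceeds the target mean speed")
        hi = 1.0
        while err(hi) < 0:
            hi *= 2.0
            if hi > 1e6:
                raise ConfigError("handling speed calibration failed to bracket")
        return float(brentq(err, 0.0, hi, xtol=1e-10))

    def _complexity(g: float) -> float:
        v = _walk(g, _solve_c(g))
        pos = np.cumsum(v, axis=0) / fr
        traveled = float(np.linalg.norm(v, axis=1).sum() / fr)
        return traveled / float(np.linalg.norm(pos[-1]))

    g_hi = 0.98 * han.mean_speed
    if han.path_complexity <= 1.02:
        drift = g_hi
    else:
        try:
            drift = float(
                brentq(lambda g: _complexity(g) - han.path_complexity, g_lo, g_hi, xtol=1e-8)
            )
        except ValueError:  # no sign change; fall back to the closed form
            drift = drift0
    v_han = _walk(drift, _solve_c(drift))

    # one draw regardless of how inclusion is decided, so explicit and
    # sampled inclusion share the rest of the random stream
    u_include = rng.random()
    include = (u_include < config.include_swallowing_p
               if include_swallowing is None else include_swallowing)
    if not include:
        # recording ends with the food at the sphincter but not past it;
        # stop 2% short of the plane so measured plane location error
        # (landmark noise) cannot flip the trial's classification
        rc_steps = start_rc_hl + np.cumsum(v_han[:, 0]) / fr
        reached = np.nonzero(rc_steps >= 0.98 * e_hl)[0]
        if len(reached):
            v_han = v_han[: max(int(reached[0]), 1)]
    n_han = len(v_han)

    # --- swallowing: food velocity = lag-shifted copy of the cranial
    #     expansion signal (lag quantized to whole frames), plus noise
    lag_frames = int(round(swa.lag_ms / 1e3 * fr))
    v_swa = np.zeros((0, 3))
    c_sig = np.zeros(0)
    if include:
        dur_ms = _truncnorm(rng, swa.duration_mean_ms, swa.duration_sd_ms,
                            low=2.0 * swa.pulse_period_ms)
        n_swa = int(round(dur_ms / 1e3 * fr))
        period = max(int(round(swa.pulse_period_ms / 1e3 * fr)), 4)
        plen = max(int(round(0.6 * period)), 2)
        c_sig = np.zeros(n_swa)
        for p0 in range(period // 3, n_swa, period):
            stop_i = min(p0 + plen, n_swa)
            c_sig[p0:stop_i] += rng.uniform(0.8, 1.2) * _half_cosine(plen)[: stop_i - p0]
        f_raw = np.zeros(n_swa)
        f_raw[lag_frames:] = c_sig[: n_swa - lag_frames]
        noise = swa.noise * rng.standard_normal((n_swa, 3))

        def swallow_speed(scale: float) -> float:
            v = noise.copy()
            v[:, 0] += scale * f_raw
            return _measured_speed(v)

        if swallow_speed(0.0) > swa.mean_speed:
            raise ConfigError("swallowing noise alone exceeds the target mean speed")
        s_hi = 1.0
        while swallow_speed(s_hi) < swa.mean_speed:
            s_hi *= 2.0
            if s_hi > 1e6:
                raise ConfigError("swallowing speed calibration failed to bracket")
        s_scale = brentq(lambda c: swallow_speed(c) - swa.mean_speed, 0.0, s_hi)
        v_swa = noise
        v_swa[:, 0] += s_scale * f_raw

    # --- assemble positions (HL, anatomical axes) by integrating velocity
    v_all = np.vstack([v_cap, v_han, v_swa])
    n = len(v_all)
    pos_hl = np.zeros((n, 3))
    pos_hl[0] = (cap.start_rc * e_hl, 0.0, 0.0)
    pos_hl[1:] = pos_hl[0] + np.cumsum(v_all[:-1], axis=0) / fr
    positions_mm = pos_hl * hl
    traj = Trajectory.from_mm(positions_mm, hl, config.esophagus_distance, fr)

    # --- cranial degree-of-freedom velocities
    bp = n_cap
    crossing = n_cap + n_han if include else None
    dofs = {}
    bell = _half_cosine(n_cap)
    for name in DOF_NAMES:
        sig = config.dof_noise * rng.standard_normal(n)
        sig[:n_cap] += _CAPTURE_DOF_AMP[name] * bell
        if include:
            sig[crossing:] += _SWALLOW_DOF_AMP[name] * c_sig
        # emit as a discrete derivative of an underlying rotation series,
        # the same convention the food velocity acquires when the analysis
        # central-differences the trajectory (half-frame alignment)
        meas = np.empty(n)
        meas[0] = sig[0]
        meas[1:] = 0.5 * (sig[:-1] + sig[1:])
        dofs[name] = meas

    from .trajectory import differentiate

    speeds = differentiate(traj).speed
    truth = {
        "breakpoint": bp,
        "crossing": crossing,
        "n_frames": n,
        "stop_rc_norm": float(start_rc_hl / e_hl),
        "stop_rc_norm_sampled": stop,
        "capture_duration_ms": dur_s * 1e3,
        "capture_peak_speed": v0,
        "lag_frames": lag_frames,
        "lag_ms": lag_frames / fr * 1e3,
        "mean_speed": {
            "capture": float(np.nanmean(speeds[:bp])),
            "handling": float(np.nanmean(speeds[bp : crossing if include else n])),
            **({"swallowing": float(np.nanmean(speeds[crossing:]))} if include else {}),
        },
    }
    return SyntheticTrial(trial_id, traj, positions_mm, dofs, truth, seed)


# ---------------------------------------------------------------------------
# study-level generation


@dataclass
class SyntheticStudy:
    trials: list[SyntheticTrial]
    metadata: list[TrialMetadata]
    landmarks: dict[str, np.ndarray]  # per-individual esophageal landmark rings
    config: GeneratorConfig
    seed: int


_FOOD_WEIGHTS = {"pellet": 10 / 25, "squid": 1 / 25, "worm": 14 / 25}
_INDIVIDUAL_WEIGHTS = (11 / 25, 11 / 25, 3 / 25)


def generate_study(
    config: GeneratorConfig | None = None,
    n_trials: int = 25,
    n_individuals: int = 3,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a seeded study of trials with per-individual head lengths.

    Trial counts per individual and food type follow the motivating
    study's proportions (three individuals contributing unevenly; pellet,
    squid and worm food items at 10:1:14); esophageal transport is
    included with the configured probability. The per-individual
    esophageal landmark rings let the full pipeline exercise its plane
    fit.
    """
    config = config or GeneratorConfig()
    config.validate()
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    individuals = [f"ind{i + 1:02d}" for i in range(n_individuals)]
    ind_w = np.asarray(
        _INDIVIDUAL_WEIGHTS[:n_individuals]
        if n_individuals <= len(_INDIVIDUAL_WEIGHTS)
        else np.ones(n_individuals),
        dtype=float,
    )
    ind_w /= ind_w.sum()
    head_lengths = {
        ind: float(config.head_length * (1.0 + 0.04 * rng.standard_normal()))
        for ind in individuals
    }
    e_hl = config.esophagus_distance / config.head_length

    trials = []
    metadata = []
    foods = list(_FOOD_WEIGHTS)
    food_w = np.array([_FOOD_WEIGHTS[f] for f in foods])
    for i in range(n_trials):
        ind = individuals[int(rng.choice(n_individuals, p=ind_w))]
        food = foods[int(rng.choice(len(foods), p=food_w))]
        include = bool(rng.random() < config.include_swallowing_p)
        hl_i = head_lengths[ind]
        cfg_i = dataclasses.replace(
            config, head_length=hl_i, esophagus_distance=e_hl * hl_i
        )
        trial_seed = int(rng.integers(2**31))
        trial_id = f"t{i + 1:03d}"
        trial = generate_trial(cfg_i, seed=trial_seed,
                               include_swallowing=include, trial_id=trial_id)
        trials.append(trial)
        metadata.append(
            TrialMetadata(
                trial_id=trial_id,
                individual_id=ind,
                food_type=food,
                head_length=hl_i,
                frame_rate=config.frame_rate,
                includes_esophageal=include,
            )
        )

    landmarks = {}
    for ind in individuals:
        e_mm = e_hl * head_lengths[ind]
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack(
            [np.full(12, e_mm), 6.0 * np.sin(theta), 6.0 * np.cos(theta)]
        )
        tilt = np.deg2rad(rng.uniform(-2.0, 2.0))  # slight off-perpendicular tilt
        rot = np.array(
            [[np.cos(tilt), -np.sin(tilt), 0.0],
             [np.sin(tilt), np.cos(tilt), 0.0],
             [0.0, 0.0, 1.0]]
        )
        center = ring.mean(axis=0)
        ring = (ring - center) @ rot.T + center
        ring += 0.15 * rng.standard_normal(ring.shape)
        landmarks[ind] = ring
    return SyntheticStudy(trials, metadata, landmarks, config, int(seed))


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write a study to disk in the pipeline's input formats.

    Produces ``metadata.csv``, per-trial ``<id>_food.csv`` (wide marker
    dialect, anatomical mm) and ``<id>_dofs.csv``, per-individual
    ``<id>_esophagus.csv`` landmark files, a ``truth.json`` and a ready
    ``study.yaml``; returns the path to the YAML.
    """
    import json

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for md in study.metadata:
        rows.append(
            {
                "trial_id": md.trial_id,
                "individual_id": md.individual_id,
                "food_type": md.food_type,
                "head_length": md.head_length,
                "frame_rate": md.frame_rate,
                "includes_esophageal": md.includes_esophageal,
            }
        )
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False, float_format="%.17g")

    for trial in study.trials:
        n = len(trial.positions_mm)
        df = pd.DataFrame(
            {
                "frame": np.arange(n),
                "food_X": trial.positions_mm[:, 0],
                "food_Y": trial.positions_mm[:, 1],
                "food_Z": trial.positions_mm[:, 2],
            }
        )
        df.to_csv(out / f"{trial.trial_id}_food.csv", index=False, float_format="%.17g")
        dof_df = pd.DataFrame({"frame": np.arange(n), **trial.dofs})
        dof_df.to_csv(out / f"{trial.trial_id}_dofs.csv", index=False, float_format="%.17g")

    for ind, ring in study.landmarks.items():
        pd.DataFrame(ring, columns=["x", "y", "z"]).to_csv(
            out / f"{ind}_esophagus.csv", index=False, float_format="%.17g"
        )

    truth = {
        "seed": study.seed,
        "trials": {t.trial_id: _jsonable(t.truth) for t in study.trials},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    cfg = {
        "trial_table": "metadata.csv",
        "data_dir": ".",
        "esophagus_landmarks": {
            ind: f"{ind}_esophagus.csv" for ind in study.landmarks
        },
        "breakpoint": {"trim": 0.02, "n_perm": 10_000, "seed": study.seed, "alpha": 1e-3},
        "synchrony": {"max_lag": 30, "spacer": 30},
    }
    yaml_path = out / "study.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return yaml_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# raw marker scenes


def generate_marker_scene(
    config: GeneratorConfig | None = None,
    seed: object = 0,
    n_frames: int = 120,
    occlusions: dict[str, tuple[int, int]] | None = None,
) -> tuple[MarkerTrackSet, dict[str, RigidMotionSeries], dict[str, list[str]]]:
    """Six marked cranial bodies plus a food marker, with known motions.

    Each body carries four markers (~30 mm spread). The neurocranium
    swims through world space; the other bodies move relative to it with
    smooth oscillatory rotations/translations that are the identity at
    frame 0, so the returned truth series map frame-0 marker positions to
    each frame directly. Gaussian noise of ``config.marker_noise`` mm is
    added to every visible coordinate; ``occlusions`` hides a marker over
    a half-open frame range.

    Returns ``(tracks, true_motions, body_definitions)``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / config.frame_rate

    def osc_transform(amp_deg: float, axis: np.ndarray, trans_amp: np.ndarray,
                      f_hz: float, ti: float) -> RigidTransform:
        ang = np.deg2rad(amp_deg) * np.sin(2 * np.pi * f_hz * ti)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        return RigidTransform(R, trans_amp * np.sin(2 * np.pi * f_hz * ti))

    body_params = {}
    centers = {}
    locals_ = {}
    body_def = {}
    tracks_clean = {}
    for bi, body in enumerate(_BODY_NAMES):
        centers[body] = rng.uniform(-40, 40, 3)
        pts = rng.uniform(-15, 15, (4, 3))
        locals_[body] = centers[body] + pts
        names = [f"{body}_m{j + 1}" for j in range(4)]
        body_def[body] = names
        body_params[body] = {
            "amp": 0.0 if body == "neurocranium" else rng.uniform(5, 15),
            "axis": rng.standard_normal(3),
            "trans": rng.uniform(-2, 2, 3) if body != "neurocranium" else np.zeros(3),
            "f": rng.uniform(1.0, 3.0),
        }
    neuro = {"amp": 4.0, "axis": rng.standard_normal(3),
             "trans": rng.uniform(-3, 3, 3), "f": 0.8}

    true_motion: dict[str, RigidMotionSeries] = {}
    for body in _BODY_NAMES:
        R = np.empty((n_frames, 3, 3))
        tr = np.empty((n_frames, 3))
        pts_world = np.empty((n_frames, 4, 3))
        p = body_params[body]
        for fidx in range(n_frames):
            T_n = osc_transform(neuro["amp"], neuro["axis"], neuro["trans"], neuro["f"], t[fidx])
            if body == "neurocranium":
                T_w = T_n
            else:
                T_rel = osc_transform(p["amp"], p["axis"], p["trans"], p["f"], t[fidx])
                T_w = T_n.compose(T_rel)
            R[fidx], tr[fidx] = T_w.rotation, T_w.translation
            pts_world[fidx] = T_w.apply(locals_[body])
        true_motion[body] = RigidMotionSeries(
            body, R, tr, np.ones(n_frames, dtype=bool), reference="world"
        )
        for j, name in enumerate(body_def[body]):
            tracks_clean[name] = pts_world[:, j, :]

    # food marker: smooth independent drift through the buccal region
    food = np.column_stack(
        [
            10 + 30 * (1 - np.exp(-t * 8)),
            3 * np.sin(2 * np.pi * 1.3 * t),
            2 * np.sin(2 * np.pi * 0.9 * t + 1.0),
        ]
    )
    tracks_clean["food"] = food

    tracks = {}
    for name, arr in tracks_clean.items():
        noisy = arr + config.marker_noise * rng.standard_normal(arr.shape)
        tracks[name] = noisy
    if occlusions:
        for name, (a, b) in occlusions.items():
            tracks[name][a:b] = np.nan
    return MarkerTrackSet(tracks), true_motion, body_def
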