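"""File formats: marker coordinate CSVs, trial tables, transforms, landmarks.

Coordinates are millimetres and time is frames everywhere in this module;
unit conversions (head lengths, seconds) happen only in
:mod:`gulpflow.trajectory`.

Two marker-CSV dialects are supported:

``wide``
    One row per frame, columns ``<marker>_X, <marker>_Y, <marker>_Z``
    (the common motion-tracking points-export layout).
``long``
    Columns ``frame, marker, x, y, z``, one row per marker per frame.

Missing samples are empty cells on disk and NaN rows (with an explicit gap
mask available) in memory — no sentinel coordinates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParseError, ValidationError

FOOD_TYPES = ("pellet", "squid", "worm")

_AXES = ("X", "Y", "Z")


# ---------------------------------------------------------------------------
# marker tracks


class MarkerTrackSet:
    """Time-indexed 3D coordinates for a set of named markers.

    Parameters
    ----------
    tracks
        Mapping from marker name to an ``(n_frames, 3)`` float array.
        Gap frames are rows of NaN (all three components NaN).
    """

    def __init__(self, tracks: Mapping[str, np.ndarray]):
        if not tracks:
            raise ValidationError("MarkerTrackSet requires at least one marker")
        lengths = {len(np.asarray(v)) for v in tracks.values()}
        if len(lengths) != 1:
            raise ValidationError(f"marker tracks have unequal lengths: {sorted(lengths)}")
        self._tracks: dict[str, np.ndarray] = {}
        for name, arr in tracks.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3:
                raise ValidationError(f"track {name!r} must be (n, 3), got {a.shape}")
            # a partially missing triplet is treated as a gap frame
            a = a.copy()
            a[np.isnan(a).any(axis=1)] = np.nan
            self._tracks[name] = a

    @property
    def markers(self) -> list[str]:
        return list(self._tracks)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self._tracks.values())))

    def get(self, marker: str) -> np.ndarray:
        return self._tracks[marker]

    def gap_mask(self, marker: str) -> np.ndarray:
        """Boolean mask, True where the marker is missing."""
        return np.isnan(self._tracks[marker]).any(axis=1)

    def __contains__(self, marker: str) -> bool:
        return marker in self._tracks

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerTrackSet):
            return NotImplemented
        if sorted(self.markers) != sorted(other.markers):
            return False
        return all(
            np.array_equal(self._tracks[m], other._tracks[m], equal_nan=True)
            for m in self.markers
        )


def read_points_csv(path: str | Path, dialect: str = "wide") -> MarkerTrackSet:
    """Read a marker-coordinate CSV into a :class:`MarkerTrackSet`.

    Frame index starts at 0; missing cells become explicit gaps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc

    if dialect == "wide":
        return _points_from_wide(df, path)
    if dialect == "long":
        return _points_from_long(df, path)
    raise ValidationError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _points_from_wide(df: pd.DataFrame, path: Path) -> MarkerTrackSet:
    cols = [c for c in df.columns if c.lower() not in ("frame", "time")]
    groups: dict[str, dict[str, str]] = {}
    for col in cols:
        if "_" not in col:
            raise FormatError(f"{path}: column {col!r} is not of the form <marker>_<X|Y|Z>")
        marker, _, axis = col.rpartition("_")
        if axis.upper() not in _AXES:
            raise FormatError(f"{path}: column {col!r} has axis suffix {axis!r}")
        groups.setdefault(marker, {})[axis.upper()] = col
    tracks = {}
    for marker, axes in groups.items():
        missing = [a for a in _AXES if a not in axes]
        if missing:
            raise FormatError(
                f"{path}: marker {marker!r} is missing column(s) "
                + ", ".join(f"{marker}_{a}" for a in missing)
            )
        block = df[[axes[a] for a in _AXES]]
        if not all(pd.api.types.is_numeric_dtype(t) for t in block.dtypes):
            bad = [c for c, t in zip(block.columns, block.dtypes) if not pd.api.types.is_numeric_dtype(t)]
            raise ParseError(f"{path}: non-numeric values in column(s) {bad}")
        tracks[marker] = block.to_numpy(dtype=float)
    if not tracks:
        raise FormatError(f"{path}: no marker coordinate columns found")
    return MarkerTrackSet(tracks)


def _points_from_long(df: pd.DataFrame, path: Path) -> MarkerTrackSet:
    need = {"frame", "marker", "x", "y", "z"}
    have = {c.lower() for c in df.columns}
    if not need <= have:
        raise FormatError(f"{path}: long dialect requires columns {sorted(need)}")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    n = int(df["frame"].max()) + 1 if len(df) else 0
    tracks = {}
    for marker, sub in df.groupby("marker", sort=True):
        arr = np.full((n, 3), np.nan)
        idx = sub["frame"].to_numpy(dtype=int)
        arr[idx] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        tracks[str(marker)] = arr
    if not tracks:
        raise FormatError(f"{path}: long dialect file contains no rows")
    return MarkerTrackSet(tracks)


def write_points_csv(tracks: MarkerTrackSet, path: str | Path, dialect: str = "wide") -> None:
    """Write marker tracks; round-trips coordinates at full float precision."""
    path = Path(path)
    if dialect == "wide":
        data = {"frame": np.arange(tracks.n_frames)}
        for m in tracks.markers:
            arr = tracks.get(m)
            for j, axis in enumerate(_AXES):
                data[f"{m}_{axis}"] = arr[:, j]
        df = pd.DataFrame(data)
        df.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "long":
        rows = []
        for m in tracks.markers:
            arr = tracks.get(m)
            ok = ~np.isnan(arr).any(axis=1)
            for i in np.nonzero(ok)[0]:
                rows.append((int(i), m, *arr[i]))
        df = pd.DataFrame(rows, columns=["frame", "marker", "x", "y", "z"])
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# trial metadata


@dataclass(frozen=True)
class TrialMetadata:
    """One feeding trial: who, what food, and the scaling constants."""

    trial_id: str
    individual_id: str
    food_type: str
    head_length: float  # mm
    frame_rate: float  # frames/s
    includes_esophageal: bool = False

    def __post_init__(self):
        if self.food_type not in FOOD_TYPES:
            raise ValidationError(
                f"unknown food type {self.food_type!r}; allowed: {', '.join(FOOD_TYPES)}"
            )
        if not self.head_length > 0:
            raise ValidationError(f"head_length must be > 0, got {self.head_length}")
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")


_TRIAL_ALIASES = {
    "individual": "individual_id",
    "food": "food_type",
    "head_length_mm": "head_length",
    "fps": "frame_rate",
}


def read_trial_table(path: str | Path) -> list[TrialMetadata]:
    """Read a per-trial metadata CSV into a list of :class:`TrialMetadata`.

    Column aliases ``individual``, ``food``, ``head_length_mm`` and ``fps``
    are accepted. ``trial_id`` defaults to ``t001``..; ``head_length`` to
    70 mm; ``frame_rate`` to 300 frames/s; ``includes_esophageal`` to False.
    An empty table yields an empty list.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={c: _TRIAL_ALIASES.get(c.lower(), c.lower()) for c in df.columns})
    if len(df) == 0:
        return []
    for col in ("individual_id", "food_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    trials = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        trial_id = str(d.get("trial_id", "") or f"t{i + 1:03d}")
        if trial_id in seen:
            raise ValidationError(f"{path}: duplicate trial_id {trial_id!r}")
        seen.add(trial_id)
        trials.append(
            TrialMetadata(
                trial_id=trial_id,
                individual_id=str(d["individual_id"]),
                food_type=str(d["food_type"]).strip().lower(),
                head_length=float(d.get("head_length", 70.0) or 70.0),
                frame_rate=float(d.get("frame_rate", 300.0) or 300.0),
                includes_esophageal=_as_bool(d.get("includes_esophageal", False)),
            )
        )
    return trials


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "t", "y")
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return False
    return bool(v)


def expand_trial_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand a per-individual x food-type count table into per-trial rows.

    Expects columns ``individual``, ``food_type``, ``trials`` and
    ``with_esophageal`` (trials whose recording includes esophageal
    transport). Returns a per-trial frame suitable for
    :func:`read_trial_table` after writing to CSV.
    """
    rows = []
    k = 0
    for rec in counts.itertuples(index=False):
        d = rec._asdict()
        n = int(d["trials"])
        n_eso = int(d["with_esophageal"])
        if n_eso > n:
            raise ValidationError("with_esophageal count exceeds trial count")
        for j in range(n):
            k += 1
            rows.append(
                {
                    "trial_id": f"t{k:03d}",
                    "individual_id": d["individual"],
                    "food_type": d["food_type"],
                    "includes_esophageal": j < n_eso,
                }
            )
    return pd.DataFrame(rows)


def trial_counts(trials: Iterable[TrialMetadata]) -> dict:
    """Summary accounting: totals and per-individual/food breakdowns."""
    trials = list(trials)
    by_ind: dict[str, int] = {}
    by_food: dict[str, int] = {}
    for t in trials:
        by_ind[t.individual_id] = by_ind.get(t.individual_id, 0) + 1
        by_food[t.food_type] = by_food.get(t.food_type, 0) + 1
    return {
        "total": len(trials),
        "with_esophageal": sum(t.includes_esophageal for t in trials),
        "by_individual": by_ind,
        "by_food_type": by_food,
    }


def load_reference_trial_table() -> list[TrialMetadata]:
    """Trial accounting of the channel catfish feeding study this pipeline
    models: 25 trials over three individuals and three food types, 16 of
    which include esophageal transport. Head lengths are nominal."""
    ref = importlib.resources.files("gulpflow") / "data" / "trial_accounting.csv"
    with importlib.resources.as_file(ref) as p:
        return read_trial_table(p)


# ---------------------------------------------------------------------------
# rigid transforms and landmark files


def read_transforms_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-frame 4x4 rigid transforms.

    Layout: columns ``frame, body, m00..m33`` (16 row-major entries).
    Returns ``{body: (n_frames, 4, 4)}`` with NaN matrices at gap frames.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cells = [f"m{i}{j}" for i in range(4) for j in range(4)]
    need = {"frame", "body", *cells}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: transforms CSV requires columns {sorted(need)}")
    n = int(df["frame"].max()) + 1 if len(df) else 0
    out = {}
    for body, sub in df.groupby("body", sort=True):
        arr = np.full((n, 4, 4), np.nan)
        idx = sub["frame"].to_numpy(dtype=int)
        arr[idx] = sub[cells].to_numpy(dtype=float).reshape(-1, 4, 4)
        out[str(body)] = arr
    return out


def write_transforms_csv(transforms: Mapping[str, np.ndarray], path: str | Path) -> None:
    cells = [f"m{i}{j}" for i in range(4) for j in range(4)]
    rows = []
    for body in sorted(transforms):
        arr = np.asarray(transforms[body], dtype=float)
        for f in range(len(arr)):
            if np.isnan(arr[f]).any():
                continue
            rows.append({"frame": f, "body": body, **dict(zip(cells, arr[f].ravel()))})
    pd.DataFrame(rows, columns=["frame", "body", *cells]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_landmarks_csv(path: str | Path) -> np.ndarray:
    """Read an (n, 3) landmark point set (columns x, y, z; mm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if not {"x", "y", "z"} <= set(df.columns):
        raise FormatError(f"{path}: landmarks CSV requires columns x, y, z")
    return df[["x", "y", "z"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# study configuration


@dataclass
class BreakpointSettings:
    """Structural-change test settings for the study driver.

    The trim fraction defaults to 0.02 at study level: the capture phase of a
    feeding trial occupies only a few per cent of the recorded frames, so a
    wider trim would exclude the capture-to-handling transition from the
    candidate window. The bare test functions default to the conventional
    0.15 for general use.
    """

    trim: float = 0.02
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 1e-3
    series: str = "rc_velocity"  # or "speed"

    def validate(self) -> None:
        if not 0 < self.trim < 0.5:
            raise ConfigError(f"trim fraction must be in (0, 0.5), got {self.trim}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.series not in ("rc_velocity", "speed"):
            raise ConfigError("series must be 'rc_velocity' or 'speed'")


@dataclass
class SynchronySettings:
    max_lag: int = 30  # frames; 100 ms at 300 frames/s
    spacer: int = 30  # missing-value gap between concatenated trials
    min_pairs: int = 10

    def validate(self) -> None:
        if self.max_lag < 1:
            raise ConfigError("max_lag must be >= 1")
        if self.spacer < self.max_lag:
            raise ConfigError("spacer gap must be >= max_lag so lags never span trials")


@dataclass
class StudyConfig:
    """Paths and settings for a full study run."""

    trial_table: Path
    data_dir: Path
    esophagus_landmarks: dict[str, Path] = field(default_factory=dict)
    esophagus_distance_mm: dict[str, float] = field(default_factory=dict)
    breakpoint: BreakpointSettings = field(default_factory=BreakpointSettings)
    synchrony: SynchronySettings = field(default_factory=SynchronySettings)
    dialect: str = "wide"

    def validate(self) -> None:
        if not Path(self.trial_table).exists():
            raise ConfigError(f"trial table not found: {self.trial_table}")
        if not Path(self.data_dir).is_dir():
            raise ConfigError(f"data directory not found: {self.data_dir}")
        for ind, p in self.esophagus_landmarks.items():
            if not Path(p).exists():
                raise ConfigError(f"esophagus landmarks for {ind!r} not found: {p}")
        self.breakpoint.validate()
        self.synchrony.validate()


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a study config YAML; relative paths resolve against the file."""
    import yaml

    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def _p(v):
        q = Path(v)
        return q if q.is_absolute() else base / q

    cfg = StudyConfig(
        trial_table=_p(raw.get("trial_table", "metadata.csv")),
        data_dir=_p(raw.get("data_dir", ".")),
        esophagus_landmarks={
            k: _p(v) for k, v in (raw.get("esophagus_landmarks") or {}).items()
        },
        esophagus_distance_mm={
            k: float(v) for k, v in (raw.get("esophagus_distance_mm") or {}).items()
        },
        breakpoint=BreakpointSettings(**(raw.get("breakpoint") or {})),
        synchrony=SynchronySettings(**(raw.get("synchrony") or {})),
        dialect=raw.get("dialect", "wide"),
    )
    cfg.validate()
    return cfg
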