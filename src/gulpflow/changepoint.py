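"""Single-breakpoint structural-change detection on food velocity.

The capture-to-handling transition of a feeding trial shows up as an
abrupt mean shift in the food's velocity series (high decelerating suction
speeds, then near-zero handling speeds). We scan all admissible split
points with a Chow-type F statistic for a one-mean vs two-means model and
take the supremum (sup-F). Significance comes from a seeded permutation
test by default; an asymptotic mode based on the limiting Brownian-bridge
process is available as an alternative.

With the esophageal-plane crossing this yields the three-phase
segmentation: capture (before the breakpoint), handling (breakpoint to
sphincter) and swallowing/esophageal transport (past the sphincter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientLengthError, NoBreakpointError, ValidationError
from .trajectory import Trajectory

_MIN_N = 8


@dataclass(frozen=True)
class FSeries:
    """F statistic at every admissible split of a series.

    ``candidates[i]`` is the size of the first segment (equivalently the
    0-based index of the first frame of the second regime); candidates span
    ``ceil(n*trim) .. n - ceil(n*trim)``.
    """

    candidates: np.ndarray  # (m,) int
    f_values: np.ndarray  # (m,) float, >= 0 (inf when the split is exact)
    trim: float
    n: int


def chow_f_series(y: np.ndarray, trim: float = 0.15) -> FSeries:
    """Chow F statistic for a mean shift at every trimmed candidate split.

    For a split after ``k`` observations,
    ``F_k = (RSS0 - RSS_k) / (RSS_k / (n - 2))`` where RSS0 is the residual
    sum of squares around one global mean and RSS_k around separate means
    of the two segments. A constant series has F = 0 everywhere; an exact
    two-level split gives F = inf. F is invariant to shifting or (positive)
    scaling of the series.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if not 0 < trim < 0.5:
        raise ValidationError(f"trim must be in (0, 0.5), got {trim}")
    if n < _MIN_N:
        raise InsufficientLengthError(f"need >= {_MIN_N} observations, got {n}")
    if np.isnan(y).any():
        raise ValidationError("series contains NaN; impute or truncate upstream")
    m = math.ceil(n * trim)
    lo, hi = m, n - m  # candidate first-segment sizes, inclusive
    if lo < 1 or hi < lo:
        raise InsufficientLengthError(f"trimmed candidate range empty for n={n}, trim={trim}")
    candidates = np.arange(lo, hi + 1)
    f = _f_scan(y[None, :], candidates)[0]
    return FSeries(candidates, f, trim, n)


def _f_scan(Y: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Vectorized F values for each row of ``Y`` at each candidate split."""
    B, n = Y.shape
    # center each row: F is shift-invariant and centering avoids the
    # catastrophic cancellation of css - cs^2/k for offset series
    scale = np.maximum(np.abs(Y).max(axis=1), 1.0)
    Y = Y - Y.mean(axis=1, keepdims=True)
    cs = np.cumsum(Y, axis=1)
    css = np.cumsum(Y * Y, axis=1)
    tot = cs[:, -1]
    rss0 = css[:, -1]  # rows are centered, so RSS0 is just the sum of squares
    k = candidates  # (m,)
    cs_k = cs[:, k - 1]
    # between-group identity: RSS0 - RSS_k = k m1^2 + (n-k) m2^2 for the
    # centered series — no large-number cancellation for small F values
    m1 = cs_k / k
    m2 = (tot[:, None] - cs_k) / (n - k)
    between = k * m1**2 + (n - k) * m2**2
    rssk = np.clip(rss0[:, None] - between, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = between / (rssk / (n - 2))
    # a constant series leaves only rounding residue after centering
    const = rss0 <= n * (1e-12 * scale) ** 2
    f = np.where(const[:, None], 0.0, f)
    f = np.where((rssk <= 0) & ~const[:, None], np.inf, f)
    return np.clip(f, 0.0, None)


@dataclass(frozen=True)
class BreakpointResult:
    """Outcome of the sup-F test on one series."""

    sup_f: float
    breakpoint_index: int  # first frame of the post-break regime
    p_value: float
    method: str  # "permutation" or "asymptotic"
    series_used: str  # "rc_velocity" or "speed"
    n_perm_used: int = 0
    f_series: FSeries | None = None


def sup_f_test(
    y: np.ndarray,
    trim: float = 0.15,
    n_perm: int = 10_000,
    seed: int = 0,
    series_used: str = "rc_velocity",
    method: str = "permutation",
    early_stop_alpha: float | None = None,
    batch: int = 2_000,
) -> BreakpointResult:
    """Sup-F structural-change test with permutation significance.

    The breakpoint estimate is the argmax of the F scan (ties broken to the
    earliest candidate). The permutation p-value is
    ``(1 + #{permuted sup-F >= observed}) / (1 + n_perm)``, deterministic
    given ``seed``. With ``early_stop_alpha`` set, permutation stops as
    soon as enough exceedances have accumulated that the final p-value
    could not fall below that threshold (futility stop); the p-value is
    then computed from the permutations actually run.
    """
    fs = chow_f_series(y, trim=trim)
    imax = int(np.argmax(fs.f_values))  # argmax returns the first maximum
    sup_f = float(fs.f_values[imax])
    bp = int(fs.candidates[imax])

    if method == "permutation":
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(seed)
        hits = 0
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            Y = rng.permuted(np.broadcast_to(y, (b, len(y))), axis=1)
            sup = _f_scan(Y, fs.candidates).max(axis=1)
            hits += int(np.count_nonzero(sup >= sup_f))
            done += b
            if early_stop_alpha is not None and (1 + hits) / (1 + n_perm) > early_stop_alpha:
                break
        p = (1 + hits) / (1 + done)
        n_used = done
    elif method == "asymptotic":
        p = _asymptotic_p(sup_f, fs.trim, seed=seed)
        n_used = 0
    else:
        raise ValidationError(f"unknown method {method!r}")
    return BreakpointResult(
        sup_f=sup_f,
        breakpoint_index=bp,
        p_value=float(min(max(p, 0.0), 1.0)),
        method=method,
        series_used=series_used,
        n_perm_used=n_used,
        f_series=fs,
    )


def _asymptotic_p(sup_f: float, trim: float, seed: int = 0,
                  n_sim: int = 20_000, grid: int = 400) -> float:
    """Asymptotic null tail probability for the sup-F statistic.

    Under the null the sup-F process converges to
    ``sup_{s in [h, 1-h]} B(s)^2 / (s (1 - s))`` with ``B`` a Brownian
    bridge; the tail is evaluated by seeded Monte-Carlo simulation of that
    limit on a time grid.
    """
    if not np.isfinite(sup_f):
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F5]))
    s = np.linspace(0.0, 1.0, grid + 1)[1:-1]
    sups = np.empty(n_sim)
    chunk = 2_000
    for a in range(0, n_sim, chunk):
        b = min(chunk, n_sim - a)
        incr = rng.standard_normal((b, grid)) / np.sqrt(grid)
        W = np.cumsum(incr, axis=1)  # W(s_j), j = 1..grid
        Bb = W[:, :-1] - s[None, :] * W[:, -1][:, None]  # bridge at interior s
        q = Bb**2 / (s * (1 - s))[None, :]
        sel = (s >= trim) & (s <= 1 - trim)
        sups[a : a + b] = q[:, sel].max(axis=1)
    return float((1 + np.count_nonzero(sups >= sup_f)) / (1 + n_sim))


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open frame ranges of the three transport phases.

    ``capture = [0, breakpoint)``, ``handling = [breakpoint, crossing)``,
    ``swallowing = [crossing, n)``; swallowing is absent when the food
    never reaches the esophageal plane (rc_norm never >= 1).
    """

    breakpoint: int
    crossing: int | None
    n_frames: int
    breakpoint_rc_norm: float
    breakpoint_position: np.ndarray  # (3,) anatomical position (HL) at the break
    breakpoint_flagged: bool = False  # True when the break frame was a gap

    def range_of(self, phase: str) -> tuple[int, int] | None:
        end_handling = self.crossing if self.crossing is not None else self.n_frames
        if phase == "capture":
            return (0, self.breakpoint)
        if phase == "handling":
            return (self.breakpoint, end_handling)
        if phase == "swallowing":
            if self.crossing is None:
                return None
            return (self.crossing, self.n_frames)
        raise ValidationError(f"unknown phase {phase!r}")

    @property
    def has_swallowing(self) -> bool:
        return self.crossing is not None


def segment_trial(
    traj: Trajectory,
    bp: BreakpointResult,
    alpha: float = 1e-3,
) -> PhaseSegmentation:
    """Assemble the three-phase segmentation from breakpoint + crossing.

    Requires strong support for the breakpoint (``p < alpha``; the study
    default 1e-3 is half a Bonferroni-corrected 0.05 over 25 trials),
    otherwise the trial is refused and excluded from phase pooling. The
    esophageal crossing is the first frame with rc_norm >= 1.
    """
    if bp.p_value >= alpha:
        raise NoBreakpointError(
            f"breakpoint not supported (p = {bp.p_value:.4g} >= alpha = {alpha:g})"
        )
    n = len(traj)
    if not 0 < bp.breakpoint_index < n:
        raise ValidationError(f"breakpoint {bp.breakpoint_index} outside trial of {n}")
    reached = np.nonzero((traj.rc_norm >= 1.0) & ~traj.gaps)[0]
    crossing = int(reached[0]) if len(reached) else None
    if crossing is not None and crossing <= bp.breakpoint_index:
        raise ValidationError(
            "esophageal crossing precedes the breakpoint; trial cannot be segmented"
        )
    rc, pos, flagged = breakpoint_location(traj, bp)
    return PhaseSegmentation(
        breakpoint=bp.breakpoint_index,
        crossing=crossing,
        n_frames=n,
        breakpoint_rc_norm=rc,
        breakpoint_position=pos,
        breakpoint_flagged=flagged,
    )


def breakpoint_location(traj: Trajectory, bp: BreakpointResult) -> tuple[float, np.ndarray, bool]:
    """Food location (rc_norm and 3D anatomical position, HL) at the break.

    If the breakpoint frame is a gap, the nearest non-gap frame is used and
    the result flagged.
    """
    i = bp.breakpoint_index
    if not 0 <= i < len(traj):
        raise ValidationError(f"breakpoint frame {i} outside trial")
    flagged = False
    if traj.gaps[i]:
        ok = np.nonzero(~traj.gaps)[0]
        if len(ok) == 0:
            raise ValidationError("trajectory has no usable frames")
        i = int(ok[np.argmin(np.abs(ok - i))])
        flagged = True
    return float(traj.rc_norm[i]), traj.positions[i].copy(), flagged
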