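"""Lagged cross-correlation of food transport and cranial motion.

Per phase, the food's rostrocaudal velocity is correlated against the
velocity of each cranial degree of freedom (hyoid retraction, girdle
retraction, hypaxial shortening, mouth opening) across a range of lags.
Trials are concatenated with missing-value spacers at least as long as the
maximum lag, so a lagged product never pairs samples from different
trials, and every trial is constrained to share one common lag — the
question being whether food motion consistently follows cranial expansion.

Positive lag means the food signal follows the cranial signal.

Also here: the across-trial regression of breakpoint location on
individual and food type (dummy-coded OLS with partial F-tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DOF_IDS = (
    "hyoid_retraction",
    "girdle_retraction",
    "hypaxial_shortening",
    "mouth_opening",
)


@dataclass(frozen=True)
class ConcatSeries:
    """Trial series concatenated with NaN spacers of length ``gap``."""

    values: np.ndarray
    boundaries: list[tuple[int, int]]  # half-open [start, stop) per trial
    gap: int


def concat_with_spacers(series: Sequence[np.ndarray], gap: int) -> ConcatSeries:
    """Concatenate per-trial series with ``gap`` missing values between them."""
    if gap < 0:
        raise ValidationError("spacer gap must be >= 0")
    if not series:
        raise ValidationError("no series to concatenate")
    parts = []
    boundaries = []
    pos = 0
    spacer = np.full(gap, np.nan)
    for i, s in enumerate(series):
        s = np.asarray(s, dtype=float).ravel()
        if i > 0:
            parts.append(spacer)
            pos += gap
        parts.append(s)
        boundaries.append((pos, pos + len(s)))
        pos += len(s)
    return ConcatSeries(np.concatenate(parts), boundaries, gap)


@dataclass(frozen=True)
class CrossCorrelogram:
    """Pearson correlation of two series as a function of lag.

    ``r[i]`` pairs ``y_t`` with ``x_{t + lags[i]}`` over pairwise-complete
    indices; x is the food signal, y the cranial signal, so a positive best
    lag means food follows cranial motion. Lags with fewer complete pairs
    than the floor, or with zero variance in either member, carry NaN and
    are listed in ``dropped_lags``.
    """

    lags: np.ndarray  # (2L+1,) int
    r: np.ndarray  # (2L+1,)
    n_pairs: np.ndarray  # (2L+1,) int
    best_lag: int
    frame_rate: float
    dropped_lags: list[int] = field(default_factory=list)

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @property
    def best_r(self) -> float:
        return float(self.r[np.nonzero(self.lags == self.best_lag)[0][0]])

    @property
    def best_r2(self) -> float:
        return self.best_r**2

    @property
    def best_lag_ms(self) -> float:
        return self.best_lag / self.frame_rate * 1e3


def lagged_correlation(
    x: ConcatSeries | np.ndarray,
    y: ConcatSeries | np.ndarray,
    max_lag: int,
    frame_rate: float,
    min_pairs: int = 10,
) -> CrossCorrelogram:
    """Cross-correlogram of x (food) against y (cranial) over [-L, L].

    The best lag maximizes the squared correlation; ties break toward the
    smaller absolute (then signed) lag. Correlation at every lag is
    invariant to linear rescaling of either series.
    """
    if isinstance(x, ConcatSeries):
        if isinstance(y, ConcatSeries) and (x.gap != y.gap or x.gap < max_lag):
            raise ValidationError(
                f"spacer gap {x.gap} must be >= max_lag {max_lag} and equal in both series"
            )
        xv = x.values
    else:
        xv = np.asarray(x, dtype=float).ravel()
    yv = y.values if isinstance(y, ConcatSeries) else np.asarray(y, dtype=float).ravel()
    if len(xv) != len(yv):
        raise ValidationError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if max_lag < 1:
        raise ValidationError("max_lag must be >= 1")

    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(len(lags), np.nan)
    n_pairs = np.zeros(len(lags), dtype=int)
    dropped = []
    n = len(xv)
    for i, lag in enumerate(lags):
        if abs(int(lag)) >= n:
            dropped.append(int(lag))
            continue
        if lag >= 0:
            yy = yv[: n - lag]
            xx = xv[lag:]
        else:
            yy = yv[-lag:]
            xx = xv[: n + lag]
        ok = np.isfinite(xx) & np.isfinite(yy)
        n_pairs[i] = int(ok.sum())
        if n_pairs[i] < min_pairs:
            dropped.append(int(lag))
            continue
        a, b = xx[ok], yy[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            dropped.append(int(lag))
            continue
        r[i] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    if not np.isfinite(r).any():
        raise ValidationError("no lag has enough complete, non-constant pairs")
    r2 = np.where(np.isfinite(r), r**2, -np.inf)
    best = r2.max()
    tied = np.nonzero(r2 >= best - 1e-15)[0]
    order = np.lexsort((lags[tied], np.abs(lags[tied])))
    best_lag = int(lags[tied[order[0]]])
    return CrossCorrelogram(lags, r, n_pairs, best_lag, frame_rate, dropped)


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score ignoring NaN; a constant series comes back all-NaN (flagged
    downstream as zero-variance)."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if sd == 0 or not np.isfinite(sd):
        return np.full_like(x, np.nan)
    return (x - mu) / sd


def phase_synchrony(
    trials: Sequence[Mapping],
    phase: str,
    max_lag: int = 30,
    spacer: int | None = None,
    min_pairs: int = 10,
) -> dict[str, dict[str, CrossCorrelogram]]:
    """Common-lag cross-correlograms for one phase, per group and DOF.

    Each element of ``trials`` is a mapping with keys ``rc_velocity``
    (food, 1D array), ``dofs`` (mapping dof_id -> 1D array),
    ``segmentation`` (:class:`~gulpflow.changepoint.PhaseSegmentation`),
    ``frame_rate`` and ``individual_id``. Phase slices are extracted and
    z-scored per trial (amplitude varies across trials; correlation itself
    is scale-free but pooled concatenation is stabler on a common scale),
    then concatenated with spacers. Groups are the pooled study
    (``"all"``) plus each individual.
    """
    if spacer is None:
        spacer = max_lag
    if spacer < max_lag:
        raise ValidationError("spacer must be >= max_lag")
    slices: dict[str, list] = {}
    frame_rate = None
    for t in trials:
        seg = t["segmentation"]
        rng = seg.range_of(phase)
        if rng is None:
            continue
        a, b = rng
        if b - a < 2:
            continue
        frame_rate = t["frame_rate"]
        food = zscore(np.asarray(t["rc_velocity"], dtype=float)[a:b])
        entry = {"individual": t["individual_id"], "food": food, "dofs": {}}
        for dof, series in t["dofs"].items():
            entry["dofs"][dof] = zscore(np.asarray(series, dtype=float)[a:b])
        slices.setdefault("all", []).append(entry)
        slices.setdefault(t["individual_id"], []).append(entry)
    if "all" not in slices:
        raise ValidationError(f"phase {phase!r} absent from every trial")

    out: dict[str, dict[str, CrossCorrelogram]] = {}
    for group, entries in slices.items():
        dofs = sorted({d for e in entries for d in e["dofs"]})
        out[group] = {}
        for dof in dofs:
            usable = [e for e in entries if dof in e["dofs"]]
            x = concat_with_spacers([e["food"] for e in usable], spacer)
            y = concat_with_spacers([e["dofs"][dof] for e in usable], spacer)
            try:
                out[group][dof] = lagged_correlation(
                    x, y, max_lag, frame_rate, min_pairs=min_pairs
                )
            except ValidationError:
                continue  # e.g. all-constant slices; group/dof omitted
    return out


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of breakpoint location on categorical predictors."""

    params: pd.Series
    term_pvalues: dict[str, float]  # partial (type II) F-test p per term
    anova: pd.DataFrame | None
    n: int
    r_squared: float
    flags: list[str]


def breakpoint_regression(
    locations: Sequence[float],
    individual: Sequence[str],
    food: Sequence[str],
) -> RegressionResult:
    """Regress breakpoint rc_norm on individual and food type.

    Both predictors enter as dummy-coded fixed-effect categorical terms
    (no interaction); each term is assessed with a partial (type II)
    F-test. Terms with a single observed level, or confounded with the
    design's rank deficiency, are flagged untestable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "rc": np.asarray(locations, dtype=float),
            "individual": list(individual),
            "food": list(food),
        }
    ).dropna()
    n = len(df)
    flags: list[str] = []
    terms = []
    for term in ("individual", "food"):
        if df[term].nunique() >= 2:
            terms.append(f"C({term})")
        else:
            flags.append(f"{term}: single level, untestable")
    if n < len(terms) + 2 or not terms:
        flags.append("insufficient data for regression")
        return RegressionResult(pd.Series(dtype=float), {}, None, n, float("nan"), flags)

    model = smf.ols("rc ~ " + " + ".join(terms), data=df)
    fit = model.fit()
    if fit.df_resid <= 0 or np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        flags.append("rank-deficient design (confounded levels); term tests unreliable")
    term_p: dict[str, float] = {}
    anova = None
    if fit.df_resid > 0:
        if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0):
            # zero residual: partial F is 0/0; treat terms as uninformative
            flags.append("zero residual variance; term p-values undefined")
            term_p = {t.strip("C()"): float("nan") for t in terms}
        else:
            anova = sm.stats.anova_lm(fit, typ=2)
            for t in terms:
                name = t  # anova_lm indexes by the formula term
                term_p[t[2:-1]] = float(anova.loc[name, "PR(>F)"])
    return RegressionResult(
        params=fit.params,
        term_pvalues=term_p,
        anova=anova,
        n=n,
        r_squared=float(fit.rsquared) if np.isfinite(fit.rsquared) else float("nan"),
        flags=flags,
    )
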