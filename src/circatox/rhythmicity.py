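"""Rhythmicity statistic (RS), free-running period and actograms.

The robustness of a fly's circadian locomotor rhythm is scored from the
autocorrelation function of its binned activity series: the correlogram peak
in the circadian lag window (default 18-30 h) is divided by the 95%
sampling-error confidence line of the correlogram, giving the rhythmicity
statistic RS. Flies with RS <= 1.5 are classed as arrhythmic; the free-running
period is the peak lag refined by parabolic interpolation, reported only for
rhythmic flies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dam_io import ActivitySeries, ActivitySeriesSet

logger = logging.getLogger(__name__)

RS_ARRHYTHMIC_THRESHOLD = 1.5
DEFAULT_SEARCH_WINDOW = (18.0, 30.0)

__all__ = [
    "Correlogram",
    "RhythmResult",
    "CohortSummary",
    "autocorrelate",
    "rhythm_statistic",
    "estimate_period",
    "score_series",
    "summarise_cohort",
    "actogram_matrix",
    "average_actogram",
    "RS_ARRHYTHMIC_THRESHOLD",
]


@dataclass(frozen=True)
class Correlogram:
    """Autocorrelation coefficients vs lag, with the 95% sampling-error line.

    ``coeffs[0] == 1`` by construction; ``ci95`` is the classical white-noise
    95% band ``2/sqrt(n_obs)`` unless overridden.
    """

    lags_h: np.ndarray
    coeffs: np.ndarray
    n_obs: int
    ci95: float

    def __post_init__(self) -> None:
        if len(self.lags_h) != len(self.coeffs):
            raise ValueError("lags and coeffs length mismatch")
        if self.ci95 <= 0:
            raise ValueError("ci95 must be positive")


@dataclass(frozen=True)
class RhythmResult:
    """RS score and classification for one fly."""

    fly_id: str | None
    rs: float
    rhythmic: bool
    period_h: float | None = None
    peak_lag_h: float | None = None


@dataclass(frozen=True)
class CohortSummary:
    """Rhythmicity summary for one genotype x age group."""

    genotype: str
    age_group: str
    n: int
    rhythmic_percent: float
    rs_mean: float
    rs_median: float
    period_mean_h: float | None
    period_median_h: float | None


def autocorrelate(
    series: ActivitySeries,
    max_lag_h: float = 60.0,
    ci95: float | None = None,
) -> Correlogram:
    """Correlogram of a mean-subtracted activity series.

    Uses the biased autocovariance estimator (divide by ``n_obs`` at every
    lag), which keeps the correlogram smooth at long lags; coefficients are
    normalised so lag 0 equals 1. The default confidence line is
    ``2/sqrt(n_obs)``.

    The series should be restricted to a single lighting segment (normally
    the DD free run) before calling; see :func:`circatox.dam_io.slice_segment`.
    """
    x = series.counts.astype(float)
    n = len(x)
    if n < 2:
        raise ValueError("series too short")
    max_lag_bins = int(np.floor(max_lag_h / series.bin_width_h))
    if max_lag_bins > n // 2:
        raise ValueError(
            f"max_lag {max_lag_h} h exceeds half the span ({series.span_h / 2:.1f} h)"
        )
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("no variance: series is constant")
    # biased estimator: sum_{t} x_t x_{t+k} / sum_t x_t^2
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag_bins]
    coeffs = full / denom
    lags = np.arange(max_lag_bins + 1) * series.bin_width_h
    if ci95 is None:
        ci95 = 2.0 / np.sqrt(n)
    return Correlogram(lags_h=lags, coeffs=coeffs, n_obs=n, ci95=float(ci95))


def _window_indices(cg: Correlogram, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    idx = np.nonzero((cg.lags_h >= lo - 1e-9) & (cg.lags_h <= hi + 1e-9))[0]
    if idx.size == 0:
        raise ValueError(f"no lags inside window {window}")
    return idx


def rhythm_statistic(
    cg: Correlogram,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    threshold: float = RS_ARRHYTHMIC_THRESHOLD,
    fly_id: str | None = None,
) -> RhythmResult:
    """RS = correlogram peak in the circadian window / the 95% confidence line.

    The peak is the maximum coefficient at lags inside ``search_window``
    (ties broken toward the smallest lag). A negative peak means no circadian
    recurrence at all, so RS is floored at 0. RS > ``threshold`` (strictly)
    classifies the fly as rhythmic; the threshold itself is arrhythmic.
    The free-running period accompanies rhythmic results only.
    """
    idx = _window_indices(cg, search_window)
    k = idx[int(np.argmax(cg.coeffs[idx]))]
    peak = float(cg.coeffs[k])
    rs = max(peak, 0.0) / cg.ci95
    rhythmic = rs > threshold
    period = estimate_period(cg, search_window) if rhythmic else None
    return RhythmResult(
        fly_id=fly_id,
        rs=float(rs),
        rhythmic=bool(rhythmic),
        period_h=period,
        peak_lag_h=float(cg.lags_h[k]),
    )


def estimate_period(
    cg: Correlogram, search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW
) -> float:
    """Free-running period: windowed correlogram peak, parabolically refined.

    Three-point parabolic interpolation around the discrete peak gives
    sub-bin resolution. A peak on the window boundary cannot be refined; the
    boundary lag is returned with a warning.
    """
    idx = _window_indices(cg, search_window)
    k = idx[int(np.argmax(cg.coeffs[idx]))]
    if k == idx[0] or k == idx[-1] or k == 0 or k == len(cg.coeffs) - 1:
        warnings.warn("correlogram peak on search-window boundary; period unrefined")
        return float(cg.lags_h[k])
    y0, y1, y2 = cg.coeffs[k - 1], cg.coeffs[k], cg.coeffs[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1, 1))
    step = cg.lags_h[1] - cg.lags_h[0]
    return float(cg.lags_h[k] + shift * step)


def score_series(
    series: ActivitySeries,
    max_lag_h: float = 60.0,
    search_window: tuple[float, float] = DEFAULT_SEARCH_WINDOW,
    ci95: float | None = None,
) -> RhythmResult:
    """Convenience: correlogram + RS for one fly's (segment-restricted) series."""
    cg = autocorrelate(series, max_lag_h=max_lag_h, ci95=ci95)
    return rhythm_statistic(cg, search_window=search_window, fly_id=series.fly_id)


def summarise_cohort(
    results: Sequence[RhythmResult], genotype: str = "", age_group: str = ""
) -> CohortSummary:
    """Cohort table row: rhythmic %, RS stats (all flies), period stats
    (rhythmic flies only)."""
    if not results:
        raise ValueError("no results to summarise")
    rs = np.array([r.rs for r in results])
    rhythmic = [r for r in results if r.rhythmic]
    periods = np.array([r.period_h for r in rhythmic if r.period_h is not None])
    return CohortSummary(
        genotype=genotype,
        age_group=age_group,
        n=len(results),
        rhythmic_percent=100.0 * len(rhythmic) / len(results),
        rs_mean=float(rs.mean()),
        rs_median=float(np.median(rs)),
        period_mean_h=float(periods.mean()) if periods.size else None,
        period_median_h=float(np.median(periods)) if periods.size else None,
    )


def _daily_matrix(series: ActivitySeries) -> np.ndarray:
    bins_per_day = series.schedule.day_length_h / series.bin_width_h
    if abs(bins_per_day - round(bins_per_day)) > 1e-9:
        raise ValueError("bin width does not divide the day")
    b = int(round(bins_per_day))
    n_days = len(series.counts) // b
    if n_days < 1:
        raise ValueError("series shorter than one day")
    return series.counts[: n_days * b].reshape(n_days, b).astype(float)


def actogram_matrix(series: ActivitySeries, double_plot: bool = True) -> np.ndarray:
    """Raster of daily activity profiles, one row per day.

    With ``double_plot`` (the standard actogram convention) row *r* shows day
    *r* followed by day *r + 1*, so each day appears twice — once on the right
    of a row and once on the left of the next — making phase drift easy to
    read by eye.
    """
    days = _daily_matrix(series)
    if not double_plot:
        return days
    if days.shape[0] < 2:
        raise ValueError("double-plotted actogram needs at least 2 complete days")
    return np.hstack([days[:-1], days[1:]])


def average_actogram(sset: ActivitySeriesSet, double_plot: bool = True) -> np.ndarray:
    """Element-wise mean of individual actogram matrices across flies."""
    if len(sset) == 0:
        raise ValueError("empty series set")
    mats = [actogram_matrix(s, double_plot=double_plot) for s in sset]
    shape0 = mats[0].shape
    for m in mats:
        if m.shape != shape0:
            raise ValueError("series are not aligned (unequal actogram shapes)")
    return np.mean(mats, axis=0)
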