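"""Clock-reporter bioluminescence analysis: detrending, FFT-NLLS cosine
fitting, relative-amplitude error and rhythmic/arrhythmic classification.

A per-luciferase trace is modelled, after removal of a linear baseline, as a
single cosine

    y(t) = A * cos(2*pi*(t - phi)/tau)

whose initial period/amplitude/phase come from the dominant discrete-Fourier
component inside the circadian window (default 18-30 h) and are refined by
nonlinear least squares. Rhythm robustness is summarised by the relative
amplitude error: the half-width of the 95% confidence interval of A divided
by A. Traces with rel-amp error > 0.7, or a period outside the window, are
called arrhythmic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import group_stats

logger = logging.getLogger(__name__)

RELAMP_ARRHYTHMIC_CUT = 0.7
DEFAULT_PERIOD_WINDOW = (18.0, 30.0)

__all__ = [
    "LuciferaseTrace",
    "LuciferaseFit",
    "detrend",
    "fft_nlls",
    "classify_trace",
    "group_profile",
    "compare_fit_parameters",
    "RELAMP_ARRHYTHMIC_CUT",
]


@dataclass
class LuciferaseTrace:
    """One fly's bioluminescence record: counts per second vs time (hours).

    ``dd_start_h`` marks where the constant-darkness portion begins (traces
    are typically recorded for 2-3 days of LD before release into DD).
    """

    fly_id: str
    times_h: np.ndarray
    cps: np.ndarray
    genotype: str | None = None
    dd_start_h: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.cps, dtype=float)
        if len(t) != len(y):
            raise ValueError("times and cps length mismatch")
        if len(t) >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (y < 0).any():
            raise ValueError("cps must be non-negative")
        self.times_h, self.cps = t, y

    def dd_portion(self) -> "LuciferaseTrace":
        """Restrict the trace to its DD portion (identity if unannotated)."""
        if self.dd_start_h is None:
            return self
        m = self.times_h >= self.dd_start_h - 1e-9
        return replace(self, times_h=self.times_h[m], cps=self.cps[m])


@dataclass(frozen=True)
class LuciferaseFit:
    """FFT-NLLS result for one trace."""

    fly_id: str
    period_h: float
    amplitude: float
    phase_h: float
    rel_amp_error: float
    rhythmic: bool
    baseline_intercept: float
    baseline_slope: float
    converged: bool = True


def detrend(trace: LuciferaseTrace) -> tuple[LuciferaseTrace, tuple[float, float]]:
    """Remove the ordinary-least-squares line from a trace.

    Returns the residual trace (which may dip below zero and is therefore
    stored without the non-negativity constraint) and the baseline
    ``(intercept, slope)``.
    """
    t, y = trace.times_h, trace.cps
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    out = replace(trace)
    out.cps = resid  # bypass __post_init__'s non-negativity check
    return out, (float(intercept), float(slope))


def _cosine(t: np.ndarray, A: float, tau: float, phi: float) -> np.ndarray:
    return A * np.cos(2 * np.pi * (t - phi) / tau)


def _fourier_seed(
    t: np.ndarray, y: np.ndarray, window: tuple[float, float]
) -> tuple[float, float, float] | None:
    """Initial (A, tau, phi) from the dominant DFT component in the window.

    Assumes an (approximately) uniform grid; non-uniform traces are linearly
    interpolated onto one.
    """
    dt = np.diff(t)
    if dt.max() - dt.min() > 1e-6 * dt.mean():
        grid = np.arange(t[0], t[-1] + 1e-9, dt.mean())
        y = np.interp(grid, t, y)
        t = grid
    n = len(t)
    step = t[1] - t[0]
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(n, d=step)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    mask = (periods >= window[0]) & (periods <= window[1])
    if not mask.any():
        return None
    k = np.nonzero(mask)[0][int(np.argmax(np.abs(spec[mask])))]
    A0 = 2.0 * np.abs(spec[k]) / n
    tau0 = periods[k]
    if A0 <= 0:
        return None
    # y ~ A cos(w t + theta), theta = angle; phi = -theta / w (shifted by t0)
    theta = np.angle(spec[k] * np.exp(2j * np.pi * freqs[k] * t[0]))
    phi0 = (-theta / (2 * np.pi)) * tau0 % tau0
    return float(A0), float(tau0), float(phi0)


def _arrhythmic_fit(trace: LuciferaseTrace, baseline, converged=True) -> LuciferaseFit:
    return LuciferaseFit(
        fly_id=trace.fly_id,
        period_h=math.nan,
        amplitude=0.0,
        phase_h=math.nan,
        rel_amp_error=math.inf,
        rhythmic=False,
        baseline_intercept=baseline[0],
        baseline_slope=baseline[1],
        converged=converged,
    )


def fft_nlls(
    trace: LuciferaseTrace,
    period_window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    dd_only: bool = True,
    relamp_cut: float = RELAMP_ARRHYTHMIC_CUT,
) -> LuciferaseFit:
    """Fourier-initialised nonlinear least-squares cosine fit of one trace.

    Procedure: linear detrend; dominant DFT component inside
    ``period_window`` seeds (A, tau, phi); Levenberg-Marquardt refines the
    single-cosine model; the half-width of the joint 95% confidence region
    of the amplitude (support-plane bound sqrt(3 F(0.95; 3, n-3)) x SE_A
    from the linearised covariance at the optimum) divided by the amplitude
    gives the relative amplitude error. ``rhythmic`` requires rel-amp error
    <= ``relamp_cut`` *and* the fitted period inside the window.

    Traces with no spectral power in the window get an arrhythmic result
    with an infinite rel-amp error; non-convergent fits are flagged
    (``converged=False``) so group summaries can exclude them.
    """
    work = trace.dd_portion() if dd_only else trace
    n = len(work.times_h)
    if n < 24:
        raise ValueError("need at least 24 samples")
    span = work.times_h[-1] - work.times_h[0]
    if span < 2 * period_window[1]:
        raise ValueError(
            f"span {span:.0f} h shorter than twice the period upper bound"
        )
    resid_trace, baseline = detrend(work)
    t, y = resid_trace.times_h, resid_trace.cps

    seed = _fourier_seed(t, y, period_window)
    if seed is None:
        logger.warning("%s: no spectral peak inside %s; arrhythmic", trace.fly_id, period_window)
        return _arrhythmic_fit(work, baseline)
    try:
        popt, pcov = optimize.curve_fit(
            _cosine, t, y, p0=seed, method="lm", maxfev=10000
        )
    except RuntimeError:
        logger.warning("%s: FFT-NLLS did not converge; excluded", trace.fly_id)
        return _arrhythmic_fit(work, baseline, converged=False)
    A, tau, phi = popt
    if A < 0:  # canonicalise: positive amplitude, shift phase by half period
        A, phi = -A, phi + tau / 2.0
    tau = abs(tau)
    phi = phi % tau

    p_fit = 3
    dof = max(n - p_fit, 1)
    se_A = float(np.sqrt(abs(pcov[0, 0]))) if np.isfinite(pcov[0, 0]) else math.inf
    if A <= 0 or not math.isfinite(se_A):
        relamp = math.inf
    else:
        # joint (support-plane) 95% confidence half-width of the amplitude:
        # sqrt(p F(0.95; p, n-p)) * SE_A, the simultaneous region over all
        # three fitted parameters, as in cosinor joint confidence limits
        crit = math.sqrt(p_fit * stats.f.ppf(0.95, p_fit, dof))
        relamp = float(crit * se_A / A)
    rhythmic = (
        relamp <= relamp_cut and period_window[0] <= tau <= period_window[1]
    )
    return LuciferaseFit(
        fly_id=trace.fly_id,
        period_h=float(tau),
        amplitude=float(A),
        phase_h=float(phi),
        rel_amp_error=relamp,
        rhythmic=bool(rhythmic),
        baseline_intercept=baseline[0],
        baseline_slope=baseline[1],
    )


def classify_trace(
    fit: LuciferaseFit,
    period_window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    relamp_cut: float = RELAMP_ARRHYTHMIC_CUT,
) -> str:
    """"rhythmic" or "arrhythmic" per the rel-amp-error > 0.7 screen.

    The cut is strict: a rel-amp error exactly at the threshold still counts
    as rhythmic. Fits with a period outside the circadian window are
    arrhythmic regardless of rel-amp error.
    """
    if not math.isfinite(fit.period_h):
        return "arrhythmic"
    if not (period_window[0] <= fit.period_h <= period_window[1]):
        return "arrhythmic"
    return "arrhythmic" if fit.rel_amp_error > relamp_cut else "rhythmic"


def group_profile(
    traces: Sequence[LuciferaseTrace],
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Pointwise mean trace across flies, with the standard error of the mean.

    Traces are linearly interpolated onto the overlapping common time grid
    (that of the first trace, restricted to the shared span). With a single
    trace the s.e.m. is None.
    """
    if not traces:
        raise ValueError("no traces")
    t_lo = max(tr.times_h[0] for tr in traces)
    t_hi = min(tr.times_h[-1] for tr in traces)
    if t_hi <= t_lo:
        raise ValueError("traces do not overlap in time")
    base = traces[0].times_h
    grid = base[(base >= t_lo - 1e-9) & (base <= t_hi + 1e-9)]
    mat = np.vstack([np.interp(grid, tr.times_h, tr.cps) for tr in traces])
    mean = mat.mean(axis=0)
    if len(traces) == 1:
        return grid, mean, None
    sem = mat.std(axis=0, ddof=1) / np.sqrt(len(traces))
    return grid, mean, sem


def compare_fit_parameters(
    fits_by_group: dict[str, Sequence[LuciferaseFit]],
    parameter: str = "period_h",
) -> group_stats.TestReport:
    """Nonparametric one-way ANOVA (Kruskal-Wallis + Dunn) on a fit
    parameter (``period_h``, ``amplitude`` or ``rel_amp_error``) across
    genotypes; non-convergent fits are excluded."""
    groups = {}
    for label, fits in fits_by_group.items():
        vals = [
            getattr(f, parameter)
            for f in fits
            if f.converged and math.isfinite(getattr(f, parameter))
        ]
        if vals:
            groups[label] = vals
    return group_stats.kruskal_dunn(groups)
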