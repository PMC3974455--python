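"""Synthetic cohorts with known ground truth for every pipeline input.

The generators emulate the statistical structure of the real assays so each
analysis stage can be validated against programmed truth:

* **Locomotor activity** — per-bin beam crosses are Poisson with a
  time-varying rate: in DD a sinusoidal modulation of amplitude A (the
  free-running rhythm, optionally decaying with age); in LD exponential
  anticipatory ramps over the 3 h before each light transition plus a
  single-bin startle spike at the transitions; in LL a flat rate.
* **Bioluminescence** — a damped cosine on a linear baseline with Gaussian
  noise, clipped at zero counts per second.
* **Lifespans** — Gompertz mortality (hazard a·exp(b·t)), the baseline
  hazard scaled up under constant light; deaths scored in whole days and
  grouped into vials of ten.
* **Images** — Gaussian-profile somata at non-overlapping random positions
  on Gaussian background noise, with ground-truth masks and counts.

Every generator is a pure function of its config (the seed lives in the
config), so identical configs give identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bioluminescence import LuciferaseTrace
from .dam_io import ActivitySeries, ActivitySeriesSet, LightSchedule
from .image_quant import RoiMask
from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LucParams",
    "SurvivalParams",
    "ImageParams",
    "SimulationConfig",
    "gen_activity",
    "gen_luciferase",
    "gen_survival",
    "gen_roi_image",
]


@dataclass(frozen=True)
class LucParams:
    """Luciferase-trace generator parameters.

    ``a0_cps`` is the initial oscillation amplitude in counts per second;
    ``damping_halflife_h`` halves it every so many hours (None = undamped);
    ``trend_slope`` is the linear baseline drift in CPS per hour.
    """

    a0_cps: float = 100.0
    baseline_cps: float = 300.0
    damping_halflife_h: float | None = None
    trend_slope: float = 0.0
    noise_sd: float = 10.0
    period_h: float = 24.0
    phase_h: float = 0.0
    span_h: float = 120.0
    sample_interval_h: float = 1.0


@dataclass(frozen=True)
class SurvivalParams:
    """Gompertz lifespan parameters.

    Hazard h(t) = a·exp(b·t); ``condition_effect`` multiplies ``a`` for the
    rhythm-disrupting (LL) arm. Defaults put the LD median at 57 dae and
    the LL median at 48 dae, the control values of the lifespan assay, with
    a demographic steepness (b = 0.16/day) typical of flies aged at 29°C.
    """

    gompertz_a: float = 1.214e-5
    gompertz_b: float = 0.16
    condition_effect: float = 4.2222
    n_flies: int = 100
    vial_size: int = 10


@dataclass(frozen=True)
class ImageParams:
    """Synthetic soma-image parameters (intensities in arbitrary grey units)."""

    shape: tuple[int, int] = (128, 128)
    n_blobs: int = 4
    blob_peak: float = 200.0
    blob_sigma_px: float = 3.0
    bg_mean: float = 20.0
    bg_sd: float = 5.0
    min_separation_px: float = 20.0
    margin_px: int = 12


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs for one synthetic cohort.

    Activity fields model a single-genotype cohort under the schedule's
    LD/DD/LL segments: Poisson counts around ``baseline_rate`` per bin,
    sinusoidally modulated in DD with amplitude ``dd_amplitude`` (optionally
    decaying with age with the given half-life, in days), with exponential
    pre-transition ramps (time constant 1 h, heights ``*_ramp_gain`` ×
    baseline at the transition) and one-bin startle spikes in LD.
    """

    n_flies: int = 16
    bin_width_min: float = 30.0
    schedule: LightSchedule = field(default_factory=LightSchedule.standard_ld_dd)
    baseline_rate: float = 8.0
    dd_amplitude: float = 0.8
    period_h: float = 24.0
    phase_h: float = 0.0
    evening_ramp_gain: float = 1.5
    morning_ramp_gain: float = 1.0
    startle_gain: float = 2.0
    amplitude_decay_halflife_days: float | None = None
    age_at_start_dae: float = 2.0
    genotype: str = "synthetic"
    luc: LucParams = field(default_factory=LucParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    image: ImageParams = field(default_factory=ImageParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dd_amplitude <= 1.0):
            raise ValueError("dd_amplitude must lie in [0, 1]")
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")


RAMP_SPAN_H = 3.0  # anticipatory ramp covers the 3 h before a transition
RAMP_TAU_H = 1.0  # exponential time constant of the ramp


def _activity_rate(cfg: SimulationConfig, t_h: np.ndarray) -> np.ndarray:
    """Expected beam crosses per bin at bin-centre times ``t_h``."""
    sched = cfg.schedule
    L = sched.day_length_h
    lam = np.full_like(t_h, cfg.baseline_rate, dtype=float)
    bw_h = cfg.bin_width_min / 60.0
    for i, t in enumerate(t_h):
        seg = sched.segment_at(t)
        if seg.regime == "DD":
            a = cfg.dd_amplitude
            if cfg.amplitude_decay_halflife_days is not None:
                age = cfg.age_at_start_dae + t / 24.0
                a = a * 2.0 ** (-age / cfg.amplitude_decay_halflife_days)
            lam[i] = cfg.baseline_rate * (
                1.0 + a * np.cos(2 * np.pi * (t - cfg.phase_h) / cfg.period_h)
            )
        elif seg.regime == "LD":
            zt = sched.zt(t)
            boost = 0.0
            # evening: ramp up to lights-off at ZT = photoperiod
            for T, gain in (
                (seg.photoperiod_h, cfg.evening_ramp_gain),
                (L, cfg.morning_ramp_gain),  # morning: up to next lights-on
            ):
                dt = (zt - T) % L - L  # in (-L, 0]
                if -RAMP_SPAN_H <= dt < 0:
                    boost += gain * np.exp(dt / RAMP_TAU_H)
                # startle spike in the first bin after the transition
                after = (zt - T) % L
                if 0 <= after < bw_h:
                    boost += cfg.startle_gain
            lam[i] = cfg.baseline_rate * (1.0 + boost)
        else:  # LL: no rhythm, no ramps
            lam[i] = cfg.baseline_rate
    return np.clip(lam, 0.0, None)


def gen_activity(cfg: SimulationConfig, n_days: float = 10.0) -> ActivitySeriesSet:
    """Poisson activity cohort under the config's light schedule."""
    rng = np.random.default_rng(cfg.seed)
    bw_h = cfg.bin_width_min / 60.0
    n_bins = int(round(n_days * 24.0 / bw_h))
    t_mid = (np.arange(n_bins) + 0.5) * bw_h
    lam = _activity_rate(cfg, t_mid)
    series = []
    for i in range(cfg.n_flies):
        counts = rng.poisson(lam)
        series.append(
            ActivitySeries(
                fly_id=f"sim{i:03d}",
                counts=counts,
                bin_width_min=cfg.bin_width_min,
                schedule=cfg.schedule,
                genotype=cfg.genotype,
                age_at_start=cfg.age_at_start_dae,
            )
        )
    return ActivitySeriesSet(series)


def gen_luciferase(cfg: SimulationConfig) -> list[LuciferaseTrace]:
    """Damped-cosine luciferase traces on a linear baseline, clipped at 0."""
    rng = np.random.default_rng(cfg.seed)
    p = cfg.luc
    t = np.arange(0.0, p.span_h + 1e-9, p.sample_interval_h)
    traces = []
    for i in range(cfg.n_flies):
        amp = p.a0_cps * (
            2.0 ** (-t / p.damping_halflife_h) if p.damping_halflife_h else 1.0
        )
        y = (
            p.baseline_cps
            + p.trend_slope * t
            + amp * np.cos(2 * np.pi * (t - p.phase_h) / p.period_h)
            + rng.normal(0.0, p.noise_sd, size=t.shape)
        )
        traces.append(
            LuciferaseTrace(
                fly_id=f"luc{i:03d}",
                times_h=t,
                cps=np.clip(y, 0.0, None),
                genotype=cfg.genotype,
            )
        )
    return traces


def gen_survival(cfg: SimulationConfig, conditions: Sequence[str] = ("LD", "LL")) -> list[SurvivalRecord]:
    """Gompertz lifespans for each light condition, vialled in groups of ten.

    Continuous death times come from inverting the Gompertz survival
    function, S(t) = exp(-a/b (e^{bt} - 1)); scoring in whole days takes the
    ceiling (a fly dying during day d is recorded at day d).
    """
    p = cfg.survival
    if p.gompertz_a <= 0 or p.gompertz_b <= 0:
        raise ValueError("Gompertz parameters must be positive")
    rng = np.random.default_rng(cfg.seed)
    records = []
    for cond in conditions:
        a = p.gompertz_a * (p.condition_effect if cond == "LL" else 1.0)
        b = p.gompertz_b
        u = rng.uniform(size=p.n_flies)
        t_cont = np.log1p(-b * np.log(u) / a) / b
        days = np.maximum(1, np.ceil(t_cont).astype(int))
        for i, d in enumerate(days):
            records.append(
                SurvivalRecord(
                    fly_id=f"{cond}_fly{i:03d}",
                    death_day=int(d),
                    condition=cond,
                    genotype=cfg.genotype,
                    vial_id=f"{cond}_v{i // p.vial_size:02d}",
                )
            )
    return records


def gen_roi_image(cfg: SimulationConfig) -> tuple[np.ndarray, list[RoiMask], int]:
    """Gaussian-blob soma image on noisy background.

    Returns the image, one ground-truth disc mask (radius 2 sigma) per blob,
    and the programmed blob count. Blob centres are rejection-sampled to
    respect ``min_separation_px``; an infeasible request errors out.
    """
    p = cfg.image
    rng = np.random.default_rng(cfg.seed)
    h, w = p.shape
    if p.n_blobs > 0:
        usable = (h - 2 * p.margin_px) * (w - 2 * p.margin_px)
        if p.n_blobs * np.pi * (p.min_separation_px / 2) ** 2 > usable:
            raise ValueError("too many blobs for the image size")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < p.n_blobs:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place non-overlapping blobs")
        c = (
            rng.uniform(p.margin_px, h - p.margin_px),
            rng.uniform(p.margin_px, w - p.margin_px),
        )
        if all(
            (c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 >= p.min_separation_px**2
            for o in centers
        ):
            centers.append(c)

    image = rng.normal(p.bg_mean, p.bg_sd, size=(h, w))
    rr, cc = np.mgrid[:h, :w]
    masks = []
    for cy, cx in centers:
        r2 = (rr - cy) ** 2 + (cc - cx) ** 2
        image = image + p.blob_peak * np.exp(-r2 / (2 * p.blob_sigma_px**2))
        masks.append(RoiMask(r2 <= (2 * p.blob_sigma_px) ** 2))
    return np.clip(image, 0.0, None), masks, p.n_blobs
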