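"""Light-entrained anticipation: daily activity profiles and the
evening/morning anticipation index.

Entrained flies ramp up locomotor activity in the hours before the
light-dark transitions. The anticipation index quantifies this per fly as
the fraction of the activity in the 6 h before a transition that falls in
the final 3 h:

    index = sum(activity in [T - 3 h, T)) / sum(activity in [T - 6 h, T))

A flat profile gives 0.5 (no anticipation); a profile concentrated just
before the transition approaches 1. The transition bin itself is excluded
from both windows so the light-driven startle response cannot masquerade as
anticipation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dam_io import ActivitySeries
from . import group_stats

logger = logging.getLogger(__name__)

__all__ = [
    "DailyProfile",
    "AnticipationResult",
    "daily_profile",
    "anticipation_index",
    "series_anticipation",
    "compare_anticipation",
]


@dataclass(frozen=True)
class DailyProfile:
    """Mean activity per daily bin, phase-aligned to ZT0 = lights-on."""

    bin_means: np.ndarray
    phase_h: np.ndarray  # ZT of each bin start
    days_used: tuple[int, ...]
    bin_width_h: float
    photoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        if len(self.bin_means) != len(self.phase_h):
            raise ValueError("bin_means and phase_h length mismatch")
        if (np.asarray(self.bin_means) < 0).any():
            raise ValueError("negative bin means")


@dataclass(frozen=True)
class AnticipationResult:
    """Per-fly anticipation index for one transition.

    ``index`` is None when the 6-h window held no activity at all (the index
    is undefined, never imputed as 0).
    """

    fly_id: str | None
    index: float | None
    transition: str
    days_used: tuple[int, ...]


def daily_profile(series: ActivitySeries, days: Iterable[int]) -> DailyProfile:
    """Per-bin mean activity over the selected recording days (0-based),
    with bins rotated so the first bin starts at ZT0 (lights-on).

    All selected days must be completely recorded and lie inside an LD
    segment of the schedule.
    """
    days = tuple(sorted(days))
    if not days:
        raise ValueError("no days selected")
    sched = series.schedule
    L = sched.day_length_h
    bins_per_day = L / series.bin_width_h
    if abs(bins_per_day - round(bins_per_day)) > 1e-9:
        raise ValueError("bin width does not divide the day")
    b = int(round(bins_per_day))

    t = series.times_h
    profiles = []
    photoperiod = None
    for d in days:
        day_start = d * L
        seg = sched.segment_at(day_start)
        if seg.regime != "LD":
            raise ValueError(f"day {d} is not within an LD segment")
        photoperiod = seg.photoperiod_h
        # rotate so bin 0 starts at lights-on
        zt0 = day_start + seg.lights_on_offset_h
        idx = np.round((zt0 - series.t0_h) / series.bin_width_h).astype(int)
        if idx < 0 or idx + b > len(series.counts):
            raise ValueError(f"day {d} not completely recorded")
        profiles.append(series.counts[idx : idx + b].astype(float))
    means = np.mean(profiles, axis=0)
    phase = np.arange(b) * series.bin_width_h
    return DailyProfile(
        bin_means=means,
        phase_h=phase,
        days_used=days,
        bin_width_h=series.bin_width_h,
        photoperiod_h=float(photoperiod),
    )


def anticipation_index(
    profile: DailyProfile,
    transition: str = "evening",
    fly_id: str | None = None,
) -> AnticipationResult:
    """Ratio of 3-h to 6-h pre-transition activity.

    The evening transition is lights-off (ZT = photoperiod); the morning
    transition is lights-on (ZT0, i.e. ZT = day length wrapping to 0). The
    windows are half-open ``[T - 6 h, T)`` and ``[T - 3 h, T)`` so the
    transition bin is excluded.
    """
    if transition not in ("evening", "morning"):
        raise ValueError("transition must be 'evening' or 'morning'")
    L = profile.phase_h[-1] + profile.bin_width_h
    T = profile.photoperiod_h if transition == "evening" else L
    w = profile.bin_width_h
    n6 = int(round(6.0 / w))
    n3 = int(round(3.0 / w))
    if n6 < 2:
        raise ValueError("bins too coarse for a 6-h window")
    # phase of each bin start, relative to transition, wrapped into (-L, 0]
    rel = (profile.phase_h - T) % L - L
    in6 = (rel >= -6.0 - 1e-9) & (rel < -1e-9)
    in3 = (rel >= -3.0 - 1e-9) & (rel < -1e-9)
    if in6.sum() < n6:
        raise ValueError("profile does not cover the 6-h pre-transition window")
    total6 = float(profile.bin_means[in6].sum())
    total3 = float(profile.bin_means[in3].sum())
    if total6 == 0.0:
        logger.warning("anticipation index undefined (no activity in 6-h window)")
        return AnticipationResult(fly_id, None, transition, profile.days_used)
    return AnticipationResult(fly_id, total3 / total6, transition, profile.days_used)


def series_anticipation(
    series: ActivitySeries, days: Iterable[int], transition: str = "evening"
) -> AnticipationResult:
    """Anticipation index of one fly, from its multi-day averaged profile."""
    prof = daily_profile(series, days)
    return anticipation_index(prof, transition=transition, fly_id=series.fly_id)


def compare_anticipation(
    groups: Mapping[str, Sequence[AnticipationResult]],
) -> group_stats.TestReport:
    """Kruskal-Wallis with Dunn post-tests across groups of per-fly indices.

    Undefined indices are dropped; a group left with no valid index is
    excluded with a warning.
    """
    numeric: dict[str, list[float]] = {}
    for label, results in groups.items():
        vals = [r.index for r in results if r.index is not None]
        if not vals:
            logger.warning("group %s has no valid anticipation indices; excluded", label)
            continue
        numeric[label] = vals
    if len(numeric) < 2:
        raise ValueError("need at least two groups with valid indices")
    return group_stats.kruskal_dunn(numeric)
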