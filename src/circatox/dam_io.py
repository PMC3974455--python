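"""Locomotor monitor I/O and activity-series handling.

Beam-cross counts from Drosophila Activity Monitors (DAM, Trikinetics) arrive
as tab-separated text files, one row per reading, 32 channels per monitor.
This module reads and writes that dialect, attaches light schedules (LD / DD /
LL segments), re-bins counts, filters flies that died during recording, and
produces the per-fly :class:`ActivitySeries` objects every downstream analysis
consumes.

Conventions
-----------
* Bins are labelled by their start time and cover half-open intervals
  ``[start, start + width)``.
* Experiment time is measured in hours from the start of the recording
  (``t0_h`` of a series); zeitgeber time ZT0 is lights-on of the entraining
  LD segment.
* Fly age is expressed in days after eclosion (dae).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAM_N_CHANNELS = 32
DAM_N_COLUMNS = 42

__all__ = [
    "ScheduleSegment",
    "LightSchedule",
    "ActivitySeries",
    "ActivitySeriesSet",
    "read_dam_monitor",
    "write_dam_monitor",
    "read_long_csv",
    "write_long_csv",
    "load_schedule",
    "rebin",
    "filter_dead",
    "mean_activity",
    "slice_segment",
]


@dataclass(frozen=True)
class ScheduleSegment:
    """One contiguous lighting regime.

    Parameters
    ----------
    start_h : float
        Hours from experiment start at which the segment begins.
    regime : str
        One of ``"LD"``, ``"DD"``, ``"LL"``.
    lights_on_offset_h : float
        Hours into the (24 h) day at which lights come on (ZT0). Ignored for
        DD/LL but kept so subjective time stays anchored.
    photoperiod_h : float
        Hours of light per day: 0 for DD, day length for LL, typically 12
        for LD.
    """

    start_h: float
    regime: str
    lights_on_offset_h: float = 0.0
    photoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD", "LL"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, non-overlapping lighting segments covering a recording.

    The canonical entrainment protocol is 3 days of 12:12 LD followed by 7
    days of DD; :meth:`standard_ld_dd` builds it.
    """

    segments: tuple[ScheduleSegment, ...]
    day_length_h: float = 24.0

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        starts = [s.start_h for s in segs]
        if sorted(starts) != starts or len(set(starts)) != len(starts):
            raise ValueError("segments must be ordered by start time and non-overlapping")
        for s in segs:
            if not (0 <= s.lights_on_offset_h < self.day_length_h):
                raise ValueError("lights_on_offset_h outside [0, day_length)")
            if not (0 <= s.photoperiod_h <= self.day_length_h):
                raise ValueError("photoperiod_h outside [0, day_length]")
            if s.regime == "DD" and s.photoperiod_h != 0:
                raise ValueError("DD segment must have photoperiod 0")
            if s.regime == "LL" and s.photoperiod_h != self.day_length_h:
                raise ValueError("LL segment must have photoperiod == day length")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def standard_ld_dd(
        cls,
        ld_days: int = 3,
        dd_days: int = 7,
        lights_on_offset_h: float = 0.0,
        photoperiod_h: float = 12.0,
    ) -> "LightSchedule":
        """The 3 d LD + 7 d DD entrainment/free-run protocol (defaults)."""
        segs = [ScheduleSegment(0.0, "LD", lights_on_offset_h, photoperiod_h)]
        if dd_days > 0:
            segs.append(ScheduleSegment(ld_days * 24.0, "DD", lights_on_offset_h, 0.0))
        return cls(tuple(segs))

    @classmethod
    def constant(cls, regime: str = "DD") -> "LightSchedule":
        pp = 0.0 if regime == "DD" else 24.0
        return cls((ScheduleSegment(0.0, regime, 0.0, pp),))

    def segment_at(self, t_h: float) -> ScheduleSegment:
        """Segment in force at experiment time ``t_h`` (hours)."""
        seg = self.segments[0]
        for s in self.segments:
            if s.start_h <= t_h:
                seg = s
            else:
                break
        return seg

    def regime_at(self, t_h: float) -> str:
        return self.segment_at(t_h).regime

    def zt(self, t_h: float) -> float:
        """Zeitgeber time of experiment time ``t_h`` (ZT0 = lights-on)."""
        seg = self.segment_at(t_h)
        return (t_h - seg.lights_on_offset_h) % self.day_length_h

    def is_light(self, t_h: float) -> bool:
        seg = self.segment_at(t_h)
        if seg.regime == "DD":
            return False
        if seg.regime == "LL":
            return True
        return self.zt(t_h) < seg.photoperiod_h


@dataclass
class ActivitySeries:
    """One fly's binned beam-cross counts with time base and light schedule."""

    fly_id: str
    counts: np.ndarray
    bin_width_min: float
    schedule: LightSchedule
    genotype: str | None = None
    age_at_start: float | None = None  # dae
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError("counts must be 1-D")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)
        if self.bin_width_min <= 0:
            raise ValueError("bin width must be positive")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def bin_width_h(self) -> float:
        return self.bin_width_min / 60.0

    @property
    def span_h(self) -> float:
        return len(self.counts) * self.bin_width_h

    @property
    def times_h(self) -> np.ndarray:
        """Bin start times in hours from experiment start."""
        return self.t0_h + np.arange(len(self.counts)) * self.bin_width_h


@dataclass
class ActivitySeriesSet:
    """Flies recorded together: shared bin width and light schedule."""

    series: list[ActivitySeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.series:
            w0 = self.series[0].bin_width_min
            s0 = self.series[0].schedule
            for s in self.series:
                if s.bin_width_min != w0:
                    raise ValueError("all series must share one bin width")
                if s.schedule != s0:
                    raise ValueError("all series must share one schedule")
            ids = [s.fly_id for s in self.series]
            if len(set(ids)) != len(ids):
                raise ValueError("fly_ids must be unique")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, i: int) -> ActivitySeries:
        return self.series[i]


# ---------------------------------------------------------------------------
# DAM monitor text dialect
# ---------------------------------------------------------------------------

def _parse_dam_timestamp(date_s: str, time_s: str, lineno: int) -> datetime:
    try:
        return datetime.strptime(f"{date_s} {time_s}", "%d %b %y %H:%M:%S")
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad timestamp {date_s!r} {time_s!r}") from exc


def read_dam_monitor(
    path: str | Path,
    channel_map: Mapping[int, Mapping[str, object]] | None = None,
    schedule: LightSchedule | None = None,
    bin_width_min: float | None = None,
) -> ActivitySeriesSet:
    """Read a DAMSystem3 "Monitor" text file into per-channel activity series.

    The dialect is tab-separated with 42 columns: reading index, date
    ("D Mon YY"), time ("HH:MM:SS"), monitor status (1 = valid), six reserved
    metadata columns, then 32 integer channel counts. Rows whose status is
    not 1 are dropped with a warning. Bin width is inferred from consecutive
    timestamps unless given.

    ``channel_map`` optionally maps channel number (1-32) to metadata dicts
    with keys ``fly_id``, ``genotype``, ``dae``; unmapped channels get ids
    ``<stem>_ch<NN>``.
    """
    path = Path(path)
    rows: list[tuple[datetime, list[int]]] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != DAM_N_COLUMNS:
                raise ValueError(
                    f"line {lineno}: expected {DAM_N_COLUMNS} columns, got {len(cols)}"
                )
            ts = _parse_dam_timestamp(cols[1], cols[2], lineno)
            try:
                status = int(cols[3])
                counts = [int(c) for c in cols[10:42]]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer field") from exc
            if status != 1:
                n_dropped += 1
                logger.warning("%s line %d: dropping row with status %d", path.name, lineno, status)
                continue
            rows.append((ts, counts))
    if not rows:
        raise ValueError(f"{path}: no valid data rows")

    if bin_width_min is None:
        if len(rows) >= 2:
            bin_width_min = (rows[1][0] - rows[0][0]).total_seconds() / 60.0
        else:
            bin_width_min = 1.0
    matrix = np.array([r[1] for r in rows], dtype=np.int64)
    if schedule is None:
        schedule = LightSchedule.constant("DD")

    series = []
    for ch in range(1, DAM_N_CHANNELS + 1):
        meta = dict(channel_map.get(ch, {})) if channel_map else {}
        series.append(
            ActivitySeries(
                fly_id=str(meta.get("fly_id", f"{path.stem}_ch{ch:02d}")),
                counts=matrix[:, ch - 1],
                bin_width_min=bin_width_min,
                schedule=schedule,
                genotype=meta.get("genotype"),
                age_at_start=meta.get("dae"),
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d invalid rows", path.name, n_dropped)
    return ActivitySeriesSet(series)


def write_dam_monitor(
    sset: ActivitySeriesSet,
    path: str | Path,
    start: datetime | None = None,
) -> Path:
    """Write a series set as a DAM monitor text file (inverse of the reader).

    At most 32 series; missing channels are written as zeros so the file is
    always a full 32-channel monitor.
    """
    if len(sset) == 0:
        raise ValueError("cannot write an empty series set")
    if len(sset) > DAM_N_CHANNELS:
        raise ValueError(f"a DAM monitor holds at most {DAM_N_CHANNELS} channels")
    n_bins = len(sset[0])
    for s in sset:
        if len(s) != n_bins:
            raise ValueError("all series must have equal length")
    if start is None:
        start = datetime(2024, 1, 1, 0, 0, 0)
    width = timedelta(minutes=sset[0].bin_width_min)

    path = Path(path)
    with open(path, "w") as fh:
        for i in range(n_bins):
            ts = start + i * width
            date_s = f"{ts.day} {ts.strftime('%b %y')}"
            cols = [str(i + 1), date_s, ts.strftime("%H:%M:%S"), "1"] + ["0"] * 6
            counts = [
                str(int(sset[j].counts[i])) if j < len(sset) else "0"
                for j in range(DAM_N_CHANNELS)
            ]
            fh.write("\t".join(cols + counts) + "\n")
    return path


# ---------------------------------------------------------------------------
# Long CSV alternative
# ---------------------------------------------------------------------------

def read_long_csv(path: str | Path, schedule: LightSchedule | None = None) -> ActivitySeriesSet:
    """Read the long-format CSV alternative.

    Columns: fly_id, genotype, dae, bin_start_iso8601, bin_width_min, counts.
    """
    df = pd.read_csv(path, parse_dates=["bin_start_iso8601"])
    if schedule is None:
        schedule = LightSchedule.constant("DD")
    series = []
    for fly_id, g in df.groupby("fly_id", sort=False):
        g = g.sort_values("bin_start_iso8601")
        width = float(g["bin_width_min"].iloc[0])
        series.append(
            ActivitySeries(
                fly_id=str(fly_id),
                counts=g["counts"].to_numpy(),
                bin_width_min=width,
                schedule=schedule,
                genotype=str(g["genotype"].iloc[0]),
                age_at_start=float(g["dae"].iloc[0]),
            )
        )
    return ActivitySeriesSet(series)


def write_long_csv(sset: ActivitySeriesSet, path: str | Path, start: datetime | None = None) -> Path:
    if start is None:
        start = datetime(2024, 1, 1)
    recs = []
    for s in sset:
        for i, c in enumerate(s.counts):
            recs.append(
                {
                    "fly_id": s.fly_id,
                    "genotype": s.genotype,
                    "dae": s.age_at_start,
                    "bin_start_iso8601": (start + timedelta(minutes=i * s.bin_width_min)).isoformat(),
                    "bin_width_min": s.bin_width_min,
                    "counts": int(c),
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False)
    return Path(path)


def load_schedule(path: str | Path) -> LightSchedule:
    """Load a light schedule from a YAML config.

    Expected form::

        day_length_h: 24
        segments:
          - {start_h: 0, regime: LD, lights_on_offset_h: 0, photoperiod_h: 12}
          - {start_h: 72, regime: DD}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    day_length = float(cfg.get("day_length_h", 24.0))
    segs = []
    for item in cfg["segments"]:
        regime = item["regime"]
        default_pp = {"LD": 12.0, "DD": 0.0, "LL": day_length}[regime]
        segs.append(
            ScheduleSegment(
                start_h=float(item["start_h"]),
                regime=regime,
                lights_on_offset_h=float(item.get("lights_on_offset_h", 0.0)),
                photoperiod_h=float(item.get("photoperiod_h", default_pp)),
            )
        )
    return LightSchedule(tuple(segs), day_length_h=day_length)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def rebin(series: ActivitySeries, new_width_min: float) -> ActivitySeries:
    """Sum counts into wider bins (e.g. 1-min readings to 30-min bins).

    ``new_width_min`` must be an integer multiple of the current width; a
    trailing partial window is dropped (and logged) rather than padded, which
    would bias means.
    """
    ratio = new_width_min / series.bin_width_min
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"new width {new_width_min} is not an integer multiple of {series.bin_width_min}"
        )
    k = int(round(ratio))
    if k == 1:
        return replace(series, counts=series.counts.copy())
    n_full = len(series.counts) // k
    dropped = len(series.counts) - n_full * k
    if dropped:
        logger.info("rebin %s: dropping %d trailing bins", series.fly_id, dropped)
    counts = series.counts[: n_full * k].reshape(n_full, k).sum(axis=1)
    return replace(series, counts=counts, bin_width_min=new_width_min)


def filter_dead(
    sset: ActivitySeriesSet, window_h: float = 24.0
) -> tuple[ActivitySeriesSet, list[str]]:
    """Drop flies with zero activity over the final ``window_h`` hours.

    Flies that die mid-recording register no beam crosses thereafter; a dead
    fly's residual record would dilute every cohort statistic. Removals are
    logged by fly_id and returned.
    """
    kept, removed = [], []
    for s in sset:
        if window_h > s.span_h:
            raise ValueError("window exceeds recording span")
        n = int(round(window_h / s.bin_width_h))
        if s.counts[-n:].sum() == 0:
            removed.append(s.fly_id)
            logger.info("filter_dead: removing %s (no activity in final %.0f h)", s.fly_id, window_h)
        else:
            kept.append(s)
    return ActivitySeriesSet(kept), removed


def mean_activity(series: ActivitySeries) -> float:
    """Mean beam crosses per bin over the full recording."""
    if len(series.counts) == 0:
        raise ValueError("empty series")
    return float(series.counts.mean())


def slice_segment(series: ActivitySeries, regime: str) -> ActivitySeries:
    """Restrict a series to the first schedule segment with the given regime.

    The returned series keeps its absolute time base (``t0_h``) and schedule
    so ZT/CT bookkeeping stays valid.
    """
    segs = series.schedule.segments
    start = None
    end = series.t0_h + series.span_h
    for i, s in enumerate(segs):
        if s.regime == regime:
            start = s.start_h
            if i + 1 < len(segs):
                end = segs[i + 1].start_h
            break
    if start is None:
        raise ValueError(f"schedule has no {regime} segment")
    t = series.times_h
    mask = (t >= start - 1e-9) & (t < end - 1e-9)
    if not mask.any():
        raise ValueError(f"series does not cover the {regime} segment")
    idx = np.nonzero(mask)[0]
    return replace(
        series,
        counts=series.counts[idx],
        t0_h=float(t[idx[0]]),
    )
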