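"""Lifespan analysis under light regimes.

The standard assay houses ten vials of ten flies per arm (n = 100) under
12:12 LD or constant light, with deaths scored in whole days after eclosion
(dae). Two complementary comparisons are provided:

* the Kaplan-Meier product-limit estimate on all individuals with the
  Mantel-Haenszel log-rank test (n = 100 per arm), and
* a conservative replicate-level test on the ten per-vial median survivals
  (Mann-Whitney by default, Student's t optionally), which respects the
  vial as the unit of replication.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "SurvivalComparison",
    "km_curve",
    "km_median",
    "logrank",
    "vial_median_test",
    "percent_change",
    "compare_conditions",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One fly's death (or censoring) day, with its vial and condition."""

    fly_id: str
    death_day: int
    condition: str = ""
    genotype: str | None = None
    vial_id: str = ""
    censored: bool = False

    def __post_init__(self) -> None:
        if self.death_day <= 0:
            raise ValueError("death_day must be a positive day count")


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-arm lifespan comparison (arm a vs arm b)."""

    median_a: float
    median_b: float
    logrank_chi2: float
    logrank_p: float
    vial_medians_a: tuple[float, ...]
    vial_medians_b: tuple[float, ...]
    vial_test_p: float
    percent_change: float


def _arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.death_day for r in records], dtype=float)
    observed = np.array([not r.censored for r in records], dtype=bool)
    return t, observed


def km_curve(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit survival function.

    Returns ``(times, S)`` where ``S[i]`` is the estimated survival just
    after ``times[i]``; right-censored records are supported although the
    default fly workflow observes every death.
    """
    if not records:
        raise ValueError("no records")
    t, observed = _arrays(records)
    if not observed.any():
        raise ValueError("need at least one uncensored death")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=observed)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def km_median(records: Sequence[SurvivalRecord]) -> float:
    """Median survival: the smallest observed time with S(t) <= 0.5.

    Returns NaN (flagged with a warning) when the curve never reaches 0.5.
    """
    times, S = km_curve(records)
    below = np.nonzero(S <= 0.5 + 1e-12)[0]
    if below.size == 0:
        logger.warning("survival never drops to 0.5; median undefined")
        return math.nan
    return float(times[below[0]])


def logrank(
    records_a: Sequence[SurvivalRecord], records_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Haenszel log-rank test between two arms: (chi2, p), 1 df."""
    if not records_a or not records_b:
        raise ValueError("both groups must be non-empty")
    ta, oa = _arrays(records_a)
    tb, ob = _arrays(records_b)
    if not oa.any() or not ob.any():
        raise ValueError("both groups need at least one death")
    res = logrank_test(ta, tb, event_observed_A=oa, event_observed_B=ob)
    return float(res.test_statistic), float(res.p_value)


def _vial_medians(records: Sequence[SurvivalRecord]) -> list[float]:
    by_vial: dict[str, list[float]] = {}
    for r in records:
        if r.censored:
            continue
        by_vial.setdefault(r.vial_id, []).append(float(r.death_day))
    medians = []
    for vial, deaths in by_vial.items():
        if not deaths:
            logger.warning("vial %s has no deaths; excluded", vial)
            continue
        medians.append(float(np.median(deaths)))
    return medians


def vial_median_test(
    records_a: Sequence[SurvivalRecord],
    records_b: Sequence[SurvivalRecord],
    method: str = "mann_whitney",
) -> float:
    """Replicate-level comparison: per-vial median survivals, then a
    two-sample test on the vial medians.

    Both Mann-Whitney and an unpaired t-test are offered; the nonparametric
    default is logged. Requires at least two vials per arm.
    """
    ma, mb = _vial_medians(records_a), _vial_medians(records_b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need at least two vials per group")
    if method == "t":
        _, p = stats.ttest_ind(ma, mb)
    elif method == "mann_whitney":
        logger.info("vial_median_test: using Mann-Whitney on vial medians")
        _, p = stats.mannwhitneyu(ma, mb, alternative="two-sided")
    else:
        raise ValueError("method must be 't' or 'mann_whitney'")
    return float(p)


def percent_change(median_a: float, median_b: float) -> float:
    """Percent change of median a relative to median b:
    ``100 * (a - b) / b`` (e.g. LD median over LL median)."""
    if not (median_b > 0) or math.isnan(median_a) or math.isnan(median_b):
        raise ValueError("medians must be positive and defined")
    return 100.0 * (median_a - median_b) / median_b


def compare_conditions(
    records_a: Sequence[SurvivalRecord],
    records_b: Sequence[SurvivalRecord],
    vial_method: str = "mann_whitney",
) -> SurvivalComparison:
    """Full two-arm comparison: KM medians, log-rank, vial-median test and
    percent change of arm a's median over arm b's."""
    med_a, med_b = km_median(records_a), km_median(records_b)
    chi2, p = logrank(records_a, records_b)
    ma, mb = _vial_medians(records_a), _vial_medians(records_b)
    vial_p = vial_median_test(records_a, records_b, method=vial_method)
    return SurvivalComparison(
        median_a=med_a,
        median_b=med_b,
        logrank_chi2=chi2,
        logrank_p=p,
        vial_medians_a=tuple(ma),
        vial_medians_b=tuple(mb),
        vial_test_p=vial_p,
        percent_change=percent_change(med_a, med_b),
    )
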