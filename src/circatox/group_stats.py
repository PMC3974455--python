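"""Shared statistical machinery: normality screening, parametric /
nonparametric routing, Kruskal-Wallis with Dunn's post-tests, chi-square.

The routing rule mirrors standard practice in behavioural work: every group
is screened with the D'Agostino-Pearson omnibus normality test; only when
all groups pass (p > alpha) are parametric tests (Student's t / one-way
ANOVA) used, otherwise Mann-Whitney / Kruskal-Wallis. Groups too small for
the omnibus test (n < 8) default to the nonparametric route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestReport",
    "normality_screen",
    "auto_compare",
    "kruskal_dunn",
    "dunn_posthoc",
    "chi2_2x2",
]


@dataclass(frozen=True)
class TestReport:
    """Outcome of a group comparison.

    ``post_hoc`` holds ``((label_a, label_b), adjusted_p)`` pairs and is
    present only for comparisons of three or more groups.
    """

    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    post_hoc: list[tuple[tuple[str, str], float]] | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def normality_screen(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """D'Agostino-Pearson omnibus screen per group.

    Returns ``"normal"`` / ``"non-normal"`` per group, or ``"insufficient"``
    when n < 8 (the omnibus test needs at least 8 observations), which
    downstream routing treats as a vote for nonparametric tests.
    """
    verdicts = {}
    for label, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if len(x) < 8:
            verdicts[label] = "insufficient"
            continue
        _, p = stats.normaltest(x)
        verdicts[label] = "normal" if p > alpha else "non-normal"
    return verdicts


def _anova(groups: Mapping[str, Sequence[float]]) -> tuple[str, float, float]:
    arrays = [np.asarray(v, float) for v in groups.values()]
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1])
        return "t-test", float(t), float(p)
    f, p = stats.f_oneway(*arrays)
    return "one-way ANOVA", float(f), float(p)


def _nonparametric(groups: Mapping[str, Sequence[float]]) -> tuple[str, float, float]:
    arrays = [np.asarray(v, float) for v in groups.values()]
    if len(arrays) == 2:
        u, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return "Mann-Whitney U", float(u), float(p)
    h, p = stats.kruskal(*arrays)
    return "Kruskal-Wallis", float(h), float(p)


def auto_compare(
    groups: Mapping[str, Sequence[float]], alpha_normality: float = 0.05
) -> TestReport:
    """Normality-screened comparison with automatic parametric routing.

    All groups normal -> t-test (2 groups) or one-way ANOVA; otherwise
    Mann-Whitney or Kruskal-Wallis. With >= 3 groups, Dunn's pairwise
    post-tests (Bonferroni-adjusted) are appended on the nonparametric
    route; Tukey-free pairwise Welch t-tests with Bonferroni on the
    parametric route.
    """
    groups = {k: list(v) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    verdicts = normality_screen(groups, alpha=alpha_normality)
    parametric = all(v == "normal" for v in verdicts.values())
    if parametric:
        name, statistic, p = _anova(groups)
    else:
        name, statistic, p = _nonparametric(groups)
    logger.info("auto_compare: normality=%s -> %s", verdicts, name)

    post_hoc = None
    if len(groups) >= 3:
        if parametric:
            pairs = list(combinations(groups, 2))
            m = len(pairs)
            post_hoc = []
            for a, b in pairs:
                _, pp = stats.ttest_ind(groups[a], groups[b])
                post_hoc.append(((a, b), min(1.0, float(pp) * m)))
        else:
            post_hoc = dunn_posthoc(groups)
    return TestReport(
        test=name,
        statistic=statistic,
        p_value=p,
        group_sizes={k: len(v) for k, v in groups.items()},
        post_hoc=post_hoc,
        notes=f"normality: {verdicts}",
    )


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> TestReport:
    """Nonparametric one-way ANOVA: Kruskal-Wallis, plus Dunn's post-tests
    (Bonferroni) when there are three or more groups."""
    groups = {k: list(v) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    name, statistic, p = _nonparametric(groups)
    post_hoc = dunn_posthoc(groups) if len(groups) >= 3 else None
    return TestReport(
        test=name,
        statistic=statistic,
        p_value=p,
        group_sizes={k: len(v) for k, v in groups.items()},
        post_hoc=post_hoc,
    )


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> list[tuple[tuple[str, str], float]]:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    For groups i, j with mean ranks Ri, Rj over the pooled mid-rank ranking
    of all N observations:

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/ni + 1/nj))

    where T = sum(t^3 - t) over tie groups. Two-sided normal p-values are
    Bonferroni-multiplied over all pairs (GraphPad's convention), clipped
    at 1.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], float) for k in labels]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - T / (12.0 * (N - 1))

    mean_ranks = {}
    start = 0
    for label, arr in zip(labels, arrays):
        mean_ranks[label] = ranks[start : start + len(arr)].mean()
        start += len(arr)

    pairs = list(combinations(labels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out.append(((a, b), float(p)))
    return out


def chi2_2x2(table: np.ndarray | Sequence[Sequence[float]]) -> TestReport:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction (matching common chronobiology practice); warns toward an
    exact test when an expected cell drops below 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if t.sum(axis=1).min() == 0:
        raise ValueError("empty group (zero row total)")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected < 1).any():
        logger.warning("chi2_2x2: expected cell < 1; consider Fisher's exact test")
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((t - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return TestReport(
        test="chi-square (2x2, no continuity correction)",
        statistic=chi2,
        p_value=p,
        group_sizes={"row0": int(t[0].sum()), "row1": int(t[1].sum())},
    )
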