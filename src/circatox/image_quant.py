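"""ROI-based fluorescence quantification and neuron counting.

Mirrors the manual workflow used on confocal images of PDF-expressing clock
neurons: a circular ROI mask is placed over the signal (e.g. the sLNv dorsal
terminus), the same-size mask is moved to a signal-free area to estimate
background, and the background mean is subtracted from the signal mean.
Labelled somata are counted per brain hemisphere (normally four per
hemisphere per neuron class); per-genotype tallies of hemispheres with the
full complement versus fewer feed a 2x2 chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from . import group_stats

logger = logging.getLogger(__name__)

__all__ = [
    "RoiMask",
    "IntensityResult",
    "NeuronCountTable",
    "disc_mask",
    "roi_mean",
    "background_subtract",
    "count_somata",
    "count_complement",
    "compare_counts",
    "group_intensity_compare",
]


@dataclass(frozen=True)
class RoiMask:
    """Boolean pixel mask over a 2-D image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError("empty mask")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class IntensityResult:
    """Background-corrected mean intensity for one sample."""

    sample_id: str
    s_signal: float
    s_background: float

    @property
    def corrected(self) -> float:
        return self.s_signal - self.s_background


@dataclass(frozen=True)
class NeuronCountTable:
    """Per-genotype tallies of hemispheres with the full soma complement.

    ``full`` / ``fewer`` map genotype -> number of hemispheres with exactly
    the full complement (normally 4) vs fewer.
    """

    full: dict[str, int]
    fewer: dict[str, int]

    def as_2x2(self, genotype_a: str, genotype_b: str) -> np.ndarray:
        return np.array(
            [
                [self.full[genotype_a], self.fewer[genotype_a]],
                [self.full[genotype_b], self.fewer[genotype_b]],
            ],
            dtype=float,
        )


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> RoiMask:
    """Circular ROI of the given radius (pixels) centred at ``center``."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return RoiMask(m)


def roi_mean(image: np.ndarray, mask: RoiMask) -> float:
    """Arithmetic mean of the pixels under the mask."""
    img = np.asarray(image, dtype=float)
    if img.shape != mask.mask.shape:
        raise ValueError("image and mask shapes differ")
    return float(img[mask.mask].mean())


def background_subtract(
    image: np.ndarray,
    signal_mask: RoiMask,
    background_mask: RoiMask,
    sample_id: str = "",
) -> IntensityResult:
    """Mean signal-ROI intensity minus mean background-ROI intensity.

    The background mask must have the same area as the signal mask (it is
    "the same ROI, moved") and be disjoint from it. A negative corrected
    intensity is possible (background brighter than signal) and is flagged.
    """
    if signal_mask.area != background_mask.area:
        raise ValueError("signal and background masks must have equal area")
    if (signal_mask.mask & background_mask.mask).any():
        raise ValueError("signal and background masks overlap")
    s = roi_mean(image, signal_mask)
    b = roi_mean(image, background_mask)
    res = IntensityResult(sample_id=sample_id, s_signal=s, s_background=b)
    if res.corrected < 0:
        logger.warning("%s: corrected intensity negative (%.3g)", sample_id, res.corrected)
    return res


def count_somata(
    image: np.ndarray,
    smooth_sigma: float = 2.0,
    threshold: float | None = None,
    min_area_px: int = 5,
) -> tuple[int, np.ndarray]:
    """Count labelled somata by smoothing + thresholding + connected
    components.

    ``threshold`` defaults to Otsu's on the smoothed image. Returns the
    count and the label image. This automates the manual count for
    well-separated, bright somata; manually scored counts can instead be
    supplied directly to :func:`count_complement`.
    """
    img = np.asarray(image, dtype=float)
    smoothed = filters.gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if threshold is None:
        threshold = filters.threshold_otsu(smoothed)
    binary = smoothed > threshold
    labels = measure.label(binary)
    keep = np.zeros_like(labels)
    n = 0
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            n += 1
            keep[labels == region.label] = n
    return n, keep


def count_complement(
    counts: Mapping[str, Sequence[int]], full: int = 4
) -> NeuronCountTable:
    """Tally hemispheres with the full soma complement vs fewer, per genotype.

    ``counts`` maps genotype -> per-hemisphere soma counts. Hemispheres
    with more than ``full`` somata are counted as full-complement (the
    comparison of interest is loss, 4 vs < 4).
    """
    table_full, table_fewer = {}, {}
    for genotype, per_hemisphere in counts.items():
        c = np.asarray(list(per_hemisphere))
        table_full[genotype] = int((c >= full).sum())
        table_fewer[genotype] = int((c < full).sum())
    return NeuronCountTable(full=table_full, fewer=table_fewer)


def compare_counts(
    table: NeuronCountTable, genotype_a: str | None = None, genotype_b: str | None = None
) -> group_stats.TestReport:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    full-vs-fewer table for two genotypes."""
    genos = list(table.full)
    if genotype_a is None or genotype_b is None:
        if len(genos) != 2:
            raise ValueError("specify genotype_a and genotype_b")
        genotype_a, genotype_b = genos
    return group_stats.chi2_2x2(table.as_2x2(genotype_a, genotype_b))


def group_intensity_compare(
    results: Mapping[str, Sequence[IntensityResult]],
) -> group_stats.TestReport:
    """Compare corrected intensities across genotypes / timepoints.

    Two groups -> Student's t-test; three or more -> one-way ANOVA with
    Bonferroni pairwise post-tests; degenerate (zero-variance) groups fall
    back to the nonparametric route with a warning. Mean ± s.e.m. per group
    go in the report notes.
    """
    groups = {k: [r.corrected for r in v] for k, v in results.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 samples")
    summary = {
        k: (float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(len(v))))
        for k, v in groups.items()
    }
    degenerate = any(np.std(v) == 0 for v in groups.values())
    if degenerate:
        logger.warning("zero-variance group; using nonparametric tests")
        report = group_stats.kruskal_dunn(groups)
    elif len(groups) == 2:
        from scipy import stats as sps

        a, b = groups.values()
        tstat, p = sps.ttest_ind(a, b)
        report = group_stats.TestReport(
            test="t-test",
            statistic=float(tstat),
            p_value=float(p),
            group_sizes={k: len(v) for k, v in groups.items()},
        )
    else:
        from scipy import stats as sps
        from itertools import combinations

        f, p = sps.f_oneway(*groups.values())
        pairs = list(combinations(groups, 2))
        post = []
        for a, b in pairs:
            _, pp = sps.ttest_ind(groups[a], groups[b])
            post.append(((a, b), min(1.0, float(pp) * len(pairs))))
        report = group_stats.TestReport(
            test="one-way ANOVA",
            statistic=float(f),
            p_value=float(p),
            group_sizes={k: len(v) for k, v in groups.items()},
            post_hoc=post,
        )
    return group_stats.TestReport(
        test=report.test,
        statistic=report.statistic,
        p_value=report.p_value,
        group_sizes=report.group_sizes,
        post_hoc=report.post_hoc,
        notes=f"mean±sem: {summary}",
    )
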