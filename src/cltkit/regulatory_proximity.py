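"""TSS-to-open-chromatin proximity test against random-LTR nulls.

The observed statistic is the set of nearest-peak distances of CLT
transcription start sites. The null is built by repeatedly sampling the
same number of LTR elements (without replacement) and measuring nearest-
peak distances from their centers. The primary p-value is a one-sided
Mann-Whitney rank comparison of observed vs pooled null distances; a
per-set empirical median rank is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation_io import GenomicInterval, RepeatElement


def nearest_peak_distances(
    positions: Sequence[tuple[str, int]],
    peaks: Sequence[GenomicInterval],
) -> list[float]:
    """Distance from each position to the nearest peak on its chromosome.

    0 when the position lies inside a peak; NaN when its chromosome has no
    peaks.
    """
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        ivs = sorted(plist, key=lambda p: (p.start, p.end))
        starts = np.array([p.start for p in ivs])
        # prefix maximum of ends: enough to answer "am I inside / how far is
        # the closest peak base to my left" among peaks starting at/before pos
        prefix_max_end = np.maximum.accumulate(np.array([p.end for p in ivs]))
        arrays[chrom] = (starts, prefix_max_end)

    out: list[float] = []
    for chrom, pos in positions:
        if chrom not in arrays:
            out.append(math.nan)
            continue
        starts, prefix_max_end = arrays[chrom]
        i = int(np.searchsorted(starts, pos, side="right"))
        best = math.inf
        if i < len(starts):
            best = float(starts[i] - pos)
        if i > 0:
            left_end = int(prefix_max_end[i - 1])
            if left_end > pos:
                best = 0.0
            else:
                best = min(best, float(pos - (left_end - 1)))
        out.append(best)
    return out


@dataclass
class ProximityResult:
    observed_distances: list[float]
    null_distances: list[list[float]]
    n_random_sets: int
    statistic: float          # Mann-Whitney U, observed vs pooled null
    p_value: float            # one-sided (observed closer)
    empirical_p: float        # fraction of null sets with median <= observed median
    observed_median: float
    null_medians: list[float]
    seed: int


def proximity_test(
    tss_set: Sequence[tuple[str, int]],
    peaks: Sequence[GenomicInterval],
    ltr_elements: Sequence[RepeatElement],
    n_sets: int = 10,
    seed: int = 0,
) -> ProximityResult:
    """Test whether TSSs are closer to peaks than random LTR-element centers.

    Each of the ``n_sets`` null sets contains exactly ``len(tss_set)`` LTR
    elements sampled without replacement; their centers (midpoint rounded
    down) are the null positions.
    """
    if len(ltr_elements) < len(tss_set):
        raise ValueError(
            f"need >= {len(tss_set)} LTR elements for null sets, have {len(ltr_elements)}"
        )
    rng = np.random.default_rng(seed)
    observed = [d for d in nearest_peak_distances(tss_set, peaks) if not math.isnan(d)]
    if not observed:
        raise ValueError("no observed distances (no peaks on TSS chromosomes?)")

    nulls: list[list[float]] = []
    for _ in range(n_sets):
        idx = rng.choice(len(ltr_elements), size=len(tss_set), replace=False)
        centers = [(ltr_elements[i].interval.chrom, ltr_elements[i].center) for i in idx]
        dist = [d for d in nearest_peak_distances(centers, peaks) if not math.isnan(d)]
        nulls.append(dist)

    pooled = [d for ns in nulls for d in ns]
    stat, p = stats.mannwhitneyu(observed, pooled, alternative="less")
    obs_median = float(np.median(observed))
    null_medians = [float(np.median(ns)) if ns else math.nan for ns in nulls]
    emp = float(np.mean([m <= obs_median for m in null_medians]))
    return ProximityResult(
        observed_distances=observed,
        null_distances=nulls,
        n_random_sets=n_sets,
        statistic=float(stat),
        p_value=float(p),
        empirical_p=emp,
        observed_median=obs_median,
        null_medians=null_medians,
        seed=seed,
    )


def result_to_dict(result: ProximityResult) -> dict:
    return {
        "n_tss": len(result.observed_distances),
        "n_random_sets": result.n_random_sets,
        "observed_median": result.observed_median,
        "null_medians": result.null_medians,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "empirical_p": result.empirical_p,
        "seed": result.seed,
    }
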