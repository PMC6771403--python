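"""Cancer-specific transcript selection, validation and usage accounting.

A transcript is called cancer-specific in a given cancer type when all
four criteria hold:

1. recurrently expressed in the discovery cohort — TPM above the
   expression threshold (default >1) in at least ``min_expressed_samples``
   (default 6) of the cohort samples, and a cohort 75th percentile above
   the same threshold;
2. low everywhere in health — below ``healthy_low_tpm`` (default 10) in at
   least ``healthy_low_fraction`` (default 90%) of all pooled healthy
   samples;
3. cohort p75 at least ``fold`` (default 3) times the highest healthy
   per-tissue median;
4. cohort p75 at least ``fold`` times the 90th percentile of the matched
   healthy tissue, skipped when no matched tissue is defined.

Fold comparisons are inclusive ("three or more times"); validation-cohort
positivity is strict ("more than three times the highest median in any
normal tissue").
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import RepeatElement, TranscriptModel, build_interval_index, overlapping_elements
from .expression_summary import ExpressionMatrix, percentile

CRITERION_IDS = (1, 2, 3, 4)


@dataclass
class SelectionCriteria:
    expressed_tpm: float = 1.0          # strict > for "expressed"
    min_expressed_samples: int = 6
    discovery_cohort_size: int = 24
    healthy_low_fraction: float = 0.90
    healthy_low_tpm: float = 10.0       # strict <
    fold: float = 3.0                   # inclusive >=
    cancer_stat: float = 75.0           # percentile for the cancer side
    require_p75_expressed: bool = True  # cohort p75 > expressed_tpm as part of c1
    scale_min_samples: bool = False     # scale min_expressed_samples to cohort size

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if not 0 < self.healthy_low_fraction <= 1:
            raise ValueError("healthy_low_fraction must be in (0, 1]")


@dataclass
class CLTRecord:
    transcript_id: str
    cancer_type: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool | None  # None when no matched tissue ("when available")
    selected: bool
    cancer_p75: float
    n_expressed_samples: int
    healthy_low_fraction: float
    max_healthy_median: float
    matched_p90: float | None

    def failing_criteria(self) -> list[int]:
        flags = {1: self.c1, 2: self.c2, 3: self.c3, 4: self.c4}
        return [i for i in CRITERION_IDS if flags[i] is False]


def evaluate_criteria(
    cancer_values: np.ndarray,
    healthy_pooled: np.ndarray,
    healthy_group_medians: Mapping[str, float],
    matched_p90: float | None,
    criteria: SelectionCriteria,
) -> CLTRecord:
    """Evaluate the four criteria for one transcript in one cancer cohort."""
    c = criteria
    n_expr = int((cancer_values > c.expressed_tpm).sum())
    cancer_p75 = percentile(cancer_values, c.cancer_stat)
    min_samples = c.min_expressed_samples
    if c.scale_min_samples and len(cancer_values) != c.discovery_cohort_size:
        min_samples = math.ceil(
            c.min_expressed_samples * len(cancer_values) / c.discovery_cohort_size
        )
    c1 = n_expr >= min_samples
    if c.require_p75_expressed:
        c1 = c1 and cancer_p75 > c.expressed_tpm

    frac_low = float((healthy_pooled < c.healthy_low_tpm).mean()) if healthy_pooled.size else 1.0
    c2 = frac_low >= c.healthy_low_fraction

    max_median = max(healthy_group_medians.values()) if healthy_group_medians else 0.0
    c3 = cancer_p75 >= c.fold * max_median

    c4: bool | None
    if matched_p90 is None:
        c4 = None
    else:
        c4 = cancer_p75 >= c.fold * matched_p90

    selected = c1 and c2 and c3 and (c4 is not False)
    return CLTRecord(
        transcript_id="",
        cancer_type="",
        c1=c1,
        c2=c2,
        c3=c3,
        c4=c4,
        selected=selected,
        cancer_p75=cancer_p75,
        n_expressed_samples=n_expr,
        healthy_low_fraction=frac_low,
        max_healthy_median=max_median,
        matched_p90=matched_p90,
    )


def select_cancer_specific(
    matrix: ExpressionMatrix,
    criteria: SelectionCriteria | None = None,
    ltr_transcript_ids: Iterable[str] | None = None,
    exclude_ids: Iterable[str] = (),
) -> list[CLTRecord]:
    """Apply the four cancer-specificity criteria per cancer type.

    ``ltr_transcript_ids`` restricts candidates to LTR-overlapping
    transcripts (the selection unit); ``exclude_ids`` is the manual
    misassembly-exclusion hook.
    """
    criteria = criteria or SelectionCriteria()
    if not matrix.cancer_groups:
        raise ValueError("matrix has no cancer groups")
    if not matrix.healthy_groups:
        raise ValueError("matrix has no healthy groups")

    candidates = list(matrix.transcript_ids)
    if ltr_transcript_ids is not None:
        keep = set(ltr_transcript_ids)
        candidates = [t for t in candidates if t in keep]
    excluded = set(exclude_ids)
    candidates = [t for t in candidates if t not in excluded]

    healthy_pooled = matrix.healthy_values()
    healthy_group_vals = {g: matrix.group_values(g) for g in matrix.healthy_groups}
    healthy_medians = {
        g: pd.Series(np.percentile(v.values, 50, axis=1), index=v.index)
        for g, v in healthy_group_vals.items()
    }

    records: list[CLTRecord] = []
    for cancer in matrix.cancer_groups:
        cohort = matrix.group_values(cancer)
        if cohort.shape[1] != criteria.discovery_cohort_size and not criteria.scale_min_samples:
            if cohort.shape[1] < criteria.min_expressed_samples:
                raise ValueError(
                    f"cancer group {cancer!r} has {cohort.shape[1]} samples, fewer than "
                    f"min_expressed_samples={criteria.min_expressed_samples}; set "
                    "scale_min_samples to adapt the criterion"
                )
        matched = matrix.matched_tissue(cancer)
        matched_p90_all = None
        if matched is not None:
            mv = healthy_group_vals[matched]
            matched_p90_all = pd.Series(np.percentile(mv.values, 90, axis=1), index=mv.index)
        for tid in candidates:
            rec = evaluate_criteria(
                cohort.loc[tid].values,
                healthy_pooled.loc[tid].values,
                {g: float(m.loc[tid]) for g, m in healthy_medians.items()},
                None if matched_p90_all is None else float(matched_p90_all.loc[tid]),
                criteria,
            )
            rec.transcript_id = tid
            rec.cancer_type = cancer
            records.append(rec)
    return records


def records_to_frame(records: Sequence[CLTRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "cancer_type": [r.cancer_type for r in records],
            "c1": [r.c1 for r in records],
            "c2": [r.c2 for r in records],
            "c3": [r.c3 for r in records],
            "c4": ["NA" if r.c4 is None else r.c4 for r in records],
            "selected": [r.selected for r in records],
            "cancer_p75": [r.cancer_p75 for r in records],
            "n_expressed_samples": [r.n_expressed_samples for r in records],
            "healthy_low_fraction": [r.healthy_low_fraction for r in records],
            "max_healthy_median": [r.max_healthy_median for r in records],
            "matched_p90": [np.nan if r.matched_p90 is None else r.matched_p90 for r in records],
        }
    )


def selected_ids(records: Iterable[CLTRecord]) -> set[tuple[str, str]]:
    return {(r.transcript_id, r.cancer_type) for r in records if r.selected}


# ---------------------------------------------------------------------------
# validation cohorts

@dataclass
class ValidationResult:
    transcript_id: str
    validation_group: str
    positive_fraction: float | None  # None when missing from the matrix
    validated: bool | None


def validate_prevalence(
    validation_matrix: ExpressionMatrix,
    clt_ids: Iterable[str],
    healthy_group_medians: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    positive_fraction: float = 0.25,
    fold: float = 3.0,
) -> list[ValidationResult]:
    """Positivity of each CLT across validation-cohort samples.

    A sample is positive iff TPM is strictly more than ``fold`` times the
    highest healthy per-tissue median; a CLT validates iff its positive
    fraction exceeds ``positive_fraction``. CLTs absent from the validation
    matrix are recorded as missing, not failed.
    """
    medians = pd.DataFrame(healthy_group_medians)
    results: list[ValidationResult] = []
    for group in validation_matrix.validation_groups:
        vals = validation_matrix.group_values(group)
        for tid in clt_ids:
            if tid not in vals.index or tid not in medians.index:
                results.append(ValidationResult(tid, group, None, None))
                continue
            cutoff = fold * float(medians.loc[tid].max())
            frac = float((vals.loc[tid].values > cutoff).mean())
            results.append(ValidationResult(tid, group, frac, frac > positive_fraction))
    return results


def validation_rate(results: Iterable[ValidationResult]) -> tuple[int, int, float]:
    """(validated, evaluable, whole-percent validated).

    The percentage is truncated to a whole percent, the reporting
    convention used for prevalence rates throughout the package.
    """
    evaluable = [r for r in results if r.validated is not None]
    n_ok = sum(1 for r in evaluable if r.validated)
    return n_ok, len(evaluable), as_whole_percent(n_ok, len(evaluable))


def as_whole_percent(numerator: int, denominator: int) -> float:
    """Truncated whole-percent ratio (86.4% -> 86)."""
    if denominator == 0:
        raise ValueError("whole-percent of empty denominator")
    return float(math.floor(100.0 * numerator / denominator))


# ---------------------------------------------------------------------------
# sharing and LTR usage

def sharing_across_types(records: Iterable[CLTRecord]) -> dict[int, int]:
    """Histogram: number of CLTs shared by exactly k cancer types."""
    per_clt = Counter(r.transcript_id for r in records if r.selected)
    hist: Counter[int] = Counter(per_clt.values())
    return dict(sorted(hist.items()))


@dataclass
class LTRUsageStats:
    total: int
    used_expressed: int
    used_clt: int
    used_healthy_only: int
    used_healthy_additionally: int
    pct_expressed: float
    pct_clt: float


def usage_percentage(used: int, total: int) -> float:
    """LTR-element usage percentage, one decimal (17.283% -> 17.3)."""
    if total <= 0:
        raise ValueError("usage percentage needs a positive total")
    return round(100.0 * used / total, 1)


def ltr_usage_stats(
    repeats: Sequence[RepeatElement],
    expressed_transcripts: Sequence[TranscriptModel],
    clt_transcripts: Sequence[TranscriptModel],
    healthy_transcripts: Sequence[TranscriptModel] = (),
) -> LTRUsageStats:
    """Counts/percentages of annotated LTR elements used by transcript sets.

    An element is "used" by a set iff it has exonic overlap with at least
    one transcript of the set.
    """
    ltr = [r for r in repeats if r.repeat_class == "LTR"]
    if not repeats:
        raise ValueError("empty repeat table")

    def used_by(transcripts: Sequence[TranscriptModel]) -> set[int]:
        exons = [e for t in transcripts for e in t.exons]
        idx = build_interval_index(exons)
        hit: set[int] = set()
        for i, el in enumerate(ltr):
            if overlapping_elements(idx, el.interval):
                hit.add(i)
        return hit

    expressed = used_by(expressed_transcripts)
    clt = used_by(clt_transcripts)
    healthy = used_by(healthy_transcripts)
    total = len(ltr)
    return LTRUsageStats(
        total=total,
        used_expressed=len(expressed),
        used_clt=len(clt),
        used_healthy_only=len(healthy - clt),
        used_healthy_additionally=len(healthy & clt),
        pct_expressed=usage_percentage(len(expressed), total),
        pct_clt=usage_percentage(len(clt), total),
    )
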