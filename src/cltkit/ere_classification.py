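"""Transcript classification against repeat and gene annotations.

Four classifiers and a splice-site recovery statistic:

* ERE overlap class (hierarchical LTR > LINE > SINE > other over exonic
  overlap only — intronic repeats never count);
* annotation status against a reference assembly (annotated /
  partially_annotated / unannotated);
* gene-biotype overlap with protein_coding > lncRNA > other_RNA precedence;
* structural position of the LTR element within the transcript — the five
  mutually exclusive categories stand_alone, ltr_initiated,
  ltr_terminal_unknown_strand, embedded and spliced.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation_io import (
    GeneAnnotation,
    GenomicInterval,
    RepeatElement,
    TranscriptModel,
    build_interval_index,
    overlapping_elements,
    splice_boundary_positions,
)

ERE_HIERARCHY = ("LTR", "LINE", "SINE", "other")
LTR_CATEGORIES = (
    "stand_alone",
    "ltr_initiated",
    "ltr_terminal_unknown_strand",
    "embedded",
    "spliced",
)
ANNOTATION_STATUSES = ("annotated", "partially_annotated", "unannotated")


@dataclass
class EREClassification:
    transcript_id: str
    ere_class: str  # LTR | LINE | SINE | other | none
    overlapping_elements: list[tuple[RepeatElement, int]]


@dataclass
class LTRPositionCall:
    transcript_id: str
    category: str
    evidence: list[tuple[RepeatElement, int]]


@dataclass
class LTRPositionParams:
    """Tunables of the structural-position decision procedure."""

    min_overlap_nt: int = 1
    standalone_coverage_fraction: float = 0.8


@dataclass
class AnnotationStatus:
    transcript_id: str
    status: str


def classify_ere_overlap(
    transcript: TranscriptModel,
    repeat_index: Mapping,
    min_overlap: int = 1,
) -> EREClassification:
    """Assign the hierarchical ERE class from exonic repeat overlap.

    A transcript is ERE-overlapping if any exon overlaps a repeat by at
    least ``min_overlap`` nt; with several classes present, LTR wins over
    LINE over SINE over other. SVA integrations count as ``other``.
    """
    per_element: dict[int, tuple[RepeatElement, int]] = {}
    for exon in transcript.exons:
        for element, nt in overlapping_elements(repeat_index, exon):
            key = id(element)
            if key in per_element:
                per_element[key] = (element, per_element[key][1] + nt)
            else:
                per_element[key] = (element, nt)
    hits = [(el, nt) for el, nt in per_element.values() if nt >= min_overlap]
    if not hits:
        return EREClassification(transcript.transcript_id, "none", [])
    classes = {el.repeat_class if el.repeat_class in ERE_HIERARCHY else "other"
               for el, _ in hits}
    for cls in ERE_HIERARCHY:
        if cls in classes:
            return EREClassification(transcript.transcript_id, cls, hits)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# annotation status

def _exon_matches(
    exon: GenomicInterval,
    position: str,  # 'internal' | 'first' | 'last' | 'mono'
    reference_exons: Sequence[tuple[GenomicInterval, str]],
) -> bool:
    """Match rule: internal exons need identical boundaries; terminal exons
    need their splice-side boundary identical (outer boundary free);
    monoexonic exons match when contained in any reference exon."""
    for ref, ref_pos in reference_exons:
        if ref.chrom != exon.chrom:
            continue
        if position == "internal":
            if ref.start == exon.start and ref.end == exon.end:
                return True
        elif position == "first":
            if ref.end == exon.end:
                return True
        elif position == "last":
            if ref.start == exon.start:
                return True
        else:  # monoexonic
            if ref.start <= exon.start and exon.end <= ref.end:
                return True
    return False


def classify_annotation_status(
    transcript: TranscriptModel,
    reference: Sequence[TranscriptModel],
) -> AnnotationStatus:
    """annotated iff every exon is present in the reference; partially
    annotated iff at least one but not all; else unannotated."""
    ref_exons: list[tuple[GenomicInterval, str]] = []
    for ref_t in reference:
        n = len(ref_t.exons)
        for i, e in enumerate(ref_t.exons):
            pos = "mono" if n == 1 else ("first" if i == 0 else "last" if i == n - 1 else "internal")
            ref_exons.append((e, pos))
    n = len(transcript.exons)
    matches = 0
    for i, exon in enumerate(transcript.exons):
        pos = "mono" if n == 1 else ("first" if i == 0 else "last" if i == n - 1 else "internal")
        if _exon_matches(exon, pos, ref_exons):
            matches += 1
    if matches == n:
        status = "annotated"
    elif matches > 0:
        status = "partially_annotated"
    else:
        status = "unannotated"
    return AnnotationStatus(transcript.transcript_id, status)


# ---------------------------------------------------------------------------
# gene-biotype overlap

_BIOTYPE_PRECEDENCE = ("protein_coding", "lncRNA", "other_RNA")


def classify_gene_overlap(
    transcript: TranscriptModel,
    genes: Sequence[GeneAnnotation],
) -> str:
    """Gene-biotype overlap class with protein_coding > lncRNA > other_RNA
    precedence; requires >=1 nt exon-to-exon intersection, so spanning a
    gene's genomic footprint without touching its exons does not count."""
    gene_exons: list[GenomicInterval] = []
    found: set[str] = set()
    for gene in genes:
        overlaps = False
        for ref_t in gene.transcripts:
            for ref_e in ref_t.exons:
                for exon in transcript.exons:
                    if exon.overlap(ref_e) > 0:
                        overlaps = True
                        break
                if overlaps:
                    break
            if overlaps:
                break
        if overlaps:
            found.add(gene.biotype)
    for bt in _BIOTYPE_PRECEDENCE:
        if bt in found:
            return bt
    return "none"


# ---------------------------------------------------------------------------
# LTR structural position

def classify_ltr_position(
    transcript: TranscriptModel,
    repeat_index: Mapping,
    params: LTRPositionParams | None = None,
    gene_overlap: str = "none",
) -> LTRPositionCall:
    """Place the LTR element within the transcript structure.

    Priority order when several rules fire: stand_alone, spliced,
    ltr_initiated, ltr_terminal_unknown_strand, embedded; embedded also
    absorbs the residual cases so every LTR-overlapping transcript gets
    exactly one category.

    Raises ValueError when called on a transcript without exonic LTR
    overlap.
    """
    params = params or LTRPositionParams()
    classification = classify_ere_overlap(transcript, repeat_index, params.min_overlap_nt)
    ltr_hits = [
        (el, nt) for el, nt in classification.overlapping_elements
        if el.repeat_class == "LTR"
    ]
    if not ltr_hits:
        raise ValueError(
            f"{transcript.transcript_id}: classify_ltr_position requires exonic LTR overlap"
        )

    tid = transcript.transcript_id

    # stand-alone: nearly all exonic sequence is LTR and no gene overlap
    ltr_covered = _exonic_ltr_coverage(transcript, ltr_hits)
    if (
        gene_overlap == "none"
        and ltr_covered / transcript.exonic_length >= params.standalone_coverage_fraction
    ):
        return LTRPositionCall(tid, "stand_alone", ltr_hits)

    # spliced: an LTR provides at least one splice site (boundary strictly inside)
    boundaries = transcript.internal_boundaries()
    spliced_ev = [
        (el, nt)
        for el, nt in ltr_hits
        if any(el.interval.start < b < el.interval.end for b in boundaries)
    ]
    if spliced_ev:
        return LTRPositionCall(tid, "spliced", spliced_ev)

    # LTR-initiated: strand known, TSS inside an LTR
    tss = transcript.tss
    if tss is not None:
        init_ev = [(el, nt) for el, nt in ltr_hits if el.interval.contains_position(tss)]
        if init_ev:
            return LTRPositionCall(tid, "ltr_initiated", init_ev)

    # terminal, strand unknown: an LTR overlaps a terminal exon
    if transcript.strand == ".":
        terminal = {transcript.exons[0], transcript.exons[-1]}
        term_ev = [
            (el, nt)
            for el, nt in ltr_hits
            if any(el.interval.overlap(e) > 0 for e in terminal)
        ]
        if term_ev:
            return LTRPositionCall(tid, "ltr_terminal_unknown_strand", term_ev)

    # embedded: LTR wholly inside one exon, no splice boundary or TSS inside it;
    # the residual cases (e.g. partial terminal overlap on a stranded
    # transcript) also land here.
    emb_ev = []
    for el, nt in ltr_hits:
        for exon in transcript.exons:
            if (
                exon.start <= el.interval.start
                and el.interval.end <= exon.end
                and not any(el.interval.start < b < el.interval.end for b in boundaries)
                and (tss is None or not el.interval.contains_position(tss))
            ):
                emb_ev.append((el, nt))
                break
    return LTRPositionCall(tid, "embedded", emb_ev or ltr_hits)


def _exonic_ltr_coverage(
    transcript: TranscriptModel, ltr_hits: Iterable[tuple[RepeatElement, int]]
) -> int:
    """Exonic nucleotides covered by the union of LTR elements."""
    segments: list[tuple[int, int]] = []
    for el, _ in ltr_hits:
        for exon in transcript.exons:
            s = max(exon.start, el.interval.start)
            e = min(exon.end, el.interval.end)
            if s < e:
                segments.append((s, e))
    segments.sort()
    covered = 0
    cur_s, cur_e = None, None
    for s, e in segments:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


# ---------------------------------------------------------------------------
# splice-site recovery

@dataclass
class SpliceSiteRecovery:
    per_transcript: dict[str, tuple[float, int]]  # tid -> (recovered fraction, missing)
    overall_percent: float
    median_missing: float
    n_reference_sites: int = field(default=0)


def splice_site_recovery(
    assembly: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
) -> SpliceSiteRecovery:
    """Fraction of reference splice boundaries recovered by the assembly.

    A reference site is recovered iff an assembly splice boundary exists at
    the identical chromosome/position. Monoexonic reference transcripts
    contribute no sites (recorded as fully recovered with 0 missing).
    """
    if not reference:
        raise ValueError("empty reference annotation")
    assembled: set[tuple[str, int]] = set()
    for t in assembly:
        assembled |= splice_boundary_positions(t)

    per_transcript: dict[str, tuple[float, int]] = {}
    all_ref_sites: set[tuple[str, int]] = set()
    for t in reference:
        sites = splice_boundary_positions(t)
        all_ref_sites |= sites
        if not sites:
            per_transcript[t.transcript_id] = (1.0, 0)
            continue
        recovered = len(sites & assembled)
        per_transcript[t.transcript_id] = (recovered / len(sites), len(sites) - recovered)

    overall = (
        100.0 * len(all_ref_sites & assembled) / len(all_ref_sites)
        if all_ref_sites
        else 100.0
    )
    median_missing = statistics.median(m for _, m in per_transcript.values())
    return SpliceSiteRecovery(per_transcript, overall, median_missing, len(all_ref_sites))


# ---------------------------------------------------------------------------
# tabular export

def classification_table(
    transcripts: Sequence[TranscriptModel],
    repeats: Sequence[RepeatElement],
    reference: Sequence[TranscriptModel] | None = None,
    genes: Sequence[GeneAnnotation] | None = None,
    params: LTRPositionParams | None = None,
):
    """One row per transcript with every classification column."""
    import pandas as pd

    index = build_interval_index(repeats)
    rows = []
    for t in transcripts:
        ere = classify_ere_overlap(t, index, (params or LTRPositionParams()).min_overlap_nt)
        gene_ov = classify_gene_overlap(t, genes) if genes is not None else "none"
        row = {
            "transcript_id": t.transcript_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "n_exons": len(t.exons),
            "ere_class": ere.ere_class,
            "gene_overlap": gene_ov,
        }
        if reference is not None:
            row["annotation_status"] = classify_annotation_status(t, reference).status
        if ere.ere_class == "LTR":
            row["ltr_position"] = classify_ltr_position(t, index, params, gene_ov).category
        else:
            row["ltr_position"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
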