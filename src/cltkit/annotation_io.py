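"""Annotation I/O and interval primitives.

Internal convention: all coordinates are 0-based half-open; conversion to
the 1-based closed conventions of GTF and RepeatMasker ``.out`` happens only
at the file boundary. Strand is one of ``+``, ``-`` or ``.`` (unknown) —
strand-unknown transcripts are kept as first-class objects because the
downstream structural taxonomy has a dedicated category for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}
REPEAT_CLASSES = ("LTR", "LINE", "SINE", "SVA", "other")
GENE_BIOTYPES = ("protein_coding", "lncRNA", "other_RNA")


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid models."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping nucleotides with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """A (possibly strand-unknown) multi-exon transcript model."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for e in exons:
            if e.chrom != self.chrom:
                raise AnnotationError(
                    f"{self.transcript_id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def tss(self) -> int | None:
        """Transcription start site: first transcribed base on the coding
        strand. Undefined (None) when the strand is unknown."""
        if self.strand == "+":
            return self.exons[0].start
        if self.strand == "-":
            return self.exons[-1].end - 1
        return None

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def internal_boundaries(self) -> list[int]:
        """Positions of internal exon boundaries (splice boundaries)."""
        out: list[int] = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(a.end)
            out.append(b.start)
        return out


@dataclass(frozen=True)
class RepeatElement:
    """One genomic repeat integration from a RepeatMasker-style annotation."""

    interval: GenomicInterval
    repeat_name: str
    repeat_family: str
    repeat_class: str

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise AnnotationError("repeat_name must be non-empty")
        if self.repeat_class not in REPEAT_CLASSES:
            raise AnnotationError(f"invalid repeat_class {self.repeat_class!r}")

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class GeneAnnotation:
    gene_id: str
    biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in GENE_BIOTYPES:
            raise AnnotationError(f"invalid biotype {self.biotype!r}")


# ---------------------------------------------------------------------------
# splice sites

def splice_sites(transcript: TranscriptModel) -> set[tuple[str, int, str]]:
    """Splice-boundary set ``{(chrom, position, side)}`` of a transcript.

    Sides are ``donor`` / ``acceptor`` when the strand is known and
    ``boundary`` when it is not. Monoexonic transcripts yield the empty set.
    """
    sites: set[tuple[str, int, str]] = set()
    for a, b in zip(transcript.exons, transcript.exons[1:]):
        if transcript.strand == "+":
            left, right = "donor", "acceptor"
        elif transcript.strand == "-":
            left, right = "acceptor", "donor"
        else:
            left = right = "boundary"
        sites.add((transcript.chrom, a.end, left))
        sites.add((transcript.chrom, b.start, right))
    return sites


def splice_boundary_positions(transcript: TranscriptModel) -> set[tuple[str, int]]:
    """Side-agnostic splice-boundary positions (for recovery comparisons)."""
    return {(c, p) for c, p, _ in splice_sites(transcript)}


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR_RE = re.compile(r'(\w+)[ =]+"?([^";]+)"?;?')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2).strip() for m in _GTF_ATTR_RE.finditer(text)}


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from GTF exon features.

    GTF 1-based closed coordinates become 0-based half-open; strand ``.`` is
    kept as unknown. A transcript_id reused across chromosomes is an error.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "exon":
                continue
            attr = _parse_gtf_attributes(attrs)
            tid = attr.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: exon without transcript_id")
            gid = attr.get("gene_id", tid)
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if tid in meta:
                if meta[tid][1] != chrom:
                    raise AnnotationError(
                        f"{path}:{lineno}: transcript_id {tid!r} spans chromosomes"
                    )
            else:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            exons.setdefault(tid, []).append(iv)
    transcripts = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        transcripts.append(
            TranscriptModel(tid, gid, chrom, strand, tuple(exons[tid]))
        )
    return transcripts


def read_gtf_biotypes(path: str | Path) -> dict[str, str]:
    """gene_id -> biotype mapping from GTF gene_biotype/gene_type attributes."""
    biotypes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            attr = _parse_gtf_attributes(fields[8])
            gid = attr.get("gene_id")
            bt = attr.get("gene_biotype") or attr.get("gene_type")
            if gid and bt:
                biotypes[gid] = bt if bt in GENE_BIOTYPES else "other_RNA"
    return biotypes


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Group a biotyped GTF into GeneAnnotation records."""
    transcripts = read_gtf(path)
    biotypes = read_gtf_biotypes(path)
    genes: dict[str, GeneAnnotation] = {}
    for t in transcripts:
        if t.gene_id not in genes:
            genes[t.gene_id] = GeneAnnotation(
                t.gene_id, biotypes.get(t.gene_id, "other_RNA")
            )
        genes[t.gene_id].transcripts.append(t)
    return list(genes.values())


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    biotypes: Mapping[str, str] | None = None,
    source: str = "cltkit",
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            extra = ""
            if biotypes and t.gene_id in biotypes:
                extra = f' gene_biotype "{biotypes[t.gene_id]}";'
            for i, e in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";{extra}'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker / BED

def _repeat_class_of(class_family: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family string into (class, family)."""
    if "/" in class_family:
        cls, fam = class_family.split("/", 1)
    else:
        cls, fam = class_family, class_family
    if cls not in REPEAT_CLASSES:
        cls = "other"
    return cls, fam


def read_repeatmasker(path: str | Path, dialect: str = "rm_out") -> list[RepeatElement]:
    """Read repeat elements from RepeatMasker ``.out`` or BED6.

    In the BED dialect the name field is ``name|family|class``. A file with
    only headers yields an empty list.
    """
    if dialect not in {"rm_out", "bed"}:
        raise AnnotationError(f"unknown repeat dialect {dialect!r}")
    repeats: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if dialect == "rm_out":
                # skip the two header lines (start with 'SW' / 'score')
                first = stripped.split()[0]
                if first in {"SW", "score"}:
                    continue
                fields = stripped.split()
                if len(fields) < 11:
                    raise AnnotationError(f"{path}:{lineno}: malformed .out row")
                try:
                    chrom = fields[4]
                    start = int(fields[5]) - 1
                    end = int(fields[6])
                    strand = "+" if fields[8] == "+" else "-"
                    name = fields[9]
                    cls, fam = _repeat_class_of(fields[10])
                except (ValueError, IndexError) as exc:
                    raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            else:
                if stripped.startswith(("track", "browser", "#")):
                    continue
                fields = stripped.split("\t")
                if len(fields) < 4:
                    raise AnnotationError(f"{path}:{lineno}: BED row needs >=4 columns")
                try:
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    parts = fields[3].split("|")
                    name = parts[0]
                    fam = parts[1] if len(parts) > 1 else name
                    cls = parts[2] if len(parts) > 2 else "other"
                    if cls not in REPEAT_CLASSES:
                        cls = "other"
                    strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
                except ValueError as exc:
                    raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            repeats.append(
                RepeatElement(GenomicInterval(chrom, start, end, strand), name, fam, cls)
            )
    return repeats


def write_repeats_bed(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            name = f"{r.repeat_name}|{r.repeat_family}|{r.repeat_class}"
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{name}\t0\t{r.interval.strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals from a BED3+ file."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: BED row needs >=3 columns")
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA (via Biopython)

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# interval index

def build_interval_index(
    elements: Sequence[RepeatElement] | Sequence[GenomicInterval],
) -> dict[str, IntervalTree]:
    """Per-chromosome IntervalTree over repeats or plain intervals."""
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        iv = el.interval if isinstance(el, RepeatElement) else el
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, el)
    return trees


def overlapping_elements(
    index: Mapping[str, IntervalTree], query: GenomicInterval
) -> list[tuple[object, int]]:
    """All indexed elements overlapping ``query`` with the overlap in nt."""
    tree = index.get(query.chrom)
    if tree is None:
        return []
    hits = []
    for node in tree.overlap(query.start, query.end):
        nt = min(node.end, query.end) - max(node.begin, query.start)
        if nt > 0:
            hits.append((node.data, nt))
    return hits
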