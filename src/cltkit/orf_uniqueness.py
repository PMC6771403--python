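"""ORF prediction, dicodon coding-potential scoring and uniqueness filtering.

Coding potential is judged by an in-frame hexamer (codon-pair) log-odds
model trained on a coding corpus against a background corpus: the score of
an ORF is the mean log-odds over its codon-stepped hexamers, and an ORF is
a coding candidate when its sense score strictly exceeds the score of its
reverse complement. Candidate CLT proteins are then screened for sequence
uniqueness against the translated ORF universe of the whole assembly by
local protein alignment (BLOSUM62, affine gaps), with percent identity
measured over the full candidate length.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_io import write_fasta

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    table = _codon_table()
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aas.append(table.get(seq[i : i + 3], "X"))
    return "".join(aas)


@dataclass
class OpenReadingFrame:
    """An ATG..stop span in transcript-local coordinates (stop included)."""

    transcript_id: str
    start: int  # 0-based
    end: int    # half-open, includes the stop codon
    frame: int
    peptide: str
    sense_score: float = math.nan
    antisense_score: float = math.nan

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.nt_length % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.frame != self.start % 3:
            raise ValueError("frame must equal start mod 3")


def find_orfs(
    sequence: str,
    min_len: int,
    transcript_id: str = "",
    all_starts: bool = False,
) -> list[OpenReadingFrame]:
    """All ATG->stop ORFs of nt length >= ``min_len`` in the three forward
    frames. Within one stop-bounded region only the 5'-most ATG is reported
    unless ``all_starts``. Codons containing N never match ATG or a stop."""
    seq = sequence.upper()
    table = _codon_table()
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            if codon == "ATG":
                if all_starts or not starts:
                    starts.append(i)
            elif codon in STOP_CODONS:
                for s in starts:
                    length = i + 3 - s
                    if length >= min_len:
                        orfs.append(
                            OpenReadingFrame(
                                transcript_id,
                                s,
                                i + 3,
                                frame,
                                translate(seq[s:i]),
                            )
                        )
                starts = []
        # ORFs without a stop codon before the sequence end are not reported
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def largest_orf(orfs: Sequence[OpenReadingFrame]) -> OpenReadingFrame | None:
    """Longest ORF; ties broken by 5'-most start."""
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-o.nt_length, o.start))


# ---------------------------------------------------------------------------
# hexamer (dicodon) model

ALL_HEXAMERS = ["".join(h) for h in itertools.product("ACGT", repeat=6)]


@dataclass
class HexamerModel:
    """In-frame hexamer log-odds table (4096 entries)."""

    log_odds: dict[str, float]
    pseudocount: float
    n_coding: int = 0
    n_background: int = 0

    def __post_init__(self) -> None:
        missing = [h for h in ALL_HEXAMERS if h not in self.log_odds]
        if missing:
            raise ValueError(f"log-odds table missing {len(missing)} hexamers")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pseudocount={self.pseudocount} n_coding={self.n_coding} "
                     f"n_background={self.n_background}\n")
            for h in ALL_HEXAMERS:
                fh.write(f"{h}\t{self.log_odds[h]:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "HexamerModel":
        log_odds = {}
        pc, nc, nb = 1e-5, 0, 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for token in line[1:].split():
                        k, _, v = token.partition("=")
                        if k == "pseudocount":
                            pc = float(v)
                        elif k == "n_coding":
                            nc = int(v)
                        elif k == "n_background":
                            nb = int(v)
                    continue
                h, v = line.split("\t")
                log_odds[h] = float(v)
        return cls(log_odds, pc, nc, nb)


def _hexamer_frequencies(sequences: Iterable[str], stride: int = 3) -> dict[str, float]:
    counts = dict.fromkeys(ALL_HEXAMERS, 0)
    total = 0
    for seq in sequences:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, stride):
            hx = seq[i : i + 6]
            if hx in counts:
                counts[hx] += 1
                total += 1
    if total == 0:
        return dict.fromkeys(ALL_HEXAMERS, 0.0)
    return {h: c / total for h, c in counts.items()}


def train_hexamer_model(
    coding: Iterable[str] | Mapping[str, str],
    background: Iterable[str] | Mapping[str, str],
    pseudocount: float = 1e-5,
    stride: int = 3,
) -> HexamerModel:
    """Log-odds of in-frame (codon-stepped) hexamer frequencies, coding vs
    background: ``log((f_coding + pc) / (f_background + pc))``."""
    coding_seqs = list(coding.values() if isinstance(coding, Mapping) else coding)
    bg_seqs = list(background.values() if isinstance(background, Mapping) else background)
    if not coding_seqs or not bg_seqs:
        raise ValueError("empty training set")
    for s in coding_seqs:
        if len(s) % 3 != 0:
            raise ValueError("coding training sequences must have length divisible by 3")
    fc = _hexamer_frequencies(coding_seqs, stride)
    fb = _hexamer_frequencies(bg_seqs, stride)
    log_odds = {
        h: math.log((fc[h] + pseudocount) / (fb[h] + pseudocount)) for h in ALL_HEXAMERS
    }
    return HexamerModel(log_odds, pseudocount, len(coding_seqs), len(bg_seqs))


def hexamer_score(sequence: str, model: HexamerModel, stride: int = 3) -> float:
    """Mean log-odds over the in-frame codon-stepped hexamers of ``sequence``."""
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    vals = []
    for i in range(0, len(seq) - 5, stride):
        hx = seq[i : i + 6]
        if hx in model.log_odds:
            vals.append(model.log_odds[hx])
    if not vals:
        raise ValueError("sequence contains no scoreable hexamers")
    return float(np.mean(vals))


def score_orf(sequence: str, model: HexamerModel, stride: int = 3) -> tuple[float, float]:
    """(sense, antisense) hexamer scores; antisense is the score of the
    reverse complement. Coding candidates require sense > antisense
    (strict)."""
    if len(sequence) < 6 or len(sequence) % 3 != 0:
        raise ValueError("ORF sequence must be >= 6 nt and divisible by 3")
    sense = hexamer_score(sequence, model, stride)
    antisense = hexamer_score(reverse_complement(sequence), model, stride)
    return sense, antisense


# ---------------------------------------------------------------------------
# candidate selection

@dataclass
class UniquenessCriteria:
    identity_threshold: float = 85.0   # percent
    orf_universe_min: int = 210        # nt
    candidate_min: int = 300           # nt
    peptide_db_min: int = 75           # nt
    evalue_cutoff: float = 1e-5        # kept for external aligner plug-ins
    healthy_median_cutoff: float = 1.0 # TPM; >= eliminates

    def __post_init__(self) -> None:
        if self.peptide_db_min > self.candidate_min:
            raise ValueError("peptide_db_min must be <= candidate_min")


@dataclass
class CodingCandidate:
    transcript_id: str
    orf: OpenReadingFrame
    max_healthy_median: float


def select_coding_clts(
    clt_ids: Iterable[str],
    sequences: Mapping[str, str],
    model: HexamerModel,
    max_healthy_median: Mapping[str, float],
    criteria: UniquenessCriteria | None = None,
) -> list[CodingCandidate]:
    """CLTs with >=1 coding-scoring ORF of candidate length and healthy
    median below the elimination cutoff ("one or more TPM" eliminates)."""
    criteria = criteria or UniquenessCriteria()
    candidates: list[CodingCandidate] = []
    for tid in clt_ids:
        if tid not in sequences:
            warnings.warn(f"{tid}: no sequence available, skipped")
            continue
        healthy = float(max_healthy_median.get(tid, 0.0))
        if healthy >= criteria.healthy_median_cutoff:
            continue
        orfs = find_orfs(sequences[tid], criteria.candidate_min, transcript_id=tid)
        passing = []
        for orf in orfs:
            orf_seq = sequences[tid][orf.start : orf.end]
            orf.sense_score, orf.antisense_score = score_orf(orf_seq, model)
            if orf.sense_score > orf.antisense_score:
                passing.append(orf)
        best = largest_orf(passing)
        if best is not None:
            candidates.append(CodingCandidate(tid, best, healthy))
    return candidates


# ---------------------------------------------------------------------------
# pairwise identity and uniqueness

def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(query: str, target: str) -> float:
    """Percent identity of the best local alignment, over the full query
    length ("over the entire length of the protein")."""
    if not query or not target:
        raise ValueError("empty peptide")
    aligner = _aligner()
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0
    aln = alignments[0]
    identical = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        identical += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
    return 100.0 * identical / len(query)


@dataclass
class UniverseORF:
    orf_id: str
    transcript_id: str
    peptide: str


def build_orf_universe(
    sequences: Mapping[str, str],
    min_len: int = 210,
) -> list[UniverseORF]:
    """Translated ORFs >= ``min_len`` nt from the whole assembly."""
    universe: list[UniverseORF] = []
    for tid in sorted(sequences):
        for k, orf in enumerate(find_orfs(sequences[tid], min_len, transcript_id=tid)):
            universe.append(UniverseORF(f"{tid}|orf{k}", tid, orf.peptide))
    return universe


@dataclass
class UniquenessCall:
    transcript_id: str
    unique: bool
    retained: bool
    partners: list[tuple[str, float]] = field(default_factory=list)


def uniqueness_filter(
    candidates: Sequence[CodingCandidate],
    orf_universe: Sequence[UniverseORF],
    transcript_status: Mapping[str, str],  # tid -> cancer_specific | healthy | other
    criteria: UniquenessCriteria | None = None,
) -> list[UniquenessCall]:
    """Uniqueness screen of candidate ORFs against the assembly universe.

    A candidate is unique iff no universe ORF from another transcript
    aligns with identity above the threshold. Non-unique candidates are
    discarded iff any high-identity partner's transcript is
    healthy-expressed, and retained otherwise (partners that are themselves
    cancer-specific, or unexpressed, do not disqualify)."""
    criteria = criteria or UniquenessCriteria()
    if not orf_universe:
        raise ValueError("empty ORF universe")
    calls: list[UniquenessCall] = []
    for cand in sorted(candidates, key=lambda c: c.transcript_id):
        partners: list[tuple[str, float]] = []
        for uni in orf_universe:
            if uni.transcript_id == cand.transcript_id:
                continue
            ident = pairwise_identity(cand.orf.peptide, uni.peptide)
            if ident > criteria.identity_threshold:
                partners.append((uni.transcript_id, ident))
        unique = not partners
        discarded = any(
            transcript_status.get(tid, "other") == "healthy" for tid, _ in partners
        )
        calls.append(
            UniquenessCall(cand.transcript_id, unique, not discarded, partners)
        )
    return calls


# ---------------------------------------------------------------------------
# peptide search database

def export_peptide_db(
    final_clt_ids: Iterable[str],
    sequences: Mapping[str, str],
    path,
    min_len: int = 75,
) -> int:
    """FASTA of translated ORFs >= ``min_len`` nt from the final CLT set.

    Headers are ``transcript_id|start-end|frame``; stop codons are excluded
    from the peptides. Returns the number of records written."""
    final_ids = sorted(set(final_clt_ids))
    if not final_ids:
        raise ValueError("empty final CLT set")
    records: dict[str, str] = {}
    for tid in final_ids:
        if tid not in sequences:
            warnings.warn(f"{tid}: no sequence available, skipped")
            continue
        for orf in find_orfs(sequences[tid], min_len, transcript_id=tid, all_starts=True):
            header = f"{tid}|{orf.start}-{orf.end}|{orf.frame}"
            records[header] = orf.peptide
    write_fasta(records, path)
    return len(records)
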