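"""Seeded synthetic fixtures with planted ground truth.

Every generator here emulates the statistical structure one downstream
stage assumes, with the truth recorded in a :class:`FixtureManifest`:

* a repeat-annotated virtual genome (coordinates only, no real homology);
* transcripts planted in each of the five LTR structural categories, which
  the structural classifier must recover exactly on these noise-free
  models;
* TPM matrices in which planted cancer-specific transcripts satisfy all
  four selection criteria with margin and each decoy violates exactly one;
* hexamer-biased coding corpora and transcripts with planted ORFs;
* survival cohorts with exponential event times whose hazard is multiplied
  by a known ratio in the top expression tertile;
* ATAC-like peak sets enriched at planted TSSs.

All generators take an explicit seed and no global random state is used;
identical seeds give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomicInterval,
    RepeatElement,
    TranscriptModel,
)

LTR_FAMILY_NAMES = ["MLT1A0", "THE1A", "HERVH", "MLT1B", "MLT1A", "MER41G", "HERVK"]
_CLASS_NAMES = {
    "LTR": (LTR_FAMILY_NAMES, "ERVL-MaLR"),
    "LINE": (["L1MB7", "L2a", "L1PA4"], "L1"),
    "SINE": (["AluSx", "AluY", "MIRb"], "Alu"),
    "other": (["MER5A", "Charlie1"], "hAT-Charlie"),
}
STRUCTURAL_CATEGORIES = (
    "stand_alone",
    "ltr_initiated",
    "ltr_terminal_unknown_strand",
    "embedded",
    "spliced",
)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureManifest:
    """Ground-truth record for one generated fixture bundle."""

    seed: int
    genome: dict[str, int] = field(default_factory=dict)
    planted_clts: list[tuple[str, str, str]] = field(default_factory=list)
    decoys: list[tuple[str, int]] = field(default_factory=list)
    planted_coding_orfs: dict[str, tuple[int, int]] = field(default_factory=dict)
    survival_effects: dict[str, float] = field(default_factory=dict)
    peak_placement: dict[str, int] = field(default_factory=dict)
    structural_truth: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_clts"] = [tuple(x) for x in raw.get("planted_clts", [])]
        raw["decoys"] = [tuple(x) for x in raw.get("decoys", [])]
        raw["planted_coding_orfs"] = {
            k: tuple(v) for k, v in raw.get("planted_coding_orfs", {}).items()
        }
        return cls(**raw)


# ---------------------------------------------------------------------------
# repeats

def generate_repeat_annotation(
    seed: int,
    n_per_class: int | Mapping[str, int],
    genome: Mapping[str, int],
) -> list[RepeatElement]:
    """Uniformly placed repeat integrations over a virtual genome.

    ``n_per_class`` is either a single count for every class in
    {LTR, LINE, SINE, other} or a per-class mapping. LTR elements carry
    family names from the common MaLR/HERV nomenclature.
    """
    if not genome or any(length <= 0 for length in genome.values()):
        raise FixtureError("genome must have positive chromosome lengths")
    if any(length <= 10_000 for length in genome.values()):
        raise FixtureError("chromosome lengths must exceed 10 kb")
    if isinstance(n_per_class, int):
        n_per_class = {cls: n_per_class for cls in _CLASS_NAMES}
    if any(n < 0 for n in n_per_class.values()):
        raise FixtureError("n_per_class must be >= 0")

    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    size_ranges = {"LTR": (300, 1200), "LINE": (500, 3000), "SINE": (100, 350),
                   "other": (150, 800)}
    repeats: list[RepeatElement] = []
    for cls in ("LTR", "LINE", "SINE", "other"):
        names, family = _CLASS_NAMES[cls]
        lo, hi = size_ranges[cls]
        for _ in range(n_per_class.get(cls, 0)):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            size = int(rng.integers(lo, hi))
            start = int(rng.integers(0, genome[chrom] - size))
            name = names[int(rng.integers(0, len(names)))]
            strand = "+" if rng.random() < 0.5 else "-"
            repeats.append(
                RepeatElement(
                    GenomicInterval(chrom, start, start + size, strand),
                    name,
                    family if cls != "LTR" else "ERVL-MaLR",
                    cls,
                )
            )
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return repeats


# ---------------------------------------------------------------------------
# transcript models in the five structural categories

def _repeat_free(
    start: int, end: int, repeats_sorted: Sequence[RepeatElement], chrom: str
) -> bool:
    for r in repeats_sorted:
        iv = r.interval
        if iv.chrom == chrom and iv.start < end and start < iv.end:
            return False
    return True


def _find_clear_ltrs(
    repeats: Sequence[RepeatElement], genome: Mapping[str, int], flank: int = 3000
) -> list[RepeatElement]:
    """LTR elements whose +/- ``flank`` neighbourhood contains no other repeat."""
    clear = []
    for r in repeats:
        if r.repeat_class != "LTR":
            continue
        iv = r.interval
        if iv.start < flank or iv.end + flank > genome.get(iv.chrom, 0):
            continue
        others = [
            x for x in repeats
            if x is not r and x.interval.chrom == iv.chrom
            and x.interval.start < iv.end + flank
            and iv.start - flank < x.interval.end
        ]
        if not others:
            clear.append(r)
    return clear


def generate_transcript_models(
    seed: int,
    repeats: Sequence[RepeatElement],
    n_per_category: int,
    genome: Mapping[str, int] | None = None,
) -> tuple[list[TranscriptModel], dict[str, str], dict[str, int]]:
    """Plant ``n_per_category`` transcripts per structural category.

    Returns (transcripts, truth labels, embedded-category CDS-end genomic
    coordinates). Fixtures are noise-free: each transcript, classified by
    the structural classifier, must yield its planted label. The embedded
    category places the LTR wholly inside the last exon, 3' of the planted
    stop-codon coordinate (an extended UTR).
    """
    if not repeats:
        raise FixtureError("repeat table is empty")
    if n_per_category == 0:
        return [], {}, {}
    if genome is None:
        genome = {}
        for r in repeats:
            genome[r.interval.chrom] = max(
                genome.get(r.interval.chrom, 0), r.interval.end + 10_000
            )
    clear = _find_clear_ltrs(repeats, genome)
    needed = 5 * n_per_category
    if len(clear) < needed:
        raise FixtureError(
            f"cannot construct fixtures: need {needed} LTR elements with clear "
            f"flanks, found {len(clear)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clear))
    transcripts: list[TranscriptModel] = []
    truth: dict[str, str] = {}
    cds_ends: dict[str, int] = {}
    k = 0
    for category in STRUCTURAL_CATEGORIES:
        for i in range(n_per_category):
            ltr = clear[order[k]]
            k += 1
            tid = f"SYN_{category.upper()}_{i:03d}"
            t = _build_category_transcript(tid, category, ltr, cds_ends)
            transcripts.append(t)
            truth[tid] = category
    return transcripts, truth, cds_ends


def _build_category_transcript(
    tid: str,
    category: str,
    ltr: RepeatElement,
    cds_ends: dict[str, int],
) -> TranscriptModel:
    iv = ltr.interval
    chrom = iv.chrom
    if category == "stand_alone":
        # monoexonic transcript covering exactly the LTR
        exons = (GenomicInterval(chrom, iv.start, iv.end, "+"),)
        strand = "+"
    elif category == "ltr_initiated":
        # TSS inside the LTR; the first exon runs past the LTR end so no
        # splice boundary falls inside it, and a long LTR-free second exon
        # keeps coverage below the stand-alone threshold
        e1 = GenomicInterval(chrom, iv.start + 10, iv.end + 200, "+")
        e2 = GenomicInterval(chrom, iv.end + 700, iv.end + 2500, "+")
        exons = (e1, e2)
        strand = "+"
    elif category == "ltr_terminal_unknown_strand":
        # strand unknown; last exon overlaps the LTR head, LTR extends past
        # the exon end (outer boundary, not a splice site)
        e1 = GenomicInterval(chrom, iv.start - 2500, iv.start - 1500, ".")
        e2 = GenomicInterval(chrom, iv.start - 400, iv.start + 100, ".")
        exons = (e1, e2)
        strand = "."
    elif category == "embedded":
        # LTR wholly inside the last exon, 3' of the planted stop codon
        e1 = GenomicInterval(chrom, iv.start - 2800, iv.start - 2200, "+")
        e2 = GenomicInterval(chrom, iv.start - 900, iv.end + 400, "+")
        exons = (e1, e2)
        strand = "+"
        cds_ends[tid] = iv.start - 300  # stop codon upstream of the LTR
    elif category == "spliced":
        # the acceptor boundary of the last exon lies strictly inside the LTR
        e1 = GenomicInterval(chrom, iv.start - 2500, iv.start - 1800, "+")
        e2 = GenomicInterval(chrom, iv.start + 50, iv.end + 1600, "+")
        exons = (e1, e2)
        strand = "+"
    else:
        raise FixtureError(f"unknown structural category {category!r}")
    return TranscriptModel(tid, f"gene_{tid}", chrom, strand, exons)


# ---------------------------------------------------------------------------
# expression matrices with planted CLTs and single-criterion decoys

@dataclass(frozen=True)
class GroupDesign:
    name: str
    kind: str  # cancer | healthy | validation
    n_samples: int
    matched_tissue: str | None = None


def default_design(
    n_cancer_types: int = 3,
    cancer_cohort: int = 24,
    n_healthy: int = 10,
    healthy_cohort: int = 20,
) -> list[GroupDesign]:
    """The default study design: per-cancer discovery cohorts of 24 samples
    compared against a panel of healthy tissues, each cancer matched to one
    healthy tissue."""
    groups = [
        GroupDesign(f"healthy_{i:02d}", "healthy", healthy_cohort)
        for i in range(n_healthy)
    ]
    groups += [
        GroupDesign(f"cancer_{chr(65 + i)}", "cancer", cancer_cohort, f"healthy_{i:02d}")
        for i in range(n_cancer_types)
    ]
    return groups


def generate_expression_matrix(
    seed: int,
    transcript_ids: Sequence[str],
    design: Sequence[GroupDesign],
    planted_clts: Sequence[tuple[str, str]],   # (transcript_id, cancer_group)
    decoys: Sequence[tuple[str, int, str]] = (),  # (transcript_id, criterion, cancer_group)
    noise_sigma: float = 0.2,
    min_samples: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix + metadata with planted CLTs and per-criterion decoys.

    Planted CLTs satisfy all four selection criteria with margin; decoy
    ``(tid, j, cancer)`` fails criterion ``j`` alone. Noise is multiplicative
    log-normal with log-scale sigma ``noise_sigma`` (zero means are exact
    zeros). Background transcripts not named in either list are flat
    ubiquitous expressers (healthy-expressed).
    """
    cancer_groups = [g for g in design if g.kind == "cancer"]
    healthy_groups = [g for g in design if g.kind == "healthy"]
    if any(g.n_samples < min_samples for g in cancer_groups):
        raise FixtureError(f"every cancer group needs >= {min_samples} samples")
    if len(healthy_groups) < 2:
        raise FixtureError("design needs >= 2 healthy tissue groups")
    known = {g.name for g in design}
    for tid, cancer in planted_clts:
        if cancer not in known:
            raise FixtureError(f"planted CLT {tid}: unknown group {cancer}")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    meta_rows = []
    for g in design:
        for i in range(g.n_samples):
            sid = f"{g.name}_s{i:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "group": g.name,
                    "group_kind": g.kind,
                    "matched_tissue": g.matched_tissue or "",
                }
            )
    metadata = pd.DataFrame(meta_rows)
    group_samples = {g.name: [s for s in sample_ids if s.startswith(g.name + "_s")]
                     for g in design}

    planted_map = dict(planted_clts)
    decoy_map = {tid: (crit, cancer) for tid, crit, cancer in decoys}

    means = pd.DataFrame(0.0, index=list(transcript_ids), columns=sample_ids)
    for tid in transcript_ids:
        if tid in planted_map:
            cancer = planted_map[tid]
            means.loc[tid, group_samples[cancer]] = 30.0
            # all other groups stay at exact zero: maximal margin on c2-c4
        elif tid in decoy_map:
            crit, cancer = decoy_map[tid]
            _plant_decoy(means, tid, crit, cancer, design, group_samples)
        else:
            # background: ubiquitously expressed in health and cancer
            means.loc[tid, :] = 20.0

    noise = np.ones(means.shape) if noise_sigma == 0 else np.exp(
        rng.normal(0.0, noise_sigma, size=means.shape)
    )
    tpm = means * noise
    return tpm, metadata


def _plant_decoy(
    means: pd.DataFrame,
    tid: str,
    criterion: int,
    cancer: str,
    design: Sequence[GroupDesign],
    group_samples: Mapping[str, list[str]],
) -> None:
    """Give one decoy transcript a mean profile failing exactly one criterion."""
    cancer_samples = group_samples[cancer]
    matched = next(g.matched_tissue for g in design if g.name == cancer)
    healthy = [g for g in design if g.kind == "healthy"]
    if criterion == 1:
        # expressed in too few cohort samples (and cohort p75 below 1 TPM);
        # healthy all zero so the fold criteria still pass
        means.loc[tid, cancer_samples[:3]] = 30.0
    elif criterion == 2:
        # >10% of pooled healthy samples above 10 TPM, spread thinly so no
        # tissue median rises and the matched tissue stays clean
        means.loc[tid, cancer_samples] = 30.0
        n_healthy_total = sum(g.n_samples for g in healthy)
        n_high = int(np.ceil(0.15 * n_healthy_total))
        pool = [g for g in healthy if g.name != matched]
        placed = 0
        for g in pool:
            take = min(max(g.n_samples // 2 - 1, 1), n_high - placed)
            if take <= 0:
                break
            means.loc[tid, group_samples[g.name][:take]] = 40.0
            placed += take
        if placed < n_high:
            raise FixtureError(f"decoy {tid}: cannot place enough high healthy samples")
    elif criterion == 3:
        # one non-matched healthy tissue with median 5 (< 10 TPM, keeping c2)
        # while the cohort p75 of 6 misses the 3x fold
        means.loc[tid, cancer_samples] = 6.0
        other = next(g for g in healthy if g.name != matched)
        means.loc[tid, group_samples[other.name]] = 5.0
    elif criterion == 4:
        # matched tissue: 45% of samples high -> median stays 0 (c3 passes)
        # but p90 = 30, so the cohort p75 of 30 misses 3 x 30
        means.loc[tid, cancer_samples] = 30.0
        m_samples = group_samples[matched]
        n_high = int(0.45 * len(m_samples))
        means.loc[tid, m_samples[:n_high]] = 30.0
    else:
        raise FixtureError(f"unknown criterion id {criterion}")


# ---------------------------------------------------------------------------
# sequences: hexamer-biased coding corpus + planted ORFs

_BASES = "ACGT"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_STOPS = {"TAA", "TAG", "TGA"}
# fixed per-codon preference weights (arbitrary but reproducible)
_CODON_WEIGHTS = dict(zip(_CODONS, np.random.default_rng(2024).normal(0.0, 1.0, 64)))


def _codon_probs(bias: float) -> np.ndarray:
    """Codon distribution interpolating uniform (bias 0) to a fixed skewed
    distribution (bias 1); stop codons are suppressed as bias grows."""
    w = np.array([
        _CODON_WEIGHTS[c] if c not in _STOPS else -10.0 for c in _CODONS
    ])
    logits = bias * 2.0 * w
    p = np.exp(logits - logits.max())
    return p / p.sum()


def _random_codons(rng: np.random.Generator, n: int, probs: np.ndarray,
                   exclude_stops: bool = False, exclude_atg: bool = False) -> str:
    p = probs.copy()
    if exclude_stops:
        for s in _STOPS:
            p[_CODONS.index(s)] = 0.0
    if exclude_atg:
        p[_CODONS.index("ATG")] = 0.0
    p = p / p.sum()
    idx = rng.choice(64, size=n, p=p)
    return "".join(_CODONS[i] for i in idx)


def generate_sequences_and_cds(
    seed: int,
    n_cds: int,
    cds_len: int,
    hexamer_bias: float,
    n_transcripts: int = 50,
    orf_len: int = 300,
    flank_len: int = 120,
    transcript_ids: Sequence[str] | None = None,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], dict[str, tuple[int, int]]]:
    """(coding FASTA, background FASTA, transcript FASTA, planted ORF coords).

    The coding corpus is drawn from a hexamer-biased in-frame codon
    distribution (bias 0 = uniform nucleotides); the background corpus is
    iid uniform nucleotides. Each transcript carries one planted ORF
    (ATG + biased non-stop codons + stop) between random ATG-free flanks.
    """
    if cds_len % 3 != 0 or cds_len < 300:
        raise FixtureError("cds_len must be divisible by 3 and >= 300")
    if hexamer_bias < 0:
        raise FixtureError("hexamer_bias must be >= 0")
    if orf_len % 3 != 0:
        raise FixtureError("orf_len must be divisible by 3")
    rng = np.random.default_rng(seed)
    probs = _codon_probs(hexamer_bias)
    uniform = _codon_probs(0.0)

    coding = {
        f"CDS_{i:04d}": _random_codons(rng, cds_len // 3, probs)
        for i in range(n_cds)
    }
    background = {
        f"BG_{i:04d}": _random_codons(rng, cds_len // 3, uniform)
        for i in range(n_cds)
    }
    transcripts: dict[str, str] = {}
    orf_coords: dict[str, tuple[int, int]] = {}
    stops = sorted(_STOPS)
    ids = list(transcript_ids) if transcript_ids is not None else [
        f"TX_{i:04d}" for i in range(n_transcripts)
    ]
    for tid in ids:
        # flanks drawn codon-wise without ATG or stops, so the planted ORF is
        # the only one in frame 0 and no upstream ATG extends it
        left = _random_codons(rng, flank_len // 3, uniform, exclude_stops=True,
                              exclude_atg=True)
        right = _random_codons(rng, flank_len // 3, uniform, exclude_stops=True,
                               exclude_atg=True)
        body = _random_codons(rng, orf_len // 3 - 2, probs, exclude_stops=True,
                              exclude_atg=False)
        stop = stops[int(rng.integers(0, 3))]
        orf = "ATG" + body + stop
        seq = left + orf + right
        transcripts[tid] = seq
        orf_coords[tid] = (len(left), len(left) + len(orf))
    return coding, background, transcripts, orf_coords


# ---------------------------------------------------------------------------
# survival cohorts

def generate_survival_cohort(
    seed: int,
    n_patients: int,
    transcript_expression: Sequence[float] | None,
    true_hr: float,
    censoring_fraction: float = 0.0,
    baseline_median_days: float = 1000.0,
    reference_year: int = 2017,
) -> pd.DataFrame:
    """Clinical table with exponential event times and tertile-linked hazard.

    The hazard of the top expression tertile is multiplied by ``true_hr``.
    Censored patients get year_of_birth / age_at_diagnosis_days fields that
    reconstruct their censoring time under the reference-year formula.
    """
    if n_patients < 30:
        raise FixtureError("survival cohort needs >= 30 patients")
    if true_hr <= 0:
        raise FixtureError("true_hr must be positive")
    if not 0 <= censoring_fraction <= 1:
        raise FixtureError("censoring_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if transcript_expression is None:
        expression = rng.lognormal(1.0, 1.0, size=n_patients)
    else:
        expression = np.asarray(transcript_expression, dtype=float)
        if expression.size != n_patients:
            raise FixtureError("expression vector length != n_patients")

    high_cut = np.percentile(expression, 200.0 / 3.0)
    high = expression > high_cut
    lam0 = np.log(2.0) / baseline_median_days
    lam = lam0 * np.where(high, true_hr, 1.0)
    event_time = rng.exponential(1.0 / lam)

    censored = rng.random(n_patients) < censoring_fraction
    time = np.where(censored, np.maximum(1.0, event_time * rng.random(n_patients)), event_time)
    time = np.maximum(1.0, np.round(time))

    rows = []
    for i in range(n_patients):
        pid = f"patient_{i:04d}"
        yob = int(rng.integers(1930, 1971))
        if censored[i]:
            age_days = 365.0 * (reference_year - yob) - time[i]
            rows.append(
                {
                    "patient_id": pid,
                    "days_to_death": np.nan,
                    "vital_status": "alive",
                    "year_of_birth": yob,
                    "age_at_diagnosis_days": age_days,
                    "expression": expression[i],
                }
            )
        else:
            age_days = float(rng.integers(10_000, 25_000))
            rows.append(
                {
                    "patient_id": pid,
                    "days_to_death": time[i],
                    "vital_status": "dead",
                    "year_of_birth": yob,
                    "age_at_diagnosis_days": age_days,
                    "expression": expression[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ATAC-like peaks

def generate_atac_peaks(
    seed: int,
    tss_set: Sequence[tuple[str, int]],
    n_background: int,
    planted_fraction: float,
    offset_sd: float,
    genome: Mapping[str, int],
    peak_width: int = 200,
) -> tuple[list[GenomicInterval], dict[int, int]]:
    """Peaks enriched at a fraction of TSSs plus uniform background peaks.

    Returns (peaks, placement) where placement maps the index of each
    TSS that received a peak to the planted centre offset.
    """
    if not 0 <= planted_fraction <= 1:
        raise FixtureError("planted_fraction must be in [0, 1]")
    if offset_sd < 0:
        raise FixtureError("offset_sd must be >= 0")
    rng = np.random.default_rng(seed)
    peaks: list[GenomicInterval] = []
    placement: dict[int, int] = {}
    half = peak_width // 2
    n_planted = int(round(planted_fraction * len(tss_set)))
    chosen = rng.choice(len(tss_set), size=n_planted, replace=False) if n_planted else []
    for i in sorted(int(j) for j in np.atleast_1d(chosen)):
        chrom, pos = tss_set[i]
        offset = int(round(rng.normal(0.0, offset_sd))) if offset_sd > 0 else 0
        center = max(half, min(pos + offset, genome[chrom] - half - 1))
        peaks.append(GenomicInterval(chrom, center - half, center + half))
        placement[i] = offset
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n_background):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        center = int(rng.integers(half, genome[chrom] - half))
        peaks.append(GenomicInterval(chrom, center - half, center + half))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks, placement


# ---------------------------------------------------------------------------
# full fixture bundle

def make_fixture_bundle(
    seed: int,
    outdir: str | Path,
    n_planted_per_category: int = 10,
    n_decoys_per_criterion: int = 50,
    n_background_transcripts: int = 20,
    n_cancer_types: int = 3,
    cancer_cohort: int = 24,
    n_healthy: int = 10,
    healthy_cohort: int = 20,
    genome: Mapping[str, int] | None = None,
    n_ltr: int = 800,
    n_other_per_class: int = 200,
    survival_true_hr: float = 3.0,
    survival_n_patients: int = 60,
    peak_offset_sd: float = 50.0,
    n_background_peaks: int = 300,
    hexamer_bias: float = 1.0,
    n_cds: int = 200,
    cds_len: int = 600,
) -> FixtureManifest:
    """Generate a complete, mutually consistent fixture bundle on disk.

    Writes transcripts.gtf, repeats.bed, tpm.tsv, metadata.tsv,
    coding.fa / background.fa / transcripts.fa, clinical.tsv, peaks.bed and
    manifest.json under ``outdir`` and returns the manifest. Regenerating
    with the same seed reproduces byte-identical files.
    """
    from .annotation_io import write_bed, write_fasta, write_gtf, write_repeats_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)
    genome = dict(genome) if genome else {f"chr{i}": 5_000_000 for i in range(1, 5)}

    n_planted = 5 * n_planted_per_category
    n_decoys = 4 * n_decoys_per_criterion
    needed = n_planted + n_decoys + n_background_transcripts
    per_cat = -(-needed // 5)  # ceil

    repeats = generate_repeat_annotation(
        rng_seed, {"LTR": n_ltr, "LINE": n_other_per_class, "SINE": n_other_per_class,
                   "other": n_other_per_class}, genome
    )
    transcripts, truth, cds_ends = generate_transcript_models(
        rng_seed + 1, repeats, per_cat, genome
    )
    # deterministic assignment: interleave categories so planted CLTs cover
    # all five structural categories
    by_cat = {c: [t for t in transcripts if truth[t.transcript_id] == c]
              for c in STRUCTURAL_CATEGORIES}
    interleaved = [t for tup in itertools.zip_longest(*by_cat.values()) for t in tup
                   if t is not None]
    planted_tx = interleaved[:n_planted]
    decoy_tx = interleaved[n_planted:n_planted + n_decoys]
    background_tx = interleaved[n_planted + n_decoys:needed]

    design = default_design(n_cancer_types, cancer_cohort, n_healthy, healthy_cohort)
    cancer_names = [g.name for g in design if g.kind == "cancer"]
    planted_clts = [
        (t.transcript_id, cancer_names[i % len(cancer_names)])
        for i, t in enumerate(planted_tx)
    ]
    decoys = [
        (t.transcript_id, 1 + i % 4, cancer_names[i % len(cancer_names)])
        for i, t in enumerate(decoy_tx)
    ]
    used_tx = planted_tx + decoy_tx + background_tx
    tpm, metadata = generate_expression_matrix(
        rng_seed + 2,
        [t.transcript_id for t in used_tx],
        design,
        planted_clts,
        decoys,
    )

    # sequences: planted CLTs carry coding ORFs; decoys and background get
    # ORF-bearing sequences too, forming the assembly-wide ORF universe
    all_ids = [t.transcript_id for t in used_tx]
    coding, background, tx_seqs, orf_coords = generate_sequences_and_cds(
        rng_seed + 3, n_cds, cds_len, hexamer_bias, transcript_ids=all_ids
    )

    # survival cohort tied to the first planted CLT
    survival_tid = planted_tx[0].transcript_id
    clinical = generate_survival_cohort(
        rng_seed + 4, survival_n_patients, None, survival_true_hr
    )

    # peaks at the strand-known planted TSSs
    stranded_planted = [t for t in planted_tx if t.tss is not None]
    tss_list = [(t.chrom, t.tss) for t in stranded_planted]
    peaks, placement = generate_atac_peaks(
        rng_seed + 5, tss_list, n_background_peaks, 1.0, peak_offset_sd, genome
    )

    write_gtf(used_tx, outdir / "transcripts.gtf")
    write_repeats_bed(repeats, outdir / "repeats.bed")
    tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="transcript_id")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_fasta(coding, outdir / "coding.fa")
    write_fasta(background, outdir / "background.fa")
    write_fasta(tx_seqs, outdir / "transcripts.fa")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    write_bed(peaks, outdir / "peaks.bed")

    manifest = FixtureManifest(
        seed=rng_seed,
        genome=genome,
        planted_clts=[
            (tid, cancer, truth[tid]) for (tid, cancer) in planted_clts
        ],
        decoys=[(tid, crit) for tid, crit, _ in decoys],
        planted_coding_orfs={tid: orf_coords[tid] for tid, _ in planted_clts},
        survival_effects={survival_tid: survival_true_hr},
        peak_placement={
            stranded_planted[i].transcript_id: off for i, off in placement.items()
        },
        structural_truth={t.transcript_id: truth[t.transcript_id] for t in used_tx},
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
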