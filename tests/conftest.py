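"""Shared fixtures: small synthetic bundles and annotation objects."""

import numpy as np
import pytest

from cltkit.annotation_io import GenomicInterval, RepeatElement, TranscriptModel
from cltkit.synthetic_data import (
    default_design,
    generate_expression_matrix,
    generate_repeat_annotation,
    generate_transcript_models,
    make_fixture_bundle,
)

GENOME = {f"chr{i}": 5_000_000 for i in range(1, 5)}


def ltr(chrom: str, start: int, end: int, name: str = "MLT1A0") -> RepeatElement:
    return RepeatElement(GenomicInterval(chrom, start, end), name, "ERVL-MaLR", "LTR")


def repeat(chrom: str, start: int, end: int, cls: str, name: str = "rep") -> RepeatElement:
    return RepeatElement(GenomicInterval(chrom, start, end), name, name, cls)


def transcript(tid: str, chrom: str, exons, strand: str = "+") -> TranscriptModel:
    return TranscriptModel(
        tid, f"g_{tid}", chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture(scope="session")
def repeats_and_transcripts():
    """A noise-free planted structural-category fixture (5 per category)."""
    repeats = generate_repeat_annotation(
        3, {"LTR": 300, "LINE": 60, "SINE": 60, "other": 60}, GENOME
    )
    transcripts, truth, cds_ends = generate_transcript_models(4, repeats, 5, GENOME)
    return repeats, transcripts, truth, cds_ends


@pytest.fixture(scope="session")
def planted_matrix():
    """Expression matrix with 10 planted CLTs and 8 single-criterion decoys."""
    rng = np.random.default_rng(0)
    tids = [f"T{i:03d}" for i in range(30)]
    cancers = ["cancer_A", "cancer_B"]
    design = default_design(n_cancer_types=2)
    planted = [(tids[i], cancers[i % 2]) for i in range(10)]
    decoys = [(tids[10 + i], 1 + i % 4, cancers[i % 2]) for i in range(8)]
    tpm, meta = generate_expression_matrix(11, tids, design, planted, decoys)
    return tpm, meta, planted, decoys


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A complete on-disk fixture bundle, small enough for pipeline tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture_bundle(
        7, outdir,
        n_planted_per_category=2,
        n_decoys_per_criterion=3,
        n_ltr=300,
        n_other_per_class=60,
    )
    return outdir, manifest
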