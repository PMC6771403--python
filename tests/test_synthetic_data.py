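"""Generator contracts: determinism, planted-truth closure, calibration."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cltkit.annotation_io import read_fasta, read_gtf, read_repeatmasker
from cltkit.expression_summary import ExpressionMatrix
from cltkit.orf_uniqueness import find_orfs
from cltkit.synthetic_data import (
    FixtureError,
    FixtureManifest,
    default_design,
    generate_atac_peaks,
    generate_expression_matrix,
    generate_repeat_annotation,
    generate_sequences_and_cds,
    generate_survival_cohort,
    generate_transcript_models,
    make_fixture_bundle,
)

GENOME = {"chr1": 1_000_000, "chr2": 1_000_000}


class TestRepeats:
    def test_zero_count_class_absent(self):
        reps = generate_repeat_annotation(
            1, {"LTR": 5, "LINE": 5, "SINE": 0, "other": 5}, GENOME
        )
        assert not [r for r in reps if r.repeat_class == "SINE"]

    def test_same_seed_identical(self):
        a = generate_repeat_annotation(2, 20, GENOME)
        b = generate_repeat_annotation(2, 20, GENOME)
        assert a == b

    def test_counts_and_bounds_by_exhaustive_scan(self):
        reps = generate_repeat_annotation(3, 50, GENOME)
        assert len(reps) == 200
        for r in reps:
            assert 0 <= r.interval.start < r.interval.end <= GENOME[r.interval.chrom]
        assert {r.repeat_class for r in reps} == {"LTR", "LINE", "SINE", "other"}
        assert all(r.repeat_name for r in reps)

    def test_zero_length_genome_rejected(self):
        with pytest.raises(FixtureError):
            generate_repeat_annotation(1, 5, {"chr1": 0})


class TestTranscripts:
    def test_zero_per_category_is_empty(self):
        reps = generate_repeat_annotation(1, 20, GENOME)
        tx, truth, _ = generate_transcript_models(1, reps, 0)
        assert tx == [] and truth == {}

    def test_labels_round_trip_through_classifier(self, repeats_and_transcripts):
        from cltkit.annotation_io import build_interval_index
        from cltkit.ere_classification import classify_ltr_position

        repeats, transcripts, truth, _ = repeats_and_transcripts
        assert len(transcripts) == 25  # 5 categories x 5
        idx = build_interval_index(repeats)
        for t in transcripts:
            assert classify_ltr_position(t, idx).category == truth[t.transcript_id]

    def test_embedded_ltr_lies_inside_last_exon_past_stop(self, repeats_and_transcripts):
        repeats, transcripts, truth, cds_ends = repeats_and_transcripts
        by_chrom = {}
        for r in repeats:
            if r.repeat_class == "LTR":
                by_chrom.setdefault(r.interval.chrom, []).append(r)
        for t in transcripts:
            if truth[t.transcript_id] != "embedded":
                continue
            last = t.exons[-1]
            inside = [
                r for r in by_chrom.get(t.chrom, [])
                if last.start <= r.interval.start and r.interval.end <= last.end
            ]
            assert inside, "embedded fixture must contain an LTR in its last exon"
            stop = cds_ends[t.transcript_id]
            assert all(r.interval.start >= stop for r in inside)

    def test_unconstructible_category_raises(self):
        # dense repeats: no LTR has clear flanks
        reps = generate_repeat_annotation(5, {"LTR": 3, "LINE": 0, "SINE": 0, "other": 0},
                                          {"chr1": 20_000})
        with pytest.raises(FixtureError, match="clear"):
            generate_transcript_models(1, reps, 50)

    def test_exons_sorted_and_disjoint(self, repeats_and_transcripts):
        _, transcripts, _, _ = repeats_and_transcripts
        for t in transcripts:
            starts = [e.start for e in t.exons]
            assert starts == sorted(starts)
            for a, b in zip(t.exons, t.exons[1:]):
                assert a.end <= b.start


class TestExpression:
    def test_zero_noise_medians_equal_means(self):
        tids = ["a", "b"]
        design = default_design(n_cancer_types=1)
        tpm, meta = generate_expression_matrix(
            1, tids, design, [("a", "cancer_A")], noise_sigma=0.0
        )
        m = ExpressionMatrix(tpm, meta)
        cancer = m.group_values("cancer_A")
        assert (cancer.loc["a"] == 30.0).all()
        assert (m.healthy_values().loc["a"] == 0.0).all()
        assert (cancer.loc["b"] == 20.0).all()

    def test_values_non_negative_and_deterministic(self):
        tids = [f"t{i}" for i in range(5)]
        design = default_design()
        a, _ = generate_expression_matrix(4, tids, design, [("t0", "cancer_A")])
        b, _ = generate_expression_matrix(4, tids, design, [("t0", "cancer_A")])
        assert (a.values >= 0).all()
        pd.testing.assert_frame_equal(a, b)

    def test_small_cancer_group_rejected(self):
        from cltkit.synthetic_data import GroupDesign

        design = [GroupDesign("c", "cancer", 4), GroupDesign("h1", "healthy", 10),
                  GroupDesign("h2", "healthy", 10)]
        with pytest.raises(FixtureError, match=">= 6"):
            generate_expression_matrix(1, ["t"], design, [])

    def test_unknown_planted_group_rejected(self):
        with pytest.raises(FixtureError, match="unknown group"):
            generate_expression_matrix(1, ["t"], default_design(), [("t", "nope")])


class TestSequences:
    def test_unbiased_corpora_indistinguishable(self):
        coding, bg, _, _ = generate_sequences_and_cds(21, 100, 600, 0.0, n_transcripts=1)
        from cltkit.orf_uniqueness import _hexamer_frequencies

        def counts(seqs):
            freqs = _hexamer_frequencies(list(seqs.values()))
            n = sum(len(s) // 6 * 2 - 1 for s in seqs.values())
            return np.array(list(freqs.values()))

        fc, fb = counts(coding), counts(bg)
        # chi-square on pooled hexamer counts (coarse 64-bin marginal on the
        # leading trinucleotide to keep expected counts reasonable)
        def tri_counts(seqs):
            c = {}
            for s in seqs.values():
                for i in range(0, len(s) - 5, 3):
                    k = s[i:i + 3]
                    c[k] = c.get(k, 0) + 1
            return c
        tc, tb = tri_counts(coding), tri_counts(bg)
        keys = sorted(set(tc) | set(tb))
        table = np.array([[tc.get(k, 0) for k in keys], [tb.get(k, 0) for k in keys]])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_negative_bias_rejected(self):
        with pytest.raises(FixtureError):
            generate_sequences_and_cds(1, 5, 300, -0.1)

    def test_bad_cds_len_rejected(self):
        with pytest.raises(FixtureError):
            generate_sequences_and_cds(1, 5, 301, 1.0)
        with pytest.raises(FixtureError):
            generate_sequences_and_cds(1, 5, 150, 1.0)

    def test_planted_orf_coordinates_are_exact(self):
        _, _, tx, coords = generate_sequences_and_cds(22, 5, 300, 1.0, n_transcripts=20)
        for tid, (s, e) in coords.items():
            seq = tx[tid]
            assert seq[s:s + 3] == "ATG"
            assert seq[e - 3:e] in {"TAA", "TAG", "TGA"}
            found = [(o.start, o.end) for o in find_orfs(seq, e - s)]
            assert (s, e) in found


class TestSurvivalCohort:
    def test_columns_and_censoring_fraction(self):
        df = generate_survival_cohort(5, 100, None, 2.0, censoring_fraction=0.3)
        assert {"patient_id", "days_to_death", "vital_status", "year_of_birth",
                "age_at_diagnosis_days"} <= set(df.columns)
        frac = (df["vital_status"] == "alive").mean()
        assert 0.15 < frac < 0.45

    def test_null_logrank_p_is_uniform(self):
        # type-I calibration of the generator + test at true HR = 1
        from cltkit.survival import build_survival_records, logrank_test, tertile_stratify

        pvals = []
        for rep in range(200):
            df = generate_survival_cohort(1000 + rep, 60, None, 1.0)
            recs = build_survival_records(df)
            expr = dict(zip(df["patient_id"], df["expression"]))
            strata = tertile_stratify(expr)
            by = {r.patient_id: r for r in recs}
            low = [by[a.patient_id] for a in strata if a.stratum == "low" and a.patient_id in by]
            high = [by[a.patient_id] for a in strata if a.stratum == "high" and a.patient_id in by]
            pvals.append(logrank_test(high, low).p_value)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_too_small_cohort_rejected(self):
        with pytest.raises(FixtureError):
            generate_survival_cohort(1, 10, None, 2.0)


class TestPeaks:
    def test_exact_placement_gives_zero_distances(self):
        from cltkit.regulatory_proximity import nearest_peak_distances

        tss = [("chr1", 10_000 * (i + 1)) for i in range(20)]
        peaks, placement = generate_atac_peaks(1, tss, 0, 1.0, 0.0, GENOME)
        assert len(placement) == 20
        assert nearest_peak_distances(tss, peaks) == [0.0] * 20

    def test_fraction_bounds_checked(self):
        with pytest.raises(FixtureError):
            generate_atac_peaks(1, [("chr1", 100)], 0, 1.5, 0.0, GENOME)

    def test_unplanted_tss_not_systematically_close(self):
        rng = np.random.default_rng(2)
        tss = [("chr1", int(p)) for p in rng.integers(1000, 990_000, 30)]
        peaks, placement = generate_atac_peaks(3, tss, 100, 0.0, 0.0, GENOME)
        assert placement == {}
        assert len(peaks) == 100


class TestBundle:
    def test_same_seed_byte_identical_files(self, tmp_path):
        kw = dict(n_planted_per_category=1, n_decoys_per_criterion=2,
                  n_ltr=200, n_other_per_class=40)
        make_fixture_bundle(7, tmp_path / "a", **kw)
        make_fixture_bundle(7, tmp_path / "b", **kw)
        files = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False
        )
        assert sorted(match) == sorted(files) and not mismatch and not errors

    def test_manifest_closure(self, small_bundle):
        outdir, manifest = small_bundle
        gtf_ids = {t.transcript_id for t in read_gtf(outdir / "transcripts.gtf")}
        tpm = pd.read_csv(outdir / "tpm.tsv", sep="\t", index_col=0)
        seqs = read_fasta(outdir / "transcripts.fa")
        for tid, cancer, category in manifest.planted_clts:
            assert tid in gtf_ids and tid in tpm.index and tid in seqs
        for tid, criterion in manifest.decoys:
            assert tid in gtf_ids and tid in tpm.index
        reloaded = FixtureManifest.from_json(outdir / "manifest.json")
        assert reloaded.planted_clts == manifest.planted_clts
        assert reloaded.decoys == manifest.decoys

    def test_repeats_file_round_trips(self, small_bundle):
        outdir, _ = small_bundle
        reps = read_repeatmasker(outdir / "repeats.bed", dialect="bed")
        assert any(r.repeat_class == "LTR" for r in reps)
        assert all(r.repeat_name for r in reps)
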