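"""ORF enumeration, hexamer scoring, identity and uniqueness filtering."""

import itertools
import math

import numpy as np
import pytest

from cltkit.orf_uniqueness import (
    HexamerModel,
    UniquenessCriteria,
    UniverseORF,
    CodingCandidate,
    build_orf_universe,
    export_peptide_db,
    find_orfs,
    hexamer_score,
    largest_orf,
    pairwise_identity,
    reverse_complement,
    score_orf,
    select_coding_clts,
    train_hexamer_model,
    uniqueness_filter,
)
from cltkit.annotation_io import read_fasta
from cltkit.synthetic_data import generate_sequences_and_cds


class TestFindOrfs:
    def test_minimal_orf_translates(self):
        (orf,) = find_orfs("ATGAAATGA", min_len=9)
        assert (orf.start, orf.end, orf.frame, orf.peptide) == (0, 9, 0, "MK")
        assert orf.nt_length == 9

    def test_no_atg_means_no_orf(self):
        assert find_orfs("AAACCCGGGTTTTAA", min_len=3) == []

    def test_length_threshold_is_inclusive(self):
        seq = "ATG" + "GCA" * 98 + "TAA"  # 300 nt
        assert len(find_orfs(seq, min_len=300)) == 1
        assert find_orfs(seq, min_len=301) == []

    def test_orf_without_stop_not_reported(self):
        assert find_orfs("ATG" + "GCA" * 10, min_len=3) == []

    def test_nested_starts_collapse_to_five_prime_most(self):
        seq = "ATGATGAAATGA"
        assert len(find_orfs(seq, min_len=3)) == 1
        assert len(find_orfs(seq, min_len=3, all_starts=True)) == 2

    def test_n_codons_never_match(self):
        assert find_orfs("ATNAAATGA", min_len=3) == []
        # N in the stop position: stop not recognized, no complete ORF
        assert find_orfs("ATGAAATNA", min_len=3) == []

    def test_frame_consistency_across_random_sequences(self):
        rng = np.random.default_rng(19)
        bases = "ACGT"
        for _ in range(20):
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=500))
            for orf in find_orfs(seq, min_len=30, all_starts=True):
                assert orf.start % 3 == orf.frame
                assert orf.nt_length % 3 == 0
                assert seq[orf.start : orf.start + 3] == "ATG"
                assert seq[orf.end - 3 : orf.end] in {"TAA", "TAG", "TGA"}
                assert len(orf.peptide) == orf.nt_length // 3 - 1

    def test_largest_orf_ties_break_five_prime(self):
        a = find_orfs("ATGAAATGA" + "ATGCCCTGA", min_len=9, all_starts=True)
        assert largest_orf(a).start == 0


class TestHexamerModel:
    def test_identical_corpora_give_zero_log_odds(self):
        seqs = ["ATGAAACCCGGG", "TTTGGGCCCAAA"]
        model = train_hexamer_model(seqs, seqs)
        assert all(v == 0.0 for v in model.log_odds.values())

    def test_hand_computed_log_odds(self):
        # coding: one sequence AAATTT repeated twice -> hexamers AAATTT, TTTAAA... wait,
        # codon-stepped on "AAATTTAAATTT": positions 0,3,6 -> AAATTT, TTTAAA, AAATTT
        coding = ["AAATTTAAATTT"]
        background = ["ACGTACGTACGT"]
        pc = 0.01
        model = train_hexamer_model(coding, background, pseudocount=pc)
        assert model.log_odds["AAATTT"] == pytest.approx(math.log((2 / 3 + pc) / (0 + pc)))
        assert model.log_odds["TTTAAA"] == pytest.approx(math.log((1 / 3 + pc) / (0 + pc)))
        # background "ACGTACGTACGT" -> hexamers ACGTAC, TACGTA, GTACGT, once each
        assert model.log_odds["ACGTAC"] == pytest.approx(math.log(pc / (1 / 3 + pc)))

    def test_retraining_is_deterministic(self, tmp_path):
        coding, bg, _, _ = generate_sequences_and_cds(5, 20, 300, 0.7, n_transcripts=1)
        m1 = train_hexamer_model(coding, bg)
        m2 = train_hexamer_model(coding, bg)
        assert m1.log_odds == m2.log_odds
        m1.to_tsv(tmp_path / "m.tsv")
        back = HexamerModel.from_tsv(tmp_path / "m.tsv")
        for h, v in m1.log_odds.items():
            assert back.log_odds[h] == pytest.approx(v)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_hexamer_model([], ["ACGTAC"])

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError):
            train_hexamer_model(["ACGTACG"], ["ACGTAC"])


class TestScoring:
    def test_reverse_complement_palindrome_scores_equal(self):
        seq = "ACGCGT" * 3  # its own reverse complement
        assert reverse_complement(seq) == seq
        model = train_hexamer_model(["AAATTTCCCGGG"], ["ACGTGCATCGAT"])
        sense, anti = score_orf(seq, model)
        assert sense == anti  # strict sense>antisense rule fails

    def test_mean_equals_brute_force_on_short_example(self):
        rng = np.random.default_rng(33)
        table = {h: float(rng.normal()) for h in
                 ("".join(x) for x in itertools.product("ACGT", repeat=6))}
        model = HexamerModel(table, 0.0)
        seq = "ATGAAACCCGGGTTTACGACGAAATTTTAG"  # 30 nt
        expected = np.mean([table[seq[i:i + 6]] for i in range(0, 25, 3)])
        assert hexamer_score(seq, model) == pytest.approx(expected)

    def test_shift_invariance_of_the_decision(self):
        coding, bg, tx, coords = generate_sequences_and_cds(7, 50, 300, 1.0, n_transcripts=5)
        model = train_hexamer_model(coding, bg)
        shifted = HexamerModel({h: v + 3.7 for h, v in model.log_odds.items()}, model.pseudocount)
        for tid, (s, e) in coords.items():
            orf = tx[tid][s:e]
            a_sense, a_anti = score_orf(orf, model)
            b_sense, b_anti = score_orf(orf, shifted)
            assert (a_sense > a_anti) == (b_sense > b_anti)
            assert b_sense - a_sense == pytest.approx(3.7)

    def test_short_sequence_rejected(self):
        model = HexamerModel(dict.fromkeys(
            ("".join(x) for x in itertools.product("ACGT", repeat=6)), 0.0), 0.0)
        with pytest.raises(ValueError):
            score_orf("ATG", model)


class TestPairwiseIdentity:
    def test_identical_peptides(self):
        pep = "MKLVWAGHERTYIPQSDFNC" * 5
        assert pairwise_identity(pep, pep) == 100.0

    def test_unrelated_short_peptides(self):
        assert pairwise_identity("MKL", "WWW") == 0.0

    def test_three_substitutions_in_twenty(self):
        q = "MKLVWAGHERTYIPQSDFNC"
        t = q[:5] + "P" + q[6:10] + "G" + q[11:15] + "W" + q[16:]
        assert pairwise_identity(q, t) == pytest.approx(85.0)

    def test_score_matches_exhaustive_dp(self):
        # independent affine-gap Smith-Waterman oracle on short peptides
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def sw_score(q, t, gap_open=11, gap_ext=1):
            n, m = len(q), len(t)
            NEG = -1e9
            M = [[0.0] * (m + 1) for _ in range(n + 1)]
            X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in t
            Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in q
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_ext)
                    Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_ext)
                    s = blosum[q[i - 1], t[j - 1]]
                    M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s,
                                  Y[i - 1][j - 1] + s)
                    best = max(best, M[i][j])
            return best

        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = blosum
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1

        rng = np.random.default_rng(44)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            q = "".join(aas[i] for i in rng.integers(0, 20, size=int(rng.integers(8, 30))))
            t = "".join(aas[i] for i in rng.integers(0, 20, size=int(rng.integers(8, 30))))
            assert aligner.align(q, t).score == pytest.approx(sw_score(q, t))


@pytest.fixture(scope="module")
def trained():
    coding, bg, tx, coords = generate_sequences_and_cds(
        9, 100, 600, 1.0, n_transcripts=10, orf_len=330
    )
    return train_hexamer_model(coding, bg), tx, coords


class TestCandidateSelection:
    def test_healthy_median_of_one_eliminates(self, trained):
        model, tx, _ = trained
        tid = next(iter(tx))
        kept = select_coding_clts([tid], tx, model, {tid: 1.0})
        assert kept == []
        kept = select_coding_clts([tid], tx, model, {tid: 0.5})
        assert [c.transcript_id for c in kept] == [tid]

    def test_short_orf_is_not_a_candidate(self, trained):
        model, _, _ = trained
        coding, bg, tx299, coords = generate_sequences_and_cds(
            10, 10, 300, 1.0, n_transcripts=1, orf_len=297
        )
        tid = next(iter(tx299))
        assert select_coding_clts([tid], tx299, model, {tid: 0.0}) == []

    def test_planted_candidates_recovered(self, trained):
        model, tx, coords = trained
        kept = select_coding_clts(list(tx), tx, model, {t: 0.0 for t in tx})
        assert {c.transcript_id for c in kept} == set(tx)
        for c in kept:
            assert (c.orf.start, c.orf.end) == coords[c.transcript_id]

    def test_missing_sequence_warns_and_skips(self, trained):
        model, tx, _ = trained
        with pytest.warns(UserWarning, match="no sequence"):
            assert select_coding_clts(["ghost"], tx, model, {}) == []


class TestUniqueness:
    PEP = "MKLVWAGHERTYIPQSDFNCMKLVWAGHERTYIPQSDFNC"  # 40 aa

    def mutate(self, pep, k, seed=0):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        out = list(pep)
        for i in rng.choice(len(pep), size=k, replace=False):
            out[i] = next(a for a in aas if a != pep[i])
        return "".join(out)

    def candidate(self, tid, pep):
        orf = find_orfs("ATG" + "GCA" * 5 + "TAA", 9)[0]
        orf.peptide = pep
        return CodingCandidate(tid, orf, 0.0)

    def test_no_partner_above_threshold_is_unique(self):
        cand = self.candidate("c1", self.PEP)
        universe = [UniverseORF("u1", "other_tx", self.mutate(self.PEP, 20))]
        (call,) = uniqueness_filter([cand], universe, {})
        assert call.unique and call.retained

    def test_healthy_partner_discards(self):
        cand = self.candidate("c1", self.PEP)
        universe = [UniverseORF("u1", "healthy_tx", self.mutate(self.PEP, 2))]
        (call,) = uniqueness_filter([cand], universe, {"healthy_tx": "healthy"})
        assert not call.unique and not call.retained

    def test_cancer_specific_partner_rescues(self):
        cand = self.candidate("c1", self.PEP)
        universe = [UniverseORF("u1", "clt_tx", self.mutate(self.PEP, 2))]
        (call,) = uniqueness_filter([cand], universe, {"clt_tx": "cancer_specific"})
        assert not call.unique and call.retained

    def test_self_locus_is_ignored(self):
        cand = self.candidate("c1", self.PEP)
        universe = [UniverseORF("u1", "c1", self.PEP)]
        (call,) = uniqueness_filter([cand], universe, {"c1": "cancer_specific"})
        assert call.unique

    def test_order_independence(self):
        cands = [self.candidate(f"c{i}", self.mutate(self.PEP, 8, seed=i)) for i in range(4)]
        universe = [UniverseORF("u1", "healthy_tx", self.PEP)]
        status = {"healthy_tx": "healthy"}
        a = {c.transcript_id: c.retained for c in uniqueness_filter(cands, universe, status)}
        b = {c.transcript_id: c.retained
             for c in uniqueness_filter(list(reversed(cands)), universe, status)}
        assert a == b

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            uniqueness_filter([self.candidate("c", self.PEP)], [], {})

    def test_controlled_identity_separation(self):
        # planted duplicate (95% identity) vs diverged (50%) around the 85% cut
        cand = self.candidate("c1", self.PEP)
        dup = self.mutate(self.PEP, 2)    # 95% identity
        far = self.mutate(self.PEP, 20)   # 50% identity
        assert pairwise_identity(self.PEP, dup) > 85
        assert pairwise_identity(self.PEP, far) <= 85
        universe = [UniverseORF("u1", "dup_tx", dup), UniverseORF("u2", "far_tx", far)]
        (call,) = uniqueness_filter([cand], universe, {"dup_tx": "healthy"})
        assert [p[0] for p in call.partners] == ["dup_tx"]


class TestPeptideDb:
    def test_threshold_selects_single_orf(self, tmp_path):
        seq = ("ATG" + "GCA" * 18 + "TAA"          # 60 nt, below cutoff
               + "ATG" + "TGC" * 28 + "TGA")        # 90 nt, exported
        out = tmp_path / "db.fa"
        n = export_peptide_db(["t"], {"t": seq}, out, min_len=75)
        assert n == 1
        rec = read_fasta(out)
        ((header, pep),) = rec.items()
        assert header.startswith("t|")
        assert pep == "M" + "C" * 28

    def test_record_count_matches_enumeration(self, tmp_path):
        _, _, tx, _ = generate_sequences_and_cds(13, 10, 300, 1.0, n_transcripts=6)
        out = tmp_path / "db.fa"
        n = export_peptide_db(list(tx), tx, out, min_len=75)
        brute = sum(len(find_orfs(s, 75, all_starts=True)) for s in tx.values())
        assert n == brute
        for header, pep in read_fasta(out).items():
            tid, coords, frame = header.split("|")
            s, e = map(int, coords.split("-"))
            assert len(pep) == (e - s) // 3 - 1

    def test_universe_construction(self):
        _, _, tx, coords = generate_sequences_and_cds(14, 10, 300, 1.0, n_transcripts=3)
        universe = build_orf_universe(tx, 210)
        assert {u.transcript_id for u in universe} == set(tx)

    def test_empty_final_set_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_peptide_db([], {}, tmp_path / "x.fa")
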