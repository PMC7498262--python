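"""PWM ingestion, scanning, the dinucleotide shuffle, and co-occurrence calls."""

import numpy as np
import pytest

from cooccupy.motifs import (
    MotifHit,
    PWM,
    classify_peak,
    dinucleotide_counts,
    dinucleotide_shuffle,
    motif_class_enrichment,
    motif_count_summary,
    motif_spacing,
    pwm_from_consensus,
    read_motifs,
    scan_sequence,
)
from cooccupy.intervals import reverse_complement

from conftest import random_dna
from oracles import brute_scan, hypergeom_upper_tail_frac


def hit_key(h):
    return (h.offset, h.strand)


class TestReadMotifs:
    def test_homer_dialect(self, tmp_path):
        f = tmp_path / "sox.motif"
        f.write_text(
            ">AAAA\tsox_test\t6.0\n"
            + "0.97\t0.01\t0.01\t0.01\n" * 4
        )
        (pwm,) = read_motifs(f, "homer", "sox")
        assert pwm.name == "sox_test" and len(pwm) == 4
        assert pwm.consensus == "AAAA" and pwm.tf_class == "sox"
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_homer_multiple_motifs(self, tmp_path):
        block = ">ACGT\tm{i}\t5\n0.9 0.03 0.03 0.04\n0.03 0.9 0.03 0.04\n0.03 0.04 0.9 0.03\n0.04 0.03 0.03 0.9\n"
        f = tmp_path / "two.motif"
        f.write_text(block.format(i=1) + block.format(i=2))
        pwms = read_motifs(f, "homer")
        assert [p.name for p in pwms] == ["m1", "m2"]

    def test_cisbp_dialect(self, tmp_path):
        f = tmp_path / "tcf7.txt"
        rows = "\n".join(f"{i + 1}\t0.1\t0.2\t0.3\t0.4" for i in range(7))
        f.write_text("Pos\tA\tC\tG\tT\n" + rows + "\n")
        (pwm,) = read_motifs(f, "cisbp", "tcf")
        assert len(pwm) == 7 and pwm.source == "cisbp" and pwm.name == "tcf7"

    def test_bad_row_sum_errors(self, tmp_path):
        f = tmp_path / "bad.motif"
        f.write_text(">AAAA\tbad\t5\n" + "0.2\t0.1\t0.1\t0.1\n" * 4)
        with pytest.raises(ValueError, match="sums to"):
            read_motifs(f, "homer")

    def test_wrong_column_count_errors(self, tmp_path):
        f = tmp_path / "bad.motif"
        f.write_text(">AAAA\tbad\t5\n0.5\t0.5\n" * 4)
        with pytest.raises(ValueError, match="4 columns"):
            read_motifs(f, "homer")

    def test_negative_entry_errors(self, tmp_path):
        f = tmp_path / "neg.motif"
        f.write_text(">AAAA\tneg\t5\n" + "1.2\t-0.1\t-0.05\t-0.05\n" * 4)
        with pytest.raises(ValueError, match="negative"):
            read_motifs(f, "homer")


class TestScanSequence:
    def test_consensus_scores_one(self, sox_pwm):
        hits = scan_sequence(sox_pwm.consensus, sox_pwm)
        assert [hit_key(h) for h in hits] == [(0, "+")]
        assert hits[0].relative_score == pytest.approx(1.0)

    def test_reverse_complement_hits_minus_strand(self, sox_pwm):
        hits = scan_sequence(reverse_complement(sox_pwm.consensus), sox_pwm)
        assert [hit_key(h) for h in hits] == [(0, "-")]
        assert hits[0].relative_score == pytest.approx(1.0)

    def test_short_sequence_is_empty_not_error(self, sox_pwm):
        assert scan_sequence("ACGT", sox_pwm) == []

    def test_n_windows_excluded(self, sox_pwm):
        seq = sox_pwm.consensus[:-1] + "N" + "ACGT" * 5 + sox_pwm.consensus
        hits = scan_sequence(seq, sox_pwm, 0.70)
        assert all(
            "N" not in seq[h.offset : h.offset + h.width] for h in hits
        )
        assert (len(seq) - 12, "+") in {hit_key(h) for h in hits}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            L = int(rng.integers(4, 13))
            probs = rng.dirichlet(np.full(4, 0.5), size=L)
            probs = (probs + 1e-3) / (probs + 1e-3).sum(axis=1, keepdims=True)
            pwm = PWM("tmp", "other", probs)
            seq = random_dna(rng, int(rng.integers(20, 400)))
            thr = float(rng.uniform(0.5, 0.95))
            got = scan_sequence(seq, pwm, thr)
            expected = brute_scan(seq, probs.tolist(), thr)
            assert [(h.offset, h.strand) for h in got] == [(o, s) for o, s, _, _ in expected]
            for h, (_, _, score, rel) in zip(got, expected):
                assert h.log_odds == pytest.approx(score, abs=1e-9)
                assert h.relative_score == pytest.approx(min(1.0, rel), abs=1e-9)

    def test_strand_symmetry(self, rng, sox_pwm):
        seq = random_dna(rng, 300)
        fwd = scan_sequence(seq, sox_pwm, 0.6)
        rev = scan_sequence(reverse_complement(seq), sox_pwm, 0.6)
        flip = {"+": "-", "-": "+"}
        mapped = sorted(
            (len(seq) - h.offset - h.width, flip[h.strand], round(h.log_odds, 9))
            for h in rev
        )
        assert mapped == sorted((h.offset, h.strand, round(h.log_odds, 9)) for h in fwd)

    def test_hit_ordering(self, sox_pwm):
        c = sox_pwm.consensus
        seq = c + "AC" + reverse_complement(c)
        hits = scan_sequence(seq, sox_pwm, 0.95)
        keys = [hit_key(h) for h in hits]
        assert keys == sorted(keys, key=lambda t: (t[0], t[1] == "-"))

    def test_invalid_threshold(self, sox_pwm):
        with pytest.raises(ValueError):
            scan_sequence("ACGT" * 10, sox_pwm, 0.0)


class TestDinucleotideShuffle:
    def test_homopolymer_is_fixed_point(self):
        ss = dinucleotide_shuffle("AAAA", n=5, seed=1, original_id="a")
        assert ss.shuffles == ("AAAA",) * 5

    def test_alternating_repeat_is_unique_arrangement(self):
        # strings with dinucleotide counts {AC:3, CA:2}, first A last C:
        # exhaustive enumeration admits only ACACAC itself
        ss = dinucleotide_shuffle("ACACAC", n=8, seed=2, original_id="b")
        assert ss.shuffles == ("ACACAC",) * 8

    def test_preserves_dinucleotide_vector_and_endpoints(self, rng):
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(2, 500)))
            ss = dinucleotide_shuffle(seq, n=3, seed=5, original_id=seq)
            for s in ss.shuffles:
                assert len(s) == len(seq)
                assert s[0] == seq[0] and s[-1] == seq[-1]
                assert dinucleotide_counts(s) == dinucleotide_counts(seq)

    def test_seeded_runs_bit_reproducible(self, rng):
        seq = random_dna(rng, 200)
        a = dinucleotide_shuffle(seq, n=10, seed=9, original_id="p1")
        b = dinucleotide_shuffle(seq, n=10, seed=9, original_id="p1")
        assert a.shuffles == b.shuffles
        c = dinucleotide_shuffle(seq, n=10, seed=10, original_id="p1")
        assert a.shuffles != c.shuffles

    def test_stream_independent_of_processing_order(self, rng):
        s1, s2 = random_dna(rng, 150), random_dna(rng, 150)
        a = dinucleotide_shuffle(s1, 3, seed=4, original_id="pk1")
        dinucleotide_shuffle(s2, 3, seed=4, original_id="pk2")
        again = dinucleotide_shuffle(s1, 3, seed=4, original_id="pk1")
        assert a.shuffles == again.shuffles

    def test_n_runs_are_separators(self):
        seq = "ACGTACGTACGT" + "NN" + "TTGCATTGCA"
        ss = dinucleotide_shuffle(seq, n=5, seed=3, original_id="n")
        for s in ss.shuffles:
            assert s[12:14] == "NN" and len(s) == len(seq)
            assert dinucleotide_counts(s[:12]) == dinucleotide_counts(seq[:12])

    def test_too_short_or_no_acgt_errors(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("A", seed=0)
        with pytest.raises(ValueError):
            dinucleotide_shuffle("NNNN", seed=0)

    def test_shuffles_actually_vary(self, rng):
        seq = random_dna(rng, 300)
        ss = dinucleotide_shuffle(seq, n=10, seed=0, original_id="v")
        assert len(set(ss.shuffles)) > 1


def mk_hit(offset, strand="+", width=8, name="m", pid="p1"):
    return MotifHit(pid, name, offset, strand, 5.0, 0.9, width)


class TestClassification:
    def test_both_classes_present(self):
        cls = classify_peak([mk_hit(3), mk_hit(20)], [mk_hit(40)])
        assert cls.label == "sox_and_tcf" and (cls.n_sox_sites, cls.n_tcf_sites) == (2, 1)

    def test_neither(self):
        cls = classify_peak([], [], peak_id="p9")
        assert cls.label == "neither" and cls.peak_id == "p9"

    def test_same_offset_hits_deduplicated(self):
        cls = classify_peak([mk_hit(5, name="sox_a"), mk_hit(5, name="sox_b")], [])
        assert cls.label == "sox_only" and cls.n_sox_sites == 1

    def test_same_offset_opposite_strands_are_distinct(self):
        cls = classify_peak([mk_hit(5, "+"), mk_hit(5, "-")], [])
        assert cls.n_sox_sites == 2


class TestEnrichment:
    def make_classes(self, n_with, n_total, label="sox_and_tcf"):
        out = []
        for i in range(n_total):
            if i < n_with:
                out.append(classify_peak([mk_hit(0)], [mk_hit(30)], peak_id=f"p{i}"))
            else:
                out.append(classify_peak([], [], peak_id=f"p{i}"))
        return out

    def test_paper_scale_counts_match_tail_oracle(self):
        real = self.make_classes(101, 191)
        bg = self.make_classes(592, 1910)
        res = motif_class_enrichment(real, bg, "sox_and_tcf")
        assert (res.a, res.b, res.c, res.d) == (101, 90, 592, 1318)
        oracle = float(hypergeom_upper_tail_frac(2101, 191, 693, 101))
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.p_value < 1e-6  # strongly enriched over the shuffles

    def test_flat_table_not_significant(self):
        res = motif_class_enrichment(self.make_classes(5, 10), self.make_classes(5, 10),
                                     "sox_and_tcf")
        assert res.odds_ratio == pytest.approx(1.0) and res.p_value > 0.5

    def test_small_exact_case(self):
        res = motif_class_enrichment(self.make_classes(3, 3), self.make_classes(0, 3),
                                     "sox_and_tcf")
        assert res.p_value == pytest.approx(0.05, abs=1e-12)

    def test_empty_real_errors(self):
        with pytest.raises(ValueError):
            motif_class_enrichment([], self.make_classes(1, 2), "sox_and_tcf")


class TestSpacingAndCounts:
    def test_center_distance_hand_case(self):
        res = motif_spacing([mk_hit(10, width=8)], [mk_hit(40, width=10)])
        assert res.min_center_distance == pytest.approx(31.0)
        assert res.clustered_within

    def test_single_class_undefined(self):
        res = motif_spacing([mk_hit(10)], [])
        assert res.min_center_distance is None and not res.clustered_within

    def test_min_over_pairs_matches_quadratic_oracle(self, rng):
        sox = [mk_hit(int(o), width=8) for o in rng.integers(0, 140, 5)]
        tcf = [mk_hit(int(o), width=10) for o in rng.integers(0, 140, 5)]
        res = motif_spacing(sox, tcf)
        oracle = min(abs(s.center - t.center) for s in sox for t in tcf)
        assert res.min_center_distance == pytest.approx(oracle)
        assert res.clustered_within == (oracle <= 50)

    def test_count_summary_fraction(self):
        classes = [
            classify_peak([mk_hit(i * 13) for i in range(n)], [], peak_id=str(j))
            for j, n in enumerate([6, 6, 1, 0])
        ]
        summary = motif_count_summary(classes, threshold=5)
        assert summary.fraction_above == pytest.approx(0.5)
        assert summary.histogram == {6: 2, 1: 1, 0: 1}

    def test_empty_input_undefined(self):
        summary = motif_count_summary([])
        assert summary.histogram == {} and summary.fraction_above is None
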