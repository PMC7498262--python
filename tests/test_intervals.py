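"""Interval arithmetic, peak I/O, annotation and sequence retrieval."""

import numpy as np
import pytest

from cooccupy.intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    annotate_peak,
    extract_sequences,
    intersect,
    read_gene_models,
    read_peaks,
    summit_window,
    write_bed,
)

from oracles import brute_intersect, brute_nearest_gene


def make_peak(chrom, start, end, summit, pid="p", score=1.0):
    return Peak(GenomicInterval(chrom, start, end), pid, summit, score)


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_summit_must_lie_in_interval(self):
        with pytest.raises(ValueError):
            make_peak("chr1", 100, 300, 300)

    def test_gene_tss_consistency(self):
        span = GenomicInterval("chr1", 100, 500, "+")
        with pytest.raises(ValueError):
            GeneModel("g1", 499, "+", span)
        GeneModel("g1", 100, "+", span)  # ok
        GeneModel("g2", 499, "-", GenomicInterval("chr1", 100, 500, "-"))


class TestReadPeaks:
    def test_narrowpeak_summit_offset(self, tmp_path):
        f = tmp_path / "p.narrowPeak"
        f.write_text("chr1\t100\t300\tp1\t0\t.\t5\t3\t2\t50\n")
        (p,) = read_peaks(f, "narrowPeak")
        assert p.summit == 150 and p.interval.start == 100 and p.interval.end == 300

    def test_narrowpeak_missing_summit_uses_midpoint(self, tmp_path):
        f = tmp_path / "p.narrowPeak"
        f.write_text("chr1\t100\t301\tp1\t0\t.\t5\t3\t2\t-1\n")
        (p,) = read_peaks(f, "narrowPeak")
        assert p.summit == 200  # floor of midpoint

    def test_bed6_midpoint_and_score(self, tmp_path):
        f = tmp_path / "p.bed"
        f.write_text("chr1\t100\t300\tp1\t7\t.\n")
        (p,) = read_peaks(f, "bed6")
        assert p.summit == 200 and p.score == 7

    def test_summit_outside_interval_errors_with_line(self, tmp_path):
        f = tmp_path / "p.narrowPeak"
        f.write_text("chr1\t100\t300\tp1\t0\t.\t5\t3\t2\t250\n")
        with pytest.raises(ValueError, match=":1:"):
            read_peaks(f, "narrowPeak")

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "p.bed"
        f.write_text("chr1\t100\t300\tp1\t7\t.\nchr1\tfoo\t400\tp2\t1\t.\n")
        with pytest.raises(ValueError, match=":2:"):
            read_peaks(f, "bed6")

    def test_bed6_round_trip_byte_identical(self, tmp_path, rng):
        lines = []
        for i in range(20):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(50, 500))
            lines.append(f"chr{1 + i % 3}\t{s}\t{e}\tpk{i}\t{int(rng.integers(0, 1000))}\t.")
        src = tmp_path / "in.bed"
        src.write_text("\n".join(lines) + "\n")
        peaks = read_peaks(src, "bed6")
        out = tmp_path / "out.bed"
        write_bed(peaks, out)
        assert out.read_text() == src.read_text()


class TestSummitWindow:
    def test_plain_arithmetic(self):
        w = summit_window(make_peak("chr1", 0, 400, 150), 150)
        assert (w.start, w.end) == (75, 225)

    def test_left_clip(self):
        w = summit_window(make_peak("chr1", 0, 400, 40), 150)
        assert (w.start, w.end) == (0, 115)

    def test_right_clip_with_chrom_lengths(self):
        w = summit_window(make_peak("chr1", 0, 400, 150), 4000, {"chr1": 2150})
        assert (w.start, w.end) == (0, 2150)

    def test_width_must_be_even_positive(self):
        with pytest.raises(ValueError):
            summit_window(make_peak("chr1", 0, 400, 150), 151)

    def test_length_equals_width_away_from_ends(self, rng):
        for _ in range(50):
            summit = int(rng.integers(100, 5000))
            p = make_peak("chr1", max(0, summit - 50), summit + 50, summit)
            w = summit_window(p, 100, {"chr1": 10_000})
            assert len(w) == 100


class TestIntersect:
    def test_one_bp_overlap_boundary(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 99, 200)]
        assert intersect(a, b) == [(0, 0, 1)]

    def test_abutting_intervals_do_not_overlap(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 100, 200)]
        assert intersect(a, b) == []

    def test_matches_quadratic_oracle(self, rng):
        def random_intervals(n):
            out = []
            for _ in range(n):
                chrom = f"chr{int(rng.integers(1, 4))}"
                s = int(rng.integers(0, 2000))
                out.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 300))))
            return out

        for _ in range(10):
            a, b = random_intervals(50), random_intervals(50)
            assert intersect(a, b) == brute_intersect(a, b)
            # symmetry up to index swap
            swapped = sorted((j, i, ov) for i, j, ov in intersect(a, b))
            assert swapped == brute_intersect(b, a)

    def test_min_overlap_filter(self, rng):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 90, 200)]
        assert intersect(a, b, min_overlap=10) == [(0, 0, 10)]
        assert intersect(a, b, min_overlap=11) == []


def _gene(gid, chrom, start, end, strand="+", exons=()):
    span = GenomicInterval(chrom, start, end, strand)
    tss = start if strand == "+" else end - 1
    return GeneModel(gid, tss, strand, span, tuple(exons))


class TestAnnotatePeak:
    def test_promoter_upstream(self):
        g = _gene("g1", "chr1", 5000, 8000)
        ann = annotate_peak(make_peak("chr1", 4400, 4600, 4500), [g])
        assert ann.feature == "promoter" and ann.distance_to_tss == -500
        assert ann.nearest_gene == "g1"

    def test_intron_inside_gene(self):
        g = _gene("g1", "chr1", 5000, 8000,
                  exons=[GenomicInterval("chr1", 5000, 5500, "+")])
        ann = annotate_peak(make_peak("chr1", 5900, 6100, 6000), [g])
        assert ann.feature == "intron" and ann.distance_to_tss == 1000

    def test_exon_beats_intron(self):
        g = _gene("g1", "chr1", 5000, 8000,
                  exons=[GenomicInterval("chr1", 6500, 7000, "+")])
        ann = annotate_peak(make_peak("chr1", 6500, 6800, 6600), [g])
        assert ann.feature == "exon"

    def test_intergenic_far_peak(self):
        g = _gene("g1", "chr1", 5000, 8000)
        ann = annotate_peak(make_peak("chr1", 19_000, 21_000, 20_000), [g])
        assert ann.feature == "intergenic" and ann.distance_to_tss == 15_000

    def test_minus_strand_distance_sign(self):
        g = _gene("g1", "chr1", 5000, 8000, strand="-")
        # summit downstream of a minus-strand TSS (toward lower coordinates)
        ann = annotate_peak(make_peak("chr1", 9000, 9400, 9200), [g])
        assert ann.distance_to_tss == 7999 - 9200

    def test_no_gene_on_chromosome(self):
        g = _gene("g1", "chr2", 5000, 8000)
        ann = annotate_peak(make_peak("chr1", 0, 200, 100), [g])
        assert ann.nearest_gene is None and ann.feature == "intergenic"
        assert ann.distance_to_tss is None

    def test_tie_breaks_lexicographically(self):
        ga = _gene("ga", "chr1", 1000, 2000)
        gb = _gene("gb", "chr1", 0, 1001, strand="-")  # tss 1000 too
        ann = annotate_peak(make_peak("chr1", 900, 1100, 1000), [gb, ga])
        assert ann.nearest_gene == "ga"

    def test_nearest_matches_exhaustive_scan(self, rng):
        genes = [
            _gene(f"g{i:03d}", f"chr{int(rng.integers(1, 3))}",
                  s := int(rng.integers(0, 50_000)), s + 2000)
            for i in range(40)
        ]
        for _ in range(50):
            chrom = f"chr{int(rng.integers(1, 3))}"
            summit = int(rng.integers(0, 52_000))
            ann = annotate_peak(make_peak(chrom, summit, summit + 10, summit), genes)
            oracle = brute_nearest_gene(summit, chrom, genes)
            assert oracle is not None
            assert ann.nearest_gene == oracle[0]
            assert abs(ann.distance_to_tss) == oracle[1]


class TestExtractSequences:
    GENOME = {"chr1": "ACGTACGT"}

    def test_plus_strand(self):
        assert extract_sequences(self.GENOME, [GenomicInterval("chr1", 0, 4)]) == ["ACGT"]

    def test_minus_strand_reverse_complements(self):
        got = extract_sequences(self.GENOME, [GenomicInterval("chr1", 1, 5, "-")])
        assert got == ["TACG"]  # revcomp of CGTA

    def test_out_of_bounds_names_interval(self):
        with pytest.raises(ValueError, match="chr1:5-12"):
            extract_sequences(self.GENOME, [GenomicInterval("chr1", 5, 12)])

    def test_missing_chromosome(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_sequences(self.GENOME, [GenomicInterval("chrX", 0, 4)])

    def test_lowercase_genome_uppercased(self):
        assert extract_sequences({"chr1": "acgt"}, [GenomicInterval("chr1", 0, 4)]) == ["ACGT"]


class TestGeneModelIO:
    def test_bed12_round_trip_fields(self, tmp_path):
        f = tmp_path / "genes.bed"
        f.write_text(
            "chr1\t100\t900\tgeneA\t0\t+\t100\t900\t0\t2\t200,300\t0,500\n"
            "chr1\t2000\t3000\tgeneB\t0\t-\t2000\t3000\t0\t1\t1000\t0\n"
        )
        genes = read_gene_models(f, "bed12")
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        assert genes[0].tss == 100 and genes[1].tss == 2999
        assert genes[0].exons[1].start == 600 and genes[0].exons[1].end == 900

    def test_tsv_dialect(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text(
            "gene_id\tchrom\ttss\tstrand\tspan_start\tspan_end\texon_blocks\n"
            "g1\tchr1\t100\t+\t100\t900\t100-300,600-900\n"
        )
        (g,) = read_gene_models(f, "tsv")
        assert g.tss == 100 and len(g.exons) == 2
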