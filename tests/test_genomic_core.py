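"""Interval arithmetic, strand-aware windows, coverage and flat-file IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ese_scan.genomic_core import (
    CoverageTrack,
    Interval,
    Peak,
    centered_window,
    downstream_window,
    flank,
    overlap_matrix,
    overlaps,
    read_bed,
    read_bedgraph,
    read_gff_genes,
    window_mean,
    write_bed,
    write_bedgraph,
    write_gff_genes,
)
from ese_scan.synthetic_data import SimConfig, simulate_annotation


class TestInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="c", start=200, end=100),
            dict(chrom="c", start=100, end=100),
            dict(chrom="", start=0, end=10),
            dict(chrom="c", start=-5, end=10),
            dict(chrom="c", start=0, end=10, strand="x"),
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            Interval(**kwargs)

    def test_length_is_half_open(self):
        assert len(Interval("c", 100, 200)) == 100

    def test_summit_bounds(self):
        with pytest.raises(ValueError):
            Peak(Interval("c", 100, 200), summit=100)
        assert Peak(Interval("c", 100, 200), summit=40).summit_pos == 140
        # midpoint fallback when summit unset
        assert Peak(Interval("c", 100, 201)).summit_pos == 150


class TestWindows:
    def test_flank_clamps_at_chrom_start(self):
        assert flank(Interval("c", 1000, 2000), 5000) == Interval("c", 0, 7000)

    def test_flank_plain_and_identity(self):
        assert flank(Interval("c", 10000, 12000), 5000) == Interval("c", 5000, 17000)
        iv = Interval("c", 10, 20, "+")
        assert flank(iv, 0) == iv

    @given(start=st.integers(6000, 10**6), length=st.integers(1, 10**4), pad=st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_flank_length_away_from_boundary(self, start, length, pad):
        iv = Interval("c", start, start + length)
        assert len(flank(iv, pad)) == length + 2 * pad

    def test_downstream_window_definitions(self):
        assert downstream_window("c", 1000, "+", 500) == Interval("c", 1000, 1500, "+")
        assert downstream_window("c", 1000, "-", 500) == Interval("c", 501, 1001, "-")
        assert downstream_window("c", 100, "-", 500) == Interval("c", 0, 101, "-")

    @given(tss=st.integers(1000, 10**6), width=st.integers(1, 999))
    @settings(max_examples=200, deadline=None)
    def test_downstream_minus_reflects_plus(self, tss, width):
        plus = downstream_window("c", tss, "+", width)
        minus = downstream_window("c", tss, "-", width)
        # mirror about the TSS: offsets downstream match in absolute distance
        assert plus.start - tss == tss - (minus.end - 1)
        assert len(plus) == len(minus) == width

    def test_centered_window_arithmetic(self):
        assert centered_window("c", 5000, 250) == Interval("c", 4750, 5250)
        assert centered_window("c", 5000, 500) == Interval("c", 4500, 5500)
        assert len(centered_window("c", 5000, 1)) == 2
        assert centered_window("c", 100, 250) == Interval("c", 0, 350)


class TestOverlaps:
    def test_half_open_touching_does_not_overlap(self):
        assert overlaps(Interval("c", 0, 10), [Interval("c", 10, 20)]) == []
        assert overlaps(Interval("c", 0, 10), [Interval("c", 9, 20)]) == [0]
        assert overlaps(Interval("c", 0, 10), [Interval("d", 0, 10)]) == []

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        def rand_ivs(n):
            out = []
            for _ in range(n):
                chrom = "c" + str(rng.integers(2))
                s = int(rng.integers(0, 5000))
                out.append(Interval(chrom, s, s + int(rng.integers(1, 300))))
            return out

        queries, targets = rand_ivs(200), rand_ivs(200)
        brute = [
            [j for j, t in enumerate(targets)
             if t.chrom == q.chrom and t.start < q.end and q.start < t.end]
            for q in queries
        ]
        assert [overlaps(q, targets) for q in queries] == brute
        assert [sorted(h) for h in overlap_matrix(queries, targets)] == brute


def _track(values, bw=10, **kw):
    return CoverageTrack("s", "chip", bw, {"c": np.asarray(values, dtype=float)}, **kw)


class TestWindowMean:
    def test_constant_field(self):
        t = _track(np.full(100, 2.0))
        assert window_mean(t, Interval("c", 37, 613)) == pytest.approx(2.0)

    def test_single_nonzero_bin(self):
        v = np.zeros(20)
        v[5] = 7.0
        assert window_mean(_track(v), Interval("c", 0, 100)) == pytest.approx(0.7)

    def test_per_base_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(2.0, 1.0, 500)
        t = _track(values)
        per_base = np.repeat(values, 10)
        for _ in range(200):
            s = int(rng.integers(0, 4900))
            e = s + int(rng.integers(1, 100))
            assert window_mean(t, Interval("c", s, e)) == pytest.approx(
                per_base[s:e].mean(), abs=1e-9
            )

    def test_raw_track_is_per_million_scaled(self):
        t = _track(np.full(10, 3.0), raw=True, library_size=2_000_000)
        assert window_mean(t, Interval("c", 0, 100)) == pytest.approx(1.5)

    def test_missing_chrom_errors(self):
        with pytest.raises(KeyError):
            window_mean(_track([1.0]), Interval("d", 0, 5))


class TestBedIO:
    def test_basic_and_narrowpeak(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "chr1\t100\t200\tpk1\n"
            "chr1\t300\t400\tpk2\t55\t+\t0\t0\t0\t40\n"
        )
        peaks = read_bed(p)
        assert peaks[0].interval == Interval("chr1", 100, 200)
        assert peaks[0].name == "pk1" and peaks[0].summit is None
        assert peaks[1].summit == 40 and peaks[1].score == 55

    def test_seven_column_summit_is_absolute(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpk\t0\t+\t140\n")
        assert read_bed(p)[0].summit == 40

    @pytest.mark.parametrize("line", ["chr1\t200\t100", "chr1\t100", "chr1\tx\t200"])
    def test_malformed_line_errors_name_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\tok\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_bed6_round_trip_byte_identical(self, tmp_path):
        text = "chr1\t100\t200\tpk1\t5\t+\nchr2\t0\t50\tpk2\t0\t-\n"
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        a.write_text(text)
        write_bed(read_bed(a), b)
        assert b.read_text() == text


class TestGffIO:
    def test_coordinate_conversion_and_strand_tss(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=gp\n"
            "c\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=gp.t1;Parent=gp\n"
            "c\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=gm\n"
            "c\tsrc\tmRNA\t5001\t6000\t.\t-\t.\tID=gm.t1;Parent=gm\n"
            "c\tsrc\tmRNA\t5001\t6000\t.\t-\t.\tID=gm.t2;Parent=gm\n"
        )
        genes = {g.gene_id: g for g in read_gff_genes(p)}
        assert genes["gp"].locus == Interval("c", 1000, 2000, "+")
        assert genes["gp"].tss_list == (1000,)
        assert genes["gm"].tss_list == (5999,)  # shared start deduplicates

    def test_gene_without_strand_errors(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\nc\tsrc\tgene\t10\t20\t.\t.\t.\tID=g1\n")
        with pytest.raises(ValueError, match="strand"):
            read_gff_genes(p)

    def test_write_read_round_trip(self, tmp_path, small_config):
        genes = simulate_annotation(small_config)
        p = tmp_path / "ann.gff3"
        write_gff_genes(genes, p)
        back = read_gff_genes(p)
        assert [(g.gene_id, g.locus, g.tss_list) for g in back] == [
            (g.gene_id, g.locus, g.tss_list) for g in genes
        ]


class TestBedGraph:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        t = _track(rng.lognormal(0, 0.3, 200).astype(np.float32))
        p = tmp_path / "t.bedgraph"
        write_bedgraph(t, p)
        back = read_bedgraph(p, bin_bp=10)
        assert np.allclose(back.bins["c"], t.bins["c"], rtol=1e-5)

    def test_unaligned_records_distribute_by_overlap(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("c\t5\t15\t2\n")  # straddles two 10-bp bins
        back = read_bedgraph(p, bin_bp=10)
        assert np.allclose(back.bins["c"], [1.0, 1.0])
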