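"""Coordinate conventions and lossless format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilechip.core_io import (GeneModel, GenomeIndex, Interval, IntervalSet,
                              ProbeTrack, ValidationError, merge_intervals,
                              read_genes, read_intervals, read_signal,
                              write_genes, write_intervals, write_signal)


class TestTypes:
    def test_interval_rejects_inverted_and_negative(self):
        with pytest.raises(ValidationError):
            Interval("chr1", 200, 100)
        with pytest.raises(ValidationError):
            Interval("chr1", -5, 10)
        with pytest.raises(ValidationError):
            Interval("chr1", 10, 10)

    def test_genome_index_rejects_bad_entries(self):
        with pytest.raises(ValidationError):
            GenomeIndex({"chr1": 0})
        with pytest.raises(ValidationError):
            GenomeIndex({"": 100})

    def test_tss_tes_strand_convention(self):
        minus = GeneModel("g", "chr1", "-", 1000, 2000)
        assert minus.tss == 1999 and minus.tes == 1000
        plus = GeneModel("g", "chr1", "+", 1000, 2000)
        assert plus.tss == 1000 and plus.tes == 1999

    def test_gene_rejects_bad_strand_and_stray_exon(self):
        with pytest.raises(ValidationError):
            GeneModel("g", "chr1", ".", 0, 10)
        with pytest.raises(ValidationError):
            GeneModel("g", "chr1", "+", 100, 200,
                      [Interval("chr1", 50, 150)])

    def test_oriented_interval_maps_strand(self):
        plus = GeneModel("g", "chr1", "+", 1000, 3000)
        assert plus.oriented_interval(-30, 300) == (970, 1300)
        minus = GeneModel("g", "chr1", "-", 1000, 3000)   # TSS 2999
        assert minus.oriented_interval(-30, 300) == (2699, 3029)

    def test_probe_track_validates_monotone_and_shape(self):
        with pytest.raises(ValidationError):
            ProbeTrack(50, [("c", 1)], {"chr1": (np.array([10, 10]),
                                                 np.zeros((2, 1)))})
        with pytest.raises(ValidationError):
            ProbeTrack(50, [("c", 1)], {"chr1": (np.array([0, 50]),
                                                 np.array([[1.0], [np.inf]]))})

    def test_condition_values_averages_replicates(self):
        t = ProbeTrack(50, [("c", 1), ("c", 2)],
                       {"chr1": (np.array([0, 50]),
                                 np.array([[1.0, 3.0], [2.0, 4.0]]))})
        assert np.allclose(t.condition_values("chr1", "c"), [2.0, 3.0])


class TestIntervalFormats:
    def test_bed_line_parses_zero_based(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2L\t100\t200\tpk1\t7\t+\n")
        ivs = list(read_intervals(p, "BED"))
        assert ivs == [Interval("chr2L", 100, 200, "pk1", 7.0, "+")]

    def test_gff_interval_converted_to_half_open(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("chr2L\tsrc\tregion\t101\t200\t5.5\t+\t.\tID=x\n")
        (iv,) = read_intervals(p, "GFF-intervals")
        assert (iv.start, iv.end, iv.score, iv.name) == (100, 200, 5.5, "x")

    def test_malformed_bed_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\tnotanint\t20\n")
        with pytest.raises(ValueError, match=":2"):
            read_intervals(p, "BED")

    def test_inverted_interval_is_validation_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValidationError):
            read_intervals(p, "BED")

    def test_random_set_round_trips(self, tmp_path, rng):
        ivs = []
        for i in range(100):
            start = int(rng.integers(0, 10_000))
            ivs.append(Interval(f"chr{rng.integers(1, 4)}", start,
                                start + int(rng.integers(1, 500)),
                                name=f"iv{i}",
                                score=float(np.round(rng.normal(), 6)),
                                strand="+" if rng.random() < 0.5 else "-"))
        original = IntervalSet(ivs)
        path = tmp_path / "rt.bed"
        write_intervals(original, path)
        assert read_intervals(path, "BED") == original


class TestGeneFormats:
    def test_round_trip_of_synthetic_annotation(self, tmp_path, rng):
        from tilechip.simulate import simulate_annotation
        _, genes, _ = simulate_annotation(n_genes=50, seed=7)
        path = tmp_path / "genes.gff3"
        write_genes(genes, path)
        back = {g.id: g for g in read_genes(path)}
        assert len(back) == len(genes)
        for g in genes:
            b = back[g.id]
            assert (b.chrom, b.strand, b.txStart, b.txEnd) == \
                (g.chrom, g.strand, g.txStart, g.txEnd)
            assert [(e.start, e.end) for e in b.exons] == \
                [(e.start, e.end) for e in g.exons]

    def test_gene_without_strand_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\nchr1\t.\tgene\t100\t200\t.\t.\t.\tID=g1\n")
        with pytest.raises(ValidationError):
            read_genes(p)

    def test_exon_outside_span_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n"
                     "chr1\t.\texon\t150\t300\t.\t+\t.\tID=e;Parent=g1\n")
        with pytest.raises(ValidationError):
            read_genes(p)

    def test_exons_merged_per_gene(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\t.\tgene\t1\t1000\t.\t+\t.\tID=g1\n"
                     "chr1\t.\texon\t1\t200\t.\t+\t.\tID=e1;Parent=g1\n"
                     "chr1\t.\texon\t150\t400\t.\t+\t.\tID=e2;Parent=g1\n")
        (g,) = read_genes(p)
        assert [(e.start, e.end) for e in g.exons] == [(0, 400)]


class TestSignalFormats:
    def test_variable_step_wiggle(self, tmp_path):
        p = tmp_path / "s.wig"
        p.write_text("track type=wiggle_0\n"
                     "variableStep chrom=chr1 span=50\n"
                     "1\t1.5\n34\t-0.25\n67\t0.0\n")
        t = read_signal(p, "wiggle")
        assert np.array_equal(t.positions("chr1"), [0, 33, 66])
        assert np.allclose(t.values("chr1")[:, 0], [1.5, -0.25, 0.0])
        assert t.probe_len == 50

    def test_fixed_step_wiggle(self, tmp_path):
        p = tmp_path / "s.wig"
        p.write_text("fixedStep chrom=chr1 start=101 step=10 span=10\n1\n2\n3\n")
        t = read_signal(p, "wiggle")
        assert np.array_equal(t.positions("chr1"), [100, 110, 120])

    def test_probe_gff_scores_become_intensities(self, tmp_path):
        p = tmp_path / "s.gff"
        p.write_text("chr1\ta\tprobe\t1\t50\t0.75\t.\t.\t.\n"
                     "chr1\ta\tprobe\t34\t83\t-1.5\t.\t.\t.\n")
        t = read_signal(p, "probe-gff")
        assert np.allclose(t.values("chr1")[:, 0], [0.75, -1.5])
        assert t.probe_len == 50

    def test_non_monotone_positions_rejected(self, tmp_path):
        p = tmp_path / "s.wig"
        p.write_text("variableStep chrom=chr1\n100\t1\n50\t2\n")
        with pytest.raises(ValidationError):
            read_signal(p, "wiggle")

    def test_missing_value_token_is_parse_error(self, tmp_path):
        p = tmp_path / "s.gff"
        p.write_text("chr1\ta\tprobe\t1\t50\t\t.\t.\t.\n")
        with pytest.raises(ValueError):
            read_signal(p, "probe-gff")

    def test_empty_track_writes_header_only(self, tmp_path):
        t = ProbeTrack(50, [("c", 1)], {})
        path = tmp_path / "e.wig"
        write_signal(t, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_internal_zero_emitted_as_one_based(self, tmp_path):
        t = ProbeTrack(50, [("c", 1)],
                       {"chr1": (np.array([0]), np.array([[2.0]]))})
        path = tmp_path / "one.wig"
        write_signal(t, path)
        assert "1\t2" in path.read_text()

    def test_wiggle_round_trip_to_1e9(self, tmp_path, rng):
        pos = np.sort(rng.choice(10_000, size=200, replace=False))
        vals = rng.normal(size=200)
        t = ProbeTrack(50, [("control", 1)], {"chr1": (pos, vals[:, None])})
        path = tmp_path / "rt.wig"
        write_signal(t, path)
        back = read_signal(path, "wiggle")
        assert np.array_equal(back.positions("chr1"), pos)
        assert np.allclose(back.values("chr1")[:, 0], vals, atol=1e-9)


class TestMergeIntervals:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 50)),
                    min_size=0, max_size=30))
    def test_merge_covers_same_positions(self, raw):
        ivs = [Interval("c", s, s + l) for s, l in raw]
        merged = merge_intervals(ivs)
        covered = set()
        for iv in ivs:
            covered |= set(range(iv.start, iv.end))
        merged_cov = set()
        for iv in merged:
            assert not merged_cov & set(range(iv.start, iv.end))
            merged_cov |= set(range(iv.start, iv.end))
        assert covered == merged_cov
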