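"""Interval arithmetic, annotation IO, and intergenic-region derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zgakit.genome import (
    GenomeAnnotation,
    GenomicInterval,
    IntervalSet,
    ParseError,
    derive_intergenic_regions,
    merge_intervals,
    read_annotation,
    read_bed,
    read_gtf_genes,
    write_bed,
)
from zgakit.simulate import intergenic_mask_per_base


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            iv("chr1", 10, 10)
        with pytest.raises(ValueError):
            iv("chr1", 20, 10)
        with pytest.raises(ValueError):
            iv("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestMerge:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(0, 10), (5, 15)], [(0, 15)]),          # overlap union
            ([(0, 10), (10, 20)], [(0, 20)]),         # touching intervals merge
            ([(0, 5), (8, 9)], [(0, 5), (8, 9)]),     # disjoint unchanged
            ([(8, 9), (0, 5)], [(0, 5), (8, 9)]),     # order-insensitive
        ],
    )
    def test_merge_cases(self, raw, expected):
        merged = merge_intervals([iv("chr1", s, e) for s, e in raw])
        got = [(i.start, i.end) for i in merged.intervals()]
        assert got == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_merge_equals_per_base_union(self, pairs):
        """The merged set covers exactly the union of the input bases."""
        merged = merge_intervals([iv("c", s, e) for s, e in pairs])
        mask = np.zeros(600, dtype=bool)
        for s, e in pairs:
            mask[s:e] = True
        got = np.zeros(600, dtype=bool)
        for i in merged.intervals():
            got[i.start : i.end] = True
        assert np.array_equal(mask, got)
        # disjoint with positive gaps
        arr = merged.arrays("c")
        assert np.all(arr[1:, 0] > arr[:-1, 1])


class TestContains:
    def setup_method(self):
        self.s = IntervalSet({"chr1": [(0, 30000)]})

    def test_strict_containment(self):
        assert self.s.contains(iv("chr1", 10000, 10150))

    def test_boundary_overlap_is_not_containment(self):
        assert not self.s.contains(iv("chr1", 29900, 30100))

    def test_absent_chromosome(self):
        assert not self.s.contains(iv("chr2", 1, 2))

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_linear_scan(self, data):
        starts = sorted(data.draw(st.sets(st.integers(0, 900), min_size=1, max_size=10)))
        members = []
        prev_end = 0
        for s in starts:
            s = max(s, prev_end + 1)
            e = s + data.draw(st.integers(1, 50))
            members.append((s, e))
            prev_end = e
        iset = IntervalSet({"c": members})
        qs = data.draw(st.integers(0, 1000))
        qe = qs + data.draw(st.integers(1, 60))
        expected = any(s <= qs and qe <= e for s, e in members)
        assert iset.contains(iv("c", qs, qe)) == expected


class TestIntergenic:
    def test_single_gene_halo(self):
        """With one 10 kb gene mid-chromosome and d = 10 kb, exactly the
        expanded gene body is excluded (per-base oracle value)."""
        ann = GenomeAnnotation(
            chrom_sizes={"chr1": 100_000},
            genes=[iv("chr1", 40_000, 50_000, name="geneA")],
        )
        got = derive_intergenic_regions(ann, 10_000)
        assert [(i.start, i.end) for i in got.intervals()] == [(0, 30_000), (60_000, 100_000)]

    def test_distance_zero_is_exact_complement(self):
        ann = GenomeAnnotation(
            chrom_sizes={"chr1": 1_000},
            genes=[iv("chr1", 100, 200, name="a"), iv("chr1", 150, 300, name="b")],
        )
        got = derive_intergenic_regions(ann, 0)
        assert [(i.start, i.end) for i in got.intervals()] == [(0, 100), (300, 1_000)]

    def test_overlapping_halos_leave_no_sliver(self):
        ann = GenomeAnnotation(
            chrom_sizes={"chr1": 100_000},
            genes=[iv("chr1", 20_000, 25_000, name="a"), iv("chr1", 30_000, 35_000, name="b")],
        )
        got = derive_intergenic_regions(ann, 10_000)
        assert [(i.start, i.end) for i in got.intervals()] == [(0, 10_000), (45_000, 100_000)]
        # per-base oracle agreement
        mask = intergenic_mask_per_base(
            100_000, np.array([[20_000, 25_000], [30_000, 35_000]]), 10_000
        )
        oracle_bp = int(mask.sum())
        assert got.total_bp() == oracle_bp

    def test_no_genes_returns_whole_chromosomes(self):
        ann = GenomeAnnotation(chrom_sizes={"chr1": 500, "chr2": 300})
        got = derive_intergenic_regions(ann, 10)
        assert got.total_bp() == 800

    def test_total_bp_monotone_in_distance(self, rng):
        genes = []
        for k in range(8):
            s = int(rng.integers(0, 90_000))
            genes.append(iv("chr1", s, s + int(rng.integers(100, 3_000)), name=f"g{k}"))
        ann = GenomeAnnotation(chrom_sizes={"chr1": 100_000}, genes=genes)
        totals = [
            derive_intergenic_regions(ann, d).total_bp() for d in (0, 100, 1_000, 5_000, 20_000)
        ]
        assert totals == sorted(totals, reverse=True)


class TestAnnotationIO:
    def test_bed_is_passed_through(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t200\tgeneA\n")
        ann = read_annotation(p, "bed", {"chr1": 1_000})
        assert ann.genes[0] == iv("chr1", 100, 200, name="geneA")

    def test_gtf_converts_coordinates(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "gA"; gene_biotype "lncRNA";\n'
        )
        genes = read_gtf_genes(p)
        assert (genes[0].start, genes[0].end) == (100, 200)
        assert genes[0].feature_class == "lncRNA"

    def test_gtf_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1\t50\t.\t+\t.\tgene_id "a";\n'
            'chr1\tsrc\tgene\t300\t200\t.\t+\t.\tgene_id "b";\n'
        )
        with pytest.raises(ParseError, match=":2"):
            read_gtf_genes(p)

    def test_feature_beyond_chromosome_is_validation_error(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t2000\tgeneA\n")
        with pytest.raises(ValueError, match="exceeds"):
            read_annotation(p, "bed", {"chr1": 1_000})

    def test_bed_round_trip(self, tmp_path, rng):
        genes = []
        pos = 0
        for k in range(20):
            pos += int(rng.integers(1, 100))
            end = pos + int(rng.integers(1, 50))
            genes.append(iv("chr1", pos, end))
            pos = end
        iset = IntervalSet.from_intervals(genes, tag="t")
        p = tmp_path / "r.bed"
        iset.to_bed(p)
        assert IntervalSet.from_bed(p, tag="t") == iset
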