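"""Coordinate model, format I/O and location classification."""

import numpy as np
import pytest

from tarlink.genome import (
    AlignedSegment,
    Gene,
    GenomeAnnotation,
    Interval,
    classify_location,
    merge_intervals,
    pair_reads,
    read_alignments,
    read_annotation,
    read_paired_bed,
    write_bed12,
    write_chrom_sizes,
    write_paired_bed,
)


class TestInterval:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            Interval("chr1", 10, 10)
        with pytest.raises(ValueError):
            Interval("chr1", -1, 5)

    def test_overlap_bp(self):
        a = Interval("chr1", 0, 100)
        assert a.overlap_bp(Interval("chr1", 50, 150)) == 50
        assert a.overlap_bp(Interval("chr2", 50, 150)) == 0
        assert a.overlap_bp(Interval("chr1", 100, 150)) == 0


class TestGene:
    def test_exons_sorted_and_merged(self):
        g = Gene("g", "+", [Interval("chr1", 300, 400), Interval("chr1", 100, 200)])
        assert [e.start for e in g.exons] == [100, 300]
        assert g.introns == [Interval("chr1", 200, 300)]
        assert g.span == Interval("chr1", 100, 400)

    def test_overlapping_records_merge_into_one_exon(self):
        g = Gene("g", "+", [Interval("chr1", 100, 250), Interval("chr1", 200, 300)])
        assert g.exons == [Interval("chr1", 100, 300)]


class TestAnnotationIO:
    def test_bed12_round_trip(self, toy_annotation, tmp_path):
        bed = tmp_path / "ann.bed12"
        sizes = tmp_path / "chrom.sizes"
        write_bed12(toy_annotation, bed)
        write_chrom_sizes(toy_annotation.chrom_sizes, sizes)
        back = read_annotation(bed, sizes)
        orig = {g.gene_id: (g.strand, g.exons) for g in toy_annotation.genes}
        new = {g.gene_id: (g.strand, g.exons) for g in back.genes}
        assert orig == new

    def test_bed12_block_count(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t1000\tg1\t0\t+\t100\t1000\t0\t3\t50,60,70,\t0,300,830,\n")
        sizes = tmp_path / "s.tsv"
        sizes.write_text("chr1\t10000\n")
        ann = read_annotation(bed, sizes)
        (g,) = ann.genes
        assert len(g.exons) == 3
        assert len(g.introns) == 2

    def test_gff3_overlapping_exons_merge(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id=gX\n"
            "chr1\tsrc\texon\t151\t250\t.\t+\t.\tgene_id=gX\n"
        )
        sizes = tmp_path / "s.tsv"
        sizes.write_text("chr1\t10000\n")
        ann = read_annotation(gff, sizes)
        (g,) = ann.genes
        assert g.exons == [Interval("chr1", 100, 250)]

    def test_unknown_chromosome_is_hard_error(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chrZ\t0\t100\tbad\t0\t+\t0\t100\t0\t1\t100,\t0,\n")
        sizes = tmp_path / "s.tsv"
        sizes.write_text("chr1\t10000\n")
        with pytest.raises(ValueError, match="bad"):
            read_annotation(bed, sizes)

    def test_zero_genes_warns_but_valid(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        sizes = tmp_path / "s.tsv"
        sizes.write_text("chr1\t10000\n")
        with pytest.warns(UserWarning):
            ann = read_annotation(bed, sizes)
        assert ann.genes == []


class TestAlignmentIO:
    SAM = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:100000\n"
        "r1\t99\tchr1\t101\t60\t10M100N25M\t=\t401\t335\t*\t*\n"
        "r1\t147\tchr1\t401\t60\t35M\t=\t101\t-335\t*\t*\n"
        "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        "single\t0\tchr1\t1001\t60\t35M\t*\t0\t0\t*\t*\n"
    )

    def test_sam_split_pairing_and_unmapped(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(self.SAM)
        segs = read_alignments(sam)
        by_id = {s.read_id: s for s in segs}
        assert set(by_id) == {"r1/1", "r1/2", "single"}
        # 10M100N25M -> two blocks (0-based: 100-110, 210-235)
        assert by_id["r1/1"].blocks == [
            Interval("chr1", 100, 110),
            Interval("chr1", 210, 235),
        ]
        pairs, singles = pair_reads(segs)
        assert len(pairs) == 1 and len(singles) == 1
        assert {pairs[0].end1.read_id, pairs[0].end2.read_id} == {"r1/1", "r1/2"}

    def test_paired_bed_round_trip(self, tmp_path):
        segs = [
            AlignedSegment("a/1", [Interval("chr1", 10, 45)], mate_of="a/2", sample="s"),
            AlignedSegment(
                "a/2",
                [Interval("chr1", 200, 215), Interval("chr1", 400, 420)],
                mate_of="a/1",
                sample="s",
            ),
            AlignedSegment("b", [Interval("chr2", 5, 40)], sample="s"),
        ]
        path = tmp_path / "reads.bed"
        write_paired_bed(segs, path)
        back = list(read_paired_bed(path))
        orig = sorted((s.read_id, tuple(s.blocks), s.mate_of) for s in segs)
        new = sorted((s.read_id, tuple(s.blocks), s.mate_of) for s in back)
        assert orig == new

    def test_mate_pairing_is_involution(self, tmp_path):
        segs = [
            AlignedSegment("a/1", [Interval("chr1", 10, 45)], mate_of="a/2"),
            AlignedSegment("a/2", [Interval("chr1", 300, 335)], mate_of="a/1"),
        ]
        pairs, singles = pair_reads(segs)
        assert not singles
        (p,) = pairs
        assert p.end1.mate_of == p.end2.read_id
        assert p.end2.mate_of == p.end1.read_id

    def test_orphan_mate_becomes_single_end(self):
        segs = [AlignedSegment("a/1", [Interval("chr1", 10, 45)], mate_of="a/2")]
        pairs, singles = pair_reads(segs)
        assert not pairs and len(singles) == 1


class TestClassifyLocation:
    def test_priority_cases(self, toy_annotation):
        assert classify_location(Interval("chr1", 10_050, 10_060), toy_annotation) == "exonic"
        # straddles exon/intron boundary -> exonic wins
        assert classify_location(Interval("chr1", 10_150, 10_300), toy_annotation) == "exonic"
        assert classify_location(Interval("chr1", 11_000, 11_100), toy_annotation) == "intronic"
        assert classify_location(Interval("chr1", 95_000, 95_100), toy_annotation) == "intergenic"

    def test_agrees_with_per_base_brute_force(self, toy_annotation):
        ann = toy_annotation
        exon_bases = {
            (g.chrom, b) for g in ann.genes for e in g.exons for b in range(e.start, e.end)
        }
        span_bases = {
            (g.chrom, b) for g in ann.genes for b in range(g.span.start, g.span.end)
        }

        def brute(iv):
            bases = [(iv.chrom, b) for b in range(iv.start, iv.end)]
            if any(b in exon_bases for b in bases):
                return "exonic"
            if any(b in span_bases for b in bases):
                return "intronic"
            return "intergenic"

        rng = np.random.default_rng(3)
        for _ in range(300):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            start = int(rng.integers(0, ann.chrom_sizes[chrom] - 200))
            iv = Interval(chrom, start, start + int(rng.integers(1, 200)))
            assert classify_location(iv, ann) == brute(iv)


def test_annotation_overlap_queries_match_brute_force(toy_annotation):
    ann = toy_annotation
    rng = np.random.default_rng(5)
    all_exons = [(g, e) for g in ann.genes for e in g.exons]
    for _ in range(200):
        start = int(rng.integers(0, 99_000))
        iv = Interval("chr1", start, start + int(rng.integers(1, 1000)))
        expected = sorted(
            g.gene_id for g, e in all_exons if e.overlaps(iv)
        )
        got = sorted({g.gene_id for g, _ in ann.overlapping_exons(iv)})
        assert got == sorted(set(expected))
        assert ann.overlaps_repeat(iv) == any(r.overlaps(iv) for r in ann.repeats)


def test_merge_intervals_properties():
    rng = np.random.default_rng(9)
    for _ in range(50):
        ivs = []
        for _ in range(int(rng.integers(1, 20))):
            s = int(rng.integers(0, 1000))
            ivs.append(Interval("c", s, s + int(rng.integers(1, 100))))
        merged = merge_intervals(ivs)
        # disjoint, sorted, same base set
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start
        base = {b for iv in ivs for b in range(iv.start, iv.end)}
        mbase = {b for iv in merged for b in range(iv.start, iv.end)}
        assert base == mbase
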