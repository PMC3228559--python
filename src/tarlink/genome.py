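"""Genomic coordinate model, annotation index, and alignment readers.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted on read. Reads are treated as unstranded throughout; strand is
carried on :class:`Gene` only.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "Gene",
    "GenomeAnnotation",
    "AlignedSegment",
    "ReadPair",
    "read_annotation",
    "read_chrom_sizes",
    "write_bed12",
    "read_alignments",
    "read_paired_bed",
    "write_paired_bed",
    "pair_reads",
    "classify_location",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval: 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Gene:
    """A gene model: sorted, disjoint exons on one chromosome.

    Introns are the gaps between consecutive exons; the span runs from the
    first exon's start to the last exon's end.
    """

    gene_id: str
    strand: str  # '+', '-', or '.'
    exons: list[Interval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = merge_intervals(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> list[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.chrom, a.end, b.start))
        return out

    @property
    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def is_single_exon(self) -> bool:
        return len(self.exons) == 1


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended intervals (per chromosome)."""
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


class GenomeAnnotation:
    """Queryable index over chromosome sizes, genes, ncRNA and repeat intervals.

    Backed by per-chromosome interval trees so overlap queries scale; tests
    cross-check against brute-force scans.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        genes: list[Gene],
        trna_rrna: Optional[list[Interval]] = None,
        repeats: Optional[list[Interval]] = None,
    ) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self.genes = list(genes)
        self.trna_rrna = list(trna_rrna or [])
        self.repeats = list(repeats or [])
        self._validate()
        self._build_indexes()

    def _validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.span.end > self.chrom_sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom}"
                )
        for name, ivs in (("trna_rrna", self.trna_rrna), ("repeats", self.repeats)):
            for iv in ivs:
                if iv.chrom not in self.chrom_sizes:
                    raise ValueError(f"{name} interval on unknown chromosome {iv.chrom}")
        if not self.genes:
            warnings.warn("annotation contains zero genes", stacklevel=3)

    def _build_indexes(self) -> None:
        self._exon_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._span_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._ncrna_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._repeat_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.genes_by_id: dict[str, Gene] = {}
        for gi, g in enumerate(self.genes):
            self.genes_by_id[g.gene_id] = g
            sp = g.span
            self._span_tree[g.chrom].addi(sp.start, sp.end, gi)
            for e in g.exons:
                self._exon_tree[g.chrom].addi(e.start, e.end, gi)
        for iv in self.trna_rrna:
            self._ncrna_tree[iv.chrom].addi(iv.start, iv.end, None)
        for iv in self.repeats:
            self._repeat_tree[iv.chrom].addi(iv.start, iv.end, None)

    # -- overlap queries -------------------------------------------------

    def overlapping_exons(self, iv: Interval) -> list[tuple[Gene, Interval]]:
        hits = []
        for h in self._exon_tree[iv.chrom].overlap(iv.start, iv.end):
            hits.append((self.genes[h.data], Interval(iv.chrom, h.begin, h.end)))
        return hits

    def overlapping_gene_spans(self, iv: Interval) -> list[Gene]:
        return [
            self.genes[h.data]
            for h in self._span_tree[iv.chrom].overlap(iv.start, iv.end)
        ]

    def overlaps_exon(self, iv: Interval) -> bool:
        return bool(self._exon_tree[iv.chrom].overlap(iv.start, iv.end))

    def overlaps_ncrna(self, iv: Interval) -> bool:
        return bool(self._ncrna_tree[iv.chrom].overlap(iv.start, iv.end))

    def overlaps_repeat(self, iv: Interval) -> bool:
        return bool(self._repeat_tree[iv.chrom].overlap(iv.start, iv.end))

    def merged_exons(self, chrom: Optional[str] = None) -> list[Interval]:
        exons = [
            e for g in self.genes for e in g.exons if chrom is None or g.chrom == chrom
        ]
        return merge_intervals(exons)


@dataclass
class AlignedSegment:
    """One mapped read end; >1 block encodes a junction-spanning split read."""

    read_id: str
    blocks: list[Interval]
    mate_of: Optional[str] = None
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no aligned blocks")
        chroms = {b.chrom for b in self.blocks}
        if len(chroms) != 1:
            raise ValueError(f"read {self.read_id} blocks span chromosomes {chroms}")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id} has overlapping blocks")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.blocks[0].start, self.blocks[-1].end)

    @property
    def aligned_bp(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def is_split(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class ReadPair:
    """A paired-end clone: two sequenced ends plus the unsequenced insert."""

    end1: AlignedSegment
    end2: AlignedSegment
    clone_length: int = 0  # L_c: 2*L_s + insert
    end_length: int = 0  # L_s

    def __post_init__(self) -> None:
        if self.clone_length and self.end_length and self.clone_length < 2 * self.end_length:
            raise ValueError("clone_length must be >= 2 x end_length")

    @property
    def ends(self) -> tuple[AlignedSegment, AlignedSegment]:
        return (self.end1, self.end2)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    if not sizes:
        raise ValueError(f"no chromosomes in {path}")
    return sizes


def _parse_bed12_line(line: str) -> Gene:
    f = line.rstrip("\n").split("\t")
    chrom, start, _end, name = f[0], int(f[1]), int(f[2]), f[3]
    strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
    if len(f) >= 12:
        n = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")[:n]]
        starts = [int(x) for x in f[11].rstrip(",").split(",")[:n]]
        exons = [
            Interval(chrom, start + s, start + s + sz) for s, sz in zip(starts, sizes)
        ]
    else:
        exons = [Interval(chrom, start, _end)]
    return Gene(gene_id=name, strand=strand, exons=exons)


def _gff3_attributes(col9: str) -> dict[str, str]:
    out = {}
    for kv in col9.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3_genes(path: str | Path) -> list[Gene]:
    """Collect exon features grouped by gene_id (or Parent) from a GFF3 file.

    GFF3 is 1-based inclusive; converted to 0-based half-open here.
    """
    exons: dict[str, list[Interval]] = defaultdict(list)
    strands: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2].lower() != "exon":
                continue
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            attrs = _gff3_attributes(f[8])
            gid = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
            if gid is None:
                raise ValueError(f"exon without gene_id/Parent in {path}: {line!r}")
            exons[gid].append(Interval(chrom, start, end))
            strands[gid] = strand if strand in "+-" else "."
    return [Gene(gid, strands[gid], ivs) for gid, ivs in exons.items()]


def read_annotation(
    path: str | Path,
    chrom_sizes_path: str | Path,
    trna_rrna_path: Optional[str | Path] = None,
    repeats_path: Optional[str | Path] = None,
) -> GenomeAnnotation:
    """Read a gene annotation (BED12 or GFF3) plus chromosome sizes.

    Overlapping exon records sharing a gene_id are merged. Features on
    chromosomes absent from the sizes file raise a hard error naming the
    offending feature.
    """
    path = Path(path)
    sizes = read_chrom_sizes(chrom_sizes_path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        genes = _read_gff3_genes(path)
    else:
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_parse_bed12_line(line))
        # merge multiple BED lines sharing a gene_id
        by_id: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in by_id:
                prev = by_id[g.gene_id]
                by_id[g.gene_id] = Gene(g.gene_id, prev.strand, prev.exons + g.exons)
            else:
                by_id[g.gene_id] = g
        genes = list(by_id.values())
    for g in genes:
        if g.chrom not in sizes:
            raise ValueError(
                f"feature {g.gene_id} on chromosome {g.chrom} absent from sizes file"
            )
    trna_rrna = read_bed_intervals(trna_rrna_path) if trna_rrna_path else []
    repeats = read_bed_intervals(repeats_path) if repeats_path else []
    return GenomeAnnotation(sizes, genes, trna_rrna=trna_rrna, repeats=repeats)


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read a BED3+ file into plain intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(Interval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed12(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as coordinate-sorted BED12; round-trips exactly."""
    rows = []
    for g in ann.genes:
        sp = g.span
        sizes = ",".join(str(len(e)) for e in g.exons) + ","
        starts = ",".join(str(e.start - sp.start) for e in g.exons) + ","
        rows.append(
            (
                g.chrom,
                sp.start,
                sp.end,
                g.gene_id,
                0,
                g.strand if g.strand in "+-" else ".",
                sp.start,
                sp.end,
                "0",
                len(g.exons),
                sizes,
                starts,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


# -- alignments --------------------------------------------------------------


def read_alignments(path: str | Path, sample: str = "") -> list[AlignedSegment]:
    """Read mapped reads from SAM/BAM or the paired-BED dialect.

    N-gapped (spliced) alignments are split into blocks; secondary,
    supplementary and unmapped records are dropped. Mate linkage is recorded
    by read name with a /1 or /2 suffix distinguishing the two ends.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return list(read_paired_bed(path))
    import pysam

    segs: list[AlignedSegment] = []
    save = pysam.set_verbosity(0)  # silence missing-index warning for SAM
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            blocks = [
                Interval(chrom, s, e) for s, e in _merge_abutting(rec.get_blocks())
            ]
            if rec.is_paired:
                this = "/1" if rec.is_read1 else "/2"
                mate = "/2" if rec.is_read1 else "/1"
                rid = rec.query_name + this
                mate_of = rec.query_name + mate if not rec.mate_is_unmapped else None
            else:
                rid, mate_of = rec.query_name, None
            segs.append(
                AlignedSegment(read_id=rid, blocks=blocks, mate_of=mate_of, sample=sample)
            )
    pysam.set_verbosity(save)
    return segs


def _merge_abutting(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # pysam get_blocks splits on I/D as well as N; only true gaps matter here
    out: list[list[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def read_paired_bed(path: str | Path) -> Iterator[AlignedSegment]:
    """Read the 7-column paired-BED dialect.

    Columns: chrom, start, end, read_id, mate_id ('.' if single-end), sample,
    blocks (comma-separated start-end pairs in genome coordinates).
    """
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, read_id, mate_id, sample = f[0], f[3], f[4], f[5]
            blocks = []
            for part in f[6].split(","):
                s, e = part.split("-")
                blocks.append(Interval(chrom, int(s), int(e)))
            yield AlignedSegment(
                read_id=read_id,
                blocks=blocks,
                mate_of=None if mate_id == "." else mate_id,
                sample=sample,
            )


def write_paired_bed(segs: Iterable[AlignedSegment], path: str | Path) -> None:
    rows = []
    for s in segs:
        sp = s.span
        blocks = ",".join(f"{b.start}-{b.end}" for b in s.blocks)
        rows.append(
            (sp.chrom, sp.start, sp.end, s.read_id, s.mate_of or ".", s.sample, blocks)
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def pair_reads(segs: Iterable[AlignedSegment]) -> tuple[list[ReadPair], list[AlignedSegment]]:
    """Resolve mate links into ReadPairs; unmatched mates fall back to single-end."""
    by_id: dict[str, AlignedSegment] = {}
    singles: list[AlignedSegment] = []
    for s in segs:
        if s.mate_of is None:
            singles.append(s)
        else:
            by_id[s.read_id] = s
    pairs: list[ReadPair] = []
    seen: set[str] = set()
    n_orphans = 0
    for rid, s in by_id.items():
        if rid in seen:
            continue
        mate = by_id.get(s.mate_of)
        if mate is None or mate.mate_of != rid:
            n_orphans += 1
            singles.append(s)
            seen.add(rid)
            continue
        first, second = sorted((s, mate), key=lambda x: x.read_id)
        pairs.append(ReadPair(end1=first, end2=second))
        seen.update((rid, s.mate_of))
    if n_orphans:
        logger.info("flagged %d unpaired mates as single-end", n_orphans)
    return pairs, singles


# ---------------------------------------------------------------------------
# Location classification
# ---------------------------------------------------------------------------


def classify_location(iv: Interval, ann: GenomeAnnotation) -> str:
    """Classify an interval as exonic, intronic or intergenic.

    Priority is fixed: any >=1 bp exon overlap wins; otherwise overlap with
    any gene span makes it intronic; otherwise intergenic. Classification is
    against the union of all genes, not per-gene.
    """
    if ann.overlaps_exon(iv):
        return "exonic"
    if ann.overlapping_gene_spans(iv):
        return "intronic"
    return "intergenic"


def classify_segment(seg: AlignedSegment, ann: GenomeAnnotation) -> str:
    """Classify a read by its blocks under the same exon>intron>intergenic priority."""
    classes = {classify_location(b, ann) for b in seg.blocks}
    if "exonic" in classes:
        return "exonic"
    if "intronic" in classes:
        return "intronic"
    return "intergenic"
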