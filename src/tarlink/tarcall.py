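"""TAR calling: coverage segments, proximity chaining, and the filter cascade.

A transcriptionally active region (TAR) is a maximal run of read coverage;
nearby runs are chained, and candidates then pass an ordered cascade —
length > 100 bp, mean coverage > 5X, no overlap with exons/tRNA/rRNA, no
overlap with repeats, and > 2 kb from every gene's first-exon start and
last-exon end (to exclude promoter/TSS/TTS-associated transcription).
Survivors are classed intronic (inside a gene span) or intergenic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from intervaltree import IntervalTree

from .genome import AlignedSegment, GenomeAnnotation, Interval

__all__ = [
    "Tar",
    "covered_segments",
    "chain_segments",
    "filter_tars",
    "tar_fraction_report",
    "call_tars",
]


@dataclass
class Tar:
    region: Interval
    n_reads: int
    mean_coverage: float
    klass: str  # {intronic, intergenic}
    host_gene: Optional[str]
    filter_trail: list[str] = field(default_factory=list)

    @property
    def tar_id(self) -> str:
        r = self.region
        return f"TAR_{r.chrom}_{r.start}_{r.end}"


def covered_segments(
    segs: Iterable[AlignedSegment], min_depth: int = 1
) -> list[Interval]:
    """Maximal intervals with per-base read depth >= min_depth (event sweep)."""
    events: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for s in segs:
        for b in s.blocks:
            events[b.chrom].append((b.start, 1))
            events[b.chrom].append((b.end, -1))
    out: list[Interval] = []
    for chrom in sorted(events):
        net: dict[int, int] = defaultdict(int)
        for pos, delta in events[chrom]:
            net[pos] += delta
        depth = 0
        start: Optional[int] = None
        for pos in sorted(net):
            new = depth + net[pos]
            if depth < min_depth <= new:
                start = pos
            elif new < min_depth <= depth and start is not None:
                if pos > start:
                    out.append(Interval(chrom, start, pos))
                start = None
            depth = new
    return out


def chain_segments(segments: list[Interval], max_gap: int = 50) -> list[Interval]:
    """Merge consecutive same-chromosome segments separated by <= max_gap bp."""
    segments = sorted(segments, key=lambda iv: (iv.chrom, iv.start))
    out: list[Interval] = []
    for iv in segments:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= max_gap:
            out[-1] = Interval(iv.chrom, out[-1].start, max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return out


def _coverage_stats(
    region: Interval, block_tree: dict[str, IntervalTree]
) -> tuple[int, int]:
    """(overlapping read count, aligned bp overlapping the region)."""
    reads: set[str] = set()
    bp = 0
    for h in block_tree[region.chrom].overlap(region.start, region.end):
        bp += min(h.end, region.end) - max(h.begin, region.start)
        reads.add(h.data)
    return len(reads), bp


def _build_block_tree(segs: Iterable[AlignedSegment]) -> dict[str, IntervalTree]:
    tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for s in segs:
        for b in s.blocks:
            tree[b.chrom].addi(b.start, b.end, s.read_id)
    return tree


def filter_tars(
    candidates: list[Interval],
    segs: Iterable[AlignedSegment],
    ann: GenomeAnnotation,
    min_length: int = 100,
    min_coverage: float = 5.0,
    vicinity: int = 2000,
    uniqueness_hook: Optional[Callable[[Interval], bool]] = None,
) -> tuple[list[Tar], list[tuple[Interval, str]]]:
    """Apply the ordered filter cascade to candidate TAR intervals.

    Returns surviving Tars and a drop log of (interval, reason). The
    uniqueness_hook, when given, stands where a genome-wide uniqueness
    screen (e.g. BLAST-back) would run; it returns True to keep a region.
    """
    block_tree = _build_block_tree(segs)

    # vicinity zones around every gene's span endpoints
    zone_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    if vicinity > 0:
        for g in ann.genes:
            sp = g.span
            for p in (sp.start, sp.end):
                zone_tree[g.chrom].addi(max(0, p - vicinity), p + vicinity + 1, None)

    tars: list[Tar] = []
    dropped: list[tuple[Interval, str]] = []
    for region in sorted(candidates, key=lambda iv: (iv.chrom, iv.start)):
        trail: list[str] = []
        if len(region) <= min_length:
            dropped.append((region, "length"))
            continue
        trail.append("length:pass")
        n_reads, bp = _coverage_stats(region, block_tree)
        mean_cov = bp / len(region)
        if mean_cov <= min_coverage:
            dropped.append((region, "coverage"))
            continue
        trail.append("coverage:pass")
        if ann.overlaps_exon(region) or ann.overlaps_ncrna(region):
            dropped.append((region, "annotated"))
            continue
        trail.append("annotated:pass")
        if ann.overlaps_repeat(region):
            dropped.append((region, "repeat"))
            continue
        trail.append("repeat:pass")
        if vicinity > 0 and zone_tree[region.chrom].overlap(region.start, region.end):
            dropped.append((region, "vicinity"))
            continue
        trail.append("vicinity:pass")
        if uniqueness_hook is not None and not uniqueness_hook(region):
            dropped.append((region, "uniqueness"))
            continue

        hosts = [g for g in ann.overlapping_gene_spans(region) if g.span.contains(region)]
        if hosts:
            klass, host = "intronic", hosts[0].gene_id
        elif ann.overlapping_gene_spans(region):
            # straddles a span boundary (possible only with vicinity=0): by midpoint
            mid = (region.start + region.end) // 2
            point = Interval(region.chrom, mid, mid + 1)
            inside = ann.overlapping_gene_spans(point)
            klass = "intronic" if inside else "intergenic"
            host = inside[0].gene_id if inside else None
        else:
            klass, host = "intergenic", None
        tars.append(
            Tar(
                region=region,
                n_reads=n_reads,
                mean_coverage=mean_cov,
                klass=klass,
                host_gene=host,
                filter_trail=trail,
            )
        )
    return tars, dropped


def call_tars(
    segs: Iterable[AlignedSegment],
    ann: GenomeAnnotation,
    min_depth: int = 1,
    max_gap: int = 50,
    min_length: int = 100,
    min_coverage: float = 5.0,
    vicinity: int = 2000,
    uniqueness_hook: Optional[Callable[[Interval], bool]] = None,
) -> tuple[list[Tar], list[tuple[Interval, str]]]:
    """Full TAR pipeline: coverage segments -> chaining -> filter cascade."""
    segs = list(segs)
    segments = covered_segments(segs, min_depth=min_depth)
    candidates = chain_segments(segments, max_gap=max_gap)
    return filter_tars(
        candidates,
        segs,
        ann,
        min_length=min_length,
        min_coverage=min_coverage,
        vicinity=vicinity,
        uniqueness_hook=uniqueness_hook,
    )


def tar_fraction_report(
    tars: list[Tar], segs: Iterable[AlignedSegment], n_bp: float
) -> dict[str, float]:
    """Percent of dataset base pairs inside intronic and intergenic TARs."""
    if n_bp <= 0:
        raise ValueError("N_bp must be positive")
    tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in tars:
        r = t.region
        tree[r.chrom].addi(r.start, r.end, t.klass)
    bp = {"intronic": 0, "intergenic": 0}
    for s in segs:
        for b in s.blocks:
            for h in tree[b.chrom].overlap(b.start, b.end):
                bp[h.data] += min(h.end, b.end) - max(h.begin, b.start)
    return {
        "intronic_pct": 100.0 * bp["intronic"] / n_bp,
        "intergenic_pct": 100.0 * bp["intergenic"] / n_bp,
    }


def write_tar_bed(tars: list[Tar], path) -> None:
    """BED6+ writer: name=TAR id, score=n_reads, extra klass/host/coverage."""
    with open(path, "w") as fh:
        for t in sorted(tars, key=lambda t: (t.region.chrom, t.region.start)):
            r = t.region
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        t.tar_id,
                        str(t.n_reads),
                        ".",
                        t.klass,
                        t.host_gene or ".",
                        f"{t.mean_coverage:.3f}",
                    ]
                )
                + "\n"
            )
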