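"""Paired-end connectivity model: is a TAR part of a longer transcript?

If a TAR of length L_r were part of a larger transcript, paired-end clones
starting near its boundaries would place one end outside it. Under a
uniform (or any internally consistent) read-start distribution the
expected number of such end-linking reads at one end is

    N_e = N_i * L_c / (2 * L_r) - T * N_i * (L_s - M) / L_r

where N_i is twice the count of clones fully internal to the TAR, L_c the
clone length, L_s the end read length, M the mapper's allowed mismatches,
and T the mapper's success rate at placing partial (junction-spanning)
reads. Observing far fewer links than N_e marks the TAR as a standalone
transcript; otherwise the link destinations decide between connection to a
known exon, to unannotated sequence on the same chromosome, or to other
chromosomes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .genome import (
    AlignedSegment,
    Gene,
    GenomeAnnotation,
    Interval,
    ReadPair,
    classify_segment,
)
from .tarcall import Tar

__all__ = [
    "ConnectivityParams",
    "ConnectivityCall",
    "expected_end_links",
    "collect_link_evidence",
    "classify_connection",
    "classify_tars",
    "validate_controls",
]

CONNECTED = "connected_known_exon"
STANDALONE = "standalone"
SAME_CHROM = "non_standalone_same_chrom"
MULTI_CHROM = "multi_chromosome"


@dataclass
class ConnectivityParams:
    L_s: int = 35  # read end length, bp
    L_c: int = 300  # clone length, bp (2*L_s + insert)
    M: int = 2  # mapper's max allowed mismatches
    T: float = 0.99  # partial-read end-mapping success rate
    standalone_frac: float = 0.20  # "significantly less than" N_e
    exon_link_frac: float = 0.50  # "significant portion" of links
    min_links: int = 2  # absolute floor for a destination verdict
    double_ne_if_both_flanks: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must be in [0, 1]")
        if not 0.0 < self.standalone_frac < 1.0:
            raise ValueError("standalone_frac must be in (0, 1)")
        if self.L_c < 2 * self.L_s:
            raise ValueError("L_c must be >= 2 x L_s")
        if self.M < 0:
            raise ValueError("M must be >= 0")


@dataclass
class ConnectivityCall:
    tar_id: str
    L_r: int
    N_i: int = 0  # twice the count of fully-internal pairs
    N_e: float = 0.0
    links: dict[str, int] = field(
        default_factory=lambda: {
            "annotated_exon": 0,
            "unannotated_same_chrom": 0,
            "other_chromosome": 0,
        }
    )
    both_flanks: bool = False
    verdict: Optional[str] = None

    @property
    def total_links(self) -> int:
        return sum(self.links.values())


def expected_end_links(
    n_i: int,
    l_r: int,
    p: ConnectivityParams,
    both_flanks: bool = False,
) -> float:
    """Expected end-linking read count N_e at one end of a TAR.

    Negative raw values are floored at 0; with link evidence on both flanks
    the expectation is doubled (reads leave through both ends).
    """
    if l_r <= 0:
        raise ValueError("L_r must be positive")
    if n_i < 0:
        raise ValueError("N_i must be nonnegative")
    raw = n_i * p.L_c / (2.0 * l_r) - p.T * n_i * (p.L_s - p.M) / l_r
    val = max(0.0, raw)
    if both_flanks and p.double_ne_if_both_flanks:
        val *= 2.0
    return val


def _end_status(end: AlignedSegment, region: Interval) -> str:
    """inside | split_out | partial | outside, relative to a region."""
    if end.chrom != region.chrom:
        return "outside"
    inside = [b for b in end.blocks if region.contains(b)]
    touching = [b for b in end.blocks if b.overlaps(region)]
    if len(inside) == len(end.blocks):
        return "inside"
    if not touching:
        return "outside"
    if any(not b.overlaps(region) for b in end.blocks):
        return "split_out"  # block chain leaves the region
    return "partial"  # single block straddling a boundary


def _outside_destination(
    end: AlignedSegment, region: Interval, ann: GenomeAnnotation
) -> str:
    if end.chrom != region.chrom:
        return "other_chromosome"
    outside_blocks = [b for b in end.blocks if not region.contains(b)]
    probe = AlignedSegment(end.read_id, outside_blocks or end.blocks, sample=end.sample)
    return (
        "annotated_exon"
        if classify_segment(probe, ann) == "exonic"
        else "unannotated_same_chrom"
    )


def collect_link_evidence(
    tar_id: str,
    region: Interval,
    pairs: Sequence[ReadPair],
    ann: GenomeAnnotation,
    params: ConnectivityParams,
) -> ConnectivityCall:
    """Count internal pairs and end-linking pairs for one region.

    A pair is internal when both ends lie wholly inside the region (adds 2
    to N_i); linking when exactly one end lies inside, with the destination
    read off the outside end. A junction-spanning end whose block chain
    leaves the region also counts as a link (destination annotated_exon if
    the outside blocks hit an exon). At most one link per pair.
    """
    call = ConnectivityCall(tar_id=tar_id, L_r=len(region))
    up = down = False
    for pair in pairs:
        s1 = _end_status(pair.end1, region)
        s2 = _end_status(pair.end2, region)
        if s1 == "inside" and s2 == "inside":
            call.N_i += 2
            continue
        link_end: Optional[AlignedSegment] = None
        if s1 == "inside" and s2 == "outside":
            link_end = pair.end2
        elif s2 == "inside" and s1 == "outside":
            link_end = pair.end1
        elif s1 == "split_out":
            link_end = pair.end1
        elif s2 == "split_out":
            link_end = pair.end2
        if link_end is None:
            continue
        dest = _outside_destination(link_end, region, ann)
        call.links[dest] += 1
        if dest != "other_chromosome":
            out_blocks = [b for b in link_end.blocks if not region.contains(b)]
            anchor = out_blocks[0] if out_blocks else link_end.blocks[0]
            mid = (anchor.start + anchor.end) // 2
            if mid < region.start:
                up = True
            elif mid >= region.end:
                down = True
    call.both_flanks = up and down
    call.N_e = expected_end_links(call.N_i, call.L_r, params, call.both_flanks)
    return call


def classify_connection(call: ConnectivityCall, p: ConnectivityParams) -> str:
    """Four-way verdict from observed links vs the expectation N_e.

    When L_r < L_c every internal clone should in theory be a linking one,
    so the standalone test compares links against standalone_frac times the
    clone total (N_i/2 + links) instead of N_e.
    """
    total = call.total_links
    if call.L_r < p.L_c:
        threshold = p.standalone_frac * (call.N_i / 2.0 + total)
    else:
        threshold = p.standalone_frac * call.N_e
    if total == 0 and threshold == 0:
        return STANDALONE
    if total < threshold:
        return STANDALONE
    other = call.links["other_chromosome"]
    exon = call.links["annotated_exon"]
    if other >= p.min_links and other >= p.exon_link_frac * total:
        return MULTI_CHROM
    if exon >= p.min_links and exon >= p.exon_link_frac * total:
        return CONNECTED
    return SAME_CHROM


def classify_tars(
    tars: Sequence[Tar],
    pairs: Sequence[ReadPair],
    ann: GenomeAnnotation,
    params: ConnectivityParams,
) -> list[ConnectivityCall]:
    """Classify every TAR; returns calls with verdicts set."""
    index = _PairIndex(pairs)
    calls = []
    for t in tars:
        call = collect_link_evidence(
            t.tar_id, t.region, index.near(t.region), ann, params
        )
        call.verdict = classify_connection(call, params)
        calls.append(call)
    return calls


class _PairIndex:
    """Position index over pair-end spans for region queries."""

    def __init__(self, pairs: Sequence[ReadPair]) -> None:
        self.pairs = list(pairs)
        self.tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for i, pr in enumerate(self.pairs):
            for end in pr.ends:
                sp = end.span
                self.tree[sp.chrom].addi(sp.start, sp.end, i)

    def near(self, region: Interval) -> list[ReadPair]:
        idx = {h.data for h in self.tree[region.chrom].overlap(region.start, region.end)}
        return [self.pairs[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Positive / negative control validation
# ---------------------------------------------------------------------------


def _masked_annotation(ann: GenomeAnnotation, gene: Gene, drop_exon: Optional[int]) -> GenomeAnnotation:
    """Annotation with one exon (or a whole gene) hidden."""
    genes = []
    for g in ann.genes:
        if g.gene_id != gene.gene_id:
            genes.append(g)
            continue
        if drop_exon is None:
            continue  # mask the whole gene
        exons = [e for i, e in enumerate(g.exons) if i != drop_exon]
        if exons:
            genes.append(Gene(g.gene_id, g.strand, exons))
    return GenomeAnnotation(
        ann.chrom_sizes, genes, trna_rrna=ann.trna_rrna, repeats=ann.repeats
    )


def validate_controls(
    ann: GenomeAnnotation,
    pairs: Sequence[ReadPair],
    params: ConnectivityParams,
    min_reads: int = 1,
) -> dict:
    """Control experiment for the connectivity model.

    Positive controls: one internal expressed exon per multi-exon gene,
    masked from the annotation and treated as an unannotated region —
    success when classified connected to known exons. Negative controls:
    expressed single-exon genes (known standalone transcripts) — success
    when classified anything but connected (multi-chromosome links still
    count as success). Requires paired-end evidence.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("paired-end reads required for control validation")
    index = _PairIndex(pairs)

    def _expressed(region: Interval) -> bool:
        n = 0
        for pr in index.near(region):
            for end in pr.ends:
                if end.chrom == region.chrom and any(
                    b.overlaps(region) for b in end.blocks
                ):
                    n += 1
        return n >= min_reads

    pos_results: list[tuple[str, str]] = []
    neg_results: list[tuple[str, str]] = []
    for g in ann.genes:
        if g.is_single_exon():
            region = g.exons[0]
            if not _expressed(region):
                continue
            masked = _masked_annotation(ann, g, drop_exon=None)
            call = collect_link_evidence(
                g.gene_id, region, index.near(region), masked, params
            )
            call.verdict = classify_connection(call, params)
            neg_results.append((g.gene_id, call.verdict))
        elif len(g.exons) >= 3:
            drop = len(g.exons) // 2  # an internal exon
            region = g.exons[drop]
            if not _expressed(region):
                continue
            masked = _masked_annotation(ann, g, drop_exon=drop)
            call = collect_link_evidence(
                f"{g.gene_id}:exon{drop}", region, index.near(region), masked, params
            )
            call.verdict = classify_connection(call, params)
            pos_results.append((g.gene_id, call.verdict))

    if not pos_results and not neg_results:
        raise ValueError("no eligible control regions with mapped reads")
    pos_ok = sum(1 for _, v in pos_results if v == CONNECTED)
    neg_ok = sum(1 for _, v in neg_results if v != CONNECTED)
    return {
        "positive_success": pos_ok / len(pos_results) if pos_results else None,
        "negative_success": neg_ok / len(neg_results) if neg_results else None,
        "n_positive": len(pos_results),
        "n_negative": len(neg_results),
        "positive_verdicts": pos_results,
        "negative_verdicts": neg_results,
    }
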