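"""Synthetic genomes and TopHat-like alignments with known ground truth.

The generator emits already-mapped reads (mapping itself is out of scope):
multi-exon genes, single-exon genes (SEGs), and planted intronic/intergenic
TARs that are either standalone transcripts or spliced to a flanking exon.
Read starts follow either a uniform distribution (random priming) or an
exponential 3'-bias (poly-dT priming). Junction-spanning reads are emitted
as split alignments subject to a minimum anchor and a partial-read mapping
success rate, emulating the behaviour that the connectivity model's T
factor corrects for.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .genome import (
    AlignedSegment,
    Gene,
    GenomeAnnotation,
    Interval,
    write_bed12,
    write_chrom_sizes,
    write_paired_bed,
)

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "PlantedTar", "SimTruth", "make_genome", "simulate_reads"]

# planted TARs keep this margin from intron boundaries so coverage chaining
# cannot merge them with flanking-exon coverage
_INTRON_PAD = 200
_GENE_SPACING = (2100, 3200)  # keeps every feature > 2 kb from foreign gene spans
_VICINITY = 2000


@dataclass
class SimConfig:
    """Parameters of the toy genome and read simulation.

    Defaults mirror the study conditions: 35-bp paired ends on 300-bp
    clones, the 2-kb clearance that the TAR vicinity filter assumes, and a
    500-bp exponential scale for the poly-dT 3' bias.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 2_000_000
    n_multi_exon_genes: int = 20
    n_seg_genes: int = 5
    exon_len: tuple[int, int] = (150, 250)
    intron_len: tuple[int, int] = (2500, 4000)
    seg_len: tuple[int, int] = (600, 1500)
    n_exons: tuple[int, int] = (4, 7)
    n_planted_intronic_tars: int = 10
    n_planted_intergenic_tars: int = 5
    tar_len: tuple[int, int] = (500, 1500)
    fraction_spliced_tars: float = 0.3
    read_mode: str = "paired"  # {single, paired}
    end_length: int = 35  # L_s
    clone_length: int = 300  # L_c
    priming: str = "random"  # {random, polydT}
    polydT_decay: float = 500.0
    gene_depth: float = 20.0
    tar_depth: float = 20.0
    junction_span_rate: float = 0.99
    min_anchor: int = 5
    background_reads: int = 0
    sample: str = "sim"

    def __post_init__(self) -> None:
        if self.read_mode not in {"single", "paired"}:
            raise ValueError(f"unknown read_mode {self.read_mode!r}")
        if self.priming not in {"random", "polydT"}:
            raise ValueError(f"unknown priming {self.priming!r}")
        if self.clone_length < 2 * self.end_length:
            raise ValueError("clone_length must be >= 2 x end_length")
        if not 0.0 <= self.fraction_spliced_tars <= 1.0:
            raise ValueError("fraction_spliced_tars must be in [0, 1]")
        if not 0.0 <= self.junction_span_rate <= 1.0:
            raise ValueError("junction_span_rate must be in [0, 1]")
        for name in ("chrom_len", "end_length", "clone_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedTar:
    tar_id: str
    region: Interval
    klass: str  # {intronic, intergenic}
    connected: bool
    host_gene: Optional[str]
    flank_exon: Optional[Interval] = None  # exon the TAR is spliced to, if connected


@dataclass
class SimTruth:
    """Generator ground truth: planted TARs and per-feature read assignment."""

    planted: list[PlantedTar] = field(default_factory=list)
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)
    read_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [
                {
                    "tar_id": t.tar_id,
                    "chrom": t.region.chrom,
                    "start": t.region.start,
                    "end": t.region.end,
                    "klass": t.klass,
                    "connected": t.connected,
                    "host_gene": t.host_gene,
                }
                for t in self.planted
            ],
            "read_counts": self.read_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rand_len(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def make_genome(cfg: SimConfig) -> tuple[GenomeAnnotation, SimTruth]:
    """Lay out genes and planted TARs on a toy genome.

    Genes are packed left to right with >2 kb spacing. Planted intronic TARs
    sit wholly inside introns, >= 2 kb from the host gene's first/last exon;
    intergenic TARs sit >= 2 kb from every gene span. Both therefore survive
    the vicinity filter by construction.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    chroms = {f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chroms)}
    chrom_names = list(chroms)

    genes: list[Gene] = []
    truth = SimTruth()
    cursors = {c: _rand_len(rng, _GENE_SPACING) for c in chrom_names}

    def _advance(chrom: str, length: int) -> int:
        start = cursors[chrom]
        end = start + length
        if end > cfg.chrom_len - _GENE_SPACING[1]:
            raise ValueError(
                "feature budget does not fit on the toy genome; "
                "increase chrom_len or reduce feature counts"
            )
        cursors[chrom] = end + _rand_len(rng, _GENE_SPACING)
        return start

    # multi-exon genes, round-robin over chromosomes
    multi_exon: list[Gene] = []
    for i in range(cfg.n_multi_exon_genes):
        chrom = chrom_names[i % len(chrom_names)]
        n_ex = _rand_len(rng, cfg.n_exons)
        ex_lens = [_rand_len(rng, cfg.exon_len) for _ in range(n_ex)]
        in_lens = [_rand_len(rng, cfg.intron_len) for _ in range(n_ex - 1)]
        total = sum(ex_lens) + sum(in_lens)
        start = _advance(chrom, total)
        exons, pos = [], start
        for j, el in enumerate(ex_lens):
            exons.append(Interval(chrom, pos, pos + el))
            pos += el
            if j < n_ex - 1:
                pos += in_lens[j]
        strand = "+" if rng.random() < 0.5 else "-"
        g = Gene(f"gene{i + 1}", strand, exons)
        genes.append(g)
        multi_exon.append(g)

    # single-exon genes (SEGs)
    for i in range(cfg.n_seg_genes):
        chrom = chrom_names[i % len(chrom_names)]
        length = _rand_len(rng, cfg.seg_len)
        start = _advance(chrom, length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"seg{i + 1}", strand, [Interval(chrom, start, start + length)]))

    # intergenic planted TARs occupy their own slots between genes
    for i in range(cfg.n_planted_intergenic_tars):
        chrom = chrom_names[i % len(chrom_names)]
        length = _rand_len(rng, cfg.tar_len)
        start = _advance(chrom, length)
        truth.planted.append(
            PlantedTar(
                tar_id=f"tar_inter{i + 1}",
                region=Interval(chrom, start, start + length),
                klass="intergenic",
                connected=False,
                host_gene=None,
            )
        )

    # intronic planted TARs inside qualifying introns of multi-exon genes
    candidates: list[tuple[Gene, Interval, Interval]] = []  # (gene, intron, left exon)
    for g in multi_exon:
        sp = g.span
        for k, intr in enumerate(g.introns):
            usable_lo = max(intr.start + _INTRON_PAD, sp.start + _VICINITY)
            usable_hi = min(intr.end - _INTRON_PAD, sp.end - _VICINITY)
            if usable_hi - usable_lo >= cfg.tar_len[1]:
                candidates.append(
                    (g, Interval(g.chrom, usable_lo, usable_hi), g.exons[k])
                )
    if len(candidates) < cfg.n_planted_intronic_tars:
        raise ValueError(
            "not enough qualifying introns for planted intronic TARs; "
            "increase chrom_len, intron_len or n_multi_exon_genes"
        )
    picks = rng.choice(len(candidates), size=cfg.n_planted_intronic_tars, replace=False)
    n_spliced = int(round(cfg.fraction_spliced_tars * cfg.n_planted_intronic_tars))
    for j, ci in enumerate(sorted(int(p) for p in picks)):
        g, usable, left_exon = candidates[ci]
        length = _rand_len(rng, cfg.tar_len)
        start = int(rng.integers(usable.start, usable.end - length + 1))
        connected = j < n_spliced
        truth.planted.append(
            PlantedTar(
                tar_id=f"tar_intron{j + 1}",
                region=Interval(g.chrom, start, start + length),
                klass="intronic",
                connected=connected,
                host_gene=g.gene_id,
                flank_exon=left_exon if connected else None,
            )
        )

    ann = GenomeAnnotation(chroms, genes)

    # transcript block lists (in genomic order; strand handled at read time)
    for g in genes:
        truth.transcripts[g.gene_id] = list(g.exons)
    for t in truth.planted:
        if t.connected and t.flank_exon is not None:
            truth.transcripts[t.tar_id] = [t.flank_exon, t.region]
        else:
            truth.transcripts[t.tar_id] = [t.region]
    return ann, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _map_to_blocks(
    blocks: list[Interval], t_start: int, t_end: int
) -> list[Interval]:
    """Map a transcript-coordinate interval onto genomic blocks."""
    out = []
    offset = 0
    for b in blocks:
        blen = len(b)
        lo = max(t_start, offset)
        hi = min(t_end, offset + blen)
        if lo < hi:
            out.append(Interval(b.chrom, b.start + (lo - offset), b.start + (hi - offset)))
        offset += blen
    if not out:
        raise ValueError("transcript interval maps to no blocks")
    return out


def _draw_starts(
    rng: np.random.Generator,
    n: int,
    t_len: int,
    frag_len: int,
    cfg: SimConfig,
    three_prime_right: bool,
) -> np.ndarray:
    """Draw fragment 5' starts in transcript coordinates."""
    max_start = max(0, t_len - frag_len)
    if cfg.priming == "random" or max_start == 0:
        return rng.integers(0, max_start + 1, size=n)
    d = rng.exponential(cfg.polydT_decay, size=n)
    if three_prime_right:
        starts = max_start - d
    else:
        starts = d
    return np.clip(np.rint(starts), 0, max_start).astype(int)


def simulate_reads(
    ann: GenomeAnnotation,
    truth: SimTruth,
    cfg: SimConfig,
) -> list[AlignedSegment]:
    """Emit mapped reads for every expressed feature.

    Per-feature depth is aligned-bp coverage: a transcript of length L at
    depth d receives round(d*L / bases-per-clone) clones. Junction-spanning
    ends need >= min_anchor bp on each side and succeed with probability
    junction_span_rate; a failed end drops its clone (the mapper would not
    have placed it). Final per-feature counts are recorded in truth.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    segs: list[AlignedSegment] = []
    ls, lc = cfg.end_length, cfg.clone_length
    paired = cfg.read_mode == "paired"

    strands = {g.gene_id: g.strand for g in ann.genes}

    for feat_id, blocks in truth.transcripts.items():
        t_len = sum(len(b) for b in blocks)
        depth = cfg.gene_depth if feat_id in strands else cfg.tar_depth
        if t_len <= 0 or depth <= 0:
            truth.read_counts[feat_id] = 0
            continue
        frag = lc if paired else ls
        if t_len < frag:
            logger.info("feature %s shorter than clone; clones truncated", feat_id)
            frag = t_len
        bases_per_clone = min(2 * ls, frag) if paired else min(ls, frag)
        n_clones = max(1, int(round(depth * t_len / bases_per_clone)))
        three_prime_right = strands.get(feat_id, "+") != "-"
        starts = _draw_starts(rng, n_clones, t_len, frag, cfg, three_prime_right)
        emitted = 0
        for i, s in enumerate(starts):
            s = int(s)
            if paired:
                e1 = (s, min(s + ls, s + frag))
                e2 = (max(s, s + frag - ls), s + frag)
                windows = [e1, e2]
            else:
                windows = [(s, s + frag)]
            read_blocks = []
            ok = True
            for lo, hi in windows:
                rb = _map_to_blocks(blocks, lo, hi)
                if len(rb) > 1:
                    if min(len(b) for b in rb) < cfg.min_anchor:
                        ok = False
                        break
                    if rng.random() > cfg.junction_span_rate:
                        ok = False
                        break
                read_blocks.append(rb)
            if not ok:
                continue
            if paired:
                r1 = f"{feat_id}:{i}/1"
                r2 = f"{feat_id}:{i}/2"
                segs.append(
                    AlignedSegment(r1, read_blocks[0], mate_of=r2, sample=cfg.sample)
                )
                segs.append(
                    AlignedSegment(r2, read_blocks[1], mate_of=r1, sample=cfg.sample)
                )
                emitted += 2
            else:
                segs.append(
                    AlignedSegment(
                        f"{feat_id}:{i}", read_blocks[0], sample=cfg.sample
                    )
                )
                emitted += 1
        truth.read_counts[feat_id] = emitted

    # optional uniform mapping-noise background (single-end)
    for i in range(cfg.background_reads):
        chrom = list(ann.chrom_sizes)[int(rng.integers(0, len(ann.chrom_sizes)))]
        start = int(rng.integers(0, ann.chrom_sizes[chrom] - ls))
        segs.append(
            AlignedSegment(
                f"bg:{i}", [Interval(chrom, start, start + ls)], sample=cfg.sample
            )
        )
    if cfg.background_reads:
        truth.read_counts["__background__"] = cfg.background_reads
    return segs


def write_simulation(
    out_dir: str | Path, ann: GenomeAnnotation, truth: SimTruth, segs: list[AlignedSegment]
) -> dict[str, str]:
    """Write annotation.bed12, chrom.sizes, reads.bed and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": str(out / "annotation.bed12"),
        "chrom_sizes": str(out / "chrom.sizes"),
        "reads": str(out / "reads.bed"),
        "truth": str(out / "truth.json"),
    }
    write_bed12(ann, paths["annotation"])
    write_chrom_sizes(ann.chrom_sizes, paths["chrom_sizes"])
    write_paired_bed(segs, paths["reads"])
    truth.to_json(paths["truth"])
    return paths
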