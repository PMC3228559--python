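"""Expression summaries: RPKM*, gene-level RPKM, genome binning, correlations.

RPKM* = C_bp * 1e12 / (N_bp * L): detected base pairs C_bp in the target
region, normalized by total mapped base pairs N_bp (the mappable data size)
and the region length L — chromosome length for chromosome profiles, summed
exon length for gene-level values. Using base pairs instead of read counts
makes datasets with different read lengths comparable.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import (
    AlignedSegment,
    Gene,
    GenomeAnnotation,
    Interval,
    classify_segment,
    merge_intervals,
)

__all__ = [
    "rpkm_star",
    "total_aligned_bp",
    "gene_rpkm",
    "bin_profile",
    "exon_density_correlation",
    "chromosome_profile",
]

SCALE = 1e12


def rpkm_star(c_bp: float, n_bp: float, length: float) -> float:
    """Detected-bp expression measure: C_bp * 1e12 / (N_bp * L)."""
    if n_bp <= 0:
        raise ValueError("N_bp must be positive")
    if length <= 0:
        raise ValueError("region length must be positive")
    if c_bp < 0:
        raise ValueError("C_bp must be nonnegative")
    return c_bp * SCALE / (n_bp * length)


def total_aligned_bp(segs: Iterable[AlignedSegment]) -> int:
    """Mappable data size N_bp: total aligned base pairs across the dataset."""
    return sum(s.aligned_bp for s in segs)


def gene_rpkm(
    gene: Gene, segs: Iterable[AlignedSegment], n_bp: float
) -> tuple[float, float]:
    """Gene expression as RPKM* over exons, plus log2(value + 1).

    C_bp counts only the base pairs of read blocks intersecting the gene's
    exons; L is the summed exon length.
    """
    c_bp = 0
    for s in segs:
        if s.chrom != gene.chrom:
            continue
        for b in s.blocks:
            for e in gene.exons:
                c_bp += b.overlap_bp(e)
    value = rpkm_star(c_bp, n_bp, gene.exon_length)
    return value, math.log2(value + 1.0)


def bin_profile(
    segs: Iterable[AlignedSegment],
    ann: GenomeAnnotation,
    bin_size: int,
) -> pd.DataFrame:
    """Fixed-width genome bins with read categories and exon content.

    Each read goes to exactly one bin, chosen by the midpoint of its aligned
    span; its category (exonic > intronic > intergenic) comes from its
    blocks. exon_fraction is the fraction of bin base pairs covered by
    merged annotated exons.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts: dict[tuple[str, int], dict[str, int]] = defaultdict(
        lambda: {"exonic": 0, "intronic": 0, "intergenic": 0}
    )
    for s in segs:
        sp = s.span
        mid = (sp.start + sp.end) // 2
        counts[(s.chrom, mid // bin_size)][classify_segment(s, ann)] += 1

    exon_by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for e in ann.merged_exons():
        exon_by_chrom[e.chrom].append(e)

    rows = []
    for chrom, length in sorted(ann.chrom_sizes.items()):
        n_bins = (length + bin_size - 1) // bin_size
        exon_bp = np.zeros(n_bins)
        for e in exon_by_chrom.get(chrom, []):
            for b in range(e.start // bin_size, (e.end - 1) // bin_size + 1):
                lo, hi = b * bin_size, min((b + 1) * bin_size, length)
                exon_bp[b] += max(0, min(e.end, hi) - max(e.start, lo))
        for b in range(n_bins):
            lo, hi = b * bin_size, min((b + 1) * bin_size, length)
            c = counts.get((chrom, b), {"exonic": 0, "intronic": 0, "intergenic": 0})
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": lo,
                    "bin_end": hi,
                    "exonic_reads": c["exonic"],
                    "intronic_reads": c["intronic"],
                    "intergenic_reads": c["intergenic"],
                    "exon_fraction": exon_bp[b] / (hi - lo),
                }
            )
    return pd.DataFrame(rows)


def exon_density_correlation(profile: pd.DataFrame) -> dict[str, Optional[float]]:
    """Pearson r of each read category vs exon content, plus pairwise r.

    Zero-variance inputs yield None (undefined correlation).
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 bins")

    def _r(x: np.ndarray, y: np.ndarray) -> Optional[float]:
        if np.std(x) == 0 or np.std(y) == 0:
            return None
        return float(np.corrcoef(x, y)[0, 1])

    cats = ["exonic_reads", "intronic_reads", "intergenic_reads"]
    ef = profile["exon_fraction"].to_numpy(float)
    out: dict[str, Optional[float]] = {}
    for c in cats:
        out[f"{c}_vs_exon_fraction"] = _r(profile[c].to_numpy(float), ef)
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            out[f"{a}_vs_{b}"] = _r(
                profile[a].to_numpy(float), profile[b].to_numpy(float)
            )
    return out


def _is_placed(chrom: str) -> bool:
    return "_" not in chrom and not chrom.lower().startswith("chrun")


def chromosome_profile(
    segs: Iterable[AlignedSegment],
    ann: GenomeAnnotation,
    n_bp: Optional[float] = None,
    mito: str = "chrM",
) -> dict:
    """Per-chromosome RPKM* vector, its spread, and mitochondrial fraction.

    Returns a dict with a per-chromosome Series of RPKM* (L = chromosome
    length), the population SD across placed non-mitochondrial chromosomes,
    and the mitochondrial RPKM* (None when the chromosome is absent).
    """
    segs = list(segs)
    if n_bp is None:
        n_bp = total_aligned_bp(segs)
    c_bp: dict[str, int] = {c: 0 for c in ann.chrom_sizes}
    for s in segs:
        if s.chrom in c_bp:
            c_bp[s.chrom] += s.aligned_bp
    values = pd.Series(
        {c: rpkm_star(c_bp[c], n_bp, L) for c, L in sorted(ann.chrom_sizes.items())}
    )
    core = [c for c in values.index if c != mito and _is_placed(c)]
    sd = float(np.std(values[core].to_numpy(), ddof=0)) if core else float("nan")
    return {
        "rpkm_star": values,
        "sd": sd,
        "mito": float(values[mito]) if mito in values.index else None,
        "sd_excludes": [c for c in values.index if c not in core],
    }
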