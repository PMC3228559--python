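"""Concordance of intronic vs exonic expression change across two stages.

Given per-gene exonic and intronic read counts at two developmental stages,
builds the 2x2 table of change directions (Fisher exact association), and
summarizes intron/exon read ratios: the per-stage statistic is the
unweighted mean of per-gene intronic/exonic ratios, while the cross-stage
statistic is a ratio of summed counts — two deliberately different
conventions, kept as such (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ConcordanceTable", "change_table", "ratio_summary", "chisq_yates"]

REQUIRED_COLS = {"gene_id", "stage", "exonic_reads", "intronic_reads"}


@dataclass
class ConcordanceTable:
    """2x2 direction-of-change table: rows exonic up/down, cols intronic up/down."""

    up_up: int  # exonic up, intronic up
    up_down: int  # exonic up, intronic down
    down_up: int  # exonic down, intronic up
    down_down: int  # exonic down, intronic down
    fisher_p: float

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.up_up, self.up_down, self.down_up, self.down_down)

    @property
    def frac_down_given_intronic_down(self) -> float:
        """Fraction of intronic-down genes that are also exonic-down (NaN if none)."""
        denom = self.up_down + self.down_down
        return self.down_down / denom if denom else float("nan")

    @property
    def frac_up_given_intronic_up(self) -> float:
        """Fraction of intronic-up genes that are also exonic-up (NaN if none)."""
        denom = self.up_up + self.down_up
        return self.up_up / denom if denom else float("nan")


def _check_df(df: pd.DataFrame) -> None:
    missing = REQUIRED_COLS - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")


def fisher_from_counts(up_up: int, up_down: int, down_up: int, down_down: int) -> ConcordanceTable:
    """Build a ConcordanceTable (with two-sided Fisher exact p) from raw cells."""
    if min(up_up, up_down, down_up, down_down) < 0:
        raise ValueError("cell counts must be nonnegative")
    if up_up + up_down + down_up + down_down == 0:
        raise ValueError("empty table")
    _, p = stats.fisher_exact(
        [[up_up, up_down], [down_up, down_down]], alternative="two-sided"
    )
    return ConcordanceTable(up_up, up_down, down_up, down_down, float(p))


def change_table(
    df: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    stage_sizes: Optional[dict[str, float]] = None,
) -> ConcordanceTable:
    """Direction-of-change 2x2 table from stage A to stage B.

    Counts are data-size-normalized (RPKM-style direction calls) when
    stage_sizes gives total mapped bp per stage; gene-length normalization
    cancels in a within-gene comparison. Genes tied in either dimension are
    excluded.
    """
    _check_df(df)
    wide = df.pivot_table(
        index="gene_id",
        columns="stage",
        values=["exonic_reads", "intronic_reads"],
        aggfunc="sum",
    )
    for st in (stage_a, stage_b):
        if ("exonic_reads", st) not in wide.columns:
            raise ValueError(f"stage {st!r} absent from input")
    norm = {stage_a: 1.0, stage_b: 1.0}
    if stage_sizes:
        norm = {st: 1.0 / stage_sizes[st] for st in (stage_a, stage_b)}
    cells = {"up_up": 0, "up_down": 0, "down_up": 0, "down_down": 0}
    n_ties = 0
    for _, row in wide.iterrows():
        d_ex = row[("exonic_reads", stage_b)] * norm[stage_b] - row[
            ("exonic_reads", stage_a)
        ] * norm[stage_a]
        d_in = row[("intronic_reads", stage_b)] * norm[stage_b] - row[
            ("intronic_reads", stage_a)
        ] * norm[stage_a]
        if d_ex == 0 or d_in == 0 or np.isnan(d_ex) or np.isnan(d_in):
            n_ties += 1
            continue
        key = ("up_" if d_ex > 0 else "down_") + ("up" if d_in > 0 else "down")
        cells[key] += 1
    if n_ties:
        logger.info("excluded %d genes with tied or missing direction", n_ties)
    return fisher_from_counts(**cells)


def ratio_summary(df: pd.DataFrame, stage_a: str, stage_b: str) -> dict[str, float]:
    """Intron/exon read-ratio summaries over a gene set.

    Per-stage: unweighted mean over genes of intronic/exonic (genes with
    zero exonic reads are excluded from the mean, logged). Cross-stage:
    ratio of summed counts stage_a/stage_b, separately for intronic and
    exonic reads.
    """
    _check_df(df)
    out: dict[str, float] = {}
    sums: dict[tuple[str, str], float] = {}
    for st in (stage_a, stage_b):
        sub = df[df["stage"] == st]
        if sub.empty:
            raise ValueError(f"stage {st!r} absent from input")
        ex = sub["exonic_reads"].to_numpy(float)
        intr = sub["intronic_reads"].to_numpy(float)
        usable = ex > 0
        if (~usable).any():
            logger.info(
                "stage %s: %d genes with zero exonic reads excluded from mean ratio",
                st,
                int((~usable).sum()),
            )
        if not usable.any():
            raise ValueError(f"no gene with exonic reads at stage {st!r}")
        out[f"mean_ratio_{st}"] = float(np.mean(intr[usable] / ex[usable]))
        sums[("exonic", st)] = float(ex.sum())
        sums[("intronic", st)] = float(intr.sum())
    for dim in ("intronic", "exonic"):
        denom = sums[(dim, stage_b)]
        out[f"{dim}_ratio_{stage_a}_over_{stage_b}"] = (
            sums[(dim, stage_a)] / denom if denom > 0 else float("nan")
        )
    return out


def chisq_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2x2 table: (statistic, p).

    statistic = sum over cells of (max(0, |O-E|-0.5))^2 / E with 1 df.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    exp = np.outer(row, col) / n
    stat = float(np.sum(np.maximum(np.abs(obs - exp) - 0.5, 0.0) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, df=1))
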