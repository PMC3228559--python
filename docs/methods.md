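# Methods

This note records the statistical model, the parameter defaults and their
rationale, what the simulator does and does not emulate, and the numerical
conventions the package commits to.

## Expression quantification (RPKM\*)

Expression is measured in detected base pairs, not read counts:

```
RPKM* = C_bp × 10¹² / (N_bp × L)
```

where `C_bp` is the number of aligned base pairs overlapping the target
region (clipping each alignment block to the region), `N_bp` the total
aligned base pairs of the dataset ("mappable data size"), and `L` the
region length in bp. With 10¹² scaling this is numerically the classical
RPKM when reads are counted in base pairs. Per-gene scores are reported
both raw and as `log2(RPKM + 1)`. Per-chromosome profiles use the
chromosome length as `L`; the across-chromosome standard deviation is the
population SD and excludes the mitochondrial chromosome and unplaced
scaffolds (names containing `_` or starting with `chrUn`), which would
otherwise dominate it.

Bin profiles assign each read to the bin containing its midpoint, so every
read is counted exactly once (conservation is asserted in the tests).
Exon-density correlations are Pearson r between per-bin read counts and
per-bin annotated-exon density; bins are 1 Mb by default.

## TAR calling

Coverage segments are maximal intervals with per-base depth ≥ 1, computed
by an event sweep that aggregates all depth changes at a position before
comparing against the threshold (naive ±1 sweeps split segments at
coincident read boundaries). Segments separated by ≤ 50 bp are chained.
Candidates then pass an ordered cascade, each drop logged with its reason:

| filter | default | rationale |
|---|---|---|
| length | > 100 bp | exclude fragments and spurious pileups |
| mean coverage | > 5X | exclude low-level noise |
| annotation | no exon/tRNA/rRNA overlap | "unannotated" by definition |
| repeats | no overlap | mapping artifacts concentrate in repeats |
| vicinity | > 2 kb from every gene-span endpoint | exclude TSS/TTS-associated transcription |
| uniqueness | hook (optional) | stands where a genome-wide uniqueness screen (e.g. BLAST-back) would run |

Distances are measured between base-pair positions inclusively. Survivors
inside a gene span are *intronic* (the host gene is recorded); others are
*intergenic*.

## Paired-end connectivity model

For a TAR of length `L_r` with `N_i` clone ends falling fully inside it,
the expected number of clones with exactly one end inside (end-linking
clones) is

```
N_e = N_i·L_c/(2·L_r) − T·N_i·(L_s − M)/L_r
```

with end length `L_s = 35`, clone length `L_c = 300`, minimum splice-
junction anchor `M = 2`, and partial-read mapping success rate `T = 0.99`.
The first term is the geometric edge effect (a uniformly placed clone
straddles a boundary with probability ∝ L_c/2 per side); the second
subtracts ends that straddle by less than the mappable anchor. Numerical
conventions:

- The raw expression is floored at 0 (it can only go negative for
  degenerate geometries that cannot arise from validated parameters).
- If linking evidence exists both upstream and downstream, `N_e` is
  doubled (both flanks contribute edges).
- If `L_r < L_c` no clone can be internal; the expectation is then the
  clone total and the decision uses all clones touching the region.
- The formula is an `O(L_c/L_r)` approximation of the true expectation;
  empirically (property test) observed links fall in the 95% Poisson band
  around `N_e` for `L_r ≫ L_c`.

A TAR with observed links < 20% of `N_e` is **standalone**. Otherwise the
majority destination decides, requiring at least half the links and ≥ 2
links: annotated exon → `connected_known_exon`; same chromosome
unannotated → `non_standalone_same_chrom`; other chromosome →
`multi_chromosome`. Junction-spanning (split) read ends whose second block
lands in an exon count as exon links.

### Control validation

- **Positive control**: for each expressed multi-exon gene (≥ 3 exons) the
  middle internal exon is masked from the annotation and classified;
  success = verdict `connected_known_exon`. Internal exons are shorter
  than `L_c`, so this exercises the `L_r < L_c` branch plus abundant
  linking into the flanking exons.
- **Negative control**: each expressed single-exon gene (SEG) is masked
  whole-gene and classified; success = any verdict other than
  `connected_known_exon` (a multi-chromosome call still counts as "not
  connected to this gene's neighbors").

## Simulator

The generator emits already-mapped alignments — mapping is out of scope;
analyses start from aligner output. It emulates:

- gene structures (4–7 exons of 150–250 bp, introns 2.5–4 kb), SEGs
  (600–1500 bp), planted intronic/intergenic TARs, laid out so every
  feature respects the 2-kb vicinity clearance the TAR filter assumes;
- paired 35-bp ends on 300-bp clones at a configurable depth (default
  20X), with clone starts uniform in transcript coordinates (random
  priming) or exponentially 3'-biased with a 500-bp scale (poly-dT
  priming; the source study says only "skewed", the exponential form and
  scale are package choices);
- junction-spanning ends emitted as split alignments, dropped when the
  anchor is < 5 bp or with probability 1 − T (T = 0.99), which is the
  behaviour the model's `T` factor corrects for;
- optional uniform background reads as a stand-in for mapping noise.

It does **not** emulate sequencing errors, multi-mapping, indels,
alternative splicing, or strand-specific protocols.

**Planted TAR lengths default to 500–1500 bp.** Paired 35-bp ends on a
300-bp clone leave a 230-bp unsequenced interior, so a transcript of
length L has an interior coverage gap of up to `530 − L` bp; below ~480 bp
the gap exceeds the 50-bp chaining distance and a single transcript is
called as two TARs (or lost to the length filter). The default keeps
planted truth unambiguous at the default chaining gap; shorter TARs can be
requested explicitly.

## Concordance

The 2×2 direction-of-change table counts genes by the sign of their exonic
and intronic read change between two stages; ties are excluded (and
logged). Direction calls can be data-size-normalized via per-stage total
mapped bp; gene-length normalization cancels within a gene. Association is
the **two-sided** Fisher exact test. Two deliberately different ratio
conventions coexist, matching how such tables are conventionally reported:
the per-stage statistic is the unweighted mean of per-gene
intronic/exonic ratios (genes with zero exonic reads excluded from the
mean), while the cross-stage statistic is the ratio of summed counts
(which does include those genes). A Yates-corrected chi-square is provided
as an alternative to Fisher for larger tables.

## GO enrichment

Each gene's annotation set is first reduced to its most specific terms
(removing any term that is an ancestor of another term of the same gene,
following `is_a` and `part_of` edges by default), so generic parents are
not credited for every specifically-annotated child. Per-term counts feed
a one-sided (over-representation) Fisher test; Bonferroni correction
multiplies by the number of terms with at least one foreground hit. Terms
are reported when foreground hits > 5 (strict) and corrected p < 0.05.

## Problem sizes and runtime

The validation and acceptance runs use a 4 × 3-Mb genome with 100
multi-exon genes and 50 SEGs at 20X depth (~90k read ends) — small enough
to run from scratch in under 10 s on one CPU while giving ≥ 100 positive
and ≥ 50 negative control observations. The full test suite runs in well
under a minute.

## Limitations

- The connectivity expectation assumes uniform clone placement; 3'-biased
  libraries violate it and shift `N_i`/`N_e` jointly, which the ratio
  decision partly absorbs but is not modeled explicitly.
- TAR classification is unstranded.
- The uniqueness screen is a hook, not an implementation; with no hook
  supplied, repeat overlap is the only mappability filter.
- Real-data figures that depend on specific sequencing runs (absolute TAR
  counts, bin correlations, dataset fractions) are outside what the
  simulator can or should reproduce; only model-level behaviours are
  validated.
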