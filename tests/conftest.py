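import pytest

from tarlink.genome import Gene, GenomeAnnotation, Interval
from tarlink.simulate import SimConfig, make_genome, simulate_reads


@pytest.fixture(scope="session")
def toy_annotation():
    """Hand-built two-chromosome annotation with known structure."""
    genes = [
        Gene(
            "gA",
            "+",
            [
                Interval("chr1", 10_000, 10_200),
                Interval("chr1", 13_000, 13_200),
                Interval("chr1", 16_000, 16_200),
            ],
        ),
        Gene("gB", "-", [Interval("chr1", 40_000, 41_000)]),
        Gene("gC", "+", [Interval("chr2", 5_000, 5_300), Interval("chr2", 9_000, 9_400)]),
    ]
    trna = [Interval("chr1", 70_000, 70_100)]
    repeats = [Interval("chr1", 80_000, 81_000)]
    return GenomeAnnotation(
        {"chr1": 100_000, "chr2": 50_000, "chrM": 16_000},
        genes,
        trna_rrna=trna,
        repeats=repeats,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Moderate simulated dataset at 10x depth with planted TARs."""
    cfg = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_len=2_500_000,
        n_multi_exon_genes=30,
        n_seg_genes=10,
        n_planted_intronic_tars=10,
        n_planted_intergenic_tars=5,
        gene_depth=10,
        tar_depth=10,
    )
    ann, truth = make_genome(cfg)
    segs = simulate_reads(ann, truth, cfg)
    return cfg, ann, truth, segs
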