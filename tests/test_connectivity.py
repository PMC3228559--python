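"""Paired-end connectivity model: formula values, link evidence, verdicts."""

import numpy as np
import pytest

from tarlink.genome import (
    AlignedSegment,
    Gene,
    GenomeAnnotation,
    Interval,
    ReadPair,
)
from tarlink.connectivity import (
    CONNECTED,
    MULTI_CHROM,
    SAME_CHROM,
    STANDALONE,
    ConnectivityCall,
    ConnectivityParams,
    classify_connection,
    collect_link_evidence,
    expected_end_links,
    validate_controls,
)


class TestExpectedEndLinks:
    def test_hand_evaluated_value(self):
        p = ConnectivityParams(L_s=35, L_c=300, M=2, T=0.99)
        # 100*300/2000 - 0.99*100*33/1000 = 15 - 3.267
        assert expected_end_links(100, 1000, p) == pytest.approx(11.733)

    def test_limiting_case_t_zero(self):
        p = ConnectivityParams(L_s=35, L_c=300, M=0, T=0.0)
        assert expected_end_links(100, 1000, p) == pytest.approx(100 * 300 / 2000)

    def test_negative_raw_floored_to_zero(self):
        # a raw negative expectation (degenerate geometry) is meaningless
        p = ConnectivityParams(L_s=100, L_c=200, M=0, T=1.0)
        p.L_c = 50  # clone shorter than its two ends cannot arise from data
        assert expected_end_links(50, 5000, p) == 0.0

    def test_doubling_on_both_flanks(self):
        p = ConnectivityParams()
        one = expected_end_links(100, 1000, p, both_flanks=False)
        assert expected_end_links(100, 1000, p, both_flanks=True) == pytest.approx(2 * one)
        p_off = ConnectivityParams(double_ne_if_both_flanks=False)
        assert expected_end_links(100, 1000, p_off, both_flanks=True) == pytest.approx(one)

    def test_invalid_region_length(self):
        with pytest.raises(ValueError):
            expected_end_links(10, 0, ConnectivityParams())


def _pair(i, b1, b2):
    e1 = AlignedSegment(f"p{i}/1", b1, mate_of=f"p{i}/2")
    e2 = AlignedSegment(f"p{i}/2", b2, mate_of=f"p{i}/1")
    return ReadPair(e1, e2)


@pytest.fixture()
def link_ann():
    gene = Gene("g", "+", [Interval("chr1", 50_000, 50_500)])
    return GenomeAnnotation({"chr1": 200_000, "chr2": 200_000}, [gene])


class TestCollectLinkEvidence:
    REGION = Interval("chr1", 10_000, 11_000)

    def test_internal_pair_counts_twice(self, link_ann):
        pairs = [_pair(0, [Interval("chr1", 10_100, 10_135)], [Interval("chr1", 10_400, 10_435)])]
        call = collect_link_evidence("t", self.REGION, pairs, link_ann, ConnectivityParams())
        assert call.N_i == 2
        assert call.total_links == 0

    def test_link_to_annotated_exon(self, link_ann):
        pairs = [_pair(0, [Interval("chr1", 10_100, 10_135)], [Interval("chr1", 50_100, 50_135)])]
        call = collect_link_evidence("t", self.REGION, pairs, link_ann, ConnectivityParams())
        assert call.links["annotated_exon"] == 1

    def test_link_to_other_chromosome(self, link_ann):
        pairs = [_pair(0, [Interval("chr1", 10_100, 10_135)], [Interval("chr2", 60_000, 60_035)])]
        call = collect_link_evidence("t", self.REGION, pairs, link_ann, ConnectivityParams())
        assert call.links["other_chromosome"] == 1

    def test_link_to_unannotated_same_chrom(self, link_ann):
        pairs = [_pair(0, [Interval("chr1", 10_100, 10_135)], [Interval("chr1", 150_000, 150_035)])]
        call = collect_link_evidence("t", self.REGION, pairs, link_ann, ConnectivityParams())
        assert call.links["unannotated_same_chrom"] == 1

    def test_split_read_into_exon_counts_as_exon_link(self, link_ann):
        # junction-spanning end: one block in the TAR, one in the exon
        pairs = [
            _pair(
                0,
                [Interval("chr1", 10_900, 10_920), Interval("chr1", 50_000, 50_015)],
                [Interval("chr1", 10_100, 10_135)],
            )
        ]
        call = collect_link_evidence("t", self.REGION, pairs, link_ann, ConnectivityParams())
        assert call.links["annotated_exon"] == 1

    def test_both_flank_detection(self, link_ann):
        pairs = [
            _pair(0, [Interval("chr1", 10_100, 10_135)], [Interval("chr1", 9_000, 9_035)]),
            _pair(1, [Interval("chr1", 10_800, 10_835)], [Interval("chr1", 12_000, 12_035)]),
        ]
        call = collect_link_evidence("t", self.REGION, pairs, link_ann, ConnectivityParams())
        assert call.both_flanks


class TestClassifyConnection:
    def _call(self, n_i=100, l_r=1000, exon=0, same=0, other=0, p=None):
        p = p or ConnectivityParams()
        call = ConnectivityCall("t", L_r=l_r, N_i=n_i)
        call.links = {
            "annotated_exon": exon,
            "unannotated_same_chrom": same,
            "other_chromosome": other,
        }
        call.N_e = expected_end_links(n_i, l_r, p)
        return call

    def test_twenty_percent_rule(self):
        p = ConnectivityParams()
        # N_e = 11.733; 1 observed < 0.2*11.733 -> standalone
        assert classify_connection(self._call(same=1), p) == STANDALONE
        assert classify_connection(self._call(same=3), p) == SAME_CHROM

    def test_connected_and_multi_chromosome_paths(self):
        p = ConnectivityParams()
        assert classify_connection(self._call(exon=8, same=1), p) == CONNECTED
        assert classify_connection(self._call(other=8, same=1), p) == MULTI_CHROM

    def test_vacuous_case_is_standalone(self):
        p = ConnectivityParams()
        assert classify_connection(self._call(n_i=0), p) == STANDALONE

    def test_short_region_uses_clone_total(self):
        p = ConnectivityParams()
        # L_r < L_c: all clones should link; zero links -> standalone
        call = ConnectivityCall("t", L_r=200, N_i=10)
        assert classify_connection(call, p) == STANDALONE
        call2 = ConnectivityCall("t", L_r=200, N_i=0)
        call2.links["annotated_exon"] = 5
        assert classify_connection(call2, p) == CONNECTED

    def test_pure_function_and_monotone(self):
        p = ConnectivityParams()
        c1 = self._call(exon=8, same=1)
        assert classify_connection(c1, p) == classify_connection(c1, p)
        # removing links can only move toward standalone
        for k in range(9):
            c = self._call(exon=k, same=0)
            v = classify_connection(c, p)
            if v == STANDALONE:
                for j in range(k):
                    assert classify_connection(self._call(exon=j, same=0), p) == STANDALONE


class TestFormulaAsExpectation:
    def test_empirical_links_match_ne_for_long_regions(self):
        """Uniform clones on a transcript containing the region: observed
        end-linking pairs should fall in a ~95% Poisson band around N_e."""
        l_r, flank, l_c, l_s = 5_000, 5_000, 300, 35
        region = Interval("chr1", 10_000, 10_000 + l_r)
        ann = GenomeAnnotation(
            {"chr1": 100_000},
            [Gene("g", "+", [Interval("chr1", 10_000 + l_r, 10_000 + l_r + flank)])],
        )
        p = ConnectivityParams()
        rng = np.random.default_rng(42)
        t_len = l_r + flank
        lam = 0.1
        covered = 0
        ratios = []
        for _ in range(200):
            n = rng.poisson(lam * (t_len - l_c + 1))
            starts = rng.integers(0, t_len - l_c + 1, size=n) + 10_000
            pairs = [
                _pair(
                    i,
                    [Interval("chr1", int(s), int(s) + l_s)],
                    [Interval("chr1", int(s) + l_c - l_s, int(s) + l_c)],
                )
                for i, s in enumerate(starts)
            ]
            call = collect_link_evidence("t", region, pairs, ann, p)
            obs, ne = call.total_links, call.N_e
            ratios.append(obs / ne)
            covered += abs(obs - ne) <= 1.96 * np.sqrt(ne)
        assert covered / 200 >= 0.85
        assert abs(np.mean(ratios) - 1.0) < 0.15


class TestValidateControls:
    def test_refuses_without_pairs(self, link_ann):
        with pytest.raises(ValueError):
            validate_controls(link_ann, [], ConnectivityParams())

    def test_control_recovery_on_simulation(self):
        from tarlink.genome import pair_reads
        from tarlink.simulate import SimConfig, make_genome, simulate_reads

        cfg = SimConfig(
            seed=8,
            n_chroms=2,
            chrom_len=2_500_000,
            n_multi_exon_genes=25,
            n_seg_genes=12,
            n_planted_intronic_tars=0,
            n_planted_intergenic_tars=0,
            gene_depth=20,
        )
        ann, truth = make_genome(cfg)
        pairs, _ = pair_reads(simulate_reads(ann, truth, cfg))
        res = validate_controls(ann, pairs, ConnectivityParams())
        assert res["n_positive"] >= 20 and res["n_negative"] >= 10
        assert res["positive_success"] >= 0.93
        assert res["negative_success"] == 1.0
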