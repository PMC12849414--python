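import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierscreen.stats import (
    bh_fdr,
    binomial_exact_test,
    compare_cohorts,
    fisher_exact,
    format_percent,
    gene_pair_edges,
    multi_gene_proportion,
    pair_cooccurrence_tests,
    pair_expected_probability,
    pair_test_grid,
    proportion_ci,
    round_half_away,
)
from carrierscreen.types import CarrierProfile, ValidationError
from oracles import bh_stepup_oracle, binomial_upper_tail_oracle, fisher_two_sided_oracle


def profile(sid, genes, group=3):
    return CarrierProfile(
        sample_id=sid,
        qualifying_variants=[(f"v_{g}", g, 1) for g in genes],
        gene_load={g: 1 for g in genes},
        moi_consistent_genes=set(genes),
        group=group if genes else 1,
    )


class TestProportionCI:
    def test_published_percent_renderings(self):
        assert format_percent(15, 1714, 2) == 0.88
        assert format_percent(45, 1714, 1) == 2.6

    def test_degenerate_at_zero(self):
        est = proportion_ci(0, 100)
        assert est.p == est.ci_low == est.ci_high == 0.0

    def test_half_width_at_p_half(self):
        est = proportion_ci(50, 100)
        assert est.ci_low == pytest.approx(0.402)
        assert est.ci_high == pytest.approx(0.598)

    def test_bounds_clamped(self):
        est = proportion_ci(1, 10)
        assert est.ci_low == 0.0  # 0.1 - 1.96*0.0949 < 0 clamps
        assert 0.0 <= est.ci_high <= 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            proportion_ci(0, 0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.5) == 3.0
        assert round_half_away(-2.5) == -3.0
        assert round_half_away(0.125, 2) == 0.13


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact(1, 2, 1, 2) == 1.0

    def test_two_vs_eight_of_ten(self):
        # full hypergeometric enumeration gives 4252/184756
        assert fisher_exact(2, 10, 8, 10) == pytest.approx(4252 / 184756, rel=1e-12)

    def test_disjoint_five_of_five(self):
        assert fisher_exact(0, 5, 5, 5) == pytest.approx(2 / 252, rel=1e-12)

    def test_matches_enumeration_oracle_small_tables(self):
        for n1, n2 in [(3, 4), (5, 5), (6, 2)]:
            for k1, k2 in itertools.product(range(n1 + 1), range(n2 + 1)):
                expected = float(fisher_two_sided_oracle(k1, n1, k2, n2))
                assert fisher_exact(k1, n1, k2, n2) == pytest.approx(expected, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact(5, 3, 0, 3)
        with pytest.raises(ValidationError):
            fisher_exact(0, 0, 1, 2)


class TestBinomialExact:
    def test_zero_observed_full_tail(self):
        assert binomial_exact_test(0, 100, 0.01) == 1.0

    def test_pair_scale_example(self):
        # two double-carriers among 435 at chance rate 1.25e-4
        assert binomial_exact_test(2, 435, 1.25e-4) == pytest.approx(1.4228e-3, rel=1e-4)

    def test_certain_success_null(self):
        assert binomial_exact_test(5, 10, 1.0) == 1.0

    @pytest.mark.parametrize("k,n,p0", [(1, 10, 0.1), (3, 50, 0.02), (7, 1000, 0.005), (2, 435, 1.25e-4)])
    def test_matches_direct_summation(self, k, n, p0):
        assert binomial_exact_test(k, n, p0) == pytest.approx(
            binomial_upper_tail_oracle(k, n, p0), rel=1e-10
        )

    def test_complement_identity(self):
        # upper(k) = 1 - lower(k-1)
        from scipy.stats import binom

        k, n, p0 = 4, 60, 0.03
        assert binomial_exact_test(k, n, p0) == pytest.approx(1 - binom.cdf(k - 1, n, p0), rel=1e-12)

    def test_two_sided_at_least_upper_tail(self):
        one = binomial_exact_test(8, 100, 0.02)
        two = binomial_exact_test(8, 100, 0.02, alternative="two-sided")
        assert two >= one


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.04]) == [0.04]

    def test_hand_stepup_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_ties(self):
        assert bh_fdr([0.05, 0.05]) == pytest.approx([0.05, 0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_stepup_oracle_and_dominates_raw(self, ps):
        adjusted = bh_fdr(ps)
        assert adjusted == pytest.approx(bh_stepup_oracle(ps), abs=1e-12)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, ps))
        order = np.argsort(ps, kind="stable")
        assert all(np.diff(np.asarray(adjusted)[order]) >= -1e-12)


class TestPairExpected:
    def test_absorbing_zero(self):
        assert pair_expected_probability(0.0, 0.7) == 0.0

    def test_study_scale_product(self):
        assert pair_expected_probability(4 / 438, 6 / 438) == pytest.approx(1.251e-4, rel=1e-3)

    def test_certainty(self):
        assert pair_expected_probability(1.0, 1.0) == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_never_exceeds_either_marginal(self, a, b):
        assert pair_expected_probability(a, b) <= min(a, b) + 1e-15


class TestMultiGene:
    def test_many_variants_one_gene_not_multigene(self):
        p = profile("S1", ["G1"])
        p.qualifying_variants = [("v1", "G1", 1), ("v2", "G1", 1), ("v3", "G1", 2)]
        est = multi_gene_proportion([p])
        assert est.k == 0

    def test_quarter_multigene(self):
        profiles = [
            profile("S1", ["G1", "G2"]),
            profile("S2", ["G1"]),
            profile("S3", ["G3"]),
            profile("S4", ["G2"]),
        ]
        est = multi_gene_proportion(profiles)
        assert est.k == 1 and est.n == 4 and est.p == 0.25

    def test_non_group3_rejected(self):
        with pytest.raises(ValidationError):
            multi_gene_proportion([profile("S1", ["G1"], group=2)])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            multi_gene_proportion([])


class TestGenePairEdges:
    def test_four_gene_carrier_contributes_six_edges(self):
        edges = gene_pair_edges([profile("S1", ["SLC35D3", "PTEN", "DYRK1B", "MCHR1"])])
        assert sum(edges.values()) == 6
        assert edges[("MCHR1", "PTEN")] == 1  # lexicographic canonical order

    def test_edge_multiplicity_counts_carriers(self):
        profiles = [profile("S1", ["PTEN", "MCHR1"]), profile("S2", ["PTEN", "MCHR1", "GHSR"])]
        edges = gene_pair_edges(profiles)
        assert edges[("MCHR1", "PTEN")] == 2
        assert sum(edges.values()) == 1 + 3

    def test_single_gene_profile_no_edges(self):
        assert gene_pair_edges([profile("S1", ["G1"])]) == {}


class TestPairCooccurrence:
    def test_expected_is_product_of_empirical_marginals(self):
        profiles = [profile(f"S{i}", ["A"]) for i in range(4)]
        profiles += [profile(f"T{i}", ["B"]) for i in range(2)]
        profiles += [profile(f"U{i}", ["A", "B"]) for i in range(2)]
        profiles += [profile(f"V{i}", ["C"]) for i in range(2)]
        results = {(r.gene_a, r.gene_b): r for r in pair_cooccurrence_tests(profiles)}
        r = results[("A", "B")]
        assert r.n == 10
        assert r.k_obs == 2
        assert r.p_expected == pytest.approx((6 / 10) * (4 / 10))
        assert r.p_value == pytest.approx(binomial_upper_tail_oracle(2, 10, 0.24), rel=1e-10)

    def test_observed_only_restricts_to_edges(self):
        profiles = [profile("S1", ["A", "B"]), profile("S2", ["C"])]
        results = pair_cooccurrence_tests(profiles, observed_only=True)
        assert [(r.gene_a, r.gene_b) for r in results] == [("A", "B")]

    def test_grid_agrees_with_scalar_api(self):
        rng = np.random.default_rng(5)
        loads = rng.random((50, 6)) < 0.2
        grid = pair_test_grid(loads)
        for row in grid.itertuples(index=False):
            assert row.p_value == pytest.approx(
                binomial_exact_test(int(row.k_obs), 50, float(row.p_expected)), rel=1e-12
            )

    def test_fewer_than_two_genes_no_tests(self):
        assert pair_cooccurrence_tests([profile("S1", ["A"])]) == []


def test_compare_cohorts_family_fdr():
    counts = [("g1", 10, 100, 5, 100), ("g2", 3, 100, 3, 100), ("g3", 30, 100, 5, 100)]
    comps = compare_cohorts(counts)
    assert all(0 < c.fisher_p <= 1 for c in comps)
    assert comps[1].fisher_p == 1.0
    raw = [c.fisher_p for c in comps]
    assert [c.fdr_q for c in comps] == pytest.approx(bh_stepup_oracle(raw))
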