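import numpy as np
import pytest

from carrierscreen.classify import (
    assign_group,
    build_profiles,
    gene_load,
    group_counts,
    prevalence_sweep,
    scope_genes,
)
from carrierscreen.filtering import FilterConfig
from carrierscreen.simulate import GeneSimSpec, SimConfig, simulate_cohort
from carrierscreen.types import CarrierProfile, GenotypeMatrix, Moi, ValidationError
from conftest import make_variant
from oracles import group_assignment_oracle


class TestGeneLoad:
    def test_multiple_variants_one_gene_cap_at_one(self, small_panel):
        vs = [(make_variant(variant_id=f"v{i}", gene="GENE001"), 1) for i in range(3)]
        load, consistent = gene_load(vs, small_panel)
        assert load == {"GENE001": 1}
        assert consistent == {"GENE001"}  # dominant gene, het suffices

    def test_het_in_recessive_gene_not_consistent(self, small_panel):
        load, consistent = gene_load([(make_variant(gene="GENE002"), 1)], small_panel)
        assert load == {"GENE002": 1}
        assert consistent == set()

    def test_hom_in_recessive_gene_consistent(self, small_panel):
        load, consistent = gene_load([(make_variant(gene="GENE002"), 2)], small_panel)
        assert consistent == {"GENE002"}

    def test_two_hets_same_recessive_gene_still_not_consistent(self, small_panel):
        # no phase: two heterozygous variants cannot be promoted to compound het
        vs = [(make_variant(variant_id=f"v{i}", gene="GENE002"), 1) for i in range(2)]
        load, consistent = gene_load(vs, small_panel)
        assert load == {"GENE002": 1}
        assert consistent == set()

    def test_hom_in_dominant_gene_consistent(self, small_panel):
        _, consistent = gene_load([(make_variant(gene="GENE001"), 2)], small_panel)
        assert consistent == {"GENE001"}

    def test_variant_in_unknown_gene_skipped(self, small_panel):
        load, consistent = gene_load([(make_variant(gene="NOT_ON_PANEL"), 1)], small_panel)
        assert load == {} and consistent == set()

    def test_dosage_zero_rejected(self, small_panel):
        with pytest.raises(ValidationError):
            gene_load([(make_variant(), 0)], small_panel)


class TestAssignGroup:
    def make_profile(self, quals, consistent):
        return CarrierProfile(
            sample_id="S",
            qualifying_variants=quals,
            gene_load={g: 1 for _, g, _ in quals},
            moi_consistent_genes=consistent,
        )

    def test_no_qualifying_variants_group1(self):
        assert assign_group(self.make_profile([], set())) == 1

    def test_het_dominant_only_group3(self):
        assert assign_group(self.make_profile([("v", "G1", 1)], {"G1"})) == 3

    def test_het_recessive_only_group2(self):
        assert assign_group(self.make_profile([("v", "G2", 1)], set())) == 2

    def test_group3_takes_precedence_over_group2(self):
        # het in recessive gene A AND hom in recessive gene B
        profile = self.make_profile([("v1", "A", 1), ("v2", "B", 2)], {"B"})
        assert assign_group(profile) == 3


class TestPrevalenceSweep:
    @pytest.fixture
    def planted_cohort(self, small_panel):
        """10 samples; 2 carry a dominant-gene variant surviving CADD 15 but not 25."""
        v_lo = make_variant(variant_id="lo", gene="GENE001", cadd_phred=18.0)
        v_hi = make_variant(variant_id="hi", gene="GENE003", cadd_phred=30.0)
        dosage = np.zeros((10, 2), dtype=np.int8)
        dosage[0, 0] = 1
        dosage[1, 0] = 1
        matrix = GenotypeMatrix([f"S{i}" for i in range(10)], ["lo", "hi"], dosage)
        return matrix, [v_lo, v_hi], small_panel

    def test_planted_group3_vanishes_at_high_threshold(self, planted_cohort):
        matrix, variants, panel = planted_cohort
        table = prevalence_sweep(matrix, variants, panel, thresholds=[15, 25], scopes=["extended"])
        g3 = table[table["group"] == 3].set_index("cadd_min")["proportion"]
        assert g3[15.0] == pytest.approx(0.2)
        assert g3[25.0] == 0.0

    def test_groups_partition_each_cell(self, planted_cohort):
        matrix, variants, panel = planted_cohort
        table = prevalence_sweep(matrix, variants, panel)
        for (_, _), cell in table.groupby(["scope", "cadd_min"]):
            assert cell["k"].sum() == matrix.n_samples
            assert cell["proportion"].sum() == pytest.approx(1.0)

    def test_unsorted_thresholds_rejected(self, planted_cohort):
        matrix, variants, panel = planted_cohort
        with pytest.raises(ValidationError):
            prevalence_sweep(matrix, variants, panel, thresholds=[25, 15])

    def test_empty_cohort_rejected(self, small_panel):
        empty = GenotypeMatrix([], ["v"], np.zeros((0, 1), dtype=np.int8))
        with pytest.raises(ValidationError):
            prevalence_sweep(empty, [make_variant(variant_id="v")], small_panel)


@pytest.mark.parametrize("seed", range(8))
def test_group_assignment_matches_bruteforce_oracle(seed):
    """Vectorised classification equals direct per-sample enumeration on
    random small cohorts, across thresholds and panel scopes."""
    config = SimConfig(
        seed=seed,
        n_samples=50,
        genes=tuple(
            GeneSimSpec(f"GENE{i + 1:03d}", Moi.RECESSIVE if i % 2 else Moi.DOMINANT,
                        nhs_panel=i < 3, n_variants=5)
            for i in range(8)
        ),
        carrier_freq=0.05,
        hom_fraction=0.3,
        missing_rate=0.01,
        n_duplicates=0,
        n_metric_fail=0,
        n_sex_discordant=0,
    )
    cohort = simulate_cohort(config)
    for cadd_min in (15.0, 20.0, 25.0):
        for scope in ("nhs", "extended"):
            profiles = build_profiles(
                cohort.matrix, cohort.variants, cohort.panel,
                FilterConfig(cadd_min=cadd_min), scope,
            )
            expected = group_assignment_oracle(
                cohort.matrix, cohort.variants, cohort.panel, cadd_min, scope
            )
            assert {p.sample_id: p.group for p in profiles} == expected


def test_monotone_and_nested_scope_invariants():
    cohort = simulate_cohort(SimConfig(seed=42, n_samples=120, n_duplicates=0,
                                       n_metric_fail=0, n_sex_discordant=0))
    g3_sets = {}
    for t in (15.0, 20.0, 25.0):
        for scope in ("nhs", "extended"):
            profiles = build_profiles(cohort.matrix, cohort.variants, cohort.panel,
                                      FilterConfig(cadd_min=t), scope)
            g3_sets[(t, scope)] = {p.sample_id for p in profiles if p.group == 3}
            assert sum(group_counts(profiles).values()) == cohort.matrix.n_samples
    for scope in ("nhs", "extended"):
        assert g3_sets[(25.0, scope)] <= g3_sets[(20.0, scope)] <= g3_sets[(15.0, scope)]
    for t in (15.0, 20.0, 25.0):
        assert g3_sets[(t, "nhs")] <= g3_sets[(t, "extended")]


def test_scope_genes_selects_panels(small_panel):
    assert [g.gene for g in scope_genes(small_panel, "nhs")] == ["GENE001", "GENE002"]
    assert len(scope_genes(small_panel, "extended")) == 4
    with pytest.raises(ValueError):
        scope_genes(small_panel, "everything")
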