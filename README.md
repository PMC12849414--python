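# carrierscreen

Rare-variant gene-panel carrier screening for severe obesity cohorts:
variant prioritization, sample QC and genotype concordance,
mode-of-inheritance (MOI) carrier classification, cohort carriage-rate
comparison, and a gene-pair co-occurrence test for oligogenic inheritance.

## The problem

Clinical screens for Mendelian obesity genotype a panel of genes (a 27-gene
clinical panel nested in an extended ~78-gene list) for rare
(MAF < 0.01) predicted-deleterious variants. For each participant the
question is whether their carriage is *consistent with the expected mode of
inheritance* of the genes involved, and — because penetrance is incomplete —
whether qualifying variants co-occur across genes more often than chance
(oligogenic inheritance). `carrierscreen` implements that analysis as a
tested, reusable pipeline, exercised end-to-end on synthetic cohorts with
planted ground truth.

## The model

**Filters.** Array-design candidates: known disease-database (HGMD) variants
pass unconditionally; population (gnomAD) variants need MAF < 0.01, a
missense/frameshift/stop-gain consequence, and for missense additionally
SIFT = damaging, PolyPhen = probably damaging and CADD-PHRED > 15. Analysis
filters then drop exclusively-intronic variants, CADD-PHRED < *t* (the sweep
threshold, *t* ∈ {15, 20, 25}) and low-confidence LOFTEE calls. Known
gain-of-function variants (e.g. *MC4R* rs2229616, associated with leanness)
are removed by an explicit exclusion list.

**Carrier strata.** Per gene *g*, a sample's capped genetic load is
L(g) = 1 if it carries ≥ 1 qualifying variant in *g* (never more, since
array calls are unphased and compound heterozygosity cannot be established).
Each sample is assigned

* **group 1** — no qualifying variant;
* **group 2** — heterozygous-only carriage confined to recessive-MOI genes;
* **group 3** — MOI-consistent carriage: ≥ 1 copy in a dominant gene, or a
  homozygous variant in a recessive gene (precedence over group 2).

**Statistics.** Proportions carry Wald 95% CIs, p ± 1.96·√(p(1−p)/n);
cohorts are compared with two-sided Fisher exact tests; for a gene pair
(a, b) the expected double-carrier probability under independence is the
product of the marginal carrier proportions p̂ₐ·p̂_b among group-3 carriers,
and the observed double-carrier count k is tested with the exact binomial
upper tail P(K ≥ k | n, p̂ₐ·p̂_b). Benjamini–Hochberg FDR is applied within
one family of tests per run.

## Worked example

```python
from carrierscreen import (
    FilterConfig, SimConfig, build_profiles, group_counts,
    multi_gene_proportion, pair_cooccurrence_tests, proportion_ci,
    qc_filter_samples,
)
from carrierscreen.simulate import simulate_cohort

cohort = simulate_cohort(SimConfig(seed=1, planted_pair=("GENE002", "GENE005", 1000.0)))
retained, report = qc_filter_samples(cohort.samples)
print(report.summary())

matrix = cohort.matrix.subset_samples([s.sample_id for s in retained])
profiles = build_profiles(matrix, cohort.variants, cohort.panel,
                          FilterConfig(cadd_min=15.0), scope="extended")
g3 = proportion_ci(group_counts(profiles)[3], len(profiles))
print(f"group 3 (MOI-consistent carriers): {g3.k}/{g3.n} = "
      f"{100*g3.p:.1f}% (95% CI {100*g3.ci_low:.1f}-{100*g3.ci_high:.1f}%)")

group3 = [p for p in profiles if p.group == 3]
multi = multi_gene_proportion(group3)
print(f"multi-gene carriers within group 3: {multi.k}/{multi.n} = {100*multi.p:.1f}%")

top = pair_cooccurrence_tests(group3, observed_only=True)[0]
print(f"most enriched pair {top.gene_a}-{top.gene_b}: observed {100*top.p_obs:.2f}% "
      f"vs expected {100*top.p_expected:.4f}%, binomial p = {top.p_value:.2g}")
```

prints

```
samples in          1766
  metric fail       25
  duplicate (QC)    22
  het/relatedness   0
  sex discordant    5
samples retained    1714
group 3 (MOI-consistent carriers): 731/1714 = 42.6% (95% CI 40.3-45.0%)
multi-gene carriers within group 3: 323/731 = 44.2%
most enriched pair GENE002-GENE005: observed 0.41% vs expected 0.0236%, binomial p = 0.00075
```

The QC ledger removes 52 of 1,766 genotyped samples (metric failures,
designated duplicate copies, sex-discordant samples) leaving 1,714. At the
CADD ≥ 15 threshold on the extended panel, 42.6% of this synthetic cohort
carries MOI-consistent variation; 44.2% of those carriers load two or more
genes. The planted gene pair GENE002–GENE005 is recovered as the most
enriched pair: joint carriage is ~17× its expected-by-chance rate, exact
binomial p = 7.5 × 10⁻⁴.

The same pipeline is available from the shell:

```sh
carrierscreen simulate --seed 1 --outdir run/
carrierscreen filter --variants run/variants.tsv --out run/kept.tsv --log run/reasons.tsv
carrierscreen qc --samples run/samples.tsv --report run/qc_report.json
carrierscreen classify --genotypes run/geno.tsv --variants run/kept.tsv \
    --panel run/panel.tsv --out run/profiles.tsv
carrierscreen stats pairs --profiles run/profiles.tsv --out run/pairs.tsv
```

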