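# Methods

## Pipeline overview

`carrierscreen` screens a cohort's genotypes over a gene panel for rare
predicted-deleterious variants and classifies each participant's carriage
against the expected mode of inheritance (MOI) of the genes involved. The
stages are independent and composable: artifact I/O (`io`), variant
prioritization (`filtering`), sample QC and concordance (`qc`),
MOI classification (`classify`), estimators and exact tests (`stats`), and a
synthetic-cohort generator (`simulate`) that serves as the test bed.

## Variant prioritization

Two stages with deliberately different CADD comparators:

* **Design stage** (`select_array_candidates`): HGMD-source variants pass
  unconditionally, irrespective of predicted pathogenicity. gnomAD-only
  variants require MAF < `maf_max` (default 0.01), consequence ∈
  {missense, frameshift, stop_gain}, and missense variants additionally
  SIFT = damaging ∧ PolyPhen = probably_damaging ∧ CADD-PHRED **>** 15.
  A gnomAD variant with no MAF fails with a logged reason code rather than
  raising: on a rare-variant array an unknown population frequency is an
  ordinary data condition, not a programming error.
* **Analysis stage** (`apply_analysis_filters`): removal if exclusively
  intronic, CADD-PHRED **<** `cadd_min`, or LOFTEE low-confidence, so
  retention is ≥ `cadd_min`. A variant at exactly CADD 15 therefore fails the
  design filter but survives the analysis filter — the two stages follow
  their respective stated rules literally, and the inconsistency at the
  boundary is intentional.

Both filters are idempotent and the analysis filter is monotone in
`cadd_min`; these are asserted as properties. Each removal records one
reason code per variant so filtering is auditable without cluster-plot
inspection (which is out of scope; externally curated exclusions enter as an
id list, like the gain-of-function list).

## Sample QC

The exclusion ledger evaluates, in order: array metric failure
(DQC < 0.82 by default), designated duplicate QC copies (the primary is
kept, the flagged copy removed), heterozygosity/relatedness flags (consumed
as booleans — kinship estimation is out of scope), and discordant genetic vs
self-reported sex (both must be known). A sample may hold several reasons
but is removed once, so `n_input − n_retained` equals the number of distinct
removed samples — an exact ledger identity asserted in tests.

Cluster categories per variant column: one distinct non-missing code →
MonoHighResolution; heterozygotes without alternate homozygotes →
NoMinorHom; alternate homozygotes alongside another genotype →
PolyHighResolution. A column holding only {0, 2} (hom-alt without hets) has
no category in the three published definitions; it is assigned
PolyHighResolution here since the hom-alt cluster resolved, and this occurs
essentially never at rare-variant frequencies.

Concordance between two aligned call vectors counts a position only when
both calls are non-missing (the only convention that keeps the agreement
fraction interpretable as ≤ 1); skipped positions are reported. Per-category
values use the same rule restricted to each category, so the overall value
is exactly the comparison-weighted mean of the per-category values. For
duplicate pairs both the per-pair values and their mean are reported, since
per-variant vs per-pair weighting conventions differ between tools.

## MOI classification

Per gene, genetic load is capped at 1: without phase, two heterozygous
variants in one gene cannot be distinguished from two variants on one
haplotype, so multiple hits never escalate to compound heterozygosity. A
gene is MOI-consistent for a sample if it is dominant with any qualifying
carriage, or recessive with a homozygous qualifying variant; a homozygote in
a dominant gene qualifies a fortiori. Groups: 1 = no qualifying variant,
3 = any MOI-consistent gene (precedence), 2 = the remainder (heterozygous
carriage in recessive genes only). Missing genotypes count as non-carrier,
matching the carrier-count semantics of array calls. Filters are always
applied before grouping; the prevalence sweep re-filters and re-groups at
each (CADD threshold, panel scope) cell, which makes the invariants exact:
groups partition the cohort, group 3 is non-increasing in the threshold,
and the clinical-panel group-3 set is nested in the extended-panel set.
Classification is verified against a brute-force per-sample enumeration
oracle on small cohorts.

## Statistics

* **Proportion CIs** use the Wald formula p ± 1.96·√(p(1−p)/n), clamped to
  [0, 1] — chosen over Wilson/Clopper–Pearson to match the plotting-error-bar
  convention of carriage-rate figures; it is degenerate at p ∈ {0, 1}.
* **Cohort comparison**: two-sided Fisher exact test (probability-mass
  two-sidedness, the dominant software convention), validated against an
  exact-integer hypergeometric enumeration oracle on every 2×2 table with
  total ≤ 30.
* **Pair co-occurrence**: for genes (a, b), expected double-carrier
  probability p₀ = p̂ₐ·p̂_b (independence of capped loads among group-3
  carriers), tested with the exact binomial upper tail P(K ≥ k | n, p₀).
  Upper-tail is the default sidedness because the scientific hypothesis is
  *excess* co-occurrence; a two-sided option exists, and at p₀ ≪ p_obs the
  two agree to reported precision. Validated against direct tail summation
  up to n = 10,000.
* **FDR**: Benjamini–Hochberg step-up, one family per analysis run
  (cohort-comparison tests form one family; the pair-test grid another, and
  unadjusted pair p-values are always emitted alongside). Validated against
  the hand step-up recursion.
* Percentages render half-away-from-zero with per-column decimals.

## Synthetic cohorts

The generator emulates: 1,744 unique samples plus 22 duplicate QC copies
(1,766 genotyped, and with 25 planted metric failures and 5 sex-discordant
samples the ledger retains 1,714); a 78-gene panel (27 NHS + 51 extended,
every third gene recessive) with 8 variants per gene (~620 variants);
per-variant carrier frequencies drawn log-uniformly between the singleton
frequency 1/(2n) and 0.005, making most carried variants singletons; CADD
from a four-component uniform mixture spanning the 15/20/25 sweep (weights
0.15/0.25/0.35/0.25 over [0,15)/[15,20)/[20,25)/[25,40]); a consequence mix
dominated by missense (0.85) with small frameshift/stop-gain fractions, as
in deleteriousness-prioritised panels; duplicate copies perturbed per call
at rate 0.003 (recovering ~99.7% concordance); genotype missingness 0.001.

Design choices:

* One counter-based RNG stream per artifact (genotypes, annotations, QC
  defects, duplicates), all keyed off a single seed — adding duplicates or
  defects never perturbs genotype draws, keeping regression tests stable.
* Homozygous carriage at recessive-gene variants is drawn directly with
  probability `hom_fraction` (default 0.05) per carrier instead of
  Hardy–Weinberg, under which rare-variant homozygotes would essentially
  never occur at n ≈ 1,700 and the recessive group-3 pathway would be
  untestable. This is a deliberate departure from population-genetics
  realism.
* The MAF column is carrier_freq/2 (allele ≈ half carrier frequency);
  adequate because filters only threshold it.
* A planted gene pair multiplies the joint carriage probability of one
  designated variant per gene by a configured factor, capped at the smaller
  marginal (warning when the cap binds); the designated variants' annotations
  are forced to qualify at every sweep threshold so the planted signal is
  never silently removed by the annotation filters. The truth record stores
  every planted quantity, including each sample's true group at the
  reference threshold (CADD 15, extended panel).

What passing tests on these cohorts do **not** show about real data: there
is no linkage or haplotype structure, no realistic site-frequency spectrum,
no genotyping-error model beyond uniform duplicate discordance and uniform
missingness, and no phenotypes — carrier status is the entire model. Carrier
frequencies here produce a higher overall carriage than clinical cohorts
show (the generated group-3 fraction at CADD 15 is ~40% rather than ~27%),
so absolute synthetic prevalences characterise the generator, not any
population.

## Problem sizes and numerical notes

The acceptance computations use one study-scale cohort (1,766 samples ×
624 variants), 2,000 replicates of 400 × 20 independent-load matrices for
pair-test calibration and 500 for planted-pair recovery, chosen as the
smallest ensembles at which Monte-Carlo error is well below the effects
being measured. Exact binomial tails are computed vectorised via the
survival function; p-values are kept in (0, 1] (underflow clamps to the
smallest positive float). Fisher inputs are validated (k ≤ n, n ≥ 1);
degenerate concordance (no jointly non-missing call) and empty cohorts
raise rather than returning NaN.

Planted-pair recovery at the calibration conditions (n = 400, 1% marginals,
30× enrichment) is fundamentally limited: the planted pair's double-carrier
count is Binomial(400, 0.003), which is zero ~30% of the time, so no test
can recover the pair as the top hit in more than ~70% of replicates; the
measured recovery with this exact test is ~0.45. The recovery-rate
computation reports this honestly rather than inflating the planted effect.

## Known limitations

X-linked and other non-autosomal MOI regimes are rejected at input, not
modelled. Compound heterozygosity is never inferred (capped load is the
contract). Annotations are consumed, never computed — no VEP/CADD/LOFTEE
integration. Relatedness and heterozygosity QC are consumed as flags.
Fisher and binomial tests are exact but unconditional power depends on
cohort sizes the caller supplies; no power planning utilities are included.
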