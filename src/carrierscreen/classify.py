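"""Mode-of-inheritance carrier classification.

Each sample is assigned a capped per-gene genetic load and one of three
carrier strata for a given gene-panel scope and CADD threshold:

* group 1 — no qualifying variant in any panel gene;
* group 2 — heterozygous-only carriage confined to recessive-MOI genes
  (carriage inconsistent with the expected inheritance);
* group 3 — carriage consistent with the expected MOI: at least one copy in a
  dominant gene, or homozygous in a recessive gene. Group 3 takes precedence
  over group 2 when both apply.

Two heterozygous variants in one recessive gene do **not** qualify for
group 3: array calls carry no phase, so compound heterozygosity cannot be
established and the conservative reading is used. Missing genotype calls are
treated as non-carrier.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .filtering import FilterConfig, apply_analysis_filters
from .stats import proportion_ci
from .types import (
    MISSING,
    CarrierProfile,
    GeneSpec,
    GenotypeMatrix,
    Moi,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger(__name__)

SCOPES = ("nhs", "extended")


def scope_genes(panel: Sequence[GeneSpec], scope: str = "extended") -> List[GeneSpec]:
    """Subset of the panel in the given scope ('nhs' or 'extended')."""
    if scope not in SCOPES:
        raise ValueError(f"panel scope must be one of {SCOPES}, got {scope!r}")
    if scope == "nhs":
        return [g for g in panel if g.nhs_panel]
    return [g for g in panel if g.extended_panel]


def gene_load(
    profile_variants: Iterable[Tuple[VariantRecord, int]],
    gene_panel: Sequence[GeneSpec],
) -> Tuple[Dict[str, int], Set[str]]:
    """Capped per-gene load and the set of MOI-consistent genes.

    ``profile_variants`` are (variant, dosage) pairs with dosage in {1, 2},
    already panel-scoped and filter-passing. A gene's load is 1 if the sample
    carries any qualifying variant in it, irrespective of how many (phase is
    unknown, so multiple variants cannot be promoted to compound
    heterozygosity). A gene is MOI-consistent if dominant with any carriage,
    or recessive with at least one homozygous variant. Variants mapped to
    genes absent from the panel are skipped with a warning.
    """
    moi_by_gene = {g.gene: g.moi for g in gene_panel}
    load: Dict[str, int] = {}
    consistent: Set[str] = set()
    for variant, dosage in profile_variants:
        if dosage not in (1, 2):
            raise ValidationError(
                f"{variant.variant_id}: qualifying dosage must be 1 or 2, got {dosage}"
            )
        moi = moi_by_gene.get(variant.gene)
        if moi is None:
            log.warning("variant %s maps to gene %s absent from the panel; skipped",
                        variant.variant_id, variant.gene)
            continue
        load[variant.gene] = 1
        if moi is Moi.DOMINANT or (moi is Moi.RECESSIVE and dosage == 2):
            consistent.add(variant.gene)
    return load, consistent


def assign_group(profile: CarrierProfile) -> int:
    """Carrier stratum of a profile with gene_load already computed."""
    if not profile.qualifying_variants:
        return 1
    if profile.moi_consistent_genes:
        return 3
    return 2


def build_profiles(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    panel: Sequence[GeneSpec],
    config: FilterConfig = FilterConfig(),
    scope: str = "extended",
) -> List[CarrierProfile]:
    """Classify every sample: filter variants, compute loads, assign groups.

    Analysis filters are applied to ``variants`` at ``config.cadd_min`` first;
    classification then only sees filter-passing variants located in panel
    genes of the requested scope and present in the genotype matrix.
    """
    genes = scope_genes(panel, scope)
    gene_set = {g.gene for g in genes}
    kept = [v for v in apply_analysis_filters(variants, config) if v.gene in gene_set]
    vids = set(matrix.variant_ids)
    usable = [v for v in kept if v.variant_id in vids]
    for v in kept:
        if v.variant_id not in vids:
            log.warning("variant %s not present in genotype matrix; skipped", v.variant_id)

    cols = np.array(
        [matrix.variant_ids.index(v.variant_id) for v in usable], dtype=np.intp
    )
    profiles: List[CarrierProfile] = []
    for i, sample_id in enumerate(matrix.sample_ids):
        row = matrix.dosage[i, cols] if len(cols) else np.empty(0, dtype=np.int8)
        carried = [
            (usable[j], int(row[j]))
            for j in range(len(usable))
            if row[j] in (1, 2)  # missing treated as non-carrier
        ]
        load, consistent = gene_load(carried, genes)
        profile = CarrierProfile(
            sample_id=sample_id,
            qualifying_variants=[(v.variant_id, v.gene, d) for v, d in carried],
            gene_load=load,
            moi_consistent_genes=consistent,
        )
        profile.group = assign_group(profile)
        profiles.append(profile)
    return profiles


def group_counts(profiles: Sequence[CarrierProfile]) -> Dict[int, int]:
    counts = {1: 0, 2: 0, 3: 0}
    for p in profiles:
        counts[p.group] += 1
    return counts


def prevalence_sweep(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    panel: Sequence[GeneSpec],
    thresholds: Sequence[float] = (15.0, 20.0, 25.0),
    scopes: Sequence[str] = SCOPES,
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Carriage rates by CADD threshold, panel scope and group.

    For every (threshold, scope) cell the analysis filter is re-applied at
    that threshold, groups are re-assigned, and each group's proportion of
    the cohort is returned with its 95% Wald CI. Proportions sum to 1 within
    each cell. Thresholds must be sorted ascending.
    """
    if matrix.n_samples == 0:
        raise ValidationError("empty cohort: prevalence undefined")
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    rows = []
    for scope in scopes:
        for t in thresholds:
            profiles = build_profiles(matrix, variants, panel, config.with_cadd_min(t), scope)
            counts = group_counts(profiles)
            n = len(profiles)
            for grp in (1, 2, 3):
                est = proportion_ci(counts[grp], n)
                rows.append(
                    {
                        "scope": scope,
                        "cadd_min": float(t),
                        "group": grp,
                        "k": counts[grp],
                        "n": n,
                        "proportion": est.p,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                )
    return pd.DataFrame(rows)
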