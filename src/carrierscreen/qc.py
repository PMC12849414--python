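"""Sample-level QC: the exclusion ledger and genotype concordance.

The exclusion ledger removes samples, in order, for (1) failing array QC
metrics (DQC below threshold), (2) being a designated duplicate copy included
for QC, (3) excess heterozygosity or relatedness, and (4) discordant genetic
vs self-reported sex. A sample may accumulate several reasons but is removed
only once, so ``n_input - n_retained`` always equals the number of distinct
removed samples.

Concordance between two genotype vectors (e.g. a sample and its duplicate, or
array calls vs exome-sequencing calls) is the fraction of agreeing calls over
positions where both calls are non-missing, reported overall and stratified by
array cluster category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    MISSING,
    ClusterCategory,
    GenotypeMatrix,
    SampleRecord,
    Sex,
    ValidationError,
)

REASON_METRIC_FAIL = "metric_fail"
REASON_DUPLICATE = "duplicate_qc_copy"
REASON_HET_RELATED = "het_or_related"
REASON_SEX_DISCORDANT = "sex_discordant"

#: evaluation order of the exclusion ledger
LEDGER_ORDER = (REASON_METRIC_FAIL, REASON_DUPLICATE, REASON_HET_RELATED, REASON_SEX_DISCORDANT)


@dataclass
class QcReport:
    """Exclusion ledger: per-reason counts plus per-sample reason codes."""

    n_input: int
    n_fail_metrics: int
    n_duplicates_removed: int
    n_het_related_removed: int
    n_sex_discordant: int
    n_retained: int
    per_sample_reasons: Dict[str, List[str]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"samples in          {self.n_input}",
            f"  metric fail       {self.n_fail_metrics}",
            f"  duplicate (QC)    {self.n_duplicates_removed}",
            f"  het/relatedness   {self.n_het_related_removed}",
            f"  sex discordant    {self.n_sex_discordant}",
            f"samples retained    {self.n_retained}",
        ]
        return "\n".join(lines)


def qc_filter_samples(
    samples: Sequence[SampleRecord], dqc_min: float = 0.82
) -> Tuple[List[SampleRecord], QcReport]:
    """Apply the exclusion ledger; returns (retained samples, report).

    ``dqc_min`` is the array dish-QC threshold (default 0.82). Duplicate
    resolution removes the flagged QC copy (``duplicate_of`` set) and keeps
    the primary. Sex discordance requires both sexes known and unequal.
    """
    ids = {s.sample_id for s in samples}
    for s in samples:
        if s.duplicate_of is not None and s.duplicate_of not in ids:
            raise ValidationError(
                f"{s.sample_id}: duplicate_of references unknown sample {s.duplicate_of!r}"
            )

    reasons: Dict[str, List[str]] = {}

    def flag(sample_id: str, reason: str) -> None:
        reasons.setdefault(sample_id, []).append(reason)

    for s in samples:
        if s.dqc is not None and s.dqc < dqc_min:
            flag(s.sample_id, REASON_METRIC_FAIL)
    for s in samples:
        if s.duplicate_of is not None:
            flag(s.sample_id, REASON_DUPLICATE)
    for s in samples:
        if s.het_outlier_flag or s.relatedness_flag:
            flag(s.sample_id, REASON_HET_RELATED)
    for s in samples:
        if (
            s.reported_sex is not Sex.MISSING
            and s.genetic_sex is not Sex.MISSING
            and s.reported_sex is not s.genetic_sex
        ):
            flag(s.sample_id, REASON_SEX_DISCORDANT)

    retained = [s for s in samples if s.sample_id not in reasons]
    counts = {r: sum(r in rs for rs in reasons.values()) for r in LEDGER_ORDER}
    report = QcReport(
        n_input=len(samples),
        n_fail_metrics=counts[REASON_METRIC_FAIL],
        n_duplicates_removed=counts[REASON_DUPLICATE],
        n_het_related_removed=counts[REASON_HET_RELATED],
        n_sex_discordant=counts[REASON_SEX_DISCORDANT],
        n_retained=len(retained),
        per_sample_reasons=reasons,
    )
    return retained, report


def classify_cluster_category(dosage_column: Iterable[int]) -> ClusterCategory:
    """Cluster category of one variant's genotype column.

    Monomorphic columns (a single non-missing code) are MonoHighResolution;
    columns with heterozygotes but no alternate homozygotes are NoMinorHom;
    columns with alternate homozygotes are PolyHighResolution. An all-missing
    column is uncallable and raises.
    """
    col = np.asarray(list(dosage_column), dtype=np.int64)
    codes = set(col[col != MISSING].tolist())
    if not codes:
        raise ValidationError("all-missing genotype column: variant is uncallable")
    if len(codes) == 1:
        return ClusterCategory.MONO_HIGH_RESOLUTION
    if 2 in codes:
        return ClusterCategory.POLY_HIGH_RESOLUTION
    return ClusterCategory.NO_MINOR_HOM


@dataclass
class ConcordanceResult:
    """Genotype agreement between two aligned call vectors."""

    n_variants_compared: int
    overall: float
    by_category: Dict[ClusterCategory, float]
    n_missing_skipped: int
    n_compared_by_category: Dict[ClusterCategory, int] = field(default_factory=dict)


def pairwise_concordance(
    a: Sequence[int],
    b: Sequence[int],
    categories: Optional[Sequence[ClusterCategory]] = None,
) -> ConcordanceResult:
    """Concordance between two genotype vectors aligned on the same variants.

    A position contributes only when both calls are non-missing; skipped
    positions are counted in ``n_missing_skipped``. ``categories``, when
    given, is aligned with the vectors and yields per-category concordances
    over each category's variants only. The overall value is exactly the
    comparison-count-weighted mean of the per-category values.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValidationError(f"vector lengths differ: {a.shape} vs {b.shape}")
    valid = (a != MISSING) & (b != MISSING)
    n_compared = int(valid.sum())
    if n_compared == 0:
        raise ValidationError("no position with both calls non-missing: concordance undefined")
    match = (a == b) & valid

    by_cat: Dict[ClusterCategory, float] = {}
    n_by_cat: Dict[ClusterCategory, int] = {}
    if categories is not None:
        cats = list(categories)
        if len(cats) != len(a):
            raise ValidationError("categories not aligned with genotype vectors")
        cats_arr = np.asarray([c.value for c in cats], dtype=object)
        for cat in ClusterCategory:
            sel = valid & (cats_arr == cat.value)
            n = int(sel.sum())
            if n:
                by_cat[cat] = float(match[sel].sum() / n)
                n_by_cat[cat] = n

    return ConcordanceResult(
        n_variants_compared=n_compared,
        overall=float(match.sum() / n_compared),
        by_category=by_cat,
        n_missing_skipped=int(a.size - n_compared),
        n_compared_by_category=n_by_cat,
    )


def matrix_cluster_categories(matrix: GenotypeMatrix) -> Dict[str, ClusterCategory]:
    """Cluster category for every callable variant column of a matrix."""
    out: Dict[str, ClusterCategory] = {}
    for j, vid in enumerate(matrix.variant_ids):
        col = matrix.dosage[:, j]
        if np.all(col == MISSING):
            continue
        out[vid] = classify_cluster_category(col)
    return out


def duplicate_concordance(
    matrix: GenotypeMatrix,
    pairs: Sequence[Tuple[str, str]],
    categories: Optional[Mapping[str, ClusterCategory]] = None,
) -> Tuple[List[ConcordanceResult], Dict[str, float]]:
    """Concordance for each (primary, duplicate) sample pair plus averages.

    Cluster categories default to those derived from the matrix itself.
    Returns per-pair results and a dict of the mean overall and mean
    per-category concordances across pairs.
    """
    if categories is None:
        categories = matrix_cluster_categories(matrix)
    cat_list = [categories.get(v) for v in matrix.variant_ids]
    usable = [i for i, c in enumerate(cat_list) if c is not None]
    results: List[ConcordanceResult] = []
    for s1, s2 in pairs:
        a = matrix.sample_row(s1)[usable]
        b = matrix.sample_row(s2)[usable]
        results.append(pairwise_concordance(a, b, [cat_list[i] for i in usable]))
    means: Dict[str, float] = {"overall": float(np.mean([r.overall for r in results]))}
    for cat in ClusterCategory:
        vals = [r.by_category[cat] for r in results if cat in r.by_category]
        if vals:
            means[cat.value] = float(np.mean(vals))
    return results, means
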