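"""Variant prioritization filters.

Two distinct filtering stages are modelled, with deliberately different CADD
comparators:

* **Array-design candidate selection** — which variants earn a probe. Known
  disease-mutation (HGMD) variants pass unconditionally; population (gnomAD)
  variants must be rare (MAF < 0.01) and of a qualifying consequence class,
  and missense candidates must additionally be called damaging by SIFT,
  probably damaging by PolyPhen and have CADD-PHRED strictly above 15.
* **Analysis filters** — which genotyped variants enter carrier analyses.
  Variants exclusively intronic, with CADD-PHRED below the threshold
  (removal rule ``< cadd_min``, i.e. retention is ``>= cadd_min``), or
  low-confidence per LOFTEE are dropped.

A boundary CADD of exactly 15 therefore fails the design filter but passes
the analysis filter at the default threshold.

Known gain-of-function variants (e.g. MC4R rs2229616, associated with
leanness rather than obesity) are removed from risk-carrier analyses by an
explicit exclusion list.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .types import Consequence, Loftee, PolyPhen, Sift, Source, ValidationError, VariantRecord

log = logging.getLogger(__name__)

#: per-variant reason codes recorded when a filter removes a variant
REASON_MAF = "maf_not_below_max"
REASON_MAF_MISSING = "maf_missing"
REASON_CONSEQUENCE = "consequence_not_allowed"
REASON_MISSENSE_SCORES = "missense_scores_fail"
REASON_INTRONIC = "intronic_only"
REASON_CADD = "cadd_below_min"
REASON_LOFTEE_LC = "loftee_low_confidence"
REASON_GOF = "gain_of_function_excluded"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both filter stages.

    ``cadd_min`` is used as a strict lower bound (> ) at the design stage and
    an inclusive one (>= ) at the analysis stage.
    """

    cadd_min: float = 15.0
    maf_max: float = 0.01
    allowed_consequences: frozenset = frozenset(
        {Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.STOP_GAIN}
    )
    drop_intronic_only: bool = True
    drop_loftee_lc: bool = True
    gof_exclusion_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.cadd_min < 0:
            raise ValidationError(f"cadd_min must be >= 0, got {self.cadd_min}")
        if not (0.0 < self.maf_max <= 1.0):
            raise ValidationError(f"maf_max must lie in (0, 1], got {self.maf_max}")

    def with_cadd_min(self, cadd_min: float) -> "FilterConfig":
        return dataclasses.replace(self, cadd_min=cadd_min)


def _design_failure(v: VariantRecord, config: FilterConfig) -> Optional[str]:
    """Reason code for removing ``v`` at the design stage, or None if it passes."""
    if v.source in (Source.HGMD, Source.BOTH):
        return None  # disease-database variants pass regardless of scores
    if v.maf is None:
        return REASON_MAF_MISSING
    if not v.maf < config.maf_max:
        return REASON_MAF
    if v.consequence not in config.allowed_consequences:
        return REASON_CONSEQUENCE
    if v.consequence is Consequence.MISSENSE and not (
        v.sift is Sift.DAMAGING
        and v.polyphen is PolyPhen.PROBABLY_DAMAGING
        and v.cadd_phred > config.cadd_min
    ):
        return REASON_MISSENSE_SCORES
    return None


def select_array_candidates(
    variants: Iterable[VariantRecord],
    config: FilterConfig = FilterConfig(),
    reasons: Optional[Dict[str, str]] = None,
) -> List[VariantRecord]:
    """Array-design candidate selection.

    Pass ``reasons`` (a dict) to collect one removal reason code per dropped
    variant, keyed by variant_id; a gnomAD variant with no MAF fails with a
    logged reason rather than raising.
    """
    kept: List[VariantRecord] = []
    for v in variants:
        why = _design_failure(v, config)
        if why is None:
            kept.append(v)
        else:
            if why == REASON_MAF_MISSING:
                log.warning("%s: gnomAD-source variant without MAF fails design selection", v.variant_id)
            if reasons is not None:
                reasons[v.variant_id] = why
    return kept


def apply_analysis_filters(
    variants: Iterable[VariantRecord],
    config: FilterConfig = FilterConfig(),
    reasons: Optional[Dict[str, str]] = None,
) -> List[VariantRecord]:
    """Post-genotyping analysis filter; order-preserving subset of the input."""
    kept: List[VariantRecord] = []
    for v in variants:
        if config.drop_intronic_only and v.consequence is Consequence.INTRONIC:
            why: Optional[str] = REASON_INTRONIC
        elif v.cadd_phred < config.cadd_min:
            why = REASON_CADD
        elif config.drop_loftee_lc and v.loftee is Loftee.LC:
            why = REASON_LOFTEE_LC
        else:
            why = None
        if why is None:
            kept.append(v)
        elif reasons is not None:
            reasons[v.variant_id] = why
    return kept


def exclude_gof_variants(
    variants: Iterable[VariantRecord], exclusion_ids: Set[str]
) -> Tuple[List[VariantRecord], List[VariantRecord]]:
    """Partition variants into (retained, gain-of-function excluded).

    Excluded records come back with ``gof_excluded=True``. Exclusion ids not
    present in the input are logged, not errors.
    """
    variants = list(variants)
    retained: List[VariantRecord] = []
    excluded: List[VariantRecord] = []
    for v in variants:
        if v.variant_id in exclusion_ids:
            excluded.append(dataclasses.replace(v, gof_excluded=True))
        else:
            retained.append(v)
    present = {v.variant_id for v in variants}
    for vid in sorted(set(exclusion_ids) - present):
        log.warning("gain-of-function exclusion id %s not found among input variants", vid)
    return retained, excluded
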