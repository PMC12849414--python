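"""Core domain types for the rare-variant carrier screening pipeline.

The pipeline works on three input artifacts — an annotated variant table, a
samples × variants genotype matrix, and a gene panel with per-gene mode of
inheritance (MOI) — plus a sample metadata table used for QC. Genotypes are
allele-dosage codes: 0 (reference homozygote), 1 (heterozygote), 2 (alternate
homozygote), with ``-1`` encoding a missing call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING = -1  # dosage code for a missing genotype call


class SchemaError(ValueError):
    """An input artifact is missing a required column or field."""


class ValidationError(ValueError):
    """An input artifact violates a content invariant (bad value, duplicate id...)."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    SPLICE = "splice"
    INTRONIC = "intronic"
    OTHER = "other"

    @classmethod
    def from_string(cls, value: str) -> "Consequence":
        """Map an annotation string to the enum; unknown strings become OTHER."""
        try:
            return cls(value.strip().lower())
        except ValueError:
            return cls.OTHER


class Sift(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


class PolyPhen(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


class Loftee(str, enum.Enum):
    HC = "HC"
    LC = "LC"
    NOT_APPLICABLE = "not_applicable"


class Source(str, enum.Enum):
    HGMD = "HGMD"
    GNOMAD = "gnomAD"
    BOTH = "both"


class Moi(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    MISSING = "missing"


class ClusterCategory(str, enum.Enum):
    """Array clustering categories for a variant's genotype column."""

    POLY_HIGH_RESOLUTION = "PolyHighResolution"
    NO_MINOR_HOM = "NoMinorHom"
    MONO_HIGH_RESOLUTION = "MonoHighResolution"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant on the canonical transcript.

    Deleteriousness annotations (CADD-PHRED, SIFT, PolyPhen, LOFTEE) and the
    population minor allele frequency are consumed, never computed here.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    cadd_phred: float
    sift: Sift = Sift.MISSING
    polyphen: PolyPhen = PolyPhen.MISSING
    loftee: Loftee = Loftee.NOT_APPLICABLE
    maf: Optional[float] = None
    source: Source = Source.GNOMAD
    gof_excluded: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.cadd_phred < 0:
            raise ValidationError(
                f"{self.variant_id}: cadd_phred must be non-negative, got {self.cadd_phred}"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValidationError(
                f"{self.variant_id}: maf must lie in [0, 1], got {self.maf}"
            )


@dataclass(frozen=True)
class GeneSpec:
    """A panel gene with its expected mode of inheritance.

    The clinical (NHS) panel is a subset of the extended panel, so
    ``nhs_panel`` implies ``extended_panel``.
    """

    gene: str
    moi: Moi
    nhs_panel: bool
    extended_panel: bool = True

    def __post_init__(self) -> None:
        if self.nhs_panel and not self.extended_panel:
            raise ValidationError(
                f"{self.gene}: nhs_panel genes are part of the extended panel by construction"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata consumed by the QC exclusion ledger."""

    sample_id: str
    cohort: str = "cohort"
    reported_sex: Sex = Sex.MISSING
    genetic_sex: Sex = Sex.MISSING
    dqc: Optional[float] = None
    duplicate_of: Optional[str] = None
    relatedness_flag: bool = False
    het_outlier_flag: bool = False

    def __post_init__(self) -> None:
        if self.dqc is not None and not (0.0 <= self.dqc <= 1.0):
            raise ValidationError(f"{self.sample_id}: dqc must lie in [0, 1], got {self.dqc}")
        if self.duplicate_of == self.sample_id:
            raise ValidationError(f"{self.sample_id}: a sample cannot duplicate itself")


class GenotypeMatrix:
    """Samples × variants allele-dosage matrix.

    Dosage codes are 0/1/2 with ``MISSING`` (−1) for no-calls. Sample and
    variant order is preserved exactly as read from file.
    """

    def __init__(self, sample_ids, variant_ids, dosage) -> None:
        self.sample_ids = list(sample_ids)
        self.variant_ids = list(variant_ids)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(
                f"dosage contains {int(bad.sum())} codes outside {{0, 1, 2, {MISSING}}}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_id in genotype matrix")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("duplicate variant_id in genotype matrix")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.dosage[self._sample_index[sample_id]]

    def variant_column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self._variant_index[variant_id]]

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return GenotypeMatrix(sample_ids, self.variant_ids, self.dosage[idx])

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = [self._variant_index[v] for v in variant_ids]
        return GenotypeMatrix(self.sample_ids, variant_ids, self.dosage[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


@dataclass
class CarrierProfile:
    """One sample's qualifying carriage under a panel scope and filter config.

    ``gene_load`` is the capped per-gene carrier indicator: multiple variants
    in one gene still count as a load of 1, because phase is unknown and
    compound heterozygosity cannot be established from array calls.
    ``group`` strata: 1 = no qualifying variants; 2 = heterozygous-only in
    recessive-MOI genes; 3 = carriage consistent with the expected MOI
    (heterozygous in a dominant gene and/or homozygous in a recessive gene).
    """

    sample_id: str
    qualifying_variants: list = field(default_factory=list)  # (variant_id, gene, dosage)
    gene_load: dict = field(default_factory=dict)  # gene -> {0, 1}
    moi_consistent_genes: set = field(default_factory=set)
    group: int = 1

    @property
    def loaded_genes(self) -> set:
        return {g for g, v in self.gene_load.items() if v == 1}
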