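"""Synthetic cohort generator.

Emulates the study conditions of a rare-variant array screen of a severe
obesity cohort: ~1,700 genotyped samples, a 78-gene panel (27 clinical-NHS
genes within an extended list of 78), several hundred carried rare variants
that are mostly singletons, per-gene dominant/recessive MOI, an optional
planted excess of joint carriage in one gene pair, duplicate sample pairs
with a small call-discordance rate, and sample-level QC defects (low-DQC
failures, sex-discordant samples).

Deliberate departures from population-genetics realism: homozygous carriage
of recessive-gene variants is drawn directly with probability
``hom_fraction`` per carrier rather than via Hardy–Weinberg (rare-variant
homozygote counts would otherwise be ~0 at n ≈ 1,700 and the recessive
group-3 pathway would never be exercised), and the variant MAF column is set
to carrier_freq/2 (allele vs carrier approximation — adequate because
filters only threshold it). No linkage, haplotypes or phenotypes are
modelled.

A single integer seed drives one independent generator stream per artifact
(genotypes, annotations, sample defects, duplicates), so e.g. adding
duplicates never perturbs the genotype draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    MISSING,
    Consequence,
    GeneSpec,
    GenotypeMatrix,
    Loftee,
    Moi,
    PolyPhen,
    SampleRecord,
    Sex,
    Sift,
    Source,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger(__name__)

_STREAM_GENOTYPES = 0
_STREAM_ANNOTATION = 1
_STREAM_DEFECTS = 2
_STREAM_DUPLICATES = 3


@dataclass(frozen=True)
class GeneSimSpec:
    """One panel gene to simulate: symbol, MOI, NHS membership, variant count."""

    symbol: str
    moi: Moi
    nhs_panel: bool
    n_variants: int


def default_gene_panel(
    n_nhs: int = 27,
    n_extended_only: int = 51,
    variants_per_gene: int = 8,
    recessive_fraction: float = 1 / 3,
) -> List[GeneSimSpec]:
    """The default 78-gene simulated panel (27 NHS + 51 extended-only).

    Every third gene is recessive by default, giving both MOI regimes in both
    scopes; 8 variants per gene yields ~600 panel variants.
    """
    genes: List[GeneSimSpec] = []
    period = max(2, round(1 / recessive_fraction)) if recessive_fraction > 0 else 0
    for i in range(n_nhs + n_extended_only):
        moi = Moi.RECESSIVE if (period and i % period == period - 1) else Moi.DOMINANT
        genes.append(
            GeneSimSpec(
                symbol=f"GENE{i + 1:03d}",
                moi=moi,
                nhs_panel=i < n_nhs,
                n_variants=variants_per_gene,
            )
        )
    return genes


#: CADD-PHRED mixture: (weight, low, high) uniform components spanning the
#: 15/20/25 threshold sweep, with most mass above 20 as on a deleteriousness-
#: prioritised array.
DEFAULT_CADD_MIXTURE: Tuple[Tuple[float, float, float], ...] = (
    (0.15, 0.0, 15.0),
    (0.25, 15.0, 20.0),
    (0.35, 20.0, 25.0),
    (0.25, 25.0, 40.0),
)

#: consequence mix of annotated panel variants; carried variants in the study
#: were overwhelmingly missense with small frameshift/stop-gain fractions.
DEFAULT_CONSEQUENCE_MIX: Tuple[Tuple[Consequence, float], ...] = (
    (Consequence.MISSENSE, 0.85),
    (Consequence.FRAMESHIFT, 0.05),
    (Consequence.STOP_GAIN, 0.03),
    (Consequence.SPLICE, 0.03),
    (Consequence.INTRONIC, 0.03),
    (Consequence.OTHER, 0.01),
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults emulate the study's cohort scale.

    ``n_samples`` counts unique participants; ``n_duplicates`` QC copies are
    appended on top (1,744 + 22 = 1,766 genotyped, and with the default 25
    metric failures and 5 sex-discordant samples the QC ledger retains
    1,714). ``carrier_freq``, when None, is drawn per variant log-uniformly
    between the singleton frequency 1/(2·n_samples) and 0.005, which makes
    most carried variants singletons.
    """

    seed: int = 0
    n_samples: int = 1744
    genes: Tuple[GeneSimSpec, ...] = tuple(default_gene_panel())
    carrier_freq: Optional[float] = None
    hom_fraction: float = 0.05
    cadd_mixture: Tuple[Tuple[float, float, float], ...] = DEFAULT_CADD_MIXTURE
    consequence_mix: Tuple[Tuple[Consequence, float], ...] = DEFAULT_CONSEQUENCE_MIX
    planted_pair: Optional[Tuple[str, str, float]] = None  # (gene_a, gene_b, joint multiplier)
    missing_rate: float = 0.001
    n_duplicates: int = 22
    dup_discordance: float = 0.003
    n_sex_discordant: int = 5
    n_metric_fail: int = 25
    dqc_min: float = 0.82

    def __post_init__(self) -> None:
        for name in ("hom_fraction", "missing_rate", "dup_discordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.carrier_freq is not None and not 0.0 <= self.carrier_freq <= 1.0:
            raise ValidationError(f"carrier_freq must lie in [0, 1], got {self.carrier_freq}")
        if self.n_duplicates > self.n_samples:
            raise ValidationError("n_duplicates cannot exceed n_samples")
        if self.n_metric_fail + self.n_sex_discordant > self.n_samples:
            raise ValidationError("more QC defects requested than samples")
        symbols = {g.symbol for g in self.genes}
        if len(symbols) != len(self.genes):
            raise ValidationError("duplicate gene symbol in simulated panel")
        if self.planted_pair is not None:
            a, b, mult = self.planted_pair
            if a not in symbols or b not in symbols or a == b:
                raise ValidationError(f"planted_pair genes must be two distinct panel genes, got {a!r}, {b!r}")
            if mult < 0:
                raise ValidationError("planted_pair multiplier must be non-negative")


@dataclass
class SimulatedCohort:
    """Everything the generator emits, plus the ground truth it planted."""

    matrix: GenotypeMatrix
    variants: List[VariantRecord]
    panel: List[GeneSpec]
    samples: List[SampleRecord]
    truth: Dict

    @property
    def duplicate_pairs(self) -> List[Tuple[str, str]]:
        return [tuple(p) for p in self.truth["duplicate_pairs"]]


def _stream(config: SimConfig, which: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), which])


def _choice(rng: np.random.Generator, options, weights) -> object:
    return options[rng.choice(len(options), p=np.asarray(weights) / np.sum(weights))]


def _simulate_variant_table(config: SimConfig, freqs: np.ndarray) -> List[VariantRecord]:
    rng = _stream(config, _STREAM_ANNOTATION)
    weights = np.array([w for w, _, _ in config.cadd_mixture])
    cons_opts = [c for c, _ in config.consequence_mix]
    cons_w = [w for _, w in config.consequence_mix]
    records: List[VariantRecord] = []
    idx = 0
    for gi, gene in enumerate(config.genes):
        chrom = str(gi % 22 + 1)
        for vi in range(gene.n_variants):
            comp = int(rng.choice(len(weights), p=weights / weights.sum()))
            _, lo, hi = config.cadd_mixture[comp]
            cadd = float(rng.uniform(lo, hi))
            consequence = _choice(rng, cons_opts, cons_w)
            if consequence in (Consequence.FRAMESHIFT, Consequence.STOP_GAIN):
                loftee = Loftee.HC if rng.random() < 0.9 else Loftee.LC
            else:
                loftee = Loftee.NOT_APPLICABLE
            sift = _choice(rng, [Sift.DAMAGING, Sift.TOLERATED, Sift.MISSING], [0.7, 0.25, 0.05])
            polyphen = _choice(
                rng,
                [PolyPhen.PROBABLY_DAMAGING, PolyPhen.POSSIBLY_DAMAGING, PolyPhen.BENIGN, PolyPhen.MISSING],
                [0.6, 0.2, 0.15, 0.05],
            )
            source = _choice(rng, [Source.HGMD, Source.GNOMAD, Source.BOTH], [0.2, 0.75, 0.05])
            ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
            records.append(
                VariantRecord(
                    variant_id=f"var{idx + 1:05d}",
                    chrom=chrom,
                    pos=1_000_000 * (gi + 1) + 100 * vi + 1,
                    ref=ref,
                    alt=alt,
                    gene=gene.symbol,
                    consequence=consequence,
                    cadd_phred=round(cadd, 2),
                    sift=sift,
                    polyphen=polyphen,
                    loftee=loftee,
                    maf=float(freqs[idx]) / 2.0,
                    source=source,
                )
            )
            idx += 1
    return records


def _true_groups(
    dosage: np.ndarray,
    variants: Sequence[VariantRecord],
    moi_by_gene: Dict[str, Moi],
    cadd_min: float = 15.0,
) -> List[int]:
    """Ground-truth group per sample, computed directly from the raw draws."""
    qualifying = [
        j
        for j, v in enumerate(variants)
        if v.consequence is not Consequence.INTRONIC
        and v.cadd_phred >= cadd_min
        and v.loftee is not Loftee.LC
    ]
    groups: List[int] = []
    for i in range(dosage.shape[0]):
        carried = [(variants[j], int(dosage[i, j])) for j in qualifying if dosage[i, j] in (1, 2)]
        if not carried:
            groups.append(1)
        elif any(
            moi_by_gene[v.gene] is Moi.DOMINANT
            or (moi_by_gene[v.gene] is Moi.RECESSIVE and d == 2)
            for v, d in carried
        ):
            groups.append(3)
        else:
            groups.append(2)
    return groups


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a complete, schema-valid synthetic cohort.

    Deterministic for a given seed. Per-variant carriers are independent
    Bernoulli draws at each variant's carrier frequency, except the designated
    first variants of a planted gene pair, whose joint carriage probability is
    the product of marginals times the planted multiplier (capped at the
    smaller marginal, with a warning when the cap binds). The returned truth
    record stores every planted quantity, including each sample's true group
    at the reference threshold (CADD 15, extended panel).
    """
    n = config.n_samples
    m = sum(g.n_variants for g in config.genes)
    rng = _stream(config, _STREAM_GENOTYPES)

    if config.carrier_freq is not None:
        freqs = np.full(m, float(config.carrier_freq))
    else:
        lo = 1.0 / (2 * n)
        hi = max(0.005, lo)  # small test cohorts: range degenerates to the singleton freq
        freqs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))

    gene_of = np.concatenate(
        [np.full(g.n_variants, gi) for gi, g in enumerate(config.genes)]
    ) if m else np.empty(0, dtype=int)
    moi_of = np.array([config.genes[gi].moi is Moi.RECESSIVE for gi in gene_of])

    carrier = rng.random((n, m)) < freqs[None, :]

    planted_cols: Optional[Tuple[int, int]] = None
    if config.planted_pair is not None:
        ga, gb, mult = config.planted_pair
        sym_index = {g.symbol: gi for gi, g in enumerate(config.genes)}
        ca = int(np.flatnonzero(gene_of == sym_index[ga])[0])
        cb = int(np.flatnonzero(gene_of == sym_index[gb])[0])
        planted_cols = (ca, cb)
        fa, fb = float(freqs[ca]), float(freqs[cb])
        p_joint = mult * fa * fb
        cap = min(fa, fb)
        if p_joint > cap:
            log.warning(
                "planted joint probability %.3g exceeds min marginal %.3g; capped", p_joint, cap
            )
            p_joint = cap
        u = rng.random(n)
        both = u < p_joint
        only_a = (u >= p_joint) & (u < fa)
        only_b = (u >= fa) & (u < fa + fb - p_joint)
        carrier[:, ca] = both | only_a
        carrier[:, cb] = both | only_b

    dosage = carrier.astype(np.int8)
    hom = carrier & moi_of[None, :] & (rng.random((n, m)) < config.hom_fraction)
    dosage[hom] = 2
    miss = rng.random((n, m)) < config.missing_rate
    dosage[miss] = MISSING

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    variants = _simulate_variant_table(config, freqs)
    if planted_cols is not None:
        # the planting guarantee: designated pair variants always qualify at
        # every sweep threshold, so the planted signal is never silently
        # removed by the annotation filters
        for col in planted_cols:
            v = variants[col]
            variants[col] = replace(
                v,
                consequence=Consequence.MISSENSE,
                cadd_phred=max(v.cadd_phred, 30.0),
                sift=Sift.DAMAGING,
                polyphen=PolyPhen.PROBABLY_DAMAGING,
                loftee=Loftee.NOT_APPLICABLE,
            )
    panel = [
        GeneSpec(gene=g.symbol, moi=g.moi, nhs_panel=g.nhs_panel, extended_panel=True)
        for g in config.genes
    ]
    matrix = GenotypeMatrix(sample_ids, [v.variant_id for v in variants], dosage)

    moi_by_gene = {g.symbol: g.moi for g in config.genes}
    true_groups = _true_groups(dosage, variants, moi_by_gene)

    # sample metadata with planted QC defects (disjoint defect sets)
    drng = _stream(config, _STREAM_DEFECTS)
    defect_ids = drng.choice(n, size=config.n_metric_fail + config.n_sex_discordant, replace=False)
    metric_fail = set(defect_ids[: config.n_metric_fail].tolist())
    sex_disc = set(defect_ids[config.n_metric_fail:].tolist())
    samples: List[SampleRecord] = []
    for i, sid in enumerate(sample_ids):
        reported = Sex.F if drng.random() < 0.5 else Sex.M
        genetic = reported
        if i in sex_disc:
            genetic = Sex.M if reported is Sex.F else Sex.F
        dqc = float(drng.uniform(0.5, config.dqc_min - 1e-4)) if i in metric_fail else float(
            drng.uniform(0.9, 0.999)
        )
        samples.append(
            SampleRecord(
                sample_id=sid,
                cohort="synthetic",
                reported_sex=reported,
                genetic_sex=genetic,
                dqc=round(dqc, 4),
            )
        )

    truth: Dict = {
        "seed": int(config.seed),
        "carrier_freq": freqs.tolist(),
        "group": dict(zip(sample_ids, true_groups)),
        "metric_fail_samples": sorted(sample_ids[i] for i in metric_fail),
        "sex_discordant_samples": sorted(sample_ids[i] for i in sex_disc),
        "duplicate_pairs": [],
    }
    if planted_cols is not None:
        ca, cb = planted_cols
        truth["planted_pair"] = {
            "gene_a": config.planted_pair[0],
            "gene_b": config.planted_pair[1],
            "multiplier": float(config.planted_pair[2]),
            "variant_a": variants[ca].variant_id,
            "variant_b": variants[cb].variant_id,
        }

    cohort = SimulatedCohort(matrix=matrix, variants=variants, panel=panel, samples=samples, truth=truth)
    if config.n_duplicates:
        matrix, pairs = simulate_duplicates(matrix, config)
        by_id = {s.sample_id: s for s in samples}
        for primary, copy in pairs:
            src = by_id[primary]
            samples.append(
                replace(
                    src,
                    sample_id=copy,
                    duplicate_of=primary,
                    dqc=src.dqc if (src.dqc or 1.0) >= config.dqc_min else 0.95,
                )
            )
        cohort.matrix = matrix
        truth["duplicate_pairs"] = [list(p) for p in pairs]
    return cohort


def simulate_duplicates(
    matrix: GenotypeMatrix, config: SimConfig
) -> Tuple[GenotypeMatrix, List[Tuple[str, str]]]:
    """Append perturbed copies of randomly chosen samples as QC duplicates.

    Each non-missing call of a copy is independently replaced by a different
    dosage code with probability ``dup_discordance``, so the expected
    concordance measured over non-missing positions is 1 − dup_discordance.
    Returns the augmented matrix and the (primary, copy) pair list.
    """
    if config.n_duplicates == 0:
        return matrix, []
    if config.n_duplicates > matrix.n_samples:
        raise ValidationError("n_duplicates cannot exceed the number of samples")
    rng = _stream(config, _STREAM_DUPLICATES)
    chosen = rng.choice(matrix.n_samples, size=config.n_duplicates, replace=False)
    rows = []
    pairs: List[Tuple[str, str]] = []
    for i in sorted(int(c) for c in chosen):
        primary = matrix.sample_ids[i]
        copy_id = f"{primary}__dup"
        row = matrix.dosage[i].copy()
        flip = (rng.random(row.size) < config.dup_discordance) & (row != MISSING)
        for j in np.flatnonzero(flip):
            others = [c for c in (0, 1, 2) if c != row[j]]
            row[j] = others[int(rng.integers(len(others)))]
        rows.append(row)
        pairs.append((primary, copy_id))
    dosage = np.vstack([matrix.dosage] + [r[None, :] for r in rows])
    sample_ids = matrix.sample_ids + [c for _, c in pairs]
    return GenotypeMatrix(sample_ids, matrix.variant_ids, dosage), pairs
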