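"""Readers and writers for the pipeline's plain-text artifacts.

All tabular artifacts are UTF-8, tab-delimited TSV with a header row and the
literal string ``NA`` for missing cells. Genotypes may alternatively be read
from a bi-allelic VCF (only the GT field is consumed). Writers and readers
round-trip bit-exactly for dosage codes, symbols and flags.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    MISSING,
    Consequence,
    GeneSpec,
    GenotypeMatrix,
    Loftee,
    Moi,
    PolyPhen,
    SampleRecord,
    SchemaError,
    Sex,
    Sift,
    Source,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger(__name__)

NA = "NA"

#: canonical column names of the variant table; a ``schema`` mapping may rename them
VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "cadd_phred",
    "sift",
    "polyphen",
    "loftee",
    "maf",
    "source",
]

_GT_CODES = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
             "1/1": 2, "1|1": 2, "./.": MISSING, ".|.": MISSING, ".": MISSING}


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise SchemaError(f"{path}: malformed TSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _cell(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in ("", NA) else value


def read_variant_table(path, schema: Optional[Dict[str, str]] = None) -> List[VariantRecord]:
    """Read an annotated variant table.

    Parameters
    ----------
    path
        TSV file with one row per variant.
    schema
        Optional mapping of canonical field name -> column name in the file,
        for tables produced with different headers. Unmapped fields use the
        canonical name.

    Unknown consequence strings map to ``other``; blank/``NA`` score cells map
    to the respective ``missing`` value. Row-level parse failures report the
    1-based data line number.
    """
    schema = dict(schema or {})
    colname = {f: schema.get(f, f) for f in VARIANT_COLUMNS}
    df = _read_tsv(path)
    _require_columns(df, list(colname.values()), path)

    records: List[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        get = lambda f: _cell(getattr(row, colname[f]))  # noqa: E731
        try:
            maf_cell = get("maf")
            cadd_cell = get("cadd_phred")
            sift = get("sift")
            polyphen = get("polyphen")
            loftee = get("loftee")
            source = get("source")
            records.append(
                VariantRecord(
                    variant_id=get("variant_id") or "",
                    chrom=get("chrom") or "",
                    pos=int(get("pos")),
                    ref=get("ref") or "",
                    alt=get("alt") or "",
                    gene=get("gene") or "",
                    consequence=Consequence.from_string(get("consequence") or "other"),
                    cadd_phred=float(cadd_cell) if cadd_cell is not None else 0.0,
                    sift=Sift(sift) if sift is not None else Sift.MISSING,
                    polyphen=PolyPhen(polyphen) if polyphen is not None else PolyPhen.MISSING,
                    loftee=Loftee(loftee) if loftee is not None else Loftee.NOT_APPLICABLE,
                    maf=float(maf_cell) if maf_cell is not None else None,
                    source=Source(source) if source is not None else Source.GNOMAD,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: data line {i}: {exc}") from exc
    return records


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "cadd_phred": repr(float(v.cadd_phred)),
                "sift": NA if v.sift is Sift.MISSING else v.sift.value,
                "polyphen": NA if v.polyphen is PolyPhen.MISSING else v.polyphen.value,
                "loftee": v.loftee.value,
                "maf": NA if v.maf is None else repr(float(v.maf)),
                "source": v.source.value,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV (sample_id + one column per variant) or VCF.

    TSV cells hold dosage codes 0/1/2 or ``NA``. For VCF, only the GT field is
    consumed and multi-allelic sites are rejected (split them upstream, e.g.
    ``bcftools norm -m-``).
    """
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotype_tsv(path) -> GenotypeMatrix:
    df = _read_tsv(path)
    if df.columns[0] != "sample_id":
        raise SchemaError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample_id(s): {', '.join(dupes)}")
    variant_ids = df.columns[1:].tolist()
    body = df.iloc[:, 1:].to_numpy(dtype=object)
    dosage = np.empty(body.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(body):
        cell = str(cell).strip()
        if cell in ("", NA):
            dosage[i, j] = MISSING
        elif cell in ("0", "1", "2"):
            dosage[i, j] = int(cell)
        else:
            raise ValidationError(
                f"{path}: data line {i + 1}, column {variant_ids[j]}: bad dosage {cell!r}"
            )
    return GenotypeMatrix(sample_ids, variant_ids, dosage)


def _read_genotype_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    variant_ids: List[str] = []
    columns: List[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{path}: multi-allelic site at {rec.CHROM}:{rec.POS}; "
                "pre-split to bi-allelic records (e.g. bcftools norm -m-)"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variant_ids.append(vid)
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            alleles = [a for a in g[:-1]]
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = int(sum(1 for a in alleles if a == 1))
        columns.append(col)
    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, variant_ids, dosage)


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    cells = matrix.dosage.astype(object)
    cells[matrix.dosage == MISSING] = NA
    df = pd.DataFrame(cells, columns=matrix.variant_ids)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, sep="\t", index=False)


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(value: str, path, line: int, column: str) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"{path}: data line {line}: column {column}: expected true/false, got {value!r}"
        ) from None


def read_gene_panel(path) -> List[GeneSpec]:
    """Read the gene panel (columns: gene, moi, nhs_panel[, extended_panel]).

    MOI values outside {dominant, recessive} are rejected: X-linked or other
    inheritance regimes are not modelled. NHS-panel genes are implicitly part
    of the extended panel.
    """
    df = _read_tsv(path)
    _require_columns(df, ["gene", "moi", "nhs_panel"], path)
    has_ext = "extended_panel" in df.columns
    specs: List[GeneSpec] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        gene = row.gene.strip()
        if gene in seen:
            raise ValidationError(f"{path}: duplicate gene symbol {gene!r} (data line {i})")
        seen.add(gene)
        try:
            moi = Moi(row.moi.strip().lower())
        except ValueError:
            raise ValidationError(
                f"{path}: data line {i}: unsupported moi {row.moi!r}; "
                "only 'dominant' and 'recessive' are modelled"
            ) from None
        nhs = _parse_bool(row.nhs_panel, path, i, "nhs_panel")
        ext = _parse_bool(row.extended_panel, path, i, "extended_panel") if has_ext else True
        specs.append(GeneSpec(gene=gene, moi=moi, nhs_panel=nhs, extended_panel=ext or nhs))
    return specs


def write_gene_panel(panel: Sequence[GeneSpec], path) -> None:
    df = pd.DataFrame(
        {
            "gene": [g.gene for g in panel],
            "moi": [g.moi.value for g in panel],
            "nhs_panel": [str(g.nhs_panel).lower() for g in panel],
            "extended_panel": [str(g.extended_panel).lower() for g in panel],
        }
    )
    df.to_csv(path, sep="\t", index=False)


SAMPLE_COLUMNS = [
    "sample_id",
    "cohort",
    "reported_sex",
    "genetic_sex",
    "dqc",
    "duplicate_of",
    "relatedness_flag",
    "het_outlier_flag",
]


def read_sample_table(path) -> List[SampleRecord]:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id"], path)
    records: List[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        get = lambda c, default=None: _cell(str(d.get(c, ""))) or default  # noqa: E731
        dqc = get("dqc")
        records.append(
            SampleRecord(
                sample_id=get("sample_id") or "",
                cohort=get("cohort", "cohort"),
                reported_sex=Sex(get("reported_sex", "missing")),
                genetic_sex=Sex(get("genetic_sex", "missing")),
                dqc=float(dqc) if dqc is not None else None,
                duplicate_of=get("duplicate_of"),
                relatedness_flag=_parse_bool(get("relatedness_flag", "false"), path, i, "relatedness_flag"),
                het_outlier_flag=_parse_bool(get("het_outlier_flag", "false"), path, i, "het_outlier_flag"),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample_id in sample table")
    return records


def write_sample_table(samples: Sequence[SampleRecord], path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "cohort": s.cohort,
                "reported_sex": s.reported_sex.value,
                "genetic_sex": s.genetic_sex.value,
                "dqc": NA if s.dqc is None else repr(float(s.dqc)),
                "duplicate_of": s.duplicate_of or NA,
                "relatedness_flag": str(s.relatedness_flag).lower(),
                "het_outlier_flag": str(s.het_outlier_flag).lower(),
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_run_config(path) -> dict:
    """Load a YAML run config referencing the input artifact paths."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: run config must be a YAML mapping")
    return cfg
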