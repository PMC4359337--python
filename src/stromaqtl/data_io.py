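"""Readers and writers for genotype, expression, annotation and result tables.

All tabular files are tab-delimited UTF-8 text; lines starting with ``#`` are
metadata comments.  Genotypes may also arrive as a minimal diploid VCF, in
which case dosages are counted for a designated risk allele (ALT by default).
The module also ships, as a packaged fixture, the published table of 47
consensus SNP-transcript associations found in prostate tumor-adjacent
stroma, together with a summariser that reports its headline counts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    AssociationTable,
    DataFormatError,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleAnnotation,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "average_replicates",
    "load_association_fixture",
    "summarize_associations",
    "AssociationSummary",
    "write_results",
    "read_results",
]

_MISSING_TOKENS = ("NA", "NaN", "nan", ".", "")

#: SHA-256 of the packaged association fixture; guards against silent corruption.
_FIXTURE_SHA256 = "825aeb0102fdcf9239e5b5063f4172cdfeef24c41f0eb32a46dd5c66bee020e3"


def _read_tsv_matrix(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, comment="#", na_values=list(_MISSING_TOKENS),
            keep_default_na=False, dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{what} file is empty: {path}") from None
    if df.shape[1] == 0:
        raise DataFormatError(f"{what} file has no data columns: {path}")
    df.index.name = None
    df.columns.name = None
    return df


def _to_float(df: pd.DataFrame, what: str) -> pd.DataFrame:
    def conv(col: pd.Series) -> pd.Series:
        try:
            return col.astype(float)
        except ValueError:
            for sample, raw in col.items():
                try:
                    float(raw)
                except (TypeError, ValueError):
                    if pd.isna(raw):
                        continue
                    raise DataFormatError(
                        f"non-numeric {what} value {raw!r} at sample {sample!r}, "
                        f"column {col.name!r}"
                    ) from None
            raise

    return df.apply(conv)


def read_genotypes(path, format_hint: str | None = None,
                   risk_allele: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read a genotype dosage matrix from a TSV matrix or a minimal VCF.

    TSV layout: samples in rows, SNPs in columns, header row of SNP ids,
    entries in {0, 1, 2} or a missing token (``NA``/``.``).  VCF: diploid GT
    per sample, dosage = count of the risk allele (ALT unless ``risk_allele``
    overrides for that SNP id).
    """
    path = Path(path)
    fmt = (format_hint or ("vcf" if path.suffix.lower() == ".vcf" else "tsv")).lower()
    if fmt == "vcf":
        return _read_genotypes_vcf(path, risk_allele)
    df = _to_float(_read_tsv_matrix(path, "genotype"), "genotype")
    return GenotypeMatrix(dosages=df, risk_allele=dict(risk_allele or {}))


def _read_genotypes_vcf(path: Path, risk_allele: Mapping[str, str] | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise DataFormatError(f"genotype file not found: {path}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    risk_allele = dict(risk_allele or {})
    cols: dict[str, np.ndarray] = {}
    alleles: dict[str, str] = {}
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in cols:
            raise DataFormatError(f"duplicate SNP id {snp_id!r} in VCF {path}")
        if len(var.ALT) != 1:
            raise DataFormatError(f"SNP {snp_id!r}: multi-allelic records not supported")
        target = risk_allele.get(snp_id, var.ALT[0])
        if target == var.ALT[0]:
            code = 1
        elif target == var.REF:
            code = 0
        else:
            raise DataFormatError(
                f"SNP {snp_id!r}: risk allele {target!r} is neither REF nor ALT"
            )
        dosages = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            calls = [a for a in gt[:-1] if a is not None]
            if len(calls) != 2:
                if all(a in (-1, None) for a in gt[:-1]):
                    continue  # missing genotype
                raise DataFormatError(
                    f"SNP {snp_id!r}, sample {samples[i]!r}: non-diploid GT {gt[:-1]}"
                )
            if any(a == -1 for a in calls):
                continue
            dosages[i] = sum(1 for a in calls if a == code)
        cols[snp_id] = dosages
        alleles[snp_id] = target
    if not cols:
        raise DataFormatError(f"VCF {path} contains no variant records")
    df = pd.DataFrame(cols, index=samples)
    return GenotypeMatrix(dosages=df, risk_allele=alleles)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.dosages.copy()
    # integers where possible, NA for missing
    out = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)) if float(v).is_integer() else str(v))
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path) -> ExpressionMatrix:
    """Read a samples x transcripts log-expression TSV matrix."""
    df = _to_float(_read_tsv_matrix(path, "expression"), "expression")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise DataFormatError(
            f"missing expression value at sample {df.index[i]!r}, "
            f"transcript {df.columns[j]!r}"
        )
    return ExpressionMatrix(values=df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


_ANNOT_NUMERIC = ("stroma_pct", "tumor_pct", "followup_time", "gleason_sum",
                  "pre_psa", "age")


def read_annotations(path) -> SampleAnnotation:
    df = _read_tsv_matrix(path, "annotation")
    for col in df.columns:
        if col in _ANNOT_NUMERIC:
            df[col] = df[col].astype(float)
    return SampleAnnotation(table=df)


def write_annotations(annot: SampleAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def average_replicates(expr: ExpressionMatrix,
                       replicate_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse biological replicate arrays to one row per patient.

    ``replicate_map`` assigns every array sample id to a patient id; a
    patient's expression row is the arithmetic mean of their replicate rows.
    Patients with a single array pass through unchanged.
    """
    missing = [s for s in expr.sample_ids if s not in replicate_map]
    if missing:
        raise DataFormatError(
            f"array samples absent from replicate map: {missing[:5]}"
        )
    patients = pd.Series({s: replicate_map[s] for s in expr.sample_ids})
    grouped = expr.values.groupby(patients).mean()
    # preserve first-appearance order of patients
    order = patients.drop_duplicates().tolist()
    return ExpressionMatrix(values=grouped.loc[order])


def load_association_fixture() -> AssociationTable:
    """Load the packaged table of 47 published stroma trans-eQTL associations.

    The fixture is verified against a SHA-256 checksum; a missing or modified
    file is rejected rather than silently summarised.
    """
    ref = resources.files("stromaqtl").joinpath("data/table2_associations.tsv")
    try:
        raw = ref.read_bytes()
    except FileNotFoundError:
        raise DataFormatError("association fixture is missing from the package") from None
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise DataFormatError(
            f"association fixture is corrupt (sha256 {digest[:12]}..., "
            f"expected {_FIXTURE_SHA256[:12]}...)"
        )
    from io import StringIO

    df = pd.read_csv(StringIO(raw.decode("utf-8")), sep="\t", dtype=str)
    df["association_id"] = df["association_id"].astype(int)
    return AssociationTable(table=df)


@dataclass
class AssociationSummary:
    """Headline counts of an association table (reported, never recomputed)."""

    total: int
    n_snps: int
    n_transcripts: int
    per_snp: dict = field(default_factory=dict)


def summarize_associations(table: AssociationTable) -> AssociationSummary:
    df = table.table
    per_snp = df.groupby("snp_id", sort=False)["probe_set"].count().to_dict()
    return AssociationSummary(
        total=len(df),
        n_snps=df["snp_id"].nunique(),
        n_transcripts=df["probe_set"].nunique(),
        per_snp=per_snp,
    )


def write_results(consensus, permutation_summaries, path, metadata: Mapping | None = None) -> None:
    """Write a consensus call table (plus optional resampling summaries) as TSV.

    Layout mirrors the published association table: one row per consensus
    call with per-stratum support columns.  Run metadata (config, seeds,
    versions) and any resampling summaries are emitted as ``#`` comment lines
    so the file re-parses as a plain TSV.
    """
    from . import __version__

    path = Path(path)
    labels = consensus.stratum_labels
    lines = [f"# stromaqtl {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    for summ in permutation_summaries or []:
        lines.append(
            f"# resampling scheme={summ.scheme} n_reps={summ.n_reps} "
            f"mean_false={summ.mean_false:.4f} n_observed={summ.n_observed} "
            f"fdr_pct={summ.fdr_pct_display}"
        )
    header = ["association_id", "snp_id", "transcript_id"] + [
        f"support_{lab}" for lab in labels
    ]
    lines.append("\t".join(header))
    for i, (snp, transcript) in enumerate(consensus.calls, start=1):
        supports = [
            f"{consensus.per_stratum_support[(snp, transcript, lab)]:.6g}"
            for lab in labels
        ]
        lines.append("\t".join([str(i), snp, transcript] + supports))
    try:
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise DataFormatError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    """Re-parse a ``write_results`` file into a DataFrame (comments skipped)."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"results file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "transcript_id": str})
    return df
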