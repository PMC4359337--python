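"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas DataFrames with sample identifiers on the
row index. Containers validate their invariants on construction so that
downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "SampleAnnotation",
    "AssociationTable",
    "DataFormatError",
]


class DataFormatError(ValueError):
    """Raised when input data violate a format or invariant contract."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Additive risk-allele dosages, samples in rows and SNPs in columns.

    Entries are counts of the designated risk allele (0, 1 or 2); missing
    genotypes are NaN.  ``risk_allele`` optionally maps each SNP id to the
    base counted as the risk allele.  Matrices that have passed through
    mean-imputation carry ``imputed=True`` and may hold fractional dosages
    in [0, 2].
    """

    dosages: pd.DataFrame
    risk_allele: dict = field(default_factory=dict)
    imputed: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "sample")
        _check_unique(self.dosages.columns, "SNP")
        vals = self.dosages.to_numpy(dtype=float)
        if self.imputed:
            ok = (vals >= 0.0) & (vals <= 2.0)
        else:
            ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataFormatError(
                f"dosage for sample {self.dosages.index[i]!r}, SNP "
                f"{self.dosages.columns[j]!r} is {vals[i, j]!r}; expected 0, 1, 2 or missing"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, samples in rows and transcripts in columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "transcript")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise DataFormatError(
                f"non-finite expression value for sample {self.values.index[i]!r}, "
                f"transcript {self.values.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def transcript_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[1]


#: Allowed relapse flags in annotation tables.
RELAPSE_LEVELS = ("yes", "no", "unknown")


@dataclass
class SampleAnnotation:
    """Per-sample tissue composition, outcome, and clinical covariates.

    Required columns: ``stroma_pct``; recognised optional columns:
    ``tumor_pct``, ``relapse`` (yes/no/unknown), ``followup_time`` and any
    clinical covariates (Gleason sum, pre-operative PSA, stage, age, margin
    status).  Sample ids live on the index.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        if "stroma_pct" not in self.table.columns:
            raise DataFormatError("annotation table lacks required column 'stroma_pct'")
        s = self.table["stroma_pct"].astype(float)
        if ((s < 0) | (s > 100)).any():
            bad = self.table.index[(s < 0) | (s > 100)][0]
            raise DataFormatError(f"stroma_pct out of [0, 100] for sample {bad!r}")
        if "tumor_pct" in self.table.columns:
            t = self.table["tumor_pct"].astype(float)
            both = s.notna() & t.notna()
            if ((s[both] + t[both]) > 100 + 1e-9).any():
                bad = s[both].index[(s[both] + t[both]) > 100 + 1e-9][0]
                raise DataFormatError(
                    f"stroma_pct + tumor_pct exceeds 100 for sample {bad!r}"
                )
        if "relapse" in self.table.columns:
            levels = set(self.table["relapse"].dropna().unique())
            unknown = levels - set(RELAPSE_LEVELS)
            if unknown:
                raise DataFormatError(f"unrecognised relapse flags: {sorted(unknown)}")
            if "followup_time" in self.table.columns:
                known = self.table["relapse"].isin(("yes", "no"))
                if self.table.loc[known, "followup_time"].isna().any():
                    bad = self.table.index[
                        known & self.table["followup_time"].isna()
                    ][0]
                    raise DataFormatError(
                        f"followup_time missing for sample {bad!r} with known relapse status"
                    )

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)


@dataclass
class AssociationTable:
    """Flat table of called SNP-transcript associations.

    Columns: ``association_id`` (contiguous from 1), ``probe_set``,
    ``gene_symbol``, ``gene_location``, ``snp_id``, ``risk_allele``,
    ``snp_locus``.
    """

    table: pd.DataFrame

    REQUIRED = (
        "association_id",
        "probe_set",
        "gene_symbol",
        "gene_location",
        "snp_id",
        "risk_allele",
        "snp_locus",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"association table lacks columns {missing}")
        ids = self.table["association_id"].astype(int)
        expected = list(range(1, len(ids) + 1))
        if sorted(ids) != expected:
            raise DataFormatError(
                "association_id must be unique and contiguous from 1"
            )
        for col in ("probe_set", "snp_id"):
            if (self.table[col].astype(str).str.len() == 0).any():
                raise DataFormatError(f"empty {col} entry in association table")

    def __len__(self) -> int:
        return len(self.table)

    def row(self, association_id: int) -> pd.Series:
        hit = self.table[self.table["association_id"] == association_id]
        if hit.empty:
            raise KeyError(f"no association with id {association_id}")
        return hit.iloc[0]
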