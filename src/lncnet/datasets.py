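"""Core data containers for developmental-brain co-expression analysis.

The pipeline operates on three aligned tables:

* an expression matrix (genes x samples, RPKM units or ``log2(RPKM + 1)``),
* per-sample metadata (brain structure, age with unit, developmental period),
* per-gene annotation (biotype, lncRNA flag, ASD-risk flag).

Containers are thin wrappers over :class:`pandas.DataFrame` that validate the
invariants the downstream stages rely on (non-negativity, unique identifiers,
period/age consistency) and tag the expression scale so that RPKM-only
operations cannot silently receive log-transformed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DataError",
    "ConfigurationError",
    "PERIODS",
    "LNCRNA_BIOTYPES",
    "validate_metadata",
    "validate_annotation",
    "age_in_days",
    "period_for_age",
    "chronological_order",
]

#: Developmental periods in chronological order, with their age bins
#: (prenatal 8-37 post-conception weeks, childhood 4 months-15 years,
#: adulthood 18-40 years).
PERIODS = ("prenatal", "childhood", "adulthood")

#: Biotypes treated as long non-coding RNA.
LNCRNA_BIOTYPES = frozenset({"antisense", "lincRNA"})

_GESTATION_DAYS = 280.0  # 40 pcw; postnatal ages are offset by a full term


class DataError(ValueError):
    """Raised when input data violate a contract (negative RPKM, wrong scale...)."""


class ConfigurationError(ValueError):
    """Raised when a parameter is outside its allowed range."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id. All entries must be
        finite and non-negative (RPKM, or log2(RPKM + 1) after transform).
    scale : {"rpkm", "log2"}
        Unit of the values. Operations check this tag; e.g. the minimum
        expression filter only accepts the ``rpkm`` scale.
    """

    values: pd.DataFrame
    scale: str = "rpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "log2"):
            raise ConfigurationError(f"unknown expression scale {self.scale!r}")
        if not self.values.index.is_unique:
            raise DataError("gene identifiers are not unique")
        if not self.values.columns.is_unique:
            raise DataError("sample identifiers are not unique")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise DataError("expression matrix contains non-finite values")
        if arr.size and arr.min() < 0:
            raise DataError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], scale=self.scale)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, scale: str = "rpkm") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale=scale)


def age_in_days(age: float, unit: str) -> float:
    """Map an (age, unit) pair onto a single chronological axis in days.

    Prenatal ages (``pcw``) count from conception; postnatal ages (``mos``,
    ``yrs``) are offset by a 280-day full term so the axis is monotone
    across birth.
    """
    if unit == "pcw":
        return age * 7.0
    if unit == "mos":
        return _GESTATION_DAYS + age * 30.44
    if unit == "yrs":
        return _GESTATION_DAYS + age * 365.25
    raise DataError(f"unknown age unit {unit!r} (expected pcw|mos|yrs)")


def period_for_age(age: float, unit: str) -> str:
    """Developmental period for an age: prenatal 8-37 pcw, childhood
    4 mos-15 yrs, adulthood 18-40 yrs. Ages in the gaps raise
    :class:`DataError`."""
    days = age_in_days(age, unit)
    if 8 * 7 <= days <= 37 * 7:
        return "prenatal"
    if _GESTATION_DAYS + 4 * 30.44 <= days <= _GESTATION_DAYS + 15 * 365.25:
        return "childhood"
    if _GESTATION_DAYS + 18 * 365.25 <= days <= _GESTATION_DAYS + 40 * 365.25:
        return "adulthood"
    raise DataError(f"age {age} {unit} falls outside the defined period bins")


_METADATA_COLUMNS = ("sample_id", "structure", "age", "age_unit", "period")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample metadata table: required columns, unique sample ids,
    known periods, and period/age consistency."""
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in metadata")
    bad = set(meta["period"]) - set(PERIODS)
    if bad:
        raise DataError(f"unknown developmental periods: {sorted(bad)}")
    for _, row in meta.iterrows():
        expected = period_for_age(row["age"], row["age_unit"])
        if expected != row["period"]:
            raise DataError(
                f"sample {row['sample_id']}: age {row['age']} {row['age_unit']} "
                f"implies period {expected!r}, metadata says {row['period']!r}"
            )
    return meta


_ANNOTATION_COLUMNS = ("gene_id", "biotype", "is_lncRNA", "is_asd_risk")


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table; the lncRNA flag must agree with the
    designated lncRNA biotype set."""
    missing = [c for c in _ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise DataError(f"gene annotation missing columns: {missing}")
    if annot["gene_id"].duplicated().any():
        raise DataError("duplicate gene ids in annotation")
    implied = annot["biotype"].isin(LNCRNA_BIOTYPES)
    if not (implied == annot["is_lncRNA"].astype(bool)).all():
        raise DataError("is_lncRNA flag inconsistent with biotype")
    return annot


def chronological_order(meta: pd.DataFrame) -> list:
    """Sample ids sorted by chronological age (ties broken by sample id)."""
    m = meta.copy()
    m["_days"] = [age_in_days(a, u) for a, u in zip(m["age"], m["age_unit"])]
    m = m.sort_values(["_days", "sample_id"], kind="mergesort")
    return list(m["sample_id"])
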