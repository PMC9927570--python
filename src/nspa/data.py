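"""Core containers and text I/O for case-control genotype data.

Genotypes are coded as the count of alternate alleles: 0 (homozygous
reference), 1 (heterozygous), 2 (homozygous alternate). Missing calls are
stored internally as :data:`MISSING` (-1) and accepted on input as ``NA``,
``nan`` or ``-1``. Phenotypes are binary with 1 = case, 0 = control.

Supported on-disk layouts:

* delimited tables (CSV/TSV): one row per subject, header row of rsIDs plus
  a phenotype column, optional leading subject-id column;
* a PLINK ``.raw``-style dialect: whitespace-delimited, six leading sample
  columns (FID IID PAT MAT SEX PHENOTYPE, phenotype coded 1=control /
  2=case) followed by allele-dosage columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PhenotypeVector",
    "Dataset",
    "read_dataset",
    "write_table",
    "read_table",
]

#: Internal code for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})

# Input tokens recognised as missing in delimited files.
_NA_TOKENS = {"NA", "na", "NaN", "nan", ""}


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclasses.dataclass
class GenotypeMatrix:
    """Subjects x variants matrix of allele-count codes.

    Parameters
    ----------
    subject_ids
        Unique, ordered subject identifiers (rows).
    variant_ids
        Unique, ordered variant identifiers / rsIDs (columns).
    codes
        Integer matrix with entries in {0, 1, 2, MISSING}.
    """

    subject_ids: list[str]
    variant_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = _check_unique(self.subject_ids, "subject")
        self.variant_ids = _check_unique(self.variant_ids, "variant")
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D matrix")
        n, m = self.codes.shape
        if n != len(self.subject_ids) or m != len(self.variant_ids):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.codes, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code {self.codes[i, j]} for subject "
                f"{self.subject_ids[i]!r}, variant {self.variant_ids[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls."""
        return self.codes == MISSING

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def subset_variants(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Column subset, preserving the stored order of ``keep``."""
        idx = [self.variant_index(v) for v in keep]
        return GenotypeMatrix(
            list(self.subject_ids),
            [self.variant_ids[i] for i in idx],
            self.codes[:, idx].copy(),
        )

    def subset_subjects(self, rows: np.ndarray) -> "GenotypeMatrix":
        """Row subset by positional index array."""
        rows = np.asarray(rows)
        return GenotypeMatrix(
            [self.subject_ids[i] for i in rows],
            list(self.variant_ids),
            self.codes[rows, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.subject_ids, columns=self.variant_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.codes, other.codes)
        )


@dataclasses.dataclass
class PhenotypeVector:
    """Binary case/control labels aligned to a GenotypeMatrix's subjects."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValidationError("phenotype labels must be 0 (control) or 1 (case)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError("both cases and controls are required")


@dataclasses.dataclass
class Dataset:
    """A genotype matrix with its aligned phenotype.

    ``metadata`` carries provenance (e.g. planted-interaction ids from the
    simulator); it is informational and never consulted by the method itself.
    """

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.phenotype) != self.genotypes.n_subjects:
            raise ValidationError(
                f"phenotype length {len(self.phenotype)} does not match "
                f"{self.genotypes.n_subjects} subjects"
            )

    @property
    def n_subjects(self) -> int:
        return self.genotypes.n_subjects

    @property
    def n_variants(self) -> int:
        return self.genotypes.n_variants

    @property
    def subject_ids(self) -> list[str]:
        return self.genotypes.subject_ids

    @property
    def variant_ids(self) -> list[str]:
        return self.genotypes.variant_ids

    def subset_subjects(self, rows: np.ndarray) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(
            self.genotypes.subset_subjects(rows),
            PhenotypeVector(self.phenotype.labels[rows].copy()),
            dict(self.metadata),
        )

    def subset_variants(self, keep: Sequence[str]) -> "Dataset":
        return Dataset(
            self.genotypes.subset_variants(keep),
            PhenotypeVector(self.phenotype.labels.copy()),
            dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _coerce_codes(df: pd.DataFrame, path: str) -> np.ndarray:
    raw = df.to_numpy()
    out = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = df[col]
        numeric = pd.to_numeric(
            vals.astype(object).map(lambda x: np.nan if str(x).strip() in _NA_TOKENS else x),
            errors="coerce",
        )
        still_bad = numeric.isna() & ~vals.astype(str).str.strip().isin(_NA_TOKENS)
        if still_bad.any():
            i = int(np.argmax(still_bad.to_numpy()))
            raise ValidationError(
                f"{path}: non-numeric genotype {vals.iloc[i]!r} for subject row "
                f"{df.index[i]!r}, variant {col!r}"
            )
        filled = numeric.fillna(MISSING).to_numpy()
        if not np.all(filled == np.floor(filled)):
            i = int(np.argmax(filled != np.floor(filled)))
            raise ValidationError(
                f"{path}: non-integer genotype for subject row {df.index[i]!r}, variant {col!r}"
            )
        col_codes = filled.astype(np.int64)
        bad = ~np.isin(col_codes, list(_VALID_CODES))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"{path}: genotype code {col_codes[i]} out of range for subject "
                f"{df.index[i]!r}, variant {col!r}"
            )
        out[:, j] = col_codes
    return out


def _coerce_phenotype(values: pd.Series, path: str, plink: bool = False) -> np.ndarray:
    y = pd.to_numeric(values, errors="coerce")
    if y.isna().any():
        raise ValidationError(f"{path}: non-numeric phenotype value {values[y.isna()].iloc[0]!r}")
    y = y.to_numpy()
    uniq = set(np.unique(y).tolist())
    if plink and uniq <= {1.0, 2.0}:
        y = y - 1  # PLINK coding: 1=control, 2=case
    if not set(np.unique(y).tolist()) <= {0.0, 1.0}:
        raise ValidationError(f"{path}: phenotype values must be 0/1 (or 1/2 in .raw files)")
    if len(set(np.unique(y).tolist())) < 2:
        raise ValidationError(f"{path}: phenotype contains a single class")
    return y.astype(np.int64)


def read_dataset(
    genotype_path: str | Path,
    fmt: str = "csv",
    phenotype_column: str = "phenotype",
) -> Dataset:
    """Read a genotype/phenotype table into a validated :class:`Dataset`.

    Parameters
    ----------
    genotype_path
        Path to the table.
    fmt
        One of ``csv``, ``tsv`` or ``plink_raw``.
    phenotype_column
        Name of the phenotype column for the delimited layouts (ignored for
        ``plink_raw``, which always uses the PHENOTYPE column).
    """
    path = Path(genotype_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if phenotype_column not in df.columns:
            raise ValidationError(f"{path}: missing phenotype column {phenotype_column!r}")
        first = df.columns[0]
        if first.lower() in ("subject", "subject_id", "sample", "sample_id", "iid", "id"):
            subject_ids = df[first].tolist()
            df = df.drop(columns=[first])
        else:
            subject_ids = [f"S{i}" for i in range(len(df))]
        y = _coerce_phenotype(df[phenotype_column], str(path))
        geno = df.drop(columns=[phenotype_column])
        geno.index = subject_ids
        codes = _coerce_codes(geno, str(path))
        return Dataset(
            GenotypeMatrix(subject_ids, list(geno.columns), codes), PhenotypeVector(y)
        )
    if fmt == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_cols = [c for c in lead if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"{path}: .raw file missing columns {missing_cols}")
        subject_ids = df["IID"].tolist()
        y = _coerce_phenotype(df["PHENOTYPE"], str(path), plink=True)
        geno = df.drop(columns=lead)
        geno.index = subject_ids
        # strip PLINK's _<counted allele> suffix from dosage column names
        variant_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
        geno.columns = variant_ids
        codes = _coerce_codes(geno, str(path))
        return Dataset(
            GenotypeMatrix(subject_ids, variant_ids, codes), PhenotypeVector(y)
        )
    raise ValueError(f"unknown format {fmt!r}; expected csv, tsv or plink_raw")


def write_table(
    frame_or_matrix,
    path: str | Path,
    fmt: str = "csv",
    phenotype: PhenotypeVector | None = None,
) -> None:
    """Write a GenotypeMatrix, transformed matrix or DataFrame as CSV/TSV.

    Missing genotype codes are written as ``NA``. When ``phenotype`` is given
    a ``phenotype`` column is appended, making the output re-readable with
    :func:`read_dataset`.
    """
    sep = "," if fmt == "csv" else "\t"
    if isinstance(frame_or_matrix, GenotypeMatrix):
        df = frame_or_matrix.to_frame().astype(object)
        df = df.mask(df == MISSING, "NA")
    else:
        df = pd.DataFrame(frame_or_matrix)
    if phenotype is not None:
        df = df.copy()
        df["phenotype"] = phenotype.labels
    df.index.name = "subject_id"
    df.to_csv(path, sep=sep)


def read_table(path: str | Path, fmt: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (subject_id index)."""
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, keep_default_na=False, na_values=[])
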