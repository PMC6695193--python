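"""Typed omics containers and flat-file I/O.

All matrices are stored samples-as-rows.  TSV is the exchange format for
matrices and clinical tables, BED (0-based, half-open) for transcription
start site (TSS) annotation, and GMT for named gene sets.  Missing values
are read from empty cells or ``NA`` and always written back as ``NA``.

Sample identifiers are matched exactly after whitespace trimming; no
barcode truncation is attempted, so callers must harmonize cohort barcodes
themselves before joining omics layers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "MatrixParseError",
    "MatrixValidationError",
    "BetaMatrix",
    "OmicsMatrix",
    "ClinicalTable",
    "read_matrix",
    "write_matrix",
    "read_tss_bed",
    "write_tss_bed",
    "read_clinical",
    "read_probe_manifest",
    "read_gmt",
    "align_samples",
]

_NA_STRINGS = {"", "NA", "NaN", "nan"}


class DataError(ValueError):
    """Base class for I/O and validation failures."""


class MatrixParseError(DataError):
    """A cell could not be parsed as a number."""


class MatrixValidationError(DataError):
    """A parsed matrix violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)
        dupes = sorted(set(dupes[dupes.duplicated()]))
        raise MatrixValidationError(f"duplicate {what} id(s): {dupes[:5]}")


@dataclass
class BetaMatrix:
    """Samples x CpG-probe matrix of methylation beta values in [0, 1].

    ``tissue`` holds per-sample labels in {"tumor", "normal"} and ``batch``
    a per-sample categorical processing-batch label; both default to a
    single level when not supplied.
    """

    values: pd.DataFrame
    tissue: pd.Series | None = None
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "probe")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise MatrixValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at sample "
                f"{self.values.index[i]!r}, probe {self.values.columns[j]!r}"
            )
        if self.tissue is None:
            self.tissue = pd.Series("tumor", index=self.values.index)
        else:
            self.tissue = pd.Series(self.tissue).reindex(self.values.index)
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.values.index)
        else:
            self.batch = pd.Series(self.batch).reindex(self.values.index)
        if len(self.tissue) != len(self.values) or len(self.batch) != len(self.values):
            raise MatrixValidationError("tissue/batch length must equal sample count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "BetaMatrix":
        """Rebuild with a new value frame, subsetting metadata to its rows."""
        return BetaMatrix(
            values=values,
            tissue=self.tissue.reindex(values.index),
            batch=self.batch.reindex(values.index),
        )

    def subset_samples(self, ids: Sequence[str]) -> "BetaMatrix":
        return self.with_values(self.values.loc[list(ids)])


@dataclass
class OmicsMatrix:
    """Samples x genes matrix of expression (log counts) or protein
    abundance (log2 relative abundance)."""

    values: pd.DataFrame
    kind: str = "expression"

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "protein"):
            raise MatrixValidationError(f"unknown omics kind {self.kind!r}")
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "gene")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values=values, kind=self.kind)

    def subset_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        return self.with_values(self.values.loc[list(ids)])


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates with declared column types.

    ``column_types`` maps each column to one of ``categorical`` (e.g.
    molecular subtype), ``ordinal`` (integer-coded, monotone in severity,
    e.g. stage or grade) or ``continuous`` (e.g. tumor size).
    """

    table: pd.DataFrame
    column_types: dict[str, str] = field(default_factory=dict)

    _TYPES = ("categorical", "ordinal", "continuous")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col, typ in self.column_types.items():
            if typ not in self._TYPES:
                raise MatrixValidationError(
                    f"clinical column {col!r} has unknown type {typ!r}; "
                    f"expected one of {self._TYPES}"
                )
            if col not in self.table.columns:
                raise MatrixValidationError(f"declared clinical column {col!r} missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def _parse_numeric(raw: pd.DataFrame, path: str) -> pd.DataFrame:
    """Convert a string frame to float, naming the first offending cell."""
    out = {}
    for col in raw.columns:
        s = raw[col].str.strip()
        missing = s.isin(_NA_STRINGS)
        try:
            # astype goes through float(), which is correctly rounded and
            # therefore byte-stable on write -> read -> write round trips
            num = s.where(~missing).astype(float)
        except (ValueError, TypeError):
            for row, val in s.items():
                if missing[row]:
                    continue
                try:
                    float(val)
                except ValueError:
                    raise MatrixParseError(
                        f"{path}: malformed numeric cell {val!r} "
                        f"at row {row!r}, column {col!r}"
                    ) from None
            raise
        out[col] = num
    return pd.DataFrame(out, index=raw.index)


def read_matrix(
    path: str | Path,
    kind: str = "beta",
    transposed: bool = False,
) -> BetaMatrix | OmicsMatrix:
    """Read a TSV matrix (header row of feature ids, first column of sample
    ids; pass ``transposed=True`` for features-as-rows dialects).

    ``kind`` is one of ``beta``, ``expression`` or ``protein``; beta values
    are validated into [0, 1].
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if transposed:
        raw = raw.T
    _check_unique(raw.index, "sample")
    _check_unique(raw.columns, "feature")
    values = _parse_numeric(raw, str(path))
    if kind == "beta":
        return BetaMatrix(values=values)
    return OmicsMatrix(values=values, kind=kind)


def write_matrix(m: BetaMatrix | OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (samples as rows, ``NA`` for missing)."""
    df = m.values
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a one-record-per-gene BED file of transcription start sites.

    The TSS is the interval start on the + strand and interval end - 1 on
    the - strand (BED intervals are 0-based, half-open).  Returns a frame
    indexed by gene id with columns chromosome, tss, strand.
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chromosome", "start", "end", "gene_id", "score", "strand"],
        dtype={"chromosome": str, "gene_id": str, "strand": str},
    )
    if bed["gene_id"].isna().any():
        raise DataError(f"{path}: BED records need a name (gene id) field")
    _check_unique(bed["gene_id"], "gene")
    if (bed["start"] < 0).any():
        raise DataError(f"{path}: negative BED coordinates")
    strand = bed["strand"].fillna("+")
    tss = np.where(strand == "-", bed["end"] - 1, bed["start"])
    out = pd.DataFrame(
        {"chromosome": bed["chromosome"], "tss": tss.astype(int), "strand": strand}
    )
    out.index = pd.Index(bed["gene_id"], name="gene_id")
    return out


def write_tss_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    ann = annotation
    start = np.where(ann["strand"] == "-", ann["tss"], ann["tss"])
    # one-base interval covering the TSS; end-1 == tss on the minus strand
    bed = pd.DataFrame(
        {
            "chromosome": ann["chromosome"],
            "start": start,
            "end": np.asarray(start) + 1,
            "gene_id": ann.index,
            "score": 0,
            "strand": ann["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CpG probe manifest TSV (probe_id, chromosome, position;
    positions 1-based)."""
    man = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    required = {"probe_id", "chromosome", "position"}
    if not required.issubset(man.columns):
        raise DataError(f"{path}: manifest needs columns {sorted(required)}")
    _check_unique(man["probe_id"], "probe")
    man = man.set_index("probe_id")
    man["position"] = man["position"].astype(int)
    return man


def read_clinical(path: str | Path, column_types: dict[str, str]) -> ClinicalTable:
    """Read a clinical TSV with a ``sample_id`` column; ``column_types``
    declares each used column as categorical/ordinal/continuous."""
    df = pd.read_csv(path, sep="\t", na_values=sorted(_NA_STRINGS))
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: clinical table needs a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df = df.set_index("sample_id")
    return ClinicalTable(table=df, column_types=dict(column_types))


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: one tab-delimited line per set
    (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def align_samples(*matrices: BetaMatrix | OmicsMatrix) -> list[str]:
    """Intersect sample ids across omics layers, preserving the order of
    the first matrix.  Mixture fitting may use all tumor methylation
    samples; regression against downstream layers uses only this matched
    subset."""
    if not matrices:
        raise DataError("align_samples needs at least one matrix")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    matched = [s for s in matrices[0].sample_ids if s in common]
    if not matched:
        raise DataError("no samples shared across the supplied matrices")
    return matched
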