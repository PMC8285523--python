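"""Tabular input/output for manifests, intensity matrices, behavior logs and result tables.

All on-disk formats are plain text with headers:

* sample manifest  — CSV, columns ``sample_id,subject_id,species,sex,treatment,body_weight_g``
  (extra columns are preserved as opaque annotations);
* intensity matrix — TSV, column 1 ``accession``, then one column per sample id;
  empty cells and ``NA`` are *missing* (not detected), ``0`` is a real measurement;
* behavior bins    — CSV, columns
  ``subject_id,session_id,bin_index,fr_value,reinforcers_earned,responses,bin_minutes``;
* result tables    — TSV with fixed column order, floats rendered to 6 significant
  digits so repeated runs on identical input are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SampleManifest",
    "IntensityMatrix",
    "read_manifest",
    "read_intensity_matrix",
    "read_behavior_bins",
    "write_tables",
    "MANIFEST_COLUMNS",
    "BIN_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when an input file violates a format invariant."""


MANIFEST_COLUMNS = ["sample_id", "subject_id", "species", "sex", "treatment", "body_weight_g"]
BIN_COLUMNS = [
    "subject_id",
    "session_id",
    "bin_index",
    "fr_value",
    "reinforcers_earned",
    "responses",
    "bin_minutes",
]

SPECIES = frozenset({"mouse", "rat"})
SEXES = frozenset({"male", "female"})
TREATMENTS = frozenset({"saline", "cocaine", "none"})

#: tokens interpreted as a missing (not-detected) intensity cell
MISSING_TOKENS = ("", "NA")


@dataclass
class SampleManifest:
    """Validated sample annotation table.

    ``table`` keeps one row per sample in file order; extra columns beyond the
    required six are carried along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"manifest missing required columns: {missing}")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id: {sorted(set(dup))}")
        for row_no, row in enumerate(t.itertuples(index=False), start=2):  # 1 header line
            if row.species not in SPECIES:
                raise ValidationError(f"row {row_no}: unknown species {row.species!r}")
            if row.sex not in SEXES:
                raise ValidationError(f"row {row_no}: unknown sex {row.sex!r}")
            if row.treatment not in TREATMENTS:
                raise ValidationError(f"row {row_no}: unknown treatment {row.treatment!r}")
            if not (float(row.body_weight_g) > 0):
                raise ValidationError(f"row {row_no}: body_weight_g must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_ids(self, sex: str | None = None, treatment: str | None = None) -> list[str]:
        """Sample ids matching the given sex and/or treatment."""
        t = self.table
        keep = pd.Series(True, index=t.index)
        if sex is not None:
            keep &= t["sex"] == sex
        if treatment is not None:
            keep &= t["treatment"] == treatment
        return list(t.loc[keep, "sample_id"])

    def body_weight(self, subject_id: str) -> float:
        t = self.table
        rows = t.loc[t["subject_id"] == subject_id, "body_weight_g"]
        if rows.empty:
            raise KeyError(subject_id)
        return float(rows.iloc[0])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class IntensityMatrix:
    """Protein-by-sample intensity matrix; NaN encodes a missing (not-detected) cell.

    A zero is a genuine low measurement and is distinct from missing.
    """

    data: pd.DataFrame  # index = accession, columns = sample ids, float values

    def __post_init__(self) -> None:
        d = self.data
        if d.index.duplicated().any():
            dups = sorted(set(d.index[d.index.duplicated()]))
            raise ValidationError(f"duplicate accession: {dups}")
        with np.errstate(invalid="ignore"):
            if (d.to_numpy() < 0).any():
                raise ValidationError("negative intensity value")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def detection_fraction(self) -> pd.Series:
        """Per-protein fraction of samples in which the protein was detected."""
        return self.data.notna().mean(axis=1)

    def check_manifest(self, manifest: SampleManifest) -> None:
        orphans = sorted(set(self.sample_ids) - set(manifest.sample_ids))
        if orphans:
            raise ValidationError(f"matrix samples absent from manifest: {orphans}")


def read_manifest(path: str | Path) -> SampleManifest:
    """Read and validate a sample manifest CSV."""
    table = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    return SampleManifest(table)


def read_intensity_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = MISSING_TOKENS,
    manifest: SampleManifest | None = None,
) -> IntensityMatrix:
    """Read a protein intensity TSV; cells equal to a missing token become NaN.

    When ``manifest`` is given, every matrix sample id must appear in it.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=list(missing_tokens),
        keep_default_na=False,
        dtype={0: str},
    )
    first = df.columns[0]
    if first != "accession":
        raise ValidationError(f"first column must be 'accession', got {first!r}")
    df = df.set_index("accession")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric intensity value: {exc}") from exc
    m = IntensityMatrix(df)
    if manifest is not None:
        m.check_manifest(manifest)
    return m


def read_behavior_bins(path: str | Path) -> pd.DataFrame:
    """Read bin-level operant records (long format, one row per bin).

    Enforces ``responses >= fr_value * reinforcers_earned`` — an animal cannot
    earn a reinforcer without emitting the full ratio requirement.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"behavior log missing columns: {missing}")
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.bin_index < 1:
            raise ValidationError(f"row {row_no}: bin_index must be >= 1")
        if row.fr_value < 1:
            raise ValidationError(f"row {row_no}: fr_value must be a positive integer")
        if row.reinforcers_earned < 0 or row.responses < 0:
            raise ValidationError(f"row {row_no}: counts must be non-negative")
        if not (row.bin_minutes > 0):
            raise ValidationError(f"row {row_no}: bin_minutes must be > 0")
        if row.responses < row.fr_value * row.reinforcers_earned:
            raise ValidationError(
                f"row {row_no}: responses ({row.responses}) < fr_value x reinforcers_earned "
                f"({row.fr_value} x {row.reinforcers_earned})"
            )
    return df[BIN_COLUMNS + [c for c in df.columns if c not in BIN_COLUMNS]]


FLOAT_FORMAT = "%.6g"


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as TSV with deterministic names and 6-sig-digit floats.

    Returns a mapping table name -> written path. Byte-identical across runs on
    identical input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in tables:
        path = out / f"{name}.tsv"
        tables[name].to_csv(
            path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
        )
        written[name] = path
    return written


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> Path:
    """Write an intensity matrix TSV; missing cells rendered as ``NA``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(
        path,
        sep="\t",
        index=True,
        index_label="accession",
        na_rep="NA",
        float_format=FLOAT_FORMAT,
        lineterminator="\n",
    )
    return path


def write_manifest(manifest: SampleManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def write_behavior_bins(bins: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bins.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path
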