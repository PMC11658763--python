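"""Tabular containers for per-read lengths and experimental design.

The central object is the :class:`LengthTable`: one row per sequenced
molecule, carrying the transcript it aligned to, the library it came
from, its templated 5' and 3' ends on the transcript (0-based,
half-open) and the aligned span in nucleotides. All downstream
statistics consume this table together with a :class:`DesignTable`
mapping libraries to conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LENGTH_TABLE_COLUMNS",
    "LengthTable",
    "DesignTable",
    "SchemaError",
    "ValidationError",
]

#: Canonical column order of the on-disk length-table TSV.
LENGTH_TABLE_COLUMNS = (
    "read_id",
    "library_id",
    "feature_id",
    "five_p",
    "three_p",
    "length",
    "adapter",
    "polya_pass",
)

#: Allowed values of the poly(A) QC state.
POLYA_STATES = ("pass", "fail", "unknown")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a table invariant (e.g. length != three_p - five_p)."""


def _validate_length_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in LENGTH_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"length table is missing required column {col!r}")
    df = df.loc[:, list(LENGTH_TABLE_COLUMNS)].copy()
    df["five_p"] = df["five_p"].astype(np.int64)
    df["three_p"] = df["three_p"].astype(np.int64)
    df["length"] = df["length"].astype(np.int64)
    df["adapter"] = df["adapter"].astype(bool)
    df["polya_pass"] = df["polya_pass"].astype(str)

    bad_state = ~df["polya_pass"].isin(POLYA_STATES)
    if bad_state.any():
        row = int(np.flatnonzero(bad_state.to_numpy())[0])
        raise ValidationError(
            f"row {row}: polya_pass must be one of {POLYA_STATES}, "
            f"got {df['polya_pass'].iloc[row]!r}"
        )
    if (df["feature_id"].astype(str).str.len() == 0).any():
        raise ValidationError("empty feature_id encountered")

    span = df["three_p"].to_numpy() - df["five_p"].to_numpy()
    bad = (df["five_p"].to_numpy() < 0) | (span < 1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {row}: require 0 <= five_p < three_p "
            f"(got five_p={df['five_p'].iloc[row]}, three_p={df['three_p'].iloc[row]})"
        )
    mismatch = df["length"].to_numpy() != span
    if mismatch.any():
        row = int(np.flatnonzero(mismatch)[0])
        raise ValidationError(
            f"row {row}: length={df['length'].iloc[row]} does not equal "
            f"three_p - five_p = {span[row]}"
        )
    dup = df.duplicated(subset=["read_id", "feature_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate (read_id, feature_id) pair "
            f"({df['read_id'].iloc[row]!r}, {df['feature_id'].iloc[row]!r})"
        )
    return df.reset_index(drop=True)


@dataclass
class LengthTable:
    """Per-read aligned-length table with provenance.

    Parameters
    ----------
    df
        One row per retained alignment with columns
        ``read_id, library_id, feature_id, five_p, three_p, length,
        adapter, polya_pass``. Coordinates are 0-based half-open on the
        transcript, so ``length == three_p - five_p >= 1``.
    provenance
        Free-text notes recording the source file and every filter
        applied, in order.
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.df = _validate_length_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LengthTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    def with_note(self, note: str) -> "LengthTable":
        return LengthTable(self.df, self.provenance + [note])

    @property
    def feature_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["feature_id"]))

    @property
    def library_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["library_id"]))

    @classmethod
    def from_records(cls, records: Iterable[dict], provenance: Sequence[str] = ()) -> "LengthTable":
        rows = list(records)
        if not rows:
            return cls.empty(provenance)
        return cls(pd.DataFrame(rows), list(provenance))

    @classmethod
    def empty(cls, provenance: Sequence[str] = ()) -> "LengthTable":
        df = pd.DataFrame(
            {
                "read_id": pd.Series(dtype=str),
                "library_id": pd.Series(dtype=str),
                "feature_id": pd.Series(dtype=str),
                "five_p": pd.Series(dtype=np.int64),
                "three_p": pd.Series(dtype=np.int64),
                "length": pd.Series(dtype=np.int64),
                "adapter": pd.Series(dtype=bool),
                "polya_pass": pd.Series(dtype=str),
            }
        )
        return cls(df, list(provenance))

    def write(self, path: str | Path) -> None:
        """Write the canonical TSV (header, tab-separated, no index).

        A comment line documents the coordinate convention.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# coordinates: 0-based half-open on transcript; length = three_p - five_p\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "LengthTable":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype={"read_id": str, "library_id": str, "feature_id": str})
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed TSV
            raise SchemaError(f"could not parse length table {path}: {exc}") from exc
        return cls(df, [f"loaded from {path}"])


def _empty_frame_like(df: pd.DataFrame) -> pd.DataFrame:
    return df.iloc[0:0]


@dataclass
class DesignTable:
    """Library-to-condition mapping with an explicit reference level.

    The condition factor must have exactly two levels; the reference
    (control) level is declared, never inferred from sort order.
    Additional columns are carried through as per-library covariates.
    """

    df: pd.DataFrame
    reference_condition: str

    def __post_init__(self) -> None:
        for col in ("library_id", "condition"):
            if col not in self.df.columns:
                raise SchemaError(f"design table is missing required column {col!r}")
        self.df = self.df.copy().reset_index(drop=True)
        self.df["library_id"] = self.df["library_id"].astype(str)
        self.df["condition"] = self.df["condition"].astype(str)
        if self.df["library_id"].duplicated().any():
            raise ValidationError("duplicate library_id in design table")
        levels = sorted(self.df["condition"].unique())
        if len(levels) != 2:
            raise ValidationError(
                f"condition must have exactly 2 levels, got {levels}"
            )
        if self.reference_condition not in levels:
            raise ValidationError(
                f"reference condition {self.reference_condition!r} not among levels {levels}"
            )

    @property
    def levels(self) -> tuple[str, str]:
        """(reference, treated) condition labels."""
        other = [c for c in self.df["condition"].unique() if c != self.reference_condition]
        return self.reference_condition, other[0]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("library_id", "condition")]

    def condition_indicator(self) -> pd.Series:
        """0/1 indicator per library (0 = reference/control)."""
        ind = (self.df["condition"] != self.reference_condition).astype(int)
        return pd.Series(ind.to_numpy(), index=self.df["library_id"].to_numpy())

    def libraries_in(self, condition_level: str) -> list[str]:
        return list(self.df.loc[self.df["condition"] == condition_level, "library_id"])

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, reference_condition: str | None = None) -> "DesignTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"library_id": str, "condition": str})
        if reference_condition is None:
            if "reference" in df.columns:
                ref_rows = df.loc[df["reference"].astype(str).str.lower().isin(("1", "true", "yes")), "condition"]
                if ref_rows.empty:
                    raise ValidationError("reference column present but no row marked as reference")
                reference_condition = str(ref_rows.iloc[0])
                df = df.drop(columns=["reference"])
            else:
                raise ValidationError(
                    "reference condition not given: pass reference_condition= or add a 'reference' column"
                )
        return cls(df, reference_condition)
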