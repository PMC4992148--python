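"""Canonical density tables and file I/O.

The interchange format is a UTF-8 CSV with one observed biovolume per
row and header columns ``assemblage, replicate, stress, day, species,
biovolume``.  Stress is stored numerically in ug/l, day as integer days
since inoculation, biovolume as a non-negative density.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DENSITY_COLUMNS = ["assemblage", "replicate", "stress", "day", "species", "biovolume"]
KEY_COLUMNS = ["assemblage", "replicate", "stress", "day", "species"]


@dataclass(frozen=True)
class DensityRecord:
    """One observed biovolume density of one species in one microcosm."""

    assemblage: str
    replicate: int
    stress: float
    day: int
    species: str
    biovolume: float


class SchemaError(ValueError):
    """Raised when a density table violates the canonical schema."""


def validate_density_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a density table in place.

    Checks the column set, value types, non-negativity of biovolume and
    uniqueness of the (assemblage, replicate, stress, day, species) key.
    """
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[DENSITY_COLUMNS].copy()
    for col, dtype in [
        ("replicate", int),
        ("stress", float),
        ("day", int),
        ("biovolume", float),
    ]:
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise SchemaError(f"column {col!r} unparseable at row {row}: {exc}") from exc
    negative = df.index[df["biovolume"] < 0]
    if len(negative):
        raise SchemaError(f"negative biovolume at row {int(negative[0])}")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        raise SchemaError(f"duplicate record key at row {int(df.index[dup.argmax()])}")
    return df


def read_density_table(path) -> pd.DataFrame:
    """Read and validate a canonical density CSV."""
    return validate_density_table(pd.read_csv(path))


def write_density_table(df: pd.DataFrame, path) -> None:
    """Write a density table as canonical CSV (validates first)."""
    validate_density_table(pd.DataFrame(df)).to_csv(path, index=False)


def records_to_frame(records) -> pd.DataFrame:
    """Convert an iterable of :class:`DensityRecord` to a table."""
    return validate_density_table(pd.DataFrame([r.__dict__ for r in records]))


def frame_to_records(df: pd.DataFrame) -> list[DensityRecord]:
    """Convert a density table to a list of :class:`DensityRecord`."""
    df = validate_density_table(df)
    return [DensityRecord(**row) for row in df.to_dict("records")]
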