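"""Cohort CSV schema validation and provenance-stamped serialisation.

All tabular interchange is plain RFC 4180 CSV.  Output files carry a single
leading comment line (``# d3cr ...``) recording the package version, profile
name and seed; readers skip ``#`` lines, so round trips preserve every value
bit-exactly (floats are serialised at full repr precision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .calibration import ETHNICITIES

__all__ = ["ValidationIssue", "read_cohort", "write_table", "read_table"]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "participant_id",
    "crn_ngml",
    "d3crn_ngml",
    "cr_ngml",
    "height_m",
    "weight_kg",
    "age_y",
    "ethnicity",
]
OPTIONAL_COLUMNS = ["mri_volume_l", "handgrip_kg"]
_NUMERIC = [
    "crn_ngml", "d3crn_ngml", "cr_ngml", "height_m", "weight_kg", "age_y",
    "mri_volume_l", "handgrip_kg",
]


@dataclass(frozen=True)
class ValidationIssue:
    row: int  # 1-based data row number
    column: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}, column {self.column!r}: {self.message}"


def read_cohort(
    path, strict: bool = False
) -> tuple[pd.DataFrame, list[ValidationIssue]]:
    """Read and validate a cohort CSV.

    Rows with missing urinary analytes or missing MRI reference are kept and
    flagged (``URINARY_MISSING`` / ``REFERENCE_MISSING`` in a ``flags``
    column); rows with invalid values (non-positive anthropometrics, unknown
    ethnicity, non-numeric fields) are dropped and reported with their
    1-based row numbers.  With ``strict=True`` any invalid row raises.
    """
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str},
                     float_precision="round_trip")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file missing required columns: {missing_cols}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")

    issues: list[ValidationIssue] = []
    drop: list[int] = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for pos in df.index[bad]:
            issues.append(
                ValidationIssue(pos + 1, col, f"non-numeric value {df.at[pos, col]!r}")
            )
            drop.append(pos)
        df[col] = coerced

    for pos in df.index:
        h, w = df.at[pos, "height_m"], df.at[pos, "weight_kg"]
        if pd.notna(h) and h <= 0:
            issues.append(ValidationIssue(pos + 1, "height_m", f"non-positive {h}"))
            drop.append(pos)
        if pd.notna(w) and w <= 0:
            issues.append(ValidationIssue(pos + 1, "weight_kg", f"non-positive {w}"))
            drop.append(pos)
        eth = df.at[pos, "ethnicity"]
        if pd.notna(eth) and eth not in ETHNICITIES:
            issues.append(
                ValidationIssue(pos + 1, "ethnicity", f"unknown label {eth!r}")
            )
            drop.append(pos)
        mri = df.at[pos, "mri_volume_l"]
        if pd.notna(mri) and mri <= 0:
            issues.append(ValidationIssue(pos + 1, "mri_volume_l", f"non-positive {mri}"))
            drop.append(pos)

    if issues and strict:
        raise ValueError(
            "cohort validation failed:\n" + "\n".join(str(i) for i in issues)
        )
    if drop:
        df = df.drop(index=sorted(set(drop)))
        for issue in issues:
            log.warning("dropped %s", issue)

    flags = []
    for _, rec in df.iterrows():
        f = []
        if rec[["crn_ngml", "d3crn_ngml", "cr_ngml"]].isna().any():
            f.append("URINARY_MISSING")
        if pd.isna(rec["mri_volume_l"]):
            f.append("REFERENCE_MISSING")
        flags.append(";".join(f))
    df = df.reset_index(drop=True)
    df["flags"] = flags
    return df, issues


def write_table(
    df: pd.DataFrame, path, profile_name: str = "iwhp2025", seed: int | None = None
) -> None:
    """Write a CSV with a provenance comment header, full float precision."""
    from . import __version__

    seed_part = f" seed={seed}" if seed is not None else ""
    with open(path, "w", newline="") as fh:
        fh.write(f"# d3cr v{__version__} profile={profile_name}{seed_part}\n")
        df.to_csv(fh, index=False, float_format=None)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips comment lines)."""
    return pd.read_csv(path, comment="#", dtype={"participant_id": str},
                       float_precision="round_trip")
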