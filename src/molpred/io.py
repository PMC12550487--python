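"""Readers/writers for the three interchange tables, with validation.

Plain comma-delimited text with a header row, matching how such ecology
tables are usually deposited.  Fixed column names:

* feeding trial: ``predator_code, prey, hours_since_feeding, detected``
* field captures: ``individual_id, predator_code, prey, detected``
  plus optional ``session`` and ``region`` grouping labels
* abundances: ``community, species, abundance``

Validation collects *all* row-level problems (with 1-based file line
numbers, header = line 1) before raising; nothing is silently dropped.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "LAB_COLUMNS",
    "FIELD_COLUMNS",
    "FIELD_OPTIONAL_COLUMNS",
    "ABUNDANCE_COLUMNS",
    "read_lab",
    "read_field",
    "read_abundance",
    "validate_lab",
    "validate_field",
    "validate_abundance",
    "write_table",
]

logger = logging.getLogger("molpred")

LAB_COLUMNS = ["predator_code", "prey", "hours_since_feeding", "detected"]
FIELD_COLUMNS = ["individual_id", "predator_code", "prey", "detected"]
FIELD_OPTIONAL_COLUMNS = ["session", "region"]
ABUNDANCE_COLUMNS = ["community", "species", "abundance"]


class ValidationError(ValueError):
    """Input table failed validation; ``errors`` lists (line, message)."""

    def __init__(self, errors: List[Tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{len(errors)} validation error(s): {lines}{more}")


def _require_columns(df: pd.DataFrame, required: List[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([(1, f"{what} table missing column(s) {missing}")])


def _line(df: pd.DataFrame, pos: np.ndarray) -> np.ndarray:
    # file line number: header is line 1, first data row line 2
    return np.asarray(pos) + 2


def _check_binary(df, col, errors):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = ~vals.isin([0, 1])
    for pos in np.flatnonzero(bad.to_numpy()):
        errors.append((pos + 2, f"{col} must be 0 or 1, got {df[col].iloc[pos]!r}"))
    return vals


def _check_nonempty_str(df, col, errors):
    s = df[col].astype(str)
    bad = (s.str.len() == 0) | s.isin(["nan", "None"]) | df[col].isna()
    for pos in np.flatnonzero(bad.to_numpy()):
        errors.append((pos + 2, f"{col} must be a nonempty label"))
    return s


def validate_lab(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a feeding-trial table; raises ValidationError."""
    _require_columns(df, LAB_COLUMNS, "feeding-trial")
    errors: List[Tuple[int, str]] = []
    _check_nonempty_str(df, "predator_code", errors)
    _check_nonempty_str(df, "prey", errors)
    hours = pd.to_numeric(df["hours_since_feeding"], errors="coerce")
    bad = ~np.isfinite(hours.to_numpy(dtype=float)) | (hours.to_numpy(dtype=float) < 0)
    for pos in np.flatnonzero(bad):
        errors.append((pos + 2,
                       f"hours_since_feeding must be finite and >= 0, "
                       f"got {df['hours_since_feeding'].iloc[pos]!r}"))
    det = _check_binary(df, "detected", errors)
    if errors:
        raise ValidationError(errors)
    out = df.copy()
    out["predator_code"] = df["predator_code"].astype(str)
    out["prey"] = df["prey"].astype(str)
    out["hours_since_feeding"] = hours.astype(float)
    out["detected"] = det.astype(int)
    return out


def validate_field(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a field-capture table; raises ValidationError."""
    _require_columns(df, FIELD_COLUMNS, "field")
    errors: List[Tuple[int, str]] = []
    _check_nonempty_str(df, "individual_id", errors)
    _check_nonempty_str(df, "predator_code", errors)
    _check_nonempty_str(df, "prey", errors)
    det = _check_binary(df, "detected", errors)
    dup = df.duplicated(subset=["individual_id", "prey"], keep="first")
    for pos in np.flatnonzero(dup.to_numpy()):
        errors.append((pos + 2,
                       f"duplicate (individual_id, prey) = "
                       f"({df['individual_id'].iloc[pos]!r}, {df['prey'].iloc[pos]!r})"))
    if errors:
        raise ValidationError(errors)
    out = df.copy()
    for col in ("individual_id", "predator_code", "prey"):
        out[col] = df[col].astype(str)
    out["detected"] = det.astype(int)
    for col in FIELD_OPTIONAL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(str)
    return out


def validate_abundance(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type an abundance table; raises ValidationError."""
    _require_columns(df, ABUNDANCE_COLUMNS, "abundance")
    errors: List[Tuple[int, str]] = []
    _check_nonempty_str(df, "community", errors)
    _check_nonempty_str(df, "species", errors)
    ab = pd.to_numeric(df["abundance"], errors="coerce")
    bad = ~np.isfinite(ab.to_numpy(dtype=float)) | (ab.to_numpy(dtype=float) < 0)
    for pos in np.flatnonzero(bad):
        errors.append((pos + 2,
                       f"abundance must be finite and >= 0, got {df['abundance'].iloc[pos]!r}"))
    if errors:
        raise ValidationError(errors)
    out = df.copy()
    out["community"] = df["community"].astype(str)
    out["species"] = df["species"].astype(str)
    out["abundance"] = ab.astype(float)
    return out


def _log_summary(df: pd.DataFrame, what: str) -> None:
    if not len(df):
        logger.warning("%s table is empty", what)
        return
    msg = f"{what}: {len(df)} rows"
    if "predator_code" in df.columns:
        msg += f", {df['predator_code'].nunique()} predator species"
    if "prey" in df.columns:
        msg += f", {df['prey'].nunique()} prey types"
        pos = df.groupby("prey")["detected"].sum()
        msg += "; positives per prey: " + ", ".join(
            f"{p}={int(k)}" for p, k in pos.items())
    logger.info(msg)


def read_lab(path, *, sep: str = ",") -> pd.DataFrame:
    """Read and validate a feeding-trial CSV."""
    df = pd.read_csv(path, sep=sep)
    df = validate_lab(df)
    _log_summary(df, "feeding-trial")
    return df


def read_field(path, *, sep: str = ",", session: Optional[str] = None) -> pd.DataFrame:
    """Read and validate a field-capture CSV.

    ``session`` optionally filters to one capture session; by default
    individuals from all sessions/regions are pooled (one rate per pair,
    constant over the year).
    """
    df = pd.read_csv(path, sep=sep)
    df = validate_field(df)
    if session is not None:
        if "session" not in df.columns:
            raise ValidationError([(1, "cannot filter: no 'session' column")])
        df = df[df["session"] == session].reset_index(drop=True)
    _log_summary(df, "field")
    return df


def read_abundance(path, *, sep: str = ",") -> pd.DataFrame:
    """Read and validate a community-abundance CSV."""
    df = pd.read_csv(path, sep=sep)
    df = validate_abundance(df)
    _log_summary(df, "abundance")
    return df


def write_table(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write a table in the interchange format (no index column)."""
    df.to_csv(path, sep=sep, index=False)
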