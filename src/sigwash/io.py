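"""Long-format CSV interfaces for raw PWT data and fit tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fitting import PATTERNS, TimeCourse

__all__ = [
    "REQUIRED_COLUMNS",
    "read_pwt_csv",
    "validate_pwt_frame",
    "frame_to_timecourses",
    "timecourses_to_frame",
]

#: Schema of the long-format PWT table: one row per (animal, pattern, timepoint).
REQUIRED_COLUMNS = (
    "animal_id",
    "pattern",
    "cohort",
    "t_stim_min",
    "time_min",
    "pwt_g",
)


def validate_pwt_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format PWT schema, raising a named-column error."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if len(df) == 0:
        raise SchemaError("empty dataset: no PWT rows")
    bad = ~df["pattern"].isin(PATTERNS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"row {row}: unknown pattern {df['pattern'].iloc[row]!r}; "
            f"expected one of {PATTERNS}")
    for col in ("t_stim_min", "time_min", "pwt_g"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise SchemaError(f"row {row}: column {col!r} is not numeric "
                              f"({df[col].iloc[row]!r})")
    if (pd.to_numeric(df["pwt_g"]) <= 0).any():
        raise SchemaError("column 'pwt_g' must be positive (grams)")
    return df


def read_pwt_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format PWT CSV (UTF-8, '.' decimal).

    Floats are parsed with correctly-rounded ("round_trip") precision so
    that a written dataset re-fits to bit-identical results.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_pwt_frame(df)


def frame_to_timecourses(df: pd.DataFrame) -> list[TimeCourse]:
    """Split a validated long-format frame into per-(animal, pattern) series."""
    validate_pwt_frame(df)
    out: list[TimeCourse] = []
    for (animal, pattern), grp in df.groupby(["animal_id", "pattern"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            TimeCourse(
                animal_id=str(animal),
                pattern=str(pattern),
                cohort=int(grp["cohort"].iloc[0]),
                t_stim_min=float(grp["t_stim_min"].iloc[0]),
                times=grp["time_min"].to_numpy(float),
                pwt=grp["pwt_g"].to_numpy(float),
            )
        )
    return out


def timecourses_to_frame(timecourses) -> pd.DataFrame:
    """Assemble TimeCourse objects into the long-format frame."""
    rows = []
    for tc in timecourses:
        for t, w in zip(tc.times, tc.pwt):
            rows.append((tc.animal_id, tc.pattern, tc.cohort, tc.t_stim_min,
                         float(t), float(w)))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
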