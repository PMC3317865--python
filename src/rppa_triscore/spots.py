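"""Spot-level table I/O.

A spot table holds one row per printed spot: antibody (slide), sample or
control identity, dilution step (0 = undiluted, each step halves the
concentration, i.e. -1 on the log2 axis), within-slide series replicate,
grid position and the quantified intensity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["antibody", "sample_id", "dilution_step", "series", "row", "col", "intensity", "role"]
ROLES = ("sample", "positive_control", "negative_control")

_SEPS = {"tab": "\t", "comma": ","}


def validate_spot_table(table: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table missing required column(s): {missing}")
    bad_roles = set(table["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown spot roles: {sorted(bad_roles)}")
    if not np.isfinite(table["intensity"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite intensities in spot table")
    steps = table.loc[table["role"] == "sample", "dilution_step"]
    if len(steps) and (steps.min() < 0 or steps.max() > 4):
        raise ValueError("dilution_step outside 0..4")


def normalize_spot_order(table: pd.DataFrame) -> pd.DataFrame:
    """Canonical row ordering so that reads are permutation-stable."""
    return table.sort_values(
        ["antibody", "role", "sample_id", "series", "dilution_step", "row", "col"],
        kind="mergesort",
    ).reset_index(drop=True)


def read_spot_table(path, dialect: str = "tab") -> pd.DataFrame:
    """Read a delimited spot table; unknown columns are preserved.

    Raises
    ------
    ValueError
        If a required column is missing, or an intensity fails to parse
        (the error names the offending file row).
    """
    sep = _SEPS[dialect]
    table = pd.read_csv(
        path, sep=sep, keep_default_na=False, na_values=[],
        dtype={"sample_id": str, "antibody": str, "role": str, "intensity": str},
    )
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table missing required column(s): {missing}")
    parsed = pd.to_numeric(table["intensity"], errors="coerce")
    bad = parsed.isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        rows = [int(i) + 2 for i in table.index[bad][:5]]
        raise ValueError(f"non-numeric intensity at file row(s) {rows}")
    table["intensity"] = parsed.astype(float)
    for col in ("dilution_step", "series", "row", "col"):
        table[col] = pd.to_numeric(table[col]).astype(int)
    validate_spot_table(table)
    return normalize_spot_order(table)


def write_spot_table(table: pd.DataFrame, path, dialect: str = "tab") -> None:
    validate_spot_table(table)
    table.to_csv(path, sep=_SEPS[dialect], index=False)
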