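"""File formats: localization CSV (ThunderSTORM dialect), cohort CSV,
denaturation CSV and multi-page TIFF stacks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_cohort",
    "write_cohort",
    "read_denaturation",
    "write_denaturation",
    "read_stack",
    "write_stack",
]

# ThunderSTORM column header -> internal column name
_TS_COLUMNS = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "intensity [photon]": "photons",
    "uncertainty [nm]": "uncertainty_nm",
}
_TS_ORDER = ["id", "frame", "x [nm]", "y [nm]", "intensity [photon]",
             "uncertainty [nm]"]


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-style localization CSV.

    Columns are matched by header name, so reordered files parse fine;
    unknown extra columns are preserved.  A missing required column raises
    with the column named.
    """
    raw = pd.read_csv(path)
    for col in _TS_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"malformed localization file {path}: "
                             f"missing column {col!r}")
    table = raw.rename(columns=_TS_COLUMNS)
    table = table.drop(columns=[c for c in ("id",) if c in table.columns])
    table["frame"] = table["frame"].astype(int)
    return table


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table in the ThunderSTORM CSV dialect.

    Full float precision is kept so write -> read round-trips losslessly;
    extra (non-dialect) columns are appended after the standard ones.
    """
    out = table.copy()
    out.insert(0, "id", np.arange(1, len(out) + 1))
    inverse = {v: k for k, v in _TS_COLUMNS.items()}
    out = out.rename(columns=inverse)
    extras = [c for c in out.columns if c not in _TS_ORDER]
    out = out[[c for c in _TS_ORDER if c in out.columns] + extras]
    out.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a long-form cohort CSV (subject, group, marker, value)."""
    cohort = pd.read_csv(path)
    required = {"subject", "group", "marker", "value"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns {sorted(missing)}")
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_denaturation(path: str | Path) -> pd.DataFrame:
    """Read a denaturation series CSV (conc_M, count_mean[, count_se])."""
    curve = pd.read_csv(path)
    for col in ("conc_M", "count_mean"):
        if col not in curve.columns:
            raise ValueError(f"denaturation file {path} missing column {col!r}")
    return curve


def write_denaturation(curve: pd.DataFrame, path: str | Path) -> None:
    curve.to_csv(path, index=False)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, h, w)."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a stack as 16-bit unsigned multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")
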