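"""CSV interchange for trial tables.

The adjustment-task schema is the canonical record set passed between
pipeline stages: participant_id, trial_index, orientation_deg,
noise_level, position_index, response_deg, error_deg.  The binary-task
schema: participant_id, trial_index, noise_level,
signed_orientation_deg, choice.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .circstats import wrap_axial

logger = logging.getLogger(__name__)

__all__ = ["read_trial_csv", "write_trial_csv", "read_binary_csv", "write_binary_csv"]

REQUIRED_COLUMNS = [
    "participant_id",
    "trial_index",
    "orientation_deg",
    "noise_level",
    "response_deg",
]
OPTIONAL_COLUMNS = ["position_index", "error_deg", "response_missing"]

BINARY_COLUMNS = [
    "participant_id",
    "trial_index",
    "noise_level",
    "signed_orientation_deg",
    "choice",
]


def _angle_column(df: pd.DataFrame, col: str, strict: bool) -> None:
    vals = df[col].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    out_of_range = finite & ((vals < 0) | (vals >= 180))
    if out_of_range.any():
        lines = (df.index[out_of_range] + 2).tolist()  # 1-based + header
        if strict:
            raise ValueError(f"{col} outside [0, 180) at file lines {lines[:10]}")
        logger.warning("%s outside [0, 180) at %d rows; wrapping", col, len(lines))
        vals[out_of_range] = wrap_axial(vals[out_of_range])
        df[col] = vals


def read_trial_csv(path, strict: bool = False) -> pd.DataFrame:
    """Read an adjustment-task trial table, validating the schema.

    Missing responses are kept (NaN) and flagged.  Angles outside
    [0, 180) are wrapped with a warning, or rejected in strict mode.
    Duplicate (participant, trial_index) pairs and malformed numeric
    cells are rejected with line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("trial_index", "orientation_deg", "response_deg"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            lines = (df.index[bad.isna() & df[col].notna()] + 2).tolist()
            raise ValueError(f"{path}: malformed {col} at file lines {lines[:10]}") from exc
    dup = df.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (participant, trial_index) at lines {lines[:10]}")
    bad_noise = ~df["noise_level"].isin(["low", "high"])
    if bad_noise.any():
        lines = (df.index[bad_noise] + 2).tolist()
        raise ValueError(f"{path}: noise_level must be low/high at lines {lines[:10]}")
    _angle_column(df, "orientation_deg", strict)
    resp_missing = ~np.isfinite(df["response_deg"].to_numpy(dtype=float))
    if resp_missing.any():
        logger.warning("%s: %d rows with missing response (flagged, kept)",
                       path, int(resp_missing.sum()))
    df["response_missing"] = resp_missing
    present = ~resp_missing
    if present.any():
        sub = df.loc[present].copy()
        _angle_column(sub, "response_deg", strict)
        df.loc[present, "response_deg"] = sub["response_deg"]
    return df


def write_trial_csv(table: pd.DataFrame, path) -> None:
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)


def read_binary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BINARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = ~df["choice"].isin(["left", "right"])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: choice must be left/right at lines {lines[:10]}")
    return df


def write_binary_csv(table: pd.DataFrame, path) -> None:
    table.loc[:, BINARY_COLUMNS].to_csv(path, index=False)
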