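"""Preprocessing of adjustment-task trial tables.

Fixed pipeline order: compute errors → subtract each participant's
circular mean error (removes a global clockwise/counter-clockwise bias)
→ remove outliers beyond 3 SD within each participant × noise-level
cell → apply participant-level exclusion rules (stimulus–response
correlation below threshold for the adjustment task; fitted psychometric
spread above threshold for the binary task, the two tasks judged
independently).

The 3-SD rule uses the linear SD of the already-acute errors (errors
live in [−90, 90), where the linear SD is well behaved); it is applied
once, after debiasing, and a zero-SD cell removes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import axial_circular_mean, axial_correlation, axial_delta

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "compute_errors",
    "debias_errors",
    "remove_outliers",
    "exclude_participants",
    "preprocess",
]

CORRELATION_THRESHOLD = 0.5
SPREAD_THRESHOLD_DEG = 60.0
OUTLIER_SD = 3.0


@dataclass
class PreprocessReport:
    """Per-participant accounting of everything preprocessing did."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns among: participant_id, mean_removed_deg, n_trials, n_removed,
    # fraction_removed, excluded, reason

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        if self.table.empty:
            return PreprocessReport(other.table.copy())
        merged = self.table.merge(
            other.table, on="participant_id", how="outer", suffixes=("", "_next")
        )
        return PreprocessReport(merged)


def compute_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``error_deg`` = signed axial difference response − stimulus.

    Rows with a missing response keep a NaN error and are flagged in
    ``response_missing`` rather than dropped.
    """
    out = table.copy()
    resp = out["response_deg"].to_numpy(dtype=float)
    missing = ~np.isfinite(resp)
    out["response_missing"] = missing
    err = np.full(len(out), np.nan)
    if (~missing).any():
        err[~missing] = axial_delta(
            resp[~missing], out["orientation_deg"].to_numpy(dtype=float)[~missing]
        )
    out["error_deg"] = err
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning("%d rows have missing responses (flagged, kept)", n_missing)
    return out


def debias_errors(table: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Subtract each participant's circular mean error from their errors.

    A participant whose error distribution has no defined circular mean
    (resultant ≈ 0) is excluded with a reason instead of silently passed
    through.
    """
    out = table.copy()
    rows = []
    drop_pids = []
    for pid, g in out.groupby("participant_id", sort=False):
        errs = g["error_deg"].dropna().to_numpy(dtype=float)
        try:
            mean = axial_circular_mean(errs)
        except ValueError as exc:
            rows.append(
                {"participant_id": pid, "mean_removed_deg": np.nan,
                 "excluded": True, "reason": str(exc)}
            )
            drop_pids.append(pid)
            continue
        idx = g.index
        out.loc[idx, "error_deg"] = axial_delta(
            g["error_deg"].to_numpy(dtype=float), mean
        )
        rows.append(
            {"participant_id": pid, "mean_removed_deg": mean,
             "excluded": False, "reason": ""}
        )
    if drop_pids:
        out = out[~out["participant_id"].isin(drop_pids)].reset_index(drop=True)
    return out, PreprocessReport(pd.DataFrame(rows))


def remove_outliers(
    table: pd.DataFrame, n_sd: float = OUTLIER_SD
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop trials whose debiased error lies more than ``n_sd`` standard
    deviations from the mean of their participant × noise-level cell.

    The mean and SD are computed separately for low- and high-noise
    trials.  Zero-SD cells remove nothing; the rule is applied once, not
    iteratively.  Rows with missing errors are not counted against the
    rule (they are already flagged).
    """
    out = table.reset_index(drop=True).copy()
    keep = np.ones(len(out), dtype=bool)
    rows = []
    for pid, g in out.groupby("participant_id", sort=False):
        removed = 0
        total = 0
        for level, cell in g.groupby("noise_level", sort=False):
            errs = cell["error_deg"].to_numpy(dtype=float)
            valid = np.isfinite(errs)
            total += int(valid.sum())
            if valid.sum() < 10:
                logger.warning(
                    "participant %s, %s-noise cell has only %d trials",
                    pid, level, int(valid.sum()),
                )
            if valid.sum() == 0:
                continue
            m, s = errs[valid].mean(), errs[valid].std(ddof=0)
            if s == 0:
                continue
            bad = valid & (np.abs(errs - m) > n_sd * s)
            keep[cell.index[bad]] = False
            removed += int(bad.sum())
        rows.append(
            {
                "participant_id": pid,
                "n_trials": total,
                "n_removed": removed,
                "fraction_removed": removed / total if total else np.nan,
            }
        )
    report = PreprocessReport(pd.DataFrame(rows))
    return out[keep].reset_index(drop=True), report


def exclude_participants(
    adjustment: pd.DataFrame | None = None,
    binary_spreads: pd.DataFrame | None = None,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    spread_threshold_deg: float = SPREAD_THRESHOLD_DEG,
) -> PreprocessReport:
    """Participant exclusion rules, applied per task independently.

    Adjustment task: excluded when the circular stimulus–response
    correlation falls below ``correlation_threshold`` (responding without
    care, or a degenerate response pattern).  Binary task: excluded when
    the fitted cumulative-Gaussian spread exceeds
    ``spread_threshold_deg``.  ``binary_spreads`` needs columns
    participant_id, spread_deg.
    """
    rows = []
    if adjustment is not None:
        for pid, g in adjustment.groupby("participant_id", sort=False):
            ok = np.isfinite(g["response_deg"].to_numpy(dtype=float))
            try:
                r = axial_correlation(
                    g["orientation_deg"].to_numpy(dtype=float)[ok],
                    g["response_deg"].to_numpy(dtype=float)[ok],
                )
            except ValueError:
                r = np.nan
            excluded = not (r >= correlation_threshold)
            rows.append(
                {
                    "participant_id": pid,
                    "task": "adjustment",
                    "statistic": r,
                    "excluded": excluded,
                    "reason": (
                        f"stimulus-response correlation {r:.3f} < {correlation_threshold}"
                        if excluded else ""
                    ),
                }
            )
    if binary_spreads is not None:
        for _, row in binary_spreads.iterrows():
            spread = float(row["spread_deg"])
            excluded = not (spread <= spread_threshold_deg)
            rows.append(
                {
                    "participant_id": row["participant_id"],
                    "task": "binary",
                    "statistic": spread,
                    "excluded": excluded,
                    "reason": (
                        f"psychometric spread {spread:.1f} > {spread_threshold_deg}"
                        if excluded else ""
                    ),
                }
            )
    return PreprocessReport(pd.DataFrame(rows))


def preprocess(
    table: pd.DataFrame,
    apply_exclusions: bool = True,
    correlation_threshold: float = CORRELATION_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Run the full adjustment-task preprocessing chain.

    Returns the cleaned table and a dict of stage reports
    (``debias``, ``outliers``, ``exclusions``).
    """
    out = compute_errors(table)
    reports: dict[str, PreprocessReport] = {}
    if apply_exclusions:
        excl = exclude_participants(out, correlation_threshold=correlation_threshold)
        reports["exclusions"] = excl
        bad = excl.table.loc[excl.table["excluded"], "participant_id"]
        if len(bad):
            logger.info("excluding participants: %s", list(bad))
        out = out[~out["participant_id"].isin(set(bad))].reset_index(drop=True)
    out, reports["debias"] = debias_errors(out)
    out, reports["outliers"] = remove_outliers(out)
    return out, reports
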