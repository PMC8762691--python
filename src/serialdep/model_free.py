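"""Model-free serial-bias statistic and 2×2 repeated-measures ANOVA.

The model-free route sidesteps DoG curve fitting (which can be thrown
off by repulsive sidebands at large orientation differences): for each
participant and condition, the bias is the median error on trials with
a positive inter-trial difference in (0°, 45°] minus the median error
on trials with a negative difference in [−45°, 0°).  Positive values
mean attraction toward the previous reference.  Per-participant biases
in the four noise-transition cells (previous × current noise, each
low/high) are then compared with a two-way repeated-measures ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .serial import ConditionedSeries

logger = logging.getLogger(__name__)

__all__ = ["AnovaResult", "bias_statistic", "bias_table", "rm_anova_2x2"]

BIAS_WINDOW_DEG = 45.0
MIN_TRIALS_PER_WINDOW = 5


@dataclass
class AnovaResult:
    """F, p and degrees of freedom for the two main effects and the
    interaction of previous × current noise."""

    f_previous: float
    p_previous: float
    f_current: float
    p_current: float
    f_interaction: float
    p_interaction: float
    df_num: int
    df_den: int
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": ["previous_noise", "current_noise", "interaction"],
                "F": [self.f_previous, self.f_current, self.f_interaction],
                "p": [self.p_previous, self.p_current, self.p_interaction],
                "df_num": self.df_num,
                "df_den": self.df_den,
            }
        )


def bias_statistic(
    deltas,
    errors,
    window_deg: float = BIAS_WINDOW_DEG,
    min_trials: int = MIN_TRIALS_PER_WINDOW,
) -> float:
    """Median error for positive differences minus median for negative.

    Windows are (0, window] and [−window, 0); trials at delta exactly 0
    belong to neither.  Returns NaN (a flagged missing cell) when either
    window holds fewer than ``min_trials`` trials.
    """
    d = np.asarray(deltas, dtype=float)
    e = np.asarray(errors, dtype=float)
    ok = np.isfinite(d) & np.isfinite(e)
    d, e = d[ok], e[ok]
    pos = (d > 0) & (d <= window_deg)
    neg = (d < 0) & (d >= -window_deg)
    if pos.sum() < min_trials or neg.sum() < min_trials:
        return float("nan")
    return float(np.median(e[pos]) - np.median(e[neg]))


def bias_table(series: ConditionedSeries, window_deg: float = BIAS_WINDOW_DEG) -> pd.DataFrame:
    """Per-participant bias in each of the four noise-transition cells.

    Columns: participant_id, previous_noise, current_noise, bias_deg.
    Cells that cannot be computed (too few trials in a sign window) are
    NaN; the ANOVA stage excludes those participants listwise.
    """
    rows = []
    for (pid, trans), g in series.data.groupby(
        ["participant_id", "transition"], sort=False
    ):
        rows.append(
            {
                "participant_id": pid,
                "previous_noise": "low" if trans[0] == "L" else "high",
                "current_noise": "low" if trans[1] == "L" else "high",
                "bias_deg": bias_statistic(g["delta_deg"], g["error_deg"], window_deg),
            }
        )
    return pd.DataFrame(rows)


def rm_anova_2x2(bias: pd.DataFrame) -> AnovaResult:
    """Two-way repeated-measures ANOVA on the 2×2 bias table.

    Participants are the random blocking factor; each effect is tested
    against its own participant-interaction error term.  With two-level
    factors no sphericity correction is needed.  Participants with an
    incomplete or non-finite cell set are excluded listwise (logged).
    """
    df = bias.copy()
    complete = (
        df.assign(ok=np.isfinite(df["bias_deg"]))
        .groupby("participant_id")["ok"]
        .agg(["sum", "count"])
    )
    good = complete[(complete["sum"] == 4) & (complete["count"] == 4)].index
    dropped = sorted(set(df["participant_id"]) - set(good))
    if dropped:
        logger.info("ANOVA: excluding participants with incomplete cells: %s", dropped)
    df = df[df["participant_id"].isin(good)]
    n = df["participant_id"].nunique()
    if n < 2:
        raise ValueError("need at least 2 complete participants")
    res = AnovaRM(
        df,
        depvar="bias_deg",
        subject="participant_id",
        within=["previous_noise", "current_noise"],
    ).fit()
    tab = res.anova_table
    prev = tab.loc["previous_noise"]
    cur = tab.loc["current_noise"]
    inter = tab.loc["previous_noise:current_noise"]
    return AnovaResult(
        f_previous=float(prev["F Value"]),
        p_previous=float(prev["Pr > F"]),
        f_current=float(cur["F Value"]),
        p_current=float(cur["Pr > F"]),
        f_interaction=float(inter["F Value"]),
        p_interaction=float(inter["Pr > F"]),
        df_num=1,
        df_den=n - 1,
        n_participants=n,
    )
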