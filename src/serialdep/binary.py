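"""Psychometric analysis of the binary left/right choice task.

Each participant × noise level is fit with a cumulative Gaussian
P(clockwise | x) = Φ((x − pse)/spread) by trial-level Bernoulli maximum
likelihood (probit regression); the fitted spread indexes how hard the
orientation was to judge and is the quantity compared between noise
levels.  The comparison is a within-participant sign-flip permutation
test on the paired spread differences, with a paired Cohen's d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["PsychometricFit", "fit_probit", "fit_all_probit", "compare_spreads"]

SPREAD_FLOOR_DEG = 0.01  # reported spread when the data are perfectly separated
SPREAD_CEILING_DEG = 1e4  # reported spread when choices carry no x information


@dataclass
class PsychometricFit:
    participant_id: str
    noise_level: str
    pse_deg: float
    spread_deg: float
    converged: bool
    n_trials: int


def fit_probit(
    x,
    choices,
    participant_id: str = "",
    noise_level: str = "",
) -> PsychometricFit:
    """Probit fit of P(clockwise) against signed orientation.

    ``choices`` may be "left"/"right" strings or 0/1 (1 = clockwise/
    right).  Perfect separation drives the ML spread to zero: the fit is
    then flagged and the spread reported at the documented floor
    (``SPREAD_FLOOR_DEG``).  Choices carrying no orientation information
    drive the slope to ~0 (or negative): flagged, spread reported at the
    ceiling — the pattern the spread-based participant exclusion rule
    catches.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(choices)
    if y.dtype.kind in "UO":
        y = (y == "right").astype(float)
    y = np.asarray(y, dtype=float)
    if x.size < 20:
        raise ValueError("need >= 20 trials")
    if y.min() == y.max():
        raise ValueError("need both response categories")
    exog = sm.add_constant(x)
    converged = True
    separated = False
    try:
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = sm.GLM(y, exog, family=sm.families.Binomial(
                link=sm.families.links.Probit())).fit(maxiter=200)
        separated = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        intercept, slope = res.params
        converged = (
            bool(res.converged) and np.all(np.isfinite(res.params)) and not separated
        )
    except Exception:
        intercept, slope, converged = 0.0, 0.0, False
    if not np.isfinite(slope) or slope <= 1.0 / SPREAD_CEILING_DEG:
        logger.warning(
            "probit fit %s/%s: choices uninformative about orientation (slope %.3g)",
            participant_id, noise_level, slope,
        )
        return PsychometricFit(participant_id, noise_level,
                               float("nan"), SPREAD_CEILING_DEG, False, x.size)
    spread = 1.0 / slope
    pse = -intercept / slope
    if spread < SPREAD_FLOOR_DEG or not converged:
        # perfect or near-perfect separation: spread not identifiable below floor
        spread = max(spread, SPREAD_FLOOR_DEG)
        converged = False
    return PsychometricFit(participant_id, noise_level, float(pse), float(spread),
                           converged, x.size)


def fit_all_probit(binary: pd.DataFrame) -> pd.DataFrame:
    """One probit fit per participant × noise level; returns a tidy frame
    with columns participant_id, noise_level, pse_deg, spread_deg,
    converged, n_trials."""
    rows = []
    for (pid, level), g in binary.groupby(["participant_id", "noise_level"], sort=False):
        f = fit_probit(
            g["signed_orientation_deg"], g["choice"],
            participant_id=str(pid), noise_level=str(level),
        )
        rows.append(vars(f))
    return pd.DataFrame(rows)


def compare_spreads(
    spreads_low,
    spreads_high,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Paired permutation test of high- vs low-noise psychometric spreads.

    Inputs are per-participant spreads aligned by participant.  The
    statistic is the mean paired difference (high − low); each
    permutation swaps the condition labels within a participant with
    probability 1/2 (equivalently flips the sign of that participant's
    difference).  Returns observed difference, p, paired Cohen's d
    (mean difference / SD of differences), and n.
    """
    lo = np.asarray(spreads_low, dtype=float)
    hi = np.asarray(spreads_high, dtype=float)
    if lo.shape != hi.shape or lo.ndim != 1:
        raise ValueError("paired spread arrays must be 1-D and equal length")
    ok = np.isfinite(lo) & np.isfinite(hi)
    if (~ok).any():
        logger.warning("dropping %d unpaired/non-finite participants", int((~ok).sum()))
    d = hi[ok] - lo[ok]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired participants")
    obs = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = (signs * d[None, :]).mean(axis=1)
    p = float(np.mean(np.abs(perm) >= abs(obs)))
    sd = float(d.std(ddof=1))
    return {
        "observed_diff_deg": obs,
        "p": p,
        "cohens_d": obs / sd if sd > 0 else (0.0 if obs == 0 else np.inf * np.sign(obs)),
        "n": n,
        "n_perm": n_perm,
        "seed": seed,
    }
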