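"""Model-based serial-dependence analysis.

The chain: condition each trial's response error on the orientation
difference from a neighbouring trial (previous stimulus or previous
response), smooth the error-vs-difference scatter with a 20° moving
average, and fit a first-derivative-of-Gaussian (DoG) tuning curve

    y(x) = x · a · w · c · exp(−(w·x)²) + b,      c = √2 · e^{1/2},

whose amplitude ``a`` equals the curve's peak height above baseline
(the extremum sits at x* = 1/(w√2)) and whose width parameter ``w``
(1/degrees) is constrained to [0.02, 0.2].  Positive ``a`` means the
current report is attracted toward the previous reference.

Significance is assessed non-parametrically: a sign-flip permutation
test for a single amplitude (each participant's errors are negated with
probability 1/2, the pooled curve refit) and a within-participant
label-swap permutation test for the difference between two conditions.

The permutation loops are heavily vectorised: per-participant window
sums over 1° delta bins are precomputed once, so each permutation is a
matrix product followed by a closed-form least-squares DoG fit on a
width grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .circstats import axial_delta

__all__ = [
    "DOG_CONSTANT",
    "W_BOUNDS",
    "ConditionedSeries",
    "DoGFit",
    "PermutationResult",
    "dog_value",
    "dog_peak_location",
    "condition_on_previous",
    "moving_average",
    "fit_dog",
    "permutation_test_amplitude",
    "permutation_test_difference",
    "alternate_flip",
]

DOG_CONSTANT: float = float(np.sqrt(2.0) * np.exp(0.5))
W_BOUNDS: tuple[float, float] = (0.02, 0.2)

GRID_DEG = np.arange(-89, 90, dtype=float)  # moving-average evaluation grid
_TRANSITIONS = ("LL", "LH", "HL", "HH")


# --------------------------------------------------------------------------
# DoG model
# --------------------------------------------------------------------------

def dog_value(x, a: float, w: float, b: float = 0.0):
    """First-derivative-of-Gaussian curve; ``a`` is the peak height above b."""
    if w <= 0:
        raise ValueError("w must be > 0")
    x = np.asarray(x, dtype=float)
    y = x * a * w * DOG_CONSTANT * np.exp(-((w * x) ** 2)) + b
    return float(y) if y.ndim == 0 else y


def dog_peak_location(w: float) -> float:
    """Delta at which the DoG attains its extremum: x* = 1/(w·√2)."""
    return 1.0 / (w * np.sqrt(2.0))


# --------------------------------------------------------------------------
# Conditioning on a neighbouring trial
# --------------------------------------------------------------------------

@dataclass
class ConditionedSeries:
    """(delta, error) pairs: error on trial t against the orientation
    difference between the reference trial t+offset and stimulus t."""

    data: pd.DataFrame  # columns: participant_id, delta_deg, error_deg, transition
    mode: Literal["stimulus_contingent", "response_contingent"]
    offset: int = -1
    transition: str = "pooled"

    def for_transition(self, transition: str) -> "ConditionedSeries":
        if transition == "pooled":
            return self
        if transition not in _TRANSITIONS:
            raise ValueError(f"unknown transition {transition!r}")
        return ConditionedSeries(
            self.data[self.data["transition"] == transition].reset_index(drop=True),
            self.mode,
            self.offset,
            transition,
        )


def condition_on_previous(
    table: pd.DataFrame,
    mode: Literal["stimulus_contingent", "response_contingent"],
    transition_filter: str | None = None,
    offset: int = -1,
) -> ConditionedSeries:
    """Pair each trial's error with its orientation difference from the
    reference trial at ``t + offset`` (−1 = previous trial; +1 gives the
    acausal control).

    The reference orientation is the neighbour's stimulus
    (stimulus-contingent) or its response (response-contingent); the
    transition label is (neighbour noise → current noise), e.g. "LH" =
    low-noise neighbour before a high-noise current trial.  Pairs never
    span participants and the boundary trial with no neighbour is dropped.
    """
    if offset == 0:
        raise ValueError("offset must be non-zero")
    if mode not in ("stimulus_contingent", "response_contingent"):
        raise ValueError(f"unknown mode {mode!r}")
    ref_col = "orientation_deg" if mode == "stimulus_contingent" else "response_deg"
    chunks = []
    for pid, g in table.groupby("participant_id", sort=False):
        g = g.sort_values("trial_index")
        ref = g[ref_col].to_numpy(dtype=float)
        noise = g["noise_level"].to_numpy()
        theta = g["orientation_deg"].to_numpy(dtype=float)
        err = g["error_deg"].to_numpy(dtype=float)
        n = len(g)
        t = np.arange(n)
        s = t + offset
        ok = (s >= 0) & (s < n)
        t, s = t[ok], s[ok]
        lab = np.char.add(
            np.where(noise[s] == "low", "L", "H"), np.where(noise[t] == "low", "L", "H")
        )
        chunks.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "delta_deg": axial_delta(ref[s], theta[t]),
                    "error_deg": err[t],
                    "transition": lab,
                }
            )
        )
    data = pd.concat(chunks, ignore_index=True)
    data = data.dropna(subset=["error_deg", "delta_deg"]).reset_index(drop=True)
    series = ConditionedSeries(data, mode, offset)
    if transition_filter is not None:
        series = series.for_transition(transition_filter)
    return series


# --------------------------------------------------------------------------
# Moving average on the delta axis
# --------------------------------------------------------------------------

def _bin_sums(deltas: np.ndarray, errors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sums and counts of errors in the 180 one-degree delta bins
    [−90,−89), ..., [89,90)."""
    idx = np.floor(deltas).astype(int) + 90
    idx = np.clip(idx, 0, 179)
    sums = np.bincount(idx, weights=errors, minlength=180)
    counts = np.bincount(idx, minlength=180).astype(float)
    return sums, counts


def _boxcar_window(arr: np.ndarray, window_deg: int) -> np.ndarray:
    """Circular boxcar sum over the 180 delta bins, evaluated at integer
    grid points −89..89.  Window [d−W/2, d+W/2) covers exactly the bins
    with left edge in {d−W/2, ..., d+W/2−1}, so the sum is exact."""
    half = window_deg // 2
    # grid point d (degrees) -> bins (d-half .. d+half-1), circular over 180
    kernel_offsets = np.arange(-half, half)
    grid_bins = (GRID_DEG.astype(int)[:, None] + 90 + kernel_offsets[None, :]) % 180
    return arr[..., grid_bins].sum(axis=-1)


def moving_average(
    series: ConditionedSeries | pd.DataFrame, window_deg: int = 20
) -> pd.DataFrame:
    """Mean error in a sliding ``window_deg`` window of delta, evaluated at
    1° steps on −89..89; the window wraps at the ±90 axial boundary.
    Empty windows yield NaN (flagged via the ``n`` column)."""
    data = series.data if isinstance(series, ConditionedSeries) else series
    if window_deg <= 0 or window_deg % 2:
        raise ValueError("window_deg must be a positive even integer")
    sums, counts = _bin_sums(
        data["delta_deg"].to_numpy(dtype=float), data["error_deg"].to_numpy(dtype=float)
    )
    wsum = _boxcar_window(sums, window_deg)
    wcount = _boxcar_window(counts, window_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wcount > 0, wsum / np.maximum(wcount, 1e-300), np.nan)
    return pd.DataFrame({"delta_deg": GRID_DEG, "mean_error_deg": mean, "n": wcount})


# --------------------------------------------------------------------------
# DoG fitting
# --------------------------------------------------------------------------

@dataclass
class DoGFit:
    a: float
    w: float
    b: float
    rmse: float
    converged: bool = True
    w_at_bound: bool = False


def _w_grid(n: int = 91) -> np.ndarray:
    return np.linspace(W_BOUNDS[0], W_BOUNDS[1], n)


def _grid_fit_curves(
    x: np.ndarray, Y: np.ndarray, w_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form least-squares DoG fit of many curves at once.

    For fixed w the model is linear in (a, b); we sweep a grid of w
    values, solve each in closed form, and keep the best.  ``Y`` has one
    curve per row, evaluated at ``x``.  Returns (a, w, rss) per row.
    """
    if w_grid is None:
        w_grid = _w_grid()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G = x.size
    # basis g_w(x), one row per w
    B = x[None, :] * w_grid[:, None] * DOG_CONSTANT * np.exp(
        -((w_grid[:, None] * x[None, :]) ** 2)
    )
    g_mean = B.mean(axis=1)                      # (W,)
    g_var = B.var(axis=1)                        # (W,)
    y_mean = Y.mean(axis=1)                      # (P,)
    y_var_tot = ((Y - y_mean[:, None]) ** 2).sum(axis=1)  # (P,)
    cov = Y @ B.T / G - y_mean[:, None] * g_mean[None, :]  # (P, W)
    a_all = cov / np.maximum(g_var[None, :], 1e-300)
    rss_all = y_var_tot[:, None] - G * a_all**2 * g_var[None, :]
    best = np.argmin(rss_all, axis=1)
    rows = np.arange(Y.shape[0])
    return a_all[rows, best], w_grid[best], np.maximum(rss_all[rows, best], 0.0)


def fit_dog(
    curve: pd.DataFrame,
    w_bounds: tuple[float, float] = W_BOUNDS,
    polish: bool = True,
) -> DoGFit:
    """Least-squares DoG fit to a smoothed curve.

    A dense grid over w (with closed-form (a, b) at each w) avoids the
    local minima of joint optimisation; the best grid point optionally
    seeds a bounded trust-region refinement.  A fit whose w lands on a
    bound is flagged (``w_at_bound``), mirroring the instability such
    fits signal during resampling.
    """
    ok = np.isfinite(curve["mean_error_deg"].to_numpy(dtype=float))
    x = curve["delta_deg"].to_numpy(dtype=float)[ok]
    y = curve["mean_error_deg"].to_numpy(dtype=float)[ok]
    if x.size < 20:
        raise ValueError("need >= 20 valid grid points to fit")
    w_grid = np.linspace(w_bounds[0], w_bounds[1], 91)
    a0, w0, rss0 = _grid_fit_curves(x, y[None, :], w_grid)
    a, w, rss = float(a0[0]), float(w0[0]), float(rss0[0])
    b = float(np.mean(y) - a * np.mean(
        x * w * DOG_CONSTANT * np.exp(-((w * x) ** 2))
    ))
    converged = True
    if polish:
        def resid(p):
            return dog_value(x, p[0], p[1], p[2]) - y

        try:
            sol = least_squares(
                resid,
                x0=[a, w, b],
                bounds=([-np.inf, w_bounds[0], -np.inf], [np.inf, w_bounds[1], np.inf]),
                method="trf",
            )
            converged = bool(sol.success)
            if sol.success and np.sum(sol.fun**2) <= rss + 1e-12:
                a, w, b = (float(v) for v in sol.x)
                rss = float(np.sum(sol.fun**2))
        except Exception:  # pragma: no cover - defensive
            converged = False
    tol = 1e-6
    return DoGFit(
        a=a,
        w=w,
        b=b,
        rmse=float(np.sqrt(rss / x.size)),
        converged=converged,
        w_at_bound=(w - w_bounds[0] < tol or w_bounds[1] - w < tol),
    )


# --------------------------------------------------------------------------
# Permutation tests
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_stat: float
    n_perm: int
    p: float
    seed: int
    observed_fit: DoGFit | None = None
    extra: dict = field(default_factory=dict)

    @property
    def p_display(self) -> str:
        """Zero exceedances are reported as a bound, not as p = 0."""
        return f"< {1.0 / self.n_perm:g}" if self.p == 0 else f"{self.p:g}"


def _participant_window_arrays(
    data: pd.DataFrame, window_deg: int
) -> tuple[list, np.ndarray, np.ndarray]:
    """Per-participant boxcar window sums/counts on the delta grid."""
    pids, sums, counts = [], [], []
    for pid, g in data.groupby("participant_id", sort=False):
        s, c = _bin_sums(
            g["delta_deg"].to_numpy(dtype=float), g["error_deg"].to_numpy(dtype=float)
        )
        pids.append(pid)
        sums.append(_boxcar_window(s, window_deg))
        counts.append(_boxcar_window(c, window_deg))
    return pids, np.array(sums), np.array(counts)


def _pooled_amplitudes(
    wsum: np.ndarray, wcount_total: np.ndarray, w_grid: np.ndarray
) -> np.ndarray:
    """Grid-fit DoG amplitudes of pooled (trial-weighted) curves.

    ``wsum`` holds one pooled window-sum vector per row; grid points with
    no trials are excluded from the fit (the same mask for every row,
    since sign flips leave counts unchanged).
    """
    valid = wcount_total > 0
    if valid.sum() < 20:
        raise ValueError("too few populated windows to fit")
    Y = wsum[:, valid] / wcount_total[valid][None, :]
    a, _, _ = _grid_fit_curves(GRID_DEG[valid], Y, w_grid)
    return a


def permutation_test_amplitude(
    series: ConditionedSeries,
    n_perm: int = 10000,
    seed: int = 0,
    window_deg: int = 20,
    w_grid_size: int = 61,
) -> PermutationResult:
    """Sign-flip permutation test of the pooled DoG amplitude.

    The observed statistic is the amplitude fitted to the trial-weighted
    pooled moving average.  Under each permutation every participant's
    errors are independently negated with probability 1/2 (a uniform draw
    over participant subsets), the pooled curve is rebuilt and refit, and
    p is the fraction of permutations with |a_perm| ≥ |a_observed|.  The
    identical grid-based fitting route is used for the observed and the
    permuted statistics.
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p value", stacklevel=2)
    pids, WS, WC = _participant_window_arrays(series.data, window_deg)
    if len(pids) < 2:
        raise ValueError("need at least 2 participants")
    total_counts = WC.sum(axis=0)
    w_grid = _w_grid(w_grid_size)
    a_obs = float(_pooled_amplitudes(WS.sum(axis=0)[None, :], total_counts, w_grid)[0])
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(pids)))
    a_perm = _pooled_amplitudes(signs @ WS, total_counts, w_grid)
    p = float(np.mean(np.abs(a_perm) >= abs(a_obs)))
    obs_fit = fit_dog(
        moving_average(series, window_deg), polish=True
    )
    return PermutationResult(
        observed_stat=a_obs,
        n_perm=n_perm,
        p=p,
        seed=seed,
        observed_fit=obs_fit,
        extra={"n_participants": len(pids), "mode": series.mode,
               "transition": series.transition},
    )


def permutation_test_difference(
    series_a: ConditionedSeries,
    series_b: ConditionedSeries,
    n_perm: int = 10000,
    seed: int = 0,
    window_deg: int = 20,
    w_grid_size: int = 61,
    swap: Literal["participant", "trial"] = "participant",
) -> PermutationResult:
    """Label-swap permutation test of the amplitude difference a_A − a_B.

    Condition labels are swapped within participants (all of a
    participant's trials together, preserving within-participant
    dependence; ``swap="trial"`` swaps individual trials instead), both
    pooled curves are refit, and p is the fraction of permuted
    |difference| ≥ |observed|.
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p value", stacklevel=2)
    da, db = series_a.data, series_b.data
    pids = sorted(set(da["participant_id"]) & set(db["participant_id"]))
    missing = set(da["participant_id"]) ^ set(db["participant_id"])
    if missing:
        raise ValueError(f"participants missing from one condition: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    if swap == "trial":
        pooled = pd.concat([da.assign(_c=0), db.assign(_c=1)], ignore_index=True)
        return _trialwise_difference(pooled, n_perm, rng, window_deg, w_grid_size, seed)
    _, WSa, WCa = _participant_window_arrays(
        da[da["participant_id"].isin(pids)], window_deg
    )
    _, WSb, WCb = _participant_window_arrays(
        db[db["participant_id"].isin(pids)], window_deg
    )
    w_grid = _w_grid(w_grid_size)

    def diff_of(sum_a, cnt_a, sum_b, cnt_b):
        aa = _pooled_amplitudes(sum_a, cnt_a.ravel(), w_grid)
        ab = _pooled_amplitudes(sum_b, cnt_b.ravel(), w_grid)
        return aa - ab

    obs = float(
        diff_of(
            WSa.sum(axis=0)[None, :], WCa.sum(axis=0),
            WSb.sum(axis=0)[None, :], WCb.sum(axis=0),
        )[0]
    )
    swaps = rng.random((n_perm, len(pids))) < 0.5  # True -> labels exchanged
    m = swaps.astype(float)
    sum_a = (1 - m) @ WSa + m @ WSb
    cnt_a = (1 - m) @ WCa + m @ WCb
    sum_b = m @ WSa + (1 - m) @ WSb
    cnt_b = m @ WCa + (1 - m) @ WCb
    # counts differ per permutation here, so fit row by row with shared mask
    diffs = np.empty(n_perm)
    valid_all = (cnt_a > 0) & (cnt_b > 0)
    for i in range(n_perm):
        v = valid_all[i]
        ya = sum_a[i, v] / cnt_a[i, v]
        yb = sum_b[i, v] / cnt_b[i, v]
        a2, _, _ = _grid_fit_curves(GRID_DEG[v], np.vstack([ya, yb]), w_grid)
        diffs[i] = a2[0] - a2[1]
    p = float(np.mean(np.abs(diffs) >= abs(obs)))
    return PermutationResult(
        observed_stat=obs, n_perm=n_perm, p=p, seed=seed,
        extra={"n_participants": len(pids), "swap": swap},
    )


def _trialwise_difference(pooled, n_perm, rng, window_deg, w_grid_size, seed):
    w_grid = _w_grid(w_grid_size)
    deltas = pooled["delta_deg"].to_numpy(dtype=float)
    errors = pooled["error_deg"].to_numpy(dtype=float)
    labels = pooled["_c"].to_numpy()

    def stat(lab):
        sa, ca = _bin_sums(deltas[lab == 0], errors[lab == 0])
        sb, cb = _bin_sums(deltas[lab == 1], errors[lab == 1])
        wa, wb = _boxcar_window(sa, window_deg), _boxcar_window(sb, window_deg)
        na, nb = _boxcar_window(ca, window_deg), _boxcar_window(cb, window_deg)
        v = (na > 0) & (nb > 0)
        a2, _, _ = _grid_fit_curves(
            GRID_DEG[v], np.vstack([wa[v] / na[v], wb[v] / nb[v]]), w_grid
        )
        return float(a2[0] - a2[1])

    obs = stat(labels)
    diffs = np.empty(n_perm)
    for i in range(n_perm):
        flip = rng.random(labels.size) < 0.5
        diffs[i] = stat(np.where(flip, 1 - labels, labels))
    p = float(np.mean(np.abs(diffs) >= abs(obs)))
    return PermutationResult(observed_stat=obs, n_perm=n_perm, p=p, seed=seed,
                             extra={"swap": "trial"})


# --------------------------------------------------------------------------
# Alternate-flip control
# --------------------------------------------------------------------------

def alternate_flip(table: pd.DataFrame) -> pd.DataFrame:
    """Invert the order of even-numbered trials within each participant.

    Trial 2 swaps contents with the last even trial, 4 with the second
    last, and so on; odd trials stay put.  Each trial keeps its own
    (orientation, response, noise) pairing, but temporal adjacency is
    destroyed — any "serial dependence" surviving this shuffle is
    artifactual (e.g. a shared orientation-dependent bias).  Applying the
    flip twice restores the original table.
    """
    out = []
    content_cols = [c for c in table.columns if c not in ("participant_id", "trial_index")]
    for _, g in table.groupby("participant_id", sort=False):
        g = g.sort_values("trial_index").reset_index(drop=True)
        if len(g) < 4:
            raise ValueError("need at least 4 trials per participant")
        even = np.flatnonzero(g["trial_index"].to_numpy() % 2 == 0)
        h = g.copy()
        for col in content_cols:
            vals = g[col].to_numpy()
            h.loc[even, col] = vals[even[::-1]]
        out.append(h)
    return pd.concat(out, ignore_index=True)
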