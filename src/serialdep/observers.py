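"""Synthetic observers for the adjustment and binary-choice tasks.

The generator is the study's ground truth: every bias the analysis
chain is supposed to detect or remove is injected here with known
parameters.  An adjustment-task trial is produced as

    percept   p_t = wrap(θ_t + ε_t),        ε_t ~ wrapped normal, SD σ(noise_t)
    pull          = DoG(Δ(r_{t−1}, p_t); a(transition), w)
    response      = wrap(p_t + pull + global bias + oblique(θ_t) [+ lapse])

where the reference r is the previous percept or the previous response
(the latter makes the process genuinely recursive), Δ is the signed
axial difference, and the DoG amplitude may depend on the noise-level
transition — the device used to build ground truth for
"current-noise-only" effects.  Lapses replace the response with a
uniform random orientation.

Noise levels follow a randomized sequence balancing the four transition
types (low→low, low→high, high→low, high→high) to within one trial, as
in the balanced designs used for this kind of experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .circstats import axial_delta, wrap_axial
from .serial import DOG_CONSTANT, W_BOUNDS, dog_value

__all__ = [
    "ObserverParams",
    "balanced_noise_sequence",
    "oblique_bias",
    "simulate_adjustment_session",
    "simulate_experiment",
    "simulate_binary_session",
    "simulate_binary_experiment",
    "ADJUSTMENT_COLUMNS",
]

ADJUSTMENT_COLUMNS = [
    "participant_id",
    "trial_index",
    "orientation_deg",
    "noise_level",
    "position_index",
    "response_deg",
    "error_deg",
]

_TRANSITIONS = ("LL", "LH", "HL", "HH")


@dataclass
class ObserverParams:
    """Generative parameters of one synthetic observer.

    ``dog_amplitude_deg`` is either a scalar (same attraction in every
    transition) or a mapping over transition labels "LL", "LH", "HL",
    "HH" (previous → current noise).  ``oblique_coeffs`` maps noise level
    to an (n_harmonics, 2) array of [sin, cos] coefficients of harmonics
    of period 180°/k — the orientation-dependent bias the pipeline's
    sum-of-sines stage must remove.
    """

    dog_amplitude_deg: float | Mapping[str, float] = 2.5
    dog_width: float = 0.05
    sigma_low_deg: float = 4.0
    sigma_high_deg: float = 8.0
    global_bias_deg: float = 0.0
    oblique_coeffs: Mapping[str, np.ndarray] | None = None
    lapse_rate: float = 0.01
    conditioning: Literal["previous_percept", "previous_response"] = "previous_response"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.sigma_low_deg <= self.sigma_high_deg):
            raise ValueError("need 0 <= sigma_low <= sigma_high")
        if not (0 <= self.lapse_rate < 1):
            raise ValueError("lapse_rate must be in [0, 1)")
        if not (W_BOUNDS[0] <= self.dog_width <= W_BOUNDS[1]):
            raise ValueError(f"dog_width must lie in {W_BOUNDS}")
        if self.conditioning not in ("previous_percept", "previous_response"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if isinstance(self.dog_amplitude_deg, Mapping):
            missing = set(_TRANSITIONS) - set(self.dog_amplitude_deg)
            if missing:
                raise ValueError(f"missing transition amplitudes: {sorted(missing)}")

    def amplitude(self, transition: str) -> float:
        if isinstance(self.dog_amplitude_deg, Mapping):
            return float(self.dog_amplitude_deg[transition])
        return float(self.dog_amplitude_deg)

    @property
    def max_amplitude(self) -> float:
        if isinstance(self.dog_amplitude_deg, Mapping):
            return max(abs(v) for v in self.dog_amplitude_deg.values())
        return abs(self.dog_amplitude_deg)


# --------------------------------------------------------------------------
# Balanced noise sequence (Eulerian-path construction)
# --------------------------------------------------------------------------

def _path_feasible(node: str, ll: int, lh: int, hl: int, hh: int) -> bool:
    """Can a path from ``node`` consume exactly the remaining transition
    counts?  (Eulerian-path condition on the two-node multigraph.)"""
    if min(ll, lh, hl, hh) < 0:
        return False
    if ll + lh + hl + hh == 0:
        return True
    if lh + hl == 0:  # only self-transitions left: must all sit at the current node
        return (node == "L" and hh == 0) or (node == "H" and ll == 0)
    d = lh - hl
    return d in (0, 1) if node == "L" else -d in (0, 1)


def balanced_noise_sequence(n_trials: int, seed_or_rng) -> np.ndarray:
    """Random low/high sequence whose four transition-type counts differ
    by at most one; deterministic per seed."""
    if n_trials < 5:
        raise ValueError("n_trials must be >= 5")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n_trans = n_trials - 1
    base, rem = divmod(n_trans, 4)
    counts = dict.fromkeys(_TRANSITIONS, base)
    for t in rng.permutation(_TRANSITIONS)[:rem]:
        counts[t] += 1
    ll, lh, hl, hh = counts["LL"], counts["LH"], counts["HL"], counts["HH"]
    starts = [s for s in rng.permutation(["L", "H"]) if _path_feasible(s, ll, lh, hl, hh)]
    node = starts[0]
    seq = [node]
    remaining = {"LL": ll, "LH": lh, "HL": hl, "HH": hh}
    for _ in range(n_trans):
        for nxt in rng.permutation(["L", "H"]):
            edge = node + nxt
            remaining[edge] -= 1
            if _path_feasible(nxt, remaining["LL"], remaining["LH"],
                              remaining["HL"], remaining["HH"]):
                seq.append(nxt)
                node = nxt
                break
            remaining[edge] += 1
        else:  # pragma: no cover - construction is always feasible
            raise RuntimeError("balanced sequence construction failed")
    return np.where(np.array(seq) == "L", "low", "high")


# --------------------------------------------------------------------------
# Adjustment task
# --------------------------------------------------------------------------

def oblique_bias(orientation_deg, coeffs: np.ndarray) -> np.ndarray:
    """Sum-of-sinusoids orientation bias: Σ_k a_k sin(2πkθ/180) + b_k cos(·)."""
    theta = np.asarray(orientation_deg, dtype=float)
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    out = np.zeros_like(theta)
    for k, (a_k, b_k) in enumerate(coeffs, start=1):
        arg = 2.0 * np.pi * k * theta / 180.0
        out = out + a_k * np.sin(arg) + b_k * np.cos(arg)
    return out


def simulate_adjustment_session(
    params: ObserverParams,
    n_trials: int = 821,
    participant_id: str = "p01",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one observer's adjustment session.

    The first trial carries no attraction (no previous reference).  With
    response conditioning the simulation runs sequentially, since each
    response feeds the next trial's pull; with percept conditioning (or a
    zero-amplitude observer) the whole session vectorises.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    theta = rng.uniform(0.0, 180.0, n_trials)
    noise = balanced_noise_sequence(n_trials, rng)
    sigma = np.where(noise == "low", params.sigma_low_deg, params.sigma_high_deg)
    percept = wrap_axial(theta + rng.normal(0.0, 1.0, n_trials) * sigma)
    lapse_mask = rng.random(n_trials) < params.lapse_rate
    lapse_vals = rng.uniform(0.0, 180.0, n_trials)

    bias = np.full(n_trials, params.global_bias_deg, dtype=float)
    if params.oblique_coeffs is not None:
        for level, coeffs in params.oblique_coeffs.items():
            m = noise == level
            bias[m] += oblique_bias(theta[m], coeffs)

    trans = np.char.add(
        np.where(noise == "low", "L", "H")[:-1], np.where(noise == "low", "L", "H")[1:]
    )
    amp = np.zeros(n_trials)
    amp[1:] = [params.amplitude(t) for t in trans] if isinstance(
        params.dog_amplitude_deg, Mapping
    ) else params.amplitude("LL")
    amp[0] = 0.0

    sequential = params.conditioning == "previous_response" and params.max_amplitude > 0
    if not sequential:
        pull = np.zeros(n_trials)
        delta = axial_delta(percept[:-1], percept[1:])
        pull[1:] = delta * amp[1:] * params.dog_width * DOG_CONSTANT * np.exp(
            -((params.dog_width * delta) ** 2)
        )
        response = np.where(
            lapse_mask, lapse_vals, wrap_axial(percept + pull + bias)
        )
    else:
        response = np.empty(n_trials)
        w = params.dog_width
        for t in range(n_trials):
            pull = 0.0
            if t > 0:
                pull = dog_value(axial_delta(response[t - 1], percept[t]), amp[t], w)
            r = wrap_axial(percept[t] + pull + bias[t])
            response[t] = lapse_vals[t] if lapse_mask[t] else r

    start = int(rng.integers(0, 8))
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": np.arange(1, n_trials + 1),
            "orientation_deg": theta,
            "noise_level": noise,
            "position_index": (start - np.arange(n_trials)) % 8,
            "response_deg": response,
            "error_deg": axial_delta(response, theta),
        }
    )


def simulate_experiment(
    params: ObserverParams,
    n_participants: int = 20,
    n_trials: int = 821,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort sharing one set of generative parameters; each
    participant gets an independent RNG stream spawned from the seed."""
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    tables = []
    for i, child in enumerate(root.spawn(n_participants), start=1):
        tables.append(
            simulate_adjustment_session(
                params,
                n_trials=n_trials,
                participant_id=f"p{i:02d}",
                rng=np.random.default_rng(child),
            )
        )
    return pd.concat(tables, ignore_index=True)


# --------------------------------------------------------------------------
# Binary choice task
# --------------------------------------------------------------------------

def simulate_binary_session(
    spread_low_deg: float,
    spread_high_deg: float,
    n_trials: int = 200,
    seed: int | np.random.Generator = 0,
    participant_id: str = "p01",
    design_range_factor: float = 3.0,
) -> pd.DataFrame:
    """Two-block left/right session governed by a cumulative Gaussian:
    P(right | x) = Φ(x / spread), with the noise level setting the spread
    and x drawn uniformly on ±design_range_factor · spread."""
    if spread_low_deg <= 0 or spread_high_deg <= 0:
        raise ValueError("spreads must be > 0")
    from scipy.stats import norm

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    idx = 1
    for level, spread in (("low", spread_low_deg), ("high", spread_high_deg)):
        half = min(design_range_factor * spread, 89.0)
        x = rng.uniform(-half, half, n_trials)
        p_right = norm.cdf(x / spread)
        choice = np.where(rng.random(n_trials) < p_right, "right", "left")
        for xi, ci in zip(x, choice):
            rows.append((participant_id, idx, level, float(xi), ci))
            idx += 1
    return pd.DataFrame(
        rows,
        columns=["participant_id", "trial_index", "noise_level",
                 "signed_orientation_deg", "choice"],
    )


def simulate_binary_experiment(
    n_participants: int = 16,
    spread_low_deg: float = 4.23,
    spread_high_deg: float = 25.24,
    between_participant_cv: float = 0.2,
    n_trials: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort of binary sessions with log-normal between-participant
    variation (coefficient of variation ``between_participant_cv``)
    around the group-level spreads."""
    root = np.random.SeedSequence(seed)
    tables = []
    s = np.sqrt(np.log1p(between_participant_cv**2))
    for i, child in enumerate(root.spawn(n_participants), start=1):
        rng = np.random.default_rng(child)
        mult = np.exp(rng.normal(-0.5 * s * s, s, 2))
        tables.append(
            simulate_binary_session(
                spread_low_deg * mult[0],
                spread_high_deg * mult[1],
                n_trials=n_trials,
                seed=rng,
                participant_id=f"p{i:02d}",
            )
        )
    return pd.concat(tables, ignore_index=True)
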