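"""Removal of orientation-dependent (oblique) response biases.

Observers show systematic errors that depend on the stimulus
orientation itself — classically largest away from the cardinal axes.
Left in place, such a bias is shared between neighbouring trials and
masquerades as serial dependence in response-contingent analyses.  The
correction fits, per participant and per noise level (uncertainty is
known to change the oblique pattern), a sum of sinusoids of orientation

    bias(θ) = Σ_{k=1..K} α_k sin(2πkθ/180) + β_k cos(2πkθ/180)

by ordinary least squares and subtracts the predicted bias from each
error.  K defaults to 2: the k = 2 harmonic carries the classic
four-fold oblique pattern, k = 1 any 180°-periodic asymmetry.

The correction is applied only in response-contingent analyses;
stimulus-contingent analyses are left uncorrected because
uncertainty-dependent differences in the oblique pattern could inject
artifacts there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ObliqueFit", "design_matrix", "fit_sum_of_sines", "fit_all", "residualize"]


@dataclass
class ObliqueFit:
    participant_id: str
    noise_level: str
    sin_coeffs: np.ndarray   # α_k, k = 1..K
    cos_coeffs: np.ndarray   # β_k
    residual_sd: float
    rank_deficient: bool = False

    @property
    def n_harmonics(self) -> int:
        return len(self.sin_coeffs)

    @property
    def amplitudes(self) -> np.ndarray:
        """Per-harmonic amplitude √(α_k² + β_k²)."""
        return np.hypot(self.sin_coeffs, self.cos_coeffs)

    def predict(self, orientation_deg) -> np.ndarray:
        theta = np.asarray(orientation_deg, dtype=float)
        out = np.zeros_like(theta)
        for k in range(1, self.n_harmonics + 1):
            arg = 2.0 * np.pi * k * theta / 180.0
            out = out + self.sin_coeffs[k - 1] * np.sin(arg)
            out = out + self.cos_coeffs[k - 1] * np.cos(arg)
        return out


def design_matrix(orientation_deg: np.ndarray, n_harmonics: int) -> np.ndarray:
    theta = np.asarray(orientation_deg, dtype=float)
    cols = []
    for k in range(1, n_harmonics + 1):
        arg = 2.0 * np.pi * k * theta / 180.0
        cols.append(np.sin(arg))
        cols.append(np.cos(arg))
    return np.column_stack(cols)


def fit_sum_of_sines(
    orientations,
    errors,
    n_harmonics: int = 2,
    participant_id: str = "",
    noise_level: str = "",
) -> ObliqueFit:
    """Least-squares fit of the harmonic bias model to (orientation, error).

    Requires at least 8 data points per harmonic.  A rank-deficient
    design (orientations clustered so the harmonics are not separable)
    is flagged on the returned fit rather than raised — the coefficients
    are then the minimum-norm solution.
    """
    theta = np.asarray(orientations, dtype=float)
    err = np.asarray(errors, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(err)
    theta, err = theta[ok], err[ok]
    if theta.size < 8 * n_harmonics:
        raise ValueError(
            f"need >= {8 * n_harmonics} points for {n_harmonics} harmonics, "
            f"got {theta.size}"
        )
    X = design_matrix(theta, n_harmonics)
    coef, _, rank, _ = np.linalg.lstsq(X, err, rcond=None)
    resid = err - X @ coef
    return ObliqueFit(
        participant_id=participant_id,
        noise_level=noise_level,
        sin_coeffs=coef[0::2].copy(),
        cos_coeffs=coef[1::2].copy(),
        residual_sd=float(resid.std(ddof=min(X.shape[1], resid.size - 1))),
        rank_deficient=rank < X.shape[1],
    )


def fit_all(table: pd.DataFrame, n_harmonics: int = 2) -> dict[tuple[str, str], ObliqueFit]:
    """One fit per participant × noise level, high and low modelled separately."""
    fits = {}
    for (pid, level), g in table.groupby(["participant_id", "noise_level"], sort=False):
        fits[(pid, level)] = fit_sum_of_sines(
            g["orientation_deg"], g["error_deg"], n_harmonics,
            participant_id=str(pid), noise_level=str(level),
        )
    return fits


def residualize(
    table: pd.DataFrame, fits: dict[tuple[str, str], ObliqueFit]
) -> pd.DataFrame:
    """Subtract each row's predicted oblique bias from its error.

    Every participant × noise-level cell present in the table must have a
    fit; a missing fit is a hard error, not a silent pass-through.
    """
    out = table.reset_index(drop=True).copy()
    err = out["error_deg"].to_numpy(dtype=float).copy()
    for (pid, level), g in out.groupby(["participant_id", "noise_level"], sort=False):
        key = (pid, level)
        if key not in fits:
            raise KeyError(f"no oblique fit for participant {pid!r}, {level} noise")
        err[g.index.to_numpy()] -= fits[key].predict(
            g["orientation_deg"].to_numpy(dtype=float)
        )
    out["error_deg"] = err
    return out


def fits_to_frame(fits: dict[tuple[str, str], ObliqueFit]) -> pd.DataFrame:
    """Flatten a fit dict for CSV export."""
    rows = []
    for (pid, level), f in fits.items():
        row = {"participant_id": pid, "noise_level": level,
               "residual_sd": f.residual_sd, "rank_deficient": f.rank_deficient}
        for k in range(f.n_harmonics):
            row[f"sin_{k + 1}"] = f.sin_coeffs[k]
            row[f"cos_{k + 1}"] = f.cos_coeffs[k]
        rows.append(row)
    return pd.DataFrame(rows)
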