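"""Axial (180°-periodic) angle arithmetic and statistics.

Orientations are axial data: an orientation of 10° is indistinguishable
from 190°.  All statistics here therefore work on doubled angles — an
axial angle θ is mapped to the circular angle 2θ, circular machinery is
applied, and the result is halved.  Public angles are in degrees; radians
appear only inside function bodies.

Conventions
-----------
* Orientations live in [0, 180).
* Signed differences (and response errors) live in [−90, 90): the
  interval is half-open, −90 is included, and an exact ±90 tie maps
  to −90.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_delta",
    "axial_circular_mean",
    "axial_resultant_length",
    "axial_correlation",
]


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")


def wrap_axial(angle):
    """Wrap angles (degrees) into the orientation range [0, 180).

    Accepts scalars or arrays; non-finite input is rejected.
    """
    a = np.asarray(angle, dtype=float)
    _check_finite(a, "angle")
    out = np.mod(a, 180.0)
    # np.mod can return 180.0 for tiny negative inputs via rounding
    out = np.where(out >= 180.0, out - 180.0, out)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


def axial_delta(a, b):
    """Signed acute difference a − b on the axial circle, in [−90, 90).

    This is the standard quantity both for response errors
    (response − stimulus) and for inter-trial orientation differences.
    Exact ±90 ties map to −90.
    """
    a_ = np.asarray(a, dtype=float)
    b_ = np.asarray(b, dtype=float)
    _check_finite(a_, "a")
    _check_finite(b_, "b")
    d = np.mod(a_ - b_ + 90.0, 180.0) - 90.0
    d = np.where(d >= 90.0, d - 180.0, d)
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(d)
    return d


def axial_resultant_length(angles) -> float:
    """Resultant length of the doubled angles; 1 = perfectly concentrated,
    0 = no preferred orientation."""
    a = np.asarray(angles, dtype=float)
    _check_finite(a, "angles")
    if a.size == 0:
        raise ValueError("empty input")
    z = np.deg2rad(2.0 * a)
    return float(np.hypot(np.mean(np.sin(z)), np.mean(np.cos(z))))


def axial_circular_mean(angles, min_resultant: float = 1e-9) -> float:
    """Circular mean of axial angles (degrees), computed on doubled angles.

    Returns the mean direction in [−90, 90), matching the signed error
    convention (a list of response errors in [−90, 90) gets a mean on the
    same scale; the wrap boundary maps to −90, so e.g. [85, −85] → −90).

    Raises ``ValueError`` when the resultant length of the doubled angles
    is below ``min_resultant`` — a perfectly uniform input has no defined
    mean orientation.
    """
    a = np.asarray(angles, dtype=float)
    _check_finite(a, "angles")
    if a.size == 0:
        raise ValueError("empty input")
    z = np.deg2rad(2.0 * a)
    s, c = np.mean(np.sin(z)), np.mean(np.cos(z))
    if np.hypot(s, c) < min_resultant:
        raise ValueError("undefined circular mean: resultant length ~ 0")
    mean = np.rad2deg(np.arctan2(s, c)) / 2.0  # in (−90, 90]
    if mean >= 90.0:
        mean -= 180.0
    return float(mean)


def axial_correlation(x, y, min_spread: float = 1e-12) -> float:
    """Circular–circular association between two axial samples.

    Uses the Fisher–Lee correlation coefficient on doubled angles:

        r = Σ_{i<j} sin(α_i − α_j) sin(β_i − β_j)
            / sqrt( Σ_{i<j} sin²(α_i − α_j) · Σ_{i<j} sin²(β_i − β_j) )

    with α = 2x, β = 2y in radians.  r = 1 for y = x exactly and r ≈ 0
    for independent samples.  Degenerate (constant) input has no defined
    correlation and raises ``ValueError``.
    """
    x_ = np.asarray(x, dtype=float)
    y_ = np.asarray(y, dtype=float)
    _check_finite(x_, "x")
    _check_finite(y_, "y")
    if x_.shape != y_.shape or x_.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x_.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    a = np.deg2rad(2.0 * x_)
    b = np.deg2rad(2.0 * y_)
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    iu = np.triu_indices(n, k=1)
    num = float(np.sum(sa[iu] * sb[iu]))
    da = float(np.sum(sa[iu] ** 2))
    db = float(np.sum(sb[iu] ** 2))
    if da < min_spread or db < min_spread:
        raise ValueError("undefined correlation: degenerate (constant) sample")
    return num / np.sqrt(da * db)
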