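"""Orientation-filtered 1/f noise stimuli.

The stimuli are circular patches of pink (1/f) noise passed through an
orientation bandpass filter whose profile over Fourier-plane angle φ is a
double-angled von Mises kernel

    W(φ) ∝ exp(κ · cos 2(φ − φ₀)),

where κ controls the orientation bandwidth: κ = 4 gives a narrow
passband (low orientation noise), κ = 0.5 a broad one (high noise), and
κ = 0 an isotropic patch with no discernible orientation (used as a
mask between trials).  The filtered noise is contrast-normalised and
windowed by a circular Gaussian envelope.

Orientation convention: an image-plane stripe orientation θ (degrees,
axial) concentrates Fourier energy along the perpendicular wave-vector
direction, φ₀ = θ + 90°.  ``estimate_orientation_energy`` applies the
inverse mapping, so synthesising at θ and estimating the energy peak
round-trips to θ.  The filter acts on Fourier *amplitude*, not power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .circstats import wrap_axial

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusSpec",
    "StimulusImage",
    "OrientationEnergy",
    "pink_noise_field",
    "orientation_filter_weights",
    "synthesize_stimulus",
    "estimate_orientation_energy",
    "save_png",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one orientation-filtered noise patch."""

    orientation_deg: float
    kappa: float
    seed: int
    size_px: int = 256
    px_per_deg: float = 32.0
    envelope_sigma_deg: float = 1.5
    rms_contrast: float = 0.15

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.size_px < 64 or self.size_px % 2:
            raise ValueError("size_px must be even and >= 64")
        object.__setattr__(self, "orientation_deg", wrap_axial(self.orientation_deg))


@dataclass
class StimulusImage:
    """Rendered stimulus: pixels in [0, 1] around mid-gray 0.5."""

    pixels: np.ndarray
    spec: StimulusSpec
    clip_fraction: float = 0.0


@dataclass
class OrientationEnergy:
    """Fourier power marginalised into 1° orientation bins."""

    bin_centers_deg: np.ndarray   # 0.5, 1.5, ..., 179.5
    density: np.ndarray           # sums to 1
    peak_deg: float               # argmax bin center
    resultant_length: float       # concentration of doubled angles
    mean_deg: float = field(default=np.nan)


def pink_noise_field(size_px: int, seed: int) -> np.ndarray:
    """Zero-mean 1/f noise raster, deterministic per seed.

    White Gaussian noise is transformed to the Fourier domain and its
    amplitude spectrum reweighted by 1/f (the DC term is zeroed); random
    phases are inherited from the white noise.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size_px, size_px))
    spectrum = np.fft.fft2(white)
    fx = np.fft.fftfreq(size_px)
    f = np.hypot(fx[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, 1.0 / f, 0.0)
    field_ = np.fft.ifft2(spectrum * amp).real
    return field_ - field_.mean()


def orientation_filter_weights(size_px: int, orientation_deg: float, kappa: float) -> np.ndarray:
    """Double-angled von Mises weights over the Fourier plane, max 1.

    ``orientation_deg`` is the image-plane stripe orientation; the kernel
    is centred on the perpendicular Fourier angle.  κ = 0 yields uniform
    weights (all-pass).  The DC weight is set to 0: mean luminance is
    handled at render time, not leaked through the filter.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    fx = np.fft.fftfreq(size_px)
    phi = np.arctan2(fx[:, None], fx[None, :])  # angle of (fy, fx)
    phi0 = np.deg2rad(wrap_axial(orientation_deg) + 90.0)
    w = np.exp(kappa * (np.cos(2.0 * (phi - phi0)) - 1.0))  # max exactly 1
    # enforce W(-f) = W(f): the Nyquist row/column is its own negative
    # frequency and would otherwise break the Hermitian symmetry that keeps
    # the filtered field real
    idx = (-np.arange(size_px)) % size_px
    w = 0.5 * (w + w[np.ix_(idx, idx)])
    f = np.hypot(fx[:, None], fx[None, :])
    w[f == 0] = 0.0
    return w


def synthesize_stimulus(spec: StimulusSpec) -> StimulusImage:
    """Render one stimulus: pink noise × orientation filter, RMS-contrast
    normalised, Gaussian-windowed, mid-gray added, clipped to [0, 1]."""
    sigma_px = spec.envelope_sigma_deg * spec.px_per_deg
    if 4.0 * sigma_px > spec.size_px:
        raise ValueError(
            f"envelope (sigma {sigma_px:.0f} px) too large for raster {spec.size_px}"
        )
    noise = pink_noise_field(spec.size_px, spec.seed)
    weights = orientation_filter_weights(spec.size_px, spec.orientation_deg, spec.kappa)
    img = np.fft.ifft2(np.fft.fft2(noise) * weights).real
    img *= spec.rms_contrast / img.std()
    c = np.arange(spec.size_px) - (spec.size_px - 1) / 2.0
    r2 = c[:, None] ** 2 + c[None, :] ** 2
    img *= np.exp(-r2 / (2.0 * sigma_px**2))
    pixels = img + 0.5
    clipped = np.mean((pixels < 0.0) | (pixels > 1.0))
    if clipped:
        logger.info("stimulus seed=%d: clipped %.3f%% of pixels", spec.seed, 100 * clipped)
    return StimulusImage(np.clip(pixels, 0.0, 1.0), spec, float(clipped))


def estimate_orientation_energy(
    image: StimulusImage | np.ndarray, min_cycles: float = 2.0
) -> OrientationEnergy:
    """Marginalise Fourier power over spatial frequency into orientation bins.

    Serves as the self-test oracle for the synthesis pipeline: the peak of
    the returned density should round-trip to the nominal stimulus
    orientation for concentrated filters.  Frequencies below ``min_cycles``
    cycles per image are excluded (the envelope dominates there and carries
    no orientation signal), and the power is pre-whitened by f² so that the
    1/f amplitude spectrum does not let a handful of noisy low-frequency
    coefficients dominate the orientation histogram — each frequency
    annulus then contributes in proportion to its coefficient count.
    """
    pixels = image.pixels if isinstance(image, StimulusImage) else np.asarray(image, float)
    if pixels.shape[0] < 64 or pixels.shape[1] < 64:
        raise ValueError("raster must be at least 64x64")
    if np.allclose(pixels, pixels.flat[0]):
        raise ValueError("constant image has no orientation energy")
    n = pixels.shape[0]
    spec = np.fft.fft2(pixels - pixels.mean())
    power = np.abs(spec) ** 2
    fx = np.fft.fftfreq(n)
    f = np.hypot(fx[:, None], fx[None, :])
    phi = np.arctan2(fx[:, None], fx[None, :])
    keep = (f * n >= min_cycles) & (f <= 0.5)
    power = power * f**2  # undo the 1/f amplitude weighting
    # Fourier angle -> image-plane stripe orientation (inverse of synthesis map)
    orient = np.mod(np.rad2deg(phi) - 90.0, 180.0)
    bins = np.clip(np.floor(orient[keep]).astype(int), 0, 179)
    density = np.bincount(bins, weights=power[keep], minlength=180)
    total = density.sum()
    if total <= 0:
        raise ValueError("image has no energy at retained frequencies")
    density = density / total
    centers = np.arange(180) + 0.5
    z = np.deg2rad(2.0 * centers)
    s = float(np.sum(density * np.sin(z)))
    c = float(np.sum(density * np.cos(z)))
    mean = wrap_axial(np.rad2deg(np.arctan2(s, c)) / 2.0)
    # smooth the histogram (circular Gaussian, SD 3 bins) before locating
    # the peak: the raw per-bin power is a small-count chi-square sum and
    # its argmax wanders over a flat-topped passband
    offs = np.arange(-9, 10)
    kern = np.exp(-0.5 * (offs / 3.0) ** 2)
    kern /= kern.sum()
    idx = (np.arange(180)[:, None] + offs[None, :]) % 180
    smoothed = (density[idx] * kern[None, :]).sum(axis=1)
    return OrientationEnergy(
        bin_centers_deg=centers,
        density=density,
        peak_deg=float(centers[int(np.argmax(smoothed))]),
        resultant_length=float(np.hypot(s, c)),
        mean_deg=float(mean),
    )


def save_png(image: StimulusImage, path) -> None:
    """Write the stimulus as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(image.pixels, 0, 1) * 255).astype(np.uint8))
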