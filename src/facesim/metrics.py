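"""Figures of merit for a frequency-encoded single-pixel microscope.

Covers image-quality and throughput metrics (contrast-to-noise ratio,
space-bandwidth-time product), the USAF-1951 resolution-chart formula, dip
detection on bar profiles, and the acousto-optic geometry that sets pixel
pitch, field of view, and the deflector time-bandwidth product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks


@dataclass(frozen=True)
class OpticsConfig:
    """Optical and acousto-optic constants.

    ``acoustic_velocity`` defaults to 650 m/s, the slow-shear velocity of a
    TeO2 deflector — a stated assumption, not a measured value.  ``comb_span``
    is the full RF modulation bandwidth per axis (f_end − f_start).
    """

    wavelength: float = 1030e-9        # m
    objective_focal: float = 7.5e-3    # m
    acoustic_velocity: float = 650.0   # m/s  (assumed slow-shear TeO2)
    beam_diameter: float = 5e-3        # m
    comb_span: float = 25e6            # Hz
    tones_per_axis: int = 80

    def __post_init__(self) -> None:
        for name in ("wavelength", "objective_focal", "acoustic_velocity",
                     "beam_diameter", "comb_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tones_per_axis < 1:
            raise ValueError("tones_per_axis must be >= 1")


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (for comparison with printed
    headline numbers)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1))


def cnr(image, target_mask, background_mask) -> float:
    """Contrast-to-noise ratio of a reconstructed amplitude image.

    (mean over target − mean over background) / sample std over background;
    the sign is preserved so dark-on-bright targets come out negative.
    """
    image = np.asarray(image, dtype=float)
    tmask = np.asarray(target_mask, dtype=bool)
    bmask = np.asarray(background_mask, dtype=bool)
    if image.shape != tmask.shape or image.shape != bmask.shape:
        raise ValueError("mask shapes must match the image")
    if np.any(tmask & bmask):
        raise ValueError("target and background masks must be disjoint")
    if tmask.sum() < 2 or bmask.sum() < 2:
        raise ValueError("each mask needs at least 2 pixels")
    bg = image[bmask]
    sigma = float(np.std(bg, ddof=1))
    if sigma == 0:
        raise ValueError("background has zero fluctuation; CNR undefined")
    return float((image[tmask].mean() - bg.mean()) / sigma)


def sbpt(fps: float, nx: int, ny: int, channels: int = 1) -> float:
    """Space-bandwidth-time product: FPS × frame size (× information channels).

    ``channels=2`` counts amplitude and phase of a complex-field system
    separately; intensity-only systems use ``channels=1``.  Use
    :func:`round_sig` to compare with 2-significant-figure headline values.
    """
    if fps <= 0 or nx <= 0 or ny <= 0 or channels not in (1, 2):
        raise ValueError("fps, nx, ny must be positive; channels in {1, 2}")
    return float(fps) * nx * ny * channels


def usaf_linewidth(group: int, element: int) -> float:
    """Line width (μm) of a USAF-1951 element: R = 2^(group + (element−1)/6)
    line pairs per mm, width = 1000 / (2R) μm."""
    if not 1 <= element <= 6:
        raise ValueError("element must be in 1..6")
    resolution = 2.0 ** (group + (element - 1) / 6.0)  # lp/mm
    return 1000.0 / (2.0 * resolution)


def profile_dips(profile, prominence: float | None = None) -> np.ndarray:
    """Locations of local minima (dips) in a 1-D profile.

    Used to confirm a three-bar element is resolved (exactly three dips across
    the bar region).  Default prominence threshold: 10% of the profile's
    dynamic range.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile must have at least 3 samples")
    if prominence is None:
        span = float(profile.max() - profile.min())
        if span == 0:
            return np.array([], dtype=int)
        prominence = 0.1 * span
    dips, _ = find_peaks(-profile, prominence=prominence)
    return dips


def pixel_pitch_and_fov(optics: OpticsConfig) -> tuple[float, float]:
    """Pixel pitch and field of view set by the deflection-angle-per-tone.

    One comb step ΔF/(tones−1) deflects by δθ = λ·Δf/V; at the objective focal
    plane that is a pitch Δx = f_obj·δθ, and the field of view spans the
    (tones−1) intervals: fov = (tones−1)·Δx.  Returns (pitch, fov) in metres.
    """
    if optics.tones_per_axis < 2:
        raise ValueError("tones_per_axis must be >= 2 for a finite pitch")
    dfreq = optics.comb_span / (optics.tones_per_axis - 1)
    dtheta = optics.wavelength * dfreq / optics.acoustic_velocity
    pitch = optics.objective_focal * dtheta
    return pitch, (optics.tones_per_axis - 1) * pitch


def time_bandwidth_product(optics: OpticsConfig) -> float:
    """N = (D/V)·ΔF: acoustic transit time across the beam aperture times the
    modulation bandwidth — the number of resolvable deflection spots per axis."""
    return optics.beam_diameter / optics.acoustic_velocity * optics.comb_span


def illumination_intensity(power_w: float = 100e-6, side_m: float = 300e-6) -> float:
    """Average illumination intensity in mW/cm² for ``power_w`` watts spread
    over a ``side_m`` × ``side_m`` field of view."""
    if power_w < 0 or side_m <= 0:
        raise ValueError("power must be >= 0 and side > 0")
    area_cm2 = (side_m * 100.0) ** 2
    return power_w * 1e3 / area_cm2


def storage_bytes(duration_s: float, sampling_rate: float, bytes_per_sample: float = 1.0) -> float:
    """Raw-trace storage requirement in bytes for continuous acquisition."""
    if duration_s < 0 or sampling_rate <= 0 or bytes_per_sample <= 0:
        raise ValueError("invalid storage parameters")
    return duration_s * sampling_rate * bytes_per_sample
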