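"""Gaussian-beam light-sheet geometry.

Quality-control utility for the acquisition metadata: the light sheet is
modelled as a Gaussian beam with waist radius ``w0 = λ / (π · NA)``, so its
full width at the waist (1/e² intensity convention, i.e. 2·w0) is
``2λ / (π · NA)`` and grows away from the waist as
``2·w0·sqrt(1 + (x / x_R)²)`` with Rayleigh range ``x_R = π·w0² / λ``.

Note the width convention: full 1/e² width (2w), which matches the printed
waist values for the 0.154-NA sheet (2.3 μm at 561 nm, 3.2 μm at 785 nm).
FWHM conventions differ by a factor ``sqrt(2 ln 2) / sqrt(2) ≈ 0.589``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["OpticsParams", "beam_waist_radius", "sheet_width_at_waist", "sheet_width_at_offset", "rayleigh_range"]


@dataclass
class OpticsParams:
    wavelength_um: float
    numerical_aperture: float
    lateral_offset_um: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must lie in (0, 1)")


def beam_waist_radius(wavelength_um: float, na: float) -> float:
    """Gaussian beam waist radius w0 = λ / (π · NA) in μm."""
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength_um / (math.pi * na)


def sheet_width_at_waist(wavelength_um: float, na: float) -> float:
    """Full 1/e² sheet width 2·w0 at the beam waist (μm)."""
    return 2.0 * beam_waist_radius(wavelength_um, na)


def rayleigh_range(wavelength_um: float, na: float) -> float:
    """Rayleigh range x_R = π·w0² / λ (μm)."""
    w0 = beam_waist_radius(wavelength_um, na)
    return math.pi * w0**2 / wavelength_um


def sheet_width_at_offset(wavelength_um: float, na: float, x_um: float) -> float:
    """Full 1/e² sheet width at lateral offset x from the waist (μm).

    Even and strictly increasing in |x|; equals the waist width at x = 0 and
    ``2·w0·sqrt(2)`` at one Rayleigh range.
    """
    if x_um < 0:
        x_um = -x_um
    w0 = beam_waist_radius(wavelength_um, na)
    xr = rayleigh_range(wavelength_um, na)
    return 2.0 * w0 * math.sqrt(1.0 + (x_um / xr) ** 2)
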