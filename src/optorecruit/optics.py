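"""Illumination-optics helpers for photo-activation dosimetry.

For laser photo-activation through a high-NA objective the illuminated
area is taken as the first ring of the Airy diffraction pattern, radius
r = 1.22·λ/(2·NA); light power density is the delivered power divided by
that area. For a 63×/1.4 NA objective this gives 1.165e-13 m² at 442 nm
and 1.42e-13 m² at 488 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["OpticsSpec", "airy_disk_radius", "airy_disk_area", "power_density"]


@dataclass(frozen=True)
class OpticsSpec:
    """Wavelength (m), numerical aperture, optional delivered power (W)."""

    wavelength: float
    numerical_aperture: float
    power: float | None = None

    def __post_init__(self) -> None:
        if not (self.wavelength > 0 and math.isfinite(self.wavelength)):
            raise ValueError("wavelength must be positive and finite")
        if not (self.numerical_aperture > 0 and math.isfinite(self.numerical_aperture)):
            raise ValueError("numerical aperture must be positive and finite")


def airy_disk_radius(spec: OpticsSpec) -> float:
    """First-ring Airy radius r = 1.22·λ/(2·NA), in metres."""
    return 1.22 * spec.wavelength / (2.0 * spec.numerical_aperture)


def airy_disk_area(spec: OpticsSpec) -> float:
    """Area of the first Airy ring, π·r², in m²."""
    r = airy_disk_radius(spec)
    return math.pi * r * r


def power_density(power: float, area: float) -> float:
    """Light power density in W/m²: delivered power over illuminated area."""
    if area <= 0:
        raise ValueError("area must be positive")
    if power < 0:
        raise ValueError("power must be >= 0")
    return power / area
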