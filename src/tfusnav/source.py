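"""Focused bowl transducer source model.

The bowl is represented on the solver's initial plane (z = 0, the exit
plane) as a flat disk of uniform amplitude carrying the converging
spherical phase ``exp(-i k (sqrt(r^2 + f^2) - f))``, so that the beam
focuses at z = f in water.  This phased-disk idiom is the standard way to
feed a focused radiator to a planar-marching angular-spectrum solver; it
is accurate for the moderate f-numbers of single-element neuromodulation
transducers and degrades for strongly curved (low f-number) bowls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransducerSpec", "bowl_source_plane", "PRESETS"]


@dataclass(frozen=True)
class TransducerSpec:
    """Single-element focused transducer.

    frequency Hz; aperture diameter and focal distance (geometric focus in
    water) in mm; standoff (gel-pad thickness) in mm; source amplitude in
    arbitrary pressure units.
    """

    frequency: float = 650e3
    aperture_diameter: float = 61.0
    focal_distance: float = 65.0
    standoff: float = 10.0
    source_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.aperture_diameter <= 0 \
                or self.focal_distance <= 0:
            raise ValueError("frequency, aperture and focal distance must be > 0")
        if self.standoff < 0:
            raise ValueError("standoff must be >= 0")

    def wavelength_mm(self, c_ref: float = 1500.0) -> float:
        return c_ref / self.frequency * 1e3


#: Three single-element geometries typical of human neuromodulation studies
#: (61 mm aperture, 650 kHz, focal distances 55/65/80 mm).
PRESETS = {
    "F55": TransducerSpec(focal_distance=55.0),
    "F65": TransducerSpec(focal_distance=65.0),
    "F80": TransducerSpec(focal_distance=80.0),
}


def bowl_source_plane(
    spec: TransducerSpec,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    c_ref: float = 1500.0,
) -> np.ndarray:
    """Complex pressure of the focused bowl on the z = 0 plane.

    *x_mm*, *y_mm* are transverse coordinate arrays (broadcastable, mm)
    relative to the beam axis.  Amplitude is ``source_amplitude`` inside
    the aperture radius, zero outside; phase is the converging spherical
    front ``-k (sqrt(r^2 + f^2) - f)`` with k the wavenumber in water.
    """
    a = spec.aperture_diameter / 2.0
    xmax = max(np.max(np.abs(x_mm)), np.max(np.abs(y_mm)))
    if xmax < a:
        raise ValueError(
            f"source plane half-width {xmax:g} mm < aperture radius {a:g} mm")
    r2 = x_mm ** 2 + y_mm ** 2  # mm^2
    k = 2.0 * np.pi * spec.frequency / c_ref  # rad/m
    f = spec.focal_distance
    phase = -k * (np.sqrt(r2 + f ** 2) - f) * 1e-3
    p = np.where(r2 <= a ** 2, spec.source_amplitude, 0.0) * np.exp(1j * phase)
    return p.astype(np.complex128)
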