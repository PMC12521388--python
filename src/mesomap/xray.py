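"""Small X-ray beam arithmetic helpers (energy/wavelength, q/d spacing)."""

from __future__ import annotations

import math

from scipy import constants

__all__ = ["wavelength_from_energy", "energy_from_wavelength",
           "d_from_q", "q_from_d"]

# hc in keV * Angstrom
_HC_KEV_A = constants.Planck * constants.c / constants.elementary_charge / 1e3 / 1e-10


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in Angstrom for a photon energy in keV.

    lambda = hc / E; e.g. a 20.137 keV beam corresponds to 0.6157 A.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return _HC_KEV_A / energy_kev


def energy_from_wavelength(wavelength_a: float) -> float:
    """Photon energy in keV for a wavelength in Angstrom."""
    if wavelength_a <= 0:
        raise ValueError("wavelength must be positive")
    return _HC_KEV_A / wavelength_a


def d_from_q(q: float) -> float:
    """Real-space repeat distance d = 2*pi/q (Angstrom for q in 1/A)."""
    return 2.0 * math.pi / q


def q_from_d(d: float) -> float:
    return 2.0 * math.pi / d
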