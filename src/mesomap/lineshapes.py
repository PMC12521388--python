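"""Pseudo-Voigt line shape shared by the SAXS and Raman forward models.

A pseudo-Voigt is the weighted sum of a Gaussian and a Lorentzian with a
common full width at half maximum (FWHM).  ``eta`` is the Lorentzian
fraction (0 = pure Gaussian, 1 = pure Lorentzian).  Profiles here are
area-normalized so peak areas add up exactly; heights follow from the
analytic height/area factor.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["pseudo_voigt", "pv_height_factor", "pv_height", "pv_area"]

_G = 2.0 * math.sqrt(math.log(2.0) / math.pi)  # Gaussian peak of unit area/FWHM


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float,
                 eta: float = 0.5, area: float = 1.0) -> np.ndarray:
    """Area-normalized pseudo-Voigt profile evaluated on ``x``."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta (Lorentzian fraction) must be in [0, 1]")
    dx = np.asarray(x, dtype=float) - center
    hw = fwhm / 2.0
    lor = (hw / math.pi) / (dx * dx + hw * hw)
    gau = (_G / fwhm) * np.exp(-4.0 * math.log(2.0) * (dx / fwhm) ** 2)
    return area * (eta * lor + (1.0 - eta) * gau)


def pv_height_factor(fwhm: float, eta: float) -> float:
    """Peak height of a unit-area pseudo-Voigt of the given width."""
    return (eta * 2.0 / (math.pi * fwhm) + (1.0 - eta) * _G / fwhm)


def pv_height(area: float, fwhm: float, eta: float) -> float:
    return area * pv_height_factor(fwhm, eta)


def pv_area(height: float, fwhm: float, eta: float) -> float:
    return height / pv_height_factor(fwhm, eta)
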