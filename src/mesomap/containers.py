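"""In-memory containers for 1D scattering curves, raster scans and
Raman spectra.

Units follow the conventions used throughout the package: q in inverse
Angstrom, wavenumber in inverse centimetre, pixel coordinates and
distances in millimetre, lattice parameters in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Optional

import numpy as np

__all__ = ["ScatteringCurve", "RasterScan", "RamanSpectrum", "PeakList"]


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


@dataclass
class ScatteringCurve:
    """A background-bearing 1D powder pattern I(q) with pixel coordinates."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    pixel_x: float = 0.0  # mm
    pixel_y: float = 0.0  # mm
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = _as_1d(self.q, "q")
        self.intensity = _as_1d(self.intensity, "intensity")
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity must have equal length")
        if self.q.size >= 2 and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            self.sigma = _as_1d(self.sigma, "sigma")
            if self.sigma.size != self.q.size:
                raise ValueError("sigma length mismatch")

    def with_intensity(self, intensity: np.ndarray,
                       **meta: Any) -> "ScatteringCurve":
        """Copy of the curve with a new intensity array and extra metadata."""
        new = replace(self, intensity=np.asarray(intensity, dtype=float),
                      metadata=dict(self.metadata))
        new.metadata.update(meta)
        return new


@dataclass
class RasterScan:
    """A grid of scattering curves sharing one q axis.

    ``intensities`` has shape (n_pixels, n_q); ``pixel_x``/``pixel_y``
    give each pixel centre in mm.  Ground-truth fields from the
    synthetic generator (phase name, lattice, weight per pixel) live in
    ``truth``.
    """

    q: np.ndarray
    intensities: np.ndarray
    pixel_x: np.ndarray
    pixel_y: np.ndarray
    pixel_pitch: float  # mm
    truth: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = _as_1d(self.q, "q")
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.pixel_x = _as_1d(self.pixel_x, "pixel_x")
        self.pixel_y = _as_1d(self.pixel_y, "pixel_y")
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2D (n_pixels, n_q)")
        n, nq = self.intensities.shape
        if nq != self.q.size:
            raise ValueError("intensities/q length mismatch")
        if self.pixel_x.size != n or self.pixel_y.size != n:
            raise ValueError("pixel coordinate length mismatch")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    def curve(self, i: int) -> ScatteringCurve:
        meta = {k: v[i] for k, v in self.truth.items()}
        return ScatteringCurve(self.q, self.intensities[i],
                               pixel_x=float(self.pixel_x[i]),
                               pixel_y=float(self.pixel_y[i]),
                               metadata=meta)

    def __iter__(self) -> Iterator[ScatteringCurve]:
        for i in range(self.n_pixels):
            yield self.curve(i)


@dataclass
class RamanSpectrum:
    """A Raman spectrum with its position along the depot radius."""

    wavenumber: np.ndarray  # 1/cm, increasing
    intensity: np.ndarray
    position_mm: float = 0.0
    age_days: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = _as_1d(self.wavenumber, "wavenumber")
        self.intensity = _as_1d(self.intensity, "intensity")
        if self.wavenumber.size != self.intensity.size:
            raise ValueError("wavenumber and intensity must match")
        if self.wavenumber.size >= 2 and np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber must be strictly increasing")


@dataclass
class PeakList:
    """Detected Bragg peaks, sorted ascending in q."""

    positions: np.ndarray   # 1/A, subgrid-refined
    heights: np.ndarray
    fwhms: np.ndarray       # 1/A
    prominences: np.ndarray

    def __post_init__(self) -> None:
        for name in ("positions", "heights", "fwhms", "prominences"):
            setattr(self, name, _as_1d(getattr(self, name), name))
        n = self.positions.size
        if any(getattr(self, f).size != n
               for f in ("heights", "fwhms", "prominences")):
            raise ValueError("peak attribute length mismatch")
        if n > 1 and np.any(np.diff(self.positions) <= 0):
            order = np.argsort(self.positions)
            for name in ("positions", "heights", "fwhms", "prominences"):
                setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return self.positions.size

    @classmethod
    def empty(cls) -> "PeakList":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), z.copy())
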