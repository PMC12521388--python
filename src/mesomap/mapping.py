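"""Invariant-based cubic-phase quantification and depot mapping.

The scattering invariant Q = integral of q^2 I(q) dq is proportional to
the scattering volume regardless of structure, so the share of the
invariant carried by the micellar cubic (111) reflection measures the
local amount of Fd3m phase.  Per pixel this module computes the
invariant, the normalized cubic-phase fraction and the Fd3m lattice
parameter, assembles them into 2D maps, reduces maps to radial
profiles, and segments the depot into cubic-bearing and cubic-free
layers.

Normalization convention: only the (111) lives in the search window, so
the window invariant is scaled by the full Fd3m ladder factor (the
inverse of the (111)'s share of a complete ladder under the generator's
geometric-decay convention); a single-phase Fd3m pattern then reads
exactly 1.0.  The result is clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import RasterScan, ScatteringCurve
from .indexing import detect_peaks, fd3m_lattice, subtract_baseline
from .phases import FD3M_WINDOW, get_phase
from .synthetic import REFLECTION_DECAY

__all__ = [
    "invariant", "cubic_fraction", "fd3m_ladder_factor",
    "assemble_map", "radial_profile", "segment_layers",
    "PhaseFractionMap", "RadialProfile", "Layer",
]


def invariant(curve: ScatteringCurve) -> float:
    """Scattering invariant Q = integral q^2 I(q) dq (trapezoidal)."""
    if curve.q.size < 2:
        raise ValueError("invariant needs at least 2 points")
    return float(np.trapezoid(curve.q ** 2 * curve.intensity, curve.q))


def fd3m_ladder_factor(decay: float = REFLECTION_DECAY) -> float:
    """Inverse share of the (111) in a full Fd3m ladder's invariant.

    With peak areas decaying geometrically (ratio ``decay``) and the
    q^2 weighting of the invariant, the (111) carries a fixed fraction
    of the whole ladder; multiplying the window invariant by this
    factor estimates the total cubic contribution.
    """
    ratios = np.asarray(get_phase("Fd3m").reflection_ratios)
    k = np.arange(ratios.size)
    return float(np.sum(ratios ** 2 * decay ** k))


_KAPPA = fd3m_ladder_factor()


def _window_pedestal(q: np.ndarray, y: np.ndarray, lo: float, hi: float,
                     edge: int = 3) -> np.ndarray:
    """Local linear pedestal under the window from its edge intensities."""
    sel = (q >= lo) & (q <= hi)
    idx = np.flatnonzero(sel)
    if idx.size < 2:
        return np.zeros(idx.size)
    left = np.median(y[idx[:edge]])
    right = np.median(y[idx[-edge:]])
    t = (q[sel] - q[sel][0]) / (q[sel][-1] - q[sel][0])
    return left + (right - left) * t


def cubic_fraction(curve: ScatteringCurve,
                   window: tuple[float, float] = FD3M_WINDOW,
                   min_prominence: float = 0.01,
                   peaks=None) -> float:
    """Invariant-normalized micellar cubic phase fraction in [0, 1].

    ``curve`` must be baseline-subtracted.  The numerator integrates
    q^2 I over the (111) window after removing a local linear pedestal;
    the denominator integrates q^2 I over all (non-negative) peak
    intensity in the full range.  The ratio is rescaled by the Fd3m
    ladder factor so a pure single-phase Fd3m pattern reads 1, and
    clipped to [0, 1].  Returns 0 when no peak is detected in the
    window or no peaks exist at all.  ``peaks`` may carry an already
    detected peak list to avoid re-detection.
    """
    if peaks is None:
        peaks = detect_peaks(curve, min_prominence=min_prominence)
    if len(peaks) == 0:
        return 0.0
    lo, hi = window
    if not np.any((peaks.positions >= lo) & (peaks.positions <= hi)):
        return 0.0
    q, y = curve.q, curve.intensity
    y_pos = np.clip(y, 0.0, None)
    # Peak intensity only: integrate within +-3 FWHM of detected peaks,
    # so clipped noise and baseline residue (q^2-amplified at high q)
    # cannot dilute the denominator.
    peak_region = np.zeros(q.size, dtype=bool)
    for pos, fw in zip(peaks.positions, peaks.fwhms):
        half = 3.0 * max(fw, 1e-12)
        peak_region |= np.abs(q - pos) <= half
    denominator = float(np.trapezoid(
        np.where(peak_region, q ** 2 * y_pos, 0.0), q))
    if denominator <= 0:
        return 0.0
    sel = (q >= lo) & (q <= hi)
    pedestal = _window_pedestal(q, y, lo, hi)
    y_cub = np.clip(y[sel] - pedestal, 0.0, None)
    numerator = float(np.trapezoid(q[sel] ** 2 * y_cub, q[sel]))
    return float(np.clip(_KAPPA * numerator / denominator, 0.0, 1.0))


# --------------------------------------------------------------------------
# Map assembly
# --------------------------------------------------------------------------

@dataclass
class PhaseFractionMap:
    """Per-pixel cubic-phase fraction and lattice-parameter images.

    Arrays are indexed ``[iy, ix]``; ``x_mm``/``y_mm`` give the pixel
    centre coordinates of the columns/rows.  ``mask`` marks in-depot
    pixels (total invariant above the buffer level).
    """

    fraction: np.ndarray
    lattice: np.ndarray       # Angstrom, NaN = absent
    total_invariant: np.ndarray
    mask: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    pixel_pitch: float
    metadata: dict = field(default_factory=dict)

    def mask_centroid(self) -> tuple[float, float]:
        if not self.mask.any():
            raise ValueError("empty mask has no centroid")
        yy, xx = np.nonzero(self.mask)
        return float(self.x_mm[xx].mean()), float(self.y_mm[yy].mean())


def assemble_map(scan: RasterScan,
                 window: tuple[float, float] = FD3M_WINDOW,
                 mask_factor: float = 5.0,
                 min_prominence: float = 0.01) -> PhaseFractionMap:
    """Compute fraction/lattice/invariant images from a raster scan.

    Per pixel: baseline subtraction, peak detection, cubic fraction and
    Fd3m lattice.  The in-depot mask keeps pixels whose total invariant
    exceeds ``mask_factor`` times the buffer level, estimated as the
    median invariant of the outermost pixel ring (the invariant is
    proportional to scattering volume, so depot pixels sit far above
    buffer).  Duplicate pixel coordinates are rejected.
    """
    xs = np.unique(np.round(scan.pixel_x, 9))
    ys = np.unique(np.round(scan.pixel_y, 9))
    coords = set(zip(np.round(scan.pixel_x, 9), np.round(scan.pixel_y, 9)))
    if len(coords) != scan.n_pixels:
        raise ValueError("duplicate pixel coordinates in manifest")
    nx, ny = xs.size, ys.size
    ix = np.searchsorted(xs, np.round(scan.pixel_x, 9))
    iy = np.searchsorted(ys, np.round(scan.pixel_y, 9))

    frac = np.full((ny, nx), np.nan)
    latt = np.full((ny, nx), np.nan)
    qtot = np.full((ny, nx), np.nan)

    q = scan.q
    q2 = q ** 2
    for i in range(scan.n_pixels):
        curve = ScatteringCurve(q, scan.intensities[i])
        qtot[iy[i], ix[i]] = float(np.trapezoid(q2 * curve.intensity, q))
        sub = subtract_baseline(curve)
        peaks = detect_peaks(sub, min_prominence=min_prominence)
        frac[iy[i], ix[i]] = cubic_fraction(sub, window=window,
                                            min_prominence=min_prominence,
                                            peaks=peaks)
        latt[iy[i], ix[i]] = fd3m_lattice(peaks, window=window).a

    # Buffer level from the outermost ring of the (filled) grid.
    ring = np.zeros((ny, nx), dtype=bool)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    ring &= np.isfinite(qtot)
    buffer_level = float(np.median(qtot[ring])) if ring.any() else 0.0
    mask = np.isfinite(qtot) & (qtot > mask_factor * buffer_level)

    meta = dict(scan.metadata)
    meta.update(window=window, mask_factor=mask_factor,
                buffer_level=buffer_level)
    return PhaseFractionMap(frac, latt, qtot, mask, xs, ys,
                            scan.pixel_pitch, metadata=meta)


# --------------------------------------------------------------------------
# Radial reduction and layering
# --------------------------------------------------------------------------

@dataclass
class RadialProfile:
    """Azimuthal averages in concentric annuli of width = pixel pitch."""

    radius_mm: np.ndarray       # annulus centres
    mean_fraction: np.ndarray
    mean_lattice: np.ndarray
    counts: np.ndarray          # in-mask pixels per annulus
    bin_width: float


def radial_profile(pmap: PhaseFractionMap,
                   center: Optional[tuple[float, float]] = None) -> RadialProfile:
    """Azimuthally average fraction and lattice around ``center`` (mm).

    Defaults to the mask centroid; a centre outside the mask is
    rejected.  Annulus width equals the pixel pitch.
    """
    if center is None:
        center = pmap.mask_centroid()
    cx, cy = center
    ix = int(np.argmin(np.abs(pmap.x_mm - cx)))
    iy = int(np.argmin(np.abs(pmap.y_mm - cy)))
    if not pmap.mask[iy, ix]:
        raise ValueError("profile centre lies outside the depot mask")

    xx, yy = np.meshgrid(pmap.x_mm - cx, pmap.y_mm - cy)
    r = np.hypot(xx, yy)
    width = pmap.pixel_pitch
    rmax = float(r[pmap.mask].max())
    edges = np.arange(0.0, rmax + width, width)
    n_bins = edges.size - 1
    mean_f = np.full(n_bins, np.nan)
    mean_a = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    which = np.digitize(r.ravel(), edges) - 1
    mask_flat = pmap.mask.ravel()
    f_flat = pmap.fraction.ravel()
    a_flat = pmap.lattice.ravel()
    for b in range(n_bins):
        sel = (which == b) & mask_flat
        counts[b] = int(sel.sum())
        if counts[b]:
            mean_f[b] = np.nanmean(f_flat[sel])
            vals = a_flat[sel]
            if np.any(np.isfinite(vals)):
                mean_a[b] = np.nanmean(vals)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, mean_f, mean_a, counts, width)


@dataclass
class Layer:
    kind: str        # "cubic" or "non-cubic"
    r_inner: float   # mm
    r_outer: float


def segment_layers(profile: RadialProfile,
                   fraction_threshold: float = 0.25) -> list[Layer]:
    """Split a radial profile into contiguous cubic / cubic-free layers.

    Annuli with in-mask pixels are classified by mean cubic fraction
    against the threshold and contiguous runs are merged; the returned
    list is ordered centre outwards.  An empty profile is rejected.
    """
    if not 0.0 < fraction_threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    valid = profile.counts > 0
    if not valid.any():
        raise ValueError("profile contains no populated annuli")
    radius = profile.radius_mm[valid]
    frac = profile.mean_fraction[valid]
    half = 0.5 * profile.bin_width
    is_cubic = frac >= fraction_threshold
    layers: list[Layer] = []
    start = 0
    for i in range(1, is_cubic.size + 1):
        if i == is_cubic.size or is_cubic[i] != is_cubic[start]:
            layers.append(Layer(
                "cubic" if is_cubic[start] else "non-cubic",
                max(0.0, float(radius[start] - half)),
                float(radius[i - 1] + half)))
            start = i
    return layers
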