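"""Raman band fitting and SPC/GDO composition-hydration chemometrics.

Depot spectra are analysed through three intensity ratios of fitted
pseudo-Voigt band heights: 1264/1301 (the cis =C-H deformation over the
CH2 twist) tracks lipid composition because SPC carries more C=C bonds
than GDO; 715/1301 (the choline trimethylamine stretch, present only in
SPC) tracks SPC and its hydration state; 1439 (CH2/CH3 scissoring,
composition-insensitive) serves as the internal standard for spectrum
normalization.  Published endmember calibrations anchor the inversion:
1264/1301 is 0.95 for pure SPC and 0.56 for pure GDO, and 715/1301
rises linearly from 0.61 to 0.68 over 0-40 % water for the 50/50
mixture (whose full hydration limit is 16 % water).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit.models import LinearModel, PseudoVoigtModel

from .containers import RamanSpectrum

__all__ = [
    "CalibrationTable", "BandFitResult", "FittedBand",
    "fit_bands", "intensity_ratios", "difference_spectrum",
    "estimate_composition", "estimate_hydration",
    "DEFAULT_FIT_TARGETS", "NORMALIZATION_BAND",
]

#: Band centres fitted by default (1/cm): the three ratio bands, the
#: 1439 internal standard and the C=C stretch.
DEFAULT_FIT_TARGETS: tuple[float, ...] = (715.0, 1264.0, 1301.0, 1439.0, 1659.0)

#: Composition-insensitive internal standard used for normalization.
NORMALIZATION_BAND = 1439.0

#: Fitted centres may wander at most this far from their target (1/cm).
_CENTER_TOL = 8.0


@dataclass(frozen=True)
class CalibrationTable:
    """Published calibration anchors for the ratio inversions.

    ``w1301_spc``/``w1301_gdo`` are relative 1301-band weights per lipid
    in the two-endmember mixing model (default 1:1; the measured dry
    50/50 ratio of 0.81 exceeds the equal-weight prediction 0.755, so
    the weights are kept configurable).
    """

    r1264_spc: float = 0.95
    r1264_gdo: float = 0.56
    r715_dry: float = 0.61     # 50/50 mixture, 0 % water
    r715_wet: float = 0.68     # 50/50 mixture, 40 % water
    water_wet: float = 0.40
    full_hydration: float = 0.16
    w1301_spc: float = 1.0
    w1301_gdo: float = 1.0

    def __post_init__(self) -> None:
        if self.r1264_spc <= self.r1264_gdo:
            raise ValueError("SPC endmember ratio must exceed GDO's")
        if min(self.r1264_spc, self.r1264_gdo, self.r715_dry,
               self.r715_wet) <= 0:
            raise ValueError("endmember ratios must be positive")


@dataclass
class FittedBand:
    center: float
    height: float
    fwhm: float
    fraction: float  # Lorentzian fraction


@dataclass
class BandFitResult:
    """Refined band parameters keyed by their library target centre."""

    bands: dict[float, FittedBand]
    residual_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def height(self, target: float) -> float:
        if target not in self.bands:
            raise KeyError(f"band {target} was not fitted")
        return self.bands[target].height


def _group_targets(targets: Sequence[float], window: float) -> list[list[float]]:
    """Cluster targets whose fit windows overlap into joint fits."""
    ts = sorted(targets)
    groups: list[list[float]] = [[ts[0]]]
    for t in ts[1:]:
        if t - groups[-1][-1] < 2.0 * window:
            groups[-1].append(t)
        else:
            groups.append([t])
    return groups


def fit_bands(spectrum: RamanSpectrum,
              targets: Sequence[float] = DEFAULT_FIT_TARGETS,
              window: float = 30.0,
              vary_fraction: bool = False) -> BandFitResult:
    """Least-squares pseudo-Voigt fit of bands near the target centres.

    Overlapping targets are fitted jointly (linear local baseline plus
    one pseudo-Voigt per band) over a window of +-``window`` 1/cm
    around the group.  Centres are bounded to +-8 1/cm of their
    targets and heights to be non-negative.  The Gaussian-Lorentzian
    mixing is held at 50:50 by default (the usual fitting convention;
    the free parameter correlates strongly with height under noise);
    pass ``vary_fraction=True`` to refine it.  A group that fails to
    converge falls back to window-maximum heights and is flagged.
    """
    nu, y = spectrum.wavenumber, spectrum.intensity
    bands: dict[float, FittedBand] = {}
    flags: list[str] = []
    converged = True
    ss_res = 0.0

    for group in _group_targets(targets, window):
        lo, hi = group[0] - window, group[-1] + window
        sel = (nu >= lo) & (nu <= hi)
        if sel.sum() < 5 * (len(group) + 1):
            raise ValueError(
                f"spectrum does not cover the {group} fit window")
        x, yy = nu[sel], y[sel]

        model = LinearModel(prefix="bl_")
        params = model.make_params(slope=0.0, intercept=float(yy.min()))
        for k, t in enumerate(group):
            pv = PseudoVoigtModel(prefix=f"b{k}_")
            model = model + pv
            i0 = int(np.argmin(np.abs(x - t)))
            h0 = max(float(yy[i0] - yy.min()), 1e-12)
            params.update(pv.make_params())
            params[f"b{k}_center"].set(value=t, min=t - _CENTER_TOL,
                                       max=t + _CENTER_TOL)
            params[f"b{k}_sigma"].set(value=6.0, min=0.5, max=40.0)
            params[f"b{k}_fraction"].set(value=0.5, min=0.0, max=1.0,
                                         vary=vary_fraction)
            params[f"b{k}_amplitude"].set(value=h0 * 6.0 * 2.0, min=0.0)

        try:
            out = model.fit(yy, params, x=x)
            ok = out.success
        except Exception:
            out, ok = None, False

        if ok:
            ss_res += float(np.sum(out.residual ** 2))
            for k, t in enumerate(group):
                p = out.params
                bands[t] = FittedBand(
                    center=float(p[f"b{k}_center"].value),
                    height=float(p[f"b{k}_height"].value),
                    fwhm=float(p[f"b{k}_fwhm"].value),
                    fraction=float(p[f"b{k}_fraction"].value))
        else:
            converged = False
            flags.append(f"fallback:{group}")
            base = float(yy.min())
            for t in group:
                near = np.abs(x - t) <= _CENTER_TOL
                h = float(yy[near].max() - base) if near.any() else 0.0
                bands[t] = FittedBand(t, max(h, 0.0), float("nan"),
                                      float("nan"))

    return BandFitResult(bands, float(np.sqrt(ss_res)), converged, flags)


def intensity_ratios(fit: BandFitResult) -> tuple[float, float]:
    """(r715, r1264) = band heights relative to the 1301 CH2 twist."""
    try:
        h1301 = fit.height(1301.0)
    except KeyError:
        raise ValueError("1301 band missing from fit") from None
    if not h1301 > 0:
        raise ValueError("1301 band height must be positive")
    h715 = fit.bands[715.0].height if 715.0 in fit.bands else 0.0
    h1264 = fit.bands[1264.0].height if 1264.0 in fit.bands else 0.0
    return h715 / h1301, h1264 / h1301


def difference_spectrum(spec: RamanSpectrum,
                        reference: RamanSpectrum) -> RamanSpectrum:
    """Normalized difference ``spec - reference`` on a common grid.

    Both spectra are scaled to unit fitted 1439 1/cm band height (the
    composition-insensitive internal standard) before subtraction, so
    the difference reflects composition/hydration changes rather than
    collection efficiency.  Disjoint wavenumber ranges are rejected.
    """
    lo = max(spec.wavenumber[0], reference.wavenumber[0])
    hi = min(spec.wavenumber[-1], reference.wavenumber[-1])
    if hi <= lo:
        raise ValueError("spectra cover disjoint wavenumber ranges")
    sel = (spec.wavenumber >= lo) & (spec.wavenumber <= hi)
    nu = spec.wavenumber[sel]

    def _norm(s: RamanSpectrum) -> np.ndarray:
        h = fit_bands(s, targets=(NORMALIZATION_BAND,)).height(
            NORMALIZATION_BAND)
        if not h > 0:
            raise ValueError("normalization band has non-positive height")
        return np.interp(nu, s.wavenumber, s.intensity) / h

    diff = _norm(spec) - _norm(reference)
    return RamanSpectrum(
        nu, diff, position_mm=spec.position_mm, age_days=spec.age_days,
        metadata={"difference_of": (spec.position_mm, reference.position_mm),
                  "normalized_to": NORMALIZATION_BAND})


def estimate_composition(r1264: float,
                         cal: CalibrationTable = CalibrationTable()
                         ) -> tuple[float, list[str]]:
    """SPC mass fraction from the 1264/1301 ratio.

    Inverts the weighted two-endmember mixing model
    r = (x*wS*rS + (1-x)*wG*rG) / (x*wS + (1-x)*wG) and clips to
    [0, 1]; ratios outside the calibrated range (+-0.05 beyond the
    endmembers) are clipped with an ``out_of_range`` flag.
    """
    flags: list[str] = []
    if not (cal.r1264_gdo - 0.05 <= r1264 <= cal.r1264_spc + 0.05):
        flags.append("out_of_range")
    num = cal.w1301_gdo * (r1264 - cal.r1264_gdo)
    den = (cal.w1301_spc * (cal.r1264_spc - r1264)
           + cal.w1301_gdo * (r1264 - cal.r1264_gdo))
    x = num / den if den != 0 else (1.0 if r1264 >= cal.r1264_spc else 0.0)
    return float(np.clip(x, 0.0, 1.0)), flags


def estimate_hydration(r715: float, x_spc: float,
                       cal: CalibrationTable = CalibrationTable()
                       ) -> tuple[float, list[str]]:
    """Water mass fraction from the 715/1301 ratio and SPC content.

    Rescales the observed ratio to the 50/50 composition (the 715 band
    height is proportional to SPC content) and linearly inverts the
    0.61 -> 0.68 hydration calibration, clipping to [0, 0.40].  For
    x_spc = 0 the 715 band is absent and hydration is undefined (NaN);
    compositions away from 50/50 carry an ``extrapolated`` flag because
    the calibration was measured for the 50/50 mixture only.
    """
    flags: list[str] = []
    if x_spc <= 0:
        return float("nan"), ["undefined_no_spc"]
    if abs(x_spc - 0.5) > 1e-6:
        flags.append("extrapolated")
    r50 = r715 * 0.5 / x_spc
    slope = (cal.r715_wet - cal.r715_dry) / cal.water_wet
    w = (r50 - cal.r715_dry) / slope
    if not 0.0 <= w <= cal.water_wet:
        flags.append("clipped")
    return float(np.clip(w, 0.0, cal.water_wet)), flags
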