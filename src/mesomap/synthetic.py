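"""Synthetic SAXS and Raman data with known ground truth.

The generators emulate the statistical and structural features of a
hydrating SPC/GDO lipid depot measured by scanning SAXS and spatially
resolved Raman spectroscopy:

* :func:`generate_curve` — a 1D powder pattern: smooth background
  (power law plus constant) plus pseudo-Voigt Bragg peaks at the
  analytic reflection positions of the requested mesophases, with
  optional Poisson counting noise.
* :func:`generate_raster` — a 50 um-pitch raster scan of a radially
  layered depot (hexagonal rim, micellar cubic interior, optionally an
  unhydrated isotropic core), one curve per pixel, buffer outside.
* :func:`generate_raman` — a spectrum built from the SPC/GDO band
  library with composition- and hydration-dependent intensity ratios
  matching the published calibrations (1264/1301 between 0.56 and 0.95;
  715/1301 from 0.61 to 0.68 over 0-40 % water at 50/50).

Every generator records its ground truth in the returned object's
metadata so analysis results can be checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .containers import RamanSpectrum, RasterScan, ScatteringCurve
from .lineshapes import pseudo_voigt, pv_height
from .phases import PhasePattern, get_phase

__all__ = [
    "SaxsBackground", "DEPOT_BACKGROUND", "BUFFER_BACKGROUND",
    "DEFAULT_Q_GRID", "DEFAULT_PEAK_FWHM", "DEFAULT_PEAK_ETA",
    "REFLECTION_DECAY", "generate_curve",
    "LayerSpec", "DepotScenario", "make_depot_scenario",
    "scenario_one_day", "scenario_four_week", "generate_raster",
    "BandLibraryEntry", "RAMAN_BAND_LIBRARY", "generate_raman",
    "DEFAULT_WAVENUMBER_GRID",
]

# --------------------------------------------------------------------------
# SAXS forward model
# --------------------------------------------------------------------------

#: Measured q-range of the beamline configuration, 0.016-0.85 1/A, on a
#: grid fine enough to resolve the default peak width (dq = 5e-4).
DEFAULT_Q_GRID = np.linspace(0.016, 0.85, 1669)

DEFAULT_PEAK_FWHM = 0.0025   # 1/A
DEFAULT_PEAK_ETA = 0.2       # Lorentzian fraction of SAXS Bragg peaks
#: Successive allowed reflections of one phase carry geometrically
#: decaying area, ratio 0.5, keeping the first reflection dominant.
REFLECTION_DECAY = 0.5

_Q_RANGE = (0.016, 0.85)


@dataclass(frozen=True)
class SaxsBackground:
    """Smooth background b*q**(-p) + c (finite on the truncated q-range)."""

    b: float = 0.01
    p: float = 2.0
    c: float = 0.5

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.b * q ** (-self.p) + self.c

    def integral(self, q: np.ndarray) -> float:
        """Trapezoidal integral of the background over the grid."""
        return float(np.trapezoid(self(q), q))

    @property
    def is_zero(self) -> bool:
        return self.b == 0.0 and self.c == 0.0


#: Lipid-depot and surrounding-buffer backgrounds.  The depot scatters
#: far more than buffer, so the total invariant of a depot pixel clears
#: the buffer level by an order of magnitude (the mask criterion).
DEPOT_BACKGROUND = SaxsBackground(b=0.01, p=2.0, c=0.5)
BUFFER_BACKGROUND = SaxsBackground(b=0.002, p=2.0, c=0.05)

PhaseSpec = tuple[Union[PhasePattern, str], float, float]


def _resolve_phase(p: Union[PhasePattern, str]) -> PhasePattern:
    return get_phase(p) if isinstance(p, str) else p


def phase_peak_table(phases: Sequence[PhaseSpec], q_grid: np.ndarray,
                     fwhm: float = DEFAULT_PEAK_FWHM,
                     eta: float = DEFAULT_PEAK_ETA,
                     decay: float = REFLECTION_DECAY):
    """Analytic peak table (center, area, phase name) for a phase mix.

    Peak areas within one phase decay geometrically and are normalized
    so the full ladder of a phase sums to its weight; reflections
    falling outside the q-grid are dropped (their area is not
    redistributed).
    """
    centers, areas, names = [], [], []
    qlo, qhi = q_grid[0], q_grid[-1]
    for spec in phases:
        pattern, lattice, weight = _resolve_phase(spec[0]), spec[1], spec[2]
        if weight < 0:
            raise ValueError("phase weights must be non-negative")
        if not pattern.has_reflections or weight == 0:
            continue
        if lattice is None or lattice <= 0:
            raise ValueError(f"{pattern.name}: lattice parameter must be > 0")
        pos = pattern.peak_positions(lattice)
        k = np.arange(pos.size)
        area = weight * decay ** k / np.sum(decay ** k)
        keep = (pos >= qlo) & (pos <= qhi)
        centers.extend(pos[keep])
        areas.extend(area[keep])
        names.extend([pattern.name] * int(keep.sum()))
    return (np.asarray(centers), np.asarray(areas), names)


def generate_curve(phases: Sequence[PhaseSpec],
                   q_grid: Optional[np.ndarray] = None,
                   background: SaxsBackground = DEPOT_BACKGROUND,
                   noise_seed: Optional[int] = None,
                   *,
                   fwhm: float = DEFAULT_PEAK_FWHM,
                   eta: float = DEFAULT_PEAK_ETA,
                   decay: float = REFLECTION_DECAY,
                   counts_scale: float = 1e3,
                   pixel_x: float = 0.0,
                   pixel_y: float = 0.0) -> ScatteringCurve:
    """Forward-model a 1D scattering curve for a mixture of mesophases.

    Parameters
    ----------
    phases
        Sequence of ``(phase, lattice_A, weight)``; ``phase`` is a
        :class:`~mesomap.phases.PhasePattern` or its name.  Weights are
        total Bragg areas in intensity units.
    q_grid
        Strictly increasing grid inside the measured 0.016-0.85 1/A
        range; defaults to :data:`DEFAULT_Q_GRID`.  Rejected when too
        coarse to put 5 points across the narrowest peak.
    background
        Smooth underlying intensity; pass ``SaxsBackground(0, 2, 0)``
        for none (rejected if the phase list is empty too).
    noise_seed
        If given, Poisson counting noise is applied at ``counts_scale``
        counts per intensity unit.  Same seed, same curve.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size < 2 or np.any(np.diff(q) <= 0):
        raise ValueError("q_grid must be a strictly increasing 1D array")
    if q[0] < _Q_RANGE[0] - 1e-9 or q[-1] > _Q_RANGE[1] + 1e-9:
        raise ValueError(
            f"q_grid must lie within the measured range {_Q_RANGE}")
    if float(np.max(np.diff(q))) * 5.0 > fwhm * (1.0 + 1e-9):
        raise ValueError(
            "q_grid too coarse: fewer than 5 points per peak FWHM "
            f"(need dq <= {fwhm / 5.0:.2e})")

    centers, areas, names = phase_peak_table(
        phases, q, fwhm=fwhm, eta=eta, decay=decay)
    if centers.size == 0 and background.is_zero:
        raise ValueError("empty phase list with zero background")

    intensity = background(q)
    for c, a in zip(centers, areas):
        intensity = intensity + pseudo_voigt(q, c, fwhm, eta=eta, area=a)

    sigma = None
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        counts = rng.poisson(np.clip(intensity, 0, None) * counts_scale)
        sigma = np.sqrt(np.clip(counts, 1, None)) / counts_scale
        intensity = counts / counts_scale

    truth = {
        "phases": [(_resolve_phase(p).name, a, w) for p, a, w in phases],
        "peak_centers": centers,
        "peak_areas": areas,
        "peak_phase": names,
        "peak_fwhm": fwhm,
        "peak_eta": eta,
        "background": (background.b, background.p, background.c),
        "noise_seed": noise_seed,
    }
    return ScatteringCurve(q, intensity, sigma=sigma,
                           pixel_x=pixel_x, pixel_y=pixel_y, metadata=truth)


# --------------------------------------------------------------------------
# Depot raster scenarios
# --------------------------------------------------------------------------

Lattice = Union[float, tuple[float, float], None]


@dataclass(frozen=True)
class LayerSpec:
    """One radial depot layer: everything from the previous layer's outer
    radius out to ``outer_radius_mm`` is this phase.  ``lattice_A`` may
    be a scalar or an ``(inner, outer)`` pair interpolated linearly in
    radius across the layer (how within-phase swelling gradients are
    emulated); ``None`` for the isotropic phase."""

    phase: str
    outer_radius_mm: float
    lattice_A: Lattice = None
    weight: float = 1.0


@dataclass
class DepotScenario:
    """Ground-truth description of one depot at one hydration age."""

    hydration_age_days: float
    depot_radius_mm: float
    layers: list[LayerSpec]
    composition_profile: Callable[[float], float]  # SPC fraction of lipid
    hydration_profile: Callable[[float], float]    # water mass fraction
    noise_seed: int = 0

    def __post_init__(self) -> None:
        radii = [ly.outer_radius_mm for ly in self.layers]
        if not radii:
            raise ValueError("scenario needs at least one layer")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("layer outer radii must strictly increase")
        if radii[-1] > self.depot_radius_mm + 1e-9:
            raise ValueError("layers must not extend past the depot radius")
        if any(ly.weight < 0 for ly in self.layers):
            raise ValueError("layer weights must be non-negative")
        r = np.linspace(0.0, self.depot_radius_mm, 64)
        for f, name in ((self.composition_profile, "composition"),
                        (self.hydration_profile, "hydration")):
            v = np.asarray([f(x) for x in r])
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"{name} profile must stay within [0, 1]")

    def layer_at(self, r_mm: float) -> Optional[LayerSpec]:
        """Layer containing radius ``r_mm``; None outside the depot."""
        if r_mm > self.depot_radius_mm + 1e-12:
            return None
        for layer in self.layers:
            if r_mm <= layer.outer_radius_mm + 1e-12:
                return layer
        return None

    def lattice_at(self, r_mm: float) -> float:
        """Ground-truth lattice parameter at radius r (NaN where none)."""
        layer = self.layer_at(r_mm)
        if layer is None or layer.lattice_A is None:
            return float("nan")
        if np.isscalar(layer.lattice_A):
            return float(layer.lattice_A)
        inner_r = 0.0
        for ly in self.layers:
            if ly is layer:
                break
            inner_r = ly.outer_radius_mm
        a0, a1 = layer.lattice_A
        span = layer.outer_radius_mm - inner_r
        t = 0.0 if span <= 0 else (r_mm - inner_r) / span
        return float(a0 + (a1 - a0) * np.clip(t, 0.0, 1.0))


def make_depot_scenario(age_days: float,
                        depot_radius_mm: float = 4.0,
                        spc_fraction: float = 0.5,
                        noise_seed: int = 0) -> DepotScenario:
    """Parametric depot scenario emulating the observed hydration course.

    The rules encode the study's phenomenology: an unhydrated isotropic
    core that shrinks and disappears within about a week; a micellar
    cubic (Fd3m) annulus whose lattice swells with age (131-153 A early,
    157-172 A at four weeks) and is always smaller towards the centre; a
    cubic-free hexagonal rim that thickens with age and with SPC
    content.  Composition and hydration profiles carry an SPC maximum at
    the rim, an SPC minimum 2-3 mm from the centre and water content
    rising towards the surface.
    """
    if age_days < 0:
        raise ValueError("age must be non-negative")
    R = depot_radius_mm
    scale = R / 4.0
    u = min(1.0, age_days / 28.0) ** 0.5
    a_center = 131.0 + (157.0 - 131.0) * u
    a_edge = 153.0 + (172.0 - 153.0) * u
    rim = (0.5 + 0.3 * u) * (1.0 + 4.0 * (spc_fraction - 0.5)) * scale
    rim = float(np.clip(rim, 0.3 * scale, 0.45 * R))
    core = 2.6 * max(0.0, 1.0 - age_days / 6.0) ** 0.8 * scale

    layers: list[LayerSpec] = []
    if core > 0.2 * scale:
        layers.append(LayerSpec("isotropic", core, None))
    elif spc_fraction >= 0.55 and 3.0 <= age_days <= 14.0:
        # SPC-rich depots transiently develop a Pm3n centre at ~1 week.
        layers.append(LayerSpec("Pm3n", 1.2 * scale, 70.0))
    layers.append(LayerSpec("Fd3m", R - rim, (a_center, a_edge)))
    layers.append(LayerSpec("H2", R, 52.0))

    mid = 2.5 * scale

    def composition(r: float) -> float:
        x = (spc_fraction
             + 0.08 * math.exp(-((r - R) / 0.6) ** 2)
             - 0.04 * min(1.0, age_days) * math.exp(-((r - mid) / 0.8) ** 2))
        return float(np.clip(x, 0.0, 1.0))

    w_core = 0.01 + 0.15 * u * u
    w_rim = 0.10 + 0.25 * u

    def hydration(r: float) -> float:
        w = w_core + (w_rim - w_core) * (r / R) ** 2
        return float(np.clip(w, 0.0, 1.0))

    return DepotScenario(age_days, R, layers, composition, hydration,
                         noise_seed=noise_seed)


def scenario_one_day(noise_seed: int = 0, **kw) -> DepotScenario:
    """Three-layer depot: hexagonal rim, Fd3m annulus, isotropic core."""
    return make_depot_scenario(1.0, noise_seed=noise_seed, **kw)


def scenario_four_week(noise_seed: int = 0, **kw) -> DepotScenario:
    """Two-layer depot: fully developed cubic interior, hexagonal rim."""
    return make_depot_scenario(28.0, noise_seed=noise_seed, **kw)


def generate_raster(scenario: DepotScenario,
                    pixel_pitch: float = 0.05,
                    q_grid: Optional[np.ndarray] = None,
                    extent_mm: Optional[float] = None,
                    noise: bool = False,
                    counts_scale: float = 1e3) -> RasterScan:
    """Raster-scan a layered depot, one scattering curve per pixel.

    Pixels whose centre lies outside the depot contain buffer background
    only.  ``extent_mm`` is the half-width of the square grid (default:
    the depot radius, so the grid corners sample buffer); a 0 extent
    degenerates to a single on-axis pixel.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    if pixel_pitch > scenario.depot_radius_mm:
        raise ValueError("pixel pitch larger than the depot radius")
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    extent = scenario.depot_radius_mm if extent_mm is None else extent_mm
    n_half = int(math.floor(extent / pixel_pitch + 1e-9))
    offsets = np.arange(-n_half, n_half + 1) * pixel_pitch

    xs, ys = np.meshgrid(offsets, offsets)
    xs, ys = xs.ravel(), ys.ravel()
    n = xs.size
    intens = np.empty((n, q.size))
    phase_names = np.empty(n, dtype=object)
    lattices = np.full(n, np.nan)
    weights = np.zeros(n)
    radii = np.hypot(xs, ys)
    in_depot = radii <= scenario.depot_radius_mm + 1e-12

    ss = np.random.SeedSequence(scenario.noise_seed)
    child_seeds = ss.generate_state(n) % (2 ** 31) if noise else None

    for i in range(n):
        seed = int(child_seeds[i]) if noise else None
        layer = scenario.layer_at(radii[i]) if in_depot[i] else None
        if layer is None:
            phase_names[i] = "buffer"
            curve = generate_curve([], q, BUFFER_BACKGROUND,
                                   noise_seed=seed,
                                   counts_scale=counts_scale)
        else:
            a = scenario.lattice_at(radii[i])
            phase_names[i] = layer.phase
            lattices[i] = a
            weights[i] = layer.weight
            spec = ([] if layer.phase == "isotropic"
                    else [(layer.phase, a, layer.weight)])
            curve = generate_curve(spec, q, DEPOT_BACKGROUND,
                                   noise_seed=seed,
                                   counts_scale=counts_scale)
        intens[i] = curve.intensity

    truth = {
        "phase": phase_names,
        "lattice_A": lattices,
        "weight": weights,
        "radius_mm": radii,
        "in_depot": in_depot,
    }
    meta = {
        "hydration_age_days": scenario.hydration_age_days,
        "depot_radius_mm": scenario.depot_radius_mm,
        "noise_seed": scenario.noise_seed,
        "noise": noise,
    }
    return RasterScan(q, intens, xs, ys, pixel_pitch,
                      truth=truth, metadata=meta)


# --------------------------------------------------------------------------
# Raman forward model
# --------------------------------------------------------------------------

DEFAULT_WAVENUMBER_GRID = np.arange(600.0, 1800.0 + 0.5, 1.0)


@dataclass(frozen=True)
class BandLibraryEntry:
    """One entry of the SPC/GDO Raman band library.

    ``source`` marks which lipid carries the band ("SPC", "GDO" or
    "both"); ``base_spc``/``base_gdo`` are the endmember heights used by
    the generator for bands whose ratios are not pinned by the
    published calibrations.
    """

    center: float          # 1/cm
    assignment: str
    source: str            # "SPC" | "GDO" | "both"
    width: float = 12.0    # FWHM, 1/cm
    gauss_fraction: float = 0.5
    base_spc: float = 0.0
    base_gdo: float = 0.0


#: Band assignments of SPC, GDO and their mixture.  The three ratio
#: bands (715, 1264, 1301) get their heights from the calibration model
#: in :func:`generate_raman`, not from the base heights.
RAMAN_BAND_LIBRARY: tuple[BandLibraryEntry, ...] = (
    BandLibraryEntry(715.0, "nu_s(N+(CH3)3)", "SPC", 10.0),
    BandLibraryEntry(845.0, "nu(C-O-C) glycerol backbone", "both", 14.0,
                     base_spc=0.10, base_gdo=0.18),
    BandLibraryEntry(874.0, "nu_as(N+(CH3)3)", "SPC", 12.0, base_spc=0.12),
    BandLibraryEntry(971.0, "delta(CH2)", "both", 12.0,
                     base_spc=0.08, base_gdo=0.10),
    BandLibraryEntry(1019.0, "nu(C-C)", "both", 10.0,
                     base_spc=0.07, base_gdo=0.08),
    BandLibraryEntry(1063.0, "nu(C-C) trans", "both", 12.0,
                     base_spc=0.28, base_gdo=0.30),
    BandLibraryEntry(1085.0, "nu(C-C) gauche / nu_s(PO2)", "both", 16.0,
                     base_spc=0.30, base_gdo=0.22),
    BandLibraryEntry(1109.0, "nu(C-C) trans, nu(C-O-C)", "GDO", 14.0,
                     base_gdo=0.22),
    BandLibraryEntry(1264.0, "delta(=C-H) cis / nu_as(PO2)", "both", 12.0),
    BandLibraryEntry(1301.0, "t(CH2)", "both", 12.0),
    BandLibraryEntry(1439.0, "delta(CH2/CH3)", "both", 16.0,
                     base_spc=0.85, base_gdo=0.85),
    BandLibraryEntry(1659.0, "nu(C=C) cis", "both", 14.0,
                     base_spc=0.80, base_gdo=0.60),
    BandLibraryEntry(1739.0, "nu(C=O)", "both", 18.0,
                     base_spc=0.22, base_gdo=0.28),
)


def raman_truth_ratios(spc_fraction: float, water_fraction: float,
                       calibration=None) -> tuple[float, float]:
    """Ground-truth (r715, r1264) for a composition/hydration state.

    r1264 interpolates linearly in SPC fraction between the GDO and SPC
    endmember values; r715 follows the 50/50 hydration calibration
    (0.61 dry to 0.68 at 40 % water) scaled by SPC content.
    """
    from .raman import CalibrationTable
    cal = calibration or CalibrationTable()
    x, w = spc_fraction, water_fraction
    r1264 = x * cal.r1264_spc + (1.0 - x) * cal.r1264_gdo
    r50 = cal.r715_dry + (cal.r715_wet - cal.r715_dry) * w / cal.water_wet
    r715 = 2.0 * x * r50
    return r715, r1264


def generate_raman(spc_fraction: float,
                   water_fraction: float,
                   library: Sequence[BandLibraryEntry] = RAMAN_BAND_LIBRARY,
                   noise_seed: Optional[int] = None,
                   *,
                   noise_level: float = 0.01,
                   n_accumulations: int = 60,
                   wavenumber: Optional[np.ndarray] = None,
                   calibration=None,
                   position_mm: float = 0.0,
                   age_days: float = 0.0) -> RamanSpectrum:
    """Synthesize a depot Raman spectrum with known band heights.

    Band heights are anchored to the 1301 1/cm CH2-twist band (height
    1); the 715 and 1264 heights implement the composition and
    hydration calibrations (see :func:`raman_truth_ratios`), all other
    bands mix their endmember base heights linearly in SPC fraction.  A
    low-order polynomial baseline (< 5 % of the tallest band) and
    optional Gaussian noise are added on top.

    ``noise_level`` is the relative noise of a single acquisition; the
    delivered spectrum emulates the usual accumulation protocol (60
    co-added acquisitions by default), so its noise is reduced by
    sqrt(n_accumulations).  Set ``n_accumulations=1`` for a single
    readout.
    """
    x, w = float(spc_fraction), float(water_fraction)
    if not 0.0 <= x <= 1.0 or not 0.0 <= w <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    nu = (DEFAULT_WAVENUMBER_GRID if wavenumber is None
          else np.asarray(wavenumber, dtype=float))

    r715, r1264 = raman_truth_ratios(x, w, calibration)
    heights: dict[float, float] = {}
    for band in library:
        if band.center == 1301.0:
            heights[band.center] = 1.0
        elif band.center == 1264.0:
            heights[band.center] = r1264
        elif band.center == 715.0:
            heights[band.center] = r715
        else:
            heights[band.center] = x * band.base_spc + (1 - x) * band.base_gdo

    intensity = np.zeros_like(nu)
    for band in library:
        h = heights[band.center]
        if h <= 0:
            continue
        eta = 1.0 - band.gauss_fraction
        intensity = intensity + pseudo_voigt(
            nu, band.center, band.width, eta=eta,
            area=h / pv_height(1.0, band.width, eta))

    h_max = max(heights.values())
    t = (nu - nu[0]) / (nu[-1] - nu[0])
    baseline = 0.04 * h_max * (0.3 + 0.4 * t + 0.3 * t * t)
    intensity = intensity + baseline

    if noise_seed is not None:
        if n_accumulations < 1:
            raise ValueError("n_accumulations must be >= 1")
        rng = np.random.default_rng(noise_seed)
        sigma_eff = (noise_level * float(np.max(intensity))
                     / math.sqrt(n_accumulations))
        intensity = intensity + rng.normal(0.0, sigma_eff, nu.size)

    truth = {
        "spc_fraction": x,
        "water_fraction": w,
        "r715": r715,
        "r1264": r1264,
        "band_heights": dict(heights),
        "noise_seed": noise_seed,
        "noise_level": noise_level if noise_seed is not None else 0.0,
        "n_accumulations": n_accumulations,
    }
    return RamanSpectrum(nu, intensity, position_mm=position_mm,
                         age_days=age_days, metadata=truth)
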