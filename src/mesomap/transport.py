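"""Hydration-driven water uptake and lipid redistribution in a depot.

Fluxes follow the generalized Fick's law, J_i = -(D_i/RT) C_i dmu_i/dx:
species move down gradients of chemical potential, not concentration,
which at phase boundaries permits uphill diffusion.  Chemical
potentials come from a three-component regular-solution (Flory-Huggins
type, unit segment sizes) free energy: water interacts more favourably
with the hydrophilic SPC than with the hydrophobic GDO
(chi_wS < chi_wG), so incoming water lowers the SPC chemical potential
and pulls SPC toward the hydrated rim.  The water/GDO interaction is
calibrated so a 50/50 lipid mixture in contact with a near-unit-activity
reservoir equilibrates at its 16 wt% hydration limit.

Geometry is 1D spherical-radial (a Cartesian slab is available for
analytic benchmarks) on a fixed grid: depot swelling is neglected, so
concentrations are per initial volume, lipid totals are conserved
exactly by the finite-volume scheme, and water enters only through the
outer boundary, held at the reservoir water activity (0.996, the value
for subcutaneous tissue).  Time stepping is explicit with the usual
diffusive stability bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SPECIES", "FreeEnergyModel", "DepotProfile",
    "chemical_potentials", "step", "run", "stable_dt",
    "uniform_profile", "profile_from_scenario", "phase_labels",
    "equilibrium_hydration", "R_GAS",
]

SPECIES = ("water", "SPC", "GDO")
R_GAS = 8.31446261815324     # J/(mol K)
_EPS = 1e-6                  # composition floor for log terms


@dataclass(frozen=True)
class FreeEnergyModel:
    """Regular-solution interaction parameters (all dimensionless chi).

    Defaults: chi_ws = 0.8 and chi_sg = 1.2 satisfy chi_ws < chi_sg,
    so arriving water lowers the SPC chemical potential (pulling SPC
    toward the hydrated rim) without driving runaway surface demixing;
    chi_wg is solved from the hydration-limit anchor unless given
    explicitly.  The invariant chi_ws < chi_wg expresses water's
    preference for the hydrophilic SPC over the hydrophobic GDO.
    """

    chi_ws: float = 0.8
    chi_wg: Optional[float] = None
    chi_sg: float = 1.2
    a_w_reservoir: float = 0.996
    hydration_limit: float = 0.16   # water fraction, 50/50 lipid

    def __post_init__(self) -> None:
        if self.chi_wg is None:
            object.__setattr__(self, "chi_wg", self._solve_chi_wg())
        if not self.chi_ws < self.chi_wg:
            raise ValueError("need chi_ws < chi_wg (water prefers SPC)")

    def _solve_chi_wg(self) -> float:
        """chi_wg making mu_water(hydration limit, 50/50) match the
        reservoir."""
        phi_w = self.hydration_limit
        phi_s = phi_g = 0.5 * (1.0 - phi_w)
        target = math.log(self.a_w_reservoir)

        def f(chi_wg: float) -> float:
            mu = (math.log(phi_w)
                  + self.chi_ws * phi_s + chi_wg * phi_g
                  - (self.chi_ws * phi_w * phi_s
                     + chi_wg * phi_w * phi_g
                     + self.chi_sg * phi_s * phi_g))
            return mu - target

        return float(brentq(f, self.chi_ws + 1e-6, 100.0))

    def effective_b(self, x_spc) -> np.ndarray:
        """Effective binary water-lipid interaction along a dilution
        path with fixed lipid ratio x_spc."""
        x = np.asarray(x_spc, dtype=float)
        return (x * self.chi_ws + (1 - x) * self.chi_wg
                - self.chi_sg * x * (1 - x))

    @cached_property
    def _cap_table(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.linspace(0.0, 1.0, 201)
        b = self.effective_b(xs)
        caps = np.ones_like(xs)
        sub = b > 2.0
        caps[sub] = _SPINODAL_MARGIN * 0.5 * (
            1.0 - np.sqrt(1.0 - 2.0 / b[sub]))
        return xs, caps

    def stability_cap(self, x_spc) -> np.ndarray:
        """Largest water fraction on the stable (diffusive) branch for
        a given lipid ratio, with a safety margin below the spinodal.

        Excess water beyond this cap is treated as a separate untracked
        water phase: the bare generalized-Fick flux is anti-diffusive
        past the spinodal, which is ill-posed without an
        interfacial-energy term this model deliberately omits.
        """
        xs, caps = self._cap_table
        return np.interp(np.asarray(x_spc, dtype=float), xs, caps)

    @property
    def chi_matrix(self) -> np.ndarray:
        """Symmetric chi matrix ordered as (water, SPC, GDO)."""
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = self.chi_ws
        m[0, 2] = m[2, 0] = self.chi_wg
        m[1, 2] = m[2, 1] = self.chi_sg
        return m


@dataclass
class DepotProfile:
    """Radial fields of water/SPC/GDO content at one instant.

    ``r_mm`` holds cell-centre radii (strictly increasing, mm);
    ``C`` has shape (n, 3) ordered (water, SPC, GDO): mass fractions of
    the initial state, evolving as concentrations per initial volume.
    ``D`` are per-species diffusion coefficients in m^2/s.
    """

    r_mm: np.ndarray
    C: np.ndarray
    time_s: float = 0.0
    D: np.ndarray = field(
        default_factory=lambda: np.array([1e-11, 1e-13, 1e-13]))
    temperature_K: float = 310.15
    geometry: str = "spherical"   # or "slab"
    outer_bc: str = "reservoir"   # or "closed" (for analytic benchmarks)

    def __post_init__(self) -> None:
        self.r_mm = np.asarray(self.r_mm, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.r_mm.ndim != 1 or np.any(np.diff(self.r_mm) <= 0):
            raise ValueError("radial grid must strictly increase")
        if self.C.shape != (self.r_mm.size, 3):
            raise ValueError("C must have shape (n_nodes, 3)")
        if np.any(self.C < -1e-12):
            raise ValueError("concentrations must be non-negative")
        if self.geometry not in ("spherical", "slab"):
            raise ValueError("geometry must be 'spherical' or 'slab'")
        if self.outer_bc not in ("reservoir", "closed"):
            raise ValueError("outer_bc must be 'reservoir' or 'closed'")

    @property
    def n(self) -> int:
        return self.r_mm.size

    @property
    def dx_m(self) -> float:
        return float(self.r_mm[1] - self.r_mm[0]) * 1e-3

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes up to a constant factor (4*pi or unit area)."""
        dx = float(self.r_mm[1] - self.r_mm[0]) if self.n > 1 else 1.0
        edges = np.concatenate((
            [max(self.r_mm[0] - dx / 2, 0.0)],
            0.5 * (self.r_mm[:-1] + self.r_mm[1:]),
            [self.r_mm[-1] + dx / 2])) * 1e-3
        if self.geometry == "spherical":
            return (edges[1:] ** 3 - edges[:-1] ** 3) / 3.0
        return edges[1:] - edges[:-1]

    def totals(self) -> np.ndarray:
        """Total mass per species (arbitrary volume units)."""
        return self.cell_volumes() @ self.C

    def lipid_spc_fraction(self) -> np.ndarray:
        lip = self.C[:, 1] + self.C[:, 2]
        return np.divide(self.C[:, 1], lip, out=np.full(self.n, np.nan),
                         where=lip > 0)


def uniform_profile(n: int = 60, radius_mm: float = 4.0,
                    spc_fraction: float = 0.5, water: float = 0.005,
                    D: Optional[np.ndarray] = None,
                    geometry: str = "spherical") -> DepotProfile:
    """Freshly injected depot: homogeneous lipids, trace initial water."""
    dx = radius_mm / n
    r = (np.arange(n) + 0.5) * dx
    lipid = 1.0 - water
    C = np.tile([water, lipid * spc_fraction, lipid * (1 - spc_fraction)],
                (n, 1))
    kw = {} if D is None else {"D": np.asarray(D, dtype=float)}
    return DepotProfile(r, C, geometry=geometry, **kw)


def profile_from_scenario(scenario, n: int = 60,
                          D: Optional[np.ndarray] = None) -> DepotProfile:
    """Initial transport state from a depot scenario's ground-truth
    composition and hydration profiles (e.g. the early-hydration
    layered state whose subsequent relaxation is being studied)."""
    dx = scenario.depot_radius_mm / n
    r = (np.arange(n) + 0.5) * dx
    w = np.array([scenario.hydration_profile(x) for x in r])
    x_spc = np.array([scenario.composition_profile(x) for x in r])
    C = np.column_stack([w, (1 - w) * x_spc, (1 - w) * (1 - x_spc)])
    kw = {} if D is None else {"D": np.asarray(D, dtype=float)}
    return DepotProfile(r, C, **kw)


def chemical_potentials(profile: DepotProfile,
                        model: FreeEnergyModel) -> np.ndarray:
    """Per-node chemical potentials mu_i (J/mol), shape (n, 3).

    Regular solution with unit segment sizes:
    mu_i/RT = ln phi_i + sum_{j != i} chi_ij phi_j
              - sum_{j<k} chi_jk phi_j phi_k,
    where phi are the node compositions normalized to sum to one.
    Vanishing fractions are floored at 1e-6 to keep the logarithm
    finite.
    """
    rt = R_GAS * profile.temperature_K
    total = profile.C.sum(axis=1, keepdims=True)
    phi = np.clip(profile.C / np.clip(total, 1e-300, None), _EPS, None)
    chi = model.chi_matrix
    pair = 0.5 * np.einsum("nj,jk,nk->n", phi, chi, phi)  # sum_{j<k} term
    mu = np.log(phi) + phi @ chi - pair[:, None]
    return rt * mu


#: Maximum boundary swelling: the hexagonal rim takes up at most about
#: 40 wt% water (the upper end of the hydration calibration range).
MAX_BOUNDARY_HYDRATION = 0.40
#: Stay this factor below the spinodal so interior cells never enter
#: the anti-diffusive (ill-posed without interfacial energy) branch.
_SPINODAL_MARGIN = 0.85


def equilibrium_hydration(model: FreeEnergyModel, x_spc: float,
                          a_w: Optional[float] = None) -> float:
    """Hydration limit: water fraction of the lipid-side branch in
    equilibrium with a reservoir of activity ``a_w``.

    Along the fixed-lipid-ratio dilution path the water chemical
    potential reduces to the binary form mu_w/RT = ln(phi_w)
    + B (1 - phi_w)^2 with B = x chi_ws + (1-x) chi_wg
    - chi_sg x (1-x).  For B > 2 the curve is non-monotone (the depot
    coexists with excess water) and the root is sought on the stable
    branch; compositions whose stable branch never reaches the
    reservoir potential are capped a safety margin below the spinodal,
    and all results are capped at the maximum rim swelling of 40 wt%.
    With default parameters x = 0.5 returns the anchored 16 % limit.
    """
    x = float(x_spc)
    target = math.log(model.a_w_reservoir if a_w is None else a_w)
    B = (x * model.chi_ws + (1 - x) * model.chi_wg
         - model.chi_sg * x * (1 - x))

    def f(p: float) -> float:
        return math.log(p) + B * (1.0 - p) ** 2 - target

    if B > 2.0:
        spinodal = 0.5 * (1.0 - math.sqrt(1.0 - 2.0 / B))
        p_cap = _SPINODAL_MARGIN * spinodal
    else:
        p_cap = MAX_BOUNDARY_HYDRATION
    if f(p_cap) < 0.0:
        phi = p_cap
    else:
        phi = float(brentq(f, 1e-12, p_cap))
    return min(phi, MAX_BOUNDARY_HYDRATION)


def stable_dt(profile: DepotProfile, safety: float = 0.25) -> float:
    """Largest explicit time step: safety * dx^2 / max(D)."""
    return safety * profile.dx_m ** 2 / float(profile.D.max())


def _face_areas(profile: DepotProfile) -> np.ndarray:
    """Interior face areas up to the same constant as cell_volumes."""
    r = profile.r_mm * 1e-3
    faces = 0.5 * (r[:-1] + r[1:])
    if profile.geometry == "spherical":
        return faces ** 2
    return np.ones(profile.n - 1)


def step(profile: DepotProfile, model: FreeEnergyModel,
         dt: float) -> DepotProfile:
    """One conservative finite-volume update of the generalized Fick flux.

    Interior face fluxes use central differences of mu and arithmetic
    mean concentrations; the inner boundary is a symmetry (zero-flux)
    face.  The outer boundary holds the water activity at the
    reservoir value: the boundary cell's water content is set to the
    local (stable-branch) equilibrium hydration while lipids see zero
    outflux — water enters the depot only by interior diffusion away
    from this saturated surface cell.  ``dt`` beyond the explicit
    stability bound is rejected with a suggested value.

    A conservative positivity limiter scales any face flux that would
    drain more than half a cell's content of a species within one
    step; it stays inactive on smooth profiles and only engages where
    chemical-potential differences spike (e.g. at a demixing rim).
    """
    dt_max = stable_dt(profile)
    if dt > dt_max * (1 + 1e-9):
        raise ValueError(
            f"dt={dt:.3g}s violates the stability bound; "
            f"use dt <= {dt_max:.3g}s")
    rt = R_GAS * profile.temperature_K
    dx = profile.dx_m
    mu = chemical_potentials(profile, model)      # (n, 3)
    C = profile.C
    n = profile.n

    c_face = 0.5 * (C[:-1] + C[1:])               # (n-1, 3)
    dmu = (mu[1:] - mu[:-1]) / dx
    flux = -(profile.D / rt) * c_face * dmu       # (n-1, 3), + = outward

    area_in = _face_areas(profile)
    vol = profile.cell_volumes()

    new_C = C.copy()
    if n > 1:
        af = area_in[:, None] * flux                  # (n-1, 3)
        # Positivity limiter: per cell and species, total outflow over
        # this step may not exceed half the cell content.
        outflow = np.zeros_like(C)
        outflow[:-1] += np.clip(af, 0.0, None)        # through right face
        outflow[1:] += np.clip(-af, 0.0, None)        # through left face
        with np.errstate(divide="ignore", invalid="ignore"):
            cell_scale = np.where(
                outflow > 0,
                np.minimum(1.0, 0.5 * C * vol[:, None] / (dt * outflow)),
                1.0)
        af = af * np.minimum(cell_scale[:-1], cell_scale[1:])
        new_C[0] -= dt * af[0] / vol[0]
        new_C[1:-1] += dt * (af[:-1] - af[1:]) / vol[1:-1, None]
        new_C[-1] += dt * af[-1] / vol[-1]
        np.clip(new_C, 0.0, None, out=new_C)

    if profile.outer_bc == "reservoir":
        # Spinodal guard: water beyond the local stable branch belongs
        # to an untracked excess-water phase and is shed.
        lip_all = new_C[:, 1] + new_C[:, 2]
        x_all = np.where(lip_all > 0, new_C[:, 1] / np.clip(lip_all, 1e-300,
                                                            None), 0.5)
        phi_cap = model.stability_cap(x_all)
        with np.errstate(divide="ignore"):
            c_cap = np.where(phi_cap < 1.0,
                             phi_cap / (1.0 - phi_cap) * lip_all, np.inf)
        new_C[:, 0] = np.minimum(new_C[:, 0], c_cap)
        lipid = new_C[-1, 1] + new_C[-1, 2]
        x_edge = new_C[-1, 1] / lipid if lipid > 0 else 0.5
        phi_eq = equilibrium_hydration(model, x_edge)
        new_C[-1, 0] = phi_eq / (1.0 - phi_eq) * lipid

    return replace(profile, C=new_C, time_s=profile.time_s + dt)


def run(initial: DepotProfile, model: FreeEnergyModel,
        horizon_days: float, cadence_days: float = 1.0,
        dt: Optional[float] = None) -> tuple[list[DepotProfile], dict]:
    """March the profile to ``horizon_days``, checkpointing at cadence.

    Returns the trajectory (including the initial state) and a
    conservation report with initial/final species totals.  A zero
    horizon returns ``[initial]``.
    """
    if horizon_days < 0:
        raise ValueError("horizon must be non-negative")
    traj = [initial]
    report = {"initial_totals": dict(zip(SPECIES, initial.totals()))}
    if horizon_days == 0:
        report["final_totals"] = report["initial_totals"]
        return traj, report

    dt = stable_dt(initial) if dt is None else dt
    horizon_s = horizon_days * 86400.0
    cadence_s = cadence_days * 86400.0
    profile = initial
    next_checkpoint = cadence_s
    while profile.time_s < horizon_s - 1e-9:
        this_dt = min(dt, horizon_s - profile.time_s)
        profile = step(profile, model, this_dt)
        if profile.time_s >= next_checkpoint - 1e-9:
            traj.append(profile)
            next_checkpoint += cadence_s
    if traj[-1] is not profile:
        traj.append(profile)

    final = profile.totals()
    report["final_totals"] = dict(zip(SPECIES, final))
    init = np.array(list(report["initial_totals"].values()))
    report["relative_drift"] = dict(
        zip(SPECIES, np.abs(final - init) / np.clip(np.abs(init), 1e-300,
                                                    None)))
    return traj, report


def phase_labels(profile: DepotProfile,
                 water_threshold: float = 0.03,
                 spc_threshold: float = 0.53) -> np.ndarray:
    """Post-hoc phase assignment from local (water, SPC) coordinates.

    A lookup mimicking the published phase-diagram topology, not a
    thermodynamic computation: nearly dry nodes are the isotropic
    reverse micellar liquid (L2); hydrated nodes split into hexagonal
    (SPC-rich) and micellar cubic Fd3m (SPC-lean).
    """
    total = profile.C.sum(axis=1)
    phi_w = profile.C[:, 0] / np.clip(total, 1e-300, None)
    x_spc = profile.lipid_spc_fraction()
    labels = np.where(phi_w < water_threshold, "L2",
                      np.where(x_spc >= spc_threshold, "H2", "Fd3m"))
    return labels.astype(object)
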