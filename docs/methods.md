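# Methods

This note records the models, conventions and numerical choices behind
`mesomap`, and what the synthetic-data tests do and do not demonstrate
about real depot data.

## Scattering forward model

A measured curve is modelled as a smooth background plus Bragg peaks:

    I(q) = b q^(-p) + c + Σ_k A_k · pV(q; q_k, Γ, η)

* `pV` is an area-normalized pseudo-Voigt (Lorentzian fraction η,
  shared FWHM Γ). Defaults: Γ = 0.0025 Å⁻¹, η = 0.2. The same line
  shape serves the Raman model (there with η = 0.5), so one
  implementation covers both.
* Reflection positions follow the standard ladders — Fd3m
  √(3:8:11:12:16:19:24:27), Pm3n √(2:4:5:6:8:10), H2 1:√3:2:√7,
  lamellar 1:2:3 — anchored by the lattice rules
  `a = 2π√(h²+k²+l²)/q` (cubic), `a = 4π/(√3 q₁₀)` (hexagonal).
* Relative reflection intensities within one phase decay geometrically
  (ratio 0.5), keeping the first reflection dominant as observed in
  depot patterns. Real structure factors are not modelled; the decay
  is a convention, and every statistic that depends on it (see the
  cubic-fraction normalization) states so.
* Background defaults `(b, p, c) = (0.01, 2, 0.5)` for depot pixels
  and `(0.002, 2, 0.05)` for surrounding buffer; the power law keeps
  the invariant integrand finite on the truncated 0.016–0.85 Å⁻¹
  range. Optional Poisson noise at 10³ counts per intensity unit.
* The default q-grid has 1669 points (Δq = 5×10⁻⁴ Å⁻¹, ≥5 points per
  FWHM); coarser grids are rejected rather than silently aliasing
  peaks.

Depot rasters place sharp concentric layers (phase, outer radius,
lattice) on a square 50 µm grid; within-layer lattice gradients are
linear in radius, which is how the observed centre-to-edge swelling
gradient (157 → 172 Å at four weeks; 131–153 Å early) is emulated.
The parametric scenario builder encodes the study phenomenology: an
isotropic core shrinking to zero within about six days, a hexagonal
rim thickening with age and SPC content, and hydration increasing
toward the surface.

## Baseline, peaks, indexing

Baseline estimation is an asymmetrically reweighted Chebyshev fit
(degree 7) of log I versus log q: the power-law-plus-constant
background is gently curved in log–log space while Bragg peaks stay
narrow positive outliers, which a uniform-stiffness smoother in linear
space cannot achieve on the steep low-q upturn. Points above the
current estimate get weight 10⁻³; 20 iterations or convergence. On
synthetic backgrounds the residual stays below 1 % and peak heights
are preserved to ~0.5 %.

Peak detection thresholds prominence at 1 % of the total
(baseline-inclusive) maximum and additionally at 5× the local noise —
per-point σ when available (counting noise grows steeply toward low
q), else a robust global estimate. Positions are refined by a local
quadratic fit (≤ half a grid step of bias).

Indexing is greedy best-first over (phase, anchor-peak) hypotheses
with relative tolerance 1.5 % (about twice the grid resolution).
Hypotheses are ranked by matched reflections, then **ladder coverage**
(the matched share of reflections predicted inside the observed
range), then mean residual, then library order. The coverage term is
required: the H2 ratios are an exact subset of the Pm3n ladder, so
match count and residual alone cannot separate them, while the absence
of Pm3n's predicted (200)/(210) lines can. When a candidate (111) lies
in the 0.058–0.085 Å⁻¹ window, Fd3m is assigned first, resolving the
Fd3m(220)/H2(10) overlap in favour of the tracked phase. A lone
otherwise-unexplained peak is labelled lamellar with a flag; an empty
peak list is the isotropic classification (a fallback, never a fit).

## Cubic-phase fraction

Per pixel, with the baseline removed:

    fraction = clip( κ · ∫_window q² I_cub dq / ∫_peaks q² I dq , 0, 1)

* numerator: the (111) window integral after removing a local linear
  pedestal (only the (111) lives in the window by construction of the
  library, so no multi-peak deconvolution is attempted);
* denominator: q²-weighted intensity restricted to ±3 FWHM of detected
  peaks — restricting to peak neighbourhoods keeps clipped noise and
  baseline residue (q²-amplified at high q) out of the total;
* κ = Σ (N_k/3)·0.5^k ≈ 4.477 rescales the (111) share to the whole
  Fd3m ladder under the generator's decay convention, so a pure
  single-phase Fd3m pattern reads 1.0. The supplement that defines
  the original normalization is not public; this convention is an
  explicit, testable stand-in and is exact only under the generator's
  intensity-decay assumption.

The in-depot mask keeps pixels whose total invariant exceeds 5× the
buffer level (median invariant of the outermost pixel ring) — the
invariant is proportional to scattering volume, so depot pixels clear
it by an order of magnitude. Radial profiles average in annuli one
pixel-pitch wide around the mask centroid; layers are contiguous runs
of annuli above/below a cubic-fraction threshold (default 0.25, far
from both the ~1 readings of cubic pixels and the ~0 of cubic-free
ones).

## Raman model and chemometrics

Band centres, assignments and sources follow the SPC/GDO band table
(715 cm⁻¹ choline stretch unique to SPC; 1264 δ(=C–H) reflecting the
higher C=C count of SPC; 1301 CH₂ twist as ratio denominator; 1439
CH₂/CH₃ scissor as composition-insensitive internal standard).
Generator amplitudes anchor the published calibrations: 1264/1301
interpolates linearly in SPC fraction between 0.56 (GDO) and 0.95
(SPC); 715/1301 follows the 50/50 hydration calibration 0.61 → 0.68
over 0–40 % water, scaled by SPC content. Delivered spectra emulate
the usual accumulation protocol (60 co-added acquisitions at 1 %
per-acquisition noise); a single-readout mode exists for noise-
sensitivity tests.

Fitting is windowed least squares (lmfit): overlapping targets share a
window with a linear local baseline and one pseudo-Voigt each; centres
bounded ±8 cm⁻¹, heights non-negative, Gaussian–Lorentzian mixing held
at 50:50 by default because the free mixing parameter correlates
strongly with height under noise. "Intensity" means fitted band
height, not area. Difference spectra normalize both inputs to unit
fitted 1439 height before subtracting. Composition inversion uses the
weighted two-endmember mixing model (default 1:1 relative 1301
weights; the measured dry 50/50 ratio of 0.81 exceeds the equal-weight
prediction 0.755, so the weights stay configurable rather than
asserted). Hydration inversion is valid at 50/50 and flagged
`extrapolated` elsewhere; the ethanol washout feature near 884 cm⁻¹ in
very young depots is deliberately excluded from the band library.

## Transport model

Fluxes follow `Jᵢ = −(Dᵢ/RT) Cᵢ dμᵢ/dx` with a ternary regular
solution (unit segment sizes):

    μᵢ/RT = ln φᵢ + Σ_{j≠i} χᵢⱼ φⱼ − Σ_{j<k} χⱼₖ φⱼ φₖ

Parameters (dimensionless): χ_wS = 0.8, χ_SG = 1.2, χ_wG ≈ 4.98 solved
so that the 50/50 mixture equilibrates at its 16 wt% hydration limit
against a reservoir of water activity 0.996 (subcutaneous tissue).
χ_wS < χ_SG makes arriving water *lower* μ_SPC, the driving force that
pulls SPC to the rim; χ_wS < χ_wG expresses water's preference for the
hydrophilic lipid. D defaults: water 10⁻¹¹ m²/s, lipids 10⁻¹³ m²/s
(self-diffusion in reverse micellar cubic phases), constant per
species.

Numerics: 1D spherical finite volume (slab option for analytic
benchmarks), default 60 cells over a 4 mm radius, explicit stepping at
0.25·Δx²/max(D). Along a fixed-lipid-ratio path the water potential
reduces to `ln φ_w + B(1−φ_w)²`; a 16 % limit against a_w ≈ 1 forces
B > 2, i.e. the depot thermodynamically coexists with excess water and
the bare Fickian flux becomes anti-diffusive past the spinodal
(ill-posed without the interfacial-energy term this model deliberately
omits). Three guards keep the scheme well-posed without touching the
smooth regime: the reservoir boundary condition is a stable-branch
Dirichlet value for the boundary cell's water (capped at 40 wt% rim
swelling and 0.85× the spinodal); water beyond the local stable branch
anywhere is shed to an untracked excess-water phase; and a
conservative positivity limiter scales any face flux that would drain
more than half a cell's species content in one step. Lipids see
zero-flux boundaries, so their totals are conserved to machine
precision (the acceptance threshold is 10⁻⁹). Concentrations evolve
per initial volume (no swelling of the grid); chemical potentials use
renormalized fractions, so the sum-to-one invariant applies to initial
states, not during uptake.

Phase labels (L2 below 3 % water; H2 above 53 % SPC-of-lipid when
hydrated; Fd3m otherwise) are a post-hoc lookup mimicking the phase-
diagram topology, not a thermodynamic computation.

## What the tests show — and what they do not

Problem sizes: mapping tests run 41×41-pixel rasters at 0.2 mm pitch
and the pipeline-level checks run 99×99 rasters at the experimental
50 µm pitch on a 2.45 mm depot; transport benchmarks use 40–200 cells.
These sizes make the whole suite run in minutes while leaving every
algorithmic path identical to full-size runs.

The generators reproduce the *structure* of the data (peak ladders,
layering, calibrated ratios, counting noise) but not instrument
resolution/smearing, detector artefacts, structure factors, baseline
chemistry of real Raman matrices, or sample misalignment. Passing
recovery tests therefore demonstrates internal consistency of the
estimators under the stated noise models, not instrument-grade
accuracy on beamline data.

Two known limitations deserve emphasis. First, the cubic-fraction
normalization κ is exact only under the generator's geometric
intensity decay; on real patterns the fraction remains a monotone,
[0, 1]-bounded index of cubic content rather than an absolute volume
fraction. Second, with constant per-species D the simulated SPC
minimum develops immediately behind the rim (the 4-week lipid
diffusion length is only ~0.7 mm), whereas depots show it 1–2 mm below
the surface; that deeper minimum forms while the early wetted material
is still an un-ordered, mobile isotropic liquid, a regime a
constant-mobility model cannot reach. Gradient-persistence comparisons
therefore start from an established early-hydration state
(`transport.profile_from_scenario`) and show: slow lipids retain >70 %
of the gradient after four weeks, equal fast diffusivities erase >80 %
of it within two — the redistribution kinetics, not water diffusion,
set the equilibration clock.
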