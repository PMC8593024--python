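# Methods

This package re-creates, at desk scale, an in-silico design pipeline for
perfusion bioreactors that seed stem cells into porous bone-substitute
blocks: porous-scaffold flow simulation, Hoover-coefficient homogeneity
scoring, a particle model of cell seeding and washout, and dynamic
PET-like quantification of the resulting cell distributions.  The real
study resolved a 9.5 µm micro-CT scan of a xenograft block in commercial
CFD and ran wet-lab perfusions; everything here runs on synthetic
surrogates, so absolute numbers from the original geometry are not
reproduction targets — orderings and directions of effect are.

## Synthetic scaffold volumes

The reference block is a 10 mm × 10 mm × 20 mm cancellous-bone cuboid
with 69% porosity and a bimodal pore structure (17 nm nanopores, ~0.107
mm macropores).  The surrogate is a Gaussian random field: seeded white
noise smoothed with a kernel of width `pore_scale_mm / 2` voxels,
thresholded at the porosity quantile (exact-count threshold, so porosity
is controlled to one voxel), after which fluid components that do not
span the longitudinal axis are solidified.  If pruning or a failed span
would push porosity more than 1 point below target, the threshold is
relaxed stepwise (more fluid) and generation fails explicitly if the
achieved porosity drifts more than 2 points.  Connectivity is 6-neighbor
face adjacency, the most conservative choice for flow.  Nanoporosity is
far below continuum resolution and is ignored.

Defaults: 0.25 mm voxels and a 0.5 mm pore scale.  The real macropore
scale (0.107 mm) cannot be resolved on a desk-scale grid; 0.5 mm gives a
resolvable macro-porous surrogate while keeping linear systems small.
The surrogate matches the block's dimensions, porosity and percolation,
not its true micro-architecture — conclusions drawn from it are about
design orderings, not absolute fields.

## Reactor geometry

The simulation domain wraps the block in a form-fitting chamber with a
nozzle ("connector") above and below.  Flow tubing (1.6 mm bore) feeds
every nozzle through a small port disc; a 1.5 mm tubing stub is included
at each end of the domain.  Cylindrical connectors are channels of
diameter D; conical connectors are linear tapers (frusta) from the
throat to a base that covers the full scaffold face.  The taper is
voxelized by sampling each layer at its scaffold-side edge, so a
diffuser of any length ends at its full base width — this encodes the
device property that the cone delivers inflow over the entire upper
scaffold surface, corners included, whereas a D = 10 mm cylindrical
channel is a circular footprint that leaves the square face's corners
starved.  Without encasement (enc−) the chamber is loose-fit: a 0.5 mm
annular bypass gap (1 mm on the coarse study grid, where half a voxel
cannot be represented) surrounds the block's lateral faces, connected to
the nozzles by a thin plenum.  With encasement (enc+) the only fluid
path crosses the scaffold.  The transverse orientation (type 3) rotates
the block so flow crosses its 10 mm dimension.

Port sizes are a modeling choice the source hardware implies but does
not quantify: the imposed inflow must enter through the tubing bore, not
uniformly over the connector mouth.  This matters physically — with a
uniform full-face inlet, connector length would have no effect at
creeping-flow conditions, contrary to the reference observations; with a
port-fed nozzle, length controls how far the stream has spread before
the scaffold face.

## Flow model

Steady incompressible creeping flow with an optional Brinkman drag:

μ ∇²**u** − (μ/K) **u** − ∇p = 0,  ∇·**u** = 0

on a staggered (MAC) voxel grid; no-slip walls with mirror ghost values,
uniform prescribed velocity over the inlet port, a mass-matched uniform
velocity over the outlet port, pressure pinned to zero at the outlet.
The sparse saddle-point system is factorized directly (SuperLU, MMD_ATA
column ordering), so divergence and cross-sectional flux errors are at
machine precision; the solver refuses fields whose plane flux deviates
more than 1% from the prescribed rate.  Fluid properties default to the
measured cell-suspension rheology at 37 °C (μ = 1.176 mPa·s, ρ = 1004
kg/m³).  At 1 ml/min through mm-scale ports the Reynolds number is small
(order 1–10 at the port, ≪1 in the block), so inertia is neglected; this
is a declared deviation from the original full CFD.  One consequence is
discussed under *Limitations*.

In RESOLVED mode scaffold solid voxels are no-slip obstacles.  In
HOMOGENIZED mode — used for all desk-scale studies — the scaffold block
carries an isotropic Brinkman drag with Kozeny–Carman permeability
K = φ³ d² / (180 (1 − φ)²) evaluated at the block porosity and the
modeled pore scale d = 0.5 mm (passed explicitly when the surrogate
volume was generated with a coarser texture).  Shear rate is
γ̇ = √(2 D:D) with D the symmetric velocity-gradient tensor from central
differences, one-sided at boundaries.

Internal units are mm/s/mPa·s (pressure in mPa); ml/min is converted in
one constants table.

## Hoover (Robin-Hood) homogeneity index

H = ½ Σᵢ |vᵢwᵢ/Σ(vw) − wᵢ/Σw| over bins with per-capita values v and
reference weights w: 0 is perfectly even, the maximum on n equal bins is
1 − 1/n.  The source never prints its formula; the Robin-Hood form
matches the stated endpoints and standard usage.  Two applications are
deliberately distinguished:

* **flow homogeneity** — the index of velocity magnitude *within* each
  cross-sectional plane (equal weights over the plane's flow-carrying
  voxels), averaged over the plane stack: the "mean Hoover coefficient"
  of a design;
* **axial distribution homogeneity** — a single index of how deposited
  cells/activity are shared *across* planes, weighted by per-plane
  scaffold fluid volume: the cell-distribution Hoover.

The default plane stack is 24 planes at 1 mm spacing centered on the
scaffold; on a 20 mm block this spans the scaffold plus ~1.5 mm into
each connector.  The exact placement of "24 planes" over a 20 mm block
is not stated in the source and is configurable here; positions snap to
voxel centers.

## Cell seeding model

The wet-lab experiments report operating conditions and outcomes but no
transport model, so this module is a declared synthetic stand-in.
Super-particles (default 3000–4000 per run, each representing an equal
share of the injected cells) are injected at the upstream port at the
concentration-times-flow rate, advected with nearest-voxel interstitial
velocity plus Stokes settling (15 µm, 1050 kg/m³ cells → ~5 µm/s) and a
small random-walk dispersion (0.01 mm²/s, standing in for pore-scale
mixing), with per-particle sub-stepping so no move exceeds 0.8 voxels.
In porous scaffold voxels a particle is captured over a path dl with
probability 1 − exp(−p_adh · f_shear · f_cap · dl/d_pore), where
f_shear = max(0, 1 − γ̇/γ̇_c) uses a pore-scale shear estimate 8v/d, and
f_cap is the voxel's remaining surface capacity (specific surface
6(1 − φ)/d at 2500 cells/mm²).  Reversals in oscillating protocols swap
the active field for its negation (exact by Stokes reversibility) and
move the injection to the new upstream port.  The particle ledger
(injected = deposited + in-domain + outflowed) is exact in integers.

Free parameters and their roles: the adhesion probability p_adh is the
single calibrated parameter — a bracketing grid plus bisection matches
the ensemble-mean efficiency at the reference operating point (80% at
0.4 × 10⁶ cells/ml, 0.5 ml/min, press-fit diffuser reactor); the shipped
default (0.0825) is that calibration's result.  The shear threshold
γ̇_c = 9 s⁻¹ makes capture collapse at high perfusion rates (the
mechanism behind the observed 90% → ~5% efficiency fall from 0.25 to
2 ml/min); the surface capacity makes efficiency fall with concentration
(saturation).  Both are order-of-magnitude physiological choices fixed
before any sweep and never fitted per condition.

The protocol defaults are the study's: 60 min seeding + 40 min washout,
5-min reporting frames, 0.5 ml/min and 0.4 × 10⁶ cells/ml as reference;
oscillating presets reverse once at 30 min (imaging protocol) or every
5 min (microscopy protocol).  The time step is 0.5 s with sub-stepping,
a desk-scale compromise documented here rather than a physical claim.

## Synthetic dynamic imaging

Each 5-min frame of the activity series is (deposited + suspended cells
per voxel) × activity per cell × the fluorine-18 physical-decay factor
(half-life 109.77 min, a physical constant), plus a circulating
free-tracer background (5% of injected activity spread over the fluid)
during the perfusion phase, a single-exponential label leak from bound
cells during washout (0.002/min, tuned only to produce the qualitative
plateau), an isotropic Gaussian PSF (1.2 mm FWHM) and optional Poisson
noise at a stated count scale.  Default label activity is 1 MBq offered
per 2 × 10⁵ cells with a free uptake-fraction parameter (0.5); absolute
MBq values are therefore model-scaled and are never compared against the
experimental enrichments.  Quantification: ROI time–activity curves
(whole block, axial thirds within the block bounding box, outflow
tract), decay correction by exp(+λt) at frame mid-times with a guard
against double correction, and the per-frame axial Hoover coefficient.
Whether the original Hoover-on-PET used decay-corrected frames is
unstated; both are available, and the axial Hoover is scale-invariant so
the choice does not affect it.

## Desk-scale study conditions

The three studies run on a 1 mm grid (homogenized scaffold, ~8–14 k
unknowns per solve, under a second each): the connector sweep (2 shapes
× 6 lengths × 5 scaffold seeds at 1 ml/min, plus the D = 1 mm pair),
the efficiency sweep (4 concentrations and 4 rates × 10 particle seeds),
and the configuration comparison (6 presets × 5 seeds at the imaging
protocol).  Problem sizes were chosen so each analysis completes in
minutes on one core; they are stated here as the package's operating
points.

## Limitations

* Creeping flow cannot reproduce inertial jet persistence.  In the
  original CFD the conical diffuser's advantage over a wide cylindrical
  connector partly reflects an inertial jet that a sudden expansion
  cannot spread; at Re → 0 a sudden expansion actually spreads *better*
  than a guided taper of equal length.  In this package the conical
  advantage emerges from a geometric mechanism instead — full-face
  (corner-covering) delivery versus a circular footprint — which is why
  faithful frustum voxelization matters (see Reactor geometry).
* Absolute Hoover values are resolution- and geometry-dependent: the
  coarse homogenized surrogate produces much smaller within-plane
  inequality (~0.03–0.12) than the resolved micro-CT geometry
  (0.41–0.62).  Only orderings are claimed.
* The deposition model is phenomenological; its parameters are
  calibrated to one operating point and validated against directions of
  effect.  Proliferation, differentiation, oxygen transport and
  multi-day culture are out of scope.
* The encasement benefit is reproduced for the diffuser reactor; for
  the 1 mm cylindrical reactor the model predicts a weak inversion
  (jet shear suppresses capture under the nozzle when flow cannot
  bypass), and the corresponding experiment also found only a marginal
  difference there.
* Scanner physics is not modeled; the synthetic series begins life
  "already reconstructed".
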