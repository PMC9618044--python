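# Methods

`ringsim` is a molecularly explicit, three-dimensional model of the
cytokinetic contractile ring of fission yeast, built to study how component
turnover controls the actomyosin contractile instability: without turnover,
myosin II aggregates hierarchically, ring tension collapses, and the ring
fractures; restoring myosin turnover rescues the organization while actin
turnover alone does not.

## Model

**Geometry.** The cell is a sphere of radius `R` (default 3.7 μm) centred at
the origin; the ring occupies an equatorial binding band of membrane width
`w_band` = 0.2 μm. Arc position `s ∈ [0, 2πR)` runs anticlockwise from the
+x axis.

**Components.** Actin filaments are inextensible bead–rod chains with one
tracked subunit per 0.1 μm (`l0`) and a discrete worm-like-chain bending
energy `H_B = (κ/l0)·Σ(1 − t̂_i·t̂_{i−1})` with `κ = kBT·lp`, `lp` = 10 μm.
Subunit 0 of each chain *is* the formin dimer: it is held at radius
`R − d_for` (30 nm below the membrane) by a normal anchoring force computed
as a Lagrange multiplier, and it elongates the filament at `v_pol`.
Myosin II is coarse-grained into membrane-anchored clusters (held at
`R − d_myo`, 80 nm) that bind every subunit within the capture radius
`r_myo` = 80 nm. α-actinin cross-links are springs (rest length 30 nm,
stiffness 25 pN/μm) joining subunit pairs on distinct filaments closer than
50 nm, rupturing beyond 50 nm.

**Forces.** Per engaged subunit: a capture spring applied only perpendicular
to the filament (`k_cap` = 400 pN/μm), and a linear force–velocity motor
pull `f = f_s·[1 − (v_i − v_α)·t̂/v_myo0]·t̂` with stall force
`f_s` = 4 pN, shared as `4·(10/n_fil)` pN when a cluster pulls more than 10
filaments. Clusters repel within 45 nm at 4 pN/nm. All components are
confined by a 20 pN/μm restoring force outside radius `R`. Anchored species
feel membrane drag (`γ_for`, `γ_myo`), subunits cytosolic drag
(0.2 pN·s/μm), and a pairwise artificial drag `γ_a` = 4 pN·s/μm acts
between bonded subunits and motor–subunit pairs. The artificial drag adds
no net force (pairwise, velocity-difference coupling); it damps the
otherwise underdamped capture spring at the working time step and is
required for stability of the explicit integrator.

**Dynamics.** The ring is overdamped. Each step solves one sparse linear
system for all component velocities plus Lagrange multipliers: filament
tensions (one per inter-subunit bond) and anchoring normal forces (one per
formin and per cluster). Constraints `g = 0` (bond lengths and anchoring
radii) are stabilized as `dg/dt = −g/τ_c`, `τ_c = 10·Δt`, and positions
advance by explicit Euler with `Δt` = 0.01 s. The growing barbed segment's
constraint target is `l0 + frac_tip`, advancing at `v_pol`, with a subunit
inserted behind the formin whenever `frac_tip ≥ l0`. The sparse system is
re-factorized every step (component turnover changes the topology);
velocities and multipliers come from a direct SuperLU solve.

**Turnover.** Formins (with their filaments), clusters and cross-links
dissociate as per-step Bernoulli events with the exact exponential
probability `1 − exp(−koff·Δt)`. In modes with association, binding rates
balance dissociation at the configured line densities (15 formins/μm,
8 clusters/μm, 25 cross-links/μm); cross-link association uses a
feedforward-plus-proportional controller (rate `koff_x·target +
(target − current)/τ`) since only the target density, not the mechanism, is
specified. Severing removes the pointed-end portion at a uniformly random
cut at rate `r_sev` per μm of filament; the cut is truncated to the subunit
grid, so severed lengths are conservative by at most `l0`. Myosin binding
is biased toward two opposite quarter-sectors (weight `sector_bias` = 4
relative to the other two), which reproduces the ~1 μm myosin density
correlation length observed at t = 0; the bias was tuned by scanning the
generator alone over seeds. The aggregation behaviour does not depend on
this bias.

**Modes.** `normal` is the intact cell. `ghost` (permeabilized cell) has no
association, `v_pol = 0`, `koff_for = 0`, slowed severing and myosin loss.
`ghost_plus_myosin_turnover` and `ghost_plus_actin_turnover` restore one
species' normal kinetics. `blebbistatin` deactivates a random
`bleb_fraction` of clusters (no pull, no capture; anchoring, drag and
excluded volume retained), re-drawn every second. `diffusion` adds a
zero-mean Gaussian force in the local membrane tangent plane. The force
correlator is sometimes written `D·γ²·δ(t−t′)`, a factor 2 below the
fluctuation–dissipation form; the default convention (`fdt`) uses
`2·D·γ²/Δt` per tangential axis so the measured free diffusivity equals
`D_myo`, with the halved correlator available as
`diffusion_convention: halved`.

## Parameters

Values stated above are model constants from measured quantities. The
following are configuration defaults chosen once, with their rationale:

| parameter | default | why |
|---|---|---|
| `v_myo0` | 0.24 μm/s | measured myosin II gliding velocity |
| `rho_myo` | 8 /μm | ~190 clusters of 8 Myo2 dimers on a 23-μm ring |
| `gamma_for`, `gamma_myo` | 500, 1000 pN·s/μm | aggregate drift of ~1 μm over ~5–10 min under few-pN net forces, consistent with aggregation over tens of minutes |
| `koff_x` | 3.3 /s | α-actinin dwell time ~0.3 s |
| `koff_for` | 0.020 /s | with `v_pol` = 0.07 μm/s and `r_sev` = 1.8 μm⁻¹min⁻¹ the stationary mean filament length is 1.40 μm |
| `koff_myo` (ghost) | 2×10⁻⁴ /s | slow, ~80-min decay of total myosin intensity |
| `r_sev` (ghost) | 0.05 μm⁻¹min⁻¹ | ~25% actin loss over 40 min |
| `sector_bias` | 4 | t = 0 correlation length 0.98 ± 0.26 μm (target ~1.0 μm) |

Units are pN–μm–s except `k_excl_myo` (pN/nm) and `r_sev` (1/(μm·min)),
kept in their conventional printed units.

## Filament length theory

With reduced rates `a = koff_for/v_pol` and `b = r_sev/v_pol`, the
stationary length density obeys `p'' + (a + b·l)·p' + 2·b·p = 0` and
depends only on `a` and `b`. The master equation fixes the boundary values
`p(0) = a` (renucleation flux) and `p′(0) = b − a²`, which select the
normalizable physical solution from the ODE's one-parameter family of
decaying solutions; in fact the solution is closed-form,
`p(l) = (a + b·l)·exp(−a·l − b·l²/2)`, with mean
`√(π/2b)·erfcx(a/√(2b))`. The package carries three independent routes —
numerical ODE integration, the closed form, and an exact event-driven
simulation of the renewal process — which agree to < 2% KS distance; the
tests use them as mutual oracles. At the normal-turnover defaults the mean
is 1.40 μm. Initial rings seed filament lengths from this distribution to
shorten equilibration.

## What the simulations emulate, and what they do not

The generator builds a pre-equilibration-style ring directly: component
counts are Poisson at the configured densities, orientations are 50/50,
filament lengths are stationary, and the myosin sector bias is applied at
placement so a t = 0-like state exists without simulating the full 11
minutes of normal turnover (which `pre_equilibrate` also provides). Not
represented: the second myosin isoform Myp2, ring constriction, membrane
deformation or detachment, motor nucleotide chemistry, photobleaching
(intensity loss is modelled through myosin off-rate only), and
hydrodynamic interactions. Passing tests therefore speak to the anchored,
non-constricting ring only.

## Numerical choices and degenerate inputs

* A step aborts if any constraint residual exceeds `0.1·l0` (time step too
  large for the parameter set); the stabilized violation otherwise decays
  as `exp(−t/τ_c)`.
* Coincident myosin clusters (probability zero) repel along a seeded
  deterministic fallback axis rather than crashing.
* A cluster engaging a single-subunit (nascent) filament has no defined
  tangent; such filaments are not engaged.
* Blebbistatin-deactivated clusters exert neither pull nor capture forces
  (the conservative reading of "forces exerted on actin filaments ...
  switched off").
* Profile bins are 0.08 μm (the acquisition pixel); the PSF is a periodic
  unit-mass Gaussian of FWHM 0.6 μm. Aggregates are peaks with prominence
  ≥ 25% of the profile mean separated by ≥ 0.3 μm; gaps are runs below 5%
  of the ring mean at least 0.6 μm wide. These thresholds are
  configuration values: the upstream observations define "peak" and
  "lacking myosin" only qualitatively.
* Ring tension samples cross-sections every 0.1 μm of arc and averages the
  tangential projections of the bond-tension multipliers crossing each
  plane. Mechanical connectivity requires every cross-section to be
  crossed by a filament or bridged by an engaged cluster (circumferential
  percolation); an isolated but internally connected aggregate counts as
  fracture.

## Problem sizes used in the test suite

Full-protocol runs (R = 3.7 μm, 10 replicates, 60 simulated minutes)
reproduce the published statistics but are overnight jobs; they are exposed
as CLI presets (`ghost_aggregation`, `rescue_*`, `blebbistatin_scan`,
`diffusion_scan`, `turnover_scan`). The routine suite runs desk-scale
configurations instead: rings scaled to R ≈ 1 μm via `scale_geometry`
(identical densities and rates — the smallest radius whose circumference
still exceeds four mean filament lengths, keeping the aggregation
mechanism local) and horizons of seconds to a couple of simulated minutes,
long enough for the onset of myosin condensation but not for the full
hierarchical cascade. Statistical assertions use fixed seeds; length-theory
comparisons use 10⁴ filaments.

## Known limitations

* With the default 50-nm radial offset between the myosin anchor sphere
  and filaments, the capture spring dimples the filament toward the
  cluster, and dragging that dimple dissipates ~15–20% of the motor drive;
  free gliding speeds therefore sit slightly below `v_myo0` even at small
  load.
* Severing truncates to the 0.1-μm subunit grid, biasing severed lengths
  down by at most half a subunit; the continuum length theory has no such
  bias, and the 3D model's mean length sits ~3% below the theory value.
* The direct sparse solve re-factorizes every step; cost grows quickly as
  aggregates densify (each engagement adds coupling blocks), which is the
  practical limit on desk-scale horizons.
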