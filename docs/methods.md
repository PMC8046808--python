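# Methods

## Model

The molecule is a trifunctional bead-spring dendrimer: a core of two bonded
monomers, each rooting two spacer chains of S bonds, branching again at
every chain end out to generation G. Monomer count N = 2 + 4S(2^G − 1);
charged-group count N_bg = 2^(G+2) − 2. The charge placement mimics a PAMAM
dendrimer at low pH: the two core monomers and every branching and terminal
group carry valence +1, spacer-internal monomers are neutral. The +1 core
charge is forced by the counting identity — for G = 4 the 62 charged groups
decompose as 2 cores + 28 branchings + 32 terminals; without the core pair
the count would be 60. N_bg monovalent anions restore electroneutrality: a
binary mixture of conventional ions (diameter 1) and bulky ions (diameter
σb\*, 2 or 3), with bulky number fraction f_b. N_b = round(f_b·N_bg) uses
round-half-to-even; on the reference G4S4 molecule the canonical f_b grid
{0, 0.16, 0.32, 0.48, 0.64, 0.8, 1} maps to N_b = {0, 10, 20, 30, 40, 50,
62}. All masses are 1, including the bulky ions — physically unusual for a
particle of 8–27× the volume, but it only affects kinetics, not the
configurational ensemble sampled here.

Interactions (reduced LJ units; energy unit ε = kB·298 K, length unit
σm = Bjerrum length of water ≈ 7 Å, so λB\* = 81/ε_r):

* WCA: truncated-and-shifted LJ 12-6, cutoff 2^(1/6)σ_αβ, arithmetic
  mixing σ_αβ = (σ_α + σ_β)/2. Purely repulsive (good solvent).
* FENE bonds, k = 30, R0 = 1.5. The diverging branch (r ≥ R0) is raised as
  an error, never returned as a non-finite number, so integrator faults
  surface immediately with the step index.
* Coulomb U/kBT = λB z_i z_j / r between **all** charged pairs under
  periodic boundary conditions via classical Ewald summation.

Bonded exclusions: bonded beads feel FENE + WCA together (the Kremer–Grest
convention; the combined bond minimum sits at 0.9609 σ, verified by a 1-D
scan) and are not excluded from Coulomb. Both conventions are switchable
(`wca_exclude_bonded`, `coulomb_exclude_bonded`) but the defaults are used
throughout.

## Electrostatics

Classical Ewald (real + reciprocal + self term, tinfoil boundary
conditions) replaces mesh methods: at the particle counts used here it is
as fast and is directly verifiable against a brute-force lattice sum. The
splitting parameter follows the standard balance heuristic for a target
relative error δ: α = sqrt(−ln δ)/r_cut, reciprocal cutoff
k_max = 2α·sqrt(−ln δ). Default δ = 1e-4 (force tolerance) and real-space
cutoff 10; the desk preset enlarges the real-space cutoff to 18 (= 0.45 L),
which at fixed accuracy moves work out of the reciprocal sum — identical
physics, ~3× cheaper for a 40-box. The reciprocal sum uses per-axis phase
recursion (no trig in the inner loop). Validation: energies agree with a
spherically ordered direct image sum (dipole-corrected to the tinfoil
limit) to better than 1e-5 relative on ≤10-particle neutral fixtures, the
total force vanishes to 1e-10, and analytic forces match central finite
differences of the energy to 1e-4 relative.

## Dynamics

BAOAB splitting of the Langevin equation with unit masses: half-kick,
half-drift, exact Ornstein–Uhlenbeck velocity update
(c1 = e^{−γΔt}, noise variance T(1 − c1²), satisfying
fluctuation–dissipation), half-drift, half-kick. BAOAB was chosen over the
velocity-Verlet-plus-friction scheme common in MD packages for its superior
configurational sampling at finite Δt; at γ = 0 it reduces exactly to
velocity Verlet, which the NVE tests exploit (relative drift 2e-4 over 1e4
steps for the neutral G2S2 dendrimer). Thermostat fidelity is checked by
equipartition: the harmonic-dimer separation variance reproduces T/k within
5%, free-particle velocity variance reaches T within 2%, and production
kinetic temperatures average to 1.00 within 3 standard errors.

Defaults follow the production protocol: Δt\* = 0.005, γ\* = 1, T\* = 1,
L\* = 100, 1e6 equilibration + 1e7 production steps, frames every 1000
steps (`paper_scale`, G4S4 — cluster-sized, configurable but not exercised
by the tests). The `desk_scale` preset used by the test suite and the
acceptance script is a G2S2 molecule (26 monomers + 14 counterions) in an
L\* = 40 box — comparable number density to the reference system — with
2e4 equilibration + 1e5 production steps sampled every 100 (1000 frames,
≈ 15 s on one CPU). These problem sizes resolve every qualitative effect
(absorption/condensation monotonicity, the delocalization maximum,
core–shell segregation, swelling trends) with block-averaged errors of a
few percent; they do not reproduce figure-level statistics of a 1e7-step
G4S4 sweep.

Velocities are initialized from Maxwell–Boltzmann at T\* (the stationary
distribution; initialization is erased during equilibration). Initial
configurations grow the dendrimer as a non-reversal random walk along the
tree (bond length 0.97) followed by a displacement-capped steepest-descent
push-off on the bonded + WCA energy; counterions are inserted uniformly
with rejection. The returned configuration guarantees all bonds < R0 and
no pair closer than 0.85 σ_αβ, and is bit-reproducible per seed.

Candidate pair lists come from a linked-cell decomposition whose contract
is *superset of all pairs within the cutoff* (verified against an O(N²)
scan); for ≤400 particles the all-pairs list is used directly and built
once, since it is position-independent. Cell-list rebuilds happen at least
every 20 steps with a 0.5 σ skin, which bounds the staleness well below
the skin at Δt = 0.005 and thermal speeds.

## Observables

* **Rg\***: RMS monomer distance from the monomer centre of mass (unit
  masses), computed after unwrapping coordinates along the bond tree
  (minimum-image per bond, BFS from the core); an unwrap producing a bond
  longer than L/2 is an error, not a number.
* **Radial profiles**: distance histograms per frame, averaged over frames.
  Pair-correlation normalization divides shell counts by exact shell volume
  × box-average target density (per centre, for the charged-monomer
  profiles); number-density normalization divides by shell volume only and
  conserves the species count to better than 2% by construction. Default
  bin width 0.1 σ for g(r); profiles around the COM use the same width
  (0.25 σ where only peak positions matter). An empty target species yields
  an explicitly flagged empty profile, never NaNs.
* **Absorption**: counterion strictly inside 2 Rg\* of the dendrimer COM.
  Rg\* here is the production-run mean by default (`rg_source="mean"`),
  not the per-frame instantaneous value: the mean is stabler for the small
  desk-scale molecule and matches the rescaled-axis convention of the
  profile analysis; the instantaneous variant is a switch away.
* **Condensation**: counterion strictly within (2 + σ_α\*)/2 of at least
  one charged monomer, counted once however many contacts it makes. Both
  thresholds use strict `<`; the boundary has zero measure, the convention
  is fixed for reproducibility.
* **Fractions**: frame-averaged counts divided by N_bg. The derived
  quantities are formed from the averaged components — f_oin = f_in +
  f_bin, f_ocond = f_cond + f_bcond, f_d = f_in − f_cond, f_bd = f_bin −
  f_bcond, f_od = f_d + f_bd — so the identity chain holds to machine
  precision by construction. Standard errors are block averages over 10
  contiguous frame blocks; trajectories shorter than the block minimum are
  rejected rather than silently under-blocked.
* **Swelling** α = Rg\*/Rg0\*. The neutral baseline Rg0\* is the same
  topology with all valences zero and **no** counterion particles present
  (they exist only to neutralize ionized groups); a variant with neutral
  ions present would probe a different (crowded) reference state.

## Synthetic fixtures

The analysis stack is tested against configurations with planted ground
truth: ions placed at 0.9× the condensation threshold from distinct charged
monomers (condensed), in the (0.5 Rg, 1.5 Rg) shell but > 1.1× threshold
from every charged monomer (absorbed-only), or beyond 3 Rg (outside);
core–shell configurations with disjoint radial supports; i.i.d. uniform
gases (g(r) = 1); and a harmonic dimer whose separation variance per
Cartesian component is exactly T/k. Every planted fixture re-verifies its
declared counts with an independent brute-force distance scan at
construction time and is bit-reproducible per seed. The dendrimer
conformation used by static fixtures is a stored coordinate set produced
once by a short neutral relaxation and frozen into the package data
(`dendrion/data/*.xyz`), so analysis tests never depend on the simulator.

What the fixtures do *not* emulate: correlated frames, thermal broadening
of the condensation shell, and coupling between absorption and conformation
— passing fixture tests validates the estimators, not the physics; the
desk-scale runs cover the latter.

## Numerical choices and limitations

* All quantities are reduced internally; SI conversions (Bjerrum length
  7 Å, reduced charge 9, LJ time 2.4 ps at 30 g/mol) live only in
  `units.py` at the I/O boundary.
* Ion counts from f_b use banker's rounding; realized f_b is within
  1/(2 N_bg) of the request.
* Trajectory text formats print 12 significant digits; round trips
  reproduce coordinates to < 1e-8 in an L = 100 box. The LAMMPS dump
  dialect (`id type q x y z`) does not carry diameters; the reader
  reconstructs them from the type map and a `sigma_b` argument.
* The desk-scale molecule (G2S2) has only 14 counterions; fractions are
  multiples of 1/14 per frame, so per-condition standard errors below ~1%
  are not reachable at this size. Quantities defined as differences of
  near-equal numbers (f_d at strong coupling) are correspondingly noisy.
* Charge regulation (pH), explicit salt, solvent structure and
  hydrodynamics are outside the model; generations above 5 are untested
  territory for the initial-configuration grower.
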