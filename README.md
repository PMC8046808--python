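# dendrion

Langevin dynamics and counterion statistics for a charged bead-spring
dendrimer immersed in a binary mixture of small ("conventional") and large
("bulky") counterions.

## The problem

Dendritic polyelectrolytes such as PAMAM become highly charged at low pH:
every branching and terminal amine protonates, and the released counterions
control the molecule's conformation. When the counterions come in two sizes,
electrostatics (how strongly ions bind to the charged monomers) competes
with excluded volume (how much space an absorbed ion occupies). `dendrion`
simulates this system with coarse-grained Langevin dynamics and computes the
statistics that characterise it: which ions are *absorbed* into the
molecule's pervaded volume, which are *condensed* onto charged monomers,
which remain *delocalized* inside the cage, and how the molecule swells or
collapses in response.

## Model

A `G`-generation dendrimer with spacers of `S` bonds is a trifunctional
bead-spring tree of

    N = 2 + 4 S (2^G − 1)   monomers,   N_bg = 2^(G+2) − 2   charged groups

(core pair + branching + terminal groups carry valence +1; N_bg monovalent
anions, a mixture of diameters σc\* = 1 and σb\* ∈ {2, 3} at bulky number
fraction f_b, neutralize them). Interactions, in reduced LJ units:

* **Excluded volume** — truncated-and-shifted LJ 12-6 cut at 2^(1/6) σ_αβ
  (WCA, purely repulsive), σ_αβ = (σ_α + σ_β)/2;
* **Bonds** — FENE springs, U = −½ k R0² ln(1 − r²/R0²), k\* = 30,
  R0\* = 1.5 (the canonical Kremer–Grest set);
* **Electrostatics** — U/kBT = λB\* z_i z_j / r between all charged pairs,
  evaluated by classical Ewald summation in a periodic cubic box. The
  reduced Bjerrum length λB\* sets the coupling strength (λB\* = 1
  corresponds to water at room temperature with the monomer diameter equal
  to the Bjerrum length of water, ≈ 7 Å).

Dynamics: BAOAB Langevin integration at T\* = 1, γ\* = 1, Δt\* = 0.005,
unit masses, periodic boundary conditions.

Key observables: the gyration radius Rg\* and swelling factor
α = Rg\*/Rg0\* (Rg0\*: neutral analogue); radial profiles around the
dendrimer centre of mass (g_cm,c, g_cm,b, ρ_cm,m) and around the charged
monomers (g_chm,c, g_chm,b); and nine counterion fractions — absorbed
(f_in, f_bin, f_oin; criterion r < 2 Rg\* from the COM), condensed
(f_cond, f_bcond, f_ocond; criterion r < (2 + σ_α\*)/2 from at least one
charged monomer) and delocalized (f_d = f_in − f_cond, f_bd, f_od).

## Worked example

A desk-scale study — a G2S2 dendrimer (26 monomers, 14 counterions, half of
them bulky with σb\* = 2) in an L\* = 40 box at λB\* = 4:

```python
from dendrion import workflows

cfg = workflows.desk_config(f_b=0.5, sigma_b=2.0, lambda_B=4.0, seed=1)
traj = workflows.run_from_config(cfg)          # 2e4 equil + 1e5 production steps
profiles, report = workflows.analyze_trajectory(traj, cfg)

print(f"mean Rg* = {report.metadata['rg_mean']:.3f}")
for name in ("f_in", "f_bin", "f_oin", "f_cond", "f_bcond", "f_ocond",
             "f_d", "f_bd", "f_od"):
    print(f"{name:8s} = {getattr(report, name):.3f} +- {report.errors[name]:.3f}")
print(f"g_chm,c peak at r* = {profiles['g_chm_c'].argmax_radius():.2f}")
print(f"g_chm,b peak at r* = {profiles['g_chm_b'].argmax_radius():.2f}")
```

prints (about a minute on one CPU):

```
mean Rg* = 2.432
f_in     = 0.354 +- 0.013
f_bin    = 0.188 +- 0.011
f_oin    = 0.542 +- 0.013
f_cond   = 0.276 +- 0.010
f_bcond  = 0.116 +- 0.008
f_ocond  = 0.392 +- 0.011
f_d      = 0.078 +- 0.006
f_bd     = 0.072 +- 0.004
f_od     = 0.150 +- 0.006
g_chm,c peak at r* = 1.15
g_chm,b peak at r* = 1.65
```

Reading it: at this intermediate coupling roughly half the counterions are
absorbed (f_oin = 0.54), most of those are condensed, and the condensation
peaks sit near contact, (1 + σ_α\*)/2 = 1.0 and 1.5 for the two species.
The errors are block-averaged standard errors (10 blocks).

The same pipeline is available from the shell:

```bash
dendrion build -G 4 -S 4 --fb 0.48 -L 100 --seed 1 --out init.xyz
dendrion run --config run.yaml --out traj.xyz
dendrion analyze --traj traj.xyz --out results/
dendrion reproduce --seed 1 --out sweep/     # λB* × f_b desk-scale grid
```

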