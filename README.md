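# dynloop — the Dynamic Loop chromatin model

Interphase chromosomes fold into confined, weakly overlapping
territories, show a leveling-off of the mean squared distance between
genomic markers beyond ~10 Mb, strongly enhanced long-range contact
probabilities, and large cell-to-cell variation — none of which plain
random-walk, self-avoiding-walk or equilibrium-globule polymer models
reproduce together.  `dynloop` implements a minimal mechanism that
does: **diffusion-driven dynamic looping**.  Whenever two beads of a
chain diffuse within a co-localization radius (distance < 3 lattice
units), a loop forms with probability P; the loop holds the pair
co-located for a Poisson-distributed lifetime and then dissolves.  No
long-range forces, no imposed confinement — transient, probabilistic
chromatin–chromatin bridging alone drives chain collapse, enhanced
contact formation and territory segregation.

The package is aimed at polymer-physics and genome-organization
researchers who want to simulate the model, reproduce its scaling
claims at desk scale, or analyze their own bead trajectories with the
same observable suite.

## What is inside

* **Engine** — a fast (numba-compiled) 3D bond-fluctuation-model Monte
  Carlo kernel: beads on a periodic lattice occupying 2×2×2 cubes, the
  canonical 108-vector bond set (lengths 2, √5, √6, 3, √10), local
  single-site moves, athermal acceptance, unfolded-coordinate tracking,
  and the dynamic-loop mechanism (formation probe after every trial
  move, Poisson lifetimes, hard co-localization constraints).
* **Equilibration** — integrated autocorrelation time of Rg² via
  Sokal's windowing procedure, the center-of-mass decorrelation
  criterion g3(t) ≥ ⟨Rg²⟩, and sampling plans built from both.
* **Observables** — internal distances R²(s); loop and random-contact
  size distributions f(l), h(l); specific contact probability Pc(s);
  power-law fits; distance-distribution moment ratios ⟨r⁴⟩/⟨r²⟩²,
  ⟨r⁶⟩/⟨r²⟩³; gyration-ellipsoid shape; g1/g3 dynamics; physical-unit
  calibration (400 kb and 480 nm per bead).
* **Melt** — dense multi-chain systems with minimum-image contact
  classification, inter-/intra-chain contact fractions, overlap
  fractions, multi-chain contact maps, per-chain shape.
* **CLI** — `dynloop simulate | melt | analyze | calibrate-loops |
  fixtures | validate-state`.

## A worked example

Collapse of an isolated 64-bead chain as loops are switched on:

```python
from dynloop import SystemConfig, LoopParams, Simulation
from dynloop import observables as obs
from dynloop.simulate import contact_decorrelation_time

cfg = SystemConfig(N=64, L=128, seed=1)
lp = LoopParams(P=1e-3, mean_lifetime=2000.0)

sim = Simulation(cfg, lp)
sim.equilibrate_saw()                      # stage 1: plain SAW
sim.state.run_mcs(300_000, lp)             # stage 2: looping on
dt = contact_decorrelation_time(sim)       # decorrelation spacing
ens = sim.sample(100, interval=int(dt), burn_in_mcs=0)

prof = obs.internal_msd(ens.positions, ens.chain_id)
h = obs.contact_size_distribution(ens.positions, ens.chain_id)
fit = obs.fit_power_law(h.sizes, h.h_density, (3.2, 32))
print(f"mean loops/chain  : {ens.mean_loop_count():.1f}")
print(f"plateau ratio     : {prof.plateau_ratio():.2f}")
print(f"h(l) decay exponent: {fit.exponent:.2f} +- {fit.stderr:.2f}")
```

Output (seed 1):

```
mean loops/chain  : 90.7
plateau ratio     : 1.47
h(l) decay exponent: 0.50 +- 0.04
```

Read: at ~91 simultaneous loops (≈ 1.4 per bead) the chain is deep in
the looping regime — the internal-distance profile is leveling off
(the plateau ratio R²(N/2)/R²(N/4) has dropped to 1.5, against 4 for a
rigid rod and ≈ 2.3 for a SAW), and the random-contact abundance h(l)
decays with an exponent of 0.5 instead of the SAW's ≈ 2.3–2.6, i.e.
contacts spanning the whole chain are enriched by orders of magnitude.
The same pipeline from the shell:

```bash
dynloop simulate --config run.yml --seed 1 --out run/
dynloop analyze run/trajectory.h5 --out run/analysis/
```

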