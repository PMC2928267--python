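# Methods

## The model

`dynloop` implements a coarse-grained chromatin chain as a lattice
polymer evolved with the bond-fluctuation model (BFM): each bead
occupies a 2×2×2 cube of lattice sites, bonds are restricted to the
canonical 108-vector set (squared lengths 4, 5, 6, 9, 10, i.e. the
sign/permutation orbits of (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0)
and (3,1,0)), and trial moves displace a uniformly chosen bead by one
lattice unit in a uniformly chosen axis direction.  A move is accepted
iff the four newly covered sites are empty, every incident bond stays
in the allowed set, and every loop constraint incident to the bead
remains satisfied.  The dynamics is athermal: there is no energy
function, every legal move is accepted, so the stationary distribution
is uniform over legal conformations subject to the active constraints.
One Monte Carlo step (MCS) is one attempted move per bead on average.

Dynamic loops are the model's defining ingredient.  After every trial
move one bead is chosen uniformly at random; if another bead of the
same chain lies within the co-localization radius (Euclidean distance
strictly below 3 lattice units, i.e. integer squared distance ≤ 8) and
at contour separation ≥ 3, a loop forms with probability P between the
probe and one uniformly chosen eligible partner.  Each loop receives a
lifetime drawn from a Poisson distribution with mean τ (in MCS) and is
removed at the first MCS sweep at which its expiry is due.  While
active, a loop is a hard constraint: any move that would put the pair
beyond the co-localization radius is rejected.  Duplicate loops on the
same pair are forbidden; a bead may simultaneously loop to several
partners (hub-like contacts).  Loop lifetimes are quoted as multipliers
(0.1, 1, 10) of the relaxation time of the loop-free chain, defined as
the integrated autocorrelation time of Rg² of the corresponding
self-avoiding-walk (SAW) system.

Two deliberate precisions of the mechanism:

* **Loop distances are unfolded distances.**  The box is periodic and
  the engine tracks unfolded coordinates so the polymer feels no
  confinement.  Co-localization (for loop formation and for the
  constraint) is evaluated on unfolded same-chain distances; the
  folded lattice scan merely nominates candidates.  Without this, two
  segments adjacent only through a periodic image could be glued
  together, which tears the chain apart in unfolded coordinates.
  Analysis contact counts for dense systems, in contrast, deliberately
  use the minimum-image convention: there the periodic images are the
  physical neighbours.
* **The Bernoulli(P) draw precedes the neighbourhood scan.**  Whether a
  loop forms is independent of which partners are available, so the
  engine draws the P-coin first and scans only on success.  The
  per-probe formation law is identical to scan-first; nearly all probes
  become O(1).

## Run protocol

1. Chains start on a regular serpentine of (±2,0,0)/(0,2,0)/(0,0,2)
   bonds (legal but atypical) and are first equilibrated with looping
   off, for ~10 chain relaxation times (default 25·N^2.2 MCS;
   τ_int(Rg²) is empirically ≈ 2·N^2.2 for dilute chains).  This stage
   is not negotiable: switching looping on before the initial
   conformation has fully relaxed glues its artificial folds in place
   and silently corrupts every downstream observable (partially
   relaxed serpentines with loops reached Rg² values twice the SAW
   value in our tests).
2. Looping is switched on and the system re-equilibrated.  Loop
   occupancy relaxes on the lifetime scale, but the *collapse* into
   the leveled-off state above the onset density coarsens much more
   slowly; production runs use 3×10⁵ MCS below the onset and 6×10⁵
   above it (N = 64).
3. A pilot segment measures the integrated autocorrelation time of Rg²
   with Sokal's windowing procedure (window constant c = 6; the window
   must satisfy M ≥ c·τ_int(M) and lie within a tenth of the series,
   otherwise the pilot is extended), and the center-of-mass
   decorrelation time t_cm — the first lag at which the mean-square COM
   displacement reaches ⟨Rg²⟩.
4. Conformations are retained every max(2·τ_int, t_cm) MCS after a
   burn-in of 10·τ_int.

### Replica sampling for collapsed ensembles

At high loop density the chain collapses into a constraint-bonded
cluster whose center of mass is dynamically arrested: t_cm can exceed
the contact-pattern decorrelation time by an order of magnitude (we
measured Jaccard decorrelation of the contact sets at ~4×10⁴ MCS
against t_cm ≈ 3×10⁵ on the same ensemble), and near the collapse
transition single trajectories are intermittent, hanging in one
dynamical branch for long stretches.  Production ensembles are
therefore built from *independent replicas*: one fully equilibrated
"mother" SAW run supplies starting conformations spaced by several
relaxation times, each replica re-equilibrates with looping on and
contributes a fixed number of snapshots spaced by ten loop lifetimes
(at least 2×10⁴ MCS).  Replicas are strictly independent, so the
merged ensemble covers the distribution over branches; within-replica
residual correlation only inflates error bars.  The COM-based single-
trajectory plan remains the package default (`Simulation.pilot` /
`plan_sampling`) and is what dilute runs use.

### Realized-count calibration

The looping probability P that produces a target mean loop count
cannot be read off short pilots: near the collapse transition the
count keeps rising for several 10⁵ MCS as the chain compacts (each
compaction step raises the co-localization rate).  `tune_probability`
therefore evaluates candidate P values on fully equilibrated replica
ensembles and updates log P by secant steps (the local log-log slope
of count vs P is ~2 below saturation and can flatten to ~0.2 near it).
The realized count of the production ensemble is always reported.

### The two dynamical branches

At fixed mean loop count the model has two qualitatively different
regimes.  When P is small and lifetimes are comparable to the chain
relaxation time, formation is selection-limited: loops form among the
standing co-localized pairs, long loops nucleate compaction, and the
chain collapses (the leveled-off regime the reference observables
describe).  When P is large and lifetimes short, every fresh encounter
is looped instantly: the population is dominated by ephemeral short-
range loops, the chain stays coil-like, and the count–P relation
becomes non-monotone.  Production calibrations therefore cap P at
0.05 and use lifetimes of 0.1× the SAW relaxation time measured from a
long (≥10⁶ MCS) pilot, which keeps all study conditions on the
collapsed branch.

## Desk-scale study conditions

The reference quantities are quoted for chains of 128–256 beads and a
4096-monomer dense system, sampled at cluster scale (10⁴–10⁵
independent conformations).  This package's default study conditions
reproduce them at desk scale:

* **Chain length N = 64** (lattice 128³ for dilute chains).  Looping
  levels are matched between chain lengths through the *loops per
  monomer*, the scale-free control parameter: e.g. the "19 loops at 256
  beads" condition becomes 4.75 loops at 64 beads.  The collapse onset
  supports this mapping (≈ 80/256 ≈ 0.31 loops per monomer isolated,
  ≈ 45/128 ≈ 0.35 in the melt).
* **Loop lifetime 0.1 × the SAW relaxation time.**  Equilibrium
  statistics depend on (P, τ) only through the mean loop count (tested
  explicitly at matched counts), and the shortest standard multiplier
  decorrelates the loop configuration fastest.
* **Ensembles of 100–300 decorrelated conformations** rather than 10⁴⁺;
  quoted uncertainties are correspondingly larger, and the scaling
  exponents carry a systematic desk-scale offset of up to ~10%
  relative to the 256-bead reference values (measured: h(l) exponent
  ≈1.89 at N=64 for the 19-loop-equivalent condition, where the
  256-bead reference is 2.01).
* **The collapse onset shifts at desk scale.**  Matching loop levels
  per monomer reproduces exponents to ~10–20%, but the onset of the
  internal-distance plateau moves from ≈0.31 loops per monomer at
  N=256 to ≈0.6–0.75 at N=64: small chains need proportionally more
  loops to level off, and shape ratios that depend on the depth of
  collapse shift accordingly (by a few percent beyond the 20% bands at
  the faithful levels).  The corresponding checks are kept at their
  reference tolerances and fail informatively rather than being
  widened; the trend-level checks are separate and pass.
* **Dense system: 8 chains × 64 beads in a 32³ box** — site density
  8·512/32³ = 0.125, the same as 4096 monomers in 64³.  Territory
  statistics pool ~10 decorrelated conformations per loop level.

A coarse bisection on warm short pilots
(`calibrate_loop_probability`) provides the starting P; the realized
count of fully equilibrated replicas then drives the secant tuning
described above.

## Observables

* **R²(s)** — mean squared distance between beads s apart, averaged
  over conformations, chains and reference positions (unfolded
  coordinates).  The collapse diagnostic is the plateau ratio
  R²(N/2)/R²(N/4), ≈ 1 on a leveled-off profile.
* **h(l)** — relative abundance of random contacts (any same-chain pair
  within the co-localization radius, contour separation ≥ 3) of size l,
  *per available fragment*: each contact is weighted by 1/(N−l) so the
  decay exponent is not distorted by the vanishing number of long
  fragments near the chain ends.  Histogrammed in unit bins up to
  l = 16 and logarithmic bins beyond; fitted as a power law l^(−α) over
  l ∈ [0.05 N, 0.5 N].
* **f(l)** — normalized size distribution of the active (functional)
  loops, per exact size.
* **Pc(s)** — probability that a specific pair at separation s is in
  contact; fitted over the short-separation window s ∈ [4, 0.15 N]
  (exponent λ1) and the long window [0.15 N, 0.9 N] (λ2).  The counting
  identity Σ_s (N−s)·Pc(s) = mean contacts per conformation holds
  exactly and is asserted in the tests.
* **Moment ratios** ⟨r⁴⟩/⟨r²⟩² and ⟨r⁶⟩/⟨r²⟩³ — dimensionless
  cell-to-cell-variation proxies (Gaussian coil: 5/3 and 105/27).
* **Gyration shape** — eigenvalues of the gyration tensor averaged over
  the ensemble before forming ratios; eigenvalue ratios are exactly the
  squared axis ratios.
* **g1/g3** — MSD of the central bead(s) and of the chain COM on
  logarithmically spaced lags with time-origin averaging; log-log
  slopes are fitted per time regime relative to the relaxation time.
* **Territories** — contacts classified by chain identity
  (minimum-image), inter-chain fraction in percent, and per-chain
  overlap fraction (beads with ≥ 1 inter-chain contact).  Contour-near
  intra-chain pairs (< 3) are excluded from all contact counts.
* **Physical calibration** — a pure relabeling: s × 400 kb per bead;
  squared distances scaled so one bead extent maps to 480 nm.

## Numerical choices and edge cases

* Box edges must be powers of two (≥ 8): folding and minimum-image
  arithmetic reduce to bit masks in the compiled kernel.  Up to 32 000
  beads (per-site bead ids are int16).
* "Distance < 3" is implemented exactly as integer squared distance
  ≤ 8; the boundary case |v| = 3 is excluded (strict inequality).
* A bead may hold at most 24 simultaneous loops; formation probes that
  would exceed this are counted and dropped (never observed below
  ~2 loops per monomer).
* Poisson lifetimes use the compiled generator of the kernel's RNG;
  a single seed determines the full trajectory, and chunked runs derive
  per-chunk streams from (seed, call counter), so trajectories are
  bit-reproducible regardless of how the run is partitioned.
* Power-law fits are ordinary least squares on log–log axes and refuse
  ranges with < 2 positive points; decay exponents are reported
  positive.
* The trimer shape-class test enumerates the reachable (b1, b2) graph
  by breadth-first search under the reference move rules and checks
  sampled uniformity by χ² — the BFM move set is not ergodic over *all*
  legal trimer shapes, only over the reachable component, and the test
  respects that.

## What the tests do and do not show

The synthetic fixtures (rigid rods, ballistic trajectories,
hand-written loop logs, AR(1) series) have closed-form observables and
validate the analysis machinery exactly.  The simulation-level checks
validate the model's emergent claims — SAW scaling against an
independent pivot-algorithm sampler, the collapse onset, the contact
exponents, territory formation, prolate chain shapes — at desk scale.
They do not probe chain lengths beyond 64 beads in anger, locus-
dependent (heterogeneous) looping probabilities, or the approach to the
thermodynamic limit; and the absolute territory fractions of the
full-size dense system (4096 monomers) are only reproduced as trends at
the reduced size, not as absolute percentages.

## Known limitations

* At loop densities well above ~1 per monomer the constraint network
  rigidifies and the dynamics arrest; ensemble averages there would
  require many independent replicas rather than one long run.
* The count–P calibration curve is steep near the collapse transition;
  calibrated counts are accurate to ~5%, not exact.
* τ_int estimates from windowed autocorrelation carry O(20–30%)
  estimator noise even on pilots of 60·τ_int; sampling intervals
  inherit that noise (always on the conservative side of the two
  criteria).
* Loops are intra-chain only, with one global P; lifetimes are
  Poisson; the co-localization radius is fixed at the formation radius.
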