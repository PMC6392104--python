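# Methods

## Model overview

`cd8sim` simulates a CD8 T-cell immune response in a lymph-node cross
section as three coupled layers advanced once per Monte-Carlo step (MCS):

1. **Cellular Potts lattice** (`potts`): cells are 4-connected node sets
   on a periodic L×L grid; index 0 is extracellular medium.  One MCS
   performs N = 3S random copy attempts (S = L² nodes).  An attempt picks
   a random source node and a random first-order neighbour, computes the
   energy change of copying the source index onto the target locally
   (contact, area and perimeter terms), adds the motility bias, and
   accepts per Metropolis: energy-decreasing copies always, increasing
   ones with probability exp(−increase/T).  Three times S attempts per
   MCS (rather than the conventional S) keeps cell speeds compatible with
   the one-minute-per-MCS time mapping.
2. **Per-cell molecular network** (`molecular`): six ODEs per T-cell
   (receptors R, activated receptors LR, Tbet, activated Fas, Caspases,
   Eomes), integrated with fixed-step RK4 over the MCS interval and
   subdivided ×10 automatically when any variable moves more than 20% in
   one step.  Negative excursions are clipped at zero and counted.
3. **IL2 reaction–diffusion field** (`il2`): forward-time centred-space
   update with a 4-neighbour Laplacian, subcycled to keep D·dt_sub
   strictly inside the 1/4 stability bound (we use ≤ 1/5 so the decay
   term cannot make the centre coefficient negative).  Secretion is a
   per-cell rate divided equally over the cell's nodes; cells read the
   field back as the sum over their boundary nodes.

The per-MCS update order is: Potts step → contact map → contact-driven
differentiation → molecular step (consuming this-MCS contacts) → field
step → threshold-driven activation → cycle/divisions → apoptosis.  The
order is fixed for reproducibility; molecular dynamics see the contacts
of the same MCS.

## Differentiation scheme and cell rules

naive → pre-activated (APC contact) → activated ([L·R] ≥ IL2R_th,
detaches from the APC and starts cycling) → effector (a daughter with
[Tb] ≥ Tbet_th at division) → memory (a *dividing* activated/effector
cell with [E] > Eomes_th converts instead of dividing and stops
proliferating).  Transitions are irreversible and guarded at runtime; the
single re-entry edge is memory → pre-activated on APC contact, used by
the recall response (molecular state is kept, activation history stays
set).  Daughters of an effector mother remain effectors (the scheme has
no backward edge); daughters of an activated mother are typed by their
Tbet.  Apoptosis removes any non-naive T-cell whose Caspases reach
Caspases_th; APCs live Uniform[48, 96] hours and do nothing but activate.

Cycle lengths at division k are Uniform[c_k − 4, c_k + 4] hours with
c_k = 6 + 28k²/(k²+100); after a division both daughters re-enter the
cycle immediately at k+1.  Division in space bisects the cell's node set
perpendicular to its principal axis into two connected, near-equal
halves (fallback: axis-aligned cut); both daughters keep the full target
geometry and regrow through the area constraint.

**Partitioning.** Each of the six concentrations is split independently:
one daughter receives k_i·[i], the other (2−k_i)·[i], with
k_i ~ Uniform[1−m/100, 1] and a fair coin deciding the receiver, so
molecule numbers are conserved exactly given half-volume daughters.  The
default degree of unevenness is m = 10 (most uneven split 45%/55%).  The
first division after activation partitions Tbet asymmetrically instead:
the proximal daughter receives (2−K)[Tb], the distal K[Tb],
K ~ Uniform[0.5, 1], so the proximal daughter never gets less Tbet.  The
asymmetric law is untouched by the m sweep.

## Default parameter set

All rates are per hour; concentrations in mol/L (lumped gene-activity /
protein units); one lattice node is 4 μm, so a 9-node T-cell is 144 μm²
with a 48 μm target perimeter (boundary edges × 4 μm — the measure under
which a 3×3 square exactly meets its target).  APCs are 140 nodes with no
perimeter constraint.

The molecular defaults are this package's own calibrated set, constructed
to satisfy four constraints simultaneously:

1. the antigen-free Tbet equation is bistable with fixed points
   ≈ 21 (unstable) and ≈ 118 (stable) mol/L — with n = 1.5 these pin
   λ_T2/k_T and λ_T3 through the two-root condition (λ_T2 = 56.634,
   λ_T3 = 83.766, k_T = 0.3);
2. the resting memory profile is ([Tb], [E], [Cas]) = (0, ≈26, ≈9):
   [E]* = λ_E4/k_E = 26 and [Cas]* = λ_c1/(k_c(1+λ_E2·26)) = 9 fix those
   ratios exactly;
3. thresholds Eomes_th = 16 and Caspases_th = 19 mol/L sit between the
   effector and memory asymptotes of their variables;
4. the population dynamics show the canonical arc (below).

The Hill exponent n = 1.5 was chosen over steeper feedback because it
widens the weakly-driven band around the unstable point: lineages with
Tbet between roughly 15 and 40 mol/L drift slowly, so the ±m/2% division
noise genuinely moves cells between basins — the "undetermined
compartment" whose gradual resolution produces simultaneous effector
death and memory emergence.  With steep feedback the asymmetric first
division alone decides every lineage and the two sub-populations decouple
into an all-or-nothing outcome.

Two slow antagonistic clocks shape the population arc.  The *Eomes
clock* ([E] rising toward 26 once Tbet is off, τ = 1/k_E ≈ 11 h)
converts low-Tbet lineages to memory roughly a day after their Tbet
collapses.  The *Caspase clock* ([Cas] rising toward
λ_c1/k_c = 22 mol/L in unprotected cells, τ ≈ 56 h) kills high-Tbet
lineages — whose Eomes stays suppressed via λ_E7 — two to four days
after commitment; Eomes protection (λ_E2) pulls the asymptote below the
19 mol/L threshold as soon as [E] exceeds ≈ 3, which rescues the memory
arm early.  Fas engagement by contacting effectors (Tb^cm) accelerates
death in effector clusters.  IL2 is kept short-ranged (D = 60 node²/h
≈ 960 μm²/h, δ = 2/h) with strong TCR-driven secretion during priming,
so activation timing is APC-local and the memory pool cannot sustain a
global IL2 bath after contraction.

The contact-energy table makes pre-activated cells adhere to APCs (their
lowest-energy contact, J = 2) and activated cells detach (J = 30); naive
and memory cells are given high motility weight (v = 40) because in a
lymph node chemokine gradients guide them to APCs, which the model's
unbiased random walk must emulate within the APC lifetime.

The Fas equation's saturation term is implemented as the bounded form
λ_F/k_F (an activated-Fas ceiling of 10 mol/L); a config switch
(`fas_product_form`) selects the multiplicative alternative λ_F·k_F.

## Presets, time mapping and problem sizes

* `full_scale_preset`: 150×150 lattice, 30 naive + 3 APCs, 30,000 MCS at
  1 min/MCS (20 d 20 h starting day 4 post-infection).  One run takes
  minutes to tens of minutes.
* `scaled_preset`: 60×60 lattice, 10 naive + 1 APC, 4,000 MCS at
  7.5 min/MCS.  The coarser time step keeps the full ~20.8-day arc —
  expansion, day ~8 peak, contraction, memory — inside a run of about
  ten seconds, which is what the test suite and the acceptance script
  exercise.  RK4 remains well inside stability at dt = 0.125 h, and the
  cycle-length floor of 2 h still spans 16 MCS.  The cost of the coarser
  step is fewer Potts sweeps per simulated hour (cells mix less) and a
  harder APC-finding problem (the APC lifetime spans fewer MCS), which
  is why a few naive cells per scaled run never engage the APC.

## Randomness and reproducibility

One root seed spawns six named generator streams (Potts kinetics,
placement, cycle lengths, partitioning, APC lifetimes, motility angles),
so experiments differing in one mechanism remain comparable.  The Potts
kernel is JIT-compiled and consumes its generator inside the compiled
loop; identical seeds give bit-identical lattices, event logs and
snapshot streams.

## What the synthetic reference emulates

`calibration.make_reference_fixture` generates smooth per-subject series
with the canonical qualitative shape (naive cells negligible after day 6,
> 94% activated/effector at the day-8 peak, memory majority by day 22,
receptor peak day 5, Tbet plateau then decline, monotone Eomes rise).  It
stands in for in-vivo cell-fraction and mRNA time courses so the distance
metrics and the calibration search are fully testable offline; it does
not emulate biological replicate structure beyond small multiplicative
jitter, cohort-level batch effects, or measurement noise models.  The
distance D = D_cell + D_prot averages summed absolute differences over
(run, subject) pairs; protein series are normalised by their own maximum
over sampled time steps (a plotting-style normalisation by the day-8
value is also available).

## Numerical choices

* RK4 stage values are clipped at zero before evaluating the right-hand
  side (the equations are defined on the non-negative orthant); clipped
  steps are counted and surfaced on the run output.
* The memory steady state is found by integrating to tolerance 1e-9 and
  snapping components below 1e-6 to exactly zero — Tbet genuinely reaches
  the zero fixed point, the snap only removes the exponential tail.
* Fixed points of the Tbet equation are located by a sign-change scan
  (linear plus log-spaced grid, so near-zero roots at shallow Hill
  exponents are not stepped over) refined by Brent's method.
* The Potts acceptance rule follows the standard Metropolis convention
  (accept energy decreases outright, else exp(−increase/T)).
* Perimeters are maintained incrementally as boundary-edge counts; a full
  recomputation path exists and the two are cross-checked in tests.
* Cell fragmentation is not forbidden; the perimeter constraint
  discourages it and `Tissue.fragmented_cells` monitors it.

## Known limitations

* The lattice is 2D and ignores chemotaxis along IL2 gradients.
* The scaled preset's founder count is small, so whether a run's memory
  arm is seeded at all is a lottery over a handful of asymmetric first
  divisions; population-level claims should average a few seeds.  The
  full-scale preset has ~5× the founders and is correspondingly stabler.
* In recall simulations the re-activated cells' Eomes must decay below
  the memory threshold before their first division completes; until then
  they cycle through re-conversion, which delays the secondary expansion
  by a few hours.  As a result the secondary response overtakes the
  primary from around the peak onward (and ends with a several-fold
  larger memory pool), but does not dominate it at every early time
  point.
* Memory conversion replaces the division of the converting cell (the
  mother converts instead of dividing); the alternative — divide, then
  both daughters convert — is available behind `memory_divides`.
* Naive-pool heterogeneity, stochastic gene expression, inflammatory
  cytokines (e.g. IL12) and TCR-affinity–dependent polarisation strength
  are out of scope.
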