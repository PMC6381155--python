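# Methods

## Dart-counting π estimation (`sawpi.dartpi`)

One trial samples N_D i.i.d. uniform points in [0,1)² and counts those with
x² + y² ≤ 1; the estimator is π_est = 4·N_D-in/N_D, an unbiased binomial
proportion scaled by 4 with variance 16·p(1−p)/N_D, p = π/4. The boundary
x² + y² = 1 counts as inside — a measure-zero convention fixed so that runs
are bit-reproducible. `mean_over_trials` averages n_T independent trials and
reports the sample standard deviation (0.0 for a single trial, where sample
spread is undefined). `optimal_inside` answers a different question: the
best *achievable* estimate at a given N_D, i.e. the integer count k
minimizing |4k/N_D − π_ref|; exact ties break toward larger k (they occur
only for rational references, e.g. N_D = 100 with π_ref = 3.14). π_ref is an
explicit parameter defaulting to full double-precision π; 3.14 reproduces
printed two-decimal conventions. `delta_per_unit_dots` is the forward
difference quotient Δπ_est/ΔN_D, a fluctuation diagnostic that shrinks with
N_D.

Randomness: all entry points consume an integer seed through
`numpy.random.SeedSequence` (PCG64 generators); sweep cells draw from
spawned child sequences, so every cell is an independent stream and the
whole grid replays exactly from one seed.

## Point-pattern quadrant counting (`sawpi.pointpi`)

A `PointPattern` holds dimensionless centroid coordinates in a square field;
a `QuadrantSpec` is a quarter circle of radius equal to the field width at
one of the four corners. The estimator counts points within the radius
(boundary inclusive, matching the dart convention) and applies the same
4·inside/total formula — by construction identical to
`dartpi.pi_from_counts` on the pattern's counts. An empty pattern raises:
π_exp is mathematically undefined with zero points; the CLI renders such
fields as 0.00 with a warning, keeping display convention out of the
arithmetic.

The synthetic generator produces uniform i.i.d. points, emulating the
large-scale statistics of imaged nanostructure centroid fields. It does not
model what real fields add: finite motif size (exclusion areas), local
clustering or lattice order, imaging-edge artefacts, or the mapping from DNA
concentration to areal density — concentration enters only through the point
count/density parameter. Tests passing on uniform patterns therefore
validate the estimator and its symmetries, not the spatial statistics of any
particular experimental system.

## The two-front growth model (`sawpi.hexgrowth`)

Geometry: vertices (u, v, s) with s ∈ {A, B}; neighbours of (u,v,A) are
(u,v,B), (u−1,v,B), (u,v−1,B) and symmetrically for B. The graph is
3-regular, bipartite, girth 6. The Cartesian embedding places A at
(1.5(u+v), √3/2·(v−u)) with B one unit east, so arms point 120° apart; this
particular chart was chosen for pure integer arithmetic, and any 3-regular
bipartite girth-6 embedding would serve.

Seed convention: seed at (0,0,A), blunt arm east toward (0,0,B); the left
front targets (−1,0,B) (120°), the right front (0,−1,B) (240°).

Step semantics: one step offers 2 orientations per front — orientation 1
puts the incoming motif's sticky arm on the clockwise remaining arm, 2 on
the counter-clockwise — giving the 4^N_S sample space. Blocked fronts
consume their orientation as a no-op, so every element of {1..4}^N_S is a
complete trial and descendants of blocked configurations stay in the count;
this is what keeps Ω_O + Ω_B = 4^N_S exact.

Blocking rules:

1. *Self-avoidance*: a front whose target site is occupied at placement time
   blocks permanently (no motif is placed).
2. *Sticky closure*: if a newly placed motif's sticky arm faces the opposite
   front's anchor while that front's sticky arm faces the new motif, the two
   sticky ends hybridize and both fronts block. This is the only way both
   fronts die in one step and produces the two full-blocked hexagon closures
   at N_S = 3.
3. A sticky arm that faces a blunt or bound arm of an occupied motif does
   **not** block immediately; the dead end is registered at the next step
   through rule 1. This timing matters: counting such arms as blocked at the
   step they are chosen changes the N_S = 3 census from 60/4 to 56/8 and
   moves the D crossover from 9.12 to 8.16 — both ruled out by the exact
   censuses this model reproduces.

Within a step the right front resolves before the left, so when both fronts
target the same site the right front places its motif and the left front
blocks. The choice is observable only at simultaneous collisions and is what
makes half-blocking left-heavy (16 left vs 8 right at N_S = 4).

`mirror` reflects a state across the seed's blunt-arm axis ((u,v,s) →
(v,u,s)), swapping the fronts' roles and the orientation parities; it is an
involution and exchanges the half-left/half-right classes exactly, which the
suite uses as a symmetry oracle.

Known discrepancy: hand-tallied pedigree charts of this model have reported
the N_S = 4 blocked split as 20 full / 10 left / 2 right. That split is
geometrically unreachable here: every newly blocked configuration at step 4
is a single-front dead end (a sticky arm meeting a blunt arm across the
central hexagon; 8 per side by mirror symmetry), because a new mutual
closure at step 4 would need an 8-cycle and the honeycomb graph has none.
The exact split under these rules is 8 full / 16 left / 8 right, while the
totals (224 open / 32 blocked), the N_S = 3 census (60/4, split 2 half +
2 full), and the crossover at 9.12 all agree with the published values.

## Configuration counting (`sawpi.sawcount`)

`enumerate_exact` is semantically the exhaustive sweep of {1..4}^N_S but
merges states that evolve identically (occupancy set + both fronts) and
carries multiplicities: a half-blocked state's four children collapse to two
with doubled weight, and full-blocked states freeze into a mass that
multiplies by 4 each step. A brute-force sweep through `apply_step` is kept
as the test oracle at N_S = 4. The guard rail is N_S ≤ 12 (4¹² ≈ 1.7·10⁷
sequences); beyond it, use the Monte-Carlo path. The test suite and the
acceptance script use exact counts to N_S = 10 and Monte-Carlo above — at
N_S = 10 the merged enumeration holds roughly 9·10⁵ states and runs in tens
of seconds, a size chosen to keep the default suite quick while bracketing
the crossover exactly.

`simulate_omega` draws uniform choice sequences with a seeded PCG64 stream
and replays them through a numba-compiled kernel that mirrors the
pure-Python transition rule for rule (the suite asserts they agree
sequence by sequence); the per-trial record is the step at which each front blocked, so
one batch at max_step yields consistent estimates at every intermediate step
and the estimated blocked fraction is monotone by construction.

Numerical conventions: D = ln Ω_O − ln Ω_B in natural log; a zero count
makes D undefined and raises (CSV writers emit an empty cell, never ±inf).
`crossover_step` linearly interpolates D between integer steps and returns a
node exactly when D is zero there. With 10⁵ trials the binomial noise on the
blocked fraction near the crossover (p ≈ 0.5) propagates to roughly ±0.03 of
a step in the interpolated crossing. The closed form Ω_A uses the honeycomb
connective constant √(2+√2) with prefactor 0.415 and exponent 11/32 taken as
given, not re-derived.

`summarize_observations` bins observed lattices by motif count (≤10, 11–20,
21–30, ≥31) and by class, pooling half-left and half-right into one
half-blocked bar (the left/right split stays available in `OmegaTable`).

## Command-line interface

`sawpi` mounts the `pi` and `saw` groups (also installed as standalone
scripts). Results go to stdout or `--out`; diagnostics to stderr; every
stochastic command takes `--seed` and is reproducible under it; an optional
YAML `--config` supplies per-command defaults mirroring the flags. CSV
output writes counts exactly and reals at 12 significant digits.

## Limitations

* No physical DNA modelling: sequences, hybridization thermodynamics and
  kinetics, and motif geometry are outside scope; motifs are lattice sites.
* Single-seed growth on the ideal honeycomb only; no multi-seed interaction,
  no other lattices.
* The Monte-Carlo Ω estimator inflates a binomial fraction, so its relative
  error on Ω_O grows as the open fraction vanishes at large N_S (at
  N_S = 50, ~10⁻³ of 10⁶ trials remain open, giving a few-percent ln-scale
  error on Ω_O itself).
* The analytic form Ω_A is an asymptotic counting formula; agreement is
  checked in relative ln terms, not on raw counts.
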