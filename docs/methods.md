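# Methods

## Model

The population is a connected, undirected, unweighted simple graph; every
node carries exactly one individual, either wild-type (fitness 1) or mutant
(fitness r > 0). One elementary event per discrete time step:

1. a node is chosen for **birth** with probability proportional to its
   fitness (global competition: the total weight is r·m + (n − m) for m
   mutants among n nodes);
2. the offspring **replaces a uniformly random neighbour** of the parent.
   The parent itself is never replaced, so on the complete graph the model
   is exactly the classical well-mixed Moran process with its 1/(N − 1)
   replacement factor.

Replacement of one's own kind leaves the state unchanged but still counts
as a step; all reported times are in these elementary events, not
generations. Mutation is absent, so the all-wild-type and all-mutant
configurations are absorbing.

## Exact machinery

A configuration is the bit-set of mutant-occupied nodes. The pipeline is

*enumerate → lump by symmetry → prune unreachable → canonical blocks →
linear solve*:

- **Symmetry lumping.** The automorphism group (brute force over node
  permutations, bounded at n ≤ 6) acts on configurations; orbits are
  dynamically equivalent states. Lumpability is not assumed: when the
  transition row of an orbit is aggregated, every orbit member is checked
  to produce the identical row, and the full 2ⁿ chain is solved alongside
  the reduced chain in the test suite.
- **Reachability.** Some states cannot occur starting from one mutant
  (on the ring, mutants invade only as a contiguous arc, so the
  opposite-pair state is unreachable). Reachability is computed from the
  zero-pattern of the chain at r = 1; the pattern is the same for all
  r > 0.
- **Ordering convention.** Transient states sort by (mutant count,
  smallest-member bit value); the two absorbing states close the list in
  the fixed order (extinction, fixation). This canonical form is what the
  solver consumes.
- **Solve.** F = (I − Q)⁻¹ gives unconditional sojourn times, Φ = F·R the
  absorption probabilities, τ_i = Σ_j F_ij the unconditional time, and
  T_ij = F_ij·φ_j/φ_i the conditional sojourn times given fixation, with
  τ_fix,i = Σ_j T_ij. The conditional construction follows the standard
  sojourn-time argument for absorbing chains and is validated against the
  one-dimensional birth–death closed form on complete graphs (agreement to
  1e−9 over a fitness grid).

**Arithmetic.** Exact mode uses `fractions.Fraction` end-to-end with a
rational Gauss–Jordan inverse — row sums are exactly 1 and quantities like
the ring's two-mutant staying probability come out as the literal rational
1/2. It is the default for the four-node analyses. Float mode (LU solve
via scipy) is used for larger state spaces and for root-finding, with
row-stochasticity enforced to 1e−12. The two modes agree to ~1e−12 on the
four-node motifs, and the crossover roots move by less than 1e−6 when the
curves are evaluated from rational chains instead.

**Degenerate inputs.** Disconnected graphs, self-loops, r ≤ 0 and invalid
state spaces are rejected at construction; a singular (I − Q) — absorption
not certain — raises rather than returning garbage. The removable r = 1
singularity exists only in the closed-form φ (patched to i/N); the linear
solve needs no special-casing at neutrality.

## Start averaging

"A mutant arises on a uniformly random node" weights each one-mutant orbit
by orbit-size/n (the diamond's two orbits get 1/2 each; the star's centre
1/4 and leaves 3/4). Two averages must not be confused:

- the **uniform** average of conditional quantities — the convention used
  for all reported curves and crossovers;
- the **fixation-weighted** average, which re-weights starts by their
  fixation probability. This is what a simulation with uniform starts
  estimates after conditioning on fixation, so simulator-vs-exact checks
  use it. The sojourn-argmax crossover moves only from 1.648 to 1.707
  between the two conventions; the uniform value is the one reported.

## Strong selection

Limits for r → ∞ are numerical: the quantity is evaluated along
r = 10², …, 10⁶ and the last value reported with a convergence flag
(successive difference < 1e−4; these quantities approach their limits at
rate O(1/r), giving final differences of order 1e−5). Validated against
the derived complete-graph limits (per-count sojourns 1, 3/2, 3: the
up-move probability tends to (N − i)/(N − 1) and visits are geometric).

## Crossover location

Both crossovers are bracketed sign changes of a difference of exact-solver
curves, found by Brent's method (xtol 1e−10). The states involved are
identified *structurally*, never by position in some fixed numbering: the
neutral sojourn argmax (a two-mutant state) and the three-mutant state
whose wild-type occupies a degree-2 node for the sojourn crossover in
(1, 3); the two one-mutant orbits (hub vs degree-2) for the placement
crossover in (2, 10).

## Simulator

The Monte Carlo simulator mirrors the exact chain event-for-event,
including no-change steps (no per-generation rescaling). Birth sampling is
O(1): choose the fitness class by its total weight, then a uniform member
from a swap-pop maintained node list; the neighbour is uniform. The RNG is
numpy's default (PCG64), seeded per call; identical seeds reproduce results
bit-for-bit. Standard errors are sample standard deviations of per-run
step counts; zero fixation events yield a flagged `None`, not an error.

## Lattice study

Square side×side lattices in six variants: open or periodic (torus)
boundaries, each plain (every unit square a 4-cycle — ring motifs), with
one consistently oriented diagonal per square (diamond motifs, interior
degree 6) or with both diagonals (K4 motifs, interior degree 8). Periodic
variants are regular, hence isothermal: their fixation probability matches
the well-mixed closed form, which the tests check within Monte Carlo
error.

The headline four-node effect scales up through the diamond-motif reading:
the open diamond-motif lattice fixates more slowly than the plain open
grid even though it has ~1.5× the links. The both-diagonal open lattice,
by contrast, is faster than the plain grid — adding *that* many links
restores the intuitive ordering — which is why the diamond-motif variant
is the meaningful "more links" comparison. Among periodic lattices the
intuitive ordering holds throughout: dropping links slows fixation.

Default problem sizes: sides 4–6 (populations 16–36) at r = 2 with 10⁴
replicates per network, chosen to give 3-pooled-SE separation on all
orderings at most sizes; comparisons that fail to separate are reported as
indeterminate, never as failures. Larger sides and replicate counts are
plain function arguments.

## What the generators do and do not emulate

The graph module *is* the data generator: the study's populations are
abstract networks, not measured data, so the generators reproduce the
study conditions themselves (the six four-node motifs, classical families,
lattices) rather than emulating noise. What passing tests do **not** show:
anything about weighted, directed or dynamic networks, other update rules
(death–birth, imitation), frequency-dependent fitness, or real contact
networks whose structure these families do not capture.

## Known limitations

- Exact solves require enumerable state spaces (default cap 2¹⁶
  configurations) and symmetry reduction requires n ≤ 6 (factorial
  automorphism search); beyond that, simulate.
- Amplifier classification is grid-based; a network whose behaviour
  changes character between grid points could be mislabelled (the label
  "none" with per-r diagnostics is emitted for mixed patterns).
- Conditional times for strongly disadvantageous mutants (r ≪ 1) have
  tiny fixation probabilities; float mode loses accuracy there, and exact
  mode is the right tool.
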