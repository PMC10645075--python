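# Methods

## Model and assumptions

The unit of study is the flowing connected directed network (FCDN): a
row-normalised weighted digraph with `N` core nodes, a single input and
a single output.  Weights are *shares* of outflow, not absolute fluxes,
so the network fixes only how energy is routed; how much energy moves
is set by the input rate.  The dynamics are a synchronous discrete-time
linear map on node throughflows,

    X(t+1) = X(t) A_core + u(t),

which assumes: conservative transformations (everything a node receives
is passed on or exported in the same iteration — no storage), linearity
(shares are independent of load), and discrete time.  Because every core
node can reach the output and rows are normalised, the core submatrix is
strictly substochastic; the map contracts, the steady state
`X* = u (I − A_core)^{-1}` exists, and under zero input total energy
decays asymptotically like `E_max(A_core)^t`.  The scarcity-tolerance
reading of `b = E_max − 1` is exactly this: the fraction of retained
energy per iteration once the input fails.  The same eigenvalue, read as
`R = −b`, is the classical return-to-equilibrium resilience; the package
reports `b` only, since the two are trivially interconvertible and the
study axis here is tolerance.

Single input/output nodes lose no generality (multiple sources or sinks
can be merged with adjusted shares).  Multiple inputs/outputs, node
capacities and stochastic flow noise are deliberately out of scope.

## Numerical conventions

- Steady states come from one linear solve (`(I − A_core)ᵀ x = u`); the
  fixed-point iteration is kept in the test suite as an independent
  oracle, not used in production paths.
- `E_max` is taken as the maximum real part of the core spectrum; for a
  nonnegative matrix the spectral radius is attained at a real
  nonnegative eigenvalue (Perron–Frobenius), so this equals the decay
  factor.  Validation flags spectral radius ≥ 1 − 1e-12 as invalid.
- Row sums are accepted within 1e-9; serialisation round-trips to
  1e-12.
- Information indexes use log base 2 (bits) with `0·log 0 := 0`.  TST
  and the AMI/ASC marginals run over core-to-core fluxes only,
  following the index definitions used here; `tst(...,
  include_boundary=True)` provides the whole-system variant for
  sensitivity checks.
- EDiff is `S_out − S_in` (positive = the system exports more entropy
  than it imports); the opposite sign convention is available via
  `ediff(..., flip_sign=True)`.  `S_in` is computed over the
  *throughflows* of input-adjacent core nodes, not over the input arcs
  themselves — with several inflows to an input-adjacent node the two
  differ, and the throughflow reading is the one implemented.
- Pulsed input: "the input misses p iterations" is implemented as
  active at `t ≡ phase (mod p+1)`, i.e. one firing followed by `p`
  silent iterations; the phase offset is configurable.
- The input rate defaults to 1.0 everywhere.  Every index used for
  selection is either invariant to it (AMI, EDiff, Finn, b, PROP_*) or
  exactly linear in it (TST, ASC, ABS_FLOW), so selection decisions do
  not depend on the choice.

## Network generation and repair

`random_fcdn(N, connectance, seed)` places `round(connectance·N(N−1))`
core arcs uniformly at random with U(0,1) weights, gives each core node
a direct dissipation arc to the output with probability `connectance`
(at least one network-wide), wires the input to
`max(1, round(connectance·N))` random core nodes, and repairs.
Connectance is measured on core-to-core arcs only, since only those
mutate structurally.  Generation is infeasible when
`connectance < 1/(N−1)` (too few arcs to give every core node an
outgoing core arc) and raises a configuration error.

`repair` performs the minimal deterministic-given-seed fixes: outflowless
core nodes get an arc to the output (weight 1); core nodes unreachable
from the input get an arc from a uniformly chosen reachable core node
(weight U(0,1)); core nodes that cannot reach the output get a direct
output arc (weight U(0,1)); only rows whose sums drifted are
renormalised, so valid networks pass through bit-for-bit (repair is
idempotent).  This is one admissible construction; ensembles produced by
other initialisation schemes will differ in distribution, which is why
the stochastic experiment outcomes are reproduced as qualitative
patterns and approximate percentages rather than exact values.

## Mutation, selection, and the connectance band

Selection is strict hill climbing: one proposal per iteration, accepted
only on strict improvement of the goal (ties rejected, so neutral drift
never masquerades as optimisation).  Candidates whose goal is undefined
(e.g. AMI with zero core flow) are rejected.

Large-time-scale proposals are add / delete / reweight with
probabilities 0.25 / 0.25 / 0.50; new and freshly redrawn weights are
U(0,1); a reweight is, with probability 0.5, a local ±10% multiplicative
tweak instead of a fresh draw.  Input arcs never change; output arcs
only change weight.  Every candidate passes through repair, so traces
contain only valid networks.  A delete whose repair re-adds the same arc
is retried with a different target (bounded retries, then the iteration
proposes no effective change and is rejected as a tie).

Equal add/delete *proposal* probabilities alone do not keep connectance
constant once selection acts: under TST maximisation nearly every added
arc is accepted (an extra core arc redistributes row shares away from
dissipation and raises whole-network retention), so density would climb
steadily.  Because the study design holds connectance roughly constant
at ~20%, the large-scale operator enforces this directly: an add (or
delete) that would push core density more than ±5 points
(`MutationPolicy.density_band`) from its value at the start of the run
falls back to a reweight.  The band is a hard envelope, not a target —
within it, proposals remain symmetric.

Short-time-scale proposals multiply one existing core-outgoing arc
weight by U(0.9, 1.1) and renormalise its row; the arc set is provably
constant over a short-scale trace.

Greedy objectives: ABS_FLOW `Σ_{i∈G} X*_i`; PROP_FLOW divides by the
total core throughflow; ABS_FINN `Σ_{i∈G} Finn_i`; PROP_FINN divides by
the total Finn.  The proportional variants use network totals as
denominators rather than "rest of network"; `x/T` and `x/(T−x)` are
monotone transforms of each other, so acceptance decisions are
identical and totals are numerically stabler.  Greedy node sets are
sampled uniformly without replacement, `round(fraction·N)` (half-up,
floor 1), independently per replicate and per cell.

## Experiment design and statistics

Per (size, systemic goal): `replicates` random networks are evolved 500
large-scale iterations ("natural history"), then each is branched from
the *identical* network into a control (same systemic goal) and one
greedy run per (scenario, fraction) cell, 5000 short-scale iterations
each.  The control branch is shared across cells of a replicate because
it does not depend on them.  Endpoint comparisons use

    diff = (control − greedy) / (|control| + |greedy|)  ∈ (−1, 1),

applied to `b` and to the *systemic* goal value (the orientor the
control optimises) evaluated on both endpoints; both-zero endpoints give
0.  Negative diffs mark replicates where greed surpassed control.
Summaries report per-cell percentages of `b_diff < 0`, `goal_diff < 0`
and their conjunction with distribution quantiles; an OLS fit of
`goal_diff` on `b_diff` restricted to the both-negative quadrant; and
the Spearman correlation of the number of greedy→output links with
`b_diff`.

Randomness: each stream is `SeedSequence(master_seed, spawn_key=(stream
tag, size, goal index, replicate, scenario index, fraction percent))`,
so any replicate or cell can be re-run in isolation bit-for-bit.

## What the synthetic generator does and does not emulate

The generator reproduces the study conditions: ensemble sizes 30–100
core nodes, ~20% connectance, uniform random shares.  It does not
emulate empirically calibrated ecosystems — no degree heterogeneity,
trophic layering, weight distributions fitted to real flow data, or
stock dynamics.  Passing tests therefore demonstrate the internal
consistency of the model and the qualitative behaviour of the
evolutionary comparison under these idealised conditions, not
quantitative predictions for real ecosystem networks.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the headline cell at full
design scale (N = 30, 100 replicates, 500 + 5000/5000 iterations,
a few minutes on one CPU) and the qualitative-ordering comparison at 20
replicates per cell; property tests use ensembles of 1000 random
networks (sizes 2–100) and 200-network oracle comparisons (sizes 2–50).
The full 4-sizes × 4-goals × 4-scenarios × 3-fractions grid is run via
the CLI when desired; it is embarrassingly parallel across replicates
but is executed serially here.

## Known limitations

- The surpass percentages are ensemble statistics, and the ensembles
  depend on free design choices — the initialisation/repair procedure,
  the mutation-type probabilities, the new-weight distribution.  All of
  these are declared above and configurable, but a different admissible
  choice would shift the percentages by several points; the robust
  outputs are the qualitative orderings (absolute > proportional
  scenarios, larger greedy fractions surpass more often) and the tight
  tolerance-performance coupling, not any single percentage.
- Under sustained TST-style optimisation the spectral radius approaches
  1 and `b` approaches 0 from below (down to ~1e-6 after 5000
  short-scale iterations); comparisons at that scale remain far above
  eigen-solver noise (~1e-14), but much longer runs would eventually
  need extended precision.
- Hill climbing finds local optima only; no annealing, populations or
  multi-objective selection are provided.
- Cycle counting is exhaustive (Johnson's algorithm) and guarded at 12
  nodes; there is no sampling estimator for larger graphs.
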