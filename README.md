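# flownetevo

Energy-based flow-network toy model for comparing *systemic* versus
*greedy* evolutionary dynamics in open, dissipative systems.

## The problem

Open natural systems — ecosystems, and by extension coupled
socio-ecological systems — take in energy, transform it through a web
of internal processes, and dissipate it back to the environment.
Systems ecology describes such a system as a weighted digraph of energy
flows and postulates *goal functions* (orientors) that natural
evolution tends to maximise: total system throughflow (power), average
mutual information (organisation), ascendency, or the entropy exported
to the surroundings.  A *greedy* strategy — say, a subsystem that
redirects flow toward its own nodes, the way industrialised human
activity redirects biospheric energy — optimises something else
entirely, and does it on a much faster time-scale than the rest of the
system can adapt to.  This package asks, by simulation: **how often can
greedy, locally-biased evolution match or beat whole-system evolution,
both in the goal it abandoned and in the system's ability to survive
energy scarcity?**

## The model

A *flowing connected directed network* (FCDN) has `N` core nodes, one
input node and one output node.  Entry `A_ij ∈ [0, 1]` of the adjacency
matrix is the share of node *i*'s outflow routed to node *j*; the input
row and every core row sum to 1, self-loops are forbidden, every core
node is reachable from the input and reaches the output.  Throughflows
follow the linear map `X(t+1) = X(t) A_core + u(t)`; with constant
input the steady state is `X* = u (I − A_core)^{-1}` and the realised
fluxes are `T_ij = X*_i A_ij`.

From `T` the package computes the classical flow indexes (log base 2):

| index | definition |
|---|---|
| TST | `Σ_{i,j=1..N} T_ij` (core-to-core fluxes) |
| AMI | `Σ (T_ij/TST) log2(T_ij·TST / (T_i· T_·j))` |
| ASC | `AMI × TST` (computed from its own flow formula) |
| EDiff | `S_out − S_in`, output-flow entropy minus input-side throughflow entropy |
| Finn | `Σ_i (core inflow_i / TST)·(L_ii − 1)/L_ii`, `L = (I − A_core)^{-1}` |
| b | `E_max(A_core) − 1`, the no-input energy decay rate ("scarcity tolerance") |

Evolution is hill climbing: one mutation per iteration, kept only if
the goal strictly improves.  Large-time-scale mutations add, delete or
reweight core arcs (connectance held near its starting value);
short-time-scale mutations only nudge existing weights by ±10%.  The
experiment design evolves random ensembles for 500 large-scale
iterations under a systemic goal ("natural history"), then branches
each network into a paired *control* (same goal) and *greedy*
(absolute/proportional flow or cycling at a random 10/30/50% subset of
core nodes) short-scale run of 5000 iterations, and compares endpoints
through normalised differences such as
`b_diff = (b_control − b_greedy)/(|b_control| + |b_greedy|)` —
negative means the greedy branch surpassed its control.

## Worked example

```python
import numpy as np
import flownetevo as fe

# in -> n1; n1 -> {n2, out}; n2 -> {n1, out}   (one 2-cycle)
a = np.zeros((4, 4))
a[2, 0] = 1.0                # input feeds n1
a[0, 1] = a[0, 3] = 0.5      # n1 splits between n2 and out
a[1, 0] = a[1, 3] = 0.5      # n2 splits between n1 and out
net = fe.FCDN(a)

print(fe.steady_state(net).x)                 # [1.33333333 0.66666667]
for k, v in fe.index_bundle(net).to_dict().items():
    print(f"{k}\t{v:.6f}")
```

```
tst     1.000000      # 2/3 + 1/3 of flux circulate between the cores
ami     0.918296      # bits: the two unequal flows are fairly articulated
asc     0.918296      # = AMI x TST
s_in    0.000000      # a single input-fed node has zero entropy
s_out   0.918296      # outputs split 2/3 : 1/3
ediff   0.918296      # exported minus imported entropy
finn_total 0.250000   # a quarter of all core flow is cycled
b       -0.500000     # energy halves each iteration once input stops
```

The same numbers fall out of the CLI (`flownetevo indexes --net
cycle.tsv`).  A full grid experiment runs from a YAML config:

```bash
flownetevo experiment --config config.yaml --out-dir results/
flownetevo report --records results/records.csv --out-dir results/
```

which writes one `ComparisonRecord` per (replicate, goal, scenario,
fraction) to `records.csv` and per-cell surpass percentages to
`summary.csv`.

## Layout

- `src/flownetevo/fcdn.py` — network container, generator, validator, repair, TSV/CSV serialisation
- `src/flownetevo/dynamics.py` — steady states, flux matrices, pulsed/scarcity simulation, decay rate
- `src/flownetevo/indexes.py` — TST, AMI, ascendency, EDiff, Finn, cycle counting
- `src/flownetevo/evolution.py` — goal functions, mutation operators, hill-climbing loop
- `src/flownetevo/experiments.py` — the paired control/greedy design and its summary statistics
- `src/flownetevo/cli.py` — `generate`, `indexes`, `evolve`, `experiment`, `report`
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
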