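"""Mutation-selection evolution of FCDNs (structural dynamic modelling).

Networks evolve by hill climbing: one mutation is proposed per
iteration and fixed ("an event in the evolutionary history") only if it
strictly increases the goal function.  Two mutation regimes model two
time-scales:

* **large** (evolutionary time-scale): a single add / delete / reweight
  of a core-to-core arc, or a reweight of a core->output arc; input arcs
  never change.  Candidates are passed through repair so every network
  in a trace is a valid FCDN.  Add and delete are proposed with equal
  probability and a density band keeps core connectance roughly
  constant over the run (see docs/methods.md).
* **short** (ecological time-scale): the arc set is frozen; one existing
  core-outgoing arc has its weight nudged multiplicatively within
  ±``vicinity`` (default 10%) and the row is renormalised.

Goal functions are either *systemic orientors* (TST, AMI, ASC, EDiff)
or *greedy objectives* evaluated on a designated set of greedy core
nodes: absolute / proportional throughflow, and absolute / proportional
per-node Finn cycling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcdn import FCDN, ConfigurationError, _repair_inplace
from .indexes import UndefinedIndexError

__all__ = [
    "GoalFunction",
    "MutationPolicy",
    "EvolutionTrace",
    "SYSTEMIC_GOALS",
    "GREEDY_GOALS",
    "LARGE",
    "SHORT",
    "evaluate_goal",
    "mutate_large",
    "mutate_short",
    "evolve",
    "select_greedy_nodes",
]

SYSTEMIC_GOALS = ("TST", "AMI", "ASC", "EDIFF")
GREEDY_GOALS = ("ABS_FLOW", "PROP_FLOW", "ABS_FINN", "PROP_FINN")

LARGE = "large"
SHORT = "short"


@dataclass(frozen=True)
class GoalFunction:
    """A named scalar objective, optionally tied to a greedy node set."""

    name: str
    greedy_nodes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.name not in SYSTEMIC_GOALS + GREEDY_GOALS:
            raise ConfigurationError(f"unknown goal function {self.name!r}")
        object.__setattr__(self, "greedy_nodes", frozenset(int(i) for i in self.greedy_nodes))
        if self.is_greedy and not self.greedy_nodes:
            raise ConfigurationError(f"greedy goal {self.name} needs a non-empty node set")
        if not self.is_greedy and self.greedy_nodes:
            raise ConfigurationError(f"systemic goal {self.name} takes no greedy nodes")

    @property
    def is_greedy(self) -> bool:
        return self.name in GREEDY_GOALS


@dataclass(frozen=True)
class MutationPolicy:
    """Mutation regime and its probabilities.

    ``p_add``/``p_delete``/``p_reweight`` (large scale only) must sum to
    one; add and delete are kept equal so connectance has no proposal
    bias.  ``vicinity`` is the half-width of the multiplicative tweak;
    ``p_vicinity_large`` the probability that a large-scale reweight is
    a local tweak rather than a fresh U(0,1) draw.  ``density_band``
    bounds how far core connectance may drift from its value at the
    start of a run (None disables the bound).
    """

    scale: str = LARGE
    p_add: float = 0.25
    p_delete: float = 0.25
    p_reweight: float = 0.50
    vicinity: float = 0.10
    p_vicinity_large: float = 0.50
    density_band: float | None = 0.05

    def __post_init__(self) -> None:
        if self.scale not in (LARGE, SHORT):
            raise ConfigurationError(f"unknown mutation scale {self.scale!r}")
        probs = (self.p_add, self.p_delete, self.p_reweight)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("p_add + p_delete + p_reweight must equal 1")
        if self.vicinity < 0:
            raise ConfigurationError("vicinity must be >= 0")

    @classmethod
    def large(cls, **kwargs) -> "MutationPolicy":
        return cls(scale=LARGE, **kwargs)

    @classmethod
    def short(cls, **kwargs) -> "MutationPolicy":
        return cls(scale=SHORT, **kwargs)


@dataclass(frozen=True)
class EvolutionTrace:
    """Per-iteration record of one hill-climbing run plus the final network.

    ``goal_values[t]`` / ``b_values[t]`` are the incumbent's goal value
    and decay rate *after* iteration ``t``; ``accepted[t]`` marks
    iterations whose mutation was fixed.  Goal values at accepted events
    are strictly increasing.
    """

    goal_values: np.ndarray
    accepted: np.ndarray
    b_values: np.ndarray
    initial_goal: float
    initial_b: float
    final: FCDN

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    @property
    def accepted_goal_values(self) -> np.ndarray:
        return self.goal_values[self.accepted]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.goal_values) + 1),
                "accepted": self.accepted,
                "goal_value": self.goal_values,
                "b": self.b_values,
            }
        )


# ---------------------------------------------------------------------------
# goal evaluation
# ---------------------------------------------------------------------------


def _goal_closure(goal: GoalFunction, n: int, input_rate: float):
    """Build a fast adjacency -> goal-value function.

    The closures recompute the steady state from scratch each call; they
    are the hot path of :func:`evolve`, so they work on raw arrays and
    avoid constructing FCDN/FlowMatrix objects.
    """
    ident = np.eye(n)
    rate = float(input_rate)
    greedy = (
        np.fromiter(sorted(goal.greedy_nodes), dtype=int, count=len(goal.greedy_nodes))
        if goal.greedy_nodes
        else None
    )
    if greedy is not None and (greedy.min() < 0 or greedy.max() >= n):
        raise ConfigurationError("greedy nodes must be core node indices")

    def steady(adj: np.ndarray) -> np.ndarray:
        return np.linalg.solve(ident - adj[:n, :n].T, rate * adj[n, :n])

    name = goal.name

    if name == "TST":

        def fn(adj):
            core = adj[:n, :n]
            return float(steady(adj) @ core.sum(axis=1))

    elif name in ("AMI", "ASC"):

        def fn(adj):
            core = adj[:n, :n]
            t = steady(adj)[:, None] * core
            total = t.sum()
            if total <= 0:
                raise UndefinedIndexError("total core flow is zero")
            p = t / total
            marg = np.outer(p.sum(axis=1), p.sum(axis=0))
            mask = p > 0
            value = float(np.sum(p[mask] * np.log2(p[mask] / marg[mask])))
            return value * total if name == "ASC" else value

    elif name == "EDIFF":

        def fn(adj):
            x = steady(adj)
            in_mask = adj[n, :n] > 0
            ti = x[in_mask]
            s = ti.sum()
            if s > 0:
                q = ti[ti > 0] / s
                s_in = float(-(q * np.log2(q)).sum())
            else:
                s_in = 0.0
            to = x * adj[:n, n + 1]
            to = to[to > 0]
            if to.size == 0:
                raise UndefinedIndexError("no core->output flow")
            q = to / to.sum()
            s_out = float(-(q * np.log2(q)).sum())
            return s_out - s_in

    elif name in ("ABS_FLOW", "PROP_FLOW"):

        def fn(adj):
            x = steady(adj)
            num = float(x[greedy].sum())
            if name == "ABS_FLOW":
                return num
            total = float(x.sum())
            return num / total if total > 0 else 0.0

    else:  # ABS_FINN / PROP_FINN

        def fn(adj):
            core = adj[:n, :n]
            x = steady(adj)
            t = x[:, None] * core
            total = t.sum()
            if total <= 0:
                raise UndefinedIndexError("total core flow is zero")
            diag = np.diagonal(np.linalg.inv(ident - core))
            per = (t.sum(axis=0) / total) * (diag - 1.0) / diag
            num = float(per[greedy].sum())
            if name == "ABS_FINN":
                return num
            tot = float(per.sum())
            return num / tot if tot > 0 else 0.0

    return fn


def evaluate_goal(net: FCDN, goal: GoalFunction, input_rate: float = 1.0) -> float:
    """Value of ``goal`` on ``net`` at steady state (input rate 1 by default)."""
    return _goal_closure(goal, net.n_core, input_rate)(net.adjacency)


# ---------------------------------------------------------------------------
# mutation operators
# ---------------------------------------------------------------------------


def _outgoing_arcs(adj: np.ndarray, n: int):
    """Existing core-outgoing arcs (core->core or core->output), as indices."""
    rows, cols = np.nonzero(adj[:n, :])
    return rows, cols


def _short_inplace(adj: np.ndarray, n: int, vicinity: float, rng: np.random.Generator) -> None:
    rows, cols = _outgoing_arcs(adj, n)
    if rows.size == 0:  # pragma: no cover - impossible for a valid FCDN
        return
    k = int(rng.integers(rows.size))
    i, j = int(rows[k]), int(cols[k])
    adj[i, j] *= rng.uniform(1.0 - vicinity, 1.0 + vicinity)
    adj[i] /= adj[i].sum()


def _large_inplace(
    adj: np.ndarray,
    n: int,
    policy: MutationPolicy,
    rng: np.random.Generator,
    density_target: float | None,
) -> str:
    """Apply one large-scale mutation plus repair; returns the op applied."""
    out = n + 1
    draw = rng.random()
    if draw < policy.p_add:
        op = "add"
    elif draw < policy.p_add + policy.p_delete:
        op = "delete"
    else:
        op = "reweight"

    if density_target is not None and policy.density_band is not None and n > 1:
        n_pairs = n * (n - 1)
        arcs = int(np.count_nonzero(adj[:n, :n]))
        if op == "add" and (arcs + 1) / n_pairs > density_target + policy.density_band:
            op = "reweight"
        elif op == "delete" and (arcs - 1) / n_pairs < density_target - policy.density_band:
            op = "reweight"

    if op == "add":
        absent = np.argwhere((adj[:n, :n] == 0) & ~np.eye(n, dtype=bool))
        if absent.shape[0] == 0:
            op = "reweight"  # saturated core: fall back
        else:
            i, j = absent[int(rng.integers(absent.shape[0]))]
            adj[int(i), int(j)] = rng.uniform()
    if op == "delete":
        present = np.argwhere(adj[:n, :n] > 0)
        if present.shape[0] == 0:
            op = "reweight"
        else:
            i, j = present[int(rng.integers(present.shape[0]))]
            adj[int(i), int(j)] = 0.0
    if op == "reweight":
        rows, cols = _outgoing_arcs(adj, n)
        if rows.size:
            k = int(rng.integers(rows.size))
            i, j = int(rows[k]), int(cols[k])
            if rng.random() < policy.p_vicinity_large:
                adj[i, j] *= rng.uniform(1.0 - policy.vicinity, 1.0 + policy.vicinity)
            else:
                adj[i, j] = rng.uniform()

    _repair_inplace(adj, rng)  # also renormalises the touched rows
    return op


def _mutate_large_adj(
    adj: np.ndarray,
    n: int,
    policy: MutationPolicy,
    rng: np.random.Generator,
    density_target: float | None,
    max_tries: int = 5,
) -> np.ndarray:
    """One large-scale candidate; retries when repair undoes the mutation."""
    before_arcs = adj > 0
    for _ in range(max_tries):
        cand = adj.copy()
        op = _large_inplace(cand, n, policy, rng, density_target)
        if op == "delete" and np.array_equal(cand > 0, before_arcs):
            continue  # repair re-added the deleted arc: propose another target
        if not np.array_equal(cand, adj):
            return cand
    return adj.copy()  # skip: no effective mutation found


def mutate_large(
    net: FCDN, policy: MutationPolicy, rng: np.random.Generator | int | None = None
) -> FCDN:
    """One large-time-scale mutation: add/delete/reweight a mutable arc.

    Only core-to-core arcs may be added or deleted; core->output arcs
    may only be reweighted; input arcs never change.  The candidate is
    repaired, so it is always a valid FCDN.
    """
    rng = np.random.default_rng(rng)
    target = net.core_density if policy.density_band is not None else None
    cand = _mutate_large_adj(net.adjacency, net.n_core, policy, rng, target)
    return FCDN(cand, list(net.labels) if net.labels else None)


def mutate_short(
    net: FCDN, policy: MutationPolicy, rng: np.random.Generator | int | None = None
) -> FCDN:
    """One short-time-scale mutation: nudge a single existing arc weight.

    The arc set is exactly preserved; the chosen weight is multiplied by
    a factor drawn U(1 - vicinity, 1 + vicinity) and the row is
    renormalised.
    """
    rng = np.random.default_rng(rng)
    cand = net.adjacency.copy()
    _short_inplace(cand, net.n_core, policy.vicinity, rng)
    return FCDN(cand, list(net.labels) if net.labels else None)


# ---------------------------------------------------------------------------
# selection loop
# ---------------------------------------------------------------------------


def _decay_b(adj: np.ndarray, n: int) -> float:
    return max(float(np.linalg.eigvals(adj[:n, :n]).real.max()), 0.0) - 1.0


def evolve(
    net: FCDN,
    goal: GoalFunction,
    policy: MutationPolicy,
    n_iter: int,
    rng: np.random.Generator | int | None = None,
    input_rate: float = 1.0,
) -> EvolutionTrace:
    """Hill-climb ``net`` for ``n_iter`` iterations under ``goal``.

    One mutation per iteration, accepted iff the goal value strictly
    increases (ties and undefined-index candidates are rejected).
    Deterministic given the rng seed.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    n = net.n_core
    adj = net.adjacency.copy()
    fn = _goal_closure(goal, n, input_rate)
    current = fn(adj)
    current_b = _decay_b(adj, n)
    initial_goal, initial_b = current, current_b

    large_scale = policy.scale == LARGE
    density_target = net.core_density if (large_scale and policy.density_band is not None) else None

    goal_values = np.empty(n_iter)
    b_values = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)

    for t in range(n_iter):
        if large_scale:
            cand = _mutate_large_adj(adj, n, policy, rng, density_target)
        else:
            cand = adj.copy()
            _short_inplace(cand, n, policy.vicinity, rng)
        try:
            value = fn(cand)
        except UndefinedIndexError:
            value = -np.inf
        if value > current:
            adj = cand
            current = value
            current_b = _decay_b(adj, n)
            accepted[t] = True
        goal_values[t] = current
        b_values[t] = current_b

    final = FCDN(adj, list(net.labels) if net.labels else None)
    return EvolutionTrace(goal_values, accepted, b_values, initial_goal, initial_b, final)


def select_greedy_nodes(
    net: FCDN, fraction: float, rng: np.random.Generator | int | None = None
) -> frozenset:
    """Uniform random sample of ``round(fraction * N)`` core nodes.

    Rounding is half-up with a floor of one node; deterministic given
    the rng seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("fraction must lie in (0, 1]")
    n = net.n_core
    k = max(1, int(np.floor(fraction * n + 0.5)))
    rng = np.random.default_rng(rng)
    return frozenset(int(i) for i in rng.choice(n, size=k, replace=False))
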