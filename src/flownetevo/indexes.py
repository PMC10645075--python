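"""Systemic indexes of energy-flow networks.

All indexes are computed from the steady-state flux matrix ``T`` of an
FCDN.  Following the flow-analysis convention used throughout this
package, sums run over the *core-to-core* fluxes only (``i, j = 1..N``);
a ``tst_include_boundary`` flag offers the alternative that also counts
boundary flows, for sensitivity checks.  Logarithms are base 2, so the
information-theoretic indexes are in bits, and ``0 * log 0 := 0``.

Indexes
-------
TST
    Total system throughflow, the sum of all core fluxes — the "power"
    of the system.
AMI
    Average mutual information of the flow distribution,
    ``sum_ij (T_ij/TST) log2(T_ij TST / (T_i. T_.j))`` — flow
    organisation; more articulated (specialised) flow structures score
    higher.
ASC
    Ascendency, ``sum_ij T_ij log2(T_ij TST / (T_i. T_.j))`` — AMI
    scaled by TST, a joint growth-and-development index.  It is computed
    from its own flow formula so the identity ``ASC = AMI * TST`` is a
    genuine numerical cross-check.
EDiff
    Entropy difference ``S_out - S_in`` between the entropy of the
    output flows and the entropy of the throughflows of the core nodes
    fed directly by the input — a proxy for entropy exported to the
    surroundings.
Finn
    Finn cycling index: fraction of total flow that cycles, from the
    diagonal of the Leontief inverse; the per-node variant attributes
    cycled flow to individual nodes and sums to the total.
b
    Energy-flux decay rate (see :mod:`flownetevo.dynamics`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

from .fcdn import FCDN, ConfigurationError, FlowNetError
from .dynamics import FlowMatrix, decay_rate, flux_matrix, leontief, steady_state

__all__ = [
    "IndexBundle",
    "UndefinedIndexError",
    "tst",
    "ami",
    "ascendency",
    "ediff",
    "EntropyDifference",
    "finn",
    "FinnResult",
    "count_cycles",
    "complete_digraph_cycle_count",
    "index_bundle",
]


class UndefinedIndexError(FlowNetError):
    """The index is undefined (e.g. no core flow at all, TST = 0)."""


def tst(flows: FlowMatrix, include_boundary: bool = False) -> float:
    """Total system throughflow: sum of core-to-core fluxes.

    With ``include_boundary=True`` the input->core and core->output
    flows are added (the conventional whole-system variant).
    """
    total = float(flows.core.sum())
    if include_boundary:
        total += float(flows.input_row.sum()) + float(flows.output_column.sum())
    return total


def ami(flows: FlowMatrix) -> float:
    """Average mutual information of the core flow distribution, in bits."""
    t = flows.core
    total = t.sum()
    if total <= 0:
        raise UndefinedIndexError("AMI undefined: total core flow is zero")
    p = t / total
    marg = np.outer(p.sum(axis=1), p.sum(axis=0))
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / marg[mask])))


def ascendency(flows: FlowMatrix) -> float:
    """Ascendency in bits * energy/iteration.

    Computed directly as ``sum_ij T_ij log2(T_ij TST / (T_i. T_.j))``;
    numerically equal to ``ami(flows) * tst(flows)``.
    """
    t = flows.core
    total = t.sum()
    if total <= 0:
        raise UndefinedIndexError("ascendency undefined: total core flow is zero")
    marg = np.outer(t.sum(axis=1), t.sum(axis=0))
    mask = t > 0
    return float(np.sum(t[mask] * np.log2(t[mask] * total / marg[mask])))


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class EntropyDifference(NamedTuple):
    s_in: float
    s_out: float
    ediff: float


def ediff(net: FCDN, flows: FlowMatrix, flip_sign: bool = False) -> EntropyDifference:
    """Entropy difference between exported and imported flow, in bits.

    ``S_in`` is the Shannon entropy of the normalised throughflows of
    the core nodes directly fed by the input; ``S_out`` the entropy of
    the normalised core->output flows.  The returned ``ediff`` is
    ``S_out - S_in`` (positive = exported entropy exceeds imported);
    ``flip_sign`` selects the opposite convention.
    """
    n = net.n_core
    in_nodes = np.flatnonzero(net.adjacency[net.input_index, :n] > 0)
    if in_nodes.size == 0:
        raise UndefinedIndexError("EDiff undefined: no core node receives the input")
    # throughflow of node i = total outflow row sum of T (balanced at steady state)
    through = flows.matrix[:n, :].sum(axis=1)[in_nodes]
    tst_in = through.sum()
    s_in = _entropy2(through / tst_in) if tst_in > 0 else 0.0

    out_flows = flows.output_column
    out_flows = out_flows[out_flows > 0]
    if out_flows.size == 0:
        raise UndefinedIndexError("EDiff undefined: no core node feeds the output")
    s_out = _entropy2(out_flows / out_flows.sum())

    value = s_in - s_out if flip_sign else s_out - s_in
    return EntropyDifference(s_in, s_out, value)


class FinnResult(NamedTuple):
    total: float
    per_node: np.ndarray


def finn(net: FCDN, flows: FlowMatrix) -> FinnResult:
    """Finn cycling index, total and per node.

    ``Finn_i = (core inflow to i / TST) * (L_ii - 1) / L_ii`` with ``L``
    the Leontief inverse; the total is the sum over nodes.  Acyclic
    cores give exactly zero (``L_ii = 1``).
    """
    total_flow = flows.core.sum()
    if total_flow <= 0:
        raise UndefinedIndexError("Finn undefined: total core flow is zero")
    diag = np.diagonal(leontief(net))
    inflow = flows.core.sum(axis=0)
    per_node = (inflow / total_flow) * (diag - 1.0) / diag
    return FinnResult(float(per_node.sum()), per_node)


# ---------------------------------------------------------------------------
# directed simple cycles
# ---------------------------------------------------------------------------


def complete_digraph_cycle_count(n: int) -> int:
    """Closed form: number of directed simple cycles (length >= 2) in K_n.

    ``sum_{k=2..n} C(n, k) (k-1)!`` — choose the k nodes on the cycle,
    then one of the (k-1)! cyclic orders.
    """
    return sum(math.comb(n, k) * math.factorial(k - 1) for k in range(2, n + 1))


def count_cycles(net, max_nodes: int = 12) -> int:
    """Count directed simple cycles (length >= 2) among core nodes.

    Accepts an :class:`FCDN` (cycles of its core subgraph), a square
    array, or a :class:`networkx.DiGraph`.  Enumeration uses Johnson's
    algorithm (via :func:`networkx.simple_cycles`), which is exhaustive;
    the ``max_nodes`` guard refuses graphs where full enumeration would
    be astronomically large — use :func:`complete_digraph_cycle_count`
    for complete graphs instead of raising the guard.
    """
    if isinstance(net, FCDN):
        graph = nx.from_numpy_array(
            (net.core_matrix > 0).astype(int), create_using=nx.DiGraph
        )
    elif isinstance(net, nx.DiGraph):
        graph = net
    else:
        graph = nx.from_numpy_array(
            (np.asarray(net) != 0).astype(int), create_using=nx.DiGraph
        )
    if graph.number_of_nodes() > max_nodes:
        raise ConfigurationError(
            f"{graph.number_of_nodes()} nodes exceeds the exhaustive-enumeration "
            f"guard ({max_nodes}); cycle sampling is not implemented and the "
            "closed form only covers complete digraphs"
        )
    return sum(1 for cycle in nx.simple_cycles(graph) if len(cycle) >= 2)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexBundle:
    """All systemic indexes of one network at steady state."""

    tst: float
    ami: float
    asc: float
    s_in: float
    s_out: float
    ediff: float
    finn_total: float
    finn_per_node: np.ndarray
    b: float

    def to_dict(self) -> dict:
        """Scalar fields only — one CSV row per network."""
        return {
            "tst": self.tst,
            "ami": self.ami,
            "asc": self.asc,
            "s_in": self.s_in,
            "s_out": self.s_out,
            "ediff": self.ediff,
            "finn_total": self.finn_total,
            "b": self.b,
        }


def index_bundle(
    net: FCDN, input_rate: float = 1.0, tst_include_boundary: bool = False
) -> IndexBundle:
    """Steady state -> flux matrix -> every systemic index, in one call."""
    state = steady_state(net, input_rate)
    flows = flux_matrix(net, state, input_rate)
    entropy = ediff(net, flows)
    cycling = finn(net, flows)
    return IndexBundle(
        tst=tst(flows, include_boundary=tst_include_boundary),
        ami=ami(flows),
        asc=ascendency(flows),
        s_in=entropy.s_in,
        s_out=entropy.s_out,
        ediff=entropy.ediff,
        finn_total=cycling.total,
        finn_per_node=cycling.per_node,
        b=decay_rate(net),
    )
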