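"""Flowing connected directed networks (FCDNs).

An FCDN is a weighted digraph describing shares of energy flow: ``N``
*core* nodes (internal energy forms), one *input* node that injects
energy into the system and one *output* node through which energy
dissipates.  Entry ``A[i, j]`` of the adjacency matrix is the fraction of
node *i*'s outflow routed to node *j*, so the input row and every core
row sum to one, the output row is all zero, self-loops are forbidden and
nothing flows back into the input.  Every core node must be reachable
from the input and must reach the output; together with row
normalisation this makes the core submatrix strictly substochastic
(spectral radius < 1), i.e. the system is dissipative.

Node indexing convention: core nodes ``0 .. N-1``, input ``N``, output
``N+1`` — used consistently by every module and serialisation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FCDN",
    "ValidationReport",
    "FlowNetError",
    "ConfigurationError",
    "NormalizationError",
    "EdgeListParseError",
    "RepairError",
    "random_fcdn",
    "validate",
    "repair",
    "normalize_rows",
    "read_edge_list",
    "write_edge_list",
    "write_adjacency_csv",
    "INPUT_LABEL",
    "OUTPUT_LABEL",
    "ROW_SUM_TOL",
]

#: tolerance on row sums of the input and core rows
ROW_SUM_TOL = 1e-9

#: reserved node names marking the boundary nodes in edge-list files
INPUT_LABEL = "in"
OUTPUT_LABEL = "out"


class FlowNetError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FlowNetError):
    """Invalid parameter combination (infeasible connectance, bad sizes...)."""


class NormalizationError(FlowNetError):
    """A row that must carry outflow has no weight to normalise."""


class EdgeListParseError(FlowNetError):
    """Malformed edge-list file; the message names the offending line."""


class RepairError(FlowNetError):
    """A candidate matrix cannot be turned into a valid FCDN."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class FCDN:
    """A flowing connected directed network.

    Parameters
    ----------
    adjacency
        ``(N+2) x (N+2)`` nonnegative matrix of outflow shares; rows/cols
        ordered core ``0..N-1``, input ``N``, output ``N+1``.
    labels
        Optional names for the core nodes (defaults to ``n1 .. nN``).
    """

    adjacency: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConfigurationError("adjacency must be a square matrix")
        if a.shape[0] < 3:
            raise ConfigurationError("an FCDN needs at least one core node")
        self.adjacency = a
        if self.labels is not None and len(self.labels) != self.n_core:
            raise ConfigurationError(
                f"expected {self.n_core} core labels, got {len(self.labels)}"
            )

    # -- indexing ----------------------------------------------------------
    @property
    def n_core(self) -> int:
        return self.adjacency.shape[0] - 2

    @property
    def input_index(self) -> int:
        return self.n_core

    @property
    def output_index(self) -> int:
        return self.n_core + 1

    @property
    def core_matrix(self) -> np.ndarray:
        """The ``N x N`` core submatrix (a view, not a copy)."""
        return self.adjacency[: self.n_core, : self.n_core]

    @property
    def core_density(self) -> float:
        """Realised fraction of possible core-to-core arcs."""
        n = self.n_core
        if n < 2:
            return 0.0
        return float(np.count_nonzero(self.core_matrix)) / (n * (n - 1))

    # -- labels ------------------------------------------------------------
    def core_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [f"n{i + 1}" for i in range(self.n_core)]

    def node_label(self, i: int) -> str:
        if i == self.input_index:
            return INPUT_LABEL
        if i == self.output_index:
            return OUTPUT_LABEL
        return self.core_labels()[i]

    # -- misc ---------------------------------------------------------------
    def copy(self) -> "FCDN":
        return FCDN(self.adjacency.copy(), list(self.labels) if self.labels else None)

    def equals(self, other: "FCDN", tol: float = 1e-12) -> bool:
        """Weight-wise equality up to ``tol`` (labels ignored)."""
        return (
            self.n_core == other.n_core
            and bool(np.all(np.abs(self.adjacency - other.adjacency) <= tol))
        )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate`: all violated rules, not just the first."""

    is_valid: bool
    violations: tuple = ()


# ---------------------------------------------------------------------------
# reachability helper (shared with repair/validate; no networkx in hot paths)
# ---------------------------------------------------------------------------


def _forward_reachable(arcs: np.ndarray, start: int) -> np.ndarray:
    """Boolean vector of nodes reachable from ``start`` over ``arcs > 0``."""
    m = arcs.shape[0]
    visited = np.zeros(m, dtype=bool)
    visited[start] = True
    frontier = [start]
    while frontier:
        mask = np.zeros(m, dtype=bool)
        for i in frontier:
            mask |= arcs[i]
        new = mask & ~visited
        visited |= new
        frontier = np.flatnonzero(new).tolist()
    return visited


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(net: FCDN) -> ValidationReport:
    """Check every FCDN invariant and report all violations.

    Rules checked: weight range [0, 1], zero diagonal (no self-loops),
    unit row sums for input and core rows, all-zero output row, all-zero
    input column, directed reachability (input -> every core node ->
    output) and strict substochasticity of the core (spectral radius < 1).
    Malformed input yields a report, never an exception.
    """
    a = net.adjacency
    n = net.n_core
    inp, out = net.input_index, net.output_index
    violations: list[tuple[str, object]] = []

    for i, j in np.argwhere((a < 0) | (a > 1)):
        violations.append(("weight-range", (int(i), int(j))))
    for i in np.flatnonzero(np.diagonal(a) != 0):
        violations.append(("self-loop", int(i)))
    for i in range(n + 1):  # core rows and the input row
        s = a[i].sum()
        if abs(s - 1.0) > ROW_SUM_TOL:
            violations.append(("row-sum", int(i)))
    for j in np.flatnonzero(a[out]):
        violations.append(("output-row", int(j)))
    for i in np.flatnonzero(a[:, inp]):
        violations.append(("input-column", int(i)))

    arcs = a > 0
    reach = _forward_reachable(arcs, inp)
    for i in range(n):
        if not reach[i]:
            violations.append(("input-unreachable", int(i)))
    coreach = _forward_reachable(arcs.T, out)
    for i in range(n):
        if not coreach[i]:
            violations.append(("output-unreachable", int(i)))

    core = net.core_matrix
    rho = float(np.max(np.abs(np.linalg.eigvals(core)))) if n else 0.0
    if rho >= 1.0 - 1e-12:
        violations.append(("spectral-radius", rho))

    return ValidationReport(not violations, tuple(violations))


# ---------------------------------------------------------------------------
# normalisation & repair
# ---------------------------------------------------------------------------


def normalize_rows(matrix: np.ndarray, skip: tuple[int, ...] = ()) -> np.ndarray:
    """Scale each row to sum to one; rows listed in ``skip`` are untouched.

    Raises :class:`NormalizationError` on negative entries or on a
    zero-sum row that is not skipped (such rows need :func:`repair`
    first — there is no outflow to renormalise).
    """
    m = np.array(matrix, dtype=float)
    one_dim = m.ndim == 1
    if one_dim:
        m = m[None, :]
    if (m < 0).any():
        raise NormalizationError("negative entries cannot be normalized")
    skipped = set(skip)
    for i in range(m.shape[0]):
        if i in skipped:
            continue
        s = m[i].sum()
        if s <= 0:
            raise NormalizationError(f"row {i} has zero outflow; repair it first")
        m[i] /= s
    return m[0] if one_dim else m


def _repair_inplace(adj: np.ndarray, rng: np.random.Generator) -> None:
    """Minimal in-place repair turning ``adj`` into a valid FCDN.

    Steps: (1) every outflow-less core node gets an arc to the output
    (weight 1); (2) core nodes unreachable from the input get an arc from
    a uniformly chosen already-reachable core node (weight U(0,1));
    (3) core nodes that cannot reach the output get a direct arc to it
    (weight U(0,1)); (4) rows whose sums drifted off one are renormalised.
    Already-valid networks pass through bit-for-bit unchanged.
    """
    m = adj.shape[0]
    n = m - 2
    inp, out = n, n + 1

    np.clip(adj, 0.0, None, out=adj)
    np.fill_diagonal(adj, 0.0)
    adj[:, inp] = 0.0
    adj[out, :] = 0.0

    for i in range(n):
        if adj[i].sum() == 0.0:
            adj[i, out] = 1.0
    if adj[inp].sum() == 0.0:
        adj[inp, int(rng.integers(n))] = 1.0

    # forward reachability from the input
    while True:
        reach = _forward_reachable(adj > 0, inp)
        missing = [i for i in range(n) if not reach[i]]
        if not missing:
            break
        target = missing[int(rng.integers(len(missing)))]
        donors = [i for i in range(n) if reach[i]]
        donor = donors[int(rng.integers(len(donors)))]
        w = float(rng.uniform())
        adj[donor, target] = w if w > 0 else 0.5

    # backward reachability to the output
    coreach = _forward_reachable((adj > 0).T, out)
    for i in range(n):
        if not coreach[i]:
            w = float(rng.uniform())
            adj[i, out] = w if w > 0 else 0.5

    for i in range(n + 1):
        s = adj[i].sum()
        if s <= 0:  # pragma: no cover - unreachable after the steps above
            raise RepairError(f"row {i} has no outflow after repair")
        if abs(s - 1.0) > ROW_SUM_TOL:
            adj[i] /= s


def repair(candidate: np.ndarray | FCDN, seed: int | np.random.Generator = 0) -> FCDN:
    """Return a valid FCDN obtained from ``candidate`` with minimal edits.

    ``candidate`` is an ``(N+2) x (N+2)`` weight matrix using the package
    node convention (input ``N``, output ``N+1``) or an :class:`FCDN`.
    Idempotent on already-valid networks; deterministic given ``seed``.
    """
    if isinstance(candidate, FCDN):
        a = candidate.adjacency.copy()
        labels = list(candidate.labels) if candidate.labels else None
    else:
        a = np.array(candidate, dtype=float)
        labels = None
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 3:
        raise RepairError("candidate must be square with at least one core node")
    rng = np.random.default_rng(seed)
    _repair_inplace(a, rng)
    return FCDN(a, labels)


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------


def random_fcdn(
    n_core: int,
    connectance: float = 0.20,
    seed: int | np.random.Generator | None = None,
) -> FCDN:
    """Generate a random valid FCDN.

    ``connectance`` is the target fraction of the ``N(N-1)`` possible
    core-to-core arcs (boundary arcs do not count).  Arc weights are
    drawn U(0,1) and row-normalised.  Each core node additionally
    receives a direct dissipation arc to the output with probability
    ``connectance`` (at least one such arc overall), and the input feeds
    ``max(1, round(connectance * N))`` random core nodes.  The result is
    passed through :func:`repair`, so all invariants hold.

    Raises :class:`ConfigurationError` when ``connectance`` cannot give
    every core node an outgoing core arc (``connectance * N * (N-1) < N``).
    """
    if n_core < 2:
        raise ConfigurationError("n_core must be at least 2")
    if not 0.0 < connectance <= 1.0:
        raise ConfigurationError("connectance must lie in (0, 1]")
    n_pairs = n_core * (n_core - 1)
    if connectance * n_pairs < n_core:
        raise ConfigurationError(
            f"connectance {connectance} gives fewer than {n_core} core arcs; "
            f"need connectance >= {1.0 / (n_core - 1):.4f}"
        )
    rng = np.random.default_rng(seed)
    m = n_core + 2
    inp, out = n_core, n_core + 1
    adj = np.zeros((m, m))

    n_arcs = int(round(connectance * n_pairs))
    chosen = rng.choice(n_pairs, size=n_arcs, replace=False)
    for k in chosen:
        i, r = divmod(int(k), n_core - 1)
        j = r if r < i else r + 1
        adj[i, j] = rng.uniform()

    out_nodes = np.flatnonzero(rng.uniform(size=n_core) < connectance)
    if out_nodes.size == 0:
        out_nodes = np.array([int(rng.integers(n_core))])
    adj[out_nodes, out] = rng.uniform(size=out_nodes.size)

    k_in = max(1, int(round(connectance * n_core)))
    targets = rng.choice(n_core, size=k_in, replace=False)
    adj[inp, targets] = rng.uniform(size=k_in)

    _repair_inplace(adj, rng)
    net = FCDN(adj)
    report = validate(net)
    if not report.is_valid:  # pragma: no cover - repair guarantees validity
        raise RepairError(f"generator produced an invalid network: {report.violations[:3]}")
    return net


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_HEADER = ["source", "target", "weight"]


def write_edge_list(net: FCDN, path) -> None:
    """Write the network as a TSV edge list (``source  target  weight``).

    The boundary nodes use the reserved names ``"in"`` and ``"out"``;
    weights are written with full float precision so a round trip is
    exact to better than 1e-12.
    """
    labels = net.core_labels()
    n, inp, out = net.n_core, net.input_index, net.output_index
    a = net.adjacency
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for j in np.flatnonzero(a[inp]):
            tgt = OUTPUT_LABEL if j == out else labels[j]
            writer.writerow([INPUT_LABEL, tgt, repr(float(a[inp, j]))])
        for i in range(n):
            for j in np.flatnonzero(a[i]):
                tgt = OUTPUT_LABEL if j == out else labels[j]
                writer.writerow([labels[i], tgt, repr(float(a[i, j]))])


def read_edge_list(path) -> FCDN:
    """Read a TSV edge list written by :func:`write_edge_list`.

    Core nodes are indexed in order of first appearance.  Parse errors
    (bad weight, duplicate edge, self-loop, arcs leaving ``"out"`` or
    entering ``"in"``, missing boundary nodes) name the offending line.
    """
    edges: list[tuple[str, str, float]] = []
    order: list[str] = []
    seen_names: set[str] = set()
    seen_edges: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _HEADER:
            expected = "\t".join(_HEADER)
            raise EdgeListParseError(f"line 1: expected header {expected!r}")
        for ln, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise EdgeListParseError(f"line {ln}: expected 3 tab-separated fields")
            src, tgt, wtxt = (f.strip() for f in row)
            try:
                w = float(wtxt)
            except ValueError:
                raise EdgeListParseError(f"line {ln}: weight {wtxt!r} is not a number")
            if not 0.0 <= w <= 1.0:
                raise EdgeListParseError(f"line {ln}: weight {w} outside [0, 1]")
            if src == OUTPUT_LABEL:
                raise EdgeListParseError(f"line {ln}: arcs cannot leave {OUTPUT_LABEL!r}")
            if tgt == INPUT_LABEL:
                raise EdgeListParseError(f"line {ln}: arcs cannot enter {INPUT_LABEL!r}")
            if src == tgt:
                raise EdgeListParseError(f"line {ln}: self-loop at {src!r}")
            if (src, tgt) in seen_edges:
                raise EdgeListParseError(f"line {ln}: duplicate edge {src!r} -> {tgt!r}")
            seen_edges.add((src, tgt))
            edges.append((src, tgt, w))
            for name in (src, tgt):
                if name not in (INPUT_LABEL, OUTPUT_LABEL) and name not in seen_names:
                    seen_names.add(name)
                    order.append(name)
    if not any(src == INPUT_LABEL for src, _, _ in edges):
        raise EdgeListParseError("no input node: no edge leaves 'in'")
    if not any(tgt == OUTPUT_LABEL for _, tgt, _ in edges):
        raise EdgeListParseError("no output node: no edge enters 'out'")
    if not order:
        raise EdgeListParseError("no core nodes found")

    n = len(order)
    index = {name: i for i, name in enumerate(order)}
    index[INPUT_LABEL] = n
    index[OUTPUT_LABEL] = n + 1
    adj = np.zeros((n + 2, n + 2))
    for src, tgt, w in edges:
        adj[index[src], index[tgt]] = w
    return FCDN(adj, labels=order)


def write_adjacency_csv(net: FCDN, path) -> None:
    """Export the dense adjacency matrix as CSV with labelled rows/columns."""
    import pandas as pd

    names = net.core_labels() + [INPUT_LABEL, OUTPUT_LABEL]
    pd.DataFrame(net.adjacency, index=names, columns=names).to_csv(path)
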