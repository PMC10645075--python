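"""Flow dynamics of FCDNs: steady states, realised fluxes, pulses, decay.

The model is a synchronous discrete-time linear map on the vector of
core-node throughflows ``X``:

    X(t+1) = X(t) @ A_core + u(t)

where ``A_core`` is the (substochastic) core submatrix and ``u(t)`` is
the input delivery vector — ``input_rate`` times the input node's row of
shares — on iterations where the input fires.  Under constant input the
map converges to the unique steady state

    X* = u @ L,      L = (I - A_core)^{-1}   (the Leontief inverse),

and the realised edge fluxes are ``T_ij = X*_i A_ij``.  With the input
cut off, total energy decays asymptotically by the factor
``E_max(A_core)`` per iteration; the *energy-flux decay rate*
``b = E_max(A_core) - 1`` in [-1, 0) is the system's scarcity tolerance
(closer to 0 = slower decay = more tolerant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcdn import FCDN, ConfigurationError, FlowNetError

__all__ = [
    "FlowState",
    "FlowMatrix",
    "InputSchedule",
    "Trajectory",
    "leontief",
    "steady_state",
    "flux_matrix",
    "simulate",
    "decay_rate",
]


@dataclass(frozen=True)
class FlowState:
    """Per-core-node throughflows at an iteration (or at steady state)."""

    x: np.ndarray
    t: int | str = "steady"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))

    @property
    def total_energy(self) -> float:
        return float(self.x.sum())


@dataclass(frozen=True)
class FlowMatrix:
    """Realised edge fluxes ``T_ij`` (energy per iteration), boundary included.

    ``matrix`` is ``(N+2) x (N+2)`` in the package node convention; the
    ``core`` view restricts to core-to-core fluxes, which is what the
    systemic indexes sum over.
    """

    matrix: np.ndarray
    n_core: int

    @property
    def core(self) -> np.ndarray:
        return self.matrix[: self.n_core, : self.n_core]

    @property
    def input_row(self) -> np.ndarray:
        return self.matrix[self.n_core, : self.n_core]

    @property
    def output_column(self) -> np.ndarray:
        return self.matrix[: self.n_core, self.n_core + 1]


@dataclass(frozen=True)
class InputSchedule:
    """When and how strongly the input node fires.

    ``period`` is the number of iterations the input *misses* between
    firings: with ``period = p`` the input is active at iterations
    ``t ≡ phase (mod p+1)``, so ``period = 0`` is constant input.
    ``t_on``/``t_off`` bound the active window (``t_off = None`` means
    forever), which is how scarcity onset (input cut) is expressed.
    """

    rate: float = 1.0
    period: int = 0
    t_on: int = 0
    t_off: int | None = None
    phase: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("input rate must be >= 0")
        if self.period < 0:
            raise ConfigurationError("period must be >= 0")

    def active(self, t: int) -> bool:
        if t < self.t_on:
            return False
        if self.t_off is not None and t >= self.t_off:
            return False
        return (t - self.t_on - self.phase) % (self.period + 1) == 0


@dataclass(frozen=True)
class Trajectory:
    """Sequence of flow states produced by :func:`simulate`.

    ``states[k]`` is the throughflow vector at iteration ``k`` (row per
    iteration, column per core node); ``total_energy[k]`` is its sum.
    """

    states: np.ndarray
    labels: tuple[str, ...] = ()

    @property
    def total_energy(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def final(self) -> FlowState:
        return FlowState(self.states[-1], t=self.states.shape[0] - 1)

    def to_dataframe(self):
        """Long-format table: iteration, node, throughflow, total_energy."""
        import pandas as pd

        t_max, n = self.states.shape
        labels = list(self.labels) or [f"n{i + 1}" for i in range(n)]
        totals = self.total_energy
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(t_max), n),
                "node": labels * t_max,
                "throughflow": self.states.ravel(),
                "total_energy": np.repeat(totals, n),
            }
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def leontief(net: FCDN) -> np.ndarray:
    """Leontief inverse ``L = (I - A_core)^{-1}``.

    Exists for every valid FCDN (spectral radius of the core < 1); the
    diagonal entries are >= 1 and ``L_ii - 1`` is the flow that returns
    to node *i* through cycles per unit of throughflow.
    """
    n = net.n_core
    try:
        L = np.linalg.inv(np.eye(n) - net.core_matrix)
    except np.linalg.LinAlgError as exc:
        raise FlowNetError("non-dissipative core: I - A is singular") from exc
    if not np.all(np.isfinite(L)):
        raise FlowNetError("non-dissipative core: Leontief inverse not finite")
    return L


def steady_state(net: FCDN, input_rate: float = 1.0) -> FlowState:
    """Steady-state throughflows ``X* = u @ (I - A_core)^{-1}``.

    ``u`` is the input node's delivery vector scaled by ``input_rate``.
    Solved as one linear system; for ``input_rate = 0`` the steady state
    is identically zero.
    """
    if input_rate < 0:
        raise ConfigurationError("input_rate must be >= 0")
    n = net.n_core
    if input_rate == 0:
        return FlowState(np.zeros(n))
    u = input_rate * net.adjacency[net.input_index, :n]
    try:
        x = np.linalg.solve(np.eye(n) - net.core_matrix.T, u)
    except np.linalg.LinAlgError as exc:
        raise FlowNetError("non-dissipative core: steady state undefined") from exc
    return FlowState(x)


def flux_matrix(net: FCDN, state: FlowState, input_rate: float = 1.0) -> FlowMatrix:
    """Realised fluxes ``T_ij = X_i A_ij`` plus the boundary flows.

    The input row carries ``input_rate`` times the input shares; at a
    steady state the result satisfies node balance (inflow = outflow at
    every core node).
    """
    n = net.n_core
    if state.x.shape != (n,):
        raise ConfigurationError(
            f"state has {state.x.shape[0] if state.x.ndim else 0} entries, expected {n}"
        )
    t = np.zeros_like(net.adjacency)
    t[:n, :] = state.x[:, None] * net.adjacency[:n, :]
    t[net.input_index, :] = input_rate * net.adjacency[net.input_index, :]
    return FlowMatrix(t, n)


def simulate(
    net: FCDN,
    schedule: InputSchedule,
    x0: FlowState | np.ndarray | None = None,
    t_max: int = 100,
) -> Trajectory:
    """Iterate the flow map for ``t_max`` steps.

    ``states[0]`` is the initial condition (zero by default) and
    ``states[t+1] = states[t] @ A_core + u(t)`` with ``u(t)`` active on
    the iterations where ``schedule`` fires.  With constant input the
    trajectory converges geometrically to :func:`steady_state`; with the
    input off, total energy is non-increasing.
    """
    if t_max < 1:
        raise ConfigurationError("t_max must be >= 1")
    n = net.n_core
    core = net.core_matrix
    u_full = net.adjacency[net.input_index, :n] * schedule.rate
    if x0 is None:
        x = np.zeros(n)
    else:
        x = np.asarray(x0.x if isinstance(x0, FlowState) else x0, dtype=float).copy()
    states = np.empty((t_max + 1, n))
    states[0] = x
    for t in range(t_max):
        x = x @ core
        if schedule.active(t):
            x = x + u_full
        states[t + 1] = x
    return Trajectory(states, tuple(net.core_labels()))


def decay_rate(net: FCDN) -> float:
    """Energy-flux decay rate ``b = E_max(A_core) - 1`` in [-1, 0).

    ``E_max`` is the spectral radius of the core matrix; for a
    nonnegative matrix it is attained by a real nonnegative eigenvalue
    (Perron–Frobenius), so ``b`` equals the asymptotic per-iteration
    log-decay of total energy under zero input: closer to 0 means more
    scarcity-tolerant.
    """
    eigvals = np.linalg.eigvals(net.core_matrix)
    rho = max(float(eigvals.real.max()), 0.0)
    b = rho - 1.0
    if b >= 0:
        raise FlowNetError(f"non-dissipative core: spectral radius {rho} >= 1")
    return b
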