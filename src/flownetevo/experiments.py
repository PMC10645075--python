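"""Experiment orchestration: paired control vs greedy evolutions.

The full design: for each ensemble size and each systemic goal
function, generate ``replicates`` random FCDNs and evolve each for
``natural_iters`` large-time-scale iterations ("natural history").
Every naturally evolved network is then branched into paired
short-time-scale runs of ``short_iters`` iterations from the *same*
starting network:

* a **control** branch that keeps maximising the systemic goal, and
* a **greedy** branch per (scenario, fraction) cell that maximises a
  greedy objective over a freshly sampled random set of greedy nodes.

Each pair yields one :class:`ComparisonRecord` holding the endpoint
decay rates, the *systemic* goal value of both endpoints, and the
normalised differences

    b_diff    = (b_control - b_greedy) / (|b_control| + |b_greedy|)
    goal_diff = (goal_control - goal_greedy) / (|goal_control| + |goal_greedy|)

in (-1, 1); negative values mark replicates where the greedy branch
surpassed its control.  Aggregation helpers compute the per-cell
percentages of surpassing replicates, the goal_diff-vs-b_diff
regression in the "better greedy" quadrant, and the relation between
scarcity tolerance and the number of greedy->output links.

Randomness: every stream is derived from ``master_seed`` via
``np.random.SeedSequence(master_seed, spawn_key=(stream, size, goal,
replicate, ...))``, so replicates are independent and individually
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .fcdn import FCDN, ConfigurationError, random_fcdn, write_edge_list
from .dynamics import decay_rate
from .indexes import index_bundle
from .evolution import (
    GREEDY_GOALS,
    SYSTEMIC_GOALS,
    EvolutionTrace,
    GoalFunction,
    MutationPolicy,
    evaluate_goal,
    evolve,
    select_greedy_nodes,
)

__all__ = [
    "ExperimentConfig",
    "ComparisonRecord",
    "run_natural_history",
    "run_branch_pair",
    "run_experiment",
    "surpass_percentages",
    "diff_scatter_stats",
    "link_vs_diff_analysis",
    "goal_correlation_matrix",
    "normalized_diff",
]

logger = logging.getLogger("flownetevo")

# stream tags for the seed-spawning scheme
_S_INIT, _S_NATURAL, _S_CONTROL, _S_SELECT, _S_GREEDY = range(5)

_GOAL_INDEX = {name: i for i, name in enumerate(SYSTEMIC_GOALS)}
_SCENARIO_INDEX = {name: i for i, name in enumerate(GREEDY_GOALS)}


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    seq = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(seq)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Parameters of the full experimental grid (defaults = study design)."""

    sizes: tuple = (30, 50, 70, 100)
    replicates: int = 100
    connectance: float = 0.20
    natural_iters: int = 500
    short_iters: int = 5000
    goals: tuple = SYSTEMIC_GOALS
    greedy_scenarios: tuple = GREEDY_GOALS
    greedy_fractions: tuple = (0.10, 0.30, 0.50)
    input_rate: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        self.goals = tuple(self.goals)
        self.greedy_scenarios = tuple(self.greedy_scenarios)
        self.greedy_fractions = tuple(float(f) for f in self.greedy_fractions)
        if not self.sizes or any(s < 2 for s in self.sizes):
            raise ConfigurationError("sizes must be integers >= 2")
        for count_name in ("replicates", "natural_iters", "short_iters"):
            if getattr(self, count_name) < 1:
                raise ConfigurationError(f"{count_name} must be positive")
        if not 0 < self.connectance <= 1:
            raise ConfigurationError("connectance must lie in (0, 1]")
        for g in self.goals:
            if g not in SYSTEMIC_GOALS:
                raise ConfigurationError(f"unknown systemic goal {g!r}")
        for s in self.greedy_scenarios:
            if s not in GREEDY_GOALS:
                raise ConfigurationError(f"unknown greedy scenario {s!r}")
        if not self.greedy_fractions or any(
            not 0 < f <= 1 for f in self.greedy_fractions
        ):
            raise ConfigurationError("greedy fractions must lie in (0, 1]")
        if self.input_rate <= 0:
            raise ConfigurationError("input_rate must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


def normalized_diff(control: float, greedy: float) -> float:
    """(control - greedy) / (|control| + |greedy|); 0 when both are 0."""
    denom = abs(control) + abs(greedy)
    if denom == 0:
        return 0.0
    return (control - greedy) / denom


@dataclass(frozen=True)
class ComparisonRecord:
    """Paired control/greedy outcome for one replicate and one grid cell."""

    replicate: int
    goal: str
    scenario: str
    size: int
    fraction: float
    b_control: float
    b_greedy: float
    goal_control: float
    goal_greedy: float
    b_diff: float
    goal_diff: float
    greedy_out_links: int

    def to_dict(self) -> dict:
        return asdict(self)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.to_dict() for r in records])


# ---------------------------------------------------------------------------
# running the design
# ---------------------------------------------------------------------------


def run_natural_history(
    config: ExperimentConfig,
    size: int,
    goal: str,
    seed: int | None = None,
) -> list[tuple[int, EvolutionTrace]]:
    """Evolve ``config.replicates`` random FCDNs under the LARGE policy.

    Returns ``(replicate_id, trace)`` pairs; a replicate that fails is
    logged with a warning and excluded.
    """
    master = config.master_seed if seed is None else seed
    gidx = _GOAL_INDEX[goal]
    policy = MutationPolicy.large()
    goal_fn = GoalFunction(goal)
    out = []
    for rep in range(config.replicates):
        try:
            net = random_fcdn(size, config.connectance, _rng(master, _S_INIT, size, gidx, rep))
            trace = evolve(
                net,
                goal_fn,
                policy,
                config.natural_iters,
                _rng(master, _S_NATURAL, size, gidx, rep),
                config.input_rate,
            )
        except Exception:  # noqa: BLE001 - a failed replicate must not kill the grid
            logger.warning("replicate %d (size=%d goal=%s) failed; excluded", rep, size, goal, exc_info=True)
            continue
        out.append((rep, trace))
        if (rep + 1) % 20 == 0:
            logger.info("natural history size=%d goal=%s: %d/%d replicates", size, goal, rep + 1, config.replicates)
    return out


def _greedy_out_link_count(net: FCDN, greedy_nodes: frozenset) -> int:
    nodes = np.fromiter(sorted(greedy_nodes), dtype=int)
    return int(np.count_nonzero(net.adjacency[nodes, net.output_index]))


def _branch_pair(
    evolved: FCDN,
    goal: str,
    scenario: str,
    fraction: float,
    *,
    short_iters: int,
    input_rate: float,
    rng_select: np.random.Generator,
    rng_greedy: np.random.Generator,
    rng_control: np.random.Generator | None = None,
    control_net: FCDN | None = None,
    replicate: int = 0,
) -> ComparisonRecord:
    policy = MutationPolicy.short()
    systemic = GoalFunction(goal)
    if control_net is None:
        control_net = evolve(evolved, systemic, policy, short_iters, rng_control, input_rate).final
    greedy_nodes = select_greedy_nodes(evolved, fraction, rng_select)
    greedy_goal = GoalFunction(scenario, greedy_nodes)
    greedy_net = evolve(evolved, greedy_goal, policy, short_iters, rng_greedy, input_rate).final

    b_control = decay_rate(control_net)
    b_greedy = decay_rate(greedy_net)
    goal_control = evaluate_goal(control_net, systemic, input_rate)
    goal_greedy = evaluate_goal(greedy_net, systemic, input_rate)
    return ComparisonRecord(
        replicate=replicate,
        goal=goal,
        scenario=scenario,
        size=evolved.n_core,
        fraction=float(fraction),
        b_control=b_control,
        b_greedy=b_greedy,
        goal_control=goal_control,
        goal_greedy=goal_greedy,
        b_diff=normalized_diff(b_control, b_greedy),
        goal_diff=normalized_diff(goal_control, goal_greedy),
        greedy_out_links=_greedy_out_link_count(greedy_net, greedy_nodes),
    )


def run_branch_pair(
    evolved: FCDN,
    goal: str,
    scenario: str,
    fraction: float,
    seed: int = 0,
    *,
    short_iters: int = 5000,
    input_rate: float = 1.0,
    replicate: int = 0,
) -> ComparisonRecord:
    """Run one control/greedy short-time-scale pair from ``evolved``.

    Both branches start from the identical network; the greedy node set
    is sampled freshly from ``seed``.  The record's ``goal_*`` values
    are the *systemic* goal (the orientor the control maximises)
    evaluated on both endpoints.
    """
    ctrl, sel, greedy = (np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3))
    return _branch_pair(
        evolved,
        goal,
        scenario,
        fraction,
        short_iters=short_iters,
        input_rate=input_rate,
        rng_select=sel,
        rng_greedy=greedy,
        rng_control=ctrl,
        replicate=replicate,
    )


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the full grid and return one :class:`ComparisonRecord` per row.

    The control branch of a replicate does not depend on the greedy
    scenario or fraction, so it is computed once per replicate and
    shared across cells.  With ``out_dir`` set, writes ``records.csv``,
    ``summary.csv``, final networks under ``networks/`` and natural-
    history traces under ``traces/``.
    """
    master = config.master_seed if seed is None else seed
    policy_short = MutationPolicy.short()
    records: list[ComparisonRecord] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "networks").mkdir(parents=True, exist_ok=True)
        (out_path / "traces").mkdir(parents=True, exist_ok=True)

    for size in config.sizes:
        for goal in config.goals:
            gidx = _GOAL_INDEX[goal]
            histories = run_natural_history(config, size, goal, master)
            for rep, trace in histories:
                start = trace.final
                control_net = evolve(
                    start,
                    GoalFunction(goal),
                    policy_short,
                    config.short_iters,
                    _rng(master, _S_CONTROL, size, gidx, rep),
                    config.input_rate,
                ).final
                for scenario in config.greedy_scenarios:
                    sidx = _SCENARIO_INDEX[scenario]
                    for fraction in config.greedy_fractions:
                        fpct = int(round(fraction * 100))
                        rec = _branch_pair(
                            start,
                            goal,
                            scenario,
                            fraction,
                            short_iters=config.short_iters,
                            input_rate=config.input_rate,
                            rng_select=_rng(master, _S_SELECT, size, gidx, rep, sidx, fpct),
                            rng_greedy=_rng(master, _S_GREEDY, size, gidx, rep, sidx, fpct),
                            control_net=control_net,
                            replicate=rep,
                        )
                        records.append(rec)
                if out_path is not None:
                    write_edge_list(
                        start, out_path / "networks" / f"size{size}_{goal}_rep{rep}.tsv"
                    )
                    trace.to_dataframe().to_csv(
                        out_path / "traces" / f"size{size}_{goal}_rep{rep}.csv", index=False
                    )
            logger.info("finished cell size=%d goal=%s (%d replicates)", size, goal, len(histories))

    frame = _records_frame(records)
    if out_path is not None:
        frame.to_csv(out_path / "records.csv", index=False)
        surpass_percentages(frame).to_csv(out_path / "summary.csv", index=False)
    return frame


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

_QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)


def surpass_percentages(
    records, group_cols: tuple[str, ...] = ("goal", "scenario", "size", "fraction")
) -> pd.DataFrame:
    """Per-cell percentages of replicates whose greedy branch surpassed.

    ``pct_tolerance`` counts ``b_diff < 0``, ``pct_performance`` counts
    ``goal_diff < 0`` and ``pct_both`` their conjunction, plus quantiles
    of both difference distributions.
    """
    df = _records_frame(records)
    if df.empty:
        logger.warning("surpass_percentages: no records; returning empty table")
        return pd.DataFrame()
    rows = []
    for key, grp in df.groupby(list(group_cols)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_cols, key))
        n = len(grp)
        tol = grp["b_diff"] < 0
        perf = grp["goal_diff"] < 0
        row.update(
            n=n,
            pct_tolerance=100.0 * tol.mean(),
            pct_performance=100.0 * perf.mean(),
            pct_both=100.0 * (tol & perf).mean(),
        )
        for q in _QUANTILES:
            row[f"b_diff_q{int(q * 100)}"] = grp["b_diff"].quantile(q)
            row[f"goal_diff_q{int(q * 100)}"] = grp["goal_diff"].quantile(q)
        rows.append(row)
    return pd.DataFrame(rows)


def diff_scatter_stats(records) -> dict:
    """OLS fit of goal_diff on b_diff in the "better greedy" quadrant.

    Restricted to records with both differences negative (greedy beat
    the control on both axes); returns slope, intercept, Pearson r and
    the number of qualifying records, or ``computable=False`` with
    fewer than three points.
    """
    df = _records_frame(records)
    sub = df[(df["b_diff"] < 0) & (df["goal_diff"] < 0)] if not df.empty else df
    if len(sub) < 3:
        return {"computable": False, "n": int(len(sub))}
    fit = scipy.stats.linregress(sub["b_diff"], sub["goal_diff"])
    return {
        "computable": True,
        "n": int(len(sub)),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
    }


def link_vs_diff_analysis(records) -> dict:
    """Relation between greedy->output link counts and scarcity tolerance.

    Spearman rank correlation of ``greedy_out_links`` with ``b_diff``
    (positive rho = fewer output links go with greedy branches that
    surpass, i.e. more negative b_diff), plus the mean b_diff per
    out-link count.
    """
    df = _records_frame(records)
    if len(df) < 3:
        return {"computable": False, "n": int(len(df))}
    if df["greedy_out_links"].nunique() < 2:
        return {"computable": False, "n": int(len(df)), "reason": "constant out-link count"}
    rho, pval = scipy.stats.spearmanr(df["greedy_out_links"], df["b_diff"])
    binned = df.groupby("greedy_out_links")["b_diff"].mean()
    return {
        "computable": True,
        "n": int(len(df)),
        "spearman_rho": float(rho),
        "p_value": float(pval),
        "binned_mean_b_diff": {int(k): float(v) for k, v in binned.items()},
    }


def goal_correlation_matrix(ensemble, input_rate: float = 1.0) -> pd.DataFrame:
    """Pearson correlations among TST, AMI, ASC, EDiff, Finn and b.

    Computed over an ensemble (iterable of FCDNs); zero-variance
    indexes yield NaN rows/columns.
    """
    nets = list(ensemble)
    if len(nets) < 3:
        raise ConfigurationError("need at least 3 networks for a correlation matrix")
    rows = []
    for net in nets:
        bundle = index_bundle(net, input_rate)
        rows.append(
            {
                "tst": bundle.tst,
                "ami": bundle.ami,
                "asc": bundle.asc,
                "ediff": bundle.ediff,
                "finn": bundle.finn_total,
                "b": bundle.b,
            }
        )
    return pd.DataFrame(rows).corr()


def write_analysis_reports(records, out_dir: str | Path) -> None:
    """Write summary.csv plus the scatter and link analyses as JSON."""
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    df = _records_frame(records)
    surpass_percentages(df).to_csv(out_path / "summary.csv", index=False)
    with open(out_path / "scatter_stats.json", "w") as fh:
        json.dump(diff_scatter_stats(df), fh, indent=2)
    with open(out_path / "link_analysis.json", "w") as fh:
        json.dump(link_vs_diff_analysis(df), fh, indent=2)
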