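"""Simulation engine: the per-period loop, full runs and parameter sweeps.

Each period unfolds in a fixed order: agents choose intended actions, the
execution error is applied, payoffs are computed on the *current* network
and accumulated, executed actions enter the histories, and only then is
the network updated for the next period (redrawn under random rewiring,
or strategically updated).  No update happens after the final period.

Payoffs are averaged over a period's interactions, so they do not depend
on the number of partners; an isolated agent earns 0 for the period.
An agent's final payoff is the sum of its per-period averages over the
``T`` periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model
from .model import (
    COOPERATE,
    RANDOM_REWIRING,
    STRATEGIC_UPDATING,
    SimulationParams,
    validate_params,
)
from .network import (
    InteractionNetwork,
    init_random_network,
    rewire_random,
    strategic_update_adjacency,
)
from .metrics import gini, pearson_correspondence

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationState",
    "PeriodRecord",
    "SimulationResult",
    "SweepResult",
    "init_state",
    "compute_payoffs",
    "run_period",
    "run_simulation",
    "run_sweep",
    "default_grid",
    "DEFAULT_CONDITIONS",
]

#: Figure-style default conditions: no reputation vs. a one-period window,
#: in each network regime.
DEFAULT_CONDITIONS: tuple[tuple[int, str], ...] = (
    (0, RANDOM_REWIRING),
    (1, RANDOM_REWIRING),
    (0, STRATEGIC_UPDATING),
    (1, STRATEGIC_UPDATING),
)


@dataclass
class SimulationState:
    """Mutable run state: strategies, histories, payoffs and the network."""

    strategies: np.ndarray  # (N,) int8 strategy codes
    executed: np.ndarray  # (N, T) int8, filled column by column
    completed: int  # number of completed periods
    payoff_acc: np.ndarray  # (N,) float accumulated payoffs
    network: InteractionNetwork
    #: the network the last completed period was played on — without
    #: reputation it is the only source of behavioural information
    previous_network: InteractionNetwork | None = None


@dataclass
class PeriodRecord:
    """Outcome of one period before the network update."""

    period: int
    executed_actions: np.ndarray  # (N,) int8
    per_agent_payoff: np.ndarray  # (N,) float, period average
    cooperation_level: float  # fraction of agents executing C


@dataclass
class SimulationResult:
    """Full outcome of one run.

    ``cooperation_rate`` is each agent's fraction of the ``T`` periods in
    which it executed cooperate; ``final_payoff`` its accumulated payoff.
    """

    params: SimulationParams
    strategies: np.ndarray
    cooperation_rate: np.ndarray  # (N,)
    final_payoff: np.ndarray  # (N,)
    cooperation_level: np.ndarray  # (T,) per-period population trace
    period_payoffs: np.ndarray | None = None  # (T, N) when requested

    def gini(self) -> float:
        return gini(self.final_payoff)

    def pearson(self) -> float:
        return pearson_correspondence(self.cooperation_rate, self.final_payoff)


@dataclass
class SweepResult:
    """Tidy per-cell, per-condition summary of a replicated grid sweep.

    ``table`` columns: p_D, p_A, r, mode, mean_gini, mean_pearson,
    mean_cooperation, n_runs, n_pearson_excluded.  Means are over
    completed runs; undefined (zero-variance) Pearson values are excluded
    from the Pearson mean and counted in ``n_pearson_excluded``.
    """

    table: pd.DataFrame
    reps: int
    master_seed: int


def init_state(params: SimulationParams, rng: np.random.Generator) -> SimulationState:
    """Fresh run state: permuted strategies on an initial random network."""
    strategies = model.strategy_vector(params, rng)
    network = init_random_network(params.N, params.m, rng)
    return SimulationState(
        strategies=strategies,
        executed=np.zeros((params.N, params.T), dtype=np.int8),
        completed=0,
        payoff_acc=np.zeros(params.N, dtype=float),
        network=network,
    )


def compute_payoffs(
    network: InteractionNetwork | np.ndarray,
    executed: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Per-agent period payoff: mean dyadic payoff over its neighbours.

    The dyadic payoff is read from the 2x2 matrix with the agent's own
    executed action as row and the neighbour's as column.  Isolates earn
    the isolate payoff 0 (no interactions, nothing earned).
    """
    adj = network.adjacency if isinstance(network, InteractionNetwork) else network
    executed = np.asarray(executed)
    matrix = params.payoff_matrix()
    degree = adj.sum(axis=1)
    # int cast: boolean matmul would reduce with logical OR, not a count
    n_coop = adj @ (executed == COOPERATE).astype(np.int64)
    n_def = degree - n_coop
    own = executed.astype(np.intp)
    total = matrix[own, COOPERATE] * n_coop + matrix[own, 0] * n_def
    with np.errstate(invalid="ignore", divide="ignore"):
        payoff = np.where(degree > 0, total / np.where(degree > 0, degree, 1), 0.0)
    return payoff


def _reputation_ok(executed: np.ndarray, completed: int, params: SimulationParams) -> np.ndarray:
    """Mask of agents whose reputation passes the partner-choice filter.

    Reputation is the average executed action over the last
    ``min(r, completed)`` periods; eligibility requires it to reach the
    unadjusted ``thetaC``.
    """
    window = min(params.r, completed)
    recent = executed[:, completed - window : completed]
    return recent.mean(axis=1) >= params.thetaC


def run_period(
    state: SimulationState,
    params: SimulationParams,
    period: int,
    rng: np.random.Generator,
    update_network: bool = True,
) -> PeriodRecord:
    """Execute one period in place and return its record.

    Event order: intended actions -> execution error -> payoffs on the
    current network -> accumulate payoffs and append histories -> update
    the network for the next period (skipped for the final period by the
    caller via ``update_network=False``).

    Conditional cooperators score the network they can observe: with
    ``r = 0`` the previous period's network (their own last partners),
    with ``r >= 1`` the current one (reputation is public).
    """
    history = state.executed[:, : state.completed]
    if params.r >= 1 or state.previous_network is None:
        info_adjacency = state.network.adjacency
    else:
        info_adjacency = state.previous_network.adjacency
    intended = model.choose_actions(
        state.strategies, history, info_adjacency, params, period, rng
    )
    executed = model.apply_execution_errors(intended, params.epsilon, rng)

    payoff = compute_payoffs(state.network, executed, params)
    state.payoff_acc += payoff
    state.executed[:, period] = executed
    state.completed = period + 1

    record = PeriodRecord(
        period=period,
        executed_actions=executed,
        per_agent_payoff=payoff,
        cooperation_level=float((executed == COOPERATE).mean()),
    )

    if update_network:
        state.previous_network = state.network
        if params.mode == RANDOM_REWIRING:
            state.network = rewire_random(params, rng)
        else:
            reputation_ok = (
                _reputation_ok(state.executed, state.completed, params)
                if params.r >= 1
                else None
            )
            adj = strategic_update_adjacency(
                state.network.adjacency, executed, reputation_ok, params, rng
            )
            state.network = InteractionNetwork(adj)
    return record


def run_simulation(
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    keep_period_payoffs: bool = False,
) -> SimulationResult:
    """Run ``T`` periods from a fresh initial network.

    Deterministic given the parameter record's seed (or the supplied
    generator): the same inputs always produce the identical result.
    """
    params = validate_params(params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_state(params, rng)
    period_payoffs = np.zeros((params.T, params.N)) if keep_period_payoffs else None
    for t in range(params.T):
        record = run_period(state, params, t, rng, update_network=(t < params.T - 1))
        if period_payoffs is not None:
            period_payoffs[t] = record.per_agent_payoff
    cooperation_level = (state.executed == COOPERATE).mean(axis=0)
    return SimulationResult(
        params=params,
        strategies=state.strategies,
        cooperation_rate=(state.executed == COOPERATE).mean(axis=1),
        final_payoff=state.payoff_acc.copy(),
        cooperation_level=cooperation_level,
        period_payoffs=period_payoffs,
    )


def default_grid(step: float = 0.1, maximum: float = 0.5) -> list[tuple[float, float]]:
    """Default (p_D, p_A) sweep grid: both axes 0..maximum in ``step``.

    The published heat-map axis ranges are not machine-readable, so the
    grid is configurable; this 6x6 simplex-constrained default spans the
    region where all three strategy types coexist.
    """
    values = np.round(np.arange(0.0, maximum + step / 2, step), 10)
    return [(float(pd_), float(pa)) for pd_ in values for pa in values if pd_ + pa <= 1.0]


def run_sweep(
    grid: list[tuple[float, float]],
    conditions: tuple[tuple[int, str], ...] = DEFAULT_CONDITIONS,
    reps: int = 100,
    base: SimulationParams | None = None,
    master_seed: int = 0,
    theta0_tracks_p_A: bool = True,
) -> SweepResult:
    """Replicated sweep over a (p_D, p_A) grid and (r, mode) conditions.

    For each cell x condition, ``reps`` independent runs are executed on
    seed substreams derived from ``master_seed``; per-run Gini and Pearson
    are computed and averaged.  Cells violating ``p_A + p_D <= 1`` are
    skipped with a logged warning.  With ``theta0_tracks_p_A`` (the
    default protocol), each cell's initial cooperation propensity is set
    to its altruist fraction.

    The result is bit-identical for a fixed ``master_seed``, grid and
    condition order.
    """
    if base is None:
        base = SimulationParams()
    rows = []
    for cell_idx, (p_D, p_A) in enumerate(grid):
        if p_A + p_D > 1.0 + 1e-12:
            logger.warning("skipping grid cell p_D=%s p_A=%s: p_A + p_D > 1", p_D, p_A)
            continue
        for cond_idx, (r, mode) in enumerate(conditions):
            overrides = dict(p_A=p_A, p_D=p_D, r=r, mode=mode)
            if theta0_tracks_p_A:
                overrides["theta0"] = p_A
            params = base.with_updates(**overrides)
            cell_seq = np.random.SeedSequence(
                master_seed, spawn_key=(cell_idx, cond_idx)
            )
            ginis = np.empty(reps)
            pearsons = np.empty(reps)
            coop = np.empty(reps)
            for rep, child in enumerate(cell_seq.spawn(reps)):
                result = run_simulation(params, rng=np.random.default_rng(child))
                ginis[rep] = result.gini()
                pearsons[rep] = result.pearson()
                coop[rep] = result.cooperation_level.mean()
            defined = ~np.isnan(pearsons)
            rows.append(
                {
                    "p_D": p_D,
                    "p_A": p_A,
                    "r": r,
                    "mode": mode,
                    "mean_gini": float(ginis.mean()),
                    "mean_pearson": float(pearsons[defined].mean()) if defined.any() else np.nan,
                    "mean_cooperation": float(coop.mean()),
                    "n_runs": reps,
                    "n_pearson_excluded": int((~defined).sum()),
                }
            )
    return SweepResult(table=pd.DataFrame(rows), reps=reps, master_seed=master_seed)
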