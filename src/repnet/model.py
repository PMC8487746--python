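"""Model parameters and per-agent decision rules.

The population plays a repeated N-person Prisoner's Dilemma on a network.
Agents carry one of three fixed strategies:

* **altruists** always cooperate,
* **defectors** never cooperate,
* **conditional cooperators** cooperate initially with probability
  ``theta0 + a0*r`` and afterwards reciprocate: they cooperate iff the
  average cooperation of their neighbours over the last ``max(r, 1)``
  periods is at least ``thetaC - aC*r``.

``r`` is the reputation window: the number of past periods over which an
agent's executed actions are publicly visible.  ``r = 0`` means no
reputational information beyond one's own neighbours' last-period actions.
Executed actions (after the execution error ``epsilon``) — not intentions —
enter histories and reputations, since observers can only see what was done.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "COOPERATE",
    "DEFECT",
    "RANDOM_REWIRING",
    "STRATEGIC_UPDATING",
    "SimulationParams",
    "AgentState",
    "validate_params",
    "assign_strategies",
    "strategy_counts",
    "reputation_score",
    "choose_action",
    "choose_actions",
    "apply_execution_error",
    "apply_execution_errors",
    "initial_cooperation_probability",
    "reciprocation_threshold",
    "clamp01",
]

# Action encoding used throughout: executed-action arrays are int8.
COOPERATE: int = 1
DEFECT: int = 0

# Strategy encoding.
ALTRUIST: int = 0
DEFECTOR: int = 1
CONDITIONAL: int = 2

STRATEGY_NAMES = ("altruist", "defector", "conditional")

RANDOM_REWIRING = "random_rewiring"
STRATEGIC_UPDATING = "strategic_updating"

Mode = Literal["random_rewiring", "strategic_updating"]


def clamp01(x: float) -> float:
    """Clamp a scalar to the closed unit interval."""
    return min(1.0, max(0.0, float(x)))


@dataclass(frozen=True)
class SimulationParams:
    """Validated parameter record for one simulation run.

    Do not construct directly; use :func:`validate_params`, which derives
    ``p_R`` and checks all invariants.

    Attributes
    ----------
    N : population size (number of agents).
    m : target average node degree of the interaction network.
    T : number of interaction periods.
    p_A, p_D, p_R : fractions of persistent altruists, persistent
        defectors and conditional cooperators; ``p_R = 1 - p_A - p_D``.
    r : reputation window length in periods (0 disables reputation).
    theta0 : baseline initial cooperation propensity of conditional
        cooperators.  ``None`` resolves to ``p_A`` (the default protocol:
        willingness to cooperate on first encounter equals the chance of
        meeting an unconditional cooperator).
    thetaC : baseline reciprocation threshold.
    a0, aC : strength of the reputation effect on the initial propensity
        and on the threshold, respectively.
    payoff_cc, payoff_cd, payoff_dc, payoff_dd : dyadic payoffs for
        (own, partner) action pairs, in game units.
    epsilon : action-execution error probability (the executed action is
        flipped with this probability).
    gamma : network-update omission error probability (an agent skips its
        entire network update with this probability).
    mode : ``"random_rewiring"`` (whole network redrawn every period) or
        ``"strategic_updating"`` (drop a defecting neighbour, form new
        links by mutual consent under the ``2m`` degree cap).
    seed : master pseudo-random seed for :func:`repnet.engine.run_simulation`.
    """

    N: int = 100
    m: int = 2
    T: int = 100
    p_A: float = 0.0
    p_D: float = 0.0
    p_R: float = field(default=1.0)
    r: int = 0
    theta0: float = 0.0
    thetaC: float = 0.5
    a0: float = 0.1
    aC: float = 0.05
    payoff_cc: float = 5.0
    payoff_cd: float = 0.0
    payoff_dc: float = 8.0
    payoff_dd: float = 2.0
    epsilon: float = 0.005
    gamma: float = 0.005
    mode: Mode = RANDOM_REWIRING
    seed: int = 0

    def payoff_matrix(self) -> np.ndarray:
        """2x2 payoff array indexed ``[own_action, partner_action]``.

        Actions use the module encoding (``DEFECT=0``, ``COOPERATE=1``),
        so ``matrix[1, 1]`` is the mutual-cooperation payoff.
        """
        return np.array(
            [
                [self.payoff_dd, self.payoff_dc],
                [self.payoff_cd, self.payoff_cc],
            ],
            dtype=float,
        )

    def with_updates(self, **changes) -> "SimulationParams":
        """Return a re-validated copy with the given fields replaced."""
        raw = replace(self, **{k: v for k, v in changes.items() if k != "p_R"})
        return validate_params(raw)


def validate_params(raw) -> SimulationParams:
    """Validate a raw parameter record and derive ``p_R``.

    Parameters
    ----------
    raw : SimulationParams or mapping
        Field values; ``p_R`` is ignored on input and recomputed.

    Raises
    ------
    ValueError
        If any invariant fails: ``p_A + p_D > 1``, probabilities outside
        their ranges, ``N < 2``, ``T < 1``, ``m`` outside ``[1, N)``,
        ``r < 0`` or an unknown ``mode``.
    """
    if isinstance(raw, SimulationParams):
        d = {f: getattr(raw, f) for f in raw.__dataclass_fields__}
    else:
        d = dict(raw)
    d.pop("p_R", None)

    N = int(d.get("N", 100))
    m = int(d.get("m", 2))
    T = int(d.get("T", 100))
    r = int(d.get("r", 0))
    p_A = float(d.get("p_A", 0.0))
    p_D = float(d.get("p_D", 0.0))
    mode = d.get("mode", RANDOM_REWIRING)

    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if not (1 <= m < N):
        raise ValueError(f"m must satisfy 1 <= m < N, got m={m}, N={N}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    if not (0.0 <= p_A <= 1.0 and 0.0 <= p_D <= 1.0):
        raise ValueError(f"p_A and p_D must lie in [0, 1], got {p_A}, {p_D}")
    if p_A + p_D > 1.0 + 1e-12:
        raise ValueError(f"p_A + p_D must not exceed 1, got {p_A + p_D}")
    if mode not in (RANDOM_REWIRING, STRATEGIC_UPDATING):
        raise ValueError(f"unknown mode {mode!r}")

    theta0 = d.get("theta0", None)
    if theta0 is None:
        theta0 = p_A
    theta0 = float(theta0)
    thetaC = float(d.get("thetaC", 0.5))
    a0 = float(d.get("a0", 0.1))
    aC = float(d.get("aC", 0.05))
    # The model states 0 < theta0, thetaC, a0, aC < 1; the endpoints are
    # admitted so that theta0 = p_A remains valid at p_A = 0 and so the
    # reputation effects can be switched off.
    for name, v in (("theta0", theta0), ("thetaC", thetaC), ("a0", a0), ("aC", aC)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")

    epsilon = float(d.get("epsilon", 0.005))
    gamma = float(d.get("gamma", 0.005))
    for name, v in (("epsilon", epsilon), ("gamma", gamma)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")

    return SimulationParams(
        N=N,
        m=m,
        T=T,
        p_A=p_A,
        p_D=p_D,
        p_R=max(0.0, 1.0 - p_A - p_D),
        r=r,
        theta0=theta0,
        thetaC=thetaC,
        a0=a0,
        aC=aC,
        payoff_cc=float(d.get("payoff_cc", 5.0)),
        payoff_cd=float(d.get("payoff_cd", 0.0)),
        payoff_dc=float(d.get("payoff_dc", 8.0)),
        payoff_dd=float(d.get("payoff_dd", 2.0)),
        epsilon=epsilon,
        gamma=gamma,
        mode=mode,
        seed=int(d.get("seed", 0)),
    )


@dataclass
class AgentState:
    """State of one agent within a run.

    The strategy is fixed for the whole run.  ``executed_actions`` records
    the post-error action for every completed period (module encoding:
    ``COOPERATE=1``, ``DEFECT=0``).
    """

    agent_id: int
    strategy: int
    executed_actions: list[int] = field(default_factory=list)
    accumulated_payoff: float = 0.0

    @property
    def strategy_name(self) -> str:
        return STRATEGY_NAMES[self.strategy]


def strategy_counts(params: SimulationParams) -> tuple[int, int, int]:
    """Deterministic (n_altruists, n_defectors, n_conditional) composition.

    Uses cumulative rounding: ``n_A = round(N * p_A)`` and
    ``n_A + n_D = round(N * (p_A + p_D))``, which guarantees the counts sum
    to at most ``N`` and keeps grid cells comparable across runs.
    """
    N = params.N
    n_a = round(N * params.p_A)
    n_ad = round(N * (params.p_A + params.p_D))
    n_d = n_ad - n_a
    return n_a, n_d, N - n_ad


def assign_strategies(params: SimulationParams, rng: np.random.Generator) -> list[AgentState]:
    """Create the agent population with randomly permuted strategy labels."""
    strategies = strategy_vector(params, rng)
    return [AgentState(agent_id=i, strategy=int(s)) for i, s in enumerate(strategies)]


def strategy_vector(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Array form of :func:`assign_strategies` (one int code per agent)."""
    n_a, n_d, n_r = strategy_counts(params)
    strategies = np.concatenate(
        [
            np.full(n_a, ALTRUIST, dtype=np.int8),
            np.full(n_d, DEFECTOR, dtype=np.int8),
            np.full(n_r, CONDITIONAL, dtype=np.int8),
        ]
    )
    return rng.permutation(strategies)


def reputation_score(agent: AgentState, r: int, current_period: int | None = None) -> float | None:
    """Average executed cooperation of one agent over its last ``r`` periods.

    Returns the fraction of the last ``min(r, completed periods)`` executed
    actions equal to cooperate, or ``None`` when no period has completed.

    Raises
    ------
    ValueError
        If ``r < 1`` — with a zero reputation window there is no
        reputational information to score.
    """
    if r < 1:
        raise ValueError("reputation_score requires r >= 1 (r = 0 disables reputation)")
    history = agent.executed_actions
    if current_period is not None:
        history = history[:current_period]
    if len(history) == 0:
        return None
    window = history[-r:]
    return float(sum(1 for a in window if a == COOPERATE) / len(window))


def initial_cooperation_probability(params: SimulationParams) -> float:
    """``clamp(theta0 + a0 * r)`` — the period-0 cooperation probability."""
    return clamp01(params.theta0 + params.a0 * params.r)


def reciprocation_threshold(params: SimulationParams) -> float:
    """``clamp(thetaC - aC * r)`` — the reciprocation threshold."""
    return clamp01(params.thetaC - params.aC * params.r)


def _neighbour_cooperation_score(
    neighbour_states: Sequence[AgentState], window: int
) -> float | None:
    """Mean over neighbours of each neighbour's executed-cooperation
    fraction over its last ``window`` completed periods.

    Neighbours with empty histories are skipped (no information); returns
    ``None`` for an empty neighbour list or when no neighbour has history.
    """
    fractions = []
    for nb in neighbour_states:
        hist = nb.executed_actions[-window:]
        if hist:
            fractions.append(sum(1 for a in hist if a == COOPERATE) / len(hist))
    if not fractions:
        return None
    return float(np.mean(fractions))


def choose_action(
    agent: AgentState,
    neighbour_states: Sequence[AgentState],
    params: SimulationParams,
    period: int,
    rng: np.random.Generator,
) -> int:
    """Intended action of one agent for the given period.

    Altruists cooperate, defectors defect.  A conditional cooperator at
    period 0 cooperates with probability ``clamp(theta0 + a0*r)``; later it
    cooperates iff the neighbour cooperation score over the last
    ``max(r, 1)`` periods is at least ``clamp(thetaC - aC*r)`` (ties
    cooperate).  Isolated conditional cooperators — and those whose
    neighbours have no observable history — repeat the initial-cooperation
    draw.

    ``neighbour_states`` must be the agents whose behaviour is observable:
    the previous period's interaction partners when ``r = 0`` (direct
    experience only), the current neighbours when ``r >= 1`` (public
    reputation).
    """
    if agent.strategy == ALTRUIST:
        return COOPERATE
    if agent.strategy == DEFECTOR:
        return DEFECT

    p_init = initial_cooperation_probability(params)
    if period == 0:
        return COOPERATE if rng.random() < p_init else DEFECT

    window = max(params.r, 1)
    score = _neighbour_cooperation_score(neighbour_states, window)
    if score is None:
        return COOPERATE if rng.random() < p_init else DEFECT
    return COOPERATE if score >= reciprocation_threshold(params) else DEFECT


def choose_actions(
    strategies: np.ndarray,
    executed: np.ndarray,
    adjacency: np.ndarray,
    params: SimulationParams,
    period: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised intended actions for the whole population.

    Implements exactly the per-agent rule of :func:`choose_action` on array
    state: ``executed`` is the ``(N, completed_periods)`` history of
    executed actions and ``adjacency`` the boolean adjacency matrix of the
    *information* network — whose partners' behaviour the agent can
    observe.  Without reputation (``r = 0``) that is the last period's
    interaction network: agents only know what their own partners did to
    them, so after rewiring their reaction lands on new, possibly
    innocent, partners.  With ``r >= 1`` reputation makes the current
    partners' records public, and the caller passes the current network.
    """
    N = len(strategies)
    intended = np.zeros(N, dtype=np.int8)
    intended[strategies == ALTRUIST] = COOPERATE
    conditional = strategies == CONDITIONAL
    if not conditional.any():
        return intended

    p_init = initial_cooperation_probability(params)
    # A single uniform draw per conditional agent serves both the period-0
    # rule and the isolate fallback; fixed draw count keeps runs replayable.
    draws = rng.random(N)
    if period == 0 or executed.shape[1] == 0:
        intended[conditional & (draws < p_init)] = COOPERATE
        return intended

    window = min(max(params.r, 1), executed.shape[1])
    frac = executed[:, -window:].mean(axis=1)  # per-agent cooperation fraction
    degree = adjacency.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = (adjacency @ frac) / np.where(degree > 0, degree, 1)
    threshold = reciprocation_threshold(params)

    connected = conditional & (degree > 0)
    intended[connected & (score >= threshold)] = COOPERATE
    isolates = conditional & (degree == 0)
    intended[isolates & (draws < p_init)] = COOPERATE
    return intended


def apply_execution_error(intended: int, epsilon: float, rng: np.random.Generator) -> int:
    """Flip the intended action with probability ``epsilon``."""
    if rng.random() < epsilon:
        return COOPERATE if intended == DEFECT else DEFECT
    return intended


def apply_execution_errors(
    intended: np.ndarray, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised :func:`apply_execution_error` over the population."""
    flips = rng.random(len(intended)) < epsilon
    return np.where(flips, 1 - intended, intended).astype(np.int8)
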