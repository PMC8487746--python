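"""Interaction-network construction and the two updating regimes.

Agents start on an Erdős–Rényi random graph with edge probability
``m / (N - 1)`` (expected mean degree ``m``, Poisson-like degrees, low
clustering).  Two regimes change the network over time:

* **random rewiring** — the whole network is redrawn independently every
  period; no structure carries over.
* **strategic updating** — every period each agent may drop one neighbour
  that defected in the last period and nominate replacement partners; a
  new link forms only by mutual nomination and only while both endpoints
  stay at or below the degree cap ``2m``.  With probability ``gamma`` an
  agent skips its entire update.

When a reputation window ``r >= 1`` is active, agents nominate only
candidates whose average executed cooperation over the last ``r`` periods
is at least ``thetaC``; candidates without any observable history cannot
demonstrate that record and are ineligible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import networkx as nx

from .model import (
    COOPERATE,
    DEFECT,
    SimulationParams,
    AgentState,
    reputation_score,
)

__all__ = [
    "InteractionNetwork",
    "init_random_network",
    "rewire_random",
    "strategic_update",
    "strategic_update_adjacency",
    "eligible_partners",
]


class InteractionNetwork:
    """Simple undirected graph over ``N`` agents.

    Thin wrapper around a boolean adjacency matrix; the matrix form is what
    the vectorised engine operates on, while edge-set accessors and
    networkx/CSV conversion serve inspection, debugging and replay.
    """

    def __init__(self, adjacency: np.ndarray):
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adjacency, adjacency.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if adjacency.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = adjacency

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    @classmethod
    def from_edges(cls, N: int, edges: Iterable[tuple[int, int]]) -> "InteractionNetwork":
        adj = np.zeros((N, N), dtype=bool)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop {i}-{j}")
            adj[i, j] = adj[j, i] = True
        return cls(adj)

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of unordered edges as (low, high) pairs."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(ii.tolist(), jj.tolist()))

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbours(self, i: int) -> list[int]:
        return np.nonzero(self.adjacency[i])[0].tolist()

    def mean_degree(self) -> float:
        return float(self.degree().mean())

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.adjacency.copy())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        n = g.number_of_nodes()
        return cls.from_edges(n, g.edges())

    def to_csv(self, path) -> None:
        """Write the edge list as two-column CSV (tail, head; 0-based ids)."""
        with open(path, "w") as fh:
            fh.write("tail,head\n")
            for i, j in self.edges():
                fh.write(f"{i},{j}\n")

    @classmethod
    def from_csv(cls, path, N: int) -> "InteractionNetwork":
        edges = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                if line.strip():
                    i, j = line.strip().split(",")
                    edges.append((int(i), int(j)))
        return cls.from_edges(N, edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionNetwork) and np.array_equal(
            self.adjacency, other.adjacency
        )


def _er_adjacency(N: int, p_edge: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean adjacency of an Erdős–Rényi draw (vectorised)."""
    upper = np.triu(rng.random((N, N)) < p_edge, k=1)
    return upper | upper.T


def init_random_network(N: int, m: float, rng: np.random.Generator) -> InteractionNetwork:
    """Erdős–Rényi graph with edge probability ``m / (N - 1)``.

    The edge probability makes the expected mean degree exactly ``m``.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if not (1 <= m < N):
        raise ValueError(f"m must satisfy 1 <= m < N, got {m}")
    return InteractionNetwork(_er_adjacency(N, m / (N - 1), rng))


def rewire_random(params: SimulationParams, rng: np.random.Generator) -> InteractionNetwork:
    """Fresh, independent random network for the next period.

    Under random rewiring no network state carries over between periods;
    each period's graph is a new Erdős–Rényi draw with the same ``N`` and
    edge probability.
    """
    return init_random_network(params.N, params.m, rng)


def eligible_partners(
    agent: AgentState,
    network: InteractionNetwork,
    agents: Sequence[AgentState],
    params: SimulationParams,
    exclude: Iterable[int] = (),
) -> set[int]:
    """Candidate ids the agent may nominate as new partners.

    Excludes self, current neighbours and any id in ``exclude`` (the
    partner dropped this period — a replacement must be someone else).
    With ``r >= 1`` the pool is further restricted to candidates whose
    reputation over the last ``r`` periods is at least ``thetaC``
    (the unadjusted partner-choice threshold); candidates with no history
    are ineligible.
    """
    banned = set(exclude)
    banned.add(agent.agent_id)
    banned.update(network.neighbours(agent.agent_id))
    pool = {a.agent_id for a in agents if a.agent_id not in banned}
    if params.r >= 1:
        ok = set()
        for cid in pool:
            score = reputation_score(agents[cid], params.r)
            if score is not None and score >= params.thetaC:
                ok.add(cid)
        pool = ok
    return pool


def strategic_update_adjacency(
    adjacency: np.ndarray,
    last_actions: np.ndarray,
    reputation_ok: np.ndarray | None,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One strategic-updating step on an adjacency matrix.

    Order of events (all drops are simultaneous, computed from the input
    network; nominations see the post-drop network):

    1. each agent skips its whole update with probability ``gamma``;
    2. each non-skipping agent with at least one neighbour whose
       last-period executed action was defect drops exactly one such
       neighbour, chosen uniformly — a link dies if either endpoint drops
       it;
    3. each non-skipping agent nominates up to ``2m - degree`` candidates,
       uniformly without replacement, from its eligible pool (non-
       neighbours, excluding self, the just-dropped pair, and — when
       ``reputation_ok`` is given — candidates without an adequate
       reputation);
    4. links form for mutual nominations, processed in random order,
       skipping any formation that would push either endpoint above the
       degree cap ``2m``.

    Parameters
    ----------
    adjacency : (N, N) boolean symmetric matrix of the current network.
    last_actions : (N,) int array of last-period executed actions.
    reputation_ok : (N,) boolean mask of candidates meeting the
        reputation requirement, or ``None`` when ``r = 0`` (no filter).
    """
    N = adjacency.shape[0]
    cap = 2 * params.m

    skip = rng.random(N) < params.gamma

    # -- step 2: simultaneous drops ------------------------------------
    defecting_neighbour = adjacency & (last_actions == DEFECT)[None, :]
    dropper = defecting_neighbour.any(axis=1) & ~skip
    keys = rng.random((N, N))
    keys[~defecting_neighbour] = -1.0
    target = keys.argmax(axis=1)  # meaningful only where dropper is True

    adj = adjacency.copy()
    dropped_pair = np.zeros((N, N), dtype=bool)
    rows = np.nonzero(dropper)[0]
    cols = target[dropper]
    adj[rows, cols] = False
    adj[cols, rows] = False
    dropped_pair[rows, cols] = True
    dropped_pair[cols, rows] = True

    # -- step 3: nominations -------------------------------------------
    eligible = ~adj & ~dropped_pair
    np.fill_diagonal(eligible, False)
    if reputation_ok is not None:
        eligible &= reputation_ok[None, :]
    budget = np.maximum(0, cap - adj.sum(axis=1))
    budget[skip] = 0

    # Uniform sampling without replacement via random keys: each agent
    # nominates the candidates holding its `budget` smallest keys.  The
    # budget never exceeds the cap, so a partial partition suffices.
    nom_keys = rng.random((N, N))
    nom_keys[~eligible] = np.inf
    nominated = np.zeros((N, N), dtype=bool)
    kth = int(budget.max())
    if kth > 0:
        top = np.argpartition(nom_keys, kth - 1, axis=1)[:, :kth]
        top_keys = np.take_along_axis(nom_keys, top, axis=1)
        order = np.argsort(top_keys, axis=1)
        top_sorted = np.take_along_axis(top, order, axis=1)
        row_idx = np.repeat(np.arange(N), kth)
        col_idx = top_sorted.ravel()
        keep = (np.tile(np.arange(kth), N) < budget[row_idx]) & np.isfinite(
            nom_keys[row_idx, col_idx]
        )
        nominated[row_idx[keep], col_idx[keep]] = True

    # -- step 4: mutual consent under the degree cap -------------------
    mutual = nominated & nominated.T
    pairs = np.argwhere(mutual)
    pairs = pairs[pairs[:, 0] < pairs[:, 1]]
    if len(pairs):
        rng.shuffle(pairs, axis=0)
        degree = adj.sum(axis=1)
        for i, j in pairs:
            if degree[i] < cap and degree[j] < cap:
                adj[i, j] = adj[j, i] = True
                degree[i] += 1
                degree[j] += 1
    return adj


def strategic_update(
    network: InteractionNetwork,
    agents: Sequence[AgentState],
    params: SimulationParams,
    rng: np.random.Generator,
) -> InteractionNetwork:
    """Strategic-updating step on agent objects (see
    :func:`strategic_update_adjacency` for the event order).

    Requires at least one completed period: drops respond to last-period
    executed actions, and the reputation filter needs observable history.
    """
    if any(len(a.executed_actions) == 0 for a in agents):
        raise ValueError("strategic updating requires at least one completed period")
    last_actions = np.array([a.executed_actions[-1] for a in agents], dtype=np.int8)
    reputation_ok = None
    if params.r >= 1:
        reputation_ok = np.zeros(len(agents), dtype=bool)
        for idx, a in enumerate(agents):
            score = reputation_score(a, params.r)
            reputation_ok[idx] = score is not None and score >= params.thetaC
    adj = strategic_update_adjacency(
        network.adjacency, last_actions, reputation_ok, params, rng
    )
    return InteractionNetwork(adj)
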