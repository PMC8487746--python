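"""Inequality outcomes: payoff dispersion and payoff–behaviour correspondence.

*Dispersion* is the Gini coefficient of accumulated payoffs — 0 when all
agents earn the same, approaching 1 as payoffs concentrate on a single
agent (for a finite group the single-holder value is ``(n-1)/n``).

*Correspondence* is the Pearson correlation between each agent's
cooperation rate (fraction of periods executing cooperate) and its final
payoff: +1 means cooperation is always proportionally rewarded, -1 perfect
inverse proportionality.  When either input is constant the correlation is
undefined and reported as ``nan``; downstream aggregation excludes (never
zero-imputes) such values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["gini", "pearson_correspondence", "InequalityResult", "inequality_from_run"]


def gini(payoffs) -> float:
    """Gini coefficient of a vector of non-negative payoffs.

    Computed as the relative mean absolute difference
    ``sum_ij |x_i - x_j| / (2 n^2 mu)`` via the O(n log n) sorted form,
    without a small-sample correction.  Scale-invariant; the all-zero
    vector is defined as perfectly equal (0).

    Raises
    ------
    ValueError
        On negative values or fewer than two observations.
    """
    x = np.asarray(payoffs, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("gini requires a 1-d vector of at least 2 values")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        logger.info("gini of all-zero payoffs: defined as 0 (perfect equality)")
        return 0.0
    n = x.size
    xs = np.sort(x)
    # sum_ij |xi - xj| = 2 * sum_i (2i - n + 1) x_(i)  with 0-based i
    return float((2.0 * np.arange(1, n + 1) - n - 1.0) @ xs / (n * total))


def pearson_correspondence(coop_rates, payoffs) -> float:
    """Pearson correlation between cooperation rates and final payoffs.

    Returns ``nan`` (the undefined sentinel) when either vector has zero
    variance — e.g. a run where every agent cooperated in every period.
    """
    x = np.asarray(coop_rates, dtype=float)
    y = np.asarray(payoffs, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("pearson requires 1-d vectors of at least 2 values")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc @ yc) / (sx * sy))


@dataclass(frozen=True)
class InequalityResult:
    """Both inequality outcomes for one group of agents."""

    gini: float
    pearson: float  # nan when undefined
    n_agents: int


def inequality_from_run(result) -> InequalityResult:
    """Convenience: both outcomes from a :class:`~repnet.engine.SimulationResult`."""
    return InequalityResult(
        gini=gini(result.final_payoff),
        pearson=pearson_correspondence(result.cooperation_rate, result.final_payoff),
        n_agents=len(result.final_payoff),
    )
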