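"""Meta-analysis machinery: exact sign test and Mann–Whitney U test.

Group-level outcomes (one Gini and one Pearson value per network) are
compared between a no-reputation control condition and each reputation
treatment within an experiment.  Each control–treatment pair yields a
Mann–Whitney U test and an effect direction; directions are then pooled
across pairs with an exact binomial sign test against the null that
positive and negative effects are equally likely.  The sign test
deliberately ignores effect magnitudes and sample sizes: the question is
whether a causal effect exists, not how large it is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sign_test",
    "mann_whitney_u",
    "MannWhitneyResult",
    "PairResult",
    "MetaAnalysisResult",
    "compare_conditions",
    "OUTCOME_COLUMNS",
]

Alternative = Literal["two-sided", "greater", "less"]

#: Required columns of an outcome table (one row per network).
OUTCOME_COLUMNS = ("experiment", "condition", "network", "gini", "pearson")

#: Largest per-sample size for which the Mann–Whitney p-value is computed
#: by complete enumeration of rank assignments.
EXACT_ENUMERATION_MAX = 8


def sign_test(k: int, n: int, alternative: Alternative = "greater") -> float:
    """Exact binomial sign test with null success probability 1/2.

    ``k`` is the number of positive effect directions among ``n``
    control–treatment pairs.  One-sided ("greater"): ``P(X >= k)``;
    "less": ``P(X <= k)``; two-sided: twice the smaller tail, capped at 1
    (for the symmetric p = 1/2 null this coincides with the
    minimum-likelihood method).
    """
    k = int(k)
    n = int(n)
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n and n >= 1, got k={k}, n={n}")
    upper = float(stats.binom.sf(k - 1, n, 0.5))  # P(X >= k)
    lower = float(stats.binom.cdf(k, n, 0.5))  # P(X <= k)
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass(frozen=True)
class MannWhitneyResult:
    """U statistic for the first sample, its p-value and the method used."""

    u: float
    p: float
    method: Literal["exact", "normal"]
    n_x: int
    n_y: int


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Midranks (ties averaged), 1-based."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(x, y, alternative: Alternative = "two-sided") -> MannWhitneyResult:
    """Mann–Whitney U test of whether ``x`` tends to exceed ``y``.

    ``U`` counts the pairs with ``x_i > y_j`` plus half the tied pairs.
    The p-value is exact — computed by complete enumeration of all
    ``C(n+m, n)`` assignments of the pooled values (ties handled through
    midranks) — whenever both samples have at most
    ``EXACT_ENUMERATION_MAX`` observations; otherwise the normal
    approximation with tie and continuity corrections is used.  The
    method actually applied is reported on the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m_ = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if n <= EXACT_ENUMERATION_MAX and m_ <= EXACT_ENUMERATION_MAX:
        total = n + m_
        offset = n * (n + 1) / 2.0
        us = np.array(
            [sum(ranks[list(idx)]) - offset for idx in combinations(range(total), n)]
        )
        eps = 1e-9
        p_ge = float((us >= u_obs - eps).mean())
        p_le = float((us <= u_obs + eps).mean())
        method = "exact"
    else:
        mu = n * m_ / 2.0
        total = n + m_
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum()) / (total * (total - 1)))
        sigma2 = n * m_ / 12.0 * (total + 1 - tie_term)
        sigma = np.sqrt(sigma2)
        if sigma == 0.0:  # all values identical
            p_ge = p_le = 1.0
        else:
            p_ge = float(stats.norm.sf((u_obs - mu - 0.5) / sigma))
            p_le = float(stats.norm.cdf((u_obs - mu + 0.5) / sigma))
        method = "normal"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MannWhitneyResult(u=u_obs, p=p, method=method, n_x=n, n_y=m_)


@dataclass(frozen=True)
class PairResult:
    """One control–treatment comparison within an experiment."""

    experiment: str
    condition: str
    outcome: str
    control_summary: float
    treatment_summary: float
    direction: int  # sign(treatment - control) of the summary; 0 = tie
    u: float
    p: float
    method: str
    n_control: int
    n_treatment: int


@dataclass(frozen=True)
class MetaAnalysisResult:
    """Per-pair comparisons plus the pooled sign test."""

    outcome: str
    pairs: pd.DataFrame
    n_pairs: int  # pairs with a nonzero direction
    n_positive: int
    n_ties_dropped: int
    sign_test_p: float
    sign_test_alternative: str

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_pairs": self.n_pairs,
            "n_positive": self.n_positive,
            "n_ties_dropped": self.n_ties_dropped,
            "sign_test_p": self.sign_test_p,
            "sign_test_alternative": self.sign_test_alternative,
        }


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in OUTCOME_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"outcome table is missing columns: {missing}")
    dup = table.duplicated(subset=["experiment", "condition", "network"])
    if dup.any():
        raise ValueError("duplicate (experiment, condition, network) rows in outcome table")


def compare_conditions(
    table: pd.DataFrame,
    outcome: Literal["gini", "pearson"],
    control_label: str = "control",
    summary: Literal["median", "mean"] = "median",
    mw_alternative: Alternative = "two-sided",
    sign_alternative: Alternative = "greater",
) -> MetaAnalysisResult:
    """Compare every reputation treatment with its experiment's control.

    For each experiment, each non-control condition is paired with the
    control: the effect direction is the sign of (treatment summary −
    control summary) of the chosen outcome (medians by default, matching
    the rank-based pair test), and a Mann–Whitney U test compares the two
    sets of per-network values.  Directions are pooled across pairs with
    the exact sign test; zero differences are dropped from it (and
    counted).

    Rows with an undefined (NaN) outcome are excluded before comparison.

    Raises
    ------
    ValueError
        If the table is malformed or an experiment lacks the control
        condition.
    """
    _validate_table(table)
    summarise = np.median if summary == "median" else np.mean
    pair_rows: list[PairResult] = []
    for experiment, group in table.groupby("experiment", sort=True):
        conditions = group["condition"].unique()
        if control_label not in conditions:
            raise ValueError(f"experiment {experiment!r} has no {control_label!r} condition")
        control_vals = group.loc[
            group["condition"] == control_label, outcome
        ].dropna().to_numpy()
        for condition in sorted(c for c in conditions if c != control_label):
            treat_vals = group.loc[
                group["condition"] == condition, outcome
            ].dropna().to_numpy()
            if len(control_vals) == 0 or len(treat_vals) == 0:
                raise ValueError(
                    f"experiment {experiment!r}, condition {condition!r}: "
                    f"no defined {outcome} values to compare"
                )
            c_sum = float(summarise(control_vals))
            t_sum = float(summarise(treat_vals))
            mw = mann_whitney_u(treat_vals, control_vals, alternative=mw_alternative)
            pair_rows.append(
                PairResult(
                    experiment=str(experiment),
                    condition=str(condition),
                    outcome=outcome,
                    control_summary=c_sum,
                    treatment_summary=t_sum,
                    direction=int(np.sign(t_sum - c_sum)),
                    u=mw.u,
                    p=mw.p,
                    method=mw.method,
                    n_control=len(control_vals),
                    n_treatment=len(treat_vals),
                )
            )
    pairs = pd.DataFrame([vars(p) for p in pair_rows])
    directions = pairs["direction"].to_numpy()
    nonzero = directions[directions != 0]
    n_pos = int((nonzero > 0).sum())
    n_pairs = int(len(nonzero))
    if n_pairs == 0:
        p_val = 1.0
    else:
        p_val = sign_test(n_pos, n_pairs, alternative=sign_alternative)
    return MetaAnalysisResult(
        outcome=outcome,
        pairs=pairs,
        n_pairs=n_pairs,
        n_positive=n_pos,
        n_ties_dropped=int((directions == 0).sum()),
        sign_test_p=p_val,
        sign_test_alternative=sign_alternative,
    )
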