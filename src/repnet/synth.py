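"""Synthetic group-level experiment outcomes for the meta-analysis layer.

Laboratory network-cooperation experiments yield a handful of independent
networks per condition, each contributing one Gini and one Pearson value.
This module generates tables with that nesting (networks in conditions in
experiments) from a truncated-normal location-shift model, and can also
produce them end-to-end by running the agent-based simulator per
condition.  The generator emulates the *structure* of such experiment
collections — it does not reproduce any particular study's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import run_simulation
from .meta import OUTCOME_COLUMNS
from .model import SimulationParams, validate_params

__all__ = [
    "ConditionSpec",
    "ExperimentDesign",
    "generate_outcomes",
    "generate_collection",
    "default_experiment_collection",
    "generate_from_simulator",
]

_GINI_BOUNDS = (0.0, 1.0 - 1e-9)  # Gini of a finite nonneg vector is < 1
_PEARSON_BOUNDS = (-1.0, 1.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: its label, size and outcome shifts.

    Shifts are additive displacements of the condition's Gini and Pearson
    distributions relative to the experiment's control centres; the
    control condition itself uses zero shifts.
    """

    label: str
    n_networks: int
    gini_shift: float = 0.0
    pearson_shift: float = 0.0

    def __post_init__(self):
        if self.n_networks < 1:
            raise ValueError("each condition needs at least one network")


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one synthetic experiment.

    Per-network outcomes are drawn independently from truncated normals:
    Gini ~ TruncNormal(gini_center + shift, gini_sd) on [0, 1) and
    Pearson ~ TruncNormal(pearson_center + shift, pearson_sd) on [-1, 1].
    Between-network standard deviations model the noise of small-group
    experiments.
    """

    experiment: str
    conditions: Sequence[ConditionSpec]
    gini_center: float = 0.3
    pearson_center: float = 0.2
    gini_sd: float = 0.08
    pearson_sd: float = 0.25
    control_label: str = "control"

    def __post_init__(self):
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if self.control_label not in labels:
            raise ValueError(f"design needs a {self.control_label!r} condition")
        if len(labels) < 2:
            raise ValueError("design needs a control and at least one treatment")
        if self.gini_sd < 0 or self.pearson_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def _truncated_draws(
    loc: float, scale: float, bounds: tuple[float, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = bounds
    if scale == 0.0:
        return np.full(size, min(hi, max(lo, loc)))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_outcomes(design: ExperimentDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one outcome table (one row per network) for a single design."""
    rows = []
    for cond in design.conditions:
        g = _truncated_draws(
            design.gini_center + cond.gini_shift,
            design.gini_sd,
            _GINI_BOUNDS,
            cond.n_networks,
            rng,
        )
        p = _truncated_draws(
            design.pearson_center + cond.pearson_shift,
            design.pearson_sd,
            _PEARSON_BOUNDS,
            cond.n_networks,
            rng,
        )
        for k in range(cond.n_networks):
            rows.append(
                {
                    "experiment": design.experiment,
                    "condition": cond.label,
                    "network": k,
                    "gini": float(g[k]),
                    "pearson": float(p[k]),
                }
            )
    return pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS))


def generate_collection(
    designs: Sequence[ExperimentDesign], rng: np.random.Generator
) -> pd.DataFrame:
    """Concatenated outcome table over several experiment designs."""
    return pd.concat(
        [generate_outcomes(d, rng) for d in designs], ignore_index=True
    )


def default_experiment_collection(
    n_experiments: int = 8,
    n_networks: int = 8,
    gini_shift: float = -0.08,
    pearson_shift: float = 0.25,
    treatment_label: str = "reputation",
    **design_kwargs,
) -> list[ExperimentDesign]:
    """A collection of same-shaped designs at laboratory scale.

    Defaults mirror the magnitudes typical of published network
    cooperation experiments — a handful of experiments, 4–16 networks per
    condition — with a modest negative Gini shift and positive Pearson
    shift under reputation.
    """
    return [
        ExperimentDesign(
            experiment=f"SYNTH{i:02d}",
            conditions=(
                ConditionSpec("control", n_networks),
                ConditionSpec(treatment_label, n_networks, gini_shift, pearson_shift),
            ),
            **design_kwargs,
        )
        for i in range(n_experiments)
    ]


def generate_from_simulator(
    conditions: Mapping[str, SimulationParams],
    reps: int = 100,
    master_seed: int = 0,
    experiment: str = "ABM",
) -> pd.DataFrame:
    """Outcome table produced by running the simulator per condition.

    Each condition label maps to a full parameter record; ``reps``
    independent runs per condition each contribute one row (the run index
    serves as the network id), making the full pipeline — simulate,
    measure inequality, meta-analyse — a single call chain.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    rows = []
    for cond_idx, (label, params) in enumerate(conditions.items()):
        params = validate_params(params)
        cond_seq = np.random.SeedSequence(master_seed, spawn_key=(cond_idx,))
        for run_idx, child in enumerate(cond_seq.spawn(reps)):
            result = run_simulation(params, rng=np.random.default_rng(child))
            rows.append(
                {
                    "experiment": experiment,
                    "condition": label,
                    "network": run_idx,
                    "gini": result.gini(),
                    "pearson": result.pearson(),
                }
            )
    return pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS))
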