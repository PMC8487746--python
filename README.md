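# repnet

Reputation, cooperation and payoff inequality in repeated network games.

Reputation systems are known to raise cooperation in social dilemmas, but
how do they shape the *distribution* of the resulting payoffs?  `repnet`
implements an agent-based model to study two aspects of inequality in
repeated N-person Prisoner's Dilemma play on networks:

* **dispersion** — the Gini coefficient *G* of payoffs accumulated over
  *T* periods, and
* **correspondence** — the Pearson correlation *ρ* between an agent's
  cooperation rate and its final payoff (does behaving well pay?).

It is written for researchers in evolutionary game theory, social
dynamics and experimental economics who want to simulate
reputation-based partner choice, replicate heat-map style grid
experiments, or meta-analyse group-level outcomes from laboratory
network-cooperation experiments.

## The model

A population of *N* agents plays a repeated Prisoner's Dilemma
(per-interaction payoffs CC = 5, CD = 0, DC = 8, DD = 2, averaged over a
period's partners) on a network with average degree *m*.  Agents hold
fixed strategies: a fraction *p*<sub>A</sub> are persistent altruists
(always cooperate), *p*<sub>D</sub> persistent defectors (never), and
*p*<sub>R</sub> = 1 − *p*<sub>A</sub> − *p*<sub>D</sub> conditional
cooperators, who cooperate initially with probability
θ₀ + *a*₀·*r* and afterwards reciprocate: cooperate iff the average
cooperation of their observable partners over the last max(*r*, 1)
periods is at least θ<sub>C</sub> − *a*<sub>C</sub>·*r*.

*r* is the **reputation window** — how many past periods of everyone's
executed actions are public.  With *r* = 0 an agent knows only what its
own last-period partners did to it; with *r* ≥ 1 it can also evaluate
strangers.  Actions are executed with a small error ε and networks are
updated in one of two regimes:

* **random rewiring** — a fresh Erdős–Rényi graph every period
  (speed-dating, rotating teams), and
* **strategic updating** — each period an agent may drop one defecting
  neighbour and nominate replacements; links form by mutual consent,
  under a degree cap of 2*m*, with an omission error γ.  With *r* ≥ 1,
  agents nominate only candidates whose reputation reaches
  θ<sub>C</sub>.

On top of the simulator sit the two inequality metrics and the
meta-analysis layer used to pool laboratory experiments: a Mann–Whitney
U test per control–treatment pair (exact by complete enumeration for
small samples) and an exact binomial sign test over effect directions
across pairs.

## Worked example

```python
import numpy as np
from repnet import validate_params, run_simulation, generate_from_simulator, compare_conditions

params = validate_params(dict(p_A=0.1, p_D=0.1, r=1, mode="strategic_updating", seed=1))
res = run_simulation(params)
print(round(res.gini(), 3), round(res.pearson(), 3), round(res.cooperation_level.mean(), 3))
# 0.352 0.988 0.65

table = generate_from_simulator(
    {"control": params.with_updates(r=0, mode="random_rewiring"),
     "reputation": params.with_updates(r=1, mode="random_rewiring")},
    reps=100, master_seed=5)
meta = compare_conditions(table, "gini")
print(meta.pairs[["control_summary", "treatment_summary", "direction"]].round(4))
```

The single strategic-updating run with a one-period reputation window
ends with payoff Gini ≈ 0.35 (defectors are isolated and earn little,
widening dispersion), Pearson ≈ 0.99 (payoffs track cooperative
behaviour closely) and a mean cooperation level of ≈ 0.65.  The
`generate_from_simulator` call then runs 100 independent simulations per
condition under random rewiring and feeds them to the meta-analysis:
the treatment median Gini (0.044) falls below the control median
(0.076, `direction == -1`), i.e. reputation *reduces* dispersion when
partners are randomly re-matched.

The same pipeline works from the shell:

```bash
repnet run --p-a 0.1 --p-d 0.1 --r 1 --mode strategic_updating --seed 1
repnet sweep --reps 100 --seed 42 --out sweep.csv
repnet synth --experiments 8 --networks 8 --seed 2 --out outcomes.csv
repnet meta outcomes.csv --outcome gini --sign-alternative less
```

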