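# Methods

This note documents the model implemented in `repnet`, the conventions
and numerical choices the implementation had to fix where the verbal
model description leaves latitude, the synthetic-data generators, and
the problem sizes used by the test suite and the reproduction script.

## The agent-based model

### Population and game

`N` agents (default 100) play a repeated N-person Prisoner's Dilemma for
`T` periods (default 100).  Per-interaction payoffs default to CC = 5,
CD = 0, DC = 8, DD = 2 (game units); each period an agent's payoff is the
*average* dyadic payoff over its current partners, so payoffs do not
scale with degree.  An isolated agent earns 0 for the period — the empty
average is taken as "no interactions, nothing earned", which also makes
exclusion costly, the economically meaningful convention for a model in
which defectors can end up cut off.  Final payoff is the *sum* of the
per-period averages.

Strategies are fixed for a run: a fraction `p_A` of persistent altruists
(always cooperate), `p_D` of persistent defectors (never), the rest
conditional cooperators.  Deterministic composition makes grid cells
comparable across runs, so fractions are converted to counts by
cumulative rounding — `n_A = round(N·p_A)`, `n_A + n_D =
round(N·(p_A+p_D))` — which cannot overflow `N`; the labels are then
randomly permuted over agent indices.

### Decision rule of conditional cooperators

A conditional cooperator cooperates in period 0 with probability
`clamp(θ₀ + a₀·r)` and in later periods iff its *neighbour cooperation
score* is at least `clamp(θ_C − a_C·r)`, with ties cooperating ("at
least").  The score is the mean, over the observable partners, of each
partner's fraction of executed cooperation over the last
`min(max(r, 1), elapsed)` periods.  `clamp` truncates to [0, 1]; at the
default parameter values it is inert.

Which partners are *observable* is the crux of the model and the channel
through which the reputation window acts:

* `r = 0` — no public information.  An agent knows only what it directly
  experienced: the actions its **previous-period partners** took.  Its
  reaction is therefore aimed at whoever it meets *now* — after random
  rewiring, typically innocent strangers.  Defection goes unpunished in
  its own dyad, cooperation unrewarded.
* `r ≥ 1` — everyone's executed actions over the last `r` periods are
  public, so the agent scores its **current partners**.  Retaliation and
  reciprocation now land on the agents that earned them.

This asymmetry is deliberate and load-bearing.  An alternative reading —
scoring current partners' histories even at `r = 0` — makes the `r = 0`
and `r = 1` rules nearly indistinguishable under random rewiring (their
decision thresholds differ only by `a_C`, and with period-1 windows the
achievable score grid rarely falls between the two thresholds), and the
regime contrast the model exists to study collapses; we verified this
empirically before fixing the information structure above.  It would
also grant agents knowledge of what strangers did in interactions they
never observed, which is precisely what reputation is for.

Behavioural parameters default to θ_C = 0.5, a₀ = 0.1, a_C = 0.05, and
θ₀ = `p_A` — the propensity to cooperate with a stranger equals the
probability that a random stranger is an unconditional cooperator.  The
stated open-interval bounds on θ₀, θ_C, a₀, a_C are admitted at the
endpoints so that θ₀ = p_A stays valid at p_A = 0 and the reputation
effects can be switched off.

Reputations and reciprocation are computed from **executed** actions:
with probability ε (default 0.005) the executed action is the opposite
of the intended one, and observers can only see what was done.
Altruists' and defectors' realized cooperation rates are therefore
`1 − ε` and `ε` in expectation.

Degenerate inputs: an isolated conditional cooperator (or one whose
observable partners have no recorded history, possible just after
rewiring) repeats the period-0 draw with probability `clamp(θ₀ + a₀·r)`
each period rather than freezing on an arbitrary absorbing action.

### Network regimes

The initial graph is Erdős–Rényi with edge probability `m/(N−1)`
(expected mean degree `m`, default 2; Poisson-like degrees, low
clustering).

**Random rewiring** draws a completely fresh graph every period.

**Strategic updating** runs, each period after payoffs:

1. each agent skips its entire update with probability γ (default
   0.005);
2. every non-skipping agent with at least one neighbour whose
   last-period executed action was defect drops exactly one such
   neighbour, uniformly at random; drops are simultaneous (computed on
   the pre-update graph) and unilateral (a link dies if either side
   drops it);
3. every non-skipping agent nominates up to `2m − degree` candidates,
   uniformly without replacement, from its eligible pool: non-neighbours
   other than itself and the partner in a just-dropped pair (a
   replacement must be someone else, for this period only).  With
   `r ≥ 1` the pool is restricted to candidates whose reputation over
   the last `min(r, elapsed)` periods reaches the *unadjusted* θ_C — the
   partner-selection threshold is not reputation-adjusted — and
   candidates with no observable history are ineligible (they cannot
   demonstrate the required record);
4. mutual nominations become links, processed in a random order
   (avoiding positional bias), skipping any formation that would push
   either endpoint above the degree cap `2m`.

The cap is enforced on formation only: an initial random graph may
contain nodes above `2m`, and updates never raise any degree beyond the
cap (nor above its pre-update value).  No update happens after the final
period.

### Outcomes

Per run: each agent's cooperation rate (fraction of `T` periods
executing cooperate) and final payoff; the per-period population
cooperation level; the Gini coefficient of final payoffs; and the
Pearson correlation between cooperation rate and final payoff.

The Gini is the plain relative mean absolute difference
`Σᵢⱼ|xᵢ−xⱼ| / (2n²μ)`, computed via the O(n log n) sorted form without a
small-sample correction: it is 0 for equal payoffs, and `(n−1)/n` — the
finite-n version of the idealized "1" — when a single agent holds
everything.  The all-zero vector is defined as perfectly equal.  The
Pearson correlation is undefined when either vector is constant (e.g.
universal cooperation); such runs are reported as NaN and *excluded* from
sweep-cell means, with the exclusion count reported — imputing zeros
would bias cells where behaviour is homogeneous.

### Sweeps and reproducibility

`run_sweep` executes a grid of (p_D, p_A) cells × (r, mode) conditions
with `reps` independent runs per combination.  The default grid spans
p_D, p_A ∈ {0, 0.1, …, 0.5} (36 simplex-feasible cells) — the heat-map
axis ranges are not fixed by the published figure, so the grid is
configurable and this default is an assumption.  Under the default
protocol θ₀ follows each cell's `p_A`.

Randomness is contractual: every stochastic operation draws only from
the generator passed to it; sweeps derive one `SeedSequence` substream
per (cell, condition, replicate) from the master seed, so results are
bit-identical for a fixed seed and iteration order.

## Meta-analysis layer

Laboratory analogues of the model yield a few independent networks per
condition, each reduced to one Gini and one Pearson value.
`compare_conditions` pairs every reputation treatment with its
experiment's no-reputation control, computes the effect direction as the
sign of the difference in *medians* (consistent with the rank-based pair
test; means are available as an option), runs a Mann–Whitney U test per
pair, and pools directions across pairs with an exact binomial sign test
(null: positive and negative effects equally likely).  Zero direction
differences are dropped from the sign test and counted, per standard
practice.  Two-sided p-values double the smaller tail, capped at 1.

The Mann–Whitney p-value is exact — complete enumeration of all
`C(n+m, n)` rank assignments, ties handled through midranks — whenever
both samples have ≤ 8 observations (the largest pair then enumerates
12 870 splits, still instantaneous); larger samples use the normal
approximation with tie and continuity corrections.  The result object
reports which method was used.

## Synthetic experiment generator

`synth` generates outcome tables with the nesting of real experiment
collections (networks in conditions in experiments) from a truncated
normal location-shift model: control networks draw Gini ~
TN(g₀, σ_g) on [0, 1) and Pearson ~ TN(ρ₀, σ_ρ) on [−1, 1]; treatments
shift the locations by (Δg, Δρ).  No distributional form for
between-network variation is dictated by the problem, so the minimal
(truncated-normal) choice is used and fully config-exposed.  Default
sizes — 8 experiments, 8 networks per condition, network-level noise
σ_g = 0.08, σ_ρ = 0.25 — mirror the orders of magnitude of published
network-cooperation experiments (4–16 networks per condition) without
reproducing any study.  `generate_from_simulator` instead runs the ABM
per condition, one table row per run.

What the generator does *not* emulate: game-specific payoff scales
(irrelevant to the scale-invariant Gini), participant learning,
within-network dependence beyond what a single (Gini, Pearson) pair
captures, and unequal network sizes within a condition.  Tests passing
on synthetic tables therefore validate the *statistical machinery*, not
any empirical claim about the original experiments.

## Problem sizes in the tests and the reproduction script

The heat-map experiment is run at 100 replicates per cell × condition
(full-scale runs: N = 100, T = 100) — enough to resolve the qualitative
cell-level contrasts (Monte-Carlo standard error of a cell's mean Gini
≈ 0.01) while keeping the sweep to minutes on one CPU; 1000-replicate
cell means agree with 100-replicate means within Monte-Carlo error.
Directional single-cell checks use 200 replicates per arm.  Null
calibration of the sign-test pipeline uses 1000 generator seeds.  In
the corner of the grid where persistent altruists dominate, the
reputation effect on strategic-updating Gini is zero at this
Monte-Carlo resolution; the test suite asserts an order-of-magnitude
separation from the defector-corner effect rather than a sign that
noise can flip.

## Known limitations

* The model is a heuristic caricature: strategies never evolve, there
  are exactly three types, and agents have no memory of partner
  identity beyond the reputation window.
* The two-sided sign-test convention (doubled smaller tail) is one of
  several; conventions differ in how they treat the mid-point mass of
  discrete distributions.
* Strategic updating drops exactly one defecting neighbour per period —
  agents with several defecting partners keep the rest until later
  periods.
* The degree cap makes the strategic regime symmetric and
  degree-constrained; buyer–seller style preferential attachment is out
  of scope.
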