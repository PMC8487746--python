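"""Parameter validation and per-agent decision rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repnet import model
from repnet.model import (
    COOPERATE,
    DEFECT,
    AgentState,
    SimulationParams,
    apply_execution_error,
    apply_execution_errors,
    assign_strategies,
    choose_action,
    choose_actions,
    initial_cooperation_probability,
    reciprocation_threshold,
    reputation_score,
    strategy_counts,
    validate_params,
)

C, D = COOPERATE, DEFECT


class TestValidateParams:
    def test_derives_conditional_fraction(self):
        p = validate_params(dict(p_A=0.2, p_D=0.3))
        assert p.p_R == pytest.approx(0.5)

    def test_default_protocol_accepted(self):
        p = validate_params(dict(p_A=0.1, p_D=0.2))
        assert (p.N, p.m, p.T) == (100, 2, 100)
        assert (p.thetaC, p.a0, p.aC) == (0.5, 0.1, 0.05)
        assert p.epsilon == p.gamma == 0.005
        assert (p.payoff_cc, p.payoff_cd, p.payoff_dc, p.payoff_dd) == (5, 0, 8, 2)

    def test_theta0_defaults_to_altruist_fraction(self):
        assert validate_params(dict(p_A=0.3, p_D=0.1)).theta0 == pytest.approx(0.3)
        assert validate_params(dict(p_A=0.3, p_D=0.1, theta0=0.7)).theta0 == 0.7

    @pytest.mark.parametrize(
        "bad",
        [
            dict(p_A=0.7, p_D=0.5),  # fractions exceed one
            dict(p_A=-0.1, p_D=0.1),
            dict(N=1),
            dict(N=10, m=10),
            dict(N=10, m=0),
            dict(T=0),
            dict(r=-1),
            dict(epsilon=1.5),
            dict(thetaC=1.2),
            dict(mode="nonsense"),
        ],
    )
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            validate_params(bad)

    def test_with_updates_revalidates(self):
        p = validate_params(dict(p_A=0.2, p_D=0.2))
        q = p.with_updates(p_D=0.5)
        assert q.p_R == pytest.approx(0.3)
        with pytest.raises(ValueError):
            p.with_updates(p_D=0.9)


class TestStrategyAssignment:
    @pytest.mark.parametrize(
        "N,p_A,p_D,expected",
        [
            (100, 0.1, 0.2, (10, 20, 70)),
            (100, 0.0, 0.0, (0, 0, 100)),
            (100, 0.5, 0.5, (50, 50, 0)),
        ],
    )
    def test_exact_multiples(self, N, p_A, p_D, expected):
        p = validate_params(dict(N=N, p_A=p_A, p_D=p_D))
        assert strategy_counts(p) == expected

    def test_cumulative_rounding_on_half_counts(self):
        # N=10 with both fractions 0.25 cannot be split exactly; the
        # cumulative rounding rule resolves it deterministically.
        p = validate_params(dict(N=10, p_A=0.25, p_D=0.25))
        counts = strategy_counts(p)
        assert counts in {(3, 2, 5), (2, 3, 5)}
        assert sum(counts) == 10

    def test_counts_always_sum_to_N(self):
        for N in (7, 10, 53, 100):
            for p_A in np.linspace(0, 1, 11):
                for p_D in np.linspace(0, 1 - p_A, 7):
                    p = validate_params(dict(N=N, p_A=float(p_A), p_D=float(p_D)))
                    counts = strategy_counts(p)
                    assert sum(counts) == N
                    assert all(c >= 0 for c in counts)

    def test_assignment_is_permutation(self, rng):
        p = validate_params(dict(N=50, p_A=0.2, p_D=0.4))
        agents = assign_strategies(p, rng)
        assert [a.agent_id for a in agents] == list(range(50))
        names = [a.strategy_name for a in agents]
        assert names.count("altruist") == 10
        assert names.count("defector") == 20
        assert names.count("conditional") == 20

    def test_assignment_deterministic_given_seed(self):
        p = validate_params(dict(N=40, p_A=0.3, p_D=0.3))
        a1 = assign_strategies(p, np.random.default_rng(5))
        a2 = assign_strategies(p, np.random.default_rng(5))
        assert [x.strategy for x in a1] == [x.strategy for x in a2]


class TestReputationScore:
    def make_agent(self, actions):
        return AgentState(agent_id=0, strategy=model.CONDITIONAL, executed_actions=list(actions))

    @pytest.mark.parametrize(
        "actions,r,expected",
        [([C, D, C, C], 2, 1.0), ([C, D, C, C], 4, 0.75), ([C, D, C, C], 10, 0.75), ([D], 1, 0.0)],
    )
    def test_window_average(self, actions, r, expected):
        assert reputation_score(self.make_agent(actions), r) == pytest.approx(expected)

    def test_no_history_sentinel(self):
        assert reputation_score(self.make_agent([]), 3) is None

    def test_zero_window_is_misuse(self):
        with pytest.raises(ValueError):
            reputation_score(self.make_agent([C]), 0)

    @given(st.lists(st.sampled_from([C, D]), min_size=1, max_size=30), st.integers(1, 40))
    @settings(deadline=None)
    def test_score_is_mean_of_trailing_window(self, actions, r):
        score = reputation_score(self.make_agent(actions), r)
        window = actions[-r:]
        assert score == pytest.approx(sum(window) / len(window))


class TestChooseAction:
    def conditional(self, aid=0):
        return AgentState(agent_id=aid, strategy=model.CONDITIONAL)

    def neighbours_with_last(self, last_actions):
        return [
            AgentState(agent_id=i + 1, strategy=model.CONDITIONAL, executed_actions=[a])
            for i, a in enumerate(last_actions)
        ]

    def test_fixed_types_ignore_context(self, rng):
        p = validate_params(dict(p_A=0.1, p_D=0.1))
        altruist = AgentState(agent_id=0, strategy=model.ALTRUIST)
        defector = AgentState(agent_id=1, strategy=model.DEFECTOR)
        nbs = self.neighbours_with_last([D, D, D])
        for period in (0, 5):
            assert choose_action(altruist, nbs, p, period, rng) == C
            assert choose_action(defector, nbs, p, period, rng) == D

    @pytest.mark.parametrize(
        "last,expected",
        [([C, C, C, D], C), ([C, D, D, D], D), ([C, C, D, D], C)],  # ties cooperate
    )
    def test_threshold_rule_last_period(self, last, expected, rng):
        p = validate_params(dict(p_A=0.1, p_D=0.1, r=0, thetaC=0.5))
        got = choose_action(self.conditional(), self.neighbours_with_last(last), p, 1, rng)
        assert got == expected

    def test_reputation_lowers_threshold(self, rng):
        # 1 of 4 cooperating fails thetaC=0.5 at r=0 but passes the
        # adjusted threshold once a long window lowers it enough.
        nbs = self.neighbours_with_last([C, D, D, D])
        p_low = validate_params(dict(p_A=0.1, p_D=0.1, r=0, thetaC=0.3, aC=0.05))
        p_rep = validate_params(dict(p_A=0.1, p_D=0.1, r=1, thetaC=0.3, aC=0.05))
        assert choose_action(self.conditional(), nbs, p_low, 1, rng) == D
        assert choose_action(self.conditional(), nbs, p_rep, 1, rng) == C

    def test_period_zero_draw_extremes(self, rng):
        always = validate_params(dict(p_A=0.0, p_D=0.0, theta0=1.0))
        never = validate_params(dict(p_A=0.0, p_D=0.0, theta0=0.0, a0=0.0))
        nbs = []
        assert choose_action(self.conditional(), nbs, always, 0, rng) == C
        assert choose_action(self.conditional(), nbs, never, 0, rng) == D

    def test_isolate_repeats_initial_draw(self, rng):
        p = validate_params(dict(p_A=0.0, p_D=0.0, theta0=1.0))
        assert choose_action(self.conditional(), [], p, period=7, rng=rng) == C

    def test_neighbour_permutation_invariance(self, rng):
        p = validate_params(dict(p_A=0.1, p_D=0.1, r=0))
        nbs = self.neighbours_with_last([C, C, D, D, C])
        perm = [nbs[i] for i in [4, 2, 0, 3, 1]]
        a = self.conditional()
        assert choose_action(a, nbs, p, 1, rng) == choose_action(a, perm, p, 1, rng)

    @given(st.integers(0, 10), st.integers(0, 10))
    @settings(deadline=None)
    def test_reputation_monotonicity(self, r1, r2):
        """A longer window never lowers the initial cooperation probability
        and never raises the reciprocation threshold."""
        lo, hi = sorted((r1, r2))
        base = dict(p_A=0.2, p_D=0.1, thetaC=0.5, a0=0.1, aC=0.05)
        p_lo = validate_params(dict(base, r=lo))
        p_hi = validate_params(dict(base, r=hi))
        assert initial_cooperation_probability(p_hi) >= initial_cooperation_probability(p_lo)
        assert reciprocation_threshold(p_hi) <= reciprocation_threshold(p_lo)
        assert 0.0 <= initial_cooperation_probability(p_hi) <= 1.0
        assert 0.0 <= reciprocation_threshold(p_hi) <= 1.0


class TestExecutionError:
    def test_no_error_limit(self, rng):
        assert apply_execution_error(C, 0.0, rng) == C
        assert apply_execution_error(D, 0.0, rng) == D

    def test_certain_flip_limit(self, rng):
        assert apply_execution_error(C, 1.0, rng) == D
        assert apply_execution_error(D, 1.0, rng) == C

    def test_flip_frequency_matches_binomial(self, rng):
        n = 1_000_000
        intended = np.full(n, C, dtype=np.int8)
        executed = apply_execution_errors(intended, 0.005, rng)
        freq = (executed != intended).mean()
        tol = 3 * np.sqrt(0.005 * 0.995 / n)
        assert abs(freq - 0.005) <= tol


class TestVectorisedConsistency:
    def test_choose_actions_matches_per_agent_rule(self, rng):
        """The array path and the per-agent rule agree wherever the
        decision is deterministic (period >= 1, connected agents)."""
        N, t = 12, 4
        strategies = np.array([0, 1, 2] * 4, dtype=np.int8)
        executed = (np.random.default_rng(3).random((N, t)) < 0.6).astype(np.int8)
        adj = np.zeros((N, N), dtype=bool)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (2, 5), (5, 6), (6, 7), (8, 9), (10, 11), (2, 9)]
        for i, j in edges:
            adj[i, j] = adj[j, i] = True
        p = validate_params(dict(N=N, m=2, p_A=0.2, p_D=0.2, r=1, thetaC=0.5))

        vec = choose_actions(strategies, executed, adj, p, period=t, rng=np.random.default_rng(0))
        agents = [
            model.AgentState(agent_id=i, strategy=int(strategies[i]),
                             executed_actions=list(executed[i]))
            for i in range(N)
        ]
        for i in range(N):
            if strategies[i] == model.CONDITIONAL and adj[i].sum() == 0:
                continue  # isolates draw at random
            nbs = [agents[j] for j in np.nonzero(adj[i])[0]]
            assert vec[i] == choose_action(agents[i], nbs, p, t, np.random.default_rng(0))
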