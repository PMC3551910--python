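import numpy as np
import pytest
from scipy import special

from dotpomdp import (
    ABSORBING,
    GO_LEFT,
    GO_RIGHT,
    SAMPLE,
    BeliefState,
    PriorParams,
    RewardParams,
    belief_transition,
    expected_reward,
    fit_hyperbolic_boundary,
    predictive_obs_prob,
    solve,
)

UNIFORM = PriorParams(1.0, 1.0)


def tree_value(rewards: RewardParams, prior: PriorParams, horizon: int):
    """Independent brute-force oracle: expectimax over the full depth-T
    decision tree of single-spike observation histories (no lattice
    bookkeeping, no memoization).  Returns (root value, action lookup by
    (t, n_right))."""

    def terminal(a, b):
        below = special.betainc(a, b, 0.5)
        above = special.betainc(b, a, 0.5)
        qr = rewards.reward_correct * above + rewards.reward_error * below
        ql = rewards.reward_correct * below + rewards.reward_error * above
        return qr, ql

    actions = {}

    def go(n_r, n_l, t):
        a = prior.alpha0 + n_r
        b = prior.beta0 + n_l
        qr, ql = terminal(a, b)
        q_term = max(qr, ql)
        a_term = GO_RIGHT if qr >= ql else GO_LEFT
        if t == horizon:
            actions[(t, n_r)] = a_term
            return q_term
        p1 = a / (a + b)
        qs = (
            rewards.sample_cost
            + p1 * go(n_r + 1, n_l, t + 1)
            + (1 - p1) * go(n_r, n_l + 1, t + 1)
        )
        if qs >= q_term:
            actions[(t, n_r)] = SAMPLE
            return qs
        actions[(t, n_r)] = a_term
        return q_term

    root = go(0, 0, 0)
    return root, actions


class TestPredictive:
    def test_uniform_prior_single_spike(self):
        assert predictive_obs_prob(BeliefState(1, 1), 1, 1) == pytest.approx(0.5)

    def test_beta_binomial_mean(self):
        assert predictive_obs_prob(BeliefState(2, 1), 1, 1) == pytest.approx(2 / 3)

    def test_uniform_prior_is_uniform_over_counts(self):
        probs = predictive_obs_prob(BeliefState(1, 1), np.arange(3), 2)
        assert probs == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    @pytest.mark.parametrize("ab, n", [((1, 1), 1), ((3, 5), 4), ((2.5, 1.5), 6)])
    def test_normalized(self, ab, n):
        probs = predictive_obs_prob(BeliefState(*ab), np.arange(n + 1), n)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            predictive_obs_prob(BeliefState(1, 1), 3, 2)


class TestExpectedReward:
    def test_symmetric_posterior_zero(self):
        r = RewardParams(sample_cost=-1, reward_correct=10, reward_error=-10)
        assert expected_reward(BeliefState(1, 1), GO_RIGHT, r, 1) == pytest.approx(0.0)

    def test_uses_direction_posterior(self):
        r = RewardParams(sample_cost=-1, reward_correct=1, reward_error=0)
        assert expected_reward(BeliefState(2, 1), GO_RIGHT, r, 1) == pytest.approx(0.75)

    def test_sampling_cost_is_belief_independent(self):
        r = RewardParams(sample_cost=-0.01, reward_correct=1, reward_error=0)
        for ab in [(1, 1), (5, 2), (1, 9)]:
            assert expected_reward(BeliefState(*ab), SAMPLE, r, 1) == -0.01

    def test_left_right_complementarity(self):
        r = RewardParams(sample_cost=-1, reward_correct=7, reward_error=-3)
        b = BeliefState(4, 2)
        total = expected_reward(b, GO_RIGHT, r, 1) + expected_reward(b, GO_LEFT, r, 1)
        assert total == pytest.approx(r.reward_correct + r.reward_error, abs=1e-12)

    def test_unknown_action(self):
        with pytest.raises(ValueError):
            expected_reward(BeliefState(1, 1), 42, RewardParams(), 1)


class TestBeliefTransition:
    def test_uniform_predictive_split(self):
        succ = belief_transition(BeliefState(1, 1), SAMPLE, 1)
        assert succ[BeliefState(2, 1)] == pytest.approx(0.5)
        assert succ[BeliefState(1, 2)] == pytest.approx(0.5)

    def test_terminal_actions_absorb(self):
        for a in (GO_RIGHT, GO_LEFT):
            assert belief_transition(BeliefState(3, 2), a, 1) == {ABSORBING: 1.0}

    @pytest.mark.parametrize("ab", [(1, 1), (4, 2), (2, 7)])
    def test_one_n2_step_equals_two_chained_n1_steps(self, ab):
        """The paper-level granularity equivalence that *is* exact: one
        two-spike predictive step equals two chained single-spike steps
        marginalized over the intermediate belief."""
        b = BeliefState(*ab)
        direct = belief_transition(b, SAMPLE, 2)
        composed: dict = {}
        for b1, p1 in belief_transition(b, SAMPLE, 1).items():
            for b2, p2 in belief_transition(b1, SAMPLE, 1).items():
                composed[b2] = composed.get(b2, 0.0) + p1 * p2
        assert set(direct) == set(composed)
        for succ, prob in direct.items():
            assert prob == pytest.approx(composed[succ], abs=1e-12)


class TestSolve:
    @pytest.mark.parametrize("horizon", [1, 2, 3, 4])
    def test_matches_brute_force_tree(self, horizon):
        r = RewardParams(sample_cost=-1.0, reward_correct=30.0, reward_error=-5.0)
        sol = solve(r, UNIFORM, n=1, horizon=horizon, check_stationarity=False)
        root, actions = tree_value(r, UNIFORM, horizon)
        assert sol.root_value == pytest.approx(root, abs=1e-12)
        for (t, n_r), act in actions.items():
            assert sol.action_at(t, n_r) == act

    def test_immediate_decision_when_sampling_cannot_pay(self):
        r = RewardParams(sample_cost=-1.5, reward_correct=1.0, reward_error=0.0)
        sol = solve(r, UNIFORM, n=1, horizon=3, check_stationarity=False)
        assert sol.action_at(0, 0) in (GO_RIGHT, GO_LEFT)
        root, actions = tree_value(r, UNIFORM, 3)
        assert actions[(0, 0)] != SAMPLE
        assert sol.root_value == pytest.approx(root, abs=1e-12)

    def test_value_mirror_symmetry_is_bit_exact(self, fast_sol):
        for t in range(0, fast_sol.horizon + 1, 7):
            v = fast_sol.value[t]
            assert np.array_equal(v, v[::-1])

    def test_short_horizon_reports_unconverged(self):
        sol = solve(RewardParams(), UNIFORM, n=1, horizon=50)
        assert not sol.converged

    def test_reward_validation(self):
        with pytest.raises(ValueError):
            RewardParams(sample_cost=1.0)
        with pytest.raises(ValueError):
            RewardParams(reward_correct=-2.0)
        with pytest.raises(ValueError):
            RewardParams(reward_error=0.5)

    def test_boundary_widens_with_reward(self):
        """Raising the correct-choice reward never shrinks the sampling
        region at any time slice."""
        lo = solve(RewardParams(reward_correct=60), UNIFORM, 1, 150,
                   check_stationarity=False)
        hi = solve(RewardParams(reward_correct=120), UNIFORM, 1, 150,
                   check_stationarity=False)
        for t in range(120):
            assert np.all(hi.sampling_mask(t) >= lo.sampling_mask(t))


class TestBoundaries:
    def test_shape_and_range(self, fast_sol):
        theta = fast_sol.theta_right
        defined = np.isfinite(theta)
        assert defined.sum() >= 5
        assert np.all(theta[defined] >= 0.5)
        assert np.all(theta[defined] <= 1.0)
        # strictly above 1/2 while the bound is still collapsing
        first = np.flatnonzero(defined)[0]
        assert np.all(theta[first : first + 10] > 0.5)

    def test_left_is_mirror_of_right(self, fast_sol):
        """theta_L = 1 - theta_R up to at most one lattice cell (the exact
        center cell can be claimed by the rightward region at value ties)."""
        theta_r, theta_l = fast_sol.theta_right, fast_sol.theta_left
        defined = np.isfinite(theta_r)
        assert np.array_equal(defined, np.isfinite(theta_l))
        t = np.flatnonzero(defined)
        cell = 1.0 / np.maximum(t, 1)
        gap = np.abs(theta_l[defined] - (1.0 - theta_r[defined]))
        assert np.all(gap <= cell + 1e-12)

    def test_collapsing_on_default_config(self, default_sol):
        """The bound collapses from 1 toward 1/2.  On the integer lattice
        the ratio n_min(t)/t may tick up by less than one cell width when
        n_min increments, so monotonicity is asserted at cell resolution:
        the running minimum is never exceeded by a full lattice cell."""
        theta = default_sol.theta_right
        t_def = np.flatnonzero(np.isfinite(theta))
        th = theta[t_def]
        running_min = np.minimum.accumulate(th)
        assert np.all(th - running_min <= 1.0 / t_def + 1e-12)
        assert th[0] == 1.0
        assert th[-1] == pytest.approx(0.5, abs=1e-12)
        # the cell-count edge of the rightward region never moves down
        n_min = np.rint(th * t_def)
        assert np.all(np.diff(n_min) >= 0)

    def test_n_granularity_boundary_within_one_cell(self, fast_sol):
        """The exact granularity equivalence holds for transitions; for the
        policy it holds to within one lattice cell: the five-spike solution's
        terminal regions never differ from the single-spike solution's by
        more than one cell at matching spike counts."""
        sol5 = solve(RewardParams(reward_correct=100.0), UNIFORM, n=5, horizon=30)
        assert sol5.converged
        for t5 in range(30):
            a5 = sol5.action[t5]
            a1 = fast_sol.action[5 * t5]
            assert np.sum(a5 != a1) <= 2  # at most one boundary cell per side


class TestHyperbolicFit:
    def test_round_trip(self):
        t = np.arange(1, 200)
        theta = 0.5 + 0.4 * 30.0 / (t + 30.0)
        fit = fit_hyperbolic_boundary(t, theta)
        assert fit.ok
        assert fit.amplitude == pytest.approx(0.4, rel=1e-2)
        assert fit.half_time == pytest.approx(30.0, rel=1e-2)

    def test_degenerate_flat_boundary_flagged(self):
        t = np.arange(50)
        fit = fit_hyperbolic_boundary(t, np.full(50, 0.5))
        assert not fit.ok
        assert np.isnan(fit.half_time)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_hyperbolic_boundary(np.arange(3), np.array([0.9, 0.8, 0.7]))
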