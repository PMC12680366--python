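"""Belief filtering, reward-rate closed forms, and the waiting-time policy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexinfer.bayes import (
    BayesModel,
    BeliefState,
    InconsistentBeliefError,
    belief_threshold,
    belief_update,
    context_transition_matrix,
    decide,
    emission_likelihood,
    estimates,
    expected_optimal_tau,
    optimal_tau,
    reset_after_feedback,
    reward_rate_curve,
    reward_rate_curve_printed,
    run_bayes_agent,
    safe_posterior_after_run,
    simulate_chain,
    state_transition_matrix,
)
from flexinfer.task import TaskConfig

from oracles import enumerate_posterior, scalar_hmm_filter


def _model(m=2, eps=0.0, lam=0.1, grid=None, **kw):
    return BayesModel(lambda_=lam, epsilon=eps, m=m, theta_grid=grid, **kw)


class TestKernels:
    def test_context_matrix_m2(self):
        P = context_transition_matrix(2, 0.1)
        assert np.allclose(P, [[0.9, 0.1], [0.1, 0.9]])

    def test_context_matrix_identity_at_zero_drift(self):
        assert np.allclose(context_transition_matrix(7, 0.0), np.eye(7))

    def test_context_matrix_off_diagonal(self):
        P = context_transition_matrix(5, 0.2)
        off = P[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.05)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_state_matrix(self):
        P = state_transition_matrix(0.1)
        assert np.allclose(P, [[0.9, 0.0], [0.1, 1.0]])
        assert np.allclose(P.sum(axis=0), 1.0)  # column-stochastic

    def test_state_matrix_deterministic_at_one(self):
        P = state_transition_matrix(1.0)
        assert P[1, 0] == 1.0 and P[0, 0] == 0.0

    @pytest.mark.parametrize("lam", [0.0, -0.1, 1.1])
    def test_invalid_lambda(self, lam):
        with pytest.raises(ValueError):
            state_transition_matrix(lam)

    def test_emission_likelihood_table(self):
        assert emission_likelihood(0, 1, 0.4) == 0.0
        assert emission_likelihood(1, 1, 0.4) == 1.0
        assert emission_likelihood(1, 0, 0.3) == 0.3
        for s in (0, 1):
            for th in (0.0, 0.3, 0.9):
                total = emission_likelihood(0, s, th) + emission_likelihood(1, s, th)
                assert total == pytest.approx(1.0)


class TestBeliefUpdate:
    def test_nogo_zeroes_safe_state(self, rng):
        model = _model(m=4, eps=0.01)
        p = rng.random((2, 4))
        b = BeliefState(p / p.sum())
        out = belief_update(b, 0, model)
        assert np.all(out.p[1] == 0.0)
        out.check()

    def test_one_step_known_context(self):
        # certain-unsafe prior, known theta=0.3, one go:
        # s_hat = lam / (lam + (1-lam) theta) = 0.1/0.37
        model = _model(m=1, grid=np.array([0.3]))
        b = BeliefState(np.array([[1.0], [0.0]]))
        out = belief_update(b, 1, model)
        assert out.p[1, 0] == pytest.approx(0.1 / 0.37, abs=1e-12)

    def test_go_run_monotonically_increases_safety(self):
        model = _model(m=5, eps=1e-3)
        b = BeliefState.initial(model)
        prev = 0.0
        for _ in range(15):
            b = belief_update(b, 1, model)
            s_hat = b.p[1].sum()
            assert s_hat > prev
            prev = s_hat

    def test_normalized_and_nonnegative_along_run(self, rng):
        model = _model(m=6, eps=0.01)
        b = BeliefState.initial(model)
        for _ in range(200):
            b = belief_update(b, int(rng.random() < 0.5), model)
            assert abs(b.p.sum() - 1.0) < 1e-12
            assert np.all(b.p >= 0.0)

    def test_impossible_observation_raises(self):
        model = _model(m=1, grid=np.array([0.0]))
        b = BeliefState(np.array([[0.0], [1.0]]))  # certain safe
        with pytest.raises(InconsistentBeliefError):
            belief_update(b, 0, model)

    @pytest.mark.parametrize("m,eps", [(1, 0.0), (2, 0.0), (2, 0.01), (3, 0.01)])
    def test_filter_matches_enumeration(self, m, eps, rng):
        """Sequential filter vs brute-force enumeration of latent paths."""
        grid = np.arange(m) / m
        model = _model(m=m, eps=eps, grid=grid)
        prior = rng.random((2, m))
        prior /= prior.sum()
        for xs in itertools.product((0, 1), repeat=6):
            try:
                b = BeliefState(prior.copy())
                for x in xs:
                    b = belief_update(b, x, model)
            except InconsistentBeliefError:
                with pytest.raises(ValueError):
                    enumerate_posterior(xs, prior, model.lambda_, grid, eps)
                continue
            ref = enumerate_posterior(xs, prior, model.lambda_, grid, eps)
            np.testing.assert_allclose(b.p, ref, atol=1e-9)

    def test_known_context_reduces_to_scalar_hmm(self, rng):
        theta = 0.35
        model = _model(m=1, grid=np.array([theta]))
        xs = (rng.random(400) < 0.5).astype(int)
        b = BeliefState(np.array([[1.0], [0.0]]))
        ours = []
        for x in xs:
            b = belief_update(b, int(x), model)
            ours.append(b.p[1, 0])
        ref = scalar_hmm_filter(xs, model.lambda_, theta, p0=0.0)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_frozen_context_support_never_grows(self, rng):
        model = _model(m=4, eps=0.0)
        p = np.zeros((2, 4))
        p[0, 1] = 0.6
        p[0, 2] = 0.4
        b = BeliefState(p)
        for _ in range(50):
            b = belief_update(b, int(rng.random() < 0.5), model)
            assert b.context_marginal[0] == 0.0 and b.context_marginal[3] == 0.0


class TestEstimatesAndReset:
    def test_uniform_belief_estimates(self):
        b = BeliefState.uniform(2)  # grid {0, 0.5}
        est = estimates(b)
        assert est.s_hat == pytest.approx(0.5)
        assert est.theta_hat == pytest.approx(0.25)

    def test_point_mass_estimates(self):
        p = np.zeros((2, 10))
        p[1, 7] = 1.0  # theta grid {0, .1, ..., .9}: index 7 -> 0.7
        est = estimates(BeliefState(p))
        assert est.s_hat == 1.0 and est.theta_hat == pytest.approx(0.7)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_estimates_match_weighted_sum(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 8))
        p = rng.random((2, m))
        p /= p.sum()
        grid = np.sort(rng.random(m))
        est = estimates(BeliefState(p), theta_grid=grid)
        s_ref = sum(p[1, j] for j in range(m))
        t_ref = sum((p[0, j] + p[1, j]) * grid[j] for j in range(m))
        assert est.s_hat == pytest.approx(s_ref)
        assert est.theta_hat == pytest.approx(t_ref)

    def test_reset_zeroes_safe_and_conditions_context(self, rng):
        model = _model(m=5, eps=0.01)
        p = rng.random((2, 5))
        b = BeliefState(p / p.sum())
        for s_known in (0, 1):
            out = reset_after_feedback(b, s_known, model)
            assert np.all(out.p[1] == 0.0)
            ref = b.p[s_known] / b.p[s_known].sum()  # direct conditional
            np.testing.assert_allclose(out.p[0], ref, atol=1e-12)

    def test_reset_independent_belief_keeps_marginal(self):
        model = _model(m=3, eps=0.0)
        marg = np.array([0.2, 0.5, 0.3])
        p = np.outer([0.4, 0.6], marg)
        out = reset_after_feedback(BeliefState(p), 1, model)
        np.testing.assert_allclose(out.p[0], marg, atol=1e-12)

    def test_reset_zero_mass_raises(self):
        model = _model(m=2)
        p = np.zeros((2, 2))
        p[0] = 0.5
        with pytest.raises(InconsistentBeliefError):
            reset_after_feedback(BeliefState(p), 1, model)


class TestRewardRate:
    def test_theta_zero_success_certain(self):
        model = _model(m=1, grid=np.array([0.0]), tau_max=50)
        c = reward_rate_curve(0.0, model)
        assert np.allclose(c.R, 1.0)
        assert c.T[0] == pytest.approx(1.0 / model.lambda_)

    def test_printed_form_fails_theta_zero(self):
        # the textbook-printed numerator gives R = 1/lambda > 1 at theta=0;
        # the chain-consistent form is the one used everywhere else
        model = _model(m=1, grid=np.array([0.0]), tau_max=10)
        printed = reward_rate_curve_printed(0.0, model)
        assert printed.R[0] > 1.0

    def test_R_is_probability_and_monotone(self):
        model = _model(m=1, grid=np.array([0.5]), tau_max=100)
        for theta in (0.1, 0.4, 0.8):
            c = reward_rate_curve(theta, model)
            assert np.all((0.0 <= c.R) & (c.R <= 1.0 + 1e-12))
            assert np.all(np.diff(c.R) >= -1e-12)
            assert np.all(c.T > 0.0)
            assert c.R[-1] > 0.999  # R -> 1 as tau grows (b < 1)

    @pytest.mark.parametrize("theta,tau", [(0.3, 3), (0.5, 5), (0.7, 4)])
    def test_closed_form_vs_monte_carlo(self, theta, tau, rng):
        model = _model(m=1, grid=np.array([theta]), tau_max=30)
        c = reward_rate_curve(theta, model)
        n = 40_000
        succ, dur = simulate_chain(theta, model.lambda_, tau, n, rng)
        R_mc = succ.mean()
        se_R = np.sqrt(R_mc * (1 - R_mc) / n)
        assert abs(c.R[tau - 1] - R_mc) < 4 * se_R
        se_T = dur.std() / np.sqrt(n)
        assert abs(c.T[tau - 1] - dur.mean()) < 4 * se_T

    def test_reward_rate_decreasing_past_optimum(self):
        model = _model(m=1, grid=np.array([0.5]), tau_max=200, T_iti=15.0)
        c = reward_rate_curve(0.5, model)
        tau_star = int(np.argmax(c.r))
        assert np.all(np.diff(c.r[tau_star:]) <= 1e-15)


class TestOptimalTau:
    def test_theta_zero_waits_one(self):
        model = _model(m=1, grid=np.array([0.0]), tau_max=100, T_iti=15.0)
        assert optimal_tau(0.0, model) == 1

    def test_monotone_in_theta(self):
        model = _model(m=1, grid=np.array([0.0]), tau_max=200, T_iti=15.0)
        taus = [optimal_tau(th, model) for th in np.linspace(0.0, 0.8, 17)]
        assert all(b >= a for a, b in zip(taus, taus[1:]))

    def test_matches_explicit_scan(self):
        model = _model(m=1, grid=np.array([0.0]), tau_max=200, T_iti=15.0)
        for theta in (0.2, 0.55, 0.75):
            curve = reward_rate_curve(theta, model)
            # independent scalar recomputation of r for each tau
            best, best_r = None, -1.0
            lam = model.lambda_
            b, c = (1 - lam) * theta, (1 - lam) * (1 - theta)
            for tau in range(1, model.tau_max + 1):
                S = sum(b**k for k in range(tau))
                R = lam * S / (1 - c * S)
                num = tau * b**tau + sum(
                    b**k * (tau * lam + c * (k + 1)) for k in range(tau)
                )
                T = num / (1 - c * S)
                r = R / (T + model.T_iti)
                if r > best_r + 1e-15:
                    best, best_r = tau, r
            assert optimal_tau(theta, model) == best

    def test_cap_too_small_raises(self):
        model = _model(m=1, grid=np.array([0.9]), tau_max=3, T_iti=15.0)
        with pytest.raises(ValueError, match="tau_max"):
            optimal_tau(0.9, model)

    def test_expected_tau_point_mass_collapses(self):
        model = _model(m=10, eps=0.0, tau_max=200, T_iti=15.0)
        p = np.zeros((2, 10))
        p[0, 3] = 1.0  # theta = 0.3
        assert expected_optimal_tau(BeliefState(p), model) == optimal_tau(0.3, model)

    def test_expected_tau_two_point_mixture(self):
        model = _model(m=10, eps=0.0, tau_max=200, T_iti=15.0)
        p = np.zeros((2, 10))
        p[0, 1] = 0.5  # theta 0.1
        p[0, 7] = 0.5  # theta 0.7
        got = expected_optimal_tau(BeliefState(p), model)
        # brute-force mixture scan
        r1 = reward_rate_curve(0.1, model).r
        r2 = reward_rate_curve(0.7, model).r
        assert got == int(np.argmax(0.5 * r1 + 0.5 * r2)) + 1

    def test_expected_tau_uniform_between_extremes(self):
        model = _model(m=10, eps=0.0, tau_max=200, T_iti=15.0)
        b = BeliefState.uniform(10)
        got = expected_optimal_tau(b, model)
        lo = optimal_tau(0.0, model)
        hi = optimal_tau(0.9, model)
        assert lo <= got <= hi


class TestThresholdAndPolicy:
    def test_threshold_known_context_tau_one(self):
        model = _model(m=1, grid=np.array([0.3]), T_iti=15.0)
        p = np.zeros((2, 1))
        p[0, 0] = 1.0
        thr = belief_threshold(BeliefState(p), 1, model)
        assert thr == pytest.approx(0.1 / 0.37, abs=1e-12)

    def test_threshold_decreases_with_uncertain_context(self):
        model = _model(m=10, eps=0.0, tau_max=200, T_iti=15.0)
        tau = 5
        lows = np.zeros((2, 10))
        lows[0, 2] = 1.0  # theta 0.2
        highs = np.zeros((2, 10))
        highs[0, 7] = 1.0  # theta 0.7
        thr_low = belief_threshold(BeliefState(lows), tau, model)
        thr_high = belief_threshold(BeliefState(highs), tau, model)
        assert thr_high < thr_low

    def test_threshold_approaches_one_for_long_runs(self):
        model = _model(m=1, grid=np.array([0.4]), tau_max=500)
        assert safe_posterior_after_run(0.4, 400, model) > 0.9999

    def test_no_act_right_after_nogo(self):
        model = _model(m=5, eps=1e-3, T_iti=15.0)
        b = BeliefState.initial(model)
        b = belief_update(b, 1, model)
        b = belief_update(b, 0, model)
        d = decide(b, model)
        assert not d.act and d.delta < 0
        assert d.delta == pytest.approx(b.p[1].sum() - d.s_threshold)

    def test_point_mass_agent_waits_exactly_tau_star(self, rng):
        theta = 0.3
        model = _model(m=1, grid=np.array([theta]), tau_max=200, T_iti=15.0)
        tau_star = optimal_tau(theta, model)
        cfg = TaskConfig(theta_set=(theta,), seed=0)
        log, _ = run_bayes_agent(cfg, model, 300, rng=rng, record=False)
        taus = {t.waiting_time_tau for t in log.trials}
        assert taus == {tau_star}


class TestClosedLoop:
    def test_waiting_times_track_context(self, rng):
        model = BayesModel(lambda_=0.1, epsilon=1e-3, m=10, T_iti=15.0)
        cfg = TaskConfig(theta_set=(0.3, 0.7), block_length_range=(20, 30), seed=5)
        log, trace = run_bayes_agent(cfg, model, 250, rng=rng)
        taus = {0.3: [], 0.7: []}
        for t in log.trials:
            if t.outcome in ("rewarded", "premature"):
                taus[t.theta].append(t.waiting_time_tau)
        assert np.mean(taus[0.7]) > np.mean(taus[0.3]) + 1.0

    def test_trace_fields_consistent(self, rng):
        model = BayesModel(lambda_=0.1, epsilon=1e-3, m=10, T_iti=15.0)
        cfg = TaskConfig(theta_set=(0.5,), seed=2)
        log, trace = run_bayes_agent(cfg, model, 20, rng=rng)
        total_steps = sum(len(t.steps) for t in log.trials)
        assert len(trace) == total_steps
        for rec in trace:
            assert rec["delta"] == pytest.approx(rec["s_hat"] - rec["s_threshold"])
            assert 0.0 <= rec["s_hat"] <= 1.0
            assert 0.0 <= rec["theta_hat"] < 1.0
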