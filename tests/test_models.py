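"""Q-learning model family: choice rule, updates, likelihood, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rebl import models, task
from rebl.models import (
    MODEL_REGISTRY,
    ModelSpec,
    ParameterVector,
    QState,
    block_negloglik,
    choice_probability,
    init_state,
    session_negloglik,
    simulate_agent,
    update_state,
)
from rebl.task import ADVANTAGEOUS, DISADVANTAGEOUS, REWARD, TrialRecord

CF = models.get_model("cf_alpha_tau")
FACTUAL = models.get_model("f_alpha_tau")


def make_trial(choice, outcome, index=0):
    return TrialRecord(
        block=REWARD, trial_index=index, choice=choice, outcome=outcome,
        reward_level="high" if outcome else "low", effort_level="high",
        required_presses=60,
    )


class TestRegistry:
    def test_eight_specs_with_two_to_four_parameters(self):
        assert len(MODEL_REGISTRY) == 8
        assert {s.n_free for s in MODEL_REGISTRY.values()} <= {2, 3, 4}
        assert sum(s.counterfactual for s in MODEL_REGISTRY.values()) == 4

    def test_gamma_requires_phi(self):
        with pytest.raises(ValueError, match="gamma"):
            ModelSpec("bad", True, use_gamma=True)

    def test_rho_specs_fix_tau(self):
        spec = models.get_model("cf_alpha_rho")
        assert "tau" not in spec.free_names and "rho" in spec.free_names


class TestChoiceProbability:
    def test_symmetric_state_gives_even_odds(self):
        for tau in (0.1, 1.0, 17.0):
            p = choice_probability(QState(q=(0.5, 0.5)), ParameterVector(alpha=0.5, tau=tau))
            assert np.allclose(p, [0.5, 0.5])

    def test_unit_temperature_closed_form(self):
        p = choice_probability(QState(q=(1.0, 0.0)), ParameterVector(alpha=0.5, tau=1.0))
        e = math.e
        assert p[0] == pytest.approx(e / (e + 1))
        assert p[1] == pytest.approx(1 / (e + 1))

    def test_high_temperature_flattens(self):
        p = choice_probability(QState(q=(1.0, 0.0)), ParameterVector(alpha=0.5, tau=100.0))
        assert abs(p[0] - 0.5) < 0.01

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector(alpha=0.5, tau=0.0)

    @given(
        q0=st.floats(0, 1), q1=st.floats(0, 1),
        tau=st.floats(0.01, 20), phi=st.floats(-5, 5),
        c0=st.floats(0, 10), c1=st.floats(0, 10),
    )
    @settings(deadline=None, derandomize=True)
    def test_probabilities_sum_to_one(self, q0, q1, tau, phi, c0, c1):
        p = choice_probability(
            QState(q=(q0, q1), c=(c0, c1)),
            ParameterVector(alpha=0.5, tau=tau, phi=phi),
        )
        assert abs(p.sum() - 1.0) < 1e-12


class TestUpdateState:
    def test_zero_learning_rate_is_inert(self):
        params = ParameterVector(alpha=0.0, tau=1.0)
        state = init_state(params)
        for o in (0, 1):
            new = update_state(state, 0, o, params, CF)
            assert new.q == state.q

    def test_full_update_hits_outcome(self):
        params = ParameterVector(alpha=1.0, tau=1.0)
        new = update_state(init_state(params), 0, 1, params, CF)
        assert new.q[0] == pytest.approx(1.0)
        assert new.q[1] == pytest.approx(0.0)  # counterfactual: toward 1 - o

    def test_hand_arithmetic(self):
        params = ParameterVector(alpha=0.4, tau=1.0)
        new = update_state(QState(q=(0.5, 0.5)), 0, 1, params, FACTUAL)
        assert new.q[0] == pytest.approx(0.7)
        assert new.q[1] == pytest.approx(0.5)  # factual: unchosen untouched

    def test_bias_trace_decays_and_increments(self):
        params = ParameterVector(alpha=0.1, tau=1.0, phi=1.0, gamma=0.5)
        spec = models.get_model("cf_alpha_tau_phi_gamma")
        s = update_state(init_state(params), 0, 1, params, spec)
        s = update_state(s, 1, 0, params, spec)
        assert s.c == (0.5, 1.0)

    def test_invalid_outcome_rejected(self):
        params = ParameterVector(alpha=0.5, tau=1.0)
        with pytest.raises(ValueError):
            update_state(init_state(params), 0, 2, params, CF)

    @given(
        alpha=st.floats(0, 1), rho=st.floats(0.1, 5),
        data=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=40),
    )
    @settings(deadline=None, derandomize=True)
    def test_q_values_stay_in_outcome_range(self, alpha, rho, data):
        """Q is a convex combination of values in [0, rho], so it stays there."""
        params = ParameterVector(alpha=alpha, tau=1.0, rho=rho)
        state = init_state(params)
        for ch, o in data:
            state = update_state(state, ch, o, params, CF)
            assert -1e-12 <= state.q[0] <= rho + 1e-12
            assert -1e-12 <= state.q[1] <= rho + 1e-12

    @given(
        alpha=st.floats(0, 1),
        data=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=40),
    )
    @settings(deadline=None, derandomize=True)
    def test_counterfactual_preserves_complement(self, alpha, data):
        """With a symmetric start, counterfactual updates keep Q(a) + Q(u) = rho."""
        params = ParameterVector(alpha=alpha, tau=1.0)
        state = init_state(params)
        for ch, o in data:
            state = update_state(state, ch, o, params, CF)
            assert state.q[0] + state.q[1] == pytest.approx(params.rho, abs=1e-10)


def unrolled_two_trial_negloglik(params, spec, trials):
    """Independent brute-force oracle: hand-unrolled 2-step recursion."""
    idx = {ADVANTAGEOUS: 0, DISADVANTAGEOUS: 1}
    q = [params.rho * 0.5, params.rho * 0.5]
    c = [0.0, 0.0]
    total = 0.0
    for t in trials:
        i = idx[t.choice]
        u = [q[0] / params.tau + params.phi * c[0], q[1] / params.tau + params.phi * c[1]]
        p_i = math.exp(u[i]) / (math.exp(u[0]) + math.exp(u[1]))
        total -= math.log(p_i)
        j = 1 - i
        q[i] = q[i] + params.alpha * (params.rho * t.outcome - q[i])
        if spec.counterfactual:
            q[j] = q[j] + params.alpha * (params.rho * (1 - t.outcome) - q[j])
        c = [params.gamma * c[0], params.gamma * c[1]]
        c[i] += 1.0
    return total


class TestSessionNegloglik:
    def test_random_choice_bound(self, agent_session):
        """At extreme temperature every choice has probability 0.5."""
        params = ParameterVector(alpha=0.5, tau=1e9)
        nll = session_negloglik(params, CF, agent_session, REWARD)
        assert nll == pytest.approx(25 * math.log(2), rel=1e-6)

    def test_single_trial_symmetric_start(self):
        params = ParameterVector(alpha=0.5, tau=1.0)
        for choice in (ADVANTAGEOUS, DISADVANTAGEOUS):
            nll = block_negloglik(params, CF, [make_trial(choice, 1)])
            assert nll == pytest.approx(math.log(2))

    @pytest.mark.parametrize("spec_name", sorted(MODEL_REGISTRY))
    def test_two_trial_brute_force_oracle(self, spec_name):
        """All 4 choice x outcome patterns match the hand-unrolled product."""
        spec = MODEL_REGISTRY[spec_name]
        rng = np.random.default_rng(2024)
        for _ in range(5):
            params = ParameterVector(
                alpha=rng.uniform(0, 1), tau=rng.uniform(0.2, 5),
                rho=rng.uniform(0.2, 3), phi=rng.uniform(-2, 2),
                gamma=rng.uniform(0, 1),
            )
            for c1 in (ADVANTAGEOUS, DISADVANTAGEOUS):
                for o1 in (0, 1):
                    trials = [make_trial(c1, o1, 0), make_trial(ADVANTAGEOUS, 1, 1)]
                    expected = unrolled_two_trial_negloglik(params, spec, trials)
                    assert block_negloglik(params, spec, trials) == pytest.approx(expected)

    def test_arrays_path_matches_object_path(self, agent_session):
        params = ParameterVector(alpha=0.37, tau=1.7)
        choices, outcomes = models.session_to_arrays(agent_session, REWARD)
        via_arrays = models.negloglik_arrays(
            params.free_values(CF), CF, choices, outcomes
        )
        assert via_arrays == pytest.approx(session_negloglik(params, CF, agent_session, REWARD))

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            block_negloglik(ParameterVector(alpha=0.5, tau=1.0), CF, [])


class TestSimulateAgent:
    def test_near_greedy_learner_beats_chance(self, default_config):
        """Low-temperature counterfactual learners exploit the 75% shape."""
        rng = np.random.default_rng(11)
        params = ParameterVector(alpha=0.433, tau=0.01)
        accs = [
            task.learning_accuracy(
                simulate_agent(params, CF, default_config, rng), REWARD
            )[0]
            for _ in range(500)
        ]
        assert np.mean(accs) > 0.70

    def test_high_temperature_is_chance_level(self, default_config):
        rng = np.random.default_rng(12)
        params = ParameterVector(alpha=0.433, tau=1000.0)
        accs = [
            task.learning_accuracy(
                simulate_agent(params, CF, default_config, rng), REWARD
            )[0]
            for _ in range(200)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.03

    def test_deterministic_under_seed(self, default_config):
        params = ParameterVector(alpha=0.4, tau=1.2)
        a = simulate_agent(params, CF, default_config, np.random.default_rng(3))
        b = simulate_agent(params, CF, default_config, np.random.default_rng(3))
        assert a.trials == b.trials
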