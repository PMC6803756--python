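"""PVL utility, expectancy updates, choice rule, and sequence likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igt_pvl import (
    DECK_IDS,
    ExpectancyState,
    PVLParameters,
    choice_probabilities,
    sequence_loglik,
    simulate_agent,
    theta_from_c,
    update_expectancies,
    utility,
)
from igt_pvl.pvl_model import sequence_loglik_reference

from conftest import make_session, random_params, random_session


class TestUtility:
    @pytest.mark.parametrize(
        "x,alpha,lam,expected",
        [(100, 1.0, 2.0, 100.0), (-100, 1.0, 2.0, -200.0), (-4, 0.5, 3.0, -6.0), (0, 0.7, 2.0, 0.0)],
    )
    def test_values(self, x, alpha, lam, expected):
        assert utility(x, alpha, lam) == pytest.approx(expected)

    @given(
        x=st.floats(0.01, 50),
        alpha=st.floats(0.05, 0.95),
        lam=st.floats(1.01, 5),
    )
    def test_loss_aversion_inequality(self, x, alpha, lam):
        """lam > 1: a loss outweighs the equal-sized gain; lam < 1 reverses."""
        assert abs(utility(-x, alpha, lam)) > utility(x, alpha, lam)
        lam_lo = 1.0 / lam
        assert abs(utility(-x, alpha, lam_lo)) < utility(x, alpha, lam_lo)

    @given(
        xs=st.lists(st.floats(-50, 50), min_size=2, max_size=10, unique=True),
        alpha=st.floats(0.05, 1.5),
        lam=st.floats(0.1, 5),
    )
    def test_strictly_increasing(self, xs, alpha, lam):
        xs = sorted(xs)
        us = [utility(x, alpha, lam) for x in xs]
        assert all(a < b for a, b in zip(us, us[1:]))


class TestExpectancyUpdates:
    def test_decay_rule_direct(self):
        state = ExpectancyState(E=np.ones(4))
        out = update_expectancies(state, "B", u=2.0, recency_A=0.5, rule="decay")
        assert np.allclose(out.E, [0.5, 2.5, 0.5, 0.5])

    def test_delta_rule_direct(self):
        state = ExpectancyState()
        out = update_expectancies(state, "A", u=1.0, recency_A=0.3, rule="delta")
        assert np.allclose(out.E, [0.3, 0, 0, 0])

    def test_delta_full_learning_rate_sets_u(self):
        state = ExpectancyState(E=np.array([0.2, 0.4, -1.0, 0.0]))
        out = update_expectancies(state, "C", u=5.0, recency_A=1.0, rule="delta")
        assert out.E[2] == pytest.approx(5.0)

    @given(
        e=st.lists(st.floats(-3, 3), min_size=4, max_size=4),
        u=st.floats(-5, 5),
        a=st.floats(0.05, 0.95),
        chosen=st.sampled_from(DECK_IDS),
    )
    def test_delta_leaves_others_unchanged_decay_moves_all(self, e, u, a, chosen):
        state = ExpectancyState(E=np.array(e))
        j = DECK_IDS.index(chosen)
        delta = update_expectancies(state, chosen, u, a, "delta")
        others = [k for k in range(4) if k != j]
        assert np.array_equal(delta.E[others], state.E[others])
        decay = update_expectancies(state, chosen, u, a, "decay")
        for k in others:
            if e[k] != 0:
                assert decay.E[k] != state.E[k]

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            update_expectancies(ExpectancyState(), "A", 1.0, 0.5, rule="q-learning")


class TestChoiceRule:
    def test_theta_mapping(self):
        assert theta_from_c(0.0) == 0.0
        assert theta_from_c(1.0) == pytest.approx(2.0)

    def test_equal_expectancies_uniform(self):
        p = choice_probabilities(ExpectancyState(E=np.full(4, 1.7)), consistency_c=2.0)
        assert np.allclose(p, 0.25)

    def test_c_zero_uniform_for_any_E(self):
        p = choice_probabilities(ExpectancyState(E=np.array([5.0, -3.0, 0.1, 2.0])), 0.0)
        assert np.allclose(p, 0.25)

    def test_hand_computed_softmax(self):
        """c=1 (theta=2), E=(1,0,0,0): p_A = e^2 / (e^2 + 3)."""
        p = choice_probabilities(ExpectancyState(E=np.array([1.0, 0, 0, 0])), 1.0)
        assert p[0] == pytest.approx(np.e**2 / (np.e**2 + 3))

    def test_overflow_safe(self):
        p = choice_probabilities(
            ExpectancyState(E=np.array([4000.0, 0.0, -4000.0, 10.0])), consistency_c=5.0
        )
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    def test_masking_and_all_unavailable(self):
        state = ExpectancyState(E=np.zeros(4))
        p = choice_probabilities(state, 1.0, available=[True, False, True, False])
        assert p[1] == 0 and p[3] == 0 and p.sum() == pytest.approx(1.0)
        with pytest.raises(RuntimeError):
            choice_probabilities(state, 1.0, available=[False] * 4)

    @given(
        e=st.lists(st.floats(-30, 30), min_size=4, max_size=4),
        c=st.floats(0, 5),
    )
    def test_normalization(self, e, c):
        p = choice_probabilities(ExpectancyState(E=np.array(e)), c)
        assert abs(p.sum() - 1.0) < 1e-12


class TestSequenceLoglik:
    def test_one_trial_uniform(self, midrange_params):
        s = make_session(["B"], nets=[100])
        assert sequence_loglik(midrange_params, s) == pytest.approx(np.log(0.25))

    def test_random_agent_loglik(self):
        p = PVLParameters(alpha=0.5, lam=2.0, recency_A=0.5, consistency_c=1e-300)
        s = simulate_agent(p, seed=1)
        # c -> 0: theta -> 0, every trial uniform over 4 available decks
        assert sequence_loglik(p, s) == pytest.approx(100 * np.log(0.25))

    def test_invalid_label_rejected(self, midrange_params):
        s = make_session(["A", "Z"], nets=[0, 0])
        with pytest.raises(ValueError):
            sequence_loglik(midrange_params, s)

    @pytest.mark.parametrize("rule", ["decay", "delta"])
    def test_oracle_equivalence(self, rule):
        """Compiled likelihood == independent trial-by-trial replay."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            params = random_params(rng, rule)
            session = random_session(rng)
            fast = sequence_loglik(params, session)
            slow = sequence_loglik_reference(params, session)
            assert fast == pytest.approx(slow, abs=1e-10)


class TestSimulateAgent:
    def test_determinism(self, midrange_params):
        a = simulate_agent(midrange_params, seed=9)
        b = simulate_agent(midrange_params, seed=9)
        assert a.choices == b.choices and a.final_balance == b.final_balance

    def test_random_agent_deck_frequency(self):
        """c ~ 0 agents choose each deck with probability ~ 1/4."""
        p = PVLParameters(alpha=0.5, lam=2.0, recency_A=0.5, consistency_c=1e-300)
        n_a = sum(
            simulate_agent(p, seed=s).choices.count("A") for s in range(40)
        )
        total = 40 * 100
        phat = n_a / total
        se = np.sqrt(0.25 * 0.75 / total)
        assert abs(phat - 0.25) < 4 * se

    def test_high_consistency_near_deterministic(self):
        """With E strongly favoring one deck, a high-c choice is near-certain."""
        state = ExpectancyState(E=np.array([0.5, 0.0, 0.0, 0.0]))
        p = choice_probabilities(state, consistency_c=4.5)
        assert p[0] > 0.999

    def test_parameters_json_round_trip(self, midrange_params):
        clone = PVLParameters.from_json(midrange_params.to_json())
        assert clone == midrange_params
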