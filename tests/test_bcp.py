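"""Change-point observer: worked examples, oracle equivalence, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import toy_block
from oracles import bcp_enum_loglik, bcp_enum_marginal
from revlearn.bcp import (
    BCPParams,
    _propagate,
    bcp_init,
    bcp_loglik,
    bcp_predict,
    bcp_trial_measures,
    bcp_update,
    hazard,
)
from revlearn.task import generate_block

RRL = np.array([1, 1, 0], dtype=np.int8)  # cues (R, R, L)


class TestBasics:
    def test_initial_belief_is_uniform_at_run_length_zero(self):
        b = bcp_init()
        assert np.allclose(b.marginal_cues, 1 / 3)
        assert np.array_equal(b.run_length_probs, [1.0])

    @pytest.mark.parametrize(
        "l,h,mode,expected",
        [
            (17, 0.08, "constant", 0.08),
            (0, 0.05, "increasing", 0.0),
            (10, 0.05, "increasing", 1 - np.exp(-0.5)),
        ],
    )
    def test_hazard_values(self, l, h, mode, expected):
        assert hazard(l, h, mode) == pytest.approx(expected, abs=1e-12)

    def test_hazard_domain_errors(self):
        with pytest.raises(ValueError):
            hazard(3, 1.2, "constant")
        with pytest.raises(ValueError):
            hazard(3, -0.1, "increasing")

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BCPParams(h=0.1, gamma=0.4, epsilon=0.0)
        with pytest.raises(ValueError):
            BCPParams(h=0.1, gamma=0.8, epsilon=0.0, response_model="maximizing")
        with pytest.raises(ValueError):
            BCPParams(h=0.1, gamma=0.8, epsilon=0.0, beta=2.0)  # simple + beta


class TestUpdateAndPredict:
    def test_single_update_marginal_hand_computed(self):
        # posterior after one consistent outcome, mixed with the hazard reset
        p = BCPParams(h=0.1, gamma=0.8, epsilon=0.0)
        after = bcp_update(bcp_init(), RRL, 1, p)
        m = _propagate(after, p).marginal_cues
        expected = 0.1 / 3 + 0.9 * np.array([4 / 9, 4 / 9, 1 / 9])
        assert np.allclose(m, expected, atol=1e-12)

    def test_simple_response_model_hand_computed(self):
        p = BCPParams(h=0.1, gamma=0.8, epsilon=0.1)
        after = bcp_update(bcp_init(), RRL, 1, p)
        resp, _ = bcp_predict(after, RRL, p)
        assert resp[1] == pytest.approx(0.9 * (13 / 15) + 0.05, abs=1e-10)

    def test_matching_model_at_gamma_half_is_chance(self, rng):
        p = BCPParams(h=0.2, gamma=0.5, epsilon=0.0, response_model="matching")
        belief = bcp_init()
        for _ in range(10):
            cues = rng.integers(0, 2, 3).astype(np.int8)
            resp, _ = bcp_predict(belief, cues, p)
            assert resp[1] == pytest.approx(0.5, abs=1e-12)
            belief = bcp_update(belief, cues, int(rng.integers(0, 2)), p)

    def test_maximizing_at_beta_one_equals_simple(self, rng):
        simple = BCPParams(h=0.15, gamma=0.8, epsilon=0.07)
        maxim = BCPParams(
            h=0.15, gamma=0.8, epsilon=0.07, beta=1.0, response_model="maximizing"
        )
        b1, b2 = bcp_init(), bcp_init()
        for _ in range(15):
            cues = rng.integers(0, 2, 3).astype(np.int8)
            t = int(rng.integers(0, 2))
            r1, _ = bcp_predict(b1, cues, simple)
            r2, _ = bcp_predict(b2, cues, maxim)
            assert np.allclose(r1, r2, atol=1e-12)
            b1 = bcp_update(b1, cues, t, simple)
            b2 = bcp_update(b2, cues, t, maxim)

    def test_full_discounting_gives_uniform_marginals(self, rng):
        p = BCPParams(h=1.0, gamma=0.9, epsilon=0.0)
        belief = bcp_init()
        for _ in range(20):
            cues = rng.integers(0, 2, 3).astype(np.int8)
            belief = bcp_update(belief, cues, int(rng.integers(0, 2)), p)
            assert np.allclose(_propagate(belief, p).marginal_cues, 1 / 3, atol=1e-12)

    def test_near_certain_validity_identifies_cue(self):
        # gamma -> 1 on a deterministic block: true cue found in 20 trials
        block = generate_block("deterministic", 40, 30, seed=21)
        p = BCPParams(h=0.01, gamma=0.9999, epsilon=0.0)
        belief = bcp_init()
        for t in range(20):
            belief = bcp_update(belief, block.cues[t], int(block.target[t]), p)
        assert belief.marginal_cues[block.relevant_cue[0]] > 0.95


class TestTrialMeasures:
    def test_surprisal_hand_computed(self):
        p = BCPParams(h=0.0, gamma=0.75, epsilon=0.0)
        after = bcp_update(bcp_init(), RRL, 1, p)
        m = bcp_trial_measures(bcp_init(), after, RRL, 1, p)
        assert m.surprisal == pytest.approx(-np.log(1.75 / 3), abs=1e-10)
        assert m.kl_update == pytest.approx(0.0943698, abs=1e-5)
        assert m.predictive_p_target == pytest.approx(1.75 / 3, abs=1e-12)

    def test_entropy_is_binary_entropy_of_prediction(self):
        p = BCPParams(h=0.1, gamma=0.75, epsilon=0.0)
        after = bcp_update(bcp_init(), RRL, 1, p)
        m = bcp_trial_measures(bcp_init(), after, RRL, 1, p)
        assert m.entropy == pytest.approx(0.679193, abs=1e-5)

    @pytest.mark.parametrize("target", [0, 1])
    def test_unanimous_cues_yield_zero_update(self, target):
        # all cues agree: feedback cannot discriminate between cues
        p = BCPParams(h=0.1, gamma=0.8, epsilon=0.0)
        cues = np.array([1, 1, 1], dtype=np.int8)
        after = bcp_update(bcp_init(), cues, target, p)
        m = bcp_trial_measures(bcp_init(), after, cues, target, p)
        assert m.kl_update == pytest.approx(0.0, abs=1e-12)

    def test_gamma_half_always_ln2_surprisal_zero_kl(self, rng):
        # maximal observation uncertainty: outcomes are unpredictable yet
        # completely uninformative
        p = BCPParams(h=0.2, gamma=0.5, epsilon=0.0)
        belief = bcp_init()
        for _ in range(25):
            cues = rng.integers(0, 2, 3).astype(np.int8)
            t = int(rng.integers(0, 2))
            after = bcp_update(belief, cues, t, p)
            m = bcp_trial_measures(belief, after, cues, t, p)
            assert m.surprisal == pytest.approx(np.log(2), abs=1e-12)
            assert m.kl_update == pytest.approx(0.0, abs=1e-12)
            assert m.entropy == pytest.approx(np.log(2), abs=1e-12)
            belief = after

    def test_measures_nonnegative_on_random_history(self, rng):
        p = BCPParams(h=0.15, gamma=0.8, epsilon=0.0)
        belief = bcp_init()
        for _ in range(40):
            cues = rng.integers(0, 2, 3).astype(np.int8)
            t = int(rng.integers(0, 2))
            after = bcp_update(belief, cues, t, p)
            m = bcp_trial_measures(belief, after, cues, t, p)
            assert m.surprisal >= 0 and m.kl_update >= 0
            assert 0 <= m.entropy <= np.log(2) + 1e-12
            belief = after


class TestOracleEquivalence:
    @pytest.mark.parametrize("T", [2, 5, 8])
    @pytest.mark.parametrize("hazard_mode", ["constant", "increasing"])
    def test_marginals_match_enumeration_on_grid(self, T, hazard_mode):
        cues, targets, _ = toy_block(T, seed=40 + T)
        for h in np.linspace(0.02, 0.9, 5):
            for g in np.linspace(0.55, 0.95, 5):
                p = BCPParams(h=h, gamma=g, epsilon=0.0, hazard_mode=hazard_mode)
                belief = bcp_init()
                for t in range(T):
                    m_rec = _propagate(belief, p).marginal_cues
                    m_enum = bcp_enum_marginal(h, g, cues, targets, t, hazard_mode)
                    assert np.allclose(m_rec, m_enum, atol=1e-8)
                    belief = bcp_update(belief, cues[t], int(targets[t]), p)

    @pytest.mark.parametrize("T", [5, 8])
    @pytest.mark.parametrize(
        "response_model,beta", [("simple", None), ("matching", None), ("maximizing", 2.5)]
    )
    def test_per_trial_likelihood_matches_enumeration(self, T, response_model, beta):
        from revlearn.task import TaskBlock

        cues, targets, responses = toy_block(T, seed=90 + T)
        block = TaskBlock(
            condition="probabilistic",
            cues=cues,
            target=targets,
            relevant_cue=np.zeros(T, dtype=np.int8),
            valid=np.ones(T, dtype=bool),
            shift_trial=T - 1,
            cue_validity=0.75,
        )
        p = BCPParams(
            h=0.2, gamma=0.8, epsilon=0.1, beta=beta, response_model=response_model
        )
        _, per_trial = bcp_loglik(p, block, responses)
        expected = bcp_enum_loglik(
            0.2, 0.8, 0.1, cues, targets, responses,
            response_model=response_model, beta=beta or 1.0,
        )
        assert np.allclose(per_trial, expected, atol=1e-10)


class TestLoglik:
    def test_pure_lapse_gives_chance_likelihood(self, prob_block, rng):
        p = BCPParams(h=0.3, gamma=0.8, epsilon=1.0)
        responses = rng.integers(0, 2, 88).astype(np.int8)
        total, per = bcp_loglik(p, prob_block, responses)
        assert total == pytest.approx(88 * np.log(0.5), abs=1e-9)

    def test_length_mismatch_rejected(self, prob_block):
        with pytest.raises(ValueError):
            bcp_loglik(BCPParams(h=0.1, gamma=0.8, epsilon=0.1), prob_block, np.zeros(10))

    def test_log_space_stability_at_extreme_gamma(self, prob_block, rng):
        # 88 trials at gamma = 0.999 must stay finite despite invalid trials
        p = BCPParams(h=0.01, gamma=0.999, epsilon=0.01)
        responses = rng.integers(0, 2, 88).astype(np.int8)
        total, per = bcp_loglik(p, prob_block, responses)
        assert np.all(np.isfinite(per))

    @given(
        h=st.floats(0.01, 0.99),
        g=st.floats(0.55, 0.999),
        seed=st.integers(0, 500),
    )
    @settings(max_examples=30, deadline=None)
    def test_beliefs_stay_normalized(self, h, g, seed):
        r = np.random.default_rng(seed)
        p = BCPParams(h=h, gamma=g, epsilon=0.0)
        belief = bcp_init()
        for _ in range(12):
            cues = r.integers(0, 2, 3).astype(np.int8)
            belief = bcp_update(belief, cues, int(r.integers(0, 2)), p)
            assert belief.run_length_probs.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.allclose(belief.cue_given_run.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(belief.run_length_probs >= 0)
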