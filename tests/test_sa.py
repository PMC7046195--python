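"""Selective-attention observer: confidence recursion, latent-cue filter,
path-sum oracle equivalence, and model recovery against random responding."""

import numpy as np
import pytest

from conftest import toy_block
from oracles import sa_enum_loglik
from revlearn.agents import simulate_agent
from revlearn.sa import (
    SAParams,
    lambda_update,
    lambda_update_uniform_shift,
    sa_filter_step,
    sa_init,
    sa_loglik,
    sa_predict,
)
from revlearn.task import AgentSpec, TaskBlock, generate_block

RRL = np.array([1, 1, 0], dtype=np.int8)


def _block_from(cues, targets):
    T = len(targets)
    return TaskBlock(
        condition="probabilistic",
        cues=cues,
        target=targets,
        relevant_cue=np.zeros(T, dtype=np.int8),
        valid=np.ones(T, dtype=bool),
        shift_trial=max(T - 1, 1),
        cue_validity=0.75,
    )


class TestLambdaUpdate:
    def test_match_hand_computed(self):
        p = SAParams(h=0.05, gamma=0.8, epsilon=0.0)
        out = lambda_update(0.9, True, p)
        assert out == pytest.approx(0.686 / 0.756, abs=1e-6)

    def test_uninformative_feedback_keeps_prior(self):
        p = SAParams(h=0.1, gamma=0.5, epsilon=0.0, lambda0=0.5)
        for match in (True, False):
            assert lambda_update(0.5, match, p, first_trial_of_context=True) == pytest.approx(0.5)

    @pytest.mark.parametrize("lam", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_consistent_evidence_raises_confidence(self, lam):
        p = SAParams(h=0.0, gamma=0.8, epsilon=0.0)
        assert lambda_update(lam, True, p) > lam

    def test_uniform_shift_coincides_at_h_zero(self):
        p = SAParams(h=0.0, gamma=0.85, epsilon=0.0, lambda0=0.4)
        for lam in (0.2, 0.6, 0.95):
            for match in (True, False):
                assert lambda_update(lam, match, p) == pytest.approx(
                    lambda_update_uniform_shift(lam, match, p), abs=1e-14
                )

    def test_uniform_shift_closed_form_at_full_discounting(self):
        p = SAParams(h=1.0, gamma=0.8, epsilon=0.0)
        out = lambda_update_uniform_shift(1.0, True, p)
        assert out == pytest.approx((0.8 / 3) / (0.8 / 3 + 0.5 * (2 / 3)), abs=1e-12)

    def test_uniform_shift_match_joint_probability(self):
        p = SAParams(h=0.05, gamma=0.8, epsilon=0.0)
        num = 0.8 * ((0.95 + 0.05 / 3) * 0.9 + (0.05 / 3) * 0.1)
        den = 0.5 * ((2 / 3) * 0.05 * 0.9 + 0.95 * 0.1)
        assert lambda_update_uniform_shift(0.9, True, p) == pytest.approx(
            num / (num + den), abs=1e-12
        )

    def test_lambda_stays_in_unit_interval_on_simulated_blocks(self):
        # 5x5x5 parameter grid over full 88-trial blocks
        block = generate_block("probabilistic", 88, 40, seed=3)
        for h in np.linspace(0.0, 1.0, 5):
            for g in np.linspace(0.5, 1.0, 5):
                for l0 in np.linspace(0.0, 1.0, 5):
                    p = SAParams(h=h, gamma=g, epsilon=0.1, lambda0=l0)
                    grid = sa_init(p)
                    for t in range(88):
                        grid = sa_filter_step(
                            grid, block.cues[t], int(block.target[t]),
                            int(block.target[t]), p,
                        )
                        assert np.all(grid.lam >= 0) and np.all(grid.lam <= 1)
                        assert grid.joint.sum() == pytest.approx(1.0, abs=1e-10)


class TestFilterStep:
    def test_full_lapse_makes_response_uninformative(self):
        p = SAParams(h=0.1, gamma=0.8, epsilon=1.0)
        grid = sa_init(p)
        before = grid.cue_marginal.copy()
        stepped = sa_filter_step(grid, RRL, 0, 1, p)
        # the response carries no information; only the target moved lambda
        assert np.allclose(stepped.cue_marginal.sum(), 1.0)
        assert np.allclose(before, 1 / 3)

    def test_first_trial_response_identifies_minority_cue(self):
        p = SAParams(h=0.1, gamma=0.8, epsilon=0.1)
        grid = sa_init(p)
        rlik = np.where(RRL == 0, 0.95, 0.05)
        w = rlik / rlik.sum()
        assert w[2] == pytest.approx(0.904762, abs=1e-6)
        # and the filter's own response weighting agrees before propagation
        from revlearn.sa import _response_likelihood

        got = _response_likelihood(RRL, 0, p) * grid.joint[0]
        got = got / got.sum()
        assert got[2] == pytest.approx(0.904762, abs=1e-6)

    def test_certain_hypotheses_never_reset(self):
        p = SAParams(h=0.0, gamma=0.9999, epsilon=0.1, lambda0=0.9999)
        grid = sa_init(p)
        # target matches every cue: all lambdas move toward 1
        cues = np.array([1, 1, 1], dtype=np.int8)
        g2 = sa_filter_step(grid, cues, 1, 1, p)
        assert g2.joint[0].sum() < 1e-3  # essentially no reset mass

    def test_predict_examples(self):
        p0 = SAParams(h=0.1, gamma=0.8, epsilon=0.0)
        assert sa_predict(sa_init(p0), RRL, p0)[1] == pytest.approx(2 / 3)
        p1 = SAParams(h=0.1, gamma=0.8, epsilon=0.1)
        grid = sa_init(p1)
        grid.joint[0] = [0.0, 0.0, 1.0]
        assert sa_predict(grid, RRL, p1)[1] == pytest.approx(0.05)
        p2 = SAParams(h=0.1, gamma=0.8, epsilon=1.0)
        assert sa_predict(sa_init(p2), RRL, p2)[1] == pytest.approx(0.5)


class TestLoglik:
    def test_pure_lapse_gives_chance_likelihood(self, prob_block, rng):
        p = SAParams(h=0.2, gamma=0.8, epsilon=1.0, lambda0=0.6)
        responses = rng.integers(0, 2, 88).astype(np.int8)
        total, _ = sa_loglik(p, prob_block, responses)
        assert total == pytest.approx(88 * np.log(0.5), abs=1e-9)

    @pytest.mark.parametrize("T", [3, 5])
    @pytest.mark.parametrize("variant", ["original", "uniform_shift"])
    def test_matches_path_sum_enumeration(self, T, variant):
        cues, targets, responses = toy_block(T, seed=70 + T)
        for h, g, l0 in ((0.05, 0.8, 0.6), (0.4, 0.65, 0.5), (0.9, 0.95, 0.2)):
            p = SAParams(h=h, gamma=g, epsilon=0.1, lambda0=l0, learning_variant=variant)
            _, per = sa_loglik(p, _block_from(cues, targets), responses)
            expected = sa_enum_loglik(h, g, 0.1, l0, cues, targets, responses, variant)
            assert np.allclose(per, expected, atol=1e-8)

    def test_fixed_lambda0_variant_equals_free_at_half(self, prob_block, rng):
        # the fitting module's fixed-lambda0 model (one fewer free
        # parameter) must equal the free model evaluated at lambda0 = 0.5
        from revlearn.hierfit import HierarchicalSpec, _make_loglik

        responses = rng.integers(0, 2, 88).astype(np.int8)
        data = [(prob_block.cues, prob_block.target, responses)]
        spec = HierarchicalSpec(model="SA", options={"lambda0_free": False})
        fixed_ll = _make_loglik(spec, data)(0, np.array([0.15, 0.8, 0.1]))
        free = SAParams(h=0.15, gamma=0.8, epsilon=0.1, lambda0=0.5)
        _, a = sa_loglik(free, prob_block, responses)
        assert np.allclose(a, fixed_ll, atol=1e-12)

    def test_sa_agents_better_fit_than_random_agents(self):
        # model recovery: per-agent SA log-likelihood at generating
        # parameters should separate SA-generated from random data
        p = SAParams(h=0.05, gamma=0.85, epsilon=0.05, lambda0=0.7)
        wins = 0
        n = 20
        for seed in range(n):
            block = generate_block("probabilistic", 88, 40, seed=1000 + seed)
            sa_resp = simulate_agent(
                AgentSpec(model="SA", params=p, seed=seed), block
            )
            rnd_resp = simulate_agent(AgentSpec(model="RANDOM", seed=seed), block)
            ll_sa, _ = sa_loglik(p, block, sa_resp)
            ll_rnd, _ = sa_loglik(p, block, rnd_resp)
            wins += ll_sa > ll_rnd
        assert wins >= 0.9 * n

    def test_own_parameters_beat_permuted_responses(self):
        p = SAParams(h=0.05, gamma=0.85, epsilon=0.05, lambda0=0.7)
        block = generate_block("probabilistic", 88, 40, seed=77)
        resp = simulate_agent(AgentSpec(model="SA", params=p, seed=5), block)
        ll_true, _ = sa_loglik(p, block, resp)
        rng = np.random.default_rng(0)
        perm_lls = []
        for _ in range(100):
            ll_perm, _ = sa_loglik(p, block, rng.permutation(resp))
            perm_lls.append(ll_perm)
        assert ll_true > np.mean(perm_lls)
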