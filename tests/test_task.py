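"""Task-block generation, agents, cohort structure, and dataset IO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn.agents import simulate_agent
from revlearn.bcp import BCPParams
from revlearn.cohort import generate_cohort, ocir_scale, sample_ocir
from revlearn.io import ParseError, read_dataset, trials_frame, write_dataset
from revlearn.task import AgentSpec, ConfigurationError, generate_block


class TestGenerateBlock:
    def test_deterministic_block_all_valid_with_shift(self):
        b = generate_block("deterministic", 88, 40, 1.0, seed=5)
        assert b.n_trials == 88
        assert b.valid.all()
        assert len(set(b.relevant_cue[:40])) == 1
        assert len(set(b.relevant_cue[40:])) == 1
        assert b.relevant_cue[39] != b.relevant_cue[40]

    def test_probabilistic_block_exact_segment_counts(self):
        b = generate_block("probabilistic", 88, 48, 0.75, seed=5)
        assert b.valid[:48].sum() == 36
        assert b.valid[48:].sum() == 30
        assert b.valid.sum() == 66

    @pytest.mark.parametrize("shift", [40, 48])
    def test_target_matches_relevant_cue_iff_valid(self, shift):
        b = generate_block("probabilistic", 88, shift, seed=7)
        rel = b.cues[np.arange(88), b.relevant_cue]
        assert np.array_equal(b.target == rel, b.valid)

    def test_deterministic_with_reduced_validity_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_block("deterministic", 88, 40, 0.75, seed=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trials": 1, "shift_trial": 0},
            {"shift_trial": 0},
            {"shift_trial": 88},
            {"cue_validity": 0.4},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        args = {"n_trials": 88, "shift_trial": 40, "cue_validity": 0.75}
        args.update(kwargs)
        with pytest.raises(ConfigurationError):
            generate_block("probabilistic", **args)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_post_shift_cue_always_differs(self, seed):
        b = generate_block("probabilistic", 20, 10, 0.8, seed=seed)
        assert b.relevant_cue[9] != b.relevant_cue[10]
        assert b.valid[:10].sum() == round(0.8 * 10)

    def test_cue_orientations_are_balanced(self):
        # each cue column is Bernoulli(0.5): check 0.5 +- 3 SE over 10,000
        # generated trials
        counts = np.zeros(3)
        n = 0
        for seed in range(120):
            b = generate_block("probabilistic", 88, 40, seed=seed)
            counts += b.cues.sum(axis=0)
            n += 88
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(counts / n - 0.5) < 3 * se)


class TestAgents:
    def test_random_agent_near_chance_accuracy(self, det_block):
        spec = AgentSpec(model="RANDOM", seed=3)
        resp = simulate_agent(spec, det_block)
        rel = det_block.cues[np.arange(88), det_block.relevant_cue]
        assert abs(np.mean(resp == rel) - 0.5) < 0.1

    def test_bcp_agent_learns_deterministic_contingency(self):
        # Monte-Carlo oracle: accuracy on trials 20-40 across 200 seeded runs
        params = BCPParams(h=0.03, gamma=0.9999, epsilon=0.02)
        accs = []
        for seed in range(200):
            b = generate_block("deterministic", 88, 40, seed=seed)
            resp = simulate_agent(AgentSpec(model="BCP", params=params, seed=seed), b)
            rel = b.cues[np.arange(88), b.relevant_cue]
            accs.append(np.mean((resp == rel)[19:40]))
        assert np.mean(accs) > 0.9

    def test_nolearn_agent_follows_unanimous_cues(self):
        b = generate_block("deterministic", 10, 5, seed=0)
        unanimous = b.cues.sum(axis=1) % 3 == 0
        resp = simulate_agent(AgentSpec(model="NOLEARN", seed=0), b)
        majority = (b.cues.sum(axis=1) >= 2).astype(int)
        assert np.array_equal(resp[unanimous], majority[unanimous])

    def test_simulation_is_bit_reproducible(self, prob_block):
        for model, params in [
            ("BCP", {"h": 0.1, "gamma": 0.8, "epsilon": 0.05}),
            ("SA", {"h": 0.1, "gamma": 0.8, "epsilon": 0.05, "lambda0": 0.6}),
            ("WSLS", {"p_stay": 0.9, "p_shift": 0.7, "epsilon": 0.1}),
            ("RANDOM", {}),
        ]:
            spec = AgentSpec(model=model, params=params, seed=99)
            a = simulate_agent(spec, prob_block)
            b = simulate_agent(spec, prob_block)
            assert np.array_equal(a, b)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            AgentSpec(model="QLEARN")


class TestCohort:
    def test_scores_and_parameters_in_range(self):
        ds = generate_cohort(25, seed=4)
        ocir = ds.ocir_scores()
        assert ocir.min() >= 0 and ocir.max() <= 50
        for cond in ("deterministic", "probabilistic"):
            h = ds.true_param("h", cond)
            g = ds.true_param("gamma", cond)
            e = ds.true_param("epsilon", cond)
            assert np.all((0 <= h) & (h <= 1))
            assert np.all((0.5 <= g) & (g <= 1))
            assert np.all((0 <= e) & (e <= 1))
        for p in ds.participants:
            for cond in ("deterministic", "probabilistic"):
                assert len(p.responses[cond]) == p.blocks[cond].n_trials

    def test_ocir_calibration_fraction_above_cutoff(self, rng):
        x = sample_ocir(20_000, rng)
        assert abs(np.mean(x > 21) - 0.40) < 0.02
        assert ocir_scale() > 0

    def test_embedded_correlation_is_unbiased(self):
        # mean sample r over 500 seeded cohorts should sit at the target
        from scipy import stats

        ds_rs = []
        for seed in range(500):
            ds = generate_cohort(
                57, effect={"probabilistic": 0.3, "deterministic": 0.0}, seed=seed
            )
            eta = stats.norm.ppf(ds.true_param("h", "probabilistic"))
            ds_rs.append(np.corrcoef(ds.ocir_scores(), eta)[0, 1])
        assert abs(np.mean(ds_rs) - 0.3) < 0.02  # ~4 SE at 500 cohorts

    def test_null_effect_stays_null(self):
        from scipy import stats

        rs = []
        for seed in range(60):
            ds = generate_cohort(
                57, effect={"probabilistic": 0.0, "deterministic": 0.0}, seed=seed
            )
            eta = stats.norm.ppf(ds.true_param("h", "probabilistic"))
            rs.append(np.corrcoef(ds.ocir_scores(), eta)[0, 1])
        # |r| < 0.26 (the alpha = .05 threshold at n = 57) almost always
        assert np.mean(np.abs(rs) < 0.26) >= 0.90

    def test_degenerate_configurations_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(1)
        with pytest.raises(ConfigurationError):
            generate_cohort(10, effect={"probabilistic": 1.5})
        bad_hypers = {
            "probabilistic": {"h": (-1.1, 0.0), "gamma": (0, 0.4), "epsilon": (-1.6, 0.3)},
            "deterministic": {"h": (-1.5, 0.7), "gamma": (2.0, 0.4), "epsilon": (-1.6, 0.3)},
        }
        with pytest.raises(ConfigurationError):
            generate_cohort(10, effect={"probabilistic": 0.3}, hypers=bad_hypers)


class TestDatasetIO:
    def test_round_trip_is_lossless(self, tmp_path):
        ds = generate_cohort(5, seed=8)
        write_dataset(ds, tmp_path / "d")
        back = read_dataset(tmp_path / "d")
        assert len(back) == len(ds)
        for a, b in zip(ds.participants, back.participants):
            assert a.id == b.id and a.ocir == b.ocir and a.dass == b.dass
            for cond in a.blocks:
                assert np.array_equal(a.responses[cond], b.responses[cond])
                assert np.array_equal(a.blocks[cond].cues, b.blocks[cond].cues)
                assert np.array_equal(a.blocks[cond].target, b.blocks[cond].target)
                assert np.array_equal(a.blocks[cond].valid, b.blocks[cond].valid)
                assert a.blocks[cond].shift_trial == b.blocks[cond].shift_trial
                for name, v in a.true_params[cond].items():
                    assert b.true_params[cond][name] == pytest.approx(v)
        assert back.provenance == ds.provenance

    def test_bad_response_code_reports_row(self, tmp_path):
        ds = generate_cohort(2, seed=8)
        write_dataset(ds, tmp_path / "d")
        trials = (tmp_path / "d" / "trials.csv").read_text().splitlines()
        parts = trials[3].split(",")
        parts[9] = "X"
        trials[3] = ",".join(parts)
        (tmp_path / "d" / "trials.csv").write_text("\n".join(trials))
        with pytest.raises(ParseError, match="row 4"):
            read_dataset(tmp_path / "d")

    def test_empty_trials_file_names_missing_header(self, tmp_path):
        ds = generate_cohort(2, seed=8)
        write_dataset(ds, tmp_path / "d")
        (tmp_path / "d" / "trials.csv").write_text("")
        with pytest.raises(ParseError, match="participant_id"):
            read_dataset(tmp_path / "d")
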