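# revlearn

Bayesian observer models of three-cue probabilistic reversal learning,
with hierarchical parameter estimation and symptom-association analyses
for computational psychiatry.

## The problem

Obsessive-compulsive (OC) symptoms involve repeated checking and
doubting of things already known. One computational account locates this
in *transition uncertainty*: an inflated subjective probability `h` that
the environment's hidden state has changed since the last observation,
which makes past evidence feel unreliable and current feedback loom
large. This package implements the full analysis pipeline for testing
that account in a reversal-learning task: on each trial three arrow cues
point left or right, exactly one (unknown) cue predicts the target's
side, and the relevant cue changes once per 88-trial block without
warning. A deterministic condition has fully valid cues; a probabilistic
condition has 75% cue validity, so participants must separate misleading
feedback from genuine contingency shifts.

## What is implemented

- **Task and cohort simulation** (`revlearn.task`, `revlearn.cohort`):
  exact-validity task blocks, generative agents for every candidate
  model, and synthetic cohorts with a right-skewed OCI-R symptom
  distribution (~40% above the clinical cutoff of 21) and a controlled
  population correlation between symptoms and probit-scale `h`.
- **Observer models** (`revlearn.bcp`, `revlearn.sa`,
  `revlearn.baselines`): the optimal Bayesian change-point (BCP)
  observer — run-length filtering over `p(l, c | D)` with constant or
  increasing hazard, free cue-validity `γ`, lapse `ε`, and simple /
  matching / maximizing response rules — plus a selective-attention (SA)
  observer that tracks a single attended cue with confidence `λ`
  (likelihood computed by marginalizing the latent attended cue),
  win-stay/lose-shift, and a no-learning proportion rule. Trial-level
  surprisal, KL belief-update, and predictive entropy come from the BCP
  posterior.
- **Hierarchical Bayesian fitting** (`revlearn.hierfit`): probit-scale
  parameters `h_s = Φ(σ_h z_s + μ_h)`, `γ_s = Φ(·)/2 + 0.5`,
  `ε_s = Φ(·)`, standard-normal hyperpriors on group means (uniform on
  the probability scale), half-t(50, 0.2) on group SDs, an adaptive
  Metropolis-within-Gibbs sampler with numba-compiled likelihoods,
  split-R-hat ≤ 1.1 convergence checks with automatic budget
  escalation, posterior-median point estimates, and the chance-level
  exclusion screen.
- **Model comparison** (`revlearn.compare`): WAIC and PSIS-LOO with
  Akaike / pseudo-BMA weights and posterior-predictive absolute fit.
- **Associations** (`revlearn.association`): accuracy, disambiguating
  trials and perseveration-attributable errors; permutation and partial
  permutation correlations between symptom scores and fitted
  parameters.
- **Pipeline** (`revlearn.pipeline`, `revlearn` CLI, `analysis/`):
  simulate → fit → compare → measures → associate, with seeded
  manifests and byte-reproducible CSV artifacts.

See `docs/methods.md` for the model equations, priors, numerical
conventions, and what the synthetic cohorts do and do not emulate.

## Worked example

The numbered scripts in `analysis/` run the canonical sequence on a
synthetic cohort (every script takes `--seed`; outputs go to
`results/`):

```bash
python analysis/01_simulate_cohort.py --seed 9
python analysis/02_fit_models.py --seed 2
python analysis/03_model_comparison.py
python analysis/05_associations.py
```

`01_simulate_cohort.py` prints, for seed 9:

```
wrote results/dataset
n = 57; OCI-R mean 18.3, 30% above cutoff 21
sample r(OCI-R, probit h | probabilistic) = 0.367 (population target 0.31)
```

i.e. a 57-participant cohort whose symptom scores have the intended skew
(the above-cutoff fraction is calibrated to 40% in expectation; at
n = 57 individual samples scatter, here 30%), and whose ground-truth
transition uncertainty correlates 0.37 with symptoms in this particular
sample (population value 0.31, sample SD ≈ 0.12). `02_fit_models.py`
fits the BCP, SA and WSLS models per condition and reports convergence
(worst split-R-hat ≈ 1.05–1.13 at the desk-scale budget);
`03_model_comparison.py` then prints

```
deterministic: best model by WAIC is BCP (WAIC 2843.4, Akaike weight 1.00)
probabilistic: best model by WAIC is BCP (WAIC 4293.8, Akaike weight 1.00)
mean absolute fit (BCP): deterministic=0.839, probabilistic=0.725
0 participant(s) flagged as chance-level responders
```

— the generating change-point model wins the comparison and predicts
72–84% of responses, well above the 0.5 chance level. Finally
`05_associations.py` reports the headline statistic computed from the
*fitted* posterior medians:

```
OCI-R ~ transition uncertainty (probabilistic): r = 0.325, permutation p = 0.0142 (n = 57, 10000 permutations)
```

the embedded symptom effect on transition uncertainty survives
simulation, hierarchical estimation, and the permutation test.
`06_recovery_study.py` quantifies how well each parameter's ordering is
recovered (for seed 5, Spearman true-vs-fitted h is 0.87 deterministic /
0.74 probabilistic), which bounds how much attenuation to expect in such
correlations.

A thin CLI wraps the same library:

```bash
revlearn run --seed 7 --out results/demo          # full pipeline, demo scale
revlearn simulate --condition probabilistic --model BCP \
    --params '{"h": 0.1, "gamma": 0.8, "epsilon": 0.05}' --seed 3 --out block.csv
```

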