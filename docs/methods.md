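# Methods

## The task

Each trial of the reversal-learning task presents three arrow cues (top,
middle, bottom), each independently pointing left or right with
probability 0.5. One cue — the *relevant* cue — predicts the side on
which a target will appear; the participant presses left/right to
predict the target before it appears. After an unsignaled contingency
shift, a *different* cue becomes relevant. Each condition is one
88-trial block with a single shift after trial 40 or 48
(counterbalanced across participants and conditions). In the
deterministic condition the relevant cue is always valid; in the
probabilistic condition it is valid on 75% of trials. The generator
allocates invalid trials by exact proportion within the pre- and
post-shift segments (66/88 valid overall), placed by a seeded
permutation, so the nominal 75% is an exact, testable property of every
generated block rather than a Bernoulli expectation.

## Observer models

### Change-point (BCP) observer

The normative observer maintains a joint posterior over the run length
`l` (trials since the last shift) and the relevant cue `c`. Before each
trial the run-length distribution passes through a hazard — the
transition uncertainty `h`, either a constant per-trial shift
probability or an increasing function `1 − exp(−h·l)` — with the shift
mass restarting at `l = 0` under a uniform distribution over all three
cues (uniform, rather than excluding the current cue, so that `h = 1`
means "discount the past entirely" instead of "the previous cue is
certainly irrelevant"). After the target is observed, every `(l, c)`
hypothesis is reweighted by `γ` if cue `c` pointed at the target and
`1 − γ` otherwise, where `γ ∈ [0.5, 1]` is the subjective cue validity
(`1 − γ` is the observation uncertainty). `γ` is held constant within a
block; learning it online is out of scope.

Run-length bookkeeping follows the standard online change-point
convention: the run length counts observations, a fresh run sits at
`l = 0` on its first observation, and the pre-experiment start acts as a
virtual run origin. Full run-length support is kept (no pruning; blocks
are at most 88 trials).

Three response rules map the propagated cue marginal `m` and the
current cue orientations to a response probability, each mixed with a
lapse rate `ε` (`P ← (1 − ε)·P + ε/2`):

- **simple** — `P(right) = Σ_{c points right} m_c`;
- **matching** — `P(right) = Σ_c p(target = right | c) m_c`, which
  collapses to chance at `γ = 0.5`;
- **maximizing** — as simple after sharpening `m ∝ m^β` with `β ≥ 1`
  (`β = 1` recovers the simple rule). The sharpness parameter replaces a
  hard argmax, which would break posterior smoothness.

Trial-level feedback measures (all in nats): surprisal
`−ln p(target_t | D_{1:t−1})`; the belief update as the KL divergence
between the successive propagated cue marginals (the beliefs that
actually drive responding — the propagation point is a convention we fix
and document, as the defining equations leave it open); and the
predictive entropy as the expectation of the surprisal over both target
outcomes. At `γ = 0.5` every trial has surprisal `ln 2` and zero KL:
feedback is maximally unpredictable yet entirely uninformative.

### Selective-attention (SA) observer

The agent attends to a single cue and keeps a scalar confidence `λ` that
it is the relevant one, updated after each outcome from the joint
probability of the outcome with the attended cue being relevant versus
not (an irrelevant cue predicts the target half the time). After each
trial attention switches with probability `1 − λ`, resampling the new
cue uniformly; a fresh context starts from the prior confidence `λ0`
(free, or fixed at 0.5). The `original` learning variant retains a known
internal inconsistency of this model family — the confidence recursion
assumes a shift lands on the attended cue with probability `0.5·h`,
while attention switches resample uniformly over all three cues; the
`uniform_shift` variant resolves it with `h/3` mixtures. Both are
implemented; the approximate form of the "attended cue is wrong" joint
probability is used literally, not replaced by an exact expression.

Because the attended cue is unobservable, the likelihood marginalizes
over a grid of (attended cue, attention run length) hypotheses, each
carrying a deterministic `λ` trajectory: responses are data about where
attention was, with per-hypothesis switch probability `1 − λ` playing
the hazard's role. The within-trial order is fixed as (i) weight
hypotheses by the response likelihood, (ii) update each hypothesis's
`λ` with the realized target, (iii) propagate run lengths with resets
uniform over cues. This ordering makes the run-length recursion
well-defined; the defining equations do not pin it down.

### Benchmarks

Win-stay/lose-shift attends to one cue and stays after an expected
outcome with probability `p_stay`, switching after an unexpected one
with probability `p_shift`; the same latent-attention grid supplies its
likelihood. A lapse `ε` is included by default for parity with the SA
observer (the source procedure leaves this open; a flag disables it).
The no-learning model responds with the proportion of cues pointing each
way — stateless and parameter-free by default, with an ε-mixed variant
behind a flag for likelihood comparisons on data containing lapses.

## Hierarchical estimation

Participant-level parameters live on a probit scale:
`h_s = Φ(σ_h z_s + μ_h)`, `ε_s` likewise, `γ_s = Φ(·)/2 + 0.5` (range
[0.5, 1]), `λ0_s = Φ(·)`, and `β_s = 1 + exp(·)` (the lower bound at 1
is the only published constraint on `β`; `1 + exp` gives unbounded
smooth support above it). Group means have standard-normal hyperpriors —
through the probit link a uniform prior on each group-level
probability — and group SDs have half-Student-t(ν = 50, scale = 0.2)
hyperpriors, which keep individual-level marginals near-uniform while
allowing spread when the group mean is extreme. Conditions are fitted
separately, each with its own group-level distributions. The probit is
computed exactly rather than by the common logistic approximation.

Sampling uses an adaptive Metropolis-within-Gibbs scheme written for
this package, with four move types per sweep:

1. per participant, with probability 0.1, an *independence proposal* of
   the whole parameter row drawn from the current group prior — the
   prior density cancels against the proposal, leaving a pure likelihood
   ratio, which lets chains hop between posterior modes (e.g. the
   high-lapse versus high-transition-uncertainty explanations of noisy
   responding);
2. coordinate-wise random-walk Metropolis on each participant's
   probit-scale parameters (step sizes adapted during warmup toward 44%
   acceptance; only that participant's likelihood is re-evaluated, via
   numba-compiled filter kernels);
3. conjugate Gibbs draws for group means and stepping-out slice sampling
   for group SDs (likelihood-free in the centered parameterization);
4. an *interweaved non-centered group move*: holding the standardized
   scores fixed, (mean, SD) of each group distribution get a joint
   random-walk proposal that rescales every participant's parameter at
   once. Alternating centered and non-centered group updates
   (ancillarity–sufficiency interweaving) breaks the funnel coupling
   between the group scale and the participant-level values — the same
   pathology the published procedure's non-centered parameterization
   addresses — and empirically moves worst-case split-R-hat on group
   scales from ≈2–8 to ≈1.1 at desk budgets.

A fully non-centered sampler variant (random-walk on standardized
scores with Metropolis group updates) is also available and agrees with
the default sampler within Monte-Carlo error on small cohorts. The default budget is 3 chains × 1000 iterations with
400 warmup, with a 1500/500 refit convention for the best-fitting model;
the tests and bundled analyses use explicitly reduced budgets (typically
2 chains × 300–750 iterations at 8–57 participants) chosen to keep a
full run of the suite in the tens of minutes.

Convergence is judged by classic split-R-hat with the inclusive
threshold 1.1 applied to all group parameters and natural-scale
participant parameters; identical-constant chains are reported as
degenerate (R-hat 1) and disjoint-constant chains as divergent (R-hat
∞), never as NaN. A fit that fails the threshold is automatically re-run
with a doubled iteration budget (up to twice) — the sampler's analogue
of escalating the acceptance-rate control until divergences disappear —
and returned flagged if it still fails. Point estimates are posterior
medians pooled across chains. Participants whose posterior-predictive
absolute fit is within 0.05 of chance (0.5) in *every* condition and
whose median lapse rate exceeds 0.5 are flagged and excluded from
association analyses, with a logged record; the fit itself always runs
on everyone first (fit, screen, then re-test associations without the
flagged participants).

## Model comparison

Relative fit uses WAIC (variance-based penalty) and PSIS-LOO on the
pointwise log-likelihood draws, both on the −2·elpd scale; Akaike
weights are formed from WAIC differences and pseudo-BMA weights from
LOO elpds (plain pseudo-BMA by default, with the Bayesian-bootstrap
variant behind a flag). Pareto-k diagnostics above 0.7 are reported,
never silently accepted; where the generalized-Pareto fit fails on
heavily tied importance ratios, plain normalized weights are used for
those points and their k is reported as NaN. Absolute fit simulates
response sequences from posterior draws on the participant's own
cue/target sequence and scores the mean per-trial match with the actual
responses (every retained draw by default; a subsampling flag trades
precision for speed). Trials on which all three cues agree are scored
as-is, which slightly inflates the chance baseline for all models
equally.

## Synthetic cohorts

The generator is the study stand-in: what it emulates, and what it does
not, bounds what a passing test shows about real data.

- **OCI-R totals** are gamma(shape 2) draws, truncated at 50 and
  rounded, with the scale calibrated so that P(score > 21) = 0.40 —
  matching the reported ~40% above the clinical cutoff. This is a
  calibration of the synthetic distribution, not a claim about the true
  population; the implied ~20% above 30 is close to the reported ~18%.
- **DASS-21 subscales** are discretized gamma scores tied to the OCI-R
  by a Gaussian copula (r = 0.50 depression, 0.35 anxiety/stress),
  giving the partial-correlation analysis realistic collinearity.
- **Parameters**: probit-scale transition uncertainty has mean −1.1 and
  SD 0.7 in the probabilistic condition (median h ≈ 0.14, individual
  values spanning roughly 0.01–0.6, matching the spread of fitted values
  in the study) and mean −1.5 in the deterministic condition; `γ`
  centers at the true validity 0.75 (probabilistic) or near 1
  (deterministic, matching the reported 0.99 inter-quartile range);
  lapses center near 0.05. The embedded effect sets
  `probit(h) = μ + σ(ρ·z + √(1−ρ²)·noise)` with `z` the
  population-standardized OCI-R, so the *population* correlation is
  exactly ρ (default 0.31 probabilistic, 0.24 deterministic) while
  sample correlations fluctuate naturally (SD ≈ 0.12 at n = 57). `γ`
  and `ε` are symptom-independent by construction.
- **Responses** come from the change-point observer; no-response
  trials, reaction times, the training block, and any within-session
  non-stationarity of real participants are not modeled.

One consequence is worth stating plainly: with a population correlation
of 0.31 at n = 57, a directional permutation test at α = .05 detects
the effect in only ~65–75% of cohorts even with error-free parameter
estimates, because the sample correlation itself often falls below the
significance threshold. End-to-end detection rates should be read
against that ceiling, not against 100%.

## Numerical conventions

Filtering runs in linear space with a renormalization every trial;
per-trial evidence is bounded below by `(1 − γ)/3` for `γ < 1` and by
the hazard reset mass otherwise, so an 88-trial block at `γ = 0.999`
stays comfortably finite (tested). Degenerate corners are defined, not
crashed on: a response with zero probability yields −∞ log-likelihood
from that trial on (so Metropolis proposals into impossible corners are
rejected); a zero-evidence target update at `γ = 1` restarts the belief
in simulation; a 0/0 confidence update in the SA recursion (certain
hypothesis meeting an impossible outcome) leaves the confidence
unchanged. Information measures use natural logarithms throughout. All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; simulation is bit-reproducible, and pipeline
reruns with the same config and seed produce byte-identical CSV
artifacts.

## Known limitations

- The sampler is random-walk based; it needs more iterations than a
  gradient-based sampler would for the same effective sample size, and
  the escalation rule (doubling iterations on an R-hat failure) is a
  budget heuristic, not a guarantee.
- Exact leave-one-out is verified against PSIS-LOO only at toy scale via
  a grid posterior; at scale, the Pareto-k diagnostics are the guard.
- The trial-level mixed-effects regressions of accuracy and of the
  feedback measures are out of scope; the pipeline exports the tables
  (`measures.csv`, `behavior.csv`) those regressions consume.
- Reproducing the published real-data information criteria requires the
  original deposit and a multi-day MCMC budget; the pipeline supports
  external datasets through the same CSV schema and configuration, but
  no test asserts those numbers.
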