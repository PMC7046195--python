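"""Optimal Bayesian change-point (BCP) observer for the three-cue task.

The observer tracks a joint posterior over the run-length ``l`` (trials
since the last contingency shift) and the identity of the relevant cue
``c``. Before each trial the run-length distribution is propagated through
a hazard function (constant ``h``, or increasing ``1 - exp(-h l)``); the
mass assigned to a shift resets to run-length 0 with a uniform distribution
over all three cues. The marginal belief over cues then drives the response
via one of three response models:

- ``simple``: respond with the side indicated by each cue, weighted by the
  cue's posterior probability, mixed with a lapse rate ``epsilon``;
- ``matching``: respond with the predictive probability of the target side,
  which additionally weighs in the estimated cue validity ``gamma``;
- ``maximizing``: as ``simple`` but with cue probabilities sharpened as
  ``p^beta`` (``beta >= 1``; ``beta = 1`` recovers ``simple``).

After the target is observed, the per-run cue posteriors are updated with
likelihood ``gamma`` (cue orientation matches the target) or ``1 - gamma``
(mismatch) and the run-length posterior is updated accordingly.

All information measures are in nats. Filtering is done in linear space
with a renormalization every trial: per-trial evidence is bounded below by
``(1 - gamma) / 3`` for ``gamma < 1`` and by the hazard reset mass
otherwise, so no underflow can accumulate across an 88-trial block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .task import TaskBlock

HazardMode = Literal["constant", "increasing"]
ResponseModel = Literal["simple", "matching", "maximizing"]

N_CUES = 3


class NumericalDegeneracyError(ArithmeticError):
    """Total evidence vanished during filtering (only possible at gamma=1)."""


@dataclass
class BCPParams:
    """Free parameters of the change-point observer.

    h : transition uncertainty, the prior per-trial shift probability
        (constant mode) or the rate of the increasing hazard.
    gamma : estimated cue validity in [0.5, 1]; 1 - gamma is the
        observation uncertainty.
    epsilon : lapse probability of the epsilon-greedy response rule.
    beta : response sharpness >= 1, used by the maximizing model only.
    """

    h: float
    gamma: float
    epsilon: float
    beta: float | None = None
    hazard_mode: HazardMode = "constant"
    response_model: ResponseModel = "simple"

    def __post_init__(self) -> None:
        if self.hazard_mode == "constant" and not (0.0 <= self.h <= 1.0):
            raise ValueError(f"h={self.h} outside [0, 1] for constant hazard")
        if self.hazard_mode == "increasing" and self.h < 0:
            raise ValueError(f"h={self.h} negative for increasing hazard")
        if not (0.5 <= self.gamma <= 1.0):
            raise ValueError(f"gamma={self.gamma} outside [0.5, 1]")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon={self.epsilon} outside [0, 1]")
        if self.response_model == "maximizing":
            if self.beta is None or self.beta < 1.0:
                raise ValueError("maximizing model requires beta >= 1")
        elif self.beta is not None:
            raise ValueError("beta is only meaningful for the maximizing model")


@dataclass
class BCPBelief:
    """Joint run-length x cue posterior.

    ``run_length_probs[l]`` is ``p(l | D)`` and ``cue_given_run[l]`` is
    ``p(c | l, D)``; ``marginal_cues`` is the mixture of the two.
    """

    run_length_probs: np.ndarray
    cue_given_run: np.ndarray

    @property
    def marginal_cues(self) -> np.ndarray:
        return self.run_length_probs @ self.cue_given_run

    def max_run_length(self) -> int:
        return len(self.run_length_probs) - 1


def bcp_init() -> BCPBelief:
    """Belief before the first trial: run length 0, uniform cues."""
    return BCPBelief(
        run_length_probs=np.array([1.0]),
        cue_given_run=np.full((1, N_CUES), 1.0 / N_CUES),
    )


def hazard(l, h: float, mode: HazardMode = "constant"):
    """Prior probability of a shift at run length ``l``.

    Constant mode returns ``h``; increasing mode returns ``1 - exp(-h l)``.
    """
    l = np.asarray(l)
    if np.any(l < 0):
        raise ValueError("run length must be >= 0")
    if mode == "constant":
        if not (0.0 <= h <= 1.0):
            raise ValueError(f"h={h} outside [0, 1]")
        return np.broadcast_to(np.float64(h), l.shape)[()]
    if mode == "increasing":
        if h < 0:
            raise ValueError(f"h={h} must be >= 0")
        return -np.expm1(-h * l)
    raise ValueError(f"unknown hazard mode {mode!r}")


def _propagate(belief: BCPBelief, params: BCPParams) -> BCPBelief:
    """Push the belief through the hazard: growth l -> l+1 plus a reset
    to l = 0 with a uniform cue distribution."""
    rl = belief.run_length_probs
    haz = np.asarray(hazard(np.arange(len(rl)), params.h, params.hazard_mode))
    reset_mass = float(np.sum(haz * rl))
    new_rl = np.empty(len(rl) + 1)
    new_rl[0] = reset_mass
    new_rl[1:] = (1.0 - haz) * rl
    new_cgr = np.empty((len(rl) + 1, N_CUES))
    new_cgr[0] = 1.0 / N_CUES
    new_cgr[1:] = belief.cue_given_run
    return BCPBelief(run_length_probs=new_rl, cue_given_run=new_cgr)


def _target_likelihood(cues: np.ndarray, target: int, gamma: float) -> np.ndarray:
    """p(target | c) for each cue c (gamma on match, 1-gamma on mismatch)."""
    return np.where(np.asarray(cues) == target, gamma, 1.0 - gamma)


def _response_probs(marginal_cues, cues, params: BCPParams) -> np.ndarray:
    """Distribution over responses (left, right) given cue beliefs."""
    m = np.asarray(marginal_cues, dtype=float)
    cues = np.asarray(cues)
    if params.response_model == "maximizing":
        w = m ** params.beta
        m = w / w.sum()
    if params.response_model == "matching":
        p_right = float(np.sum(_target_likelihood(cues, 1, params.gamma) * m))
    else:
        p_right = float(np.sum(m[cues == 1]))
    p_right = (1.0 - params.epsilon) * p_right + 0.5 * params.epsilon
    return np.array([1.0 - p_right, p_right])


def bcp_predict(
    belief: BCPBelief, cues, params: BCPParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-trial prediction.

    Returns ``(response_probs, target_probs)``: the response distribution
    over (left, right) under the configured response model, and the
    predictive distribution of the target side. Both use the
    hazard-propagated marginal cue belief.
    """
    m = _propagate(belief, params).marginal_cues
    p_target_right = float(np.sum(_target_likelihood(cues, 1, params.gamma) * m))
    return _response_probs(m, cues, params), np.array(
        [1.0 - p_target_right, p_target_right]
    )


def bcp_update(belief: BCPBelief, cues, target: int, params: BCPParams) -> BCPBelief:
    """Observe the target and return the posterior belief.

    Propagates through the hazard, weighs every (run-length, cue)
    hypothesis by the target likelihood, and renormalizes.
    """
    prop = _propagate(belief, params)
    lik = _target_likelihood(cues, target, params.gamma)  # (3,)
    joint = prop.run_length_probs[:, None] * prop.cue_given_run * lik[None, :]
    evidence = joint.sum()
    if evidence <= 0.0:
        raise NumericalDegeneracyError(
            "zero total evidence in BCP update (gamma = 1 with contradictory "
            "history)"
        )
    joint /= evidence
    rl = joint.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cgr = np.where(rl[:, None] > 0, joint / rl[:, None], 1.0 / N_CUES)
    return BCPBelief(run_length_probs=rl, cue_given_run=cgr)


@dataclass
class TrialMeasures:
    """Information-theoretic feedback measures for one trial (nats)."""

    surprisal: float
    kl_update: float
    entropy: float
    predictive_p_target: float


def bcp_trial_measures(
    belief_before: BCPBelief,
    belief_after: BCPBelief,
    cues,
    target: int,
    params: BCPParams,
) -> TrialMeasures:
    """Surprisal, KL belief update, and predictive entropy for one trial.

    ``belief_before`` is the posterior after trial t-1 and ``belief_after``
    the posterior after trial t (as returned by :func:`bcp_update`).
    Surprisal is the negative log predictive probability of the realized
    target; the KL divergence is taken between the successive
    hazard-propagated cue marginals (the beliefs that drive responding);
    entropy is the expectation of the surprisal over both target outcomes.
    """
    m_prior = _propagate(belief_before, params).marginal_cues
    lik = _target_likelihood(cues, target, params.gamma)
    p_realized = float(np.sum(lik * m_prior))
    p_right = float(np.sum(_target_likelihood(cues, 1, params.gamma) * m_prior))
    p = np.array([1.0 - p_right, p_right])
    entropy = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    m_post = _propagate(belief_after, params).marginal_cues
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(m_post > 0, m_post / m_prior, 1.0)
        kl = float(np.sum(np.where(m_post > 0, m_post * np.log(ratio), 0.0)))
    return TrialMeasures(
        surprisal=-float(np.log(p_realized)),
        kl_update=max(kl, 0.0),
        entropy=entropy,
        predictive_p_target=p_realized,
    )


def bcp_response_prob_trace(params: BCPParams, block: TaskBlock) -> np.ndarray:
    """Per-trial probability of responding 'right', computed online.

    The BCP belief depends only on cues and targets, never on responses,
    so the whole response-probability sequence is a function of the block.
    """
    from . import _kernels

    return _kernels.bcp_response_prob_kernel(
        params.h,
        params.gamma,
        params.epsilon,
        1.0 if params.beta is None else params.beta,
        block.cues,
        block.target,
        _kernels.HAZARD_CODES[params.hazard_mode],
        _kernels.RESPONSE_CODES[params.response_model],
    )


def bcp_loglik(
    params: BCPParams, block: TaskBlock, responses: np.ndarray
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of a response sequence."""
    responses = np.asarray(responses)
    if len(responses) != block.n_trials:
        raise ValueError(
            f"{len(responses)} responses for {block.n_trials} trials"
        )
    from . import _kernels

    per_trial = _kernels.bcp_loglik_kernel(
        params.h,
        params.gamma,
        params.epsilon,
        1.0 if params.beta is None else params.beta,
        block.cues,
        block.target,
        responses.astype(np.int8),
        _kernels.HAZARD_CODES[params.hazard_mode],
        _kernels.RESPONSE_CODES[params.response_model],
    )
    if np.any(np.isnan(per_trial)):
        bad = int(np.flatnonzero(np.isnan(per_trial))[0]) + 1
        raise NumericalDegeneracyError(
            f"non-finite BCP log-likelihood at trial {bad}"
        )
    return float(per_trial.sum()), per_trial


def bcp_measures_table(
    params: BCPParams, block: TaskBlock, participant_id: str = "", condition: str | None = None
) -> pd.DataFrame:
    """Trial-level feedback-processing measures for one block.

    Returns the table consumed by downstream trial-level regressions:
    participant_id, condition, trial, surprisal, kl_update, entropy,
    predictive_p_target, valid.
    """
    belief = bcp_init()
    rows = []
    for t in range(block.n_trials):
        after = bcp_update(belief, block.cues[t], int(block.target[t]), params)
        meas = bcp_trial_measures(
            belief, after, block.cues[t], int(block.target[t]), params
        )
        rows.append(
            {
                "participant_id": participant_id,
                "condition": condition or block.condition,
                "trial": t + 1,
                "surprisal": meas.surprisal,
                "kl_update": meas.kl_update,
                "entropy": meas.entropy,
                "predictive_p_target": meas.predictive_p_target,
                "valid": bool(block.valid[t]),
            }
        )
        belief = after
    return pd.DataFrame(rows)
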