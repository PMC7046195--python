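"""Selective-attention (SA) observer.

The agent attends to a single cue per trial and tracks a scalar confidence
``lambda`` that the attended cue is the relevant one; after each trial it
switches attention with probability ``1 - lambda``, resampling the new cue
uniformly from all three. Because the attended cue is unobservable, the
likelihood of a response sequence marginalizes over a grid of
(attended cue, attention run-length) hypotheses, each carrying its own
deterministic ``lambda`` trajectory: the participant's responses are
treated as data about which cue was attended, and the per-hypothesis
switch probability ``1 - lambda`` plays the role of the hazard in a
change-point filter.

Two learning variants are provided. The ``original`` variant keeps the
historical confidence recursion, in which a shift moves the relevant cue
to one of the *two other* cues (probability ``0.5 h`` of landing on the
attended cue) while attentional switches resample uniformly over all
three -- an acknowledged internal inconsistency of that model. The
``uniform_shift`` variant assumes all three cues are equally probable
after a shift, replacing the ``0.5 h`` terms with ``h / 3`` mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bcp import NumericalDegeneracyError
from .task import TaskBlock

THIRD = 1.0 / 3.0


@dataclass
class SAParams:
    """Free parameters of the selective-attention observer.

    lambda0 : prior confidence in a newly attended cue (free, or fixed
        at 0.5 to recover the classic deterministic-switch model's start).
    """

    h: float
    gamma: float
    epsilon: float
    lambda0: float = 0.5
    learning_variant: str = "original"
    response_model: str = "simple"

    def __post_init__(self) -> None:
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"h={self.h} outside [0, 1]")
        if not (0.5 <= self.gamma <= 1.0):
            raise ValueError(f"gamma={self.gamma} outside [0.5, 1]")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon={self.epsilon} outside [0, 1]")
        if not (0.0 <= self.lambda0 <= 1.0):
            raise ValueError(f"lambda0={self.lambda0} outside [0, 1]")
        if self.learning_variant not in ("original", "uniform_shift"):
            raise ValueError(f"unknown learning variant {self.learning_variant!r}")
        if self.response_model not in ("simple", "matching"):
            raise ValueError(f"unknown response model {self.response_model!r}")


def lambda_update(
    lambda_prev: float,
    attended_match: bool,
    params: SAParams,
    first_trial_of_context: bool = False,
) -> float:
    """Confidence update after observing one outcome (original variant).

    The numerator is the joint probability of the outcome and the attended
    cue being relevant; the denominator adds the joint with it being
    irrelevant (an irrelevant cue predicts the target half the time). On
    the first feedback of an attention context the prior confidence
    ``lambda0`` is used directly.
    """
    p_s = params.gamma if attended_match else 1.0 - params.gamma
    h = params.h
    if first_trial_of_context:
        num = p_s * params.lambda0
        den = 0.5 * (1.0 - params.lambda0)
    else:
        num = p_s * ((1.0 - h) * lambda_prev + 0.5 * h * (1.0 - lambda_prev))
        den = 0.5 * (h * lambda_prev + (1.0 - h) * (1.0 - lambda_prev))
    if num + den <= 0.0:
        return lambda_prev  # zero-probability outcome under this hypothesis
    return num / (num + den)


def lambda_update_uniform_shift(
    lambda_prev: float,
    attended_match: bool,
    params: SAParams,
    first_trial_of_context: bool = False,
) -> float:
    """Confidence update assuming shifts land uniformly on all three cues."""
    p_s = params.gamma if attended_match else 1.0 - params.gamma
    h = params.h
    if first_trial_of_context:
        num = p_s * params.lambda0
        den = 0.5 * (1.0 - params.lambda0)
    else:
        num = p_s * (
            (1.0 - h + h * THIRD) * lambda_prev + h * THIRD * (1.0 - lambda_prev)
        )
        den = 0.5 * (2.0 * THIRD * h * lambda_prev + (1.0 - h) * (1.0 - lambda_prev))
    if num + den <= 0.0:
        return lambda_prev  # zero-probability outcome under this hypothesis
    return num / (num + den)


def _lambda_next(lam, match, params: SAParams, first) -> float:
    fn = (
        lambda_update
        if params.learning_variant == "original"
        else lambda_update_uniform_shift
    )
    return fn(lam, match, params, first)


@dataclass
class SAHypothesisGrid:
    """Experimenter-level distribution over (attention run-length, attended
    cue), with the per-hypothesis confidence ``lambda``.

    ``joint[l, c]`` is the probability that the participant has attended
    cue ``c`` for ``l`` trials; ``lam[l, c]`` is that hypothesis's
    confidence entering the current trial.
    """

    joint: np.ndarray
    lam: np.ndarray

    @property
    def cue_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    @property
    def run_length_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=1)


def sa_init(params: SAParams) -> SAHypothesisGrid:
    """Grid before the first trial: run length 0, uniform attended cue."""
    return SAHypothesisGrid(
        joint=np.full((1, 3), THIRD),
        lam=np.full((1, 3), params.lambda0),
    )


def _response_likelihood(cues, response: int, params: SAParams) -> np.ndarray:
    """p(response | attended cue) for each cue."""
    match = np.asarray(cues) == response
    eps = params.epsilon
    if params.response_model == "simple":
        return np.where(match, (1.0 - eps) + 0.5 * eps, 0.5 * eps)
    g = params.gamma
    return np.where(
        match, (1.0 - eps) * g + 0.5 * eps, (1.0 - eps) * (1.0 - g) + 0.5 * eps
    )


def sa_predict(grid: SAHypothesisGrid, cues, params: SAParams) -> np.ndarray:
    """Response distribution over (left, right) given the current grid."""
    p_right = float(np.sum(grid.cue_marginal * _response_likelihood(cues, 1, params)))
    return np.array([1.0 - p_right, p_right])


def sa_filter_step(
    grid: SAHypothesisGrid, cues, response: int, target: int, params: SAParams
) -> SAHypothesisGrid:
    """Advance the hypothesis grid by one trial.

    Order within the trial: (i) weight each hypothesis by the likelihood
    of the observed response; (ii) update each hypothesis's confidence
    with the realized target; (iii) propagate run lengths, each hypothesis
    switching with probability ``1 - lambda`` into a uniform reset.
    """
    rlik = _response_likelihood(cues, response, params)
    joint = grid.joint * rlik[None, :]
    total = joint.sum()
    if total <= 0.0:
        raise NumericalDegeneracyError("zero response likelihood in SA filter")
    joint = joint / total

    L = joint.shape[0]
    lam_new = np.empty_like(grid.lam)
    for l in range(L):
        for c in range(3):
            match = bool(np.asarray(cues)[c] == target)
            lam_new[l, c] = _lambda_next(grid.lam[l, c], match, params, l == 0)

    new_joint = np.zeros((L + 1, 3))
    new_lam = np.empty((L + 1, 3))
    new_joint[1:] = joint * lam_new
    new_lam[1:] = lam_new
    reset_mass = float(np.sum(joint * (1.0 - lam_new)))
    new_joint[0] = reset_mass * THIRD
    new_lam[0] = params.lambda0
    new_joint /= new_joint.sum()
    return SAHypothesisGrid(joint=new_joint, lam=new_lam)


def sa_loglik(
    params: SAParams, block: TaskBlock, responses: np.ndarray
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of a response sequence."""
    responses = np.asarray(responses)
    if len(responses) != block.n_trials:
        raise ValueError(f"{len(responses)} responses for {block.n_trials} trials")
    from . import _kernels

    per_trial = _kernels.sa_loglik_kernel(
        params.h,
        params.gamma,
        params.epsilon,
        params.lambda0,
        block.cues,
        block.target,
        responses.astype(np.int8),
        _kernels.SA_VARIANT_CODES[params.learning_variant],
        0 if params.response_model == "simple" else 1,
    )
    if np.any(np.isnan(per_trial)):
        bad = int(np.flatnonzero(np.isnan(per_trial))[0]) + 1
        raise NumericalDegeneracyError(f"non-finite SA log-likelihood at trial {bad}")
    return float(per_trial.sum()), per_trial
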