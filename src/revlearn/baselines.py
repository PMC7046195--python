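"""Benchmark models: win-stay/lose-shift and a no-learning proportion rule.

WSLS attends to a single cue, stays with it after an expected outcome
(target matches the attended cue's orientation) with probability
``p_stay`` and switches after an unexpected outcome with probability
``p_shift``. Like the selective-attention observer, the attended cue is
latent, so the likelihood marginalizes over the same
(attended cue, run-length) hypothesis grid, with the stay/shift rule
supplying the switch probabilities.

The no-learning model responds according to the proportion of cues
pointing each way, with no state at all; an epsilon-mixed variant is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import TaskBlock


@dataclass
class WSLSParams:
    p_stay: float
    p_shift: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_stay", "p_shift", "epsilon"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def wsls_loglik(
    params: WSLSParams, block: TaskBlock, responses: np.ndarray
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood under win-stay/lose-shift."""
    responses = np.asarray(responses)
    if len(responses) != block.n_trials:
        raise ValueError(f"{len(responses)} responses for {block.n_trials} trials")
    from . import _kernels

    per_trial = _kernels.wsls_loglik_kernel(
        params.p_stay,
        params.p_shift,
        params.epsilon,
        block.cues,
        block.target,
        responses.astype(np.int8),
    )
    return float(per_trial.sum()), per_trial


def nolearn_predict(cues, epsilon: float = 0.0) -> np.ndarray:
    """Response distribution from the proportion of right-pointing cues.

    With ``epsilon > 0`` the proportion rule is mixed with uniform lapses;
    the default model has no free parameters.
    """
    cues = np.asarray(cues)
    p_right = float(np.sum(cues == 1)) / cues.size
    p_right = (1.0 - epsilon) * p_right + 0.5 * epsilon
    return np.array([1.0 - p_right, p_right])


def nolearn_loglik(
    block: TaskBlock, responses: np.ndarray, epsilon: float = 0.0
) -> tuple[float, np.ndarray]:
    """Log-likelihood under the no-learning proportion rule.

    Stateless: each trial depends only on that trial's cues, so the total
    is invariant to trial order. Responses that the rule assigns zero
    probability (all cues pointing the other way, epsilon = 0) yield
    ``-inf`` for that trial.
    """
    responses = np.asarray(responses)
    if len(responses) != block.n_trials:
        raise ValueError(f"{len(responses)} responses for {block.n_trials} trials")
    p_right = (np.sum(block.cues == 1, axis=1) / 3.0).astype(float)
    p_right = (1.0 - epsilon) * p_right + 0.5 * epsilon
    p = np.where(responses == 1, p_right, 1.0 - p_right)
    with np.errstate(divide="ignore"):
        per_trial = np.log(p)
    return float(per_trial.sum()), per_trial
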