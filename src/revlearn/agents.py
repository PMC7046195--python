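"""Generative agents: sample response sequences from any candidate model.

Each agent inverts its model's response rule online: beliefs (or the
attended cue) are updated after every trial's target, and the next
response is sampled from the model's trial-wise response distribution.
Simulation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .baselines import WSLSParams, nolearn_predict
from .bcp import BCPParams, bcp_response_prob_trace
from .sa import SAParams, _lambda_next
from .task import AgentSpec, TaskBlock

THIRD = 1.0 / 3.0


def _coerce_params(spec: AgentSpec):
    if spec.model == "BCP":
        return spec.params if isinstance(spec.params, BCPParams) else BCPParams(**spec.params)
    if spec.model == "SA":
        return spec.params if isinstance(spec.params, SAParams) else SAParams(**spec.params)
    if spec.model == "WSLS":
        return spec.params if isinstance(spec.params, WSLSParams) else WSLSParams(**spec.params)
    return dict(spec.params) if not isinstance(spec.params, dict) else spec.params


def simulate_agent(
    spec: AgentSpec, block: TaskBlock, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate one response sequence (0 = left, 1 = right) for a block."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = _coerce_params(spec)
    T = block.n_trials

    if spec.model == "RANDOM":
        return rng.integers(0, 2, size=T).astype(np.int8)

    if spec.model == "NOLEARN":
        eps = params.get("epsilon", 0.0) if isinstance(params, dict) else 0.0
        p_right = np.array(
            [nolearn_predict(block.cues[t], eps)[1] for t in range(T)]
        )
        return (rng.random(T) < p_right).astype(np.int8)

    if spec.model == "BCP":
        # the BCP belief never depends on the agent's own responses
        p_right = bcp_response_prob_trace(params, block)
        return (rng.random(T) < p_right).astype(np.int8)

    if spec.model == "SA":
        return _simulate_sa(params, block, rng)

    return _simulate_wsls(params, block, rng)


def _eps_greedy(orientation: int, epsilon: float, rng) -> int:
    if rng.random() < epsilon:
        return int(rng.integers(0, 2))
    return int(orientation)


def _simulate_sa(params: SAParams, block: TaskBlock, rng) -> np.ndarray:
    responses = np.empty(block.n_trials, dtype=np.int8)
    attended = int(rng.integers(3))
    lam = params.lambda0
    fresh = True  # no feedback observed yet in this attention context
    for t in range(block.n_trials):
        responses[t] = _eps_greedy(int(block.cues[t, attended]), params.epsilon, rng)
        match = bool(block.cues[t, attended] == block.target[t])
        lam = _lambda_next(lam, match, params, fresh)
        fresh = False
        if rng.random() < 1.0 - lam:  # switch attention, uniform over all cues
            attended = int(rng.integers(3))
            lam = params.lambda0
            fresh = True
    return responses


def _simulate_wsls(params: WSLSParams, block: TaskBlock, rng) -> np.ndarray:
    responses = np.empty(block.n_trials, dtype=np.int8)
    attended = int(rng.integers(3))
    for t in range(block.n_trials):
        responses[t] = _eps_greedy(int(block.cues[t, attended]), params.epsilon, rng)
        expected = bool(block.cues[t, attended] == block.target[t])
        p_switch = (1.0 - params.p_stay) if expected else params.p_shift
        if rng.random() < p_switch:
            attended = int(rng.integers(3))
    return responses
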