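"""Independent brute-force oracles used to pin down the recursive filters.

These deliberately avoid the run-length recursion: the change-point
observer is checked by exhaustive enumeration over reset patterns, and
the latent-attention models by exhaustive enumeration over attention
paths (stay / switch-to-cue decisions). They are exponential in the
number of trials and only usable on toy blocks.
"""

from __future__ import annotations

from itertools import product

import numpy as np

THIRD = 1.0 / 3.0


def _hazard(l: int, h: float, mode: str) -> float:
    return h if mode == "constant" else 1.0 - np.exp(-h * l)


def bcp_enum_marginal(
    h: float,
    gamma: float,
    cues: np.ndarray,
    targets: np.ndarray,
    t: int,
    hazard_mode: str = "constant",
) -> np.ndarray:
    """Predictive cue marginal entering trial ``t`` (0-based), by summing
    over all reset patterns of trials 1..t.

    A pattern assigns to each trial j in 1..t a binary indicator of a
    shift immediately before j. Trial 0 always starts a run. The pattern
    prior multiplies hazard terms; each completed segment contributes the
    marginal likelihood of its targets under a uniformly drawn cue; the
    open segment's posterior over cues is the predictive marginal.
    """
    total = 0.0
    acc = np.zeros(3)
    for pattern in product([0, 1], repeat=t):
        prior = 1.0
        # run length at a reset is 0 on the reset trial itself, while the
        # initial run counts from a virtual pre-experiment start (the
        # standard online change-point convention)
        seg_start = -1
        boundaries = []
        for j in range(1, t + 1):
            hz = _hazard(j - seg_start - 1, h, hazard_mode)
            if pattern[j - 1]:
                prior *= hz
                boundaries.append(j)
                seg_start = j
            else:
                prior *= 1.0 - hz
        segments = []
        start = 0
        for b in boundaries:
            segments.append((start, b))
            start = b
        open_start = start
        lik = 1.0
        for s0, s1 in segments:
            seg = 0.0
            for c in range(3):
                pc = THIRD
                for j in range(s0, s1):
                    pc *= gamma if cues[j, c] == targets[j] else 1.0 - gamma
                seg += pc
            lik *= seg
        cue_w = np.zeros(3)
        for c in range(3):
            pc = THIRD
            for j in range(open_start, t):
                pc *= gamma if cues[j, c] == targets[j] else 1.0 - gamma
            cue_w[c] = pc
        w = prior * lik
        total += w * cue_w.sum()
        acc += w * cue_w
    return acc / total


def bcp_enum_loglik(
    h: float,
    gamma: float,
    eps: float,
    cues: np.ndarray,
    targets: np.ndarray,
    responses: np.ndarray,
    hazard_mode: str = "constant",
    response_model: str = "simple",
    beta: float = 1.0,
) -> np.ndarray:
    """Per-trial response log-likelihood via the enumeration marginal."""
    T = len(targets)
    out = np.empty(T)
    for t in range(T):
        m = bcp_enum_marginal(h, gamma, cues, targets, t, hazard_mode)
        if response_model == "maximizing":
            w = m**beta
            m = w / w.sum()
        if response_model == "matching":
            p_right = float(
                np.sum(np.where(cues[t] == 1, gamma, 1 - gamma) * m)
            )
        else:
            p_right = float(np.sum(m[cues[t] == 1]))
        p_right = (1 - eps) * p_right + 0.5 * eps
        out[t] = np.log(p_right if responses[t] == 1 else 1 - p_right)
    return out


def _sa_lambda_next(lam, match, h, gamma, lam0, fresh, variant):
    p_s = gamma if match else 1.0 - gamma
    if fresh:
        num, den = p_s * lam0, 0.5 * (1.0 - lam0)
    elif variant == "original":
        num = p_s * ((1 - h) * lam + 0.5 * h * (1 - lam))
        den = 0.5 * (h * lam + (1 - h) * (1 - lam))
    else:
        num = p_s * ((1 - h + h / 3) * lam + (h / 3) * (1 - lam))
        den = 0.5 * ((2 / 3) * h * lam + (1 - h) * (1 - lam))
    return num / (num + den)


def _attention_paths_loglik(
    cues,
    targets,
    responses,
    response_lik,
    switch_prob,
    init_state,
    after_feedback,
):
    """Shared path-sum over latent attention trajectories.

    States are (probability, attended cue, model-specific memory). At
    each trial the path weight is multiplied by the likelihood of the
    observed response; after feedback each path branches into `stay` and
    three `switch` continuations. Per-trial conditionals come from the
    ratio of successive total path masses.
    """
    T = len(targets)
    states = [(THIRD, c) + init_state(c) for c in range(3)]
    out = np.empty(T)
    prev_mass = 1.0
    for t in range(T):
        states = [
            (s[0] * response_lik(t, s[1]),) + s[1:] for s in states if s[0] > 0
        ]
        mass = sum(s[0] for s in states)
        out[t] = np.log(mass / prev_mass)
        prev_mass = mass
        if t == T - 1:
            break
        new_states = []
        for s in states:
            w, c = s[0], s[1]
            mem = after_feedback(t, s)
            p_sw = switch_prob(t, s, mem)
            if w * (1 - p_sw) > 0:
                new_states.append((w * (1 - p_sw), c) + mem)
            for c2 in range(3):
                if w * p_sw > 0:
                    new_states.append(
                        (w * p_sw * THIRD, c2) + init_state(c2)
                    )
        states = new_states
    return out


def sa_enum_loglik(
    h, gamma, eps, lam0, cues, targets, responses, variant="original"
) -> np.ndarray:
    """Per-trial SA log-likelihood by exhaustive attention-path summation."""

    def response_lik(t, c):
        match = cues[t, c] == responses[t]
        return (1 - eps) + 0.5 * eps if match else 0.5 * eps

    def init_state(c):
        return (lam0, True)

    def after_feedback(t, s):
        _, c, lam, fresh = s
        match = cues[t, c] == targets[t]
        return (_sa_lambda_next(lam, match, h, gamma, lam0, fresh, variant), False)

    def switch_prob(t, s, mem):
        return 1.0 - mem[0]

    return _attention_paths_loglik(
        cues, targets, responses, response_lik, switch_prob, init_state, after_feedback
    )


def wsls_enum_loglik(p_stay, p_shift, eps, cues, targets, responses) -> np.ndarray:
    """Per-trial WSLS log-likelihood by attention-path summation."""

    def response_lik(t, c):
        match = cues[t, c] == responses[t]
        return (1 - eps) + 0.5 * eps if match else 0.5 * eps

    def init_state(c):
        return ()

    def after_feedback(t, s):
        return ()

    def switch_prob(t, s, mem):
        c = s[1]
        expected = cues[t, c] == targets[t]
        return (1.0 - p_stay) if expected else p_shift

    return _attention_paths_loglik(
        cues, targets, responses, response_lik, switch_prob, init_state, after_feedback
    )
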