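"""Three-cue probabilistic reversal-learning task structure.

Each trial presents three arrow cues (top, middle, bottom), each pointing
left or right. Exactly one cue -- the *relevant* cue -- predicts the side on
which the target appears; after an unsignaled contingency shift a different
cue becomes relevant. In the deterministic condition the relevant cue always
predicts the target; in the probabilistic condition it does so on an exact
75% of trials within each of the pre- and post-shift segments.

Sides are coded internally as integers (0 = left, 1 = right); cue indices
are 0-based internally and 1-based in all text output. Trials are 1-based
everywhere a trial index is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

LEFT, RIGHT = 0, 1
SIDE_CODES = {"L": LEFT, "R": RIGHT}
SIDE_LABELS = {LEFT: "L", RIGHT: "R"}

Condition = Literal["deterministic", "probabilistic"]

#: standard block layout: 88 trials, shift after trial 40 or 48
DEFAULT_N_TRIALS = 88
SHIFT_TRIALS = (40, 48)
DEFAULT_CUE_VALIDITY = {"deterministic": 1.0, "probabilistic": 0.75}


class ConfigurationError(ValueError):
    """Raised for invalid task or generator configurations."""


@dataclass
class TaskBlock:
    """One condition's cue/target sequence with ground truth.

    Attributes
    ----------
    condition : {"deterministic", "probabilistic"}
    cues : (n_trials, 3) int array of sides, columns = top, middle, bottom.
    target : (n_trials,) int array of target sides.
    relevant_cue : (n_trials,) int array, 0-based index of the relevant cue.
    valid : (n_trials,) bool array, True where the target matched the
        relevant cue's orientation.
    shift_trial : 1-based index of the *last* trial of the old contingency.
    cue_validity : nominal probability that the relevant cue is valid.
    """

    condition: str
    cues: np.ndarray
    target: np.ndarray
    relevant_cue: np.ndarray
    valid: np.ndarray
    shift_trial: int
    cue_validity: float

    @property
    def n_trials(self) -> int:
        return len(self.target)

    def __post_init__(self) -> None:
        self.cues = np.asarray(self.cues, dtype=np.int8)
        self.target = np.asarray(self.target, dtype=np.int8)
        self.relevant_cue = np.asarray(self.relevant_cue, dtype=np.int8)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.target)
        if self.cues.shape != (n, 3):
            raise ConfigurationError(
                f"cues shape {self.cues.shape} does not match {n} trials"
            )
        if not (1 <= self.shift_trial < n):
            raise ConfigurationError(
                f"shift_trial {self.shift_trial} outside 1..{n - 1}"
            )

    def segment(self) -> np.ndarray:
        """Per-trial segment label: 'pre' or 'post' shift."""
        t = np.arange(1, self.n_trials + 1)
        return np.where(t <= self.shift_trial, "pre", "post")


def _exact_valid_mask(n: int, validity: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with exactly round(validity * n) True entries, placed
    by a seeded permutation."""
    n_valid = int(round(validity * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:n_valid]] = True
    return mask


def generate_block(
    condition: Condition,
    n_trials: int = DEFAULT_N_TRIALS,
    shift_trial: int = 40,
    cue_validity: float | None = None,
    seed: int | np.random.Generator = 0,
) -> TaskBlock:
    """Generate one task block.

    The relevant cue is drawn uniformly for the pre-shift segment and
    uniformly from the two *other* cues for the post-shift segment (the same
    cue is never resampled after a shift). Cue orientations are independent
    Bernoulli(0.5). Invalid trials are allocated by exact proportion within
    each segment, placed by a seeded permutation.
    """
    if condition not in ("deterministic", "probabilistic"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if cue_validity is None:
        cue_validity = DEFAULT_CUE_VALIDITY[condition]
    if condition == "deterministic" and cue_validity != 1.0:
        raise ConfigurationError(
            "deterministic condition requires cue_validity 1.0, got "
            f"{cue_validity}"
        )
    if not (0.5 < cue_validity <= 1.0):
        raise ConfigurationError(f"cue_validity {cue_validity} outside (0.5, 1]")
    if n_trials < 2:
        raise ConfigurationError("n_trials must be >= 2")
    if not (1 <= shift_trial < n_trials):
        raise ConfigurationError(
            f"shift_trial {shift_trial} outside 1..{n_trials - 1}"
        )

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cues = rng.integers(0, 2, size=(n_trials, 3), dtype=np.int8)
    pre_cue = int(rng.integers(3))
    post_cue = int(rng.choice([c for c in range(3) if c != pre_cue]))
    relevant = np.where(np.arange(n_trials) < shift_trial, pre_cue, post_cue)

    valid = np.ones(n_trials, dtype=bool)
    if cue_validity < 1.0:
        valid[:shift_trial] = _exact_valid_mask(shift_trial, cue_validity, rng)
        valid[shift_trial:] = _exact_valid_mask(
            n_trials - shift_trial, cue_validity, rng
        )

    rel_orient = cues[np.arange(n_trials), relevant]
    target = np.where(valid, rel_orient, 1 - rel_orient).astype(np.int8)

    return TaskBlock(
        condition=condition,
        cues=cues,
        target=target,
        relevant_cue=relevant,
        valid=valid,
        shift_trial=shift_trial,
        cue_validity=cue_validity,
    )


@dataclass
class AgentSpec:
    """A generative agent: a model name, its parameters, and a seed."""

    model: str  # BCP | SA | WSLS | NOLEARN | RANDOM
    params: dict = field(default_factory=dict)
    seed: int = 0

    VALID_MODELS = ("BCP", "SA", "WSLS", "NOLEARN", "RANDOM")

    def __post_init__(self) -> None:
        if self.model not in self.VALID_MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}")
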