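"""Synthetic cohorts with known parameter-symptom structure.

The generator emulates the study conditions: each participant completes
one deterministic and one probabilistic 88-trial block (shift after trial
40 or 48, counterbalanced), responses are simulated from the change-point
observer at participant-specific parameters, and the symptom scores have
a right-skewed distribution calibrated so that ~40% of participants
exceed the common clinical cutoff of 21 on the OCI-R (0-50).

The embedded effect is a population correlation ``rho`` between the
OCI-R total and the probit-scale transition uncertainty: with ``z`` the
population-standardized OCI-R score,

    probit(h) = mu_h + sigma_h * (rho * z + sqrt(1 - rho^2) * noise).

Cue-validity and lapse parameters are drawn from their group
distributions independently of symptoms, matching the null pattern
reported for those parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .agents import simulate_agent
from .bcp import BCPParams
from .task import AgentSpec, ConfigurationError, TaskBlock, generate_block

CONDITIONS = ("deterministic", "probabilistic")

#: group-level hyperparameters on the probit scale (mu, sigma) per condition.
#: Transition uncertainty has median ~0.14 (probabilistic) / ~0.07
#: (deterministic) with individual values spanning roughly 0.01-0.6,
#: matching the spread of fitted values in the study; gamma centers at
#: the true validity (0.75) in the probabilistic condition and near 1 in
#: the deterministic one; lapses center near 0.05.
DEFAULT_HYPERS = {
    "probabilistic": {
        "h": (-1.1, 0.7),
        "gamma": (0.0, 0.4),
        "epsilon": (-1.6449, 0.3),
    },
    "deterministic": {
        "h": (-1.5, 0.7),
        "gamma": (2.0537, 0.4),
        "epsilon": (-1.6449, 0.3),
    },
}

#: embedded correlation between OCI-R and probit-scale h per condition,
#: matching the reported effect sizes (r = .31 probabilistic, .24
#: deterministic).
DEFAULT_EFFECT = {"probabilistic": 0.31, "deterministic": 0.24}

#: Gaussian-copula correlations between OCI-R and the DASS subscales.
DASS_SPEC = {
    "depression": {"r": 0.50, "shape": 1.5, "mean": 6.0, "max": 19},
    "anxiety": {"r": 0.35, "shape": 1.5, "mean": 5.0, "max": 18},
    "stress": {"r": 0.35, "shape": 1.5, "mean": 7.0, "max": 20},
}

OCIR_MAX = 50
OCIR_CUTOFF = 21
OCIR_TARGET_FRAC_ABOVE = 0.40
OCIR_SHAPE = 2.0


@lru_cache(maxsize=None)
def ocir_scale(
    shape: float = OCIR_SHAPE,
    frac_above: float = OCIR_TARGET_FRAC_ABOVE,
    cutoff: int = OCIR_CUTOFF,
    max_score: int = OCIR_MAX,
) -> float:
    """Gamma scale calibrated so that P(score > cutoff) = frac_above.

    Scores are gamma draws truncated at max_score + 0.5 and rounded; this
    is a calibration of the synthetic distribution's shape, not a claim
    about the true population.
    """

    def excess(scale):
        dist = stats.gamma(shape, scale=scale)
        hi = dist.cdf(max_score + 0.5)
        return (hi - dist.cdf(cutoff + 0.5)) / hi - frac_above

    return float(optimize.brentq(excess, 1.0, 40.0))


@lru_cache(maxsize=None)
def _ocir_moments(scale: float) -> tuple[float, float]:
    """Population mean and SD of the discretized truncated score."""
    dist = stats.gamma(OCIR_SHAPE, scale=scale)
    edges = np.arange(OCIR_MAX + 2) - 0.5
    pmf = np.diff(dist.cdf(np.clip(edges, 0, None)))
    pmf /= pmf.sum()
    k = np.arange(OCIR_MAX + 1)
    mean = float(np.sum(k * pmf))
    sd = float(np.sqrt(np.sum((k - mean) ** 2 * pmf)))
    return mean, sd


def sample_ocir(n: int, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed integer OCI-R totals on [0, 50]."""
    scale = ocir_scale()
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.gamma(OCIR_SHAPE, scale, size=2 * (n - filled))
        draw = draw[draw <= OCIR_MAX + 0.5][: n - filled]
        out[filled : filled + len(draw)] = np.round(draw).astype(np.int64)
        filled += len(draw)
    return np.clip(out, 0, OCIR_MAX)


@dataclass
class Participant:
    id: str
    ocir: int
    dass: dict
    true_params: dict  # condition -> {"h": ..., "gamma": ..., "epsilon": ...}
    blocks: dict = field(default_factory=dict)  # condition -> TaskBlock
    responses: dict = field(default_factory=dict)  # condition -> int8 array


@dataclass
class CohortDataset:
    participants: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.participants)

    def ocir_scores(self) -> np.ndarray:
        return np.array([p.ocir for p in self.participants])

    def true_param(self, name: str, condition: str) -> np.ndarray:
        return np.array(
            [p.true_params[condition][name] for p in self.participants]
        )


def generate_cohort(
    n_participants: int = 57,
    effect: dict | None = None,
    hypers: dict | None = None,
    seed: int = 0,
    n_trials: int = 88,
) -> CohortDataset:
    """Generate a synthetic cohort with BCP-generated responses.

    ``effect`` maps condition to the target population correlation between
    OCI-R and probit-scale transition uncertainty.
    """
    if n_participants < 2:
        raise ConfigurationError("a cohort needs at least 2 participants")
    effect = DEFAULT_EFFECT if effect is None else dict(effect)
    hypers = DEFAULT_HYPERS if hypers is None else hypers
    for cond, rho in effect.items():
        if not (-1.0 < rho < 1.0):
            raise ConfigurationError(f"rho={rho} outside (-1, 1)")
        if rho != 0.0 and hypers[cond]["h"][1] == 0.0:
            raise ConfigurationError(
                f"embedded correlation in {cond} requires sigma_h > 0"
            )

    rng = np.random.default_rng(seed)
    scale = ocir_scale()
    mean, sd = _ocir_moments(scale)
    ocir = sample_ocir(n_participants, rng)
    z = (ocir - mean) / sd

    dass = {}
    for name, spec in DASS_SPEC.items():
        latent = spec["r"] * z + np.sqrt(1 - spec["r"] ** 2) * rng.standard_normal(
            n_participants
        )
        g = stats.gamma(spec["shape"], scale=spec["mean"] / spec["shape"])
        scores = np.round(g.ppf(np.clip(stats.norm.cdf(latent), 1e-9, 1 - 1e-9)))
        dass[name] = np.clip(scores, 0, spec["max"]).astype(np.int64)

    participants = []
    for i in range(n_participants):
        true_params = {}
        for cond in CONDITIONS:
            hyp = hypers[cond]
            rho = effect.get(cond, 0.0)
            eta_h = hyp["h"][0] + hyp["h"][1] * (
                rho * z[i] + np.sqrt(1 - rho**2) * rng.standard_normal()
            )
            eta_g = hyp["gamma"][0] + hyp["gamma"][1] * rng.standard_normal()
            eta_e = hyp["epsilon"][0] + hyp["epsilon"][1] * rng.standard_normal()
            true_params[cond] = {
                "h": float(stats.norm.cdf(eta_h)),
                "gamma": float(stats.norm.cdf(eta_g) / 2 + 0.5),
                "epsilon": float(stats.norm.cdf(eta_e)),
            }
        # counterbalance the shift position across participants/conditions
        shifts = (40, 48) if i % 2 == 0 else (48, 40)
        blocks, responses = {}, {}
        for cond, shift in zip(CONDITIONS, shifts):
            block = generate_block(
                cond,
                n_trials=n_trials,
                shift_trial=shift,
                seed=np.random.default_rng(rng.integers(2**31)),
            )
            spec = AgentSpec(
                model="BCP",
                params=BCPParams(**true_params[cond]),
                seed=int(rng.integers(2**31)),
            )
            blocks[cond] = block
            responses[cond] = simulate_agent(spec, block)
        participants.append(
            Participant(
                id=f"p{i + 1:03d}",
                ocir=int(ocir[i]),
                dass={k: int(v[i]) for k, v in dass.items()},
                true_params=true_params,
                blocks=blocks,
                responses=responses,
            )
        )

    provenance = {
        "generator": "revlearn.cohort.generate_cohort",
        "n_participants": n_participants,
        "effect": effect,
        "seed": seed,
        "n_trials": n_trials,
        "ocir_gamma_shape": OCIR_SHAPE,
        "ocir_gamma_scale": scale,
    }
    return CohortDataset(participants=participants, provenance=provenance)
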