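"""Hierarchical Bayesian estimation of per-participant model parameters.

Participant-level parameters live on a latent probit scale: for
participant ``s`` and parameter ``k``, ``eta_sk ~ Normal(mu_k, sigma_k)``
and the natural-scale value is obtained through a parameter-specific
transform (probit for probabilities; probit rescaled to [0.5, 1] for the
cue validity ``gamma``; ``1 + exp`` for the response sharpness ``beta``).
Group means have standard-normal hyperpriors -- through the probit link
this is a uniform prior on each group-level probability -- and group SDs
have half-Student-t(nu=50, scale=0.2) hyperpriors, which keeps the
individual-level prior close to uniform while still allowing spread when
the group mean is extreme.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme:

- each participant's ``eta_s`` is updated coordinate-wise by random-walk
  Metropolis with step sizes adapted during warmup toward a 44%
  acceptance rate (only that participant's likelihood is evaluated);
- each group mean is a conjugate Gibbs draw;
- each group SD is drawn by stepping-out slice sampling.

By default the sampler runs in this centered parameterization; a
non-centered parameterization (random-walk updates of standardized
scores ``z_s`` with Metropolis updates of the group parameters) is
available for cross-checking. Chains are compared with the classic
split-R-hat; a fit whose worst R-hat exceeds 1.1 is re-run with a doubled
iteration budget (up to ``max_escalations`` times) and flagged if it
still fails. Point estimates are posterior medians pooled across chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from . import _kernels
from .cohort import CohortDataset
from .task import ConfigurationError

RHAT_THRESHOLD = 1.1

#: published estimation procedure: 3 chains of 1000 iterations, 400 warmup;
#: best-fitting models are refit at 1500 iterations with 500 warmup.
FULL_SCALE = {"chains": 3, "iterations": 1000, "warmup": 400}
BEST_MODEL_REFIT = {"chains": 3, "iterations": 1500, "warmup": 500}

#: transform kinds per parameter name
TRANSFORMS = {
    "h": "probit",
    "epsilon": "probit",
    "lambda0": "probit",
    "p_stay": "probit",
    "p_shift": "probit",
    "gamma": "probit_half",
    "beta": "one_plus_exp",
}

SIGMA_PRIOR_DF = 50
SIGMA_PRIOR_SCALE = 0.2


def transform_params(z, mu: float, sigma: float, kind: str):
    """Map an auxiliary score to the natural scale: ``eta = sigma z + mu``
    pushed through the parameter's link."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    eta = np.asarray(sigma * np.asarray(z) + mu, dtype=float)
    return _natural(eta, kind)


def _natural(eta, kind: str):
    if kind == "probit":
        return special.ndtr(eta)
    if kind == "probit_half":
        return special.ndtr(eta) / 2.0 + 0.5
    if kind == "one_plus_exp":
        return 1.0 + np.exp(eta)
    raise ValueError(f"unknown transform kind {kind!r}")


def model_parameters(model: str, options: dict) -> list[str]:
    """Free-parameter names for a model configuration, in sampler order."""
    if model == "BCP":
        names = ["h", "gamma", "epsilon"]
        if options.get("response_model", "simple") == "maximizing":
            names.append("beta")
        return names
    if model == "SA":
        names = ["h", "gamma", "epsilon"]
        if options.get("lambda0_free", True):
            names.append("lambda0")
        return names
    if model == "WSLS":
        return ["p_stay", "p_shift", "epsilon"]
    raise ConfigurationError(f"unknown model {model!r}")


@dataclass
class HierarchicalSpec:
    """Configuration of one hierarchical fit."""

    model: str = "BCP"
    options: dict = field(default_factory=dict)
    chains: int = 3
    iterations: int = 1000  # per chain, including warmup
    warmup: int = 400
    seed: int = 0
    max_escalations: int = 2
    parameterization: str = "centered"

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ConfigurationError("at least 2 chains are required")
        if self.iterations <= self.warmup:
            raise ConfigurationError("iterations must exceed warmup")
        if self.iterations <= 0 or self.warmup < 0:
            raise ConfigurationError("invalid iteration budget")
        if self.parameterization not in ("centered", "noncentered"):
            raise ConfigurationError(
                f"unknown parameterization {self.parameterization!r}"
            )
        self.param_names = model_parameters(self.model, self.options)


@dataclass
class PosteriorDraws:
    """Posterior draws and diagnostics from one hierarchical fit."""

    params: dict  # name -> (chains, draws, participants) natural scale
    group_mu: dict  # name -> (chains, draws)
    group_sigma: dict  # name -> (chains, draws)
    pointwise: np.ndarray  # (chains, draws, participants, trials) log-lik
    participant_ids: list
    spec: HierarchicalSpec
    condition: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.pointwise.shape[0] * self.pointwise.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """(total draws, participants) natural-scale draws, chains pooled."""
        a = self.params[name]
        return a.reshape(-1, a.shape[-1])

    def pointwise_matrix(self) -> np.ndarray:
        """(total draws, participants * trials) pointwise log-likelihood."""
        c, d, s, t = self.pointwise.shape
        return self.pointwise.reshape(c * d, s * t)


def _model_data(dataset: CohortDataset, condition: str):
    data = []
    ids = []
    for p in dataset.participants:
        if condition not in p.blocks or condition not in p.responses:
            continue
        block = p.blocks[condition]
        data.append(
            (
                np.ascontiguousarray(block.cues, dtype=np.int8),
                np.ascontiguousarray(block.target, dtype=np.int8),
                np.ascontiguousarray(p.responses[condition], dtype=np.int8),
            )
        )
        ids.append(p.id)
    return data, ids


def _kernel_opts(spec: HierarchicalSpec) -> tuple[int, int, int]:
    model = _kernels.MODEL_CODES[spec.model]
    o = spec.options
    if spec.model == "BCP":
        opt0 = _kernels.HAZARD_CODES[o.get("hazard_mode", "constant")]
        opt1 = _kernels.RESPONSE_CODES[o.get("response_model", "simple")]
    elif spec.model == "SA":
        opt0 = _kernels.SA_VARIANT_CODES[o.get("learning_variant", "original")]
        opt1 = 0 if o.get("response_model", "simple") == "simple" else 1
    else:
        opt0 = opt1 = 0
    return model, opt0, opt1


def _make_loglik(spec: HierarchicalSpec, data):
    """Per-participant per-trial log-likelihood as a function of the
    natural-scale parameter vector."""
    model, opt0, opt1 = _kernel_opts(spec)
    names = spec.param_names
    fixed_lambda0 = (
        spec.model == "SA" and not spec.options.get("lambda0_free", True)
    )

    def loglik(s: int, theta: np.ndarray) -> np.ndarray:
        p = dict(zip(names, theta))
        if spec.model == "BCP":
            args = (p["h"], p["gamma"], p["epsilon"], p.get("beta", 1.0))
        elif spec.model == "SA":
            lam0 = 0.5 if fixed_lambda0 else p["lambda0"]
            args = (p["h"], p["gamma"], p["epsilon"], lam0)
        else:
            args = (p["p_stay"], p["p_shift"], p["epsilon"], 0.0)
        cues, target, resp = data[s]
        return _kernels.loglik_dispatch(
            model, *args, cues, target, resp, opt0, opt1
        )

    return loglik


def _sigma_log_prior(sigma: float) -> float:
    # half-t(nu, scale) density up to a constant
    if sigma <= 0:
        return -np.inf
    return float(
        stats.t.logpdf(sigma / SIGMA_PRIOR_SCALE, df=SIGMA_PRIOR_DF)
    )


def _slice_sample_sigma(
    sigma: float, eta_k: np.ndarray, mu_k: float, rng, width: float = 0.3
) -> float:
    """Stepping-out slice sampler for one group SD."""

    n = len(eta_k)
    ssq = float(np.sum((eta_k - mu_k) ** 2))

    def logp(s):
        if s <= 0:
            return -np.inf
        return _sigma_log_prior(s) - n * np.log(s) - 0.5 * ssq / (s * s)

    y = logp(sigma) + np.log(rng.random())
    lo = sigma - width * rng.random()
    hi = lo + width
    while lo > 0 and logp(lo) > y:
        lo -= width
    lo = max(lo, 1e-6)
    while logp(hi) > y:
        hi += width
    for _ in range(100):
        prop = rng.uniform(lo, hi)
        if logp(prop) > y:
            return prop
        if prop < sigma:
            lo = prop
        else:
            hi = prop
    return sigma


def _run_chain(spec: HierarchicalSpec, data, kinds, rng, iterations, warmup):
    S = len(data)
    K = len(spec.param_names)
    T = data[0][1].shape[0]
    loglik = _make_loglik(spec, data)
    noncentered = spec.parameterization == "noncentered"

    model, opt0, opt1 = _kernel_opts(spec)
    fixed_lam0 = int(
        spec.model == "SA" and not spec.options.get("lambda0_free", True)
    )
    kind_codes = np.array([_kernels.KIND_CODES[k] for k in kinds], dtype=np.int64)
    cues_all = np.stack([d[0] for d in data])
    targ_all = np.stack([d[1] for d in data])
    resp_all = np.stack([d[2] for d in data])

    mu = 0.5 * rng.standard_normal(K)
    sigma = rng.uniform(0.1, 0.4, K)
    z = rng.standard_normal((S, K)) * 0.5
    eta = mu + sigma * z

    def natural(eta_row):
        return np.array(
            [_natural(eta_row[k], kinds[k]) for k in range(K)]
        )

    cur_ll = np.empty((S, T))
    cur_sum = np.empty(S)
    for s in range(S):
        cur_ll[s] = loglik(s, natural(eta[s]))
        cur_sum[s] = cur_ll[s].sum()

    step = np.full((S, K), 0.25)
    group_step = np.full((K, 2), 0.15)  # noncentered only: mu, log-sigma
    n_kept = iterations - warmup
    kept_params = np.empty((n_kept, S, K))
    kept_mu = np.empty((n_kept, K))
    kept_sigma = np.empty((n_kept, K))
    kept_pointwise = np.empty((n_kept, S, T))
    accept = np.zeros((S, K))

    for it in range(iterations):
        adapt = it < warmup
        accept += _kernels.mwg_participant_sweep(
            model,
            opt0,
            opt1,
            fixed_lam0,
            kind_codes,
            eta,
            mu,
            sigma,
            step,
            cur_sum,
            cur_ll,
            cues_all,
            targ_all,
            resp_all,
            1 if noncentered else 0,
            z,
            rng.standard_normal((S, K)),
            rng.random((S, K)),
            rng.random(S),
            rng.standard_normal((S, K)),
            1 if adapt else 0,
        )

        if noncentered:
            # Metropolis updates of group parameters; every participant's
            # likelihood depends on them through eta = mu + sigma z
            for k in range(K):
                for which in range(2):
                    if which == 0:
                        mu_prop, sig_prop = (
                            mu[k] + group_step[k, 0] * rng.standard_normal(),
                            sigma[k],
                        )
                        lp_diff = -0.5 * (mu_prop**2 - mu[k] ** 2)
                    else:
                        log_sig = np.log(sigma[k]) + group_step[
                            k, 1
                        ] * rng.standard_normal()
                        mu_prop, sig_prop = mu[k], float(np.exp(log_sig))
                        lp_diff = (
                            _sigma_log_prior(sig_prop)
                            - _sigma_log_prior(sigma[k])
                            + np.log(sig_prop)
                            - np.log(sigma[k])  # Jacobian of log step
                        )
                    eta_prop_all = eta.copy()
                    eta_prop_all[:, k] = mu_prop + sig_prop * z[:, k]
                    new_lls = np.empty_like(cur_ll)
                    new_sums = np.empty(S)
                    for s in range(S):
                        e = eta[s].copy()
                        e[k] = eta_prop_all[s, k]
                        new_lls[s] = loglik(s, natural(e))
                        new_sums[s] = new_lls[s].sum()
                    if np.log(rng.random()) < new_sums.sum() - cur_sum.sum() + lp_diff:
                        mu[k], sigma[k] = mu_prop, sig_prop
                        eta[:, k] = eta_prop_all[:, k]
                        cur_ll[:] = new_lls
                        cur_sum[:] = new_sums
                        if adapt:
                            group_step[k, which] *= np.exp(0.1)
                    elif adapt:
                        group_step[k, which] *= np.exp(-0.1 * 0.3 / 0.7)
        else:
            for k in range(K):
                # conjugate Gibbs for the group mean, N(0,1) hyperprior
                prec = 1.0 + S / sigma[k] ** 2
                mean = (np.sum(eta[:, k]) / sigma[k] ** 2) / prec
                mu[k] = mean + rng.standard_normal() / np.sqrt(prec)
                sigma[k] = _slice_sample_sigma(sigma[k], eta[:, k], mu[k], rng)
            # interweaved non-centered group move: breaks the funnel
            # coupling between the group scale and participant values
            _kernels.asis_group_sweep(
                model,
                opt0,
                opt1,
                fixed_lam0,
                kind_codes,
                eta,
                mu,
                sigma,
                group_step,
                cur_sum,
                cur_ll,
                cues_all,
                targ_all,
                resp_all,
                rng.standard_normal((K, 2)),
                rng.random(K),
                1 if adapt else 0,
            )

        if it >= warmup:
            j = it - warmup
            for k in range(K):
                kept_params[j, :, k] = _natural(eta[:, k], kinds[k])
            kept_mu[j] = mu
            kept_sigma[j] = sigma
            kept_pointwise[j] = cur_ll

    return kept_params, kept_mu, kept_sigma, kept_pointwise, accept / iterations


def split_rhat(chains: np.ndarray) -> float:
    """Classic split-R-hat for one quantity, input shape (chains, draws).

    Zero between- and within-chain variance (all chains constant at one
    value) is reported as 1.0 (degenerate); zero within-chain variance
    with distinct chains diverges to infinity.
    """
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = float(np.mean(halves.var(axis=1, ddof=1)))
    b = float(n * np.var(means, ddof=1))
    tiny = 1e-24 * (1.0 + float(np.mean(np.abs(halves)))) ** 2
    if b <= tiny and w <= tiny:
        return 1.0
    if w <= tiny:
        return np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def convergence_check(draws: PosteriorDraws) -> dict:
    """Split-R-hat for all group parameters and per-participant
    natural-scale parameters. Passes iff every R-hat <= 1.1."""
    rhats = {}
    degenerate = []
    for name in draws.spec.param_names:
        rhats[f"mu_{name}"] = split_rhat(draws.group_mu[name])
        rhats[f"sigma_{name}"] = split_rhat(draws.group_sigma[name])
        a = draws.params[name]  # (chains, draws, S)
        for s, pid in enumerate(draws.participant_ids):
            r = split_rhat(a[:, :, s])
            rhats[f"{name}[{pid}]"] = r
            if r == 1.0 and np.ptp(a[:, :, s]) == 0.0:
                degenerate.append(f"{name}[{pid}]")
    finite = [v for v in rhats.values() if np.isfinite(v)]
    max_rhat = max(rhats.values()) if rhats else np.nan
    return {
        "rhat": rhats,
        "max_rhat": float(max_rhat),
        "degenerate": degenerate,
        "pass": bool(max_rhat <= RHAT_THRESHOLD),
    }


def fit_hierarchical(
    spec: HierarchicalSpec, dataset: CohortDataset, condition: str
) -> PosteriorDraws:
    """Fit one model to one condition's data across all participants.

    Conditions are fitted separately with their own group-level
    distributions. If the worst split-R-hat exceeds 1.1, the fit is
    re-run with a doubled iteration budget up to ``max_escalations``
    times; a still-unconverged result is returned flagged, never
    silently.
    """
    data, ids = _model_data(dataset, condition)
    if len(data) < 2:
        raise ConfigurationError(
            f"hierarchy undefined: {len(data)} participant(s) with complete "
            f"blocks in condition {condition!r}"
        )
    kinds = [TRANSFORMS[n] for n in spec.param_names]

    iterations, warmup = spec.iterations, spec.warmup
    ss = np.random.SeedSequence(spec.seed)
    for escalation in range(spec.max_escalations + 1):
        chain_seeds = ss.spawn(spec.chains)
        results = [
            _run_chain(
                spec, data, kinds, np.random.default_rng(cs), iterations, warmup
            )
            for cs in chain_seeds
        ]
        params = {
            name: np.stack([r[0][:, :, k] for r in results])
            for k, name in enumerate(spec.param_names)
        }
        group_mu = {
            name: np.stack([r[1][:, k] for r in results])
            for k, name in enumerate(spec.param_names)
        }
        group_sigma = {
            name: np.stack([r[2][:, k] for r in results])
            for k, name in enumerate(spec.param_names)
        }
        pointwise = np.stack([r[3] for r in results])
        draws = PosteriorDraws(
            params=params,
            group_mu=group_mu,
            group_sigma=group_sigma,
            pointwise=pointwise,
            participant_ids=ids,
            spec=spec,
            condition=condition,
        )
        report = convergence_check(draws)
        draws.diagnostics = {
            **report,
            "iterations": iterations,
            "warmup": warmup,
            "escalations": escalation,
            "divergences": 0,
            "mean_acceptance": float(np.mean([r[4] for r in results])),
            "converged": report["pass"],
        }
        if report["pass"] or escalation == spec.max_escalations:
            return draws
        iterations *= 2
        warmup *= 2
    raise AssertionError("unreachable")


def point_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior medians per participant, chains pooled. Index is the
    participant id; one column per natural-scale parameter."""
    cols = {
        name: np.median(draws.pooled(name), axis=0)
        for name in draws.spec.param_names
    }
    return pd.DataFrame(cols, index=pd.Index(draws.participant_ids, name="participant_id"))


def prior_predictive(
    n: int, kinds: dict | None = None, seed: int = 0, level: str = "group"
) -> dict:
    """Sample the hierarchical prior pushed through the transforms.

    At ``level="group"`` the group-level parameter Phi(mu) with
    mu ~ N(0,1) is returned: through the probit link the standard-normal
    hyperprior is *exactly* a uniform prior on each group-level
    probability (on [0,1], or [0.5,1] for gamma). At
    ``level="participant"`` the participant-level spread is included
    (sigma ~ half-t(50, 0.2), z ~ N(0,1)), which is uniform only up to
    the mild widening by sigma.
    """
    if kinds is None:
        kinds = {"h": "probit", "gamma": "probit_half", "epsilon": "probit"}
    if level not in ("group", "participant"):
        raise ValueError(f"unknown level {level!r}")
    rng = np.random.default_rng(seed)
    out = {}
    for name, kind in kinds.items():
        eta = rng.standard_normal(n)
        if level == "participant":
            sigma = (
                np.abs(stats.t.rvs(SIGMA_PRIOR_DF, size=n, random_state=rng))
                * SIGMA_PRIOR_SCALE
            )
            eta = eta + sigma * rng.standard_normal(n)
        out[name] = _natural(eta, kind)
    return out


def exclusion_screen(
    absolute_fit: pd.DataFrame,
    epsilon_medians: pd.DataFrame,
    chance_delta: float = 0.05,
    epsilon_threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag participants responding at chance.

    A participant is flagged when the posterior-predictive absolute fit is
    within ``chance_delta`` of 0.5 in *every* condition and the posterior
    median of the lapse rate exceeds ``epsilon_threshold`` in at least one
    condition. Both inputs are participant x condition frames.
    """
    near_chance = (absolute_fit - 0.5).abs().le(chance_delta).all(axis=1)
    high_eps = epsilon_medians.gt(epsilon_threshold).any(axis=1)
    return pd.DataFrame(
        {
            "near_chance_all_conditions": near_chance,
            "high_epsilon": high_eps,
            "excluded": near_chance & high_eps,
        }
    )


def mle_fit(spec: HierarchicalSpec, data_triplet, x0=None):
    """Per-participant maximum-likelihood fit on the probit scale.

    Test utility only -- the analysis pipeline always uses the
    hierarchical posterior.
    """
    from scipy import optimize

    kinds = [TRANSFORMS[n] for n in spec.param_names]
    loglik = _make_loglik(spec, [data_triplet])

    def nll(eta):
        theta = np.array([_natural(e, k) for e, k in zip(eta, kinds)])
        return -float(loglik(0, theta).sum()) + 0.001 * float(np.sum(eta**2))

    x0 = np.zeros(len(kinds)) if x0 is None else x0
    res = optimize.minimize(nll, x0, method="Nelder-Mead")
    return np.array(
        [_natural(e, k) for e, k in zip(res.x, kinds)]
    ), -res.fun
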