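"""Model comparison: WAIC, PSIS-LOO, model weights, and absolute fit.

Relative fit uses the matrix of pointwise log-likelihood draws (posterior
draws x data points). WAIC uses the variance-based penalty; PSIS-LOO uses
Pareto-smoothed importance sampling (smoothing via ``arviz.psislw``).
Both are reported on the -2 * elpd (deviance) scale, lower is better.
Weights translate criteria into relative probabilities of being the best
model: Akaike weights from criterion differences, pseudo-BMA weights from
the LOO elpd (plain, without Bayesian-bootstrap regularization; a flag
enables the bootstrap variant).

Absolute fit simulates response sequences from posterior parameter draws
on the participant's own cue/target sequence and scores the average
per-trial match with the actual responses; chance is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .agents import simulate_agent
from .baselines import WSLSParams
from .bcp import BCPParams
from .hierfit import PosteriorDraws, point_estimates
from .sa import SAParams
from .task import AgentSpec, TaskBlock


def _check_loglik(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, points)")
    if ll.shape[0] < 2:
        raise ValueError("at least 2 draws are required")
    if not np.all(np.isfinite(ll)):
        d, i = np.argwhere(~np.isfinite(ll))[0]
        raise ValueError(f"non-finite log-likelihood at draw {d}, point {i}")
    return ll


def waic(pointwise_loglik: np.ndarray) -> tuple[float, float, float]:
    """(WAIC, SE, p_waic) on the deviance scale.

    lppd_i = log mean_d exp(ll_di); p_i = var_d(ll_di);
    WAIC = -2 sum_i (lppd_i - p_i).
    """
    ll = _check_loglik(pointwise_loglik)
    n_draws, n_points = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    se = float(2.0 * np.sqrt(n_points * np.var(elpd_i, ddof=1)))
    return float(-2.0 * elpd_i.sum()), se, float(p_i.sum())


def psis_loo(pointwise_loglik: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(LOO, SE, pareto_k) on the deviance scale.

    Importance ratios 1/p(y_i | theta_d) are Pareto-smoothed in the upper
    tail per point; points with shape diagnostic k > 0.7 are unreliable
    and are reported (never silently accepted) via the returned array.
    """
    ll = _check_loglik(pointwise_loglik)
    n_draws, n_points = ll.shape
    if np.allclose(ll, ll[0], atol=0.0):
        # degenerate posterior: LOO reduces exactly to the lppd
        lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
        se = float(2.0 * np.sqrt(n_points * np.var(lppd_i, ddof=1)))
        return float(-2.0 * lppd_i.sum()), se, np.zeros(n_points)
    import arviz as az

    lw, k = az.psislw(-ll.T)  # arviz expects (points, draws) log-ratios
    lw = np.asarray(lw)
    k = np.asarray(k, dtype=float).copy()
    # the generalized-Pareto fit can fail on heavily tied ratio
    # distributions; fall back to plain normalized importance weights there
    bad = ~np.all(np.isfinite(lw), axis=1)
    if np.any(bad):
        raw = -ll.T[bad]
        lw[bad] = raw - logsumexp(raw, axis=1, keepdims=True)
        k[bad] = np.nan
    elpd_i = logsumexp(ll.T + lw, axis=1)
    se = float(2.0 * np.sqrt(n_points * np.var(elpd_i, ddof=1)))
    return float(-2.0 * elpd_i.sum()), se, np.asarray(k)


def model_weights(criteria, kind: str = "akaike") -> np.ndarray:
    """Normalized model weights.

    ``akaike``: w_i proportional to exp(-0.5 * (crit_i - min crit)) for
    deviance-scale criteria (WAIC or LOO). ``pseudo_bma``: w_i
    proportional to exp(elpd_i); pass elpd values (or deviance-scale LOO,
    which is converted by -1/2).
    """
    c = np.asarray(criteria, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 models to weight")
    if kind == "akaike":
        x = -0.5 * (c - c.min())
    elif kind == "pseudo_bma":
        elpd = -0.5 * c if np.all(c > 0) else c
        x = elpd - elpd.max()
    else:
        raise ValueError(f"unknown weight kind {kind!r}")
    w = np.exp(x)
    return w / w.sum()


def pseudo_bma_weights(
    pointwise_elpds: list[np.ndarray],
    bayesian_bootstrap: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-BMA weights from per-point elpd vectors of each model.

    All models must score the same points. The default is plain
    pseudo-BMA; with ``bayesian_bootstrap`` the weights are averaged over
    Dirichlet-reweighted replicates.
    """
    lens = {len(e) for e in pointwise_elpds}
    if len(lens) != 1:
        raise ValueError("models were scored on different point counts")
    E = np.stack(pointwise_elpds)  # (models, points)
    if not bayesian_bootstrap:
        return model_weights(E.sum(axis=1), kind="pseudo_bma")
    rng = np.random.default_rng(seed)
    n = E.shape[1]
    acc = np.zeros(E.shape[0])
    for _ in range(n_boot):
        w = rng.dirichlet(np.ones(n)) * n
        acc += model_weights(E @ w, kind="pseudo_bma")
    return acc / n_boot


def _draw_to_params(model: str, names, values, options: dict):
    p = dict(zip(names, values))
    if model == "BCP":
        return BCPParams(
            h=p["h"],
            gamma=p["gamma"],
            epsilon=p["epsilon"],
            beta=p.get("beta"),
            hazard_mode=options.get("hazard_mode", "constant"),
            response_model=options.get("response_model", "simple"),
        )
    if model == "SA":
        return SAParams(
            h=p["h"],
            gamma=p["gamma"],
            epsilon=p["epsilon"],
            lambda0=p.get("lambda0", 0.5),
            learning_variant=options.get("learning_variant", "original"),
            response_model=options.get("response_model", "simple"),
        )
    return WSLSParams(p_stay=p["p_stay"], p_shift=p["p_shift"], epsilon=p["epsilon"])


def absolute_fit(
    draws: PosteriorDraws,
    block: TaskBlock,
    responses: np.ndarray,
    participant_index: int,
    n_draws: int | None = None,
    n_sim_per_draw: int = 1,
    seed: int = 0,
) -> float:
    """Mean posterior-predictive response match for one participant.

    By default every retained posterior draw is used once; ``n_draws``
    subsamples them for speed.
    """
    responses = np.asarray(responses)
    spec = draws.spec
    pooled = {n: draws.pooled(n)[:, participant_index] for n in spec.param_names}
    total = len(next(iter(pooled.values())))
    rng = np.random.default_rng(seed)
    idx = (
        np.arange(total)
        if n_draws is None or n_draws >= total
        else rng.choice(total, n_draws, replace=False)
    )
    matches = 0.0
    count = 0
    for d in idx:
        params = _draw_to_params(
            spec.model, spec.param_names, [pooled[n][d] for n in spec.param_names],
            spec.options,
        )
        for _ in range(n_sim_per_draw):
            sim = simulate_agent(
                AgentSpec(model=spec.model, params=params, seed=0), block, rng=rng
            )
            matches += float(np.mean(sim == responses))
            count += 1
    return matches / count


@dataclass
class ComparisonRow:
    model: str
    condition: str
    waic: float
    waic_se: float
    p_waic: float
    loo: float
    loo_se: float
    n_bad_k: int
    akaike_weight: float = np.nan
    pseudo_bma_weight: float = np.nan


def comparison_table(fits: dict[str, PosteriorDraws]) -> pd.DataFrame:
    """Per-model WAIC/PSIS-LOO and weights for fits of the same data.

    ``fits`` maps a model label to its posterior; all fits must cover the
    same participants and trials.
    """
    points = {k: v.pointwise_matrix().shape[1] for k, v in fits.items()}
    if len(set(points.values())) != 1:
        raise ValueError(f"fits scored different point counts: {points}")
    rows = []
    for label, draws in fits.items():
        ll = draws.pointwise_matrix()
        w, w_se, p_w = waic(ll)
        lo, lo_se, k = psis_loo(ll)
        rows.append(
            ComparisonRow(
                model=label,
                condition=draws.condition,
                waic=w,
                waic_se=w_se,
                p_waic=p_w,
                loo=lo,
                loo_se=lo_se,
                n_bad_k=int(np.sum(k > 0.7)),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df) == 1:
        df["akaike_weight"] = 1.0
        df["pseudo_bma_weight"] = 1.0
    else:
        df["akaike_weight"] = model_weights(df["waic"].to_numpy(), kind="akaike")
        df["pseudo_bma_weight"] = model_weights(
            df["loo"].to_numpy(), kind="pseudo_bma"
        )
    return df


def absolute_fit_table(
    fits: dict[str, PosteriorDraws],
    dataset,
    n_draws: int | None = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant absolute fit for each fitted model."""
    rows = []
    for label, draws in fits.items():
        cond = draws.condition
        by_id = {p.id: p for p in dataset.participants}
        for i, pid in enumerate(draws.participant_ids):
            part = by_id[pid]
            fit = absolute_fit(
                draws,
                part.blocks[cond],
                part.responses[cond],
                i,
                n_draws=n_draws,
                seed=seed + i,
            )
            rows.append(
                {
                    "model": label,
                    "condition": cond,
                    "participant_id": pid,
                    "absolute_fit": fit,
                }
            )
    return pd.DataFrame(rows)
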