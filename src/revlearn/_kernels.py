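"""Numba kernels for the per-trial likelihood filters.

These mirror the reference implementations in :mod:`revlearn.bcp`,
:mod:`revlearn.sa` and :mod:`revlearn.baselines` trial for trial; the
reference implementations and the brute-force enumeration oracles in the
test suite pin them down. Filtering is linear-space with a per-trial
renormalization (see the module docstring of :mod:`revlearn.bcp`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

HAZARD_CODES = {"constant": 0, "increasing": 1}
RESPONSE_CODES = {"simple": 0, "matching": 1, "maximizing": 2}
SA_VARIANT_CODES = {"original": 0, "uniform_shift": 1}

THIRD = 1.0 / 3.0


@njit(cache=True)
def bcp_loglik_kernel(h, gamma, eps, beta, cues, target, responses, hmode, rmode):
    """Per-trial response log-likelihood under the BCP observer.

    The joint p(run length, cue | data) is carried unnormalized per run
    (J[l, c]); hazard propagation, the cue marginal, and the likelihood
    update are fused into single passes per trial.
    """
    T = target.shape[0]
    J = np.zeros((T + 1, 3))
    PJ = np.zeros((T + 1, 3))
    for c in range(3):
        J[0, c] = THIRD
    n = 1
    out = np.empty(T)
    m = np.empty(3)
    for t in range(T):
        # hazard propagation (growth l -> l+1, reset to l = 0) fused with
        # the predictive cue marginal
        reset = 0.0
        m[0] = 0.0
        m[1] = 0.0
        m[2] = 0.0
        for l in range(n):
            hz = h if hmode == 0 else 1.0 - np.exp(-h * l)
            grow = 1.0 - hz
            row = 0.0
            for c in range(3):
                v = grow * J[l, c]
                PJ[l + 1, c] = v
                m[c] += v
                row += J[l, c]
            reset += hz * row
        r3 = reset * THIRD
        for c in range(3):
            PJ[0, c] = r3
            m[c] += r3
        n += 1
        # response probability
        if rmode == 2:
            w0 = m[0] ** beta
            w1 = m[1] ** beta
            w2 = m[2] ** beta
            ws = w0 + w1 + w2
            m0, m1, m2 = w0 / ws, w1 / ws, w2 / ws
        else:
            m0, m1, m2 = m[0], m[1], m[2]
        p_right = 0.0
        if rmode == 1:
            for c in range(3):
                lik_r = gamma if cues[t, c] == 1 else 1.0 - gamma
                p_right += lik_r * m[c]
        else:
            mm = (m0, m1, m2)
            for c in range(3):
                if cues[t, c] == 1:
                    p_right += mm[c]
        p_right = (1.0 - eps) * p_right + 0.5 * eps
        p_resp = p_right if responses[t] == 1 else 1.0 - p_right
        if p_resp <= 0.0:
            for tt in range(t, T):
                out[tt] = -np.inf
            return out
        out[t] = np.log(p_resp)
        # observe the target: weight every hypothesis and renormalize
        ev = 0.0
        for l in range(n):
            for c in range(3):
                lik = gamma if cues[t, c] == target[t] else 1.0 - gamma
                v = PJ[l, c] * lik
                PJ[l, c] = v
                ev += v
        if ev <= 0.0:
            # impossible history under gamma = 1: zero-probability data
            for tt in range(t + 1, T):
                out[tt] = -np.inf
            return out
        for l in range(n):
            for c in range(3):
                J[l, c] = PJ[l, c] / ev
    return out


@njit(cache=True)
def _sa_lambda_next(lam, p_s, h, lam0, l, variant):
    """One-step confidence update for an attended-cue hypothesis.

    ``l`` is the hypothesized run length entering the trial; ``l == 0``
    means this is the first feedback of the attention context, which uses
    the prior confidence ``lam0`` directly.
    """
    if l == 0:
        num = p_s * lam0
        den = 0.5 * (1.0 - lam0)
    elif variant == 0:
        num = p_s * ((1.0 - h) * lam + 0.5 * h * (1.0 - lam))
        den = 0.5 * (h * lam + (1.0 - h) * (1.0 - lam))
    else:
        num = p_s * ((1.0 - h + h * THIRD) * lam + h * THIRD * (1.0 - lam))
        den = 0.5 * (2.0 * THIRD * h * lam + (1.0 - h) * (1.0 - lam))
    if num + den <= 0.0:
        return lam  # zero-probability outcome under this hypothesis
    return num / (num + den)


@njit(cache=True)
def sa_loglik_kernel(h, gamma, eps, lam0, cues, target, responses, variant, rmode):
    """Per-trial response log-likelihood under the selective-attention
    observer, marginalizing over the latent attended cue and attention
    run length."""
    T = target.shape[0]
    G = np.zeros((T + 1, 3))
    lam = np.zeros((T + 1, 3))
    for c in range(3):
        G[0, c] = THIRD
        lam[0, c] = lam0
    n = 1
    out = np.empty(T)
    nG = np.zeros((T + 1, 3))
    nlam = np.zeros((T + 1, 3))
    for t in range(T):
        # response likelihood per attended cue (Eq 19 / 20 form)
        rlik = np.empty(3)
        for c in range(3):
            match = cues[t, c] == responses[t]
            if rmode == 0:
                rlik[c] = (1.0 - eps) + 0.5 * eps if match else 0.5 * eps
            else:
                rlik[c] = (
                    (1.0 - eps) * gamma + 0.5 * eps
                    if match
                    else (1.0 - eps) * (1.0 - gamma) + 0.5 * eps
                )
        # predictive probability of the realized response
        p = 0.0
        for l in range(n):
            for c in range(3):
                p += G[l, c] * rlik[c]
        if p <= 0.0:
            for tt in range(t, T):
                out[tt] = -np.inf
            return out
        out[t] = np.log(p)
        # (i) condition on the response
        for l in range(n):
            for c in range(3):
                G[l, c] = G[l, c] * rlik[c] / p
        # (ii) update confidence with the realized target,
        # (iii) propagate: stay with prob lambda', switch to uniform
        reset = 0.0
        for l in range(n):
            for c in range(3):
                p_s = gamma if cues[t, c] == target[t] else 1.0 - gamma
                lnew = _sa_lambda_next(lam[l, c], p_s, h, lam0, l, variant)
                nG[l + 1, c] = G[l, c] * lnew
                nlam[l + 1, c] = lnew
                reset += G[l, c] * (1.0 - lnew)
        for c in range(3):
            nG[0, c] = reset * THIRD
            nlam[0, c] = lam0
        n += 1
        tot = 0.0
        for l in range(n):
            for c in range(3):
                tot += nG[l, c]
        for l in range(n):
            for c in range(3):
                G[l, c] = nG[l, c] / tot
                lam[l, c] = nlam[l, c]
    return out


@njit(cache=True)
def wsls_loglik_kernel(p_stay, p_shift, eps, cues, target, responses):
    """Per-trial response log-likelihood under win-stay/lose-shift with a
    latent attended cue (same grid machinery as the SA observer, with
    outcome-dependent stay/shift probabilities in place of confidence)."""
    T = target.shape[0]
    G = np.zeros((T + 1, 3))
    for c in range(3):
        G[0, c] = THIRD
    n = 1
    out = np.empty(T)
    nG = np.zeros((T + 1, 3))
    for t in range(T):
        rlik = np.empty(3)
        for c in range(3):
            match = cues[t, c] == responses[t]
            rlik[c] = (1.0 - eps) + 0.5 * eps if match else 0.5 * eps
        p = 0.0
        for l in range(n):
            for c in range(3):
                p += G[l, c] * rlik[c]
        if p <= 0.0:
            for tt in range(t, T):
                out[tt] = -np.inf
            return out
        out[t] = np.log(p)
        for l in range(n):
            for c in range(3):
                G[l, c] = G[l, c] * rlik[c] / p
        reset = 0.0
        for l in range(n):
            for c in range(3):
                expected = cues[t, c] == target[t]
                p_switch = (1.0 - p_stay) if expected else p_shift
                nG[l + 1, c] = G[l, c] * (1.0 - p_switch)
                reset += G[l, c] * p_switch
        for c in range(3):
            nG[0, c] = reset * THIRD
        n += 1
        tot = 0.0
        for l in range(n):
            for c in range(3):
                tot += nG[l, c]
        for l in range(n):
            for c in range(3):
                G[l, c] = nG[l, c] / tot
    return out


MODEL_CODES = {"BCP": 0, "SA": 1, "WSLS": 2}


@njit(cache=True)
def loglik_dispatch(model, p0, p1, p2, p3, cues, target, responses, opt0, opt1):
    """Uniform entry point used by the MCMC sampler.

    model 0 (BCP): p = (h, gamma, epsilon, beta), opts (hazard, response).
    model 1 (SA): p = (h, gamma, epsilon, lambda0), opts (variant, response).
    model 2 (WSLS): p = (p_stay, p_shift, epsilon, -), opts unused.
    """
    if model == 0:
        return bcp_loglik_kernel(
            p0, p1, p2, p3, cues, target, responses, opt0, opt1
        )
    elif model == 1:
        return sa_loglik_kernel(
            p0, p1, p2, p3, cues, target, responses, opt0, opt1
        )
    else:
        return wsls_loglik_kernel(p0, p1, p2, cues, target, responses)


# ---------------------------------------------------------------------------
# sampler support: transforms and one Metropolis-within-Gibbs participant sweep

from math import erf, sqrt

KIND_CODES = {"probit": 0, "probit_half": 1, "one_plus_exp": 2}


@njit(cache=True)
def natural_scalar(eta, kind):
    if kind == 0:
        return 0.5 * (1.0 + erf(eta / sqrt(2.0)))
    elif kind == 1:
        return 0.25 * (1.0 + erf(eta / sqrt(2.0))) + 0.5
    else:
        return 1.0 + np.exp(eta)


@njit(cache=True)
def _theta_from_eta(eta_row, kinds, model, fixed_lam0):
    """Map a probit-scale row to the 4-slot kernel argument vector."""
    p = np.empty(4)
    p[3] = 1.0 if model == 0 else (0.5 if model == 1 else 0.0)
    for k in range(eta_row.shape[0]):
        p[k] = natural_scalar(eta_row[k], kinds[k])
    if model == 1 and fixed_lam0 == 1:
        p[3] = 0.5
    return p


@njit(cache=True)
def mwg_participant_sweep(
    model,
    opt0,
    opt1,
    fixed_lam0,
    kinds,
    eta,
    mu,
    sigma,
    step,
    cur_sum,
    cur_ll,
    cues_all,
    targ_all,
    resp_all,
    noncentered,
    z,
    randn,
    randu,
    jump_u,
    jump_randn,
    adapt,
):
    """One Metropolis sweep over participants.

    Each participant gets, with probability 0.1, an independence proposal
    of the whole parameter row drawn from the group prior (the prior
    density cancels against the proposal, leaving a pure likelihood
    ratio; this lets chains hop between posterior modes), followed by
    coordinate-wise random-walk proposals with step sizes adapted during
    warmup. Mutates eta (and z when non-centered), cur_sum, cur_ll and
    the step sizes. All proposal noise and acceptance uniforms are
    supplied by the caller so that randomness flows from one seeded
    generator.
    """
    S, K = eta.shape
    acc = np.zeros((S, K))
    for s in range(S):
        if jump_u[s] < 0.1:
            eta_prop = np.empty(K)
            for k in range(K):
                eta_prop[k] = mu[k] + sigma[k] * jump_randn[s, k]
            p = _theta_from_eta(eta_prop, kinds, model, fixed_lam0)
            new_ll = loglik_dispatch(
                model,
                p[0],
                p[1],
                p[2],
                p[3],
                cues_all[s],
                targ_all[s],
                resp_all[s],
                opt0,
                opt1,
            )
            new_sum = new_ll.sum()
            if np.log(jump_u[s] / 0.1) < new_sum - cur_sum[s]:
                for k in range(K):
                    eta[s, k] = eta_prop[k]
                    if noncentered == 1:
                        z[s, k] = jump_randn[s, k]
                cur_sum[s] = new_sum
                cur_ll[s] = new_ll
        for k in range(K):
            if noncentered == 1:
                z_old = z[s, k]
                z_new = z_old + step[s, k] * randn[s, k]
                eta_new = mu[k] + sigma[k] * z_new
                lp_diff = -0.5 * (z_new * z_new - z_old * z_old)
            else:
                eta_old = eta[s, k]
                eta_new = eta_old + step[s, k] * randn[s, k]
                d_new = eta_new - mu[k]
                d_old = eta_old - mu[k]
                lp_diff = -0.5 * (d_new * d_new - d_old * d_old) / (
                    sigma[k] * sigma[k]
                )
            eta_prop = eta[s].copy()
            eta_prop[k] = eta_new
            p = _theta_from_eta(eta_prop, kinds, model, fixed_lam0)
            new_ll = loglik_dispatch(
                model,
                p[0],
                p[1],
                p[2],
                p[3],
                cues_all[s],
                targ_all[s],
                resp_all[s],
                opt0,
                opt1,
            )
            new_sum = new_ll.sum()
            if np.log(randu[s, k]) < new_sum - cur_sum[s] + lp_diff:
                eta[s, k] = eta_new
                if noncentered == 1:
                    z[s, k] = z_new
                cur_sum[s] = new_sum
                cur_ll[s] = new_ll
                acc[s, k] = 1.0
                if adapt == 1:
                    step[s, k] *= np.exp(0.1)
            elif adapt == 1:
                step[s, k] *= np.exp(-0.1 * 0.44 / 0.56)
    return acc


@njit(cache=True)
def bcp_response_prob_kernel(h, gamma, eps, beta, cues, target, hmode, rmode):
    """Per-trial P(response = right) under the BCP observer.

    The belief depends only on cues and targets, so the whole trace is a
    function of the block alone (used by the generative agent and by
    posterior-predictive simulation).
    """
    T = target.shape[0]
    J = np.zeros((T + 1, 3))
    PJ = np.zeros((T + 1, 3))
    for c in range(3):
        J[0, c] = THIRD
    n = 1
    out = np.empty(T)
    m = np.empty(3)
    for t in range(T):
        reset = 0.0
        m[0] = 0.0
        m[1] = 0.0
        m[2] = 0.0
        for l in range(n):
            hz = h if hmode == 0 else 1.0 - np.exp(-h * l)
            grow = 1.0 - hz
            row = 0.0
            for c in range(3):
                v = grow * J[l, c]
                PJ[l + 1, c] = v
                m[c] += v
                row += J[l, c]
            reset += hz * row
        r3 = reset * THIRD
        for c in range(3):
            PJ[0, c] = r3
            m[c] += r3
        n += 1
        if rmode == 2:
            w0 = m[0] ** beta
            w1 = m[1] ** beta
            w2 = m[2] ** beta
            ws = w0 + w1 + w2
            m0, m1, m2 = w0 / ws, w1 / ws, w2 / ws
        else:
            m0, m1, m2 = m[0], m[1], m[2]
        p_right = 0.0
        if rmode == 1:
            for c in range(3):
                lik_r = gamma if cues[t, c] == 1 else 1.0 - gamma
                p_right += lik_r * m[c]
        else:
            mm = (m0, m1, m2)
            for c in range(3):
                if cues[t, c] == 1:
                    p_right += mm[c]
        out[t] = (1.0 - eps) * p_right + 0.5 * eps
        ev = 0.0
        for l in range(n):
            for c in range(3):
                lik = gamma if cues[t, c] == target[t] else 1.0 - gamma
                v = PJ[l, c] * lik
                PJ[l, c] = v
                ev += v
        if ev <= 0.0:
            # impossible history under gamma = 1: restart the belief
            n = 1
            for c in range(3):
                J[0, c] = THIRD
            continue
        for l in range(n):
            for c in range(3):
                J[l, c] = PJ[l, c] / ev
    return out


@njit(cache=True)
def natural_scalar(eta, kind):
    if kind == 0:
        return 0.5 * (1.0 + erf(eta / sqrt(2.0)))
    elif kind == 1:
        return 0.25 * (1.0 + erf(eta / sqrt(2.0))) + 0.5
    else:
        return 1.0 + np.exp(eta)


@njit(cache=True)
def _theta_from_eta(eta_row, kinds, model, fixed_lam0):
    """Map a probit-scale row to the 4-slot kernel argument vector."""
    p = np.empty(4)
    p[3] = 1.0 if model == 0 else (0.5 if model == 1 else 0.0)
    for k in range(eta_row.shape[0]):
        p[k] = natural_scalar(eta_row[k], kinds[k])
    if model == 1 and fixed_lam0 == 1:
        p[3] = 0.5
    return p


@njit(cache=True)
def mwg_participant_sweep(
    model,
    opt0,
    opt1,
    fixed_lam0,
    kinds,
    eta,
    mu,
    sigma,
    step,
    cur_sum,
    cur_ll,
    cues_all,
    targ_all,
    resp_all,
    noncentered,
    z,
    randn,
    randu,
    jump_u,
    jump_randn,
    adapt,
):
    """One Metropolis sweep over participants.

    Each participant gets, with probability 0.1, an independence proposal
    of the whole parameter row drawn from the group prior (the prior
    density cancels against the proposal, leaving a pure likelihood
    ratio; this lets chains hop between posterior modes), followed by
    coordinate-wise random-walk proposals with step sizes adapted during
    warmup. Mutates eta (and z when non-centered), cur_sum, cur_ll and
    the step sizes. All proposal noise and acceptance uniforms are
    supplied by the caller so that randomness flows from one seeded
    generator.
    """
    S, K = eta.shape
    acc = np.zeros((S, K))
    for s in range(S):
        if jump_u[s] < 0.1:
            eta_prop = np.empty(K)
            for k in range(K):
                eta_prop[k] = mu[k] + sigma[k] * jump_randn[s, k]
            p = _theta_from_eta(eta_prop, kinds, model, fixed_lam0)
            new_ll = loglik_dispatch(
                model,
                p[0],
                p[1],
                p[2],
                p[3],
                cues_all[s],
                targ_all[s],
                resp_all[s],
                opt0,
                opt1,
            )
            new_sum = new_ll.sum()
            if np.log(jump_u[s] / 0.1) < new_sum - cur_sum[s]:
                for k in range(K):
                    eta[s, k] = eta_prop[k]
                    if noncentered == 1:
                        z[s, k] = jump_randn[s, k]
                cur_sum[s] = new_sum
                cur_ll[s] = new_ll
        for k in range(K):
            if noncentered == 1:
                z_old = z[s, k]
                z_new = z_old + step[s, k] * randn[s, k]
                eta_new = mu[k] + sigma[k] * z_new
                lp_diff = -0.5 * (z_new * z_new - z_old * z_old)
            else:
                eta_old = eta[s, k]
                eta_new = eta_old + step[s, k] * randn[s, k]
                d_new = eta_new - mu[k]
                d_old = eta_old - mu[k]
                lp_diff = -0.5 * (d_new * d_new - d_old * d_old) / (
                    sigma[k] * sigma[k]
                )
            eta_prop = eta[s].copy()
            eta_prop[k] = eta_new
            p = _theta_from_eta(eta_prop, kinds, model, fixed_lam0)
            new_ll = loglik_dispatch(
                model,
                p[0],
                p[1],
                p[2],
                p[3],
                cues_all[s],
                targ_all[s],
                resp_all[s],
                opt0,
                opt1,
            )
            new_sum = new_ll.sum()
            if np.log(randu[s, k]) < new_sum - cur_sum[s] + lp_diff:
                eta[s, k] = eta_new
                if noncentered == 1:
                    z[s, k] = z_new
                cur_sum[s] = new_sum
                cur_ll[s] = new_ll
                acc[s, k] = 1.0
                if adapt == 1:
                    step[s, k] *= np.exp(0.1)
            elif adapt == 1:
                step[s, k] *= np.exp(-0.1 * 0.44 / 0.56)
    return acc


@njit(cache=True)
def bcp_response_prob_kernel(h, gamma, eps, beta, cues, target, hmode, rmode):
    """Per-trial P(response = right) under the BCP observer.

    The belief depends only on cues and targets, so the whole trace is a
    function of the block alone (used by the generative agent and by
    posterior-predictive simulation).
    """
    T = target.shape[0]
    rl = np.zeros(T + 1)
    cgr = np.zeros((T + 1, 3))
    rl[0] = 1.0
    for c in range(3):
        cgr[0, c] = THIRD
    n = 1
    out = np.empty(T)
    prl = np.zeros(T + 1)
    pcgr = np.zeros((T + 1, 3))
    for t in range(T):
        reset = 0.0
        for l in range(n):
            hz = h if hmode == 0 else 1.0 - np.exp(-h * l)
            reset += hz * rl[l]
            prl[l + 1] = (1.0 - hz) * rl[l]
            for c in range(3):
                pcgr[l + 1, c] = cgr[l, c]
        prl[0] = reset
        for c in range(3):
            pcgr[0, c] = THIRD
        n += 1
        m = np.zeros(3)
        for l in range(n):
            for c in range(3):
                m[c] += prl[l] * pcgr[l, c]
        if rmode == 2:
            w0 = m[0] ** beta
            w1 = m[1] ** beta
            w2 = m[2] ** beta
            ws = w0 + w1 + w2
            m0, m1, m2 = w0 / ws, w1 / ws, w2 / ws
        else:
            m0, m1, m2 = m[0], m[1], m[2]
        p_right = 0.0
        if rmode == 1:
            for c in range(3):
                lik_r = gamma if cues[t, c] == 1 else 1.0 - gamma
                p_right += lik_r * m[c]
        else:
            mm = (m0, m1, m2)
            for c in range(3):
                if cues[t, c] == 1:
                    p_right += mm[c]
        out[t] = (1.0 - eps) * p_right + 0.5 * eps
        ev = 0.0
        for l in range(n):
            s = 0.0
            for c in range(3):
                lik = gamma if cues[t, c] == target[t] else 1.0 - gamma
                v = prl[l] * pcgr[l, c] * lik
                pcgr[l, c] = v
                s += v
            prl[l] = s
            ev += s
        if ev <= 0.0:
            # impossible history under gamma = 1: restart the belief
            n = 1
            rl[0] = 1.0
            for c in range(3):
                cgr[0, c] = THIRD
            continue
        for l in range(n):
            if prl[l] > 0.0:
                for c in range(3):
                    pcgr[l, c] /= prl[l]
            else:
                for c in range(3):
                    pcgr[l, c] = THIRD
            rl[l] = prl[l] / ev
            for c in range(3):
                cgr[l, c] = pcgr[l, c]
    return out


@njit(cache=True)
def asis_group_sweep(
    model,
    opt0,
    opt1,
    fixed_lam0,
    kinds,
    eta,
    mu,
    sigma,
    group_step,
    cur_sum,
    cur_ll,
    cues_all,
    targ_all,
    resp_all,
    randn,
    randu,
    adapt,
):
    """Interweaved non-centered update of the group parameters.

    With the standardized scores z = (eta - mu) / sigma held fixed, each
    (mu_k, sigma_k) pair gets a joint random-walk proposal (log scale for
    sigma), which moves every participant's natural-scale parameter at
    once and re-evaluates all likelihoods. Alternating this with the
    centered Gibbs updates breaks the funnel coupling between group
    scale and participant-level values.
    """
    S, K = eta.shape
    for k in range(K):
        mu_new = mu[k] + group_step[k, 0] * randn[k, 0]
        sig_new = sigma[k] * np.exp(group_step[k, 1] * randn[k, 1])
        # prior ratio: standard normal on mu, half-t(nu=50, scale=0.2)
        # on sigma, plus the log-scale Jacobian
        lp = -0.5 * (mu_new * mu_new - mu[k] * mu[k])
        nu = 50.0
        scale = 0.2
        x_new = sig_new / scale
        x_old = sigma[k] / scale
        lp += -0.5 * (nu + 1.0) * (
            np.log(1.0 + x_new * x_new / nu) - np.log(1.0 + x_old * x_old / nu)
        )
        lp += np.log(sig_new) - np.log(sigma[k])
        eta_col = np.empty(S)
        for s in range(S):
            zsk = (eta[s, k] - mu[k]) / sigma[k]
            eta_col[s] = mu_new + sig_new * zsk
        new_lls = np.empty((S, cur_ll.shape[1]))
        delta = 0.0
        for s in range(S):
            eta_prop = eta[s].copy()
            eta_prop[k] = eta_col[s]
            p = _theta_from_eta(eta_prop, kinds, model, fixed_lam0)
            ll = loglik_dispatch(
                model,
                p[0],
                p[1],
                p[2],
                p[3],
                cues_all[s],
                targ_all[s],
                resp_all[s],
                opt0,
                opt1,
            )
            new_lls[s] = ll
            delta += ll.sum() - cur_sum[s]
        if np.log(randu[k]) < delta + lp:
            mu[k] = mu_new
            sigma[k] = sig_new
            for s in range(S):
                eta[s, k] = eta_col[s]
                cur_sum[s] = new_lls[s].sum()
                cur_ll[s] = new_lls[s]
            if adapt == 1:
                group_step[k, 0] *= np.exp(0.1)
                group_step[k, 1] *= np.exp(0.1)
        elif adapt == 1:
            group_step[k, 0] *= np.exp(-0.1 * 0.3 / 0.7)
            group_step[k, 1] *= np.exp(-0.1 * 0.3 / 0.7)
    return 0
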