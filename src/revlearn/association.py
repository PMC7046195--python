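"""Behavioral measures and symptom-parameter association statistics.

Behavioral measures per trial: accuracy against the relevant cue,
*disambiguating* trials (the response matches the orientation of exactly
one cue, revealing which cue was chosen), and perseveration-attributable
errors (post-shift disambiguating errors selecting the cue that was
relevant before the shift).

Associations between questionnaire scores and fitted parameters use
permutation tests of the Pearson correlation (questionnaire scores are
strongly right-skewed, so normal-theory p-values are not trusted), with
+1 smoothing so p can never be zero. Partial correlations residualize
both variables on the covariate and permute the residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .task import TaskBlock


def behavior_metrics(block: TaskBlock, responses: np.ndarray) -> pd.DataFrame:
    """Trial-level behavior table for one block.

    Columns: trial, segment (pre/post), trial_in_segment, accuracy,
    is_disambiguating, chosen_cue (1-based; <NA> off disambiguating
    trials), is_perseverative_error.
    """
    responses = np.asarray(responses)
    if len(responses) != block.n_trials:
        raise ValueError(
            f"{len(responses)} responses for {block.n_trials} trials"
        )
    n = block.n_trials
    rel_orient = block.cues[np.arange(n), block.relevant_cue]
    accuracy = responses == rel_orient
    match = block.cues == responses[:, None]
    n_match = match.sum(axis=1)
    disamb = n_match == 1
    chosen = np.where(disamb, np.argmax(match, axis=1), -1)
    trial = np.arange(1, n + 1)
    post = trial > block.shift_trial
    pre_cue = int(block.relevant_cue[0])
    persev = post & disamb & ~accuracy & (chosen == pre_cue)
    chosen_out = pd.array(
        np.where(disamb, chosen + 1, 0), dtype="Int64"
    )
    chosen_out[~disamb] = pd.NA
    return pd.DataFrame(
        {
            "trial": trial,
            "segment": np.where(post, "post", "pre"),
            "trial_in_segment": np.where(
                post, trial - block.shift_trial, trial
            ),
            "accuracy": accuracy,
            "is_disambiguating": disamb,
            "chosen_cue": chosen_out,
            "is_perseverative_error": persev,
        }
    )


def _validate_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return x, y


def perm_corr(
    x,
    y,
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "two",
) -> tuple[float, float]:
    """Pearson correlation with a permutation p-value.

    p = (1 + #{extreme permutations}) / (n_perm + 1). ``sided`` is
    "two" (|r_perm| >= |r|), "greater" or "less".
    """
    x, y = _validate_xy(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    count = 0
    for _ in range(n_perm):
        rp = float(np.dot(xc, rng.permutation(yc))) / denom
        if sided == "two":
            count += abs(rp) >= abs(r) - 1e-12
        elif sided == "greater":
            count += rp >= r - 1e-12
        else:
            count += rp <= r + 1e-12
    return r, (1 + count) / (n_perm + 1)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_perm_corr(
    x,
    y,
    z,
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "two",
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for z, with a
    permutation p-value on the residuals."""
    x, y = _validate_xy(x, y)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValueError("z must match x and y in length")
    for v, name in ((x, "x"), (y, "y")):
        r2 = float(stats.pearsonr(v, z).statistic) ** 2 if np.ptp(z) > 0 else 0.0
        if r2 > 0.999:
            raise ValueError(f"covariate z is collinear with {name}")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero-variance residuals: partial correlation undefined")
    return perm_corr(rx, ry, n_perm=n_perm, seed=seed, sided=sided)


#: parameter -> reported quantity: observation uncertainty is 1 - gamma
REPORTED_SCALES = {
    "h": ("transition_uncertainty", lambda v: v),
    "gamma": ("observation_uncertainty", lambda v: 1.0 - v),
    "epsilon": ("lapse", lambda v: v),
}


def headline_analysis(
    dataset,
    medians_by_condition: dict[str, pd.DataFrame],
    excluded: list | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Symptom-parameter association report.

    For every condition and fitted parameter, permutation correlations of
    the posterior medians with the OCI-R total and each DASS subscale,
    plus OCI-R partial correlations controlling for DASS depression.
    ``excluded`` participants are dropped before testing. Participants
    with missing scores are dropped per scale.
    """
    excluded = set(excluded or [])
    rows = []
    rng = np.random.default_rng(seed)
    for cond, medians in medians_by_condition.items():
        keep_ids = [i for i in medians.index if i not in excluded]
        med = medians.loc[keep_ids]
        by_id = {p.id: p for p in dataset.participants}
        scales = {
            "ocir": np.array([by_id[i].ocir for i in keep_ids], dtype=float)
        }
        for sub in ("anxiety", "stress", "depression"):
            vals = [by_id[i].dass.get(sub) for i in keep_ids]
            scales[f"dass_{sub}"] = np.array(
                [np.nan if v is None else v for v in vals], dtype=float
            )
        for param in med.columns:
            name, to_reported = REPORTED_SCALES.get(param, (param, lambda v: v))
            values = to_reported(med[param].to_numpy(dtype=float))
            for scale_name, scores in scales.items():
                ok = ~np.isnan(scores)
                if ok.sum() < 3:
                    continue
                r, p = perm_corr(
                    scores[ok],
                    values[ok],
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
                rows.append(
                    {
                        "condition": cond,
                        "parameter": name,
                        "scale": scale_name,
                        "kind": "marginal",
                        "r": r,
                        "p": p,
                        "n": int(ok.sum()),
                        "n_perm": n_perm,
                    }
                )
            # specificity: OCI-R effect controlling for depressive symptoms
            dep = scales["dass_depression"]
            ok = ~np.isnan(dep)
            if ok.sum() >= 3:
                r, p = partial_perm_corr(
                    scales["ocir"][ok],
                    values[ok],
                    dep[ok],
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
                rows.append(
                    {
                        "condition": cond,
                        "parameter": name,
                        "scale": "ocir_given_depression",
                        "kind": "partial",
                        "r": r,
                        "p": p,
                        "n": int(ok.sum()),
                        "n_perm": n_perm,
                    }
                )
    return pd.DataFrame(rows)
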