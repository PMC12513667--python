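"""MCMC convergence diagnostics and information-criteria model comparison.

Split-chain rank-normalised Rhat and bulk ESS are delegated to ``arviz``.
DIC uses the plug-in deviance at the posterior mean of the parameters
(pD = mean deviance - deviance at the mean); WAIC uses the pointwise
log-predictive density with the variance-based penalty
p_waic = sum over subjects of Var over draws of the log-likelihood.
Lower is better for both; WAIC is the primary ranking criterion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .joint import PosteriorDraws

__all__ = ["convergence_diagnostics", "information_criteria", "compare_models"]


def convergence_diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.01):
    """Per-parameter split-Rhat and ESS, with flags for Rhat > threshold.

    Zero-variance (constant) chains get Rhat 1.0 by convention and are
    flagged as degenerate.  Requires >= 2 chains and >= 4 retained draws.
    """
    import arviz as az

    flat = draws.flat()
    first = next(iter(flat.values()))
    if first.shape[0] < 2:
        raise ValueError("Rhat is undefined for a single chain")
    if first.shape[1] < 4:
        raise ValueError("need at least 4 retained draws per chain")
    rhat, ess, flags, degenerate = {}, {}, [], []
    labels = [l for l, a in flat.items() if not np.allclose(a, a.flat[0])]
    for label in flat:
        if label not in labels:
            rhat[label] = 1.0
            ess[label] = float("nan")
            degenerate.append(label)
    if labels:
        stacked = np.stack([flat[l] for l in labels], axis=-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(stacked)
            r_all = np.atleast_1d(az.rhat(ds)["x"].values)
            e_all = np.atleast_1d(az.ess(ds)["x"].values)
        for label, r, e in zip(labels, r_all, e_all):
            rhat[label] = float(r)
            ess[label] = float(e)
            if r > rhat_threshold:
                flags.append(label)
    return {"rhat": rhat, "ess": ess, "flagged": flags, "degenerate": degenerate,
            "threshold": rhat_threshold}


def information_criteria(draws: PosteriorDraws) -> tuple[float, float]:
    """(DIC, WAIC) from per-draw, per-subject log-likelihood contributions."""
    ll = draws.pointwise_loglik  # (chains, ndraw, n)
    if ll.size == 0:
        raise ValueError("no retained draws")
    if not np.all(np.isfinite(ll)):
        bad = np.where(~np.isfinite(ll).all(axis=(0, 1)))[0].tolist()
        raise ValueError(f"non-finite pointwise log-likelihoods for subjects {bad}")
    flat = ll.reshape(-1, ll.shape[-1])  # (draws, n)
    mean_dev = float(-2.0 * flat.sum(axis=1).mean())
    if draws.pointwise_loglik_at_mean is not None:
        dev_at_mean = float(-2.0 * draws.pointwise_loglik_at_mean.sum())
    else:
        dev_at_mean = mean_dev
    pd_ = mean_dev - dev_at_mean
    dic = mean_dev + pd_

    # WAIC: lppd via stable log-mean-exp per subject
    m = flat.max(axis=0)
    lppd = float(np.sum(np.log(np.exp(flat - m).mean(axis=0)) + m))
    p_waic = float(np.sum(flat.var(axis=0, ddof=1 if flat.shape[0] > 1 else 0)))
    waic = -2.0 * (lppd - p_waic)
    return dic, waic


def compare_models(fits: dict[str, PosteriorDraws]) -> pd.DataFrame:
    """Rank >= 2 fitted models (on identical data) by WAIC, with DIC shown.

    Rows are sorted ascending by WAIC; a flag marks WAIC/DIC rank
    disagreement on the top model.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    keys = {d.meta.get("data_key") for d in fits.values()}
    if len(keys) > 1:
        raise ValueError("fits were computed on differing cohorts")
    rows = []
    for label, d in fits.items():
        dic, waic = information_criteria(d)
        rows.append({"model": label,
                     "structure": d.meta.get("structure", ""),
                     "waic": waic, "dic": dic})
    tab = pd.DataFrame(rows).sort_values("waic", kind="mergesort").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    best_by_dic = tab.loc[tab["dic"].idxmin(), "model"]
    tab.attrs["criteria_disagree"] = bool(best_by_dic != tab.loc[0, "model"])
    return tab
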