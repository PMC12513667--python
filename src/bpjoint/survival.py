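"""Descriptive survival layer: person-time, Kaplan-Meier, log-rank, Cox screen.

These are the classical right-censored analyses run before the joint model:
incidence density with an exact Poisson interval, the product-limit survival
curve with Greenwood variance, the log-rank comparison, and a Cox
proportional-hazards screen with Schoenfeld and martingale residual
diagnostics.  Fitting is delegated to ``lifelines``; the residual-based
proportional-hazards statistics follow the usual transform-correlation form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IncidenceResult",
    "KMCurve",
    "CoxFit",
    "person_years_and_incidence",
    "km_estimate",
    "km_at",
    "logrank_test",
    "cox_fit",
    "ph_diagnostics",
    "bivariable_screen",
]


@dataclass
class IncidenceResult:
    """Events per 100 person-years with an exact Poisson 95% interval."""

    n_events: int
    person_years: float
    rate_per_100py: float
    ci95: tuple[float, float]
    proportion_pct: float | None = None
    proportion_ci95: tuple[float, float] | None = None

    def to_dict(self):
        return {
            "n_events": self.n_events,
            "person_years": self.person_years,
            "rate_per_100py": self.rate_per_100py,
            "rate_ci95": list(self.ci95),
            "proportion_pct": self.proportion_pct,
            "proportion_ci95": list(self.proportion_ci95 or ()),
        }


def person_years_and_incidence(outcomes: pd.DataFrame) -> IncidenceResult:
    """Person-years, incidence density per 100 PY and exact Poisson 95% CI.

    Follow-up is recorded in months; person-years = sum(followup_m)/12.  The
    interval uses chi-square quantiles (lower bound exactly 0 when there are
    no events).  The cumulative-incidence proportion gets a Clopper-Pearson
    interval.
    """
    if len(outcomes) == 0:
        raise ValueError("outcome table is empty")
    py = float(outcomes["followup_m"].sum()) / 12.0
    if py <= 0:
        raise ValueError("total person-time is zero")
    d = int(outcomes["event"].sum())
    rate = 100.0 * d / py
    if d == 0:
        low = 0.0
    else:
        low = 100.0 * stats.chi2.ppf(0.025, 2 * d) / 2.0 / py
    high = 100.0 * stats.chi2.ppf(0.975, 2 * d + 2) / 2.0 / py
    n = len(outcomes)
    p_low = 0.0 if d == 0 else stats.beta.ppf(0.025, d, n - d + 1)
    p_high = 1.0 if d == n else stats.beta.ppf(0.975, d + 1, n - d)
    return IncidenceResult(
        n_events=d, person_years=py, rate_per_100py=rate, ci95=(low, high),
        proportion_pct=100.0 * d / n,
        proportion_ci95=(100.0 * p_low, 100.0 * p_high),
    )


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci95: tuple[np.ndarray, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_m": self.event_times,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
                "ci_low": self.ci95[0],
                "ci_high": self.ci95[1],
            }
        )


def km_estimate(outcomes: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and log-scale 95% band."""
    if len(outcomes) == 0:
        raise ValueError("outcome table is empty")
    if (outcomes["followup_m"] < 0).any():
        raise ValueError("negative follow-up times")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(outcomes["followup_m"], outcomes["event"])
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    times = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    # Greenwood: Var[S] = S^2 * cumsum d/(n(n-d)) over event times
    full = kmf.event_table
    ev = full[full["observed"] > 0]
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    cum = np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
    var = surv**2 * cum
    # 95% band on the log scale: S * exp(+/- z * sqrt(cum))
    z = stats.norm.ppf(0.975)
    with np.errstate(invalid="ignore"):
        low = np.clip(surv * np.exp(-z * np.sqrt(cum)), 0.0, 1.0)
        high = np.clip(surv * np.exp(z * np.sqrt(cum)), 0.0, 1.0)
    low[surv == 0] = 0.0
    high[surv == 0] = 0.0
    var[surv == 0] = 0.0
    return KMCurve(event_times=times, survival=surv, greenwood_var=var,
                   ci95=(low, high))


def km_at(curve: KMCurve, t: float) -> float:
    """Step-function value S(t)."""
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(outcomes: pd.DataFrame, group_labels) -> tuple[float, int, float]:
    """Log-rank chi-square across >= 2 groups; returns (chi2, df, p)."""
    groups = np.asarray(group_labels)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test requires at least two groups")
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(
        outcomes["followup_m"], groups, outcomes["event"]
    )
    df = len(uniq) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties)."""

    coef: pd.Series
    se: pd.Series
    hr: pd.Series
    loglik: float
    martingale: pd.Series
    schoenfeld: pd.DataFrame | None = None
    ties: str = "efron"
    _frame: pd.DataFrame | None = field(default=None, repr=False)
    _cph: object = field(default=None, repr=False)


def _check_cox_inputs(outcomes, covariates):
    if int(outcomes["event"].sum()) == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"covariate(s) constant across subjects: {const}")


def cox_fit(outcomes: pd.DataFrame, covariates: pd.DataFrame,
            ties: str = "efron") -> CoxFit:
    """Fit the Cox screen; ``covariates`` rows align with ``outcomes`` rows.

    ``ties`` is ``"efron"`` (default, via lifelines) or ``"breslow"``
    (Newton on the Breslow partial likelihood).  Monotone likelihood /
    non-convergence raises with the offending covariate named where known.
    """
    covariates = covariates.reset_index(drop=True)
    _check_cox_inputs(outcomes, covariates)
    if ties == "breslow":
        return _cox_breslow(outcomes, covariates)
    if ties != "efron":
        raise ValueError(f"unknown tie handling {ties!r}")
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    frame = covariates.copy()
    frame["followup_m"] = outcomes["followup_m"].to_numpy()
    frame["event"] = outcomes["event"].to_numpy()
    cph = CoxPHFitter()
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="followup_m", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    mart = cph.compute_residuals(frame, kind="martingale")["martingale"]
    mart = mart.sort_index()
    return CoxFit(
        coef=cph.params_, se=cph.standard_errors_, hr=np.exp(cph.params_),
        loglik=float(cph.log_likelihood_), martingale=mart,
        ties="efron", _frame=frame, _cph=cph,
    )


def _breslow_neg_loglik(beta, T, E, X):
    order = np.argsort(-T, kind="mergesort")
    T, E, X = T[order], E[order], X[order]
    eta = X @ beta
    m = eta.max()
    cum = np.logaddexp.accumulate(eta - m) + m  # log sum over risk set (desc time)
    # subjects with equal T share the same risk set: take last index of tie group
    logrisk = np.empty(len(T))
    i = 0
    while i < len(T):
        j = i
        while j + 1 < len(T) and T[j + 1] == T[i]:
            j += 1
        logrisk[i : j + 1] = cum[j]
        i = j + 1
    return -np.sum(E * (eta - logrisk))


def _cox_breslow(outcomes, covariates):
    from scipy.optimize import minimize

    T = outcomes["followup_m"].to_numpy(dtype=float)
    E = outcomes["event"].to_numpy(dtype=float)
    X = covariates.to_numpy(dtype=float)
    res = minimize(
        _breslow_neg_loglik, np.zeros(X.shape[1]), args=(T, E, X),
        method="BFGS", options={"gtol": 1e-9, "maxiter": 500},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        raise RuntimeError(f"Breslow Cox fit did not converge: {res.message}")
    beta = res.x
    # observed information via finite differences of the gradient
    from scipy.optimize import approx_fprime

    H = np.empty((len(beta), len(beta)))
    eps = 1e-5
    for k in range(len(beta)):
        def gk(b, k=k):
            return approx_fprime(
                b, _breslow_neg_loglik, 1e-7, T, E, X
            )[k]
        H[k] = approx_fprime(beta, gk, eps)
    H = (H + H.T) / 2
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    names = list(covariates.columns)
    coef = pd.Series(beta, index=names)
    # Breslow baseline cumulative hazard for martingale residuals
    risk = np.exp(X @ beta)
    ets = np.sort(np.unique(T[E == 1]))
    cumhaz = np.zeros(len(T))
    base = 0.0
    increments = {}
    for t in ets:
        denom = risk[T >= t].sum()
        increments[t] = (E[T == t]).sum() / denom
    for i in range(len(T)):
        base = sum(inc for t, inc in increments.items() if t <= T[i])
        cumhaz[i] = base * risk[i]
    mart = pd.Series(E - cumhaz)
    return CoxFit(coef=coef, se=pd.Series(se, index=names),
                  hr=np.exp(coef), loglik=float(-res.fun), martingale=mart,
                  ties="breslow",
                  _frame=pd.concat(
                      [covariates,
                       pd.DataFrame({"followup_m": T, "event": E})], axis=1))


def ph_diagnostics(fit: CoxFit) -> dict:
    """Schoenfeld-residual PH tests (per covariate + global) and martingale sums.

    The per-covariate and global statistics regress the Schoenfeld residuals
    on the rank of the event time, in the usual scaled-residual form; under
    proportional hazards each statistic is chi-square distributed.
    """
    if fit._frame is None or fit._cph is None:
        if fit.ties == "breslow":
            raise ValueError("PH diagnostics are only available for Efron fits")
        raise ValueError("fit lacks the data needed for diagnostics")
    frame = fit._frame
    if int(frame["event"].sum()) == 0:
        raise ValueError("no events: PH diagnostics undefined")
    cph = fit._cph
    sch = cph.compute_residuals(frame, kind="schoenfeld")
    # rows are events, ordered by time via the index
    ev_times = frame.loc[sch.index, "followup_m"].to_numpy(dtype=float)
    order = np.argsort(ev_times, kind="mergesort")
    R = sch.to_numpy(dtype=float)[order]
    d, p = R.shape
    g = stats.rankdata(ev_times[order], method="average")
    gc = g - g.mean()
    # average per-event covariance of the covariates over risk sets,
    # approximated by the observed information / number of events
    names = list(fit.coef.index)
    I = np.linalg.inv(cph.variance_matrix_.loc[names, names].to_numpy())
    Vbar = I / d
    u = R.T @ gc  # (p,)
    denom = float(gc @ gc)
    per_cov = {}
    for k, name in enumerate(names):
        chi2 = u[k] ** 2 / (denom * Vbar[k, k])
        per_cov[name] = {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1))}
    chi2_global = float(u @ np.linalg.solve(denom * Vbar, u))
    return {
        "per_covariate": per_cov,
        "global": {
            "chi2": chi2_global, "df": p,
            "p": float(stats.chi2.sf(chi2_global, p)),
        },
        "martingale_sum": float(fit.martingale.sum()),
    }


def bivariable_screen(outcomes: pd.DataFrame, covariates: pd.DataFrame,
                      p_threshold: float = 0.25) -> pd.DataFrame:
    """One-at-a-time Cox fits; flags covariates passing the p <= threshold screen.

    A reporting helper (the joint model's covariate list stays user-specified).
    """
    rows = []
    for col in covariates.columns:
        f = cox_fit(outcomes, covariates[[col]])
        z = f.coef[col] / f.se[col]
        pval = 2 * stats.norm.sf(abs(z))
        rows.append({"covariate": col, "coef": f.coef[col], "se": f.se[col],
                     "hr": f.hr[col], "p": pval, "selected": pval <= p_threshold})
    return pd.DataFrame(rows)
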