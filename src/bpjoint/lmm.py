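"""Linear mixed-effects submodels for the longitudinal blood-pressure outcomes.

Each outcome (SBP, DBP) follows

    y_i(t) = x_i(t)' beta + z_i(t)' b_i + eps_i(t),
    b_i ~ N(0, D),  eps ~ N(0, sigma^2),

with x = [1, spline(t), covariate dummies] and z = [1, spline(t)].  Outcomes
are modelled on an internal scale of mmHg/10, so a typical systolic intercept
is ~12 units; readers and writers convert at the boundary.

Estimation is by maximum likelihood (so AIC/BIC comparisons across fixed
effect sets are coherent) through ``statsmodels`` MixedLM; a generalised
least squares closed form is used when the variance components are supplied
as known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import NaturalCubicSplineBasis

__all__ = [
    "INTERNAL_SCALE",
    "DEFAULT_LONG_COVARIATES",
    "SplineSpec",
    "LMMFit",
    "covariate_matrix",
    "build_design",
    "fit_lmm",
    "fit_outcome_lmm",
    "select_random_structure",
    "design_rows_for_times",
]

#: BP values are divided by this before modelling (mmHg -> internal units).
INTERNAL_SCALE = 10.0

#: Fixed-effect covariates of the longitudinal submodels.
DEFAULT_LONG_COVARIATES = [
    "sex", "dm", "chd", "aki", "htn_stage", "treatment", "htn_duration",
]

_REFERENCE = {
    "age_group": "18_64", "sex": "female", "fbs_cat": "normal",
    "bun_cat": "normal", "tg_cat": "normal", "tc_cat": "normal",
    "hdl_cat": "normal", "ldl_cat": "normal", "proteinuria": "negative",
    "aki": "no", "dm": "no", "chd": "no", "vd": "no", "fhhtn": "no",
    "htn_stage": "stage1", "treatment": "single",
}
_LEVELS = {
    "htn_stage": ("stage1", "stage2", "crisis"),
}


@dataclass
class SplineSpec:
    """Natural cubic spline time basis specification."""

    df: int = 3
    boundary: tuple | None = None  # (0, max observed time) when None
    knots: tuple | None = None     # explicit interior knots override quantiles

    def build(self, times) -> NaturalCubicSplineBasis:
        times = np.asarray(times, dtype=float)
        boundary = self.boundary or (0.0, float(np.max(times)))
        if self.knots is not None:
            return NaturalCubicSplineBasis(list(self.knots), boundary=boundary)
        return NaturalCubicSplineBasis.from_times(times, df=self.df, boundary=boundary)


def covariate_matrix(baseline: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-encode baseline covariates (reference levels dropped).

    Returns a DataFrame indexed by subject_id and the column names.
    Unknown category levels raise ``ValueError`` naming the level.
    """
    b = baseline.set_index("subject_id")
    cols = {}
    for cov in covariates:
        if cov == "htn_duration":
            cols["htn_duration"] = b["htn_duration"].astype(float)
            continue
        from .cohort import BASELINE_LEVELS

        levels = BASELINE_LEVELS[cov]
        ref = _REFERENCE[cov]
        vals = b[cov]
        unknown = sorted(set(vals) - set(levels))
        if unknown:
            raise ValueError(f"covariate {cov}: unexpected level(s) {unknown}")
        for lv in levels:
            if lv == ref:
                continue
            cols[f"{cov}[{lv}]"] = (vals == lv).astype(float)
    W = pd.DataFrame(cols, index=b.index)
    return W, list(W.columns)


def build_design(visits: pd.DataFrame, baseline: pd.DataFrame,
                 spline_spec: SplineSpec | None = None,
                 covariate_list=None, outcome: str = "sbp",
                 basis: NaturalCubicSplineBasis | None = None):
    """Assemble (X, Z, y, grouping) for one longitudinal outcome.

    X columns: intercept, spline basis (df cols), covariate dummies.
    Z columns: intercept, spline basis.  y is on the internal /10 scale;
    rows with a missing value of the outcome are dropped.

    Returns ``(X, Z, y, groups, info)`` where ``info`` carries the basis and
    column names for downstream reuse.
    """
    if covariate_list is None:
        covariate_list = DEFAULT_LONG_COVARIATES
    v = visits[visits[outcome].notna()]
    if len(v) == 0:
        raise ValueError(f"no observed values for outcome {outcome}")
    times = v["time_m"].to_numpy(dtype=float)
    if basis is None:
        basis = (spline_spec or SplineSpec()).build(times)
    B = basis.design(times)
    W, wnames = covariate_matrix(baseline, covariate_list)
    Wrows = W.loc[v["subject_id"]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(v)), B, Wrows])
    Z = np.column_stack([np.ones(len(v)), B])
    y = v[outcome].to_numpy(dtype=float) / INTERNAL_SCALE
    groups = v["subject_id"].to_numpy()
    xnames = ["intercept"] + [f"time{j+1}" for j in range(B.shape[1])] + wnames
    info = {"basis": basis, "xnames": xnames, "covariates": list(covariate_list),
            "outcome": outcome}
    return X, Z, y, groups, info


@dataclass
class LMMFit:
    """Maximum-likelihood fit of one longitudinal submodel."""

    beta: np.ndarray
    beta_names: list[str]
    beta_se: np.ndarray
    D_hat: np.ndarray
    sigma2_hat: float
    loglik: float
    aic: float
    bic: float
    blups: dict
    random_structure: str
    n_obs: int
    n_params: int
    converged: bool
    boundary_D: bool
    info: dict = field(default_factory=dict)
    _data_key: tuple = ()

    @property
    def basis(self):
        return self.info.get("basis")

    def summary_frame(self) -> pd.DataFrame:
        z = 1.959963984540054
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.beta_se,
                "ci_low": self.beta - z * self.beta_se,
                "ci_high": self.beta + z * self.beta_se,
            },
            index=self.beta_names,
        )


_STRUCT_COLS = {"intercept": 1, "intercept_slope": 2, "full": None}


def fit_lmm(X, Z, y, grouping, random_structure: str = "full",
            fixed_variance: tuple | None = None, info: dict | None = None) -> LMMFit:
    """Fit the mixed model by ML, or by GLS when (D, sigma2) are known.

    ``random_structure`` selects leading columns of Z: ``intercept`` (1),
    ``intercept_slope`` (2: intercept + first basis column) or ``full``.
    """
    if random_structure not in _STRUCT_COLS:
        raise ValueError(f"unknown random structure {random_structure!r}")
    ncols = _STRUCT_COLS[random_structure] or Z.shape[1]
    Zs = np.asarray(Z, dtype=float)[:, :ncols]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(grouping)
    data_key = (len(y), float(np.sum(y)), float(np.sum(X)))

    if fixed_variance is not None:
        return _gls_fit(X, Zs, y, groups, random_structure, fixed_variance,
                        info or {}, data_key)

    import statsmodels.api as sm

    model = sm.MixedLM(y, X, groups=groups, exog_re=Zs)
    import warnings

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # optimisers occasionally report success with a non-finite
        # likelihood at a variance boundary; keep the best finite fit
        for method in ("lbfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=400)
            except Exception:
                continue
            if not np.isfinite(cand.llf):
                continue
            if res is None or (cand.converged and not res.converged) or (
                    cand.converged == res.converged and cand.llf > res.llf + 1e-8):
                res = cand
            if res.converged:
                break
    if res is None or not res.converged:
        raise RuntimeError(
            f"mixed model ({random_structure}) did not converge"
            + (f"; final loglik {res.llf:.4f}" if res is not None else "")
        )
    beta = np.asarray(res.fe_params)
    D = np.asarray(res.cov_re)
    sigma2 = float(res.scale)
    eig = np.linalg.eigvalsh((D + D.T) / 2)
    boundary = bool(eig.min() < 1e-8 * max(eig.max(), 1.0))
    p = X.shape[1] + ncols * (ncols + 1) // 2 + 1
    ll = float(res.llf)
    # BLUPs computed directly (robust to boundary/singular D estimates):
    # b_i = D Z_i' V_i^{-1} (y_i - X_i beta)
    blups = {}
    resid = y - X @ beta
    for gid in pd.unique(groups):
        idx = np.where(groups == gid)[0]
        Vi = Zs[idx] @ D @ Zs[idx].T + sigma2 * np.eye(len(idx))
        blups[gid] = D @ Zs[idx].T @ np.linalg.solve(Vi, resid[idx])
    names = (info or {}).get("xnames") or [f"x{j}" for j in range(X.shape[1])]
    return LMMFit(
        beta=beta, beta_names=list(names), beta_se=np.asarray(res.bse_fe),
        D_hat=D, sigma2_hat=sigma2, loglik=ll,
        aic=-2 * ll + 2 * p, bic=-2 * ll + p * np.log(len(y)),
        blups=blups, random_structure=random_structure, n_obs=len(y),
        n_params=p, converged=True, boundary_D=boundary, info=info or {},
        _data_key=data_key,
    )


def _gls_fit(X, Z, y, groups, structure, fixed_variance, info, data_key) -> LMMFit:
    D, sigma2 = fixed_variance
    D = np.atleast_2d(np.asarray(D, dtype=float))[: Z.shape[1], : Z.shape[1]]
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    order = pd.unique(groups)
    per_group = {}
    ll_const = 0.0
    for g in order:
        idx = np.where(groups == g)[0]
        Vi = Z[idx] @ D @ Z[idx].T + sigma2 * np.eye(len(idx))
        Li = np.linalg.cholesky(Vi)
        Xi = np.linalg.solve(Li, X[idx])
        yi = np.linalg.solve(Li, y[idx])
        XtVX += Xi.T @ Xi
        XtVy += Xi.T @ yi
        per_group[g] = (idx, Vi, Li)
        ll_const += -np.log(np.diag(Li)).sum() - 0.5 * len(idx) * np.log(2 * np.pi)
    beta = np.linalg.solve(XtVX, XtVy)
    ll = ll_const
    blups = {}
    for g, (idx, Vi, Li) in per_group.items():
        r = y[idx] - X[idx] @ beta
        u = np.linalg.solve(Li, r)
        ll += -0.5 * u @ u
        blups[g] = D @ Z[idx].T @ np.linalg.solve(Vi, r)
    p = X.shape[1]
    se = np.sqrt(np.diag(np.linalg.inv(XtVX)))
    names = info.get("xnames") or [f"x{j}" for j in range(X.shape[1])]
    return LMMFit(
        beta=beta, beta_names=list(names), beta_se=se, D_hat=D,
        sigma2_hat=float(sigma2), loglik=float(ll),
        aic=-2 * ll + 2 * p, bic=-2 * ll + p * np.log(len(y)),
        blups=blups, random_structure=structure, n_obs=len(y), n_params=p,
        converged=True, boundary_D=False, info=info, _data_key=data_key,
    )


def fit_outcome_lmm(cohort, outcome: str = "sbp", spline_spec: SplineSpec | None = None,
                    covariates=None, random_structure: str = "full",
                    basis=None) -> LMMFit:
    """Convenience wrapper: build the design from a cohort and fit."""
    X, Z, y, groups, info = build_design(
        cohort.visits, cohort.baseline, spline_spec, covariates,
        outcome=outcome, basis=basis,
    )
    return fit_lmm(X, Z, y, groups, random_structure, info=info)


def select_random_structure(fits: dict[str, LMMFit]):
    """Pick the random-effects structure minimising AIC.

    Ties break toward fewer parameters; a flag marks AIC/BIC disagreement.
    All fits must be on identical data.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted structures to compare")
    keys = {f._data_key for f in fits.values()}
    if len(keys) > 1:
        raise ValueError("fits were computed on differing data")
    table = pd.DataFrame(
        {
            "structure": list(fits),
            "n_params": [f.n_params for f in fits.values()],
            "loglik": [f.loglik for f in fits.values()],
            "aic": [f.aic for f in fits.values()],
            "bic": [f.bic for f in fits.values()],
        }
    ).sort_values(["aic", "n_params"], kind="mergesort").reset_index(drop=True)
    chosen = table.iloc[0]["structure"]
    bic_choice = table.sort_values(["bic", "n_params"], kind="mergesort").iloc[0]["structure"]
    return {
        "chosen": chosen,
        "bic_choice": bic_choice,
        "criteria_disagree": bool(chosen != bic_choice),
        "table": table,
    }


def design_rows_for_times(fit: LMMFit, baseline: pd.DataFrame, subject_id, times):
    """(X, Z) rows for one subject at arbitrary times, using the fit's basis."""
    basis = fit.basis
    if basis is None:
        raise ValueError("fit carries no spline basis (was it built via build_design?)")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    B = basis.design(times)
    W, _ = covariate_matrix(baseline, fit.info["covariates"])
    w = W.loc[subject_id].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(times)), B, np.tile(w, (len(times), 1))])
    Z = np.column_stack([np.ones(len(times)), B])
    return X, Z
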