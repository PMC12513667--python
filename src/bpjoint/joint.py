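"""Bayesian multivariate joint model of BP trajectories and time to CKD.

Model
-----
Two longitudinal outcomes (SBP, DBP on the internal mmHg/10 scale) follow
linear mixed submodels

    y_ki(t) = eta_ki(t) + eps,   eta_ki(t) = x_ki(t)' beta_k + z_ki(t)' b_ki,

and the hazard of CKD for subject i is

    h_i(t) = h0(t) exp[ gamma' w_i + sum_k sum_l alpha_kl f_kl(t) ],

where h0 is piecewise-constant over intervals cut at event-time quantiles
and f_kl is a functional of the latent trajectory: its current value
(centred at a fixed population constant c_k), its quarterly rate of change
(3x the per-month derivative), or the running area under the centred
trajectory.  Centring is a pure reparameterisation of h0 that keeps
exp(alpha * f) numerically tame without changing the meaning of alpha as a
log hazard ratio per unit of the functional.

Inference is Metropolis-within-Gibbs: conjugate updates for the residual
variances (inverse-gamma), D (inverse-Wishart) and the baseline heights
(gamma, exploiting that the cumulative hazard is linear in each height);
Metropolis-Hastings updates for beta_k and the per-subject b_i using the
exact longitudinal-conditional Gaussian as proposal (so the acceptance
ratio reduces to the survival part); adaptive random-walk blocks for gamma
and alpha with Robbins-Monro scaling toward 0.234 (multivariate) / 0.44
(scalar), frozen after burn-in.  The survival integral uses Gauss-Legendre
quadrature per baseline interval intersected with [0, T_i].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    DEFAULT_LONG_COVARIATES,
    INTERNAL_SCALE,
    SplineSpec,
    covariate_matrix,
)
from .splines import NaturalCubicSplineBasis

logger = logging.getLogger(__name__)

__all__ = [
    "ASSOCIATION_STRUCTURES",
    "DEFAULT_SURV_COVARIATES",
    "AssociationSpec",
    "BaselineHazardSpec",
    "PriorSpec",
    "MCMCSettings",
    "JointModelSpec",
    "PosteriorDraws",
    "eta_eval",
    "SubjectHazard",
    "subject_loglik",
    "run_mcmc",
    "two_stage_init",
    "summarize_fit",
]

#: Active trajectory functionals per association structure.
ASSOCIATION_STRUCTURES: dict[str, tuple[str, ...]] = {
    "none": (),
    "current_value": ("value",),
    "slope": ("slope",),
    "value_and_slope": ("value", "slope"),
    "area": ("area",),
    "area_and_value": ("area", "value"),
}

#: Survival-submodel covariates (the fitted survival table's covariate set).
DEFAULT_SURV_COVARIATES = [
    "age_group", "sex", "tg_cat", "tc_cat", "hdl_cat", "bun_cat",
    "dm", "chd", "vd", "proteinuria", "aki", "treatment",
]


@dataclass
class AssociationSpec:
    """Which trajectory functionals enter the hazard, and their centring."""

    structure: str = "value_and_slope"
    centering: tuple = (12.0, 9.2)  # internal-scale constants per outcome

    def __post_init__(self):
        if self.structure not in ASSOCIATION_STRUCTURES:
            raise ValueError(
                f"unknown association structure {self.structure!r}; "
                f"choose from {sorted(ASSOCIATION_STRUCTURES)}"
            )

    @property
    def terms(self) -> tuple[str, ...]:
        return ASSOCIATION_STRUCTURES[self.structure]

    def labels(self, outcomes) -> list[str]:
        return [f"alpha_{k}_{term}" for k in outcomes for term in self.terms]

    def n_alpha(self, n_outcomes: int) -> int:
        return n_outcomes * len(self.terms)


@dataclass
class BaselineHazardSpec:
    """Piecewise-constant baseline hazard with knots at event-time quantiles."""

    n_intervals: int = 12
    cutpoints: np.ndarray | None = None  # interior cutpoints + upper bound

    def resolve(self, event_times, max_time) -> np.ndarray:
        """Interval edges (0, c_1, ..., c_J] with c_J = max follow-up."""
        if self.cutpoints is not None:
            cp = np.asarray(self.cutpoints, dtype=float)
            if np.any(np.diff(cp) <= 0) or cp[0] <= 0:
                raise ValueError("cutpoints must be strictly increasing and > 0")
            return cp
        ev = np.sort(np.asarray(event_times, dtype=float))
        J = self.n_intervals
        if len(ev) == 0:
            inner = np.linspace(0, max_time, J + 1)[1:-1]
        else:
            qs = np.quantile(ev, np.linspace(0, 1, J + 1)[1:-1])
            inner = np.clip(qs, 1e-6, max_time - 1e-6)
            inner = np.maximum.accumulate(inner)
            for i in range(1, len(inner)):
                if inner[i] <= inner[i - 1]:
                    inner[i] = inner[i - 1] + 1e-3
        return np.append(inner, max_time)


@dataclass
class PriorSpec:
    """Vague priors mirroring the fitted model's stated choices.

    ``fixed_effect_spread`` 0.001 is read as a *precision* by default
    (variance 1000); set ``reading="variance"`` for the literal reading.
    Residual variances get InvGamma(shape, scale); baseline heights get
    independent Gamma(a0, b0); D gets InvWishart(q+1, I).
    """

    fixed_effect_spread: float = 0.001
    reading: str = "precision"  # or "variance"
    sigma2_shape: float = 1.0
    sigma2_scale: float = 0.005
    lambda_a0: float = 0.01
    lambda_b0: float = 0.01

    @property
    def coef_precision(self) -> float:
        if self.reading == "precision":
            return self.fixed_effect_spread
        return 1.0 / self.fixed_effect_spread


@dataclass
class MCMCSettings:
    chains: int = 3
    total_iterations: int = 100_000
    burn_in: int = 25_000
    thin: int = 12
    seed: int = 0
    quadrature_points: int = 15
    adaptation: bool = True

    def __post_init__(self):
        if self.total_iterations and self.burn_in >= self.total_iterations:
            raise ValueError("burn_in must be < total_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return max(self.total_iterations - self.burn_in, 0) // self.thin


@dataclass
class JointModelSpec:
    association: AssociationSpec = field(default_factory=AssociationSpec)
    outcomes: tuple = ("sbp", "dbp")
    long_covariates: list = field(default_factory=lambda: list(DEFAULT_LONG_COVARIATES))
    surv_covariates: list = field(default_factory=lambda: list(DEFAULT_SURV_COVARIATES))
    baseline_hazard: BaselineHazardSpec = field(default_factory=BaselineHazardSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    spline: SplineSpec = field(default_factory=SplineSpec)
    d_structure: str = "full"  # or "blockdiag"


# ---------------------------------------------------------------------------
# trajectory functionals
# ---------------------------------------------------------------------------

def eta_eval(t, beta_k, b_ki, design_info, mode: str = "value"):
    """Evaluate the latent trajectory (or its slope / running area) at t.

    ``design_info`` carries ``basis`` (the spline) and ``w`` (the subject's
    covariate dummy row).  ``mode``: ``value`` = eta(t); ``slope`` = d eta/dt
    per month; ``area`` = integral of eta from 0 to t.  Beyond the basis
    boundary the natural spline continues linearly (no error).
    """
    basis: NaturalCubicSplineBasis = design_info["basis"]
    w = np.asarray(design_info.get("w", ()), dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    beta_k = np.asarray(beta_k, dtype=float)
    b_ki = np.asarray(b_ki, dtype=float)
    df = basis.df
    bt, bw = beta_k[1 : 1 + df], beta_k[1 + df :]
    wpart = float(w @ bw) if len(w) else 0.0
    if mode == "value":
        B = basis.design(t)
        out = beta_k[0] + B @ bt + wpart + b_ki[0] + B @ b_ki[1:]
    elif mode == "slope":
        Bd = basis.deriv(t)
        out = Bd @ bt + Bd @ b_ki[1:]
    elif mode == "area":
        IB = basis.integral(t)
        out = (beta_k[0] + wpart + b_ki[0]) * t + IB @ bt + IB @ b_ki[1:]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.shape != (1,) else float(out[0])


class SubjectHazard:
    """Per-subject hazard evaluator shared by the simulator and the fitter.

    log h(t) = log lambda(t) + gamma'w + sum_k sum_l alpha_kl f_kl(t) with
    the centred functionals described in the module docstring.  The
    cumulative hazard integrates by Gauss-Legendre per baseline interval.
    """

    def __init__(self, basis, beta_by_outcome, b_by_outcome, w_long,
                 gamma_dot_w, alpha, association: AssociationSpec,
                 cutpoints, log_lambda, quad_points: int = 15):
        self.basis = basis
        self.beta = [np.asarray(b, float) for b in beta_by_outcome]
        self.b = [np.asarray(b, float) for b in b_by_outcome]
        self.w_long = np.asarray(w_long, float)
        self.gamma_dot_w = float(gamma_dot_w)
        self.alpha = np.asarray(alpha, float)
        self.assoc = association
        self.cut = np.asarray(cutpoints, float)
        self.log_lambda = np.asarray(log_lambda, float)
        self.quad = quad_points
        self._gl = np.polynomial.legendre.leggauss(quad_points)

    def f(self, t):
        """Association offset sum_k sum_l alpha_kl f_kl(t) (vectorised in t)."""
        t = np.atleast_1d(np.asarray(t, float))
        info_cache = [{"basis": self.basis, "w": self.w_long} for _ in self.beta]
        out = np.zeros_like(t)
        idx = 0
        for k, (bk, bik) in enumerate(zip(self.beta, self.b)):
            c = self.assoc.centering[k]
            for term in self.assoc.terms:
                a = self.alpha[idx]
                idx += 1
                if a == 0.0:
                    continue
                if term == "value":
                    g = np.atleast_1d(eta_eval(t, bk, bik, info_cache[k], "value")) - c
                elif term == "slope":
                    g = 3.0 * np.atleast_1d(eta_eval(t, bk, bik, info_cache[k], "slope"))
                else:  # area
                    g = np.atleast_1d(eta_eval(t, bk, bik, info_cache[k], "area")) - c * t
                out = out + a * g
        return out

    def _interval_index(self, t):
        return np.minimum(np.searchsorted(self.cut, t, side="left"),
                          len(self.cut) - 1)

    def log_hazard(self, t):
        t = np.atleast_1d(np.asarray(t, float))
        return self.log_lambda[self._interval_index(t)] + self.gamma_dot_w + self.f(t)

    def cumulative(self, t: float) -> float:
        """Lambda(t) = integral of the hazard from 0 to t."""
        t = float(t)
        if t <= 0:
            return 0.0
        edges = np.concatenate([[0.0], self.cut])
        xg, wg = self._gl
        total = 0.0
        for j in range(len(self.cut)):
            a, b = edges[j], min(edges[j + 1], t)
            if b <= a and not (j == len(self.cut) - 1 and t > self.cut[-1]):
                if t <= edges[j]:
                    break
                continue
            # the last interval extends beyond its upper cutpoint if t does
            if j == len(self.cut) - 1:
                b = t if t > a else b
            if b <= a:
                continue
            half = (b - a) / 2.0
            nodes = a + half * (xg + 1.0)
            total += half * np.sum(wg * np.exp(self.log_hazard(nodes)))
        return total


def subject_loglik(subject_data: dict, params: dict, spec: JointModelSpec):
    """Reference (scalar, per-subject) joint log-likelihood.

    ``subject_data``: ``times_k``/``y_k`` per outcome (internal scale),
    ``w_long``, ``w_surv``, ``T``, ``delta``.  ``params``: ``beta`` (list per
    outcome), ``b`` (list per outcome), ``sigma2`` (list), ``gamma``,
    ``alpha``, ``log_lambda``, ``cutpoints``, ``basis``.

    Returns ``(longitudinal_part, survival_part)``.  The vectorised sampler
    must agree with this implementation; tests enforce it.
    """
    basis = params["basis"]
    long_ll = 0.0
    for k, name in enumerate(spec.outcomes):
        t = np.asarray(subject_data[f"times_{name}"], float)
        y = np.asarray(subject_data[f"y_{name}"], float)
        if len(t) == 0:
            continue
        info = {"basis": basis, "w": subject_data["w_long"]}
        eta = np.atleast_1d(eta_eval(t, params["beta"][k], params["b"][k], info, "value"))
        s2 = params["sigma2"][k]
        long_ll += float(np.sum(stats.norm.logpdf(y, eta, np.sqrt(s2))))
    gamma = np.asarray(params["gamma"], float)
    w_surv = np.asarray(subject_data["w_surv"], float)
    gw = float(w_surv @ gamma) if len(gamma) else 0.0
    haz = SubjectHazard(
        basis, params["beta"], params["b"], subject_data["w_long"], gw,
        params["alpha"], spec.association, params["cutpoints"],
        params["log_lambda"], quad_points=params.get("quad_points", 15),
    )
    T, delta = float(subject_data["T"]), float(subject_data["delta"])
    surv_ll = delta * float(haz.log_hazard(np.array([T]))[0]) - haz.cumulative(T)
    if not (np.isfinite(long_ll) and np.isfinite(surv_ll)):
        raise FloatingPointError(
            f"non-finite log-likelihood for subject (long={long_ll}, surv={surv_ll})"
        )
    return long_ll, surv_ll


# ---------------------------------------------------------------------------
# vectorised fit data
# ---------------------------------------------------------------------------

class _FitData:
    """Precomputed design/quadrature arrays for the sampler."""

    def __init__(self, cohort, spec: JointModelSpec, quad_points: int):
        from .cohort import Cohort  # noqa: F401  (typing only)

        self.spec = spec
        out = cohort.outcomes.sort_values("subject_id").reset_index(drop=True)
        self.subject_ids = list(out["subject_id"])
        sid_index = {s: i for i, s in enumerate(self.subject_ids)}
        self.n = len(self.subject_ids)
        self.T = out["followup_m"].to_numpy(float)
        self.delta = out["event"].to_numpy(float)

        Wl, self.long_names = covariate_matrix(cohort.baseline, spec.long_covariates)
        self.W_long = Wl.loc[self.subject_ids].to_numpy(float)
        if spec.surv_covariates:
            Wg, self.surv_names = covariate_matrix(cohort.baseline, spec.surv_covariates)
            self.W_surv = Wg.loc[self.subject_ids].to_numpy(float)
        else:
            self.surv_names = []
            self.W_surv = np.zeros((self.n, 0))

        all_times = cohort.visits["time_m"].to_numpy(float)
        boundary = spec.spline.boundary or (0.0, float(max(all_times.max(), self.T.max())))
        self.basis = spec.spline.build(all_times) if spec.spline.knots is None else \
            NaturalCubicSplineBasis(list(spec.spline.knots), boundary=boundary)
        if spec.spline.knots is None and spec.spline.boundary is None:
            # rebuild with boundary covering follow-up times
            self.basis = NaturalCubicSplineBasis(
                list(self.basis.knots[1:-1]), boundary=boundary
            )
        self.df = self.basis.df
        self.q = 1 + self.df            # random effects per outcome
        self.K = len(spec.outcomes)
        self.qtot = self.q * self.K

        # longitudinal arrays per outcome
        self.y, self.X, self.Z, self.sub = [], [], [], []
        self.XtX, self.ZtZ_per_sub = [], []
        for name in spec.outcomes:
            v = cohort.visits[cohort.visits[name].notna()]
            t = v["time_m"].to_numpy(float)
            B = self.basis.design(t)
            Wrows = Wl.loc[v["subject_id"]].to_numpy(float)
            X = np.column_stack([np.ones(len(v)), B, Wrows])
            Z = np.column_stack([np.ones(len(v)), B])
            y = v[name].to_numpy(float) / INTERNAL_SCALE
            sub = np.array([sid_index[s] for s in v["subject_id"]])
            order = np.argsort(sub, kind="mergesort")
            self.y.append(y[order]); self.X.append(X[order])
            self.Z.append(Z[order]); self.sub.append(sub[order])
            self.XtX.append(X.T @ X)
            ZtZ = np.zeros((self.n, self.q, self.q))
            np.add.at(ZtZ, sub, Z[:, :, None] * Z[:, None, :])
            self.ZtZ_per_sub.append(ZtZ)
        self.p = self.X[0].shape[1]
        self.n_obs = [len(y) for y in self.y]

        # baseline hazard intervals + quadrature
        ev_times = self.T[self.delta == 1]
        self.cut = spec.baseline_hazard.resolve(ev_times, float(self.T.max()))
        self.J = len(self.cut)
        edges = np.concatenate([[0.0], self.cut])
        xg, wg = np.polynomial.legendre.leggauss(quad_points)
        node_t, node_w, node_sub, node_int = [], [], [], []
        for i in range(self.n):
            Ti = self.T[i]
            for j in range(self.J):
                a = edges[j]
                b = min(edges[j + 1], Ti) if j < self.J - 1 else min(max(edges[j + 1], Ti), Ti)
                if Ti > edges[j] and b > a:
                    half = (b - a) / 2.0
                    node_t.append(a + half * (xg + 1.0))
                    node_w.append(half * wg)
                    node_sub.append(np.full(quad_points, i))
                    node_int.append(np.full(quad_points, j))
                if Ti <= edges[j + 1]:
                    break
        self.node_t = np.concatenate(node_t)
        self.node_w = np.concatenate(node_w)
        self.node_sub = np.concatenate(node_sub)
        self.node_int = np.concatenate(node_int)
        self.ev_int = np.minimum(np.searchsorted(self.cut, self.T, side="left"),
                                 self.J - 1)

        # association design at quadrature nodes and at event times
        self._build_assoc_designs()

        key = (self.n, float(self.T.sum()), float(self.delta.sum()),
               tuple(round(float(s), 6) for s in np.sort(self.T)[:5]))
        self.data_key = key

    def _assoc_mats(self, t, sub):
        """(G, H, offset_scale) per term type at times t for subjects sub."""
        B, Bd, IB = self.basis.design(t), self.basis.deriv(t), self.basis.integral(t)
        W = self.W_long[sub]
        mats = {}
        G = np.column_stack([np.ones(len(t)), B, W])
        mats["value"] = (G, np.column_stack([np.ones(len(t)), B]), np.ones(len(t)))
        Gs = np.zeros((len(t), self.p)); Gs[:, 1 : 1 + self.df] = 3.0 * Bd
        mats["slope"] = (Gs, np.column_stack([np.zeros(len(t)), 3.0 * Bd]),
                         np.zeros(len(t)))
        Ga = np.column_stack([t, IB, W * t[:, None]])
        mats["area"] = (Ga, np.column_stack([t, IB]), t.copy())
        return mats

    def _build_assoc_designs(self):
        self.assoc_nodes = self._assoc_mats(self.node_t, self.node_sub)
        self.assoc_T = self._assoc_mats(self.T, np.arange(self.n))

    def term_values(self, which: str, beta_k, b_k, k: int):
        """m_kl arrays at quadrature nodes and event times for one outcome."""
        mn = self.term_beta_part(which, beta_k, k)[0] + self.term_b_part(which, b_k)[0]
        mT = self.term_beta_part(which, beta_k, k)[1] + self.term_b_part(which, b_k)[1]
        return mn, mT

    def term_beta_part(self, which: str, beta_k, k: int):
        """Fixed-effect (+ centring) share of a term at nodes and event times."""
        c = self.spec.association.centering[k]
        Gn, _, on = self.assoc_nodes[which]
        GT, _, oT = self.assoc_T[which]
        return Gn @ beta_k - c * on, GT @ beta_k - c * oT

    def term_b_part(self, which: str, b_k):
        """Random-effect share of a term at nodes and event times."""
        _, Hn, _ = self.assoc_nodes[which]
        _, HT, _ = self.assoc_T[which]
        return (np.einsum("nj,nj->n", Hn, b_k[self.node_sub]),
                np.einsum("nj,nj->n", HT, b_k))


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus per-draw subject log-likelihoods."""

    params: dict                      # name -> (chains, ndraw) or (chains, ndraw, dim)
    param_labels: dict                # name -> list of flat labels
    pointwise_loglik: np.ndarray      # (chains, ndraw, n_subjects)
    pointwise_loglik_at_mean: np.ndarray | None
    acceptance: dict
    meta: dict

    @property
    def n_retained_per_chain(self) -> int:
        first = next(iter(self.params.values()))
        return first.shape[1]

    @property
    def n_chains(self) -> int:
        first = next(iter(self.params.values()))
        return first.shape[0]

    def flat(self) -> dict[str, np.ndarray]:
        """Flat label -> (chains, ndraw) array."""
        out = {}
        for name, arr in self.params.items():
            labels = self.param_labels[name]
            if arr.ndim == 2:
                out[labels[0]] = arr
            else:
                for j, lab in enumerate(labels):
                    out[lab] = arr[:, :, j]
        return out

    def pooled(self, label: str) -> np.ndarray:
        return self.flat()[label].reshape(-1)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _default_init(data: _FitData, spec: JointModelSpec, cohort):
    """Two-stage warm start: LMM per outcome, Cox screen, crude hazard."""
    from .lmm import fit_outcome_lmm
    from .survival import cox_fit

    beta, sigma2, Dblocks, blups = [], [], [], []
    for k, name in enumerate(spec.outcomes):
        try:
            f = fit_outcome_lmm(cohort, outcome=name, covariates=spec.long_covariates,
                                basis=data.basis)
            beta.append(np.asarray(f.beta))
            sigma2.append(max(f.sigma2_hat, 1e-4))
            Dk = np.asarray(f.D_hat)
            Dk = Dk + 1e-4 * np.eye(data.q)
            Dblocks.append(Dk)
            bl = np.zeros((data.n, data.q))
            for i, sid in enumerate(data.subject_ids):
                if sid in f.blups:
                    bl[i] = f.blups[sid]
            blups.append(bl)
        except Exception as exc:  # pragma: no cover - fallback path
            logger.warning("LMM warm start failed for %s (%s); using OLS", name, exc)
            X, y = data.X[k], data.y[k]
            bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
            beta.append(bhat)
            sigma2.append(float(np.var(y - X @ bhat)) or 1e-2)
            Dblocks.append(0.05 * np.eye(data.q))
            blups.append(np.zeros((data.n, data.q)))
    D = np.zeros((data.qtot, data.qtot))
    for k, Dk in enumerate(Dblocks):
        D[k * data.q:(k + 1) * data.q, k * data.q:(k + 1) * data.q] = Dk
    b = np.concatenate(blups, axis=1)

    gamma = np.zeros(len(data.surv_names))
    if len(data.surv_names) and data.delta.sum() >= 5:
        try:
            cov = pd.DataFrame(data.W_surv, columns=data.surv_names)
            cf = cox_fit(pd.DataFrame({"followup_m": data.T, "event": data.delta}), cov)
            gamma = np.clip(cf.coef.loc[data.surv_names].to_numpy(), -3, 3)
        except Exception:
            pass

    # crude per-interval event rates
    edges = np.concatenate([[0.0], data.cut])
    lam = np.empty(data.J)
    for j in range(data.J):
        at_risk_time = np.clip(np.minimum(data.T, edges[j + 1]) - edges[j], 0, None).sum()
        d_j = ((data.ev_int == j) & (data.delta == 1)).sum()
        lam[j] = (d_j + 0.5) / max(at_risk_time, 1e-8)
    return {
        "beta": beta, "sigma2": sigma2, "D": D, "b": b,
        "gamma": gamma, "alpha": np.zeros(spec.association.n_alpha(data.K)),
        "log_lambda": np.log(lam),
    }


def two_stage_init(cohort, spec: JointModelSpec | None = None,
                   quadrature_points: int = 15) -> dict:
    """Public warm start (LMM + Cox screen + crude hazard rates).

    Reusable across association structures on the same cohort: ``run_mcmc``
    resizes the ``alpha`` entry to the structure's dimension.
    """
    spec = spec or JointModelSpec()
    data = _FitData(cohort, spec, quadrature_points)
    return _default_init(data, spec, cohort)


class _Chain:
    """One MCMC chain over the vectorised fit data.

    Caches the association term arrays split into fixed-effect and
    random-effect shares, the combined association offset (fn at quadrature
    nodes, fT at event times), the survival linear predictor gamma'w and the
    per-subject survival log-likelihood, invalidating only what an accepted
    update actually changes.
    """

    def __init__(self, data: _FitData, spec: JointModelSpec,
                 settings: MCMCSettings, init: dict, rng):
        self.d = data
        self.spec = spec
        self.set = settings
        self.rng = rng
        self.prior_prec = spec.priors.coef_precision
        self.beta = [np.array(b, float) for b in init["beta"]]
        self.sigma2 = [float(s) for s in init["sigma2"]]
        self.D = np.array(init["D"], float)
        self.b = np.array(init["b"], float)            # (n, qtot)
        self.gamma = np.array(init["gamma"], float)
        self.alpha = np.array(init["alpha"], float)
        self.log_lambda = np.array(init["log_lambda"], float)
        self.terms = spec.association.terms
        self.n_terms = len(self.terms)
        # adaptive RW state: scalar log-scale + diagonal preconditioner
        # learned online (Welford) during burn-in
        self.ls_gamma, self.ls_alpha = np.log(0.1), np.log(0.1)
        self._adapt_stats = {
            "gamma": [0, np.zeros(len(self.gamma)), np.zeros(len(self.gamma))],
            "alpha": [0, np.zeros(len(self.alpha)), np.zeros(len(self.alpha))],
        }
        self.acc = {"beta": [0, 0], "b": [0, 0], "gamma": [0, 0], "alpha": [0, 0]}
        self._refresh_eta()
        # association caches: flat index = k * n_terms + j
        self.Gb_n, self.Gb_T, self.Hb_n, self.Hb_T = [], [], [], []
        for k in range(data.K):
            for term in self.terms:
                gn, gT = data.term_beta_part(term, self.beta[k], k)
                hn, hT = data.term_b_part(term, self._bk(k))
                self.Gb_n.append(gn); self.Gb_T.append(gT)
                self.Hb_n.append(hn); self.Hb_T.append(hT)
        self.gw = data.W_surv @ self.gamma if len(self.gamma) else np.zeros(data.n)
        self._rebuild_f()
        self.surv = self._surv_eval(self.log_lambda, self.gw, self.fn, self.fT)
        if not np.all(np.isfinite(self.surv)):
            raise FloatingPointError("non-finite posterior at initialization "
                                     "(survival block)")

    # -- cached quantities -------------------------------------------------
    def _bk(self, k):
        return self.b[:, k * self.d.q:(k + 1) * self.d.q]

    def _refresh_eta(self):
        d = self.d
        self.eta = [d.X[k] @ self.beta[k] +
                    np.einsum("nj,nj->n", d.Z[k], self._bk(k)[d.sub[k]])
                    for k in range(d.K)]

    def _rebuild_f(self):
        self.fn = np.zeros(len(self.d.node_t))
        self.fT = np.zeros(self.d.n)
        for a, gn, hn, gT, hT in zip(self.alpha, self.Gb_n, self.Hb_n,
                                     self.Gb_T, self.Hb_T):
            if a != 0.0:
                self.fn += a * (gn + hn)
                self.fT += a * (gT + hT)

    def _surv_eval(self, log_lambda, gw, fn, fT):
        """Per-subject survival log-likelihood for given components."""
        d = self.d
        s_nodes = log_lambda[d.node_int] + gw[d.node_sub] + fn
        with np.errstate(over="ignore"):
            haz_nodes = d.node_w * np.exp(s_nodes)
        Lam = np.bincount(d.node_sub, weights=haz_nodes, minlength=d.n)
        logh = log_lambda[d.ev_int] + gw + fT
        return d.delta * logh - Lam

    def _surv_parts(self):
        return self.surv

    def _surv_loglik_total(self):
        return float(np.sum(self.surv))

    def _long_parts(self):
        d = self.d
        out = np.zeros(d.n)
        for k in range(d.K):
            r = d.y[k] - self.eta[k]
            ll = -0.5 * (r**2 / self.sigma2[k] + np.log(2 * np.pi * self.sigma2[k]))
            out += np.bincount(d.sub[k], weights=ll, minlength=d.n)
        return out

    # -- conjugate updates -------------------------------------------------
    def update_sigma2(self):
        pr = self.spec.priors
        for k in range(self.d.K):
            r = self.d.y[k] - self.eta[k]
            shape = pr.sigma2_shape + 0.5 * len(r)
            scale = pr.sigma2_scale + 0.5 * float(r @ r)
            self.sigma2[k] = scale / self.rng.gamma(shape)

    def update_D(self):
        d = self.d
        if self.spec.d_structure == "blockdiag":
            Dn = np.zeros_like(self.D)
            for k in range(d.K):
                sl = slice(k * d.q, (k + 1) * d.q)
                Sk = np.eye(d.q) + self.b[:, sl].T @ self.b[:, sl]
                Dn[sl, sl] = stats.invwishart.rvs(
                    df=d.q + 1 + d.n, scale=Sk, random_state=self.rng)
            self.D = Dn
        else:
            S = np.eye(d.qtot) + self.b.T @ self.b
            self.D = stats.invwishart.rvs(df=d.qtot + 1 + d.n, scale=S,
                                          random_state=self.rng)

    def update_lambda(self):
        d = self.d
        pr = self.spec.priors
        with np.errstate(over="ignore"):
            expo = d.node_w * np.exp(self.gw[d.node_sub] + self.fn)
        A = np.bincount(d.node_int, weights=expo, minlength=d.J)
        dj = np.bincount(d.ev_int, weights=d.delta, minlength=d.J)
        lam = self.rng.gamma(pr.lambda_a0 + dj, 1.0 / (pr.lambda_b0 + A))
        self.log_lambda = np.log(np.maximum(lam, 1e-300))
        self.surv = self._surv_eval(self.log_lambda, self.gw, self.fn, self.fT)

    # -- MH updates --------------------------------------------------------
    def update_beta(self):
        """Longitudinal-conditional Gaussian proposal; survival MH correction."""
        d = self.d
        for k in range(d.K):
            prec = d.XtX[k] / self.sigma2[k] + self.prior_prec * np.eye(d.p)
            resid = d.y[k] - np.einsum("nj,nj->n", d.Z[k], self._bk(k)[d.sub[k]])
            rhs = d.X[k].T @ resid / self.sigma2[k]
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            prop = mean + np.linalg.solve(L.T, self.rng.standard_normal(d.p))
            new_Gn, new_GT = {}, {}
            fn, fT = self.fn.copy(), self.fT.copy()
            for j, term in enumerate(self.terms):
                idx = k * self.n_terms + j
                gn, gT = d.term_beta_part(term, prop, k)
                new_Gn[idx], new_GT[idx] = gn, gT
                a = self.alpha[idx]
                if a != 0.0:
                    fn += a * (gn - self.Gb_n[idx])
                    fT += a * (gT - self.Gb_T[idx])
            surv1 = self._surv_eval(self.log_lambda, self.gw, fn, fT)
            self.acc["beta"][1] += 1
            if np.log(self.rng.uniform()) < float(np.sum(surv1) - np.sum(self.surv)):
                self.beta[k] = prop
                for idx, gn in new_Gn.items():
                    self.Gb_n[idx] = gn
                    self.Gb_T[idx] = new_GT[idx]
                self.fn, self.fT, self.surv = fn, fT, surv1
                self.acc["beta"][0] += 1
        self._refresh_eta()

    def update_b(self):
        """Per-subject MH with the longitudinal-conditional as proposal."""
        d = self.d
        Dinv = np.linalg.inv(self.D)
        prec = np.tile(Dinv, (d.n, 1, 1))
        rhs = np.zeros((d.n, d.qtot))
        for k in range(d.K):
            sl = slice(k * d.q, (k + 1) * d.q)
            prec[:, sl, sl] += d.ZtZ_per_sub[k] / self.sigma2[k]
            r = d.y[k] - d.X[k] @ self.beta[k]
            M = d.Z[k] * (r / self.sigma2[k])[:, None]
            acc = np.zeros((d.n, d.q))
            np.add.at(acc, d.sub[k], M)
            rhs[:, sl] += acc
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
        z = self.rng.standard_normal((d.n, d.qtot))
        prop = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]

        new_Hn, new_HT = [], []
        fn, fT = self.fn.copy(), self.fT.copy()
        for k in range(d.K):
            bk = prop[:, k * d.q:(k + 1) * d.q]
            for j, term in enumerate(self.terms):
                idx = k * self.n_terms + j
                hn, hT = d.term_b_part(term, bk)
                new_Hn.append(hn); new_HT.append(hT)
                a = self.alpha[idx]
                if a != 0.0:
                    fn += a * (hn - self.Hb_n[idx])
                    fT += a * (hT - self.Hb_T[idx])
        surv1 = self._surv_eval(self.log_lambda, self.gw, fn, fT)
        accept = np.log(self.rng.uniform(size=d.n)) < (surv1 - self.surv)
        self.b = np.where(accept[:, None], prop, self.b)
        node_acc = accept[d.node_sub]
        for idx in range(len(self.Hb_n)):
            self.Hb_n[idx] = np.where(node_acc, new_Hn[idx], self.Hb_n[idx])
            self.Hb_T[idx] = np.where(accept, new_HT[idx], self.Hb_T[idx])
        self.surv = np.where(accept, surv1, self.surv)
        self._rebuild_f()
        self.acc["b"][0] += int(accept.sum())
        self.acc["b"][1] += d.n
        self._refresh_eta()

    def _prop_scale(self, name):
        cnt, mean, m2 = self._adapt_stats[name]
        if cnt < 50:
            return 1.0
        sd = np.sqrt(m2 / cnt)
        return np.maximum(sd, 0.05 * max(float(sd.max()), 1e-8))

    def _adapt_record(self, name, value):
        st = self._adapt_stats[name]
        st[0] += 1
        delta = value - st[1]
        st[1] = st[1] + delta / st[0]
        st[2] = st[2] + delta * (value - st[1])

    def update_gamma(self, it, adapting):
        if len(self.gamma) == 0:
            return
        s = np.exp(self.ls_gamma) * self._prop_scale("gamma")
        prop = self.gamma + s * self.rng.standard_normal(len(self.gamma))
        gw1 = self.d.W_surv @ prop
        surv1 = self._surv_eval(self.log_lambda, gw1, self.fn, self.fT)
        lp0 = -0.5 * self.prior_prec * float(self.gamma @ self.gamma)
        lp1 = -0.5 * self.prior_prec * float(prop @ prop)
        delta = float(np.sum(surv1) - np.sum(self.surv)) + lp1 - lp0
        self.acc["gamma"][1] += 1
        accepted = np.log(self.rng.uniform()) < delta
        if accepted:
            self.gamma, self.gw, self.surv = prop, gw1, surv1
            self.acc["gamma"][0] += 1
        if adapting:
            tgt = 0.44 if len(self.gamma) == 1 else 0.234
            self.ls_gamma += (it + 1) ** -0.6 * (float(accepted) - tgt)
            self._adapt_record("gamma", self.gamma)

    def update_alpha(self, it, adapting):
        if len(self.alpha) == 0:
            return
        s = np.exp(self.ls_alpha) * self._prop_scale("alpha")
        prop = self.alpha + s * self.rng.standard_normal(len(self.alpha))
        fn = np.zeros(len(self.d.node_t))
        fT = np.zeros(self.d.n)
        for a, gn, hn, gT, hT in zip(prop, self.Gb_n, self.Hb_n,
                                     self.Gb_T, self.Hb_T):
            if a != 0.0:
                fn += a * (gn + hn)
                fT += a * (gT + hT)
        surv1 = self._surv_eval(self.log_lambda, self.gw, fn, fT)
        lp0 = -0.5 * self.prior_prec * float(self.alpha @ self.alpha)
        lp1 = -0.5 * self.prior_prec * float(prop @ prop)
        delta = float(np.sum(surv1) - np.sum(self.surv)) + lp1 - lp0
        self.acc["alpha"][1] += 1
        accepted = np.log(self.rng.uniform()) < delta
        if accepted:
            self.alpha, self.fn, self.fT, self.surv = prop, fn, fT, surv1
            self.acc["alpha"][0] += 1
        if adapting:
            tgt = 0.44 if len(self.alpha) == 1 else 0.234
            self.ls_alpha += (it + 1) ** -0.6 * (float(accepted) - tgt)
            self._adapt_record("alpha", self.alpha)

    # -- iteration ---------------------------------------------------------
    def sweep(self, it, adapting):
        self.update_b()
        self.update_beta()
        self.update_sigma2()
        self.update_D()
        self.update_gamma(it, adapting)
        self.update_alpha(it, adapting)
        self.update_lambda()

    def pointwise(self):
        return self._long_parts() + self._surv_parts()

    def snapshot(self):
        d = self.d
        tri = np.tril_indices(d.qtot)
        return {
            **{f"beta_{self.spec.outcomes[k]}": self.beta[k].copy()
               for k in range(d.K)},
            **{f"sigma2_{self.spec.outcomes[k]}": np.array([self.sigma2[k]])
               for k in range(d.K)},
            "gamma": self.gamma.copy(),
            "alpha": self.alpha.copy(),
            "log_lambda": self.log_lambda.copy(),
            "D_tril": self.D[tri].copy(),
        }



def _param_labels(data: _FitData, spec: JointModelSpec):
    labels = {}
    for k, name in enumerate(spec.outcomes):
        xn = ["intercept"] + [f"time{j+1}" for j in range(data.df)] + data.long_names
        labels[f"beta_{name}"] = [f"beta_{name}[{c}]" for c in xn]
        labels[f"sigma2_{name}"] = [f"sigma2_{name}"]
    labels["gamma"] = [f"gamma[{c}]" for c in data.surv_names]
    labels["alpha"] = spec.association.labels(spec.outcomes)
    labels["log_lambda"] = [f"log_lambda[{j+1}]" for j in range(data.J)]
    tri = np.tril_indices(data.qtot)
    labels["D_tril"] = [f"D[{a},{b}]" for a, b in zip(*tri)]
    return labels


def run_mcmc(cohort, model_spec: JointModelSpec | None = None,
             settings: MCMCSettings | None = None,
             init: dict | None = None) -> PosteriorDraws:
    """Sample the joint posterior; bitwise reproducible given seed and chain.

    Returns a :class:`PosteriorDraws` with per-draw subject log-likelihood
    contributions (for WAIC/DIC) and, when draws exist, the pointwise
    log-likelihood at the posterior mean of all parameters (for DIC's
    plug-in deviance).
    """
    spec = model_spec or JointModelSpec()
    settings = settings or MCMCSettings()
    data = _FitData(cohort, spec, settings.quadrature_points)
    labels = _param_labels(data, spec)
    meta = {
        "structure": spec.association.structure,
        "n_subjects": data.n,
        "data_key": data.data_key,
        "cutpoints": data.cut.tolist(),
        "outcomes": list(spec.outcomes),
        "settings": settings,
        "basis_knots": data.basis.knots.tolist(),
    }

    nret = settings.n_retained
    if settings.total_iterations == 0 or nret == 0:
        empty = {k: np.zeros((settings.chains, 0, len(v)))
                 for k, v in labels.items()}
        return PosteriorDraws(empty, labels, np.zeros((settings.chains, 0, data.n)),
                              None, {}, meta)

    init0 = init or _default_init(data, spec, cohort)
    n_alpha = spec.association.n_alpha(data.K)
    if len(np.atleast_1d(init0.get("alpha", []))) != n_alpha:
        init0 = dict(init0)
        init0["alpha"] = np.zeros(n_alpha)
    store = {k: np.empty((settings.chains, nret, len(v))) for k, v in labels.items()}
    pw = np.empty((settings.chains, nret, data.n))
    acc_report = {}
    b_mean_accum = np.zeros((data.n, data.qtot))

    for c in range(settings.chains):
        rng = np.random.default_rng([settings.seed, c])
        chain_init = {k: (np.array(v, float) if not isinstance(v, list)
                          else [np.array(x, float) for x in v])
                      for k, v in init0.items()}
        if c > 0:  # overdispersed starts: jitter coefficient blocks
            for k in range(data.K):
                chain_init["beta"][k] = chain_init["beta"][k] + \
                    0.05 * rng.standard_normal(data.p)
            chain_init["gamma"] = chain_init["gamma"] + \
                0.1 * rng.standard_normal(len(chain_init["gamma"]))
            chain_init["alpha"] = chain_init["alpha"] + \
                0.1 * rng.standard_normal(len(chain_init["alpha"]))
        ch = _Chain(data, spec, settings, chain_init, rng)
        j = 0
        for it in range(settings.total_iterations):
            adapting = settings.adaptation and it < settings.burn_in
            ch.sweep(it, adapting)
            if it >= settings.burn_in and (it - settings.burn_in + 1) % settings.thin == 0:
                if j < nret:
                    snap = ch.snapshot()
                    for kname, arr in snap.items():
                        store[kname][c, j] = arr
                    pw[c, j] = ch.pointwise()
                    b_mean_accum += ch.b
                    j += 1
        rates = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in ch.acc.items()}
        acc_report[f"chain_{c}"] = rates
        for blk, r in rates.items():
            if blk in ("gamma", "alpha") and np.isfinite(r) and not (0.05 <= r <= 0.95):
                logger.warning("chain %d: %s acceptance rate %.3f outside [0.05, 0.95]",
                               c, blk, r)

    draws = PosteriorDraws(store, labels, pw, None, acc_report, meta)

    # pointwise loglik at posterior means (plug-in for DIC)
    mean_params = {k: store[k].mean(axis=(0, 1)) for k in store}
    b_mean = b_mean_accum / (settings.chains * nret)
    mean_init = {
        "beta": [mean_params[f"beta_{nm}"] for nm in spec.outcomes],
        "sigma2": [float(mean_params[f"sigma2_{nm}"][0]) for nm in spec.outcomes],
        "D": _tril_to_full(mean_params["D_tril"], data.qtot),
        "b": b_mean,
        "gamma": mean_params["gamma"],
        "alpha": mean_params["alpha"],
        "log_lambda": mean_params["log_lambda"],
    }
    ch = _Chain(data, spec, settings, mean_init, np.random.default_rng(0))
    draws.pointwise_loglik_at_mean = ch.pointwise()
    return draws


def _tril_to_full(tril_vals, q):
    D = np.zeros((q, q))
    D[np.tril_indices(q)] = tril_vals
    D = D + np.tril(D, -1).T
    return D


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_fit(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior means, 95% credible intervals, Rhat and ESS per parameter.

    gamma and alpha rows additionally report the adjusted hazard ratio
    exp(mean) with the exp-transformed interval.  Slope-association rows are
    on the quarterly (3-month) rate scale.
    """
    from .diagnostics import convergence_diagnostics

    flat = draws.flat()
    if not flat:
        raise ValueError("no parameters in draws")
    first = next(iter(flat.values()))
    if first.size <= 1:
        raise ValueError("need more than one retained draw to summarize")
    conv = None
    if first.shape[0] >= 2 and first.shape[1] >= 4:
        conv = convergence_diagnostics(draws)
    rows = []
    for label, arr in flat.items():
        pooled = arr.reshape(-1)
        mean = float(pooled.mean())
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        row = {"parameter": label, "mean": mean, "cri_low": float(lo),
               "cri_high": float(hi)}
        if conv is not None:
            row["rhat"] = conv["rhat"].get(label, np.nan)
            row["ess"] = conv["ess"].get(label, np.nan)
        if label.startswith(("gamma[", "alpha_")):
            row["ahr"] = float(np.exp(mean))
            row["ahr_low"] = float(np.exp(lo))
            row["ahr_high"] = float(np.exp(hi))
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
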