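"""Synthetic hypertensive-cohort generator with known ground truth.

The generator draws from exactly the joint law the model assumes: baseline
covariates as independent categoricals with configurable prevalences,
subject random effects b_i ~ N(0, D), quarterly BP visits whose observed
values are eta(t) + noise (converted to mmHg at the boundary), and event
times whose hazard is the piecewise-constant baseline times
exp(gamma'w + association terms), inverted from a uniform draw with the same
cumulative-hazard evaluator the fitter uses.  Follow-up is the minimum of
the event time, an exponential loss-to-follow-up time, and the
administrative cutoff.

Default parameter values mirror the fitted model tables of the motivating
cohort study (trajectory coefficients and random-effect SDs on the internal
mmHg/10 scale, survival log hazard ratios, covariate prevalences) with the
baseline height calibrated so that roughly 14% of subjects experience the
event over 120 months.

All randomness flows from a single seed through named substreams, so
covariates, random effects, measurement noise, censoring and missingness
are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, scheduled_times
from .joint import AssociationSpec, SubjectHazard
from .lmm import INTERNAL_SCALE, covariate_matrix, DEFAULT_LONG_COVARIATES
from .splines import NaturalCubicSplineBasis

__all__ = ["GeneratorConfig", "CohortTruth", "simulate_cohort",
           "simulate_event_time", "schedule_visits"]

#: Covariate prevalences of the motivating cohort (proportion in the
#: non-reference level).  The fraction aged >= 65 is a config choice.
DEFAULT_PREVALENCES = {
    "age_group": 0.25,
    "sex": 185 / 408,
    "fbs_cat": 127 / 408,
    "bun_cat": 208 / 408,
    "tg_cat": 177 / 408,
    "tc_cat": 144 / 408,
    "hdl_cat": 122 / 408,
    "ldl_cat": 249 / 408,
    "proteinuria": 128 / 408,
    "aki": 109 / 408,
    "dm": 122 / 408,
    "chd": 123 / 408,
    "vd": 109 / 408,
    "fhhtn": 98 / 408,
    "treatment": 270 / 408,
}
DEFAULT_STAGE_PROBS = (53 / 408, 255 / 408, 100 / 408)  # stage1, stage2, crisis

# Trajectory fixed effects on the internal /10 scale, ordered
# [intercept, time1..3, sex, dm, chd, aki, stage2, crisis, two_plus, duration]
DEFAULT_BETA_SBP = (11.99, -0.13, -1.41, -0.37,
                    0.072, 0.17, 0.12, 0.04, 0.16, 0.46, -0.02, -0.13)
DEFAULT_BETA_DBP = (9.19, -0.14, -0.95, -0.37,
                    0.09, 0.45, 0.38, 0.07, 0.15, 0.5, -0.04, -0.08)

DEFAULT_RE_SD_SBP = (0.36, 0.54, 0.89, 0.53)
DEFAULT_RE_SD_DBP = (0.497, 0.37, 0.77, 0.45)
DEFAULT_SIGMA_SBP = 0.62
DEFAULT_SIGMA_DBP = 0.53

# Survival log hazard ratios, ordered as bpjoint.joint.DEFAULT_SURV_COVARIATES
DEFAULT_GAMMA = tuple(np.log([4.64, 0.43, 1.33, 1.06, 3.32, 1.69,
                              3.08, 1.89, 1.16, 2.85, 1.83, 0.78]))

# Association coefficients per structure: per outcome, per active term.
DEFAULT_ALPHA = {
    "none": (),
    "current_value": (np.log(6.25), np.log(4.32)),
    "slope": (np.log(3.75), np.log(5.64)),
    "value_and_slope": (np.log(6.25), np.log(3.75), np.log(4.32), np.log(5.64)),
    "area": (0.02, 0.02),
    "area_and_value": (0.02, np.log(6.25), 0.02, np.log(4.32)),
}

#: Baseline hazard height (per month) calibrated so the default configuration
#: yields ~14% cumulative events over 120 months; see docs/methods.md.
DEFAULT_LAMBDA0 = 1.28e-4


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic data-generating process."""

    n_subjects: int = 408
    visit_interval_m: float = 3.0
    max_followup_m: float = 120.0
    covariate_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    stage_probs: tuple = DEFAULT_STAGE_PROBS
    beta_sbp: tuple = DEFAULT_BETA_SBP
    beta_dbp: tuple = DEFAULT_BETA_DBP
    re_sd_sbp: tuple = DEFAULT_RE_SD_SBP
    re_sd_dbp: tuple = DEFAULT_RE_SD_DBP
    cross_block: np.ndarray | None = None     # optional 4x4 SBP-DBP covariance
    D: np.ndarray | None = None               # explicit 8x8 override
    sigma_eps_sbp: float = DEFAULT_SIGMA_SBP
    sigma_eps_dbp: float = DEFAULT_SIGMA_DBP
    baseline_heights: tuple = (DEFAULT_LAMBDA0,)
    baseline_cutpoints: tuple | None = None   # defaults to (max_followup_m,)
    gamma: tuple = DEFAULT_GAMMA
    surv_covariates: list | None = None       # None = the full default list
    alpha: tuple | None = None                # None = structure default
    association_structure: str = "value_and_slope"
    centering: tuple = (12.0, 9.2)
    censoring_rate: float = 0.008             # exponential LTFU per month
    missing_rate: float = 0.002               # per scheduled BP value
    htn_duration_mean_y: float = 3.0
    htn_duration_max_y: float = 10.0
    quadrature_points: int = 15
    spline_knots: tuple | None = None         # defaults to thirds of follow-up
    seed: int = 0

    def resolved_alpha(self) -> np.ndarray:
        a = self.alpha if self.alpha is not None else DEFAULT_ALPHA[self.association_structure]
        return np.asarray(a, dtype=float)

    def association_spec(self) -> AssociationSpec:
        return AssociationSpec(structure=self.association_structure,
                               centering=self.centering)

    def resolved_D(self) -> np.ndarray:
        if self.D is not None:
            D = np.asarray(self.D, dtype=float)
        else:
            D = np.zeros((8, 8))
            D[:4, :4] = np.diag(np.square(self.re_sd_sbp))
            D[4:, 4:] = np.diag(np.square(self.re_sd_dbp))
            if self.cross_block is not None:
                cb = np.asarray(self.cross_block, dtype=float)
                D[:4, 4:] = cb
                D[4:, :4] = cb.T
        try:
            np.linalg.cholesky(D)
        except np.linalg.LinAlgError as exc:
            raise ValueError("random-effects covariance D is not positive "
                             "definite") from exc
        return D

    def resolved_cutpoints(self) -> np.ndarray:
        if self.baseline_cutpoints is None:
            return np.array([self.max_followup_m], dtype=float)
        return np.asarray(self.baseline_cutpoints, dtype=float)

    def basis(self) -> NaturalCubicSplineBasis:
        if self.spline_knots is not None:
            return NaturalCubicSplineBasis(list(self.spline_knots),
                                           boundary=(0.0, self.max_followup_m))
        m = self.max_followup_m
        return NaturalCubicSplineBasis([m / 3, 2 * m / 3], boundary=(0.0, m))

    def validate(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for k, p in self.covariate_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {k} outside [0, 1]")
        if any(h <= 0 for h in self.baseline_heights):
            raise ValueError("baseline hazard heights must be positive")
        heights = np.asarray(self.baseline_heights)
        if len(heights) != len(self.resolved_cutpoints()):
            raise ValueError("need one baseline height per interval")
        self.resolved_D()


@dataclass
class CohortTruth:
    """Latent quantities behind a simulated cohort."""

    subject_ids: list
    b: np.ndarray                 # (n, 8) random effects [sbp | dbp]
    event_time: np.ndarray        # true event times (inf = never)
    censor_time: np.ndarray
    followup: np.ndarray
    event: np.ndarray
    config: GeneratorConfig

    def to_dict(self):
        def clean(x):
            return [None if not np.isfinite(v) else float(v) for v in x]

        return {
            "subject_ids": [str(s) for s in self.subject_ids],
            "b": self.b.tolist(),
            "event_time": clean(self.event_time),
            "censor_time": clean(self.censor_time),
            "followup": self.followup.tolist(),
            "event": self.event.astype(int).tolist(),
            "association_structure": self.config.association_structure,
            "alpha": self.config.resolved_alpha().tolist(),
            "seed": self.config.seed,
        }


def schedule_visits(followup_m: float, interval_m: float = 3.0) -> np.ndarray:
    """Visit times {0, q, 2q, ...} strictly below followup_m."""
    return scheduled_times(followup_m, interval_m)


def _subject_hazard(w_long, b_i, config: GeneratorConfig, basis,
                    gamma_dot_w: float) -> SubjectHazard:
    return SubjectHazard(
        basis,
        [np.asarray(config.beta_sbp, float), np.asarray(config.beta_dbp, float)],
        [b_i[:4], b_i[4:]],
        w_long, gamma_dot_w, config.resolved_alpha(),
        config.association_spec(), config.resolved_cutpoints(),
        np.log(np.asarray(config.baseline_heights, float)),
        quad_points=config.quadrature_points,
    )


def simulate_event_time(subject_covariates, b_i, config: GeneratorConfig,
                        u: float, basis=None, gamma_dot_w=None) -> float:
    """Invert S(t) = exp(-Lambda(t)) at u; +inf if no event by the horizon.

    ``subject_covariates`` is the longitudinal covariate dummy row; the
    survival linear predictor gamma'w is passed precomputed (0 by default).
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    basis = basis or config.basis()
    gw = 0.0 if gamma_dot_w is None else float(gamma_dot_w)
    haz = _subject_hazard(np.asarray(subject_covariates, float),
                          np.asarray(b_i, float), config, basis, gw)
    target = -np.log(u)
    horizon = config.max_followup_m
    if haz.cumulative(horizon) < target:
        return np.inf
    return brentq(lambda t: haz.cumulative(t) - target, 1e-12, horizon,
                  xtol=1e-10)


def _draw_baseline(config: GeneratorConfig, rng) -> pd.DataFrame:
    from .cohort import BASELINE_LEVELS

    n = config.n_subjects
    cols = {"subject_id": [f"S{i+1:04d}" for i in range(n)]}
    for cov, levels in BASELINE_LEVELS.items():
        if cov == "htn_stage":
            cols[cov] = rng.choice(list(levels), size=n, p=list(config.stage_probs))
        else:
            p = config.covariate_prevalences[cov]
            cols[cov] = np.where(rng.uniform(size=n) < p, levels[1], levels[0])
    dur = rng.exponential(config.htn_duration_mean_y, size=n)
    cols["htn_duration"] = np.round(np.minimum(dur, config.htn_duration_max_y), 2)
    return pd.DataFrame(cols)


def simulate_cohort(config: GeneratorConfig) -> tuple[Cohort, CohortTruth]:
    """Draw a full cohort (visits, baseline, outcomes) plus its latent truth."""
    config.validate()
    from .joint import DEFAULT_SURV_COVARIATES

    rng_cov = np.random.default_rng([config.seed, 11])
    rng_eff = np.random.default_rng([config.seed, 13])
    rng_noise = np.random.default_rng([config.seed, 17])
    rng_cens = np.random.default_rng([config.seed, 19])
    rng_miss = np.random.default_rng([config.seed, 23])
    rng_event = np.random.default_rng([config.seed, 29])

    n = config.n_subjects
    basis = config.basis()
    baseline = _draw_baseline(config, rng_cov)
    if n == 0:
        empty_vis = pd.DataFrame(columns=["subject_id", "time_m", "sbp", "dbp"])
        empty_out = pd.DataFrame(columns=["subject_id", "followup_m", "event"])
        truth = CohortTruth([], np.zeros((0, 8)), np.zeros(0), np.zeros(0),
                            np.zeros(0), np.zeros(0), config)
        return Cohort(empty_vis, baseline, empty_out), truth

    D = config.resolved_D()
    b = rng_eff.multivariate_normal(np.zeros(8), D, size=n,
                                    method="cholesky")

    Wl, _ = covariate_matrix(baseline, DEFAULT_LONG_COVARIATES)
    W_long = Wl.loc[baseline["subject_id"]].to_numpy(float)
    surv_covs = (DEFAULT_SURV_COVARIATES if config.surv_covariates is None
                 else config.surv_covariates)
    gamma = np.asarray(config.gamma, float)
    if len(surv_covs):
        Wg, _ = covariate_matrix(baseline, surv_covs)
        gw_all = Wg.loc[baseline["subject_id"]].to_numpy(float) @ gamma
    else:
        gw_all = np.zeros(n)

    u = rng_event.uniform(size=n)
    event_time = np.array([
        simulate_event_time(W_long[i], b[i], config, u[i], basis=basis,
                            gamma_dot_w=gw_all[i])
        for i in range(n)
    ])
    if config.censoring_rate > 0:
        censor = rng_cens.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    followup = np.minimum(np.minimum(event_time, censor), config.max_followup_m)
    followup = np.round(np.maximum(followup, 1e-3), 3)
    event = (event_time <= np.minimum(censor, config.max_followup_m)).astype(int)

    beta = [np.asarray(config.beta_sbp, float), np.asarray(config.beta_dbp, float)]
    sig = [config.sigma_eps_sbp, config.sigma_eps_dbp]
    rows = []
    sids = baseline["subject_id"].to_numpy()
    for i in range(n):
        times = schedule_visits(followup[i], config.visit_interval_m)
        if len(times) == 0:
            times = np.array([0.0])
            followup[i] = max(followup[i], config.visit_interval_m / 2)
        B = basis.design(times)
        X = np.column_stack([np.ones(len(times)), B,
                             np.tile(W_long[i], (len(times), 1))])
        Z = np.column_stack([np.ones(len(times)), B])
        vals = {}
        eta = {}
        for k, name in enumerate(("sbp", "dbp")):
            bk = b[i, :4] if k == 0 else b[i, 4:]
            eta[name] = X @ beta[k] + Z @ bk
        sbp = eta["sbp"] + sig[0] * rng_noise.standard_normal(len(times))
        dbp = eta["dbp"] + sig[1] * rng_noise.standard_normal(len(times))
        # physiologic constraint: redraw noise where SBP <= DBP, then floor
        # the rare visit whose latent trajectories themselves cross
        for _ in range(50):
            bad = sbp <= dbp
            if not bad.any():
                break
            sbp[bad] = eta["sbp"][bad] + sig[0] * rng_noise.standard_normal(bad.sum())
            dbp[bad] = eta["dbp"][bad] + sig[1] * rng_noise.standard_normal(bad.sum())
        dbp = np.minimum(dbp, sbp - 0.2)
        vals["sbp"] = sbp * INTERNAL_SCALE
        vals["dbp"] = dbp * INTERNAL_SCALE
        if config.missing_rate > 0:
            for name in ("sbp", "dbp"):
                miss = rng_miss.uniform(size=len(times)) < config.missing_rate
                vals[name] = np.where(miss, np.nan, vals[name])
        rows.append(pd.DataFrame({
            "subject_id": sids[i], "time_m": times,
            "sbp": vals["sbp"], "dbp": vals["dbp"],
        }))
    visits = pd.concat(rows, ignore_index=True)
    outcomes = pd.DataFrame({
        "subject_id": sids,
        "followup_m": np.round(followup, 3),
        "event": event,
    })
    truth = CohortTruth(list(sids), b, event_time, censor, followup,
                        event.astype(float), config)
    return Cohort(visits, baseline, outcomes), truth
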