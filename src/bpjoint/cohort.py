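"""Cohort tables: reading, validation, eligibility rules and missing-data handling.

A cohort consists of three delimited-text tables sharing a subject identifier:

* ``visits.csv``    — long format: ``subject_id,time_m,sbp,dbp``; one row per
  scheduled visit, BP in mmHg, time in months since hypertension diagnosis.
* ``baseline.csv``  — one row per subject; categorical covariates as lowercase
  tokens (see :data:`BASELINE_LEVELS`) plus ``htn_duration`` in years.
* ``outcomes.csv``  — one row per subject: ``subject_id,followup_m,event``
  with event 1 = chronic kidney disease, 0 = censored.

Missing BP values are written as empty fields; both empty and ``NA`` are
accepted on input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "ExclusionReport",
    "BASELINE_LEVELS",
    "load_cohort",
    "write_cohort",
    "apply_eligibility",
    "complete_case_filter",
    "impute_predictive",
    "scheduled_times",
]

#: Admissible category levels for every baseline covariate (first = reference).
BASELINE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("18_64", "ge65"),
    "sex": ("female", "male"),
    "fbs_cat": ("normal", "high"),
    "bun_cat": ("normal", "high"),
    "tg_cat": ("normal", "high"),
    "tc_cat": ("normal", "high"),
    "hdl_cat": ("normal", "low"),
    "ldl_cat": ("normal", "high"),
    "proteinuria": ("negative", "positive"),
    "aki": ("no", "yes"),
    "dm": ("no", "yes"),
    "chd": ("no", "yes"),
    "vd": ("no", "yes"),
    "fhhtn": ("no", "yes"),
    "htn_stage": ("stage1", "stage2", "crisis"),
    "treatment": ("single", "two_plus"),
}

VISIT_COLUMNS = ["subject_id", "time_m", "sbp", "dbp"]
OUTCOME_COLUMNS = ["subject_id", "followup_m", "event"]
BASELINE_COLUMNS = ["subject_id"] + list(BASELINE_LEVELS) + ["htn_duration"]

_NA_VALUES = ["", "NA"]


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort tables."""


@dataclass
class Cohort:
    """Linked visit, baseline and outcome tables for one set of subjects."""

    visits: pd.DataFrame
    baseline: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def subject_ids(self) -> list:
        return list(self.outcomes["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.outcomes)

    def visit_counts(self) -> pd.Series:
        return self.visits.groupby("subject_id").size()

    def subset(self, keep_ids) -> "Cohort":
        keep = set(keep_ids)
        return Cohort(
            visits=self.visits[self.visits["subject_id"].isin(keep)].reset_index(drop=True),
            baseline=self.baseline[self.baseline["subject_id"].isin(keep)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["subject_id"].isin(keep)].reset_index(drop=True),
        )

    def copy(self) -> "Cohort":
        return Cohort(self.visits.copy(), self.baseline.copy(), self.outcomes.copy())

    def equals(self, other: "Cohort") -> bool:
        def _norm(df, keys):
            return df.sort_values(keys).reset_index(drop=True)

        a = _norm(self.visits, ["subject_id", "time_m"])
        b = _norm(other.visits, ["subject_id", "time_m"])
        if not np.array_equal(a["subject_id"].to_numpy(), b["subject_id"].to_numpy()):
            return False
        for col in ("time_m", "sbp", "dbp"):
            if not np.allclose(a[col], b[col], rtol=0, atol=1e-9, equal_nan=True):
                return False
        return (
            _norm(self.baseline, ["subject_id"]).round(9).equals(_norm(other.baseline, ["subject_id"]).round(9))
            and np.allclose(
                _norm(self.outcomes, ["subject_id"])[["followup_m", "event"]],
                _norm(other.outcomes, ["subject_id"])[["followup_m", "event"]],
                atol=1e-9,
            )
            and list(_norm(self.outcomes, ["subject_id"])["subject_id"])
            == list(_norm(other.outcomes, ["subject_id"])["subject_id"])
        )


@dataclass
class ExclusionReport:
    """Per-rule accounting of subjects dropped by the eligibility screen."""

    n_input: int
    n_dropped_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.n_dropped_by_rule.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_dropped_by_rule": self.n_dropped_by_rule,
                "n_retained": self.n_retained,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# loading / validation
# ---------------------------------------------------------------------------

def _read(path, required_cols, label):
    try:
        df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortError(f"{label} table {path}: failed to parse ({exc})") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise CohortError(f"{label} table {path}: missing required column(s) {missing}")
    return df


def load_cohort(visits_path, baseline_path, outcomes_path, validate: bool = True) -> Cohort:
    """Read and cross-validate the three cohort tables.

    Raises :class:`CohortError` naming the file and offending subjects on
    duplicate visits, subject-set mismatches between tables, or visits at or
    beyond a subject's recorded follow-up time.
    """
    visits = _read(visits_path, VISIT_COLUMNS, "visits")
    baseline = _read(baseline_path, BASELINE_COLUMNS, "baseline")
    outcomes = _read(outcomes_path, OUTCOME_COLUMNS, "outcomes")
    visits = visits[VISIT_COLUMNS].copy()
    for c in ("time_m", "sbp", "dbp"):
        visits[c] = pd.to_numeric(visits[c], errors="coerce" if c != "time_m" else "raise")
    cohort = Cohort(visits, baseline, outcomes)
    if validate:
        validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: Cohort) -> None:
    v, b, o = cohort.visits, cohort.baseline, cohort.outcomes
    if (v["time_m"] < 0).any():
        bad = v.loc[v["time_m"] < 0, "subject_id"].tolist()
        raise CohortError(f"visits: negative time_m for subjects {bad}")
    both = v["sbp"].notna() & v["dbp"].notna()
    if ((v.loc[both, "sbp"] <= v.loc[both, "dbp"])).any():
        bad = v.loc[both & (v["sbp"] <= v["dbp"]), "subject_id"].tolist()
        raise CohortError(f"visits: sbp <= dbp for subjects {bad}")
    dup = v.duplicated(subset=["subject_id", "time_m"])
    if dup.any():
        pairs = v.loc[dup, ["subject_id", "time_m"]].values.tolist()
        raise CohortError(f"visits: duplicate (subject, time) rows {pairs}")
    dup_b = b["subject_id"].duplicated()
    if dup_b.any():
        raise CohortError(f"baseline: duplicate subjects {b.loc[dup_b, 'subject_id'].tolist()}")
    dup_o = o["subject_id"].duplicated()
    if dup_o.any():
        raise CohortError(f"outcomes: duplicate subjects {o.loc[dup_o, 'subject_id'].tolist()}")

    sets = {
        "visits": set(v["subject_id"]),
        "baseline": set(b["subject_id"]),
        "outcomes": set(o["subject_id"]),
    }
    all_ids = set.union(*sets.values())
    for name, ids in sets.items():
        if ids != all_ids:
            raise CohortError(
                f"subject sets disagree: missing from {name}: {sorted(all_ids - ids)!r}"
            )
    for col, levels in BASELINE_LEVELS.items():
        bad = ~b[col].isin(levels)
        if bad.any():
            raise CohortError(
                f"baseline: column {col} has levels outside {levels}: "
                f"{sorted(b.loc[bad, col].astype(str).unique())}"
            )
    if b["htn_duration"].isna().any() or (b["htn_duration"] < 0).any():
        raise CohortError("baseline: htn_duration must be present and non-negative")
    if (o["followup_m"] <= 0).any():
        bad = o.loc[o["followup_m"] <= 0, "subject_id"].tolist()
        raise CohortError(f"outcomes: followup_m must be positive; subjects {bad}")
    if not o["event"].isin([0, 1]).all():
        raise CohortError("outcomes: event must be 0 or 1")
    fup = o.set_index("subject_id")["followup_m"]
    late = v["time_m"].to_numpy() >= fup.loc[v["subject_id"]].to_numpy()
    if late.any():
        bad = sorted(set(v.loc[late, "subject_id"]))
        raise CohortError(f"visits at or beyond followup_m for subjects {bad}")


def write_cohort(cohort: Cohort, outdir, prefix: str = "") -> dict[str, Path]:
    """Write the three tables as CSV (missing values as empty fields)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": outdir / f"{prefix}visits.csv",
        "baseline": outdir / f"{prefix}baseline.csv",
        "outcomes": outdir / f"{prefix}outcomes.csv",
    }
    cohort.visits.to_csv(paths["visits"], index=False, na_rep="")
    cohort.baseline.to_csv(paths["baseline"], index=False, na_rep="")
    cohort.outcomes.to_csv(paths["outcomes"], index=False, na_rep="")
    return paths


# ---------------------------------------------------------------------------
# eligibility / missing-data rules
# ---------------------------------------------------------------------------

def apply_eligibility(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Apply the study's eligibility rules and report per-rule drop counts.

    Rules, applied in order (a subject is counted under the first rule that
    removes it):

    1. ``missing_enrollment_or_outcome`` — follow-up time absent/non-positive
       or event flag absent.
    2. ``baseline_ckd`` — optional ``baseline_ckd`` column in the baseline
       table equals ``"yes"``.
    3. ``single_measurement`` — fewer than two recorded visits.
    """
    o = cohort.outcomes
    drops: dict[str, int] = {
        "missing_enrollment_or_outcome": 0,
        "baseline_ckd": 0,
        "single_measurement": 0,
    }
    n_input = len(o)
    bad_outcome = o["followup_m"].isna() | (o["followup_m"] <= 0) | o["event"].isna()
    dropped = set(o.loc[bad_outcome, "subject_id"])
    drops["missing_enrollment_or_outcome"] = len(dropped)

    if "baseline_ckd" in cohort.baseline.columns:
        ckd = set(
            cohort.baseline.loc[cohort.baseline["baseline_ckd"] == "yes", "subject_id"]
        )
        new = ckd - dropped
        drops["baseline_ckd"] = len(new)
        dropped |= new

    counts = cohort.visit_counts()
    few = set(counts[counts < 2].index) | (set(o["subject_id"]) - set(counts.index))
    new = few - dropped
    drops["single_measurement"] = len(new)
    dropped |= new

    keep = [s for s in o["subject_id"] if s not in dropped]
    return cohort.subset(keep), ExclusionReport(n_input=n_input, n_dropped_by_rule=drops)


def scheduled_times(followup_m: float, interval_m: float = 3.0) -> np.ndarray:
    """Scheduled visit grid {0, q, 2q, ...} strictly below follow-up."""
    if interval_m <= 0:
        raise ValueError("visit interval must be positive")
    if followup_m <= 0:
        raise ValueError("followup_m must be positive")
    n = int(np.ceil(followup_m / interval_m - 1e-12))
    return np.arange(n) * interval_m


def _has_missing_scheduled(sub_visits: pd.DataFrame, followup: float,
                           interval: float, tol: float) -> bool:
    times = sub_visits["time_m"].to_numpy()
    grid = scheduled_times(followup, interval)
    for g in grid:
        close = np.abs(times - g) <= tol
        if not close.any():
            return True  # unmatched grid point counts as missing
        row = sub_visits.iloc[int(np.argmax(close))]
        if pd.isna(row["sbp"]) or pd.isna(row["dbp"]):
            return True
    return False


def complete_case_filter(cohort: Cohort, interval_m: float = 3.0,
                         tol: float = 0.5) -> tuple[Cohort, int]:
    """Drop subjects with any missing scheduled BP value before follow-up.

    A visit matches grid point ``q*interval`` when ``|time_m - q*interval| <= tol``;
    unmatched grid points before follow-up also count as missing.
    """
    fup = cohort.outcomes.set_index("subject_id")["followup_m"]
    dropped = []
    for sid, sub in cohort.visits.groupby("subject_id"):
        if _has_missing_scheduled(sub, float(fup.loc[sid]), interval_m, tol):
            dropped.append(sid)
    keep = [s for s in cohort.subject_ids if s not in set(dropped)]
    return cohort.subset(keep), len(dropped)


def impute_predictive(cohort: Cohort, lmm_fits: dict, n_imputations: int,
                      seed: int) -> list[Cohort]:
    """Fill missing BP values by draws from the subject-conditional normal.

    ``lmm_fits`` maps outcome name (``"sbp"``/``"dbp"``) to a fitted
    :class:`bpjoint.lmm.LMMFit`.  For each subject the joint normal implied by
    the fitted mixed model, ``y_i ~ N(X_i beta, Z_i D Z_i' + sigma^2 I)``, is
    conditioned on the subject's observed values and the missing entries are
    replaced by draws from that conditional (exact conditional mean when the
    conditional variance is zero).  Values are converted between mmHg and the
    model's internal scale at this boundary.

    Returns ``n_imputations`` completed cohorts; reproducible given ``seed``.
    """
    from .lmm import INTERNAL_SCALE, design_rows_for_times

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_imputations):
        comp = cohort.copy()
        for outcome, fit in lmm_fits.items():
            col = comp.visits[outcome]
            if not col.isna().any():
                continue
            for sid, sub in comp.visits.groupby("subject_id"):
                miss = sub[outcome].isna()
                if not miss.any():
                    continue
                obs = ~miss
                if not obs.any():
                    raise CohortError(
                        f"subject {sid}: no observed {outcome} values to condition on"
                    )
                t = sub["time_m"].to_numpy()
                X, Z = design_rows_for_times(fit, comp.baseline, sid, t)
                mu = X @ fit.beta
                V = Z @ fit.D_hat @ Z.T + fit.sigma2_hat * np.eye(len(t))
                io, im = np.where(obs)[0], np.where(miss)[0]
                y_obs = sub.loc[obs, outcome].to_numpy() / INTERNAL_SCALE
                Voo = V[np.ix_(io, io)]
                Vmo = V[np.ix_(im, io)]
                sol = np.linalg.solve(Voo, y_obs - mu[io])
                cmean = mu[im] + Vmo @ sol
                cvar = (
                    V[np.ix_(im, im)]
                    - Vmo @ np.linalg.solve(Voo, Vmo.T)
                )
                cvar = (cvar + cvar.T) / 2
                w, U = np.linalg.eigh(cvar)
                w = np.clip(w, 0.0, None)
                draw = cmean + U @ (np.sqrt(w) * rng.standard_normal(len(im)))
                comp.visits.loc[sub.index[im], outcome] = draw * INTERNAL_SCALE
        out.append(comp)
    return out
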