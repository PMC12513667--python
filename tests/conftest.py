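"""Shared fixtures: tiny hand-written cohorts and scaled study conditions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bpjoint.cohort import BASELINE_LEVELS, Cohort
from bpjoint.simulate import GeneratorConfig


def make_baseline(subject_ids, **overrides) -> pd.DataFrame:
    """Baseline table with every covariate at its reference level."""
    n = len(subject_ids)
    cols = {"subject_id": list(subject_ids)}
    for cov, levels in BASELINE_LEVELS.items():
        cols[cov] = [overrides.get(cov, levels[0])] * n
    cols["htn_duration"] = [overrides.get("htn_duration", 1.0)] * n
    return pd.DataFrame(cols)


def make_cohort(visits_spec, events_spec, **baseline_overrides) -> Cohort:
    """Cohort from {sid: [(t, sbp, dbp), ...]} and {sid: (followup, event)}."""
    rows = []
    for sid, vs in visits_spec.items():
        for t, sbp, dbp in vs:
            rows.append({"subject_id": sid, "time_m": t, "sbp": sbp, "dbp": dbp})
    visits = pd.DataFrame(rows)
    outcomes = pd.DataFrame(
        [{"subject_id": s, "followup_m": f, "event": e}
         for s, (f, e) in events_spec.items()]
    )
    baseline = make_baseline(list(events_spec), **baseline_overrides)
    return Cohort(visits, baseline, outcomes)


@pytest.fixture
def three_subject_cohort() -> Cohort:
    """Event at 2, censored at 4, event at 6 — the hand product-limit fixture."""
    visits = {
        "A": [(0.0, 150.0, 95.0), (1.0, 148.0, 93.0)],
        "B": [(0.0, 140.0, 90.0), (3.0, 139.0, 88.0)],
        "C": [(0.0, 160.0, 100.0), (3.0, 158.0, 99.0)],
    }
    events = {"A": (2.0, 1), "B": (4.0, 0), "C": (6.0, 1)}
    return make_cohort(visits, events)


# ---------------------------------------------------------------------------
# scaled study conditions shared by the joint-model experiments
# ---------------------------------------------------------------------------

#: The survival submodel's significant predictors, used at desk scale.
SURV_COVS_SCALED = ["age_group", "hdl_cat", "dm", "proteinuria"]
GAMMA_SCALED = tuple(np.log([4.64, 3.32, 3.08, 2.85]))
ALPHA_TRUTH = tuple(np.log([6.25, 3.75, 4.32, 5.64]))

#: Baseline height calibrated so the 4-covariate condition keeps ~14% events.
LAMBDA0_SCALED = 2.0e-4
#: Null condition (alpha = gamma = 0) height for the same event fraction.
LAMBDA0_NULL = 1.9e-3


def scaled_generator(seed: int, **overrides) -> GeneratorConfig:
    base = dict(
        n_subjects=150,
        surv_covariates=SURV_COVS_SCALED,
        gamma=GAMMA_SCALED,
        baseline_heights=(LAMBDA0_SCALED,),
        association_structure="value_and_slope",
        missing_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def scaled_model_spec(structure: str = "value_and_slope"):
    from bpjoint.joint import (AssociationSpec, BaselineHazardSpec,
                               JointModelSpec)
    from bpjoint.lmm import SplineSpec

    return JointModelSpec(
        association=AssociationSpec(structure),
        surv_covariates=SURV_COVS_SCALED,
        baseline_hazard=BaselineHazardSpec(n_intervals=6),
        spline=SplineSpec(knots=(40.0, 80.0), boundary=(0.0, 120.0)),
    )
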