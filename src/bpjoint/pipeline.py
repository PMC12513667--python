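"""Config-driven orchestration: simulate -> describe -> fit-lmm -> fit-joint
-> compare, with a hashed artifact manifest and a reproducibility log.

Every stage writes plain CSV/JSON files so any stage can be inspected or
re-run in isolation; a failed stage leaves a ``FAILED`` marker naming it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, load_cohort, write_cohort
from .joint import (
    AssociationSpec,
    BaselineHazardSpec,
    JointModelSpec,
    MCMCSettings,
    run_mcmc,
    summarize_fit,
    two_stage_init,
)
from .lmm import SplineSpec, fit_outcome_lmm
from .simulate import GeneratorConfig, simulate_cohort
from .survival import km_estimate, person_years_and_incidence

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "describe", "fit_lmm", "fit_joint", "compare")


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and model settings for one pipeline run."""

    outdir: str = "bpjoint_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    generator: dict | None = None          # GeneratorConfig kwargs
    inputs: dict | None = None             # visits/baseline/outcomes paths
    model: dict = field(default_factory=dict)      # JointModelSpec knobs
    mcmc: dict = field(default_factory=dict)       # MCMCSettings kwargs
    compare_structures: tuple = ()                  # extra structures to rank

    def __post_init__(self):
        if (self.generator is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'generator' and 'inputs' must be given"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if v is not None})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_spec(cfg: PipelineConfig) -> JointModelSpec:
    m = dict(cfg.model)
    assoc = AssociationSpec(
        structure=m.pop("association_structure", "value_and_slope"),
        centering=tuple(m.pop("centering", (12.0, 9.2))),
    )
    bh = BaselineHazardSpec(n_intervals=int(m.pop("n_intervals", 12)))
    spl_knots = m.pop("spline_knots", None)
    spl = SplineSpec(knots=tuple(spl_knots) if spl_knots else None,
                     boundary=tuple(m["spline_boundary"]) if m.get("spline_boundary") else None)
    m.pop("spline_boundary", None)
    return JointModelSpec(association=assoc, baseline_hazard=bh, spline=spl, **m)


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Execute the enabled stages in order; return (exit status, manifest)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logpath = outdir / "run.log"
    loglines = [f"bpjoint {__version__} | seed={config.seed}"]
    manifest: dict[str, str] = {}
    artifacts: list[Path] = []

    def log(msg):
        loglines.append(msg)
        logger.info(msg)

    def add(path: Path):
        artifacts.append(path)

    cohort: Cohort | None = None
    current = ""
    try:
        if "simulate" in config.stages:
            current = "simulate"
            t0 = time.perf_counter()
            gen = GeneratorConfig(**{**(config.generator or {}), "seed": config.seed})
            cohort, truth = simulate_cohort(gen)
            paths = write_cohort(cohort, outdir)
            for p in paths.values():
                add(p)
            tp = outdir / "truth.json"
            tp.write_text(json.dumps(truth.to_dict(), indent=1))
            add(tp)
            log(f"simulate: n={cohort.n_subjects} "
                f"events={int(cohort.outcomes['event'].sum())} "
                f"({time.perf_counter()-t0:.1f}s)")
        else:
            current = "load"
            ins = config.inputs or {}
            cohort = load_cohort(ins["visits"], ins["baseline"], ins["outcomes"])
            log(f"load: n={cohort.n_subjects}")

        if "describe" in config.stages:
            current = "describe"
            t0 = time.perf_counter()
            inc = person_years_and_incidence(cohort.outcomes)
            p = outdir / "incidence.json"
            p.write_text(json.dumps(inc.to_dict(), indent=1))
            add(p)
            km = km_estimate(cohort.outcomes)
            p = outdir / "km.csv"
            km.to_frame().to_csv(p, index=False)
            add(p)
            log(f"describe: {inc.n_events} events / {inc.person_years:.1f} PY "
                f"= {inc.rate_per_100py:.2f}/100PY ({time.perf_counter()-t0:.1f}s)")

        lmm_fits = {}
        if "fit_lmm" in config.stages:
            current = "fit_lmm"
            t0 = time.perf_counter()
            for outcome in ("sbp", "dbp"):
                f = fit_outcome_lmm(cohort, outcome=outcome)
                lmm_fits[outcome] = f
                tab = f.summary_frame()
                sds = np.sqrt(np.maximum(np.diag(f.D_hat), 0))
                extra = pd.DataFrame(
                    {"estimate": list(sds) + [np.sqrt(f.sigma2_hat)]},
                    index=[f"sd_random_{c}" for c in
                           ["intercept"] + [f"time{j}" for j in
                                            range(1, len(sds))]] + ["sd_residual"],
                )
                p = outdir / f"lmm_{outcome}.csv"
                pd.concat([tab, extra]).to_csv(p)
                add(p)
            log(f"fit_lmm done ({time.perf_counter()-t0:.1f}s)")

        draws_main = None
        if "fit_joint" in config.stages:
            current = "fit_joint"
            t0 = time.perf_counter()
            spec = _model_spec(config)
            settings = MCMCSettings(**{**config.mcmc, "seed": config.seed})
            draws_main = run_mcmc(cohort, spec, settings)
            summ = summarize_fit(draws_main)
            p = outdir / "joint_summary.csv"
            summ.to_csv(p)
            add(p)
            acc = json.dumps(draws_main.acceptance, indent=1)
            p = outdir / "joint_acceptance.json"
            p.write_text(acc)
            add(p)
            log(f"fit_joint[{spec.association.structure}]: "
                f"{settings.chains}x{settings.total_iterations} "
                f"({time.perf_counter()-t0:.1f}s) acceptance={acc}")

        if "compare" in config.stages and config.compare_structures:
            current = "compare"
            from .diagnostics import compare_models

            t0 = time.perf_counter()
            spec0 = _model_spec(config)
            settings = MCMCSettings(**{**config.mcmc, "seed": config.seed})
            init = two_stage_init(cohort, spec0, settings.quadrature_points)
            fits = {}
            if draws_main is not None:
                fits[spec0.association.structure] = draws_main
            for st in config.compare_structures:
                if st in fits:
                    continue
                cfg_s = PipelineConfig(
                    outdir=config.outdir, seed=config.seed,
                    generator=config.generator, inputs=config.inputs,
                    model={**config.model, "association_structure": st},
                    mcmc=config.mcmc)
                fits[st] = run_mcmc(cohort, _model_spec(cfg_s), settings, init=init)
            table = compare_models(fits)
            p = outdir / "comparison.csv"
            table.to_csv(p, index=False)
            add(p)
            log(f"compare: best={table.iloc[0]['model']} "
                f"({time.perf_counter()-t0:.1f}s)")

        for p in artifacts:
            manifest[str(p.relative_to(outdir))] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logpath.write_text("\n".join(loglines) + "\n")
        return 0, manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={current}\nerror={exc}\n")
        loglines.append(f"FAILED at {current}: {exc}")
        logpath.write_text("\n".join(loglines) + "\n")
        logger.error("pipeline failed at stage %s: %s", current, exc)
        return 1, manifest
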