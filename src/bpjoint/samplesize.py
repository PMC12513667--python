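"""Closed-form sample-size calculators for the two study outcomes.

Longitudinal (repeated-measures difference in means):

    n = 4 (z_{a/2} + z_beta)^2 * sigma^2 (1 + (J-1) rho) / (J delta^2)

Survival (log hazard-ratio test):

    n = 4 (z_{a/2} + z_beta)^2 / (P theta^2)

Both round up (sample sizes are conservative).  By default the z-values are
the two-decimal constants of applied practice (1.96, 0.84), which reproduce
the published 393 (SBP) / 249 (DBP); exact standard-normal quantiles are
available via ``z_mode="exact"`` for auditability.  The survival formula
with its published inputs evaluates to ~374-375 under either convention,
not the printed 373; the calculator reports its own value (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["LongitudinalAssumptions", "SurvivalAssumptions",
           "n_longitudinal", "n_survival", "final_n", "z_values"]


@dataclass
class LongitudinalAssumptions:
    alpha: float = 0.05
    power: float = 0.80
    J: int = 15                 # repeated measurements per subject
    rho: float = 0.5            # within-subject correlation
    delta: float = 0.8          # effect size (Cohen)
    sigma2: float = 15.0348     # outcome variance (internal scale units^2)

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class SurvivalAssumptions:
    alpha: float = 0.05
    power: float = 0.80
    P: float = 0.176            # probability of developing the event
    theta: float = 0.69         # log hazard ratio magnitude

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.P < 1:
            raise ValueError("P must be in (0, 1)")
        if self.theta == 0:
            raise ValueError("theta must be nonzero")


def z_values(alpha: float, power: float, z_mode: str = "rounded"):
    """(z_{alpha/2}, z_beta); rounded = two-decimal applied-practice values."""
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    if z_mode == "rounded":
        return round(za, 2), round(zb, 2)
    if z_mode == "exact":
        return float(za), float(zb)
    raise ValueError(f"unknown z_mode {z_mode!r}")


def n_longitudinal(assumptions: LongitudinalAssumptions,
                   z_mode: str = "rounded", raw: bool = False):
    """Repeated-measures sample size, rounded up to the next integer."""
    a = assumptions
    a.validate()
    za, zb = z_values(a.alpha, a.power, z_mode)
    value = 4 * (za + zb) ** 2 * a.sigma2 * (1 + (a.J - 1) * a.rho) / (a.J * a.delta**2)
    return value if raw else max(1, math.ceil(value - 1e-9))


def n_survival(assumptions: SurvivalAssumptions,
               z_mode: str = "rounded", raw: bool = False):
    """Log hazard-ratio sample size, rounded up to the next integer."""
    a = assumptions
    a.validate()
    za, zb = z_values(a.alpha, a.power, z_mode)
    value = 4 * (za + zb) ** 2 / (a.P * a.theta**2)
    return value if raw else max(1, math.ceil(value - 1e-9))


def final_n(candidate_sizes, contingency_fraction: float = 0.10) -> int:
    """max(candidates) inflated by the contingency fraction, rounded up."""
    sizes = list(candidate_sizes)
    if not sizes:
        raise ValueError("candidate list must be nonempty")
    if contingency_fraction < 0:
        raise ValueError("contingency fraction must be >= 0")
    return math.ceil(max(sizes) * (1 + contingency_fraction) - 1e-9)
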