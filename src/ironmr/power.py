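"""A-priori power for two-sample MR with a binary outcome.

Normal-approximation power for the IVW estimate of the effect of a
standardized exposure on a case-control outcome:

    power = Phi(|ln OR| * sqrt(N * R2 * phi * (1 - phi)) - z_{1-alpha/2})

where N is the outcome GWAS size, phi its case fraction and R2 the
variance in the exposure explained by the instrument set. The inverse
gives the smallest detectable odds ratio at a target power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs (and optionally the result) of an MR power calculation."""

    n: int
    case_fraction: float
    r2_sum: float
    alpha: float = 0.05
    or_alt: float | None = None
    power: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0,1)")
        if self.r2_sum <= 0.0:
            raise ValueError("r2_sum must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")


def _scale(spec: PowerSpec) -> float:
    return math.sqrt(spec.n * spec.r2_sum * spec.case_fraction * (1.0 - spec.case_fraction))


def mr_power(spec: PowerSpec) -> float:
    """Power to detect ``spec.or_alt`` at two-sided level alpha."""
    if spec.or_alt is None or spec.or_alt <= 0:
        raise ValueError("or_alt must be a positive odds ratio")
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(abs(math.log(spec.or_alt)) * _scale(spec) - z_alpha))


def detectable_or(spec: PowerSpec) -> float:
    """Smallest OR >= 1 detectable at ``spec.power`` (inverts mr_power)."""
    if spec.power is None or not (spec.alpha / 2.0 < spec.power < 1.0):
        raise ValueError("power target must lie in (alpha/2, 1)")
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.power)
    return math.exp((z_power + z_alpha) / _scale(spec))
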