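"""Frequency of sex and realized recombination rates in facultatively
sexual populations.

In a population that reproduces clonally except for a fraction f of
generations, mutations accrue every cell division while recombination only
happens in sexual ones. Diversity θ = 2Nₑμ therefore scales with the total
number of generations, but the population recombination rate ρ = 2Nₑrf
scales with the sexual ones, giving

    f  =  (ρ / r) / (θ / μ)        (meioses per mitosis)

from a population ρ and θ plus lab-measured per-meiosis r and per-division
μ. The same scaling converts a population ρ into the realized per-generation
crossover rate r′ = ρ / 2Nₑ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: 1 cM/Mb = 0.01 crossovers per 10^6 bp = 1e-8 crossovers per bp
CM_PER_MB_TO_PER_BP = 1e-8


@dataclass
class SexFrequencyInputs:
    """Scalar inputs to the frequency-of-sex estimator.

    rho: population recombination rate per bp (2Nₑr·f)
    theta: per-bp diversity (2Nₑμ)
    r_cm_mb: lab (per-meiosis) recombination rate in cM/Mb
    mu: mutations per bp per generation
    ne: effective population size (only needed for realized r)
    doublings_per_day: asexual generations per day
    """

    rho: float
    theta: float
    r_cm_mb: float
    mu: float
    ne: float | None = None
    doublings_per_day: float = 2.5

    def __post_init__(self):
        for name in ("rho", "theta", "r_cm_mb", "mu", "doublings_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ne is not None and self.ne <= 0:
            raise ValueError("ne must be positive")


def frequency_of_sex(inputs: SexFrequencyInputs) -> tuple[float, float]:
    """(f, generations per sexual cycle) from ρ, θ, r and μ.

    f = (ρ/r)/(θ/μ) with r converted from cM/Mb to per-bp. Values above 1
    indicate the approximation has broken down and are returned with a
    warning rather than clamped.
    """
    r_bp = inputs.r_cm_mb * CM_PER_MB_TO_PER_BP
    f = (inputs.rho / r_bp) / (inputs.theta / inputs.mu)
    if f > 1:
        warnings.warn(f"estimated f = {f:.3g} > 1; inputs outside the "
                      "domain of the approximation", stacklevel=2)
    return f, 1.0 / f


def realized_r(rho: float, ne: float) -> float:
    """Realized per-generation recombination rate ρ/(2Nₑ), in cM/Mb."""
    if ne <= 0:
        raise ValueError("ne must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    return rho / (2.0 * ne) / CM_PER_MB_TO_PER_BP


def generations_to_days(generations: float, doublings_per_day: float = 2.5) -> float:
    """Calendar days spanned by a number of asexual generations."""
    if doublings_per_day <= 0:
        raise ValueError("doublings_per_day must be positive")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return generations / doublings_per_day
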