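"""Sublethal-damage repair between consecutive hits during a fraction.

During delivery of a dose fraction at rate ``Ddot`` (Gy/s), hits on the
sensitive volume arrive as a Poisson process with rate ``a = Ddot / z_F``
per second, so the interval between consecutive hits is exponential with
density ``a * exp(-a*dt)``.  With first-order repair kinetics (rate
``mu = ln2 / half-time``), the probability that a cell completes repair of
the damage from one hit before the next hit arrives, within a fraction of
duration ``t_f``, is

    P_R = integral_0^{t_f} a e^{-a dt} (1 - e^{-mu dt}) d(dt)
        = mu/(mu + a) - e^{-a t_f} * (1 - a e^{-mu t_f} / (a + mu)).

For clinical dose rates and the ~1 h half-time of sublethal-damage repair
in mammalian cells this probability is small, which is why damage keeps
accumulating over the fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .core import ParameterDomainError

__all__ = [
    "RepairScenario",
    "fraction_hit_count",
    "interval_density",
    "repair_completion_prob",
    "repair_completion_prob_quadrature",
]


@dataclass(frozen=True)
class RepairScenario:
    """One fraction-delivery scenario.

    dose_rate in Gy/s, fraction_dose in Gy, z_f in Gy,
    repair_half_time in s; all strictly positive.
    """

    dose_rate: float
    fraction_dose: float
    z_f: float
    repair_half_time: float

    def __post_init__(self) -> None:
        for name in ("dose_rate", "fraction_dose", "z_f", "repair_half_time"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ParameterDomainError(f"{name} must be positive, got {v}")

    @property
    def fraction_time(self) -> float:
        """Fraction delivery time t_f = fraction dose / dose rate, s."""
        return self.fraction_dose / self.dose_rate

    @property
    def hit_rate(self) -> float:
        """Hit arrival rate a = dose rate / z_F, 1/s."""
        return self.dose_rate / self.z_f

    @property
    def repair_rate(self) -> float:
        """Repair rate constant mu = ln2 / half-time, 1/s."""
        return math.log(2.0) / self.repair_half_time


def fraction_hit_count(scenario: RepairScenario) -> float:
    """Mean number of hits during one fraction, N_f = fraction dose / z_F.

    Independent of the dose rate: rate and delivery time cancel.
    """
    return scenario.fraction_dose / scenario.z_f


def interval_density(dt, a: float):
    """Exponential density a*exp(-a*dt) of the time between two hits."""
    if a <= 0:
        raise ParameterDomainError("hit rate a must be > 0")
    dt = np.asarray(dt, float)
    if np.any(dt < 0):
        raise ParameterDomainError("dt must be >= 0")
    out = a * np.exp(-a * dt)
    return float(out) if out.ndim == 0 else out


def repair_completion_prob(scenario: RepairScenario) -> float:
    """Closed-form probability P_R of completing repair between hits.

    Total-probability integral of the inter-hit interval density against
    the exponential-repair completion probability, over one fraction.
    Lies in [0, 1); increases with the repair rate and fraction time.
    """
    a = scenario.hit_rate
    mu = scenario.repair_rate
    tf = scenario.fraction_time
    return mu / (mu + a) - math.exp(-a * tf) * (
        1.0 - a * math.exp(-mu * tf) / (a + mu)
    )


def repair_completion_prob_quadrature(
    scenario: RepairScenario, rtol: float = 1e-12
) -> float:
    """P_R by adaptive quadrature of the defining integral (cross-check)."""
    a = scenario.hit_rate
    mu = scenario.repair_rate
    tf = scenario.fraction_time
    val, _ = quad(
        lambda dt: a * math.exp(-a * dt) * (1.0 - math.exp(-mu * dt)),
        0.0,
        tf,
        epsrel=rtol,
        epsabs=0.0,
    )
    return val
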