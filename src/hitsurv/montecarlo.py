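"""Stochastic oracles and synthetic-fixture generators.

Every closed form in the package has an independent brute-force
counterpart here: cell survival is simulated hit by hit (Poisson hit
counts, per-hit survival lookup), repair windows by sampling inter-hit
intervals and repair times, and the damage profile of survivors by
conditioning the simulated population on survival.  These simulators are
deliberately naive — their only job is to agree with the analytics within
binomial error.

The module also generates the synthetic datasets the inference tools are
exercised on: noisy survival curves (multiplicative lognormal noise, the
roughly constant relative error of clonogenic assays on a log plot) and
(alpha, beta, LET) record compilations scattered around a given
z_F,max-versus-ln LET trend with optional gross outliers.

All simulators are bit-reproducible: each derives its generator from the
config seed combined with a fixed per-operation salt, so different
operations draw from independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ParameterDomainError, SurvivalModel, survival
from .inference import AlphaBetaRecord, SurvivalCurve
from .repair import RepairScenario

__all__ = [
    "SimulationConfig",
    "MonteCarloEstimate",
    "InsufficientSurvivorsError",
    "simulate_survival",
    "simulate_curve",
    "simulate_alpha_beta_dataset",
    "simulate_repair_window",
    "simulate_hit_fractions",
]

# per-operation salts; combined with the master seed they give each
# simulator its own independent stream
_SALT_SURVIVAL = 101
_SALT_CURVE = 202
_SALT_ALPHABETA = 303
_SALT_REPAIR = 404
_SALT_FRACTIONS = 505


class InsufficientSurvivorsError(RuntimeError):
    """No survivors at this dose; increase n_samples."""


@dataclass(frozen=True)
class SimulationConfig:
    """Sample size, master seed and noise level for the simulators."""

    n_samples: int = 100_000
    seed: int = 0
    noise_sigma: float = 0.0  # lognormal sigma on surviving fraction

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(salt)])


@dataclass(frozen=True)
class MonteCarloEstimate:
    value: float
    se: float
    n: int


def _per_hit_survival(model: SurvivalModel, k: np.ndarray) -> np.ndarray:
    """Probability of surviving k hits, vectorized over cells."""
    if model.mode == "independent_repair":
        return model.s[0] ** k
    s = model.s_full()
    p = np.zeros(k.shape)
    inside = k <= model.order
    p[inside] = s[k[inside]]
    return p


def simulate_survival(
    model: SurvivalModel, dose: float, config: SimulationConfig
) -> MonteCarloEstimate:
    """Brute-force survival: Poisson hits per cell, per-hit survival table.

    Returns the surviving fraction with its binomial standard error.
    """
    if dose < 0:
        raise ParameterDomainError("dose must be >= 0")
    rng = config.rng(_SALT_SURVIVAL)
    n = config.n_samples
    k = rng.poisson(dose / model.z_f, size=n)
    p = _per_hit_survival(model, k)
    alive = rng.random(n) < p
    s_hat = float(alive.mean())
    se = float(np.sqrt(max(s_hat * (1.0 - s_hat), 0.0) / n))
    return MonteCarloEstimate(value=s_hat, se=se, n=n)


def simulate_curve(
    model: SurvivalModel, doses: Sequence[float], config: SimulationConfig
) -> SurvivalCurve:
    """Synthetic survival curve: closed-form S times lognormal noise.

    ``S_obs = S * exp(sigma * eps)``, ``eps ~ N(0,1)`` i.i.d. per point;
    points that would exceed 1 are clipped to 1 (a plating measurement
    cannot exceed full survival).  The per-point sd is recorded as
    ``sigma * S`` (delta method).  Deterministic under a fixed seed.
    """
    rng = config.rng(_SALT_CURVE)
    doses = np.asarray(doses, float)
    s = np.asarray(survival(model, doses), float)
    sigma = config.noise_sigma
    if sigma > 0:
        obs = s * np.exp(sigma * rng.standard_normal(doses.shape))
        obs = np.minimum(obs, 1.0)
        sd = sigma * s
    else:
        obs = s
        sd = None
    return SurvivalCurve(
        doses=doses,
        surviving_fraction=obs,
        sf_sd=sd,
        label=f"synthetic z_F={model.z_f:g} s={model.s}",
    )


def simulate_alpha_beta_dataset(
    coef: Sequence[float],
    let_range: tuple[float, float],
    n_records: int,
    config: SimulationConfig,
    *,
    scatter: float = 0.0,
    outlier_rate: float = 0.0,
    outlier_shift: tuple[float, float] = (1.5, 3.0),
    particle: str = "synthetic",
) -> list[AlphaBetaRecord]:
    """Synthetic (alpha, beta, LET) compilation around a z_F,max trend.

    LET is sampled log-uniformly over ``let_range``; the trend polynomial
    ``coef`` (descending powers of ln LET) gives z_F,max, perturbed by
    Gaussian ``scatter`` (Gy, truncated below at 0.05 Gy to stay
    physical).  Each record's (alpha, beta) is a random split that sits
    exactly on its z_F,max: with ``t ~ U(0,1)``,
    ``alpha = t/z`` and ``beta = (1-t)^2/(2 z^2)``, so that
    ``1/(alpha + sqrt(2 beta)) = z`` identically.  Gross outliers (rate
    ``outlier_rate``) get a one-sided upward shift drawn uniformly from
    ``outlier_shift`` Gy.
    """
    rng = config.rng(_SALT_ALPHABETA)
    coef = np.asarray(coef, float)
    lo, hi = let_range
    if not (0 < lo < hi):
        raise ValueError("let_range must satisfy 0 < lo < hi")
    let = np.exp(rng.uniform(np.log(lo), np.log(hi), n_records))
    x = np.log(let)
    z_trend = np.polyval(coef, x)
    if np.any(z_trend <= 0):
        raise ValueError("trend produces non-positive z_F,max in this LET range")
    z = z_trend + (scatter * rng.standard_normal(n_records) if scatter > 0 else 0.0)
    if outlier_rate > 0:
        mask = rng.random(n_records) < outlier_rate
        z = z + mask * rng.uniform(*outlier_shift, n_records)
    z = np.maximum(z, 0.05)
    t = rng.random(n_records)
    alpha = t / z
    beta = (1.0 - t) ** 2 / (2.0 * z ** 2)
    return [
        AlphaBetaRecord(
            alpha=float(a), beta=float(b), let=float(l), particle=particle
        )
        for a, b, l in zip(alpha, beta, let)
    ]


def simulate_repair_window(
    scenario: RepairScenario, config: SimulationConfig
) -> MonteCarloEstimate:
    """Empirical P_R: sample inter-hit interval and repair time.

    ``dt ~ Exp(a)``, ``t_repair ~ Exp(mu)``; a trial succeeds when the
    next hit falls inside the fraction (``dt <= t_f``) and repair finished
    first (``t_repair <= dt``).
    """
    rng = config.rng(_SALT_REPAIR)
    n = config.n_samples
    dt = rng.exponential(1.0 / scenario.hit_rate, n)
    t_rep = rng.exponential(1.0 / scenario.repair_rate, n)
    ok = (dt <= scenario.fraction_time) & (t_rep <= dt)
    p = float(ok.mean())
    se = float(np.sqrt(max(p * (1.0 - p), 0.0) / n))
    return MonteCarloEstimate(value=p, se=se, n=n)


def simulate_hit_fractions(
    model: SurvivalModel, dose: float, config: SimulationConfig
) -> tuple[np.ndarray, int]:
    """Empirical hit-count histogram among surviving cells.

    Simulates cells exactly as :func:`simulate_survival`, conditions on
    survival and histograms the hit counts over ``k = 0 .. K``.  Returns
    ``(fractions, n_survivors)``; the fractions sum to 1 exactly.
    """
    if model.mode != "truncated":
        raise ParameterDomainError("hit-fraction simulation needs a truncated model")
    rng = config.rng(_SALT_FRACTIONS)
    n = config.n_samples
    k = rng.poisson(dose / model.z_f, size=n)
    p = _per_hit_survival(model, k)
    alive = rng.random(n) < p
    n_surv = int(alive.sum())
    if n_surv == 0:
        raise InsufficientSurvivorsError(
            f"no survivors among {n} cells at {dose} Gy; increase n_samples"
        )
    counts = np.bincount(k[alive], minlength=model.order + 1)
    return counts / n_surv, n_surv
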