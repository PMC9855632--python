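"""Closed-form evaluation of the Poisson hit-statistics cell-survival model.

The model describes clonogenic survival after a dose ``D`` of ionizing
radiation as a mixture over the number of energy-deposition events ("hits")
received by a subcellular sensitive volume (SV).  Hits are Poisson
distributed with mean ``N = D / z_F``, where ``z_F`` (Gy) is the
frequency-mean specific energy — the average energy per unit mass deposited
in the SV by a single event.  A cell that received ``k`` hits survives with
probability ``s_k`` (``s_0 = 1``: zero hits cannot kill), so

    S(D) = exp(-N) * sum_i s_i * N**i / i!

Two parameterizations are supported:

``truncated``
    ``s_k = 0`` for ``k > K``; the series is a polynomial of order ``K``.
    At high dose the slope of ``ln S`` versus dose tends to the constant
    ``1/z_F`` — the survival curve becomes a straight line.
``independent_repair``
    Damage from each hit is repaired independently, ``s_i = s_1**i``; the
    series sums in closed form to ``exp(-(D/z_F) * (1 - s_1))`` — a pure
    exponential with slope ``(1 - s_1)/z_F``.

At low dose the model reduces to the linear-quadratic (LQ) form
``-ln S = alpha*D + beta*D**2`` with ``alpha = (1 - s_1)/z_F`` and
``beta = (s_1**2 - s_2) / (2 z_F**2)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

__all__ = [
    "SurvivalModel",
    "HitDistribution",
    "DamageFractionProfile",
    "InversionResult",
    "ParameterDomainError",
    "hit_mean",
    "hit_pmf",
    "survival",
    "log_survival",
    "survival_ir",
    "lq_alpha",
    "lq_beta",
    "asymptotic_slope",
    "invert_alpha_beta",
    "surviving_fractions",
]

Mode = Literal["truncated", "independent_repair"]


class ParameterDomainError(ValueError):
    """A model or operation parameter is outside its physical domain."""


@dataclass(frozen=True)
class SurvivalModel:
    """Parameters of the hit-statistics survival model.

    Parameters
    ----------
    z_f:
        Frequency-mean specific energy per event, Gy.  Must be positive.
    s:
        Per-hit survival probabilities ``s_1 ... s_K`` (``s_0 = 1`` is
        implicit and never a parameter).  In ``truncated`` mode
        ``s_k = 0`` for ``k > K``; in ``independent_repair`` mode only
        ``s_1`` is used and ``s_i = s_1**i``.
    mode:
        ``"truncated"`` or ``"independent_repair"``.
    require_monotone:
        Optionally enforce ``s_1 >= s_2 >= ...`` (off by default; the
        theory only implies ``s_2 <= s_1**2``).
    """

    z_f: float
    s: tuple[float, ...] = ()
    mode: Mode = "truncated"
    require_monotone: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", tuple(float(v) for v in self.s))
        object.__setattr__(self, "z_f", float(self.z_f))
        if not np.isfinite(self.z_f) or self.z_f <= 0:
            raise ParameterDomainError(f"z_f must be positive, got {self.z_f}")
        for k, v in enumerate(self.s, start=1):
            if not (0.0 <= v <= 1.0):
                raise ParameterDomainError(f"s{k}={v} outside [0, 1]")
        if self.mode not in ("truncated", "independent_repair"):
            raise ParameterDomainError(f"unknown mode {self.mode!r}")
        if self.mode == "independent_repair" and len(self.s) < 1:
            raise ParameterDomainError("independent_repair mode requires s1")
        if len(self.s) >= 2 and self.s[1] > self.s[0] ** 2 + 1e-12:
            # Conditional survival of a second hit cannot exceed s1; fitted
            # parameters may violate this within noise, so warn only.
            warnings.warn(
                f"s2={self.s[1]:.4g} exceeds s1^2={self.s[0] ** 2:.4g}; "
                "the LQ beta of this model is negative",
                stacklevel=2,
            )
        if self.require_monotone and any(
            self.s[i + 1] > self.s[i] for i in range(len(self.s) - 1)
        ):
            raise ParameterDomainError("s_k not non-increasing in k")

    @property
    def order(self) -> int:
        """Highest hit count K with (possibly) nonzero survival."""
        return len(self.s)

    def s_full(self) -> np.ndarray:
        """Survival probabilities ``s_0 .. s_K`` including implicit s_0=1."""
        return np.concatenate([[1.0], np.asarray(self.s, float)])

    def replace(self, **kw) -> "SurvivalModel":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class HitDistribution:
    """Poisson distribution of the number of hits at a given dose."""

    n_mean: float

    def __post_init__(self) -> None:
        if self.n_mean < 0:
            raise ParameterDomainError("mean hit count must be >= 0")

    def pmf(self, k) -> np.ndarray | float:
        return hit_pmf(k, self.n_mean)

    def pmf_array(self, k_max: int) -> np.ndarray:
        """Probabilities for k = 0 .. k_max."""
        return poisson.pmf(np.arange(k_max + 1), self.n_mean)


@dataclass(frozen=True)
class DamageFractionProfile:
    """Composition of the surviving population by number of hits sustained.

    ``fractions[k]`` is the fraction of *surviving* cells that received
    exactly ``k`` hits: ``f_k = s_k h_k / S``.  Cells with ``k >= 1`` carry
    sublethal damage; the profile quantifies how a nominally homogeneous
    population partitions into subsets of differing radiosensitivity.
    """

    dose: float
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, float)
        object.__setattr__(self, "fractions", f)
        if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")


@dataclass(frozen=True)
class InversionResult:
    """(s1, s2) recovered from LQ (alpha, beta) at an assumed z_F.

    ``feasible`` is False when either probability falls outside [0, 1] —
    the signal that the assumed z_F exceeds its upper bound
    ``1/(alpha + sqrt(2 beta))``.
    """

    s1: float
    s2: float
    z_f: float
    feasible: bool


# ---------------------------------------------------------------------------
# hit statistics


def hit_mean(dose, z_f: float):
    """Mean number of energy-deposition events N = D / z_F."""
    if z_f <= 0:
        raise ParameterDomainError(f"z_f must be positive, got {z_f}")
    dose = np.asarray(dose, float)
    if np.any(dose < 0):
        raise ParameterDomainError("dose must be >= 0")
    out = dose / z_f
    return float(out) if out.ndim == 0 else out

def hit_pmf(k, n_mean):
    """Poisson probability of exactly k hits at mean hit count N."""
    k = np.asarray(k)
    if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer):
        raise ParameterDomainError("k must be a nonnegative integer")
    if np.any(np.asarray(n_mean) < 0):
        raise ParameterDomainError("mean hit count must be >= 0")
    out = poisson.pmf(k, n_mean)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# survival

_LOG_DOMAIN_N = 30.0  # above this, sum the series in the log domain


def log_survival(model: SurvivalModel, dose):
    """ln S(D); stable for large mean hit counts.

    For ``N > 30`` the polynomial terms ``s_i N^i / i!`` are summed with a
    log-sum-exp over ``ln s_i + i ln N - ln i!``; naive evaluation of
    ``exp(-N) * N**i`` under/overflows at radiotherapy-relevant doses.
    """
    dose = np.asarray(dose, float)
    scalar = dose.ndim == 0
    dose = np.atleast_1d(dose)
    if np.any(dose < 0):
        raise ParameterDomainError("dose must be >= 0")
    n = dose / model.z_f

    if model.mode == "independent_repair":
        out = -n * (1.0 - model.s[0])
        return float(out[0]) if scalar else out

    s = model.s_full()
    idx = np.nonzero(s > 0)[0]
    out = np.empty_like(n)

    small = n <= _LOG_DOMAIN_N
    if np.any(small):
        ns = n[small]
        # exact polynomial sum; every term is O(1) here
        terms = s[idx][:, None] * ns[None, :] ** idx[:, None] / np.exp(
            gammaln(idx + 1)
        )[:, None]
        out[small] = -ns + np.log(terms.sum(axis=0))
    if np.any(~small):
        nl = n[~small]
        logn = np.log(nl)
        logterms = (
            np.log(s[idx])[:, None]
            + idx[:, None] * logn[None, :]
            - gammaln(idx + 1)[:, None]
        )
        out[~small] = -nl + logsumexp(logterms, axis=0)
    return float(out[0]) if scalar else out


def survival(model: SurvivalModel, dose):
    """Surviving fraction S(D) = exp(-N) * sum_i s_i N^i / i!, s_0 = 1."""
    out = np.exp(log_survival(model, dose))
    return out


def survival_ir(s1: float, z_f: float, dose):
    """Independent-repair closed form S = exp(-(D/z_F)(1 - s1)).

    Equals the full series with ``s_i = s1**i``; the survival curve is a
    pure exponential with slope ``(1 - s1)/z_F``.
    """
    if not (0.0 <= s1 <= 1.0):
        raise ParameterDomainError(f"s1={s1} outside [0, 1]")
    n = hit_mean(dose, z_f)
    out = np.exp(-np.asarray(n) * (1.0 - s1))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# LQ limit and asymptote


def _s1_s2(model: SurvivalModel) -> tuple[float, float]:
    if model.mode == "independent_repair":
        s1 = model.s[0]
        return s1, s1 ** 2
    s1 = model.s[0] if model.order >= 1 else 0.0
    s2 = model.s[1] if model.order >= 2 else 0.0
    return s1, s2


def lq_alpha(model: SurvivalModel) -> float:
    """Low-dose linear coefficient alpha = (1 - s1) / z_F, Gy^-1."""
    s1, _ = _s1_s2(model)
    return (1.0 - s1) / model.z_f


def lq_beta(model: SurvivalModel) -> float:
    """Low-dose quadratic coefficient beta = (s1^2 - s2) / (2 z_F^2), Gy^-2.

    Nonnegative whenever ``s2 <= s1**2`` (conditional survival of a second
    hit cannot exceed that of the first).
    """
    s1, s2 = _s1_s2(model)
    return (s1 ** 2 - s2) / (2.0 * model.z_f ** 2)


def asymptotic_slope(model: SurvivalModel) -> float:
    """High-dose slope of -ln S versus dose: alpha_inf = 1 / z_F, Gy^-1.

    Defined for the truncated model, where one additional hit is lethal
    once accumulated damage saturates.  Rejected for independent repair
    with ``s1 > 0``, whose limiting slope is ``(1 - s1)/z_F`` instead.
    """
    if model.mode == "independent_repair" and model.s[0] > 0:
        raise ParameterDomainError(
            "independent-repair survival is exponential with slope "
            "(1 - s1)/z_F; the 1/z_F asymptote applies to truncated models"
        )
    return 1.0 / model.z_f


def invert_alpha_beta(alpha: float, beta: float, z_f: float) -> InversionResult:
    """Recover (s1, s2) from LQ coefficients at an assumed z_F.

    ``s1 = 1 - alpha z_F`` and ``s2 = s1^2 - 2 beta z_F^2``.  Values
    outside [0, 1] are reported, not clamped: an infeasible pair signals
    that ``z_F`` exceeds its upper bound ``1/(alpha + sqrt(2 beta))``.
    """
    if alpha < 0 or beta < 0:
        raise ParameterDomainError("alpha and beta must be >= 0")
    if z_f <= 0:
        raise ParameterDomainError("z_f must be positive")
    s1 = 1.0 - alpha * z_f
    s2 = s1 ** 2 - 2.0 * beta * z_f ** 2
    feasible = (0.0 <= s1 <= 1.0) and (0.0 <= s2 <= 1.0)
    return InversionResult(s1=s1, s2=s2, z_f=z_f, feasible=feasible)


# ---------------------------------------------------------------------------
# damage composition of the surviving population


def surviving_fractions(model: SurvivalModel, dose: float) -> DamageFractionProfile:
    """Fractions f_k = s_k h_k / S of surviving cells that received k hits.

    Computed as a normalized weight vector over ``k = 0 .. K`` in the log
    domain, so the normalization is exact at any dose.  Only defined for
    the truncated model (the profile has finite support).
    """
    if model.mode != "truncated":
        raise ParameterDomainError(
            "damage-fraction profile requires a truncated model"
        )
    dose = float(dose)
    if dose < 0:
        raise ParameterDomainError("dose must be >= 0")
    n = dose / model.z_f
    s = model.s_full()
    k = np.arange(model.order + 1)
    if n == 0.0:
        f = np.zeros_like(s)
        f[0] = 1.0
        return DamageFractionProfile(dose=dose, fractions=f)
    with np.errstate(divide="ignore"):
        logw = np.where(s > 0, np.log(s) + k * np.log(n) - gammaln(k + 1), -np.inf)
    f = np.exp(logw - logsumexp(logw))
    f /= f.sum()
    return DamageFractionProfile(dose=dose, fractions=f)
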