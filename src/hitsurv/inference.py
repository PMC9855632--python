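"""Estimation of the frequency-mean specific energy z_F from survival data.

Two routes are implemented.

*Bounds from LQ coefficients* ("method 1"): since ``alpha = (1 - s1)/z_F``
with ``s1`` a probability, and ``beta <= (1 - alpha z_F)^2 / (2 z_F^2)``,
any measured (alpha, beta) pair bounds the specific energy from above:
``z_F <= 1/(alpha + sqrt(2 beta)) = z_F,max``.  Applied to published
(alpha, beta, LET) compilations, the bounds follow smooth trends in
``ln LET`` which are fitted here by Huber-robust linear or polynomial
regression with bootstrap confidence bands.

*Asymptotic slope* ("method 2"): at high dose the truncated model's
``ln S`` becomes linear in dose with slope ``-1/z_F``, so z_F follows from
a weighted linear fit over the terminal straight segment of a measured
curve.  The segment itself is detected by growing a right-anchored window
while the running linear fit stays statistically linear.

Full nonlinear fits of the survival model (bounded least squares on
``ln S``, multi-start) and data-driven selection of the model order K
(prune ``s_{K+1}`` consistent with zero) complete the toolkit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import norm

from .core import ParameterDomainError, SurvivalModel, log_survival

__all__ = [
    "SurvivalCurve",
    "AlphaBetaRecord",
    "RegressionResult",
    "ZfPrediction",
    "ZfSlopeEstimate",
    "SegmentConfig",
    "FitOptions",
    "FitResult",
    "PruneResult",
    "InsufficientDataError",
    "ConvergenceError",
    "NotAsymptoticError",
    "zf_upper_bound",
    "regress_zfmax_loglinear",
    "regress_zfmax_polynomial",
    "predict_zfmax",
    "detect_linear_segment",
    "zf_from_slope",
    "fit_survival_model",
    "prune_model_order",
]

HUBER_T = 1.345  # 95% Gaussian efficiency


class InsufficientDataError(ValueError):
    """Too few (or too degenerate) data points for the requested fit."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged; carries the best attempt."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class NotAsymptoticError(ValueError):
    """The fitted segment has a non-negative slope of ln S versus dose."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SurvivalCurve:
    """Measured (or simulated) clonogenic survival curve.

    doses in Gy, strictly increasing; surviving fractions in (0, 1];
    optional per-point standard deviation of the surviving fraction.
    """

    doses: np.ndarray
    surviving_fraction: np.ndarray
    sf_sd: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, float)
        s = np.asarray(self.surviving_fraction, float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "surviving_fraction", s)
        if d.shape != s.shape or d.ndim != 1:
            raise ValueError("doses and surviving fractions must be equal-length 1-d")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("surviving fractions must lie in (0, 1]")
        if self.sf_sd is not None:
            sd = np.asarray(self.sf_sd, float)
            object.__setattr__(self, "sf_sd", sd)
            if sd.shape != d.shape or np.any(sd < 0):
                raise ValueError("sf_sd must be nonnegative and match length")

    def __len__(self) -> int:
        return len(self.doses)

    def log_sf(self) -> np.ndarray:
        return np.log(self.surviving_fraction)

    def log_sf_sd(self) -> np.ndarray | None:
        """First-order sd of ln S: sd(S)/S."""
        if self.sf_sd is None:
            return None
        return self.sf_sd / self.surviving_fraction


@dataclass(frozen=True)
class AlphaBetaRecord:
    """One published LQ (alpha, beta) pair with its radiation-quality LET."""

    alpha: float  # Gy^-1
    beta: float  # Gy^-2
    let: float  # keV/um
    particle: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.let <= 0:
            raise ValueError(f"LET must be > 0, got {self.let}")


@dataclass(frozen=True)
class RegressionResult:
    """Robust regression of z_F,max on ln LET.

    ``coef`` is ``[a, b]`` for the log-linear form ``a*ln(LET) + b`` and
    ``[c_d, ..., c_1, c_0]`` (descending powers of ln LET) for polynomials.
    The 95% band is a nonparametric bootstrap over records on ``band_let``.
    """

    kind: Literal["loglinear", "polynomial"]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loss: str
    let_range: tuple[float, float]
    n_records: int
    band_let: np.ndarray | None = None
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None

    def design_row(self, let) -> np.ndarray:
        x = np.log(np.asarray(let, float))
        degree = len(self.coef) - 1
        return np.vstack([x ** p for p in range(degree, -1, -1)]).T

    def predict(self, let) -> np.ndarray | float:
        out = self.design_row(let) @ self.coef
        return float(out[0]) if np.ndim(let) == 0 else out


@dataclass(frozen=True)
class ZfPrediction:
    """Regression-predicted z_F,max with propagated 1-sd uncertainty."""

    zf_max: float  # Gy
    sd: float  # Gy
    let: float
    extrapolated: bool


@dataclass(frozen=True)
class ZfSlopeEstimate:
    """z_F from the terminal slope of ln S versus dose (method 2)."""

    z_f: float  # Gy
    se: float  # Gy
    slope: float  # Gy^-1 (negative)
    slope_se: float
    segment: tuple[int, int]  # [start, stop) indices into the curve


# ---------------------------------------------------------------------------
# method 1: bounds and regressions


def zf_upper_bound(alpha, beta):
    """Upper bound z_F,max = 1 / (alpha + sqrt(2 beta)), Gy.

    With ``alpha = beta = 0`` the bound is unbounded and ``inf`` is
    returned as the flag.  Vectorized over arrays.
    """
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    if np.any(alpha < 0) or np.any(beta < 0):
        raise ParameterDomainError("alpha and beta must be >= 0")
    denom = alpha + np.sqrt(2.0 * beta)
    with np.errstate(divide="ignore"):
        out = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), np.inf)
    return float(out) if out.ndim == 0 else out


def _records_xy(records: Sequence[AlphaBetaRecord]) -> tuple[np.ndarray, np.ndarray]:
    let = np.array([r.let for r in records], float)
    z = zf_upper_bound(
        np.array([r.alpha for r in records], float),
        np.array([r.beta for r in records], float),
    )
    keep = np.isfinite(z)
    return np.log(let[keep]), np.asarray(z)[keep]


def _rlm_fit(x: np.ndarray, y: np.ndarray, degree: int):
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    X = np.vstack([x ** p for p in range(degree, 0, -1)] + [np.ones_like(x)]).T
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T))
    with warnings.catch_warnings():
        # a perfect (noiseless) fit collapses the robust scale to zero,
        # which statsmodels reports as a convergence warning
        warnings.simplefilter("ignore", ConvergenceWarning)
        return model.fit()


def _bootstrap_band(
    x: np.ndarray,
    y: np.ndarray,
    degree: int,
    grid_x: np.ndarray,
    n_boot: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = len(x)
    Xg = np.vstack([grid_x ** p for p in range(degree, 0, -1)] + [np.ones_like(grid_x)]).T
    preds = np.empty((n_boot, len(grid_x)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        try:
            fit = _rlm_fit(xb, yb, degree)
            preds[b] = Xg @ fit.params
        except Exception:  # singular resample
            preds[b] = np.nan
    lo = np.nanpercentile(preds, 2.5, axis=0)
    hi = np.nanpercentile(preds, 97.5, axis=0)
    return lo, hi


def _regress(
    records: Sequence[AlphaBetaRecord],
    degree: int,
    kind: str,
    n_boot: int,
    seed: int,
    band_points: int,
) -> RegressionResult:
    x, y = _records_xy(records)
    if len(np.unique(x)) < degree + 2:
        raise InsufficientDataError(
            f"need >= {degree + 2} records with distinct LET, have {len(np.unique(x))}"
        )
    fit = _rlm_fit(x, y, degree)
    coef = np.asarray(fit.params)
    cov = np.asarray(fit.bcov_scaled)
    se = np.sqrt(np.diag(cov))
    let_lo, let_hi = float(np.exp(x.min())), float(np.exp(x.max()))
    band_let = band_lo = band_hi = None
    if n_boot > 0:
        band_let = np.geomspace(let_lo, let_hi, band_points)
        band_lo, band_hi = _bootstrap_band(
            x, y, degree, np.log(band_let), n_boot, seed
        )
        # ensure the band encloses the point estimate
        center = np.vstack(
            [np.log(band_let) ** p for p in range(degree, 0, -1)]
            + [np.ones(band_points)]
        ).T @ coef
        band_lo = np.minimum(band_lo, center)
        band_hi = np.maximum(band_hi, center)
    return RegressionResult(
        kind=kind,
        coef=coef,
        se=se,
        cov=cov,
        loss=f"huber(t={HUBER_T})",
        let_range=(let_lo, let_hi),
        n_records=len(records),
        band_let=band_let,
        band_lo=band_lo,
        band_hi=band_hi,
    )


def regress_zfmax_loglinear(
    records: Sequence[AlphaBetaRecord],
    *,
    n_boot: int = 1000,
    seed: int = 0,
    band_points: int = 50,
) -> RegressionResult:
    """Huber-robust fit of z_F,max = a*ln(LET) + b over a record compilation.

    Each record contributes its bound ``1/(alpha + sqrt(2 beta))``;
    unbounded records (alpha = beta = 0) are dropped.  Returns coefficients
    ``[a, b]`` with 1-sd uncertainties and a bootstrap 95% band.
    """
    return _regress(records, 1, "loglinear", n_boot, seed, band_points)


def regress_zfmax_polynomial(
    records: Sequence[AlphaBetaRecord],
    degree: int = 2,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    band_points: int = 50,
) -> RegressionResult:
    """Huber-robust polynomial (default quadratic) fit of z_F,max in ln LET."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    return _regress(records, degree, "polynomial", n_boot, seed, band_points)


def predict_zfmax(result: RegressionResult, let: float) -> ZfPrediction:
    """Evaluate a z_F,max regression at one LET, with 1-sd uncertainty.

    The uncertainty propagates the coefficient covariance through the
    design row; predictions outside the fitted LET range are flagged as
    extrapolations.
    """
    if let <= 0:
        raise ParameterDomainError("LET must be > 0")
    row = result.design_row(let)[0]
    value = float(row @ result.coef)
    sd = float(np.sqrt(row @ result.cov @ row))
    extrapolated = not (result.let_range[0] <= let <= result.let_range[1])
    return ZfPrediction(zf_max=value, sd=sd, let=float(let), extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# method 2: terminal linear segment


@dataclass(frozen=True)
class SegmentConfig:
    """Criterion for the approximately linear terminal segment.

    Anchored at the highest dose, the window grows leftward while the
    residuals of the running linear fit pass a Wald-Wolfowitz runs test at
    ``runs_alpha`` and the slope moves by less than ``slope_tol_se``
    standard errors per added point.
    """

    min_points: int = 3
    runs_alpha: float = 0.05
    slope_tol_se: float = 1.0


def _runs_test_pvalue(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs."""
    signs = np.sign(residuals[np.abs(residuals) > 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0 or n < 3:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mean = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n ** 2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    W = np.ones_like(x) if w is None else w
    X = np.vstack([x, np.ones_like(x)]).T
    fit = sm.WLS(y, X, weights=W).fit()
    return fit  # params[0]=slope, bse[0]=slope se


def detect_linear_segment(
    curve: SurvivalCurve, config: SegmentConfig | None = None
) -> tuple[int, int]:
    """Largest right-anchored index range [start, stop) where ln S is linear.

    Always contains the highest-dose point; the returned window has at
    least ``config.min_points`` points.
    """
    config = config or SegmentConfig()
    n = len(curve)
    if n < max(4, config.min_points):
        raise InsufficientDataError(
            f"need >= {max(4, config.min_points)} points, have {n}"
        )
    x = curve.doses
    y = curve.log_sf()
    sd = curve.log_sf_sd()
    w = None if sd is None else 1.0 / np.maximum(sd, 1e-12) ** 2

    start = n - config.min_points
    prev = _wls_line(x[start:], y[start:], None if w is None else w[start:])
    while start > 0:
        cand = start - 1
        fit = _wls_line(x[cand:], y[cand:], None if w is None else w[cand:])
        resid = y[cand:] - fit.fittedvalues
        slope_shift = abs(fit.params[0] - prev.params[0])
        slope_se = max(float(fit.bse[0]), 1e-300)
        # an essentially perfect fit (exactly linear data) passes outright;
        # otherwise rounding noise in residual signs and a collapsed slope
        # se would spuriously terminate the growth
        perfect = np.max(np.abs(resid)) <= 1e-10 * (1.0 + np.max(np.abs(y[cand:])))
        if not perfect and (
            _runs_test_pvalue(resid) <= config.runs_alpha
            or slope_shift >= config.slope_tol_se * slope_se
        ):
            break
        start = cand
        prev = fit
    return start, n


def zf_from_slope(
    curve: SurvivalCurve, segment: tuple[int, int] | None = None
) -> ZfSlopeEstimate:
    """z_F from the slope of ln S versus dose over a linear segment.

    Weighted least squares (weights from per-point uncertainties when
    present); ``z_F = -1/slope`` with the standard error propagated to
    first order, ``se(z_F) = se(slope)/slope^2``.
    """
    if segment is None:
        segment = detect_linear_segment(curve)
    start, stop = segment
    if stop - start < 2:
        raise InsufficientDataError("segment must contain >= 2 points")
    x = curve.doses[start:stop]
    y = curve.log_sf()[start:stop]
    sd = curve.log_sf_sd()
    w = None if sd is None else 1.0 / np.maximum(sd[start:stop], 1e-12) ** 2
    fit = _wls_line(x, y, w)
    slope = float(fit.params[0])
    slope_se = float(fit.bse[0])
    if slope >= 0:
        raise NotAsymptoticError(
            f"segment slope {slope:.3g} is non-negative; the curve is not "
            "in its high-dose asymptotic regime"
        )
    z_f = -1.0 / slope
    return ZfSlopeEstimate(
        z_f=z_f,
        se=slope_se / slope ** 2,
        slope=slope,
        slope_se=slope_se,
        segment=(start, stop),
    )


# ---------------------------------------------------------------------------
# nonlinear model fitting and order selection


@dataclass(frozen=True)
class FitOptions:
    """Options for the bounded nonlinear least-squares fit on ln S.

    The multi-start grid is the deterministic cross product
    ``z_F in zf_starts`` x ``s_k in s_starts`` (first best wins ties);
    pass explicit ``starts`` to override it.
    """

    zf_starts: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    s_starts: tuple[float, ...] = (0.1, 0.5, 0.9)
    zf_bounds: tuple[float, float] = (1e-3, 1e3)
    starts: tuple[tuple[float, ...], ...] | None = None
    weighted: bool = True


@dataclass(frozen=True)
class FitResult:
    """Best-fit survival model with curvature-based standard errors."""

    model: SurvivalModel
    se: np.ndarray  # se of [z_f, s1..sK]
    order: int
    cost: float  # 0.5 * sum of squared (weighted) residuals
    residuals: np.ndarray
    n_starts: int
    success: bool

    @property
    def zf_se(self) -> float:
        return float(self.se[0])

    def s_se(self, k: int) -> float:
        return float(self.se[k])


@dataclass(frozen=True)
class PruneResult:
    """Model-order selection outcome with per-order fits for diagnostics."""

    selected_order: int
    fits: dict[int, FitResult]
    rule: str = "|s_{K+1}| < 1 se"

    @property
    def selected_fit(self) -> FitResult:
        return self.fits[self.selected_order]


def _fit_residual_fn(curve: SurvivalCurve, order: int, weighted: bool):
    y = curve.log_sf()
    sd = curve.log_sf_sd() if weighted else None
    sigma = np.ones_like(y) if sd is None else np.maximum(sd, 1e-12)

    def resid(p: np.ndarray) -> np.ndarray:
        model = SurvivalModel(z_f=p[0], s=tuple(p[1:]))
        return (log_survival(model, curve.doses) - y) / sigma

    return resid


def fit_survival_model(
    curve: SurvivalCurve, order: int, options: FitOptions | None = None
) -> FitResult:
    """Fit the truncated model (z_F, s_1..s_K) to a curve, K = ``order``.

    Bounded least squares on ln S (z_F > 0, s_k in [0, 1]) from a
    deterministic multi-start grid.  Standard errors come from the local
    curvature (Gauss-Newton covariance scaled by the residual variance).
    """
    options = options or FitOptions()
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(curve) < order + 2:
        raise InsufficientDataError(
            f"need >= {order + 2} points to fit order {order}, have {len(curve)}"
        )
    resid = _fit_residual_fn(curve, order, options.weighted)
    lower = np.array([options.zf_bounds[0]] + [0.0] * order)
    upper = np.array([options.zf_bounds[1]] + [1.0] * order)
    if options.starts is not None:
        starts = [np.asarray(p, float) for p in options.starts]
    else:
        starts = [
            np.array((zf,) + s)
            for zf in options.zf_starts
            for s in itertools.product(options.s_starts, repeat=order)
        ]

    import warnings as _w

    best = None
    for p0 in starts:
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # transient s2 > s1^2 during search
            try:
                sol = least_squares(
                    resid, np.clip(p0, lower, upper), bounds=(lower, upper)
                )
            except Exception:
                continue
        if not (np.all(np.isfinite(sol.x)) and np.isfinite(sol.cost)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    # a start counts as converged if the optimizer says so or the
    # first-order optimality is tiny (degenerate ridges on noiseless data
    # exhaust maxfev at an essentially perfect fit)
    if best is None or not (best.success or best.optimality < 1e-8 or best.cost < 1e-16):
        raise ConvergenceError(
            f"no start converged for order {order}", best=best
        )

    n, p = len(curve), order + 1
    dof = max(n - p, 1)
    s2 = 2.0 * best.cost / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JtJ) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JtJ) * s2
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    import warnings as _warn

    with _warn.catch_warnings():
        _warn.simplefilter("ignore")  # fitted params may sit just past s2<=s1^2
        model = SurvivalModel(z_f=best.x[0], s=tuple(best.x[1:]))
    return FitResult(
        model=model,
        se=se,
        order=order,
        cost=float(best.cost),
        residuals=best.fun,
        n_starts=len(starts),
        success=bool(best.success),
    )


def prune_model_order(
    curve: SurvivalCurve, k_max: int, options: FitOptions | None = None
) -> PruneResult:
    """Select the smallest order K whose next parameter is noise.

    Fits orders 0..k_max and picks the smallest K such that the fitted
    ``s_{K+1}`` at order K+1 is consistent with zero (|estimate| smaller
    than its own standard error).  Falls back to ``k_max`` when every
    added parameter is significant.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits: dict[int, FitResult] = {}
    for k in range(0, k_max + 1):
        try:
            fits[k] = fit_survival_model(curve, k, options)
        except InsufficientDataError:
            break
    selected = max(fits)
    for k in range(0, max(fits)):
        nxt = fits.get(k + 1)
        if nxt is None:
            break
        s_next = nxt.model.s[k]  # s_{K+1} of the order-(K+1) fit
        # the 1e-6 floor covers noiseless data, where the residual variance
        # (hence the se) collapses to zero and the rule would be undecidable
        if abs(s_next) <= max(nxt.s_se(k + 1), 1e-6):
            selected = k
            break
    return PruneResult(selected_order=selected, fits=fits)
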