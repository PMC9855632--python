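"""Sensitive-volume size from microdosimetric quantities.

For a spherical sensitive volume (SV) of radius ``R`` (um) and density
``rho`` (g/cm^3), the frequency-mean specific energy per event relates to
the frequency-mean lineal energy ``y_F`` (keV/um) through

    z_F [Gy] = C * y_F(E, R) / (pi * rho * R**2),   C = 0.1602,

where the constant converts keV per gram-weighted um^3 to Gy
(1 keV = 1.602e-16 J and 1 um^3 at 1 g/cm^3 weighs 1e-15 kg).  Because
``y_F`` varies only weakly with ``R`` (it plateaus above a few tenths of a
micrometer), the right-hand side decreases monotonically in ``R`` and the
equation has a unique root: given a ``z_F`` estimate, the radius follows by
bracketed root finding.  Using the *upper bound* z_F,max yields the *lower
bound* radius R_min.

``y_F`` is supplied by a provider: either a tabulated set of Monte-Carlo or
measured values (interpolated log-linearly in energy/LET, linearly in
radius, with plateau extension beyond the largest tabulated radius), or the
high-energy approximation ``y_F ~ LET``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import ParameterDomainError

__all__ = [
    "UNIT_C",
    "DEFAULT_DENSITY",
    "YfProvider",
    "LetApproximation",
    "MicrodosimetryTable",
    "TableYfProvider",
    "OutOfRangeError",
    "NonMonotoneError",
    "NoSolutionError",
    "yf_lookup",
    "zf_from_radius",
    "solve_radius",
    "radius_from_cross_section",
]

#: Gy per (keV/um) / (g/cm^3 * um^2): 1.602e-16 J/keV / 1e-15 kg/um^3-at-1g/cm3
UNIT_C = 0.1602
DEFAULT_DENSITY = 1.0  # g/cm^3, water-equivalent SV material


class OutOfRangeError(ValueError):
    """Queried key lies outside the tabulated range (no extrapolation)."""


class NonMonotoneError(RuntimeError):
    """Provider violates the monotone-decreasing contract of the solver."""


class NoSolutionError(RuntimeError):
    """No sign change of the radius equation inside the search bracket."""


class YfProvider(Protocol):
    def lookup(self, key: float, radius: float) -> float:
        """y_F in keV/um for a particle key (energy or LET) and SV radius."""
        ...


@dataclass(frozen=True)
class LetApproximation:
    """y_F ~ LET: valid when track length across the SV greatly exceeds the
    SV diameter, so the event energy is LET times the mean chord length.
    Returns the key itself (interpreted as LET) at any radius."""

    def lookup(self, key: float, radius: float) -> float:
        if key <= 0:
            raise ParameterDomainError("LET must be > 0")
        return float(key)


@dataclass(frozen=True)
class MicrodosimetryTable:
    """Tabulated y_F values keyed by particle and energy/LET x SV radius.

    ``data`` columns: ``particle``, ``let_kev_um`` (and/or ``energy_mev``),
    ``radius_um``, ``yf_kev_um``.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data
        need = {"particle", "radius_um", "yf_kev_um"}
        if not need.issubset(df.columns):
            raise ValueError(f"table must have columns {sorted(need)}")
        if "let_kev_um" not in df.columns and "energy_mev" not in df.columns:
            raise ValueError("table needs a let_kev_um or energy_mev column")
        if (df["yf_kev_um"] <= 0).any():
            raise ValueError("y_F values must be positive")

    def provider(self, particle: str, key_column: str = "let_kev_um") -> "TableYfProvider":
        sub = self.data[self.data["particle"] == particle]
        if sub.empty:
            raise KeyError(f"no rows for particle {particle!r}")
        return TableYfProvider.from_frame(sub, key_column)


@dataclass(frozen=True)
class TableYfProvider:
    """Interpolating y_F provider for one particle type.

    Log-linear interpolation along the key axis (energy or LET), linear
    along the radius axis; constant (plateau) extension beyond the largest
    and below the smallest tabulated radius; strict out-of-range error
    along the key axis.
    """

    keys: np.ndarray  # sorted energies or LETs
    radii: tuple[np.ndarray, ...]  # per key, sorted radii
    yf: tuple[np.ndarray, ...]  # per key, y_F at those radii

    @classmethod
    def from_frame(cls, df: pd.DataFrame, key_column: str = "let_kev_um"):
        if key_column not in df.columns:
            raise ValueError(f"missing key column {key_column!r}")
        keys = np.sort(df[key_column].unique().astype(float))
        radii, yf = [], []
        for k in keys:
            sub = df[df[key_column] == k].sort_values("radius_um")
            radii.append(sub["radius_um"].to_numpy(float))
            yf.append(sub["yf_kev_um"].to_numpy(float))
        return cls(keys=keys, radii=tuple(radii), yf=tuple(yf))

    def _at_key_index(self, i: int, radius: float) -> float:
        r, y = self.radii[i], self.yf[i]
        # plateau on both ends; np.interp clamps, which is exactly that
        return float(np.interp(radius, r, y))

    def lookup(self, key: float, radius: float) -> float:
        if radius <= 0:
            raise ParameterDomainError("radius must be > 0")
        k = float(key)
        if k < self.keys[0] or k > self.keys[-1]:
            raise OutOfRangeError(
                f"key {k} outside tabulated range "
                f"[{self.keys[0]}, {self.keys[-1]}]"
            )
        i = int(np.searchsorted(self.keys, k))
        if i < len(self.keys) and self.keys[i] == k:
            return self._at_key_index(i, radius)
        lo, hi = i - 1, i
        y0 = self._at_key_index(lo, radius)
        y1 = self._at_key_index(hi, radius)
        t = (np.log(k) - np.log(self.keys[lo])) / (
            np.log(self.keys[hi]) - np.log(self.keys[lo])
        )
        return float((1.0 - t) * y0 + t * y1)


def yf_lookup(provider: YfProvider, key: float, radius: float) -> float:
    """y_F (keV/um) for a particle key and SV radius, via the provider."""
    return provider.lookup(key, radius)


def zf_from_radius(
    provider: YfProvider,
    key: float,
    radius: float,
    density: float = DEFAULT_DENSITY,
) -> float:
    """z_F (Gy) of a spherical SV: C * y_F / (pi * rho * R^2)."""
    if radius <= 0 or density <= 0:
        raise ParameterDomainError("radius and density must be > 0")
    yf = provider.lookup(key, radius)
    return UNIT_C * yf / (np.pi * density * radius ** 2)


def solve_radius(
    provider: YfProvider,
    key: float,
    z_f: float,
    density: float = DEFAULT_DENSITY,
    bracket: tuple[float, float] = (1e-3, 50.0),
    rtol: float = 1e-6,
    monotone_check_points: int = 64,
) -> float:
    """Radius (um) of the spherical SV whose specific energy equals z_F.

    Solves ``z_F = C*y_F(key, R)/(pi*rho*R^2)`` by bracketed root finding
    after verifying that the right-hand side is monotone decreasing over
    the bracket (which guarantees a unique root when one exists).
    """
    if z_f <= 0:
        raise ParameterDomainError("z_f must be > 0")
    lo, hi = bracket
    grid = np.geomspace(lo, hi, monotone_check_points)
    rhs = np.array([zf_from_radius(provider, key, r, density) for r in grid])
    if np.any(np.diff(rhs) > 1e-12 * rhs[:-1]):
        raise NonMonotoneError(
            "z_F(R) is not monotone decreasing over the bracket; "
            "the radius equation may not have a unique solution"
        )

    def g(r: float) -> float:
        return zf_from_radius(provider, key, r, density) - z_f

    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise NoSolutionError(
            f"no sign change on [{lo}, {hi}] um: z_F(R) spans "
            f"[{rhs[-1]:.3g}, {rhs[0]:.3g}] Gy but z_F={z_f:.3g} Gy"
        )
    return float(brentq(g, lo, hi, rtol=rtol))


def radius_from_cross_section(sigma: float) -> float:
    """Equivalent radius R = sqrt(sigma/pi) of an inactivation cross
    section sigma (um^2)."""
    if sigma < 0:
        raise ParameterDomainError("cross section must be >= 0")
    return float(np.sqrt(sigma / np.pi))
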