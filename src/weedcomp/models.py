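"""Rectangular-hyperbola competition model family.

Pure algebra, no fitting.  Grain yield `Y` (t ha⁻¹) under weed density
`X` (plants m⁻²) follows the Cousens rectangular hyperbola

    Y = Y0 / (1 + beta * X)

where ``Y0`` is the weed-free yield and ``beta`` the per-plant weed
competitiveness.  Under elevated temperature both parameters move with
accumulated thermal time (growing degree days, GDD, °C·days from
transplanting to flowering): the weed-free yield follows a quadratic,

    Y0(GDD) = a + b*GDD + c*GDD²,

and competitiveness a straight line,

    beta(GDD) = l + m*GDD,

giving the five-parameter combined model

    Y = (a + b*GDD + c*GDD²) / (1 + (l + m*GDD) * X).

Units are fixed throughout: yields in t ha⁻¹, densities in plants m⁻²,
thermal time in °C·days.  Functions return the algebraic value — a
quadratic that dips negative at extreme GDD is returned as-is; clamping
to zero is a reporting-layer concern so that least squares never sees a
silent clamp.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = [
    "HyperbolaParams",
    "CombinedParams",
    "hyperbola",
    "quadratic_y0",
    "linear_beta",
    "combined_yield",
    "relative_yield",
    "quadratic_peak",
]

#: denominators smaller than this in magnitude are treated as poles
_POLE_TOL = 1e-12


@dataclass(frozen=True)
class HyperbolaParams:
    """(Y0, beta) of one temperature level, with optional standard errors.

    ``level_key`` identifies the level, conventionally ``(year, regime)``
    or a GDD tag.
    """

    y0: float
    beta: float
    se_y0: float | None = None
    se_beta: float | None = None
    level_key: object | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.y0) or not math.isfinite(self.beta):
            raise DomainError("y0 and beta must be finite")
        if self.y0 < 0:
            raise DomainError(f"weed-free yield must be >= 0, got {self.y0}")
        for name in ("se_y0", "se_beta"):
            se = getattr(self, name)
            if se is not None and (not math.isfinite(se) or se < 0):
                raise DomainError(f"{name} must be a finite non-negative number")


@dataclass(frozen=True)
class CombinedParams:
    """Parameters (a, b, c, l, m) of the combined hyperbolic model.

    a [t ha⁻¹], b [t ha⁻¹ per °C·day], c [t ha⁻¹ per (°C·day)²] shape the
    weed-free yield quadratic; l [per plants m⁻²] and m [per plants m⁻²
    per °C·day] shape the competitiveness line.  A concave yield response
    needs c < 0; c >= 0 is permitted but warned about.
    """

    a: float
    b: float
    c: float
    l: float
    m: float
    se_a: float | None = None
    se_b: float | None = None
    se_c: float | None = None
    se_l: float | None = None
    se_m: float | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "l", "m"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"parameter {name} must be finite")
        if self.c >= 0:
            warnings.warn(
                f"c = {self.c} >= 0: weed-free yield response is not concave in GDD",
                stacklevel=2,
            )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.l, self.m)


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite")
    return arr


def hyperbola(y0: float, beta: float, x):
    """Yield at weed density ``x``: ``y0 / (1 + beta*x)``.

    Scalar or array ``x``.  Raises :class:`DomainError` at the pole
    ``1 + beta*x == 0``.
    """
    _check_finite("y0", y0)
    _check_finite("beta", beta)
    x = _check_finite("x", x)
    denom = 1.0 + beta * x
    if np.any(np.abs(denom) < _POLE_TOL):
        raise DomainError(f"pole: 1 + beta*x vanishes (beta={beta})")
    out = y0 / denom
    return float(out) if out.ndim == 0 else out


def quadratic_y0(a: float, b: float, c: float, gdd):
    """Weed-free yield quadratic ``a + b*gdd + c*gdd**2`` (t ha⁻¹)."""
    for name, v in (("a", a), ("b", b), ("c", c)):
        _check_finite(name, v)
    gdd = _check_finite("gdd", gdd)
    out = a + b * gdd + c * gdd**2
    return float(out) if out.ndim == 0 else out


def linear_beta(l: float, m: float, gdd):
    """Competitiveness line ``l + m*gdd`` (per plants m⁻²)."""
    for name, v in (("l", l), ("m", m)):
        _check_finite(name, v)
    gdd = _check_finite("gdd", gdd)
    out = l + m * gdd
    return float(out) if out.ndim == 0 else out


def combined_yield(params: CombinedParams, gdd, x):
    """Combined model: ``quadratic_y0 / (1 + linear_beta * x)``.

    Exact composition of :func:`quadratic_y0` and :func:`linear_beta`;
    raises :class:`DomainError` at a pole.
    """
    num = quadratic_y0(params.a, params.b, params.c, gdd)
    beta = linear_beta(params.l, params.m, gdd)
    x = _check_finite("x", x)
    denom = 1.0 + np.asarray(beta) * x
    if np.any(np.abs(denom) < _POLE_TOL):
        raise DomainError("pole: 1 + (l + m*gdd)*x vanishes")
    out = np.asarray(num) / denom
    return float(out) if out.ndim == 0 else out


def relative_yield(beta: float, x):
    """Fraction of weed-free yield retained at density ``x``: ``1/(1+beta*x)``.

    Independent of ``y0``; in (0, 1] for ``beta >= 0``, ``x >= 0``.
    Requires ``1 + beta*x > 0``.
    """
    _check_finite("beta", beta)
    x = _check_finite("x", x)
    denom = 1.0 + beta * x
    if np.any(denom <= _POLE_TOL):
        raise DomainError(f"relative yield undefined: 1 + beta*x <= 0 (beta={beta})")
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def quadratic_peak(a: float, b: float, c: float) -> tuple[float, float]:
    """GDD at which the weed-free yield quadratic peaks, and the peak yield.

    Only defined for a concave response (c < 0): returns
    ``(-b/(2c), quadratic_y0(a, b, c, -b/(2c)))``.
    """
    for name, v in (("a", a), ("b", b), ("c", c)):
        _check_finite(name, v)
    if c >= 0:
        raise DomainError(f"no interior maximum: c = {c} >= 0")
    gdd_star = -b / (2.0 * c)
    return gdd_star, quadratic_y0(a, b, c, gdd_star)
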