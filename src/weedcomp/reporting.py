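"""Prediction surfaces, percent-of-weed-free tables and the correlation screen.

This is the reporting layer: negative model yields are displayed as 0
with an explicit flag (the model functions themselves never clamp), and
pole cells are flagged rather than failing the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, UndefinedStatisticError
from .models import CombinedParams, linear_beta, quadratic_y0, relative_yield

__all__ = [
    "PredictionGrid",
    "CorrelationScreen",
    "predict_surface",
    "percent_of_weed_free",
    "correlation_screen",
    "moisture_adjust",
]


@dataclass
class PredictionGrid:
    """Yield and relative-yield matrices over a GDD × density grid.

    ``yields[i, j]`` is the predicted yield at ``gdd_values[i]``,
    ``densities[j]`` (t ha⁻¹, negative model values clamped to 0 and
    flagged in ``clamped``); ``relative`` the fraction of the weed-free
    yield; pole cells are NaN and flagged in ``pole``.
    """

    gdd_values: np.ndarray
    densities: np.ndarray
    yields: np.ndarray
    relative: np.ndarray
    clamped: np.ndarray
    pole: np.ndarray

    def __post_init__(self) -> None:
        expect = (len(self.gdd_values), len(self.densities))
        for name in ("yields", "relative", "clamped", "pole"):
            if getattr(self, name).shape != expect:
                raise ValueError(f"{name} shape does not match grid axes")

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (gdd, density) cell."""
        gg, dd = np.meshgrid(self.gdd_values, self.densities, indexing="ij")
        return pd.DataFrame(
            {
                "gdd": gg.ravel(),
                "density": dd.ravel(),
                "yield_t_ha": self.yields.ravel(),
                "relative": self.relative.ravel(),
                "clamped": self.clamped.ravel(),
                "pole": self.pole.ravel(),
            }
        )


def predict_surface(
    params: CombinedParams, gdd_values, densities
) -> PredictionGrid:
    """Combined-model yield surface over a GDD × density grid."""
    gdd_values = np.atleast_1d(np.asarray(gdd_values, dtype=float))
    densities = np.atleast_1d(np.asarray(densities, dtype=float))
    num = quadratic_y0(params.a, params.b, params.c, gdd_values)[:, None]
    beta = linear_beta(params.l, params.m, gdd_values)[:, None]
    denom = 1.0 + beta * densities[None, :]
    pole = denom <= 1e-12
    safe = np.where(pole, np.nan, denom)
    raw = num / safe
    clamped = raw < 0
    yields = np.where(clamped, 0.0, raw)
    relative = 1.0 / safe
    return PredictionGrid(
        gdd_values=gdd_values,
        densities=densities,
        yields=yields,
        relative=relative,
        clamped=np.where(np.isnan(raw), False, clamped),
        pole=pole,
    )


def percent_of_weed_free(params: CombinedParams, x, gdd):
    """Predicted yield as a percentage of the weed-free yield.

    ``100 / (1 + (l + m*gdd) * x)``; exactly 100 at x = 0.
    """
    beta = np.asarray(linear_beta(params.l, params.m, gdd))
    x = np.asarray(x, dtype=float)
    denom = 1.0 + beta * x
    if np.any(denom <= 1e-12):
        raise DomainError("percent of weed-free undefined: 1 + beta*x <= 0")
    out = 100.0 / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class CorrelationScreen:
    """Pairwise product-moment correlations with significance flags.

    ``r``/``p`` are symmetric matrices (unit/zero diagonal); ``flag``
    holds "*" where P < alpha and "ns" otherwise.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    flag: pd.DataFrame
    alpha: float


def correlation_screen(
    data: pd.DataFrame, variables: list[str] | None = None, alpha: float = 0.05
) -> CorrelationScreen:
    """Pearson correlation screen over the given (or all numeric) columns.

    Significance from the two-sided t-test of each pairwise correlation.
    Raises for fewer than 3 complete rows or any constant variable.
    """
    if variables is None:
        variables = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    sub = data[variables].dropna()
    if len(sub) < 3:
        raise UndefinedStatisticError("correlation screen needs >= 3 complete rows")
    for col in variables:
        if sub[col].nunique() < 2:
            raise UndefinedStatisticError(
                f"correlation undefined for constant variable {col!r}"
            )
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(sub[variables[i]], sub[variables[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    flag = np.where(p < alpha, "*", "ns")
    np.fill_diagonal(flag, "")
    return CorrelationScreen(
        r=pd.DataFrame(r, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
        flag=pd.DataFrame(flag, index=variables, columns=variables),
        alpha=alpha,
    )


def moisture_adjust(fresh_yield, moisture_fraction):
    """Convert a fresh grain yield to the standard 12 % moisture basis.

    ``fresh_yield * (1 - moisture_fraction) / 0.88``.
    """
    m = np.asarray(moisture_fraction, dtype=float)
    if np.any(m < 0) or np.any(m >= 1):
        raise DomainError("moisture fraction must lie in [0, 1)")
    out = np.asarray(fresh_yield, dtype=float) * (1.0 - m) / 0.88
    return float(out) if out.ndim == 0 else out
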