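"""Nonlinear least-squares estimation of the competition model family.

Three nested models are fitted to long-format trial observations
(yield vs weed density across temperature levels):

* per-level: an independent hyperbola ``(Y0_i, beta_i)`` at each
  temperature level — the "full" model of the nested family;
* intermediate: shared quadratic weed-free yield ``a + b*GDD + c*GDD²``
  with level-specific ``beta_i``;
* combined: the five-parameter model with ``beta(GDD) = l + m*GDD``.

Estimators follow the scikit-learn contract (``fit`` / ``predict`` /
``get_params``, fitted attributes with trailing underscores) so they
compose with sklearn model selection; module-level ``fit_*`` functions
are thin wrappers that accept observation DataFrames and return
:class:`FitResult` records.

Numerics: trust-region least squares with analytic Jacobians and
deterministic initial values (Y0 from the mean yield at the lowest
density, beta from the 1/Y-vs-X linearization; the joint fits start
from the two-stage regressions), with a small multi-start fallback.
Standard errors are the conventional asymptotic NLS ones, from the
SVD pseudo-inverse of J'J at the optimum times the residual mean
square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import (
    ConvergenceError,
    DesignError,
    UndefinedStatisticError,
    UnstableFitWarning,
)
from .models import CombinedParams, HyperbolaParams, combined_yield, hyperbola

__all__ = [
    "FitResult",
    "RectangularHyperbola",
    "PerLevelHyperbola",
    "IntermediateHyperbola",
    "CombinedHyperbola",
    "fit_hyperbola",
    "fit_per_level_pooled",
    "fit_intermediate",
    "fit_combined",
    "fit_stage2_quadratic",
    "fit_stage2_linear",
    "pseudo_r2",
    "rms",
    "select_levels",
    "per_level_table",
]

_DENOM_FLOOR = 1e-9  # keeps the optimiser away from the hyperbola pole


# ---------------------------------------------------------------------------
# fit summary record


@dataclass
class FitResult:
    """Summary of one least-squares fit."""

    model_id: str
    params: dict[str, float]
    ses: dict[str, float]
    rss: float
    df_resid: int
    n_params: int
    n_obs: int
    rms: float
    pseudo_r2: float
    converged: bool

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if self.df_resid != self.n_obs - self.n_params or self.df_resid <= 0:
            raise ValueError(
                f"df_resid must equal n_obs - n_params > 0 "
                f"(got {self.df_resid} = {self.n_obs} - {self.n_params}?)"
            )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": dict(self.params),
            "ses": dict(self.ses),
            "rss": self.rss,
            "df_resid": self.df_resid,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "rms": self.rms,
            "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
        }


def pseudo_r2(rss: float, y) -> float:
    """``1 - rss / total SS`` about the mean; may be negative for poor fits."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise UndefinedStatisticError("pseudo-R² needs at least two observations")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedStatisticError("pseudo-R² undefined: zero total variance")
    return 1.0 - rss / tss


def _pseudo_r2_or_nan(rss: float, y) -> float:
    """pseudo_r2, or NaN when the response has no variance (flat data)."""
    try:
        return pseudo_r2(rss, y)
    except UndefinedStatisticError:
        return float("nan")


def rms(rss: float, df_resid: int) -> float:
    """Root residual mean square, ``sqrt(rss / df_resid)`` (t ha⁻¹)."""
    if df_resid <= 0:
        raise UndefinedStatisticError(f"df_resid must be positive, got {df_resid}")
    return float(np.sqrt(rss / df_resid))


# ---------------------------------------------------------------------------
# shared NLS machinery


def _covariance_se(jac: np.ndarray, rss: float, df_resid: int) -> np.ndarray:
    """Asymptotic standard errors from the Jacobian at the optimum."""
    _, s, vt = np.linalg.svd(jac, full_matrices=False)
    threshold = np.finfo(float).eps * max(jac.shape) * (s[0] if s.size else 0.0)
    keep = s > threshold
    s, vt = s[keep], vt[keep]
    s2 = rss / df_resid
    cov = (vt.T / s**2) @ vt * s2
    diag = np.clip(np.diag(cov), 0.0, np.inf)
    return np.sqrt(diag)


def _run_nls(fun, jac, starts, x_scale, tol: float, max_nfev=None):
    """Trust-region least squares with multi-start fallback.

    The deterministic primary start is tried first; further starts run
    only if it fails to converge, and the lowest-cost converged solution
    wins.
    """
    best = None
    for p0 in starts:
        try:
            res = least_squares(
                fun,
                np.asarray(p0, dtype=float),
                jac=jac,
                method="trf",
                x_scale=x_scale,
                ftol=tol,
                xtol=tol,
                gtol=tol,
                max_nfev=max_nfev,
            )
        except Exception:  # singular step from a pathological start: try next
            continue
        if res.success:
            if best is None or not best.success or res.cost < best.cost:
                best = res
            break  # fallback starts are for non-convergence only
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ConvergenceError("all optimizer starts failed")
    if not best.success:
        raise ConvergenceError(
            f"least squares did not converge after {len(list(starts))} starts "
            f"(status {best.status}: {best.message}); widen the multi-start set"
        )
    return best


def _guarded(denom: np.ndarray) -> np.ndarray:
    sign = np.where(denom >= 0, 1.0, -1.0)
    return np.where(np.abs(denom) < _DENOM_FLOOR, sign * _DENOM_FLOOR, denom)


def _hyperbola_inits(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic start plus fallbacks for the 2-parameter hyperbola."""
    xmin = x.min()
    y0_init = float(np.mean(y[x == xmin]))
    if not np.isfinite(y0_init) or y0_init <= 0:
        y0_init = max(float(np.mean(y)), 0.1)
    # linearisation: 1/Y = 1/Y0 + (beta/Y0) X  =>  beta = slope / intercept
    beta_init = 0.01
    pos = y > max(1e-3, 0.02 * y.max(initial=1.0))
    if pos.sum() >= 2 and np.unique(x[pos]).size >= 2:
        inv = 1.0 / y[pos]
        slope, intercept = np.polyfit(x[pos], inv, 1)
        if np.isfinite(slope) and np.isfinite(intercept) and intercept > 0:
            cand = slope / intercept
            if np.isfinite(cand):
                beta_init = float(cand)
    y0_hi = max(float(y.max(initial=0.1)), 0.1)
    starts = [
        (y0_init, beta_init),
        (y0_init, 0.0),
        (y0_hi, 0.01),
        (float(np.mean(y)) if np.mean(y) > 0 else 0.1, 0.05),
        (y0_hi, 0.1),
    ]
    return [np.array(s, dtype=float) for s in starts]


# ---------------------------------------------------------------------------
# estimators


class RectangularHyperbola(RegressorMixin, BaseEstimator):
    """Hyperbolic yield–density regression for a single temperature level.

    Fits ``Y = y0 / (1 + beta * X)`` by least squares.  ``X`` is the
    weed density (single feature), ``y`` the grain yield in t ha⁻¹.

    Attributes after ``fit``: ``y0_``, ``beta_``, ``se_y0_``,
    ``se_beta_``, ``rss_``, ``df_resid_``, ``rms_``, ``pseudo_r2_``,
    ``converged_``, ``n_obs_``, ``result_``.
    """

    def __init__(self, *, n_starts: int = 5, tol: float = 1e-12):
        self.n_starts = n_starts
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if X.shape[1] != 1:
            raise ValueError("X must have a single column: weed density")
        x = X[:, 0]
        if np.unique(x).size < 2:
            raise DesignError("need observations at >= 2 distinct weed densities")

        def resid(p):
            return y - p[0] / _guarded(1.0 + p[1] * x)

        def jac(p):
            d = _guarded(1.0 + p[1] * x)
            return np.column_stack([-1.0 / d, p[0] * x / d**2])

        starts = _hyperbola_inits(x, y)[: max(1, self.n_starts)]
        res = _run_nls(resid, jac, starts, x_scale=[1.0, 0.01], tol=self.tol)

        self.y0_, self.beta_ = (float(v) for v in res.x)
        self.rss_ = float(2.0 * res.cost)
        self.n_obs_ = len(y)
        self.n_params_ = 2
        self.df_resid_ = self.n_obs_ - 2
        se = _covariance_se(res.jac, self.rss_, self.df_resid_)
        self.se_y0_, self.se_beta_ = (float(v) for v in se)
        self.rms_ = rms(self.rss_, self.df_resid_)
        self.pseudo_r2_ = _pseudo_r2_or_nan(self.rss_, y)
        self.converged_ = bool(res.success)
        collapsed = self.y0_ < 1.0  # near-zero-yield level: beta barely identified
        wide_se = self.se_beta_ > abs(self.beta_) and self.se_beta_ > 0.02
        if collapsed or wide_se:
            warnings.warn(
                f"unstable competitiveness estimate: beta = {self.beta_:.4g} "
                f"with SE {self.se_beta_:.4g} at weed-free yield {self.y0_:.3g} t/ha",
                UnstableFitWarning,
                stacklevel=2,
            )
        self.result_ = FitResult(
            model_id="per_level",
            params={"y0": self.y0_, "beta": self.beta_},
            ses={"y0": self.se_y0_, "beta": self.se_beta_},
            rss=self.rss_,
            df_resid=self.df_resid_,
            n_params=2,
            n_obs=self.n_obs_,
            rms=self.rms_,
            pseudo_r2=self.pseudo_r2_,
            converged=self.converged_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return hyperbola(self.y0_, self.beta_, X[:, 0])

    @property
    def hyperbola_params_(self) -> HyperbolaParams:
        check_is_fitted(self)
        return HyperbolaParams(
            y0=max(self.y0_, 0.0),
            beta=self.beta_,
            se_y0=self.se_y0_,
            se_beta=self.se_beta_,
        )


def _resolve_levels(X, levels):
    """Level key per row; defaults to the GDD value itself."""
    gdd = X[:, 0]
    if levels is None:
        keys = pd.Series(gdd).astype(float)
    else:
        keys = pd.Series(list(levels))
        if len(keys) != len(gdd):
            raise ValueError("levels must have one entry per observation")
    codes, uniques = pd.factorize(keys, use_na_sentinel=False)
    return codes, list(uniques)


class PerLevelHyperbola(RegressorMixin, BaseEstimator):
    """Independent hyperbola per temperature level — the full model.

    ``X`` has two columns, (GDD to flowering, weed density); rows with
    the same level key (by default, the same GDD value; override with
    ``fit(..., levels=...)``) share one ``(y0_i, beta_i)`` pair.  The
    pooled RSS is the sum of the level RSS and the parameter count is
    twice the number of levels.
    """

    def __init__(self, *, n_starts: int = 5, tol: float = 1e-12):
        self.n_starts = n_starts
        self.tol = tol

    def fit(self, X, y, levels=None):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (gdd, density)")
        codes, uniques = _resolve_levels(X, levels)
        records = []
        rss = 0.0
        converged = True
        for code, key in enumerate(uniques):
            mask = codes == code
            est = RectangularHyperbola(n_starts=self.n_starts, tol=self.tol)
            est.fit(X[mask, 1:2], y[mask])
            rss += est.rss_
            converged = converged and est.converged_
            records.append(
                {
                    "level": key,
                    "gdd": float(np.median(X[mask, 0])),
                    "y0": est.y0_,
                    "beta": est.beta_,
                    "se_y0": est.se_y0_,
                    "se_beta": est.se_beta_,
                    "rss": est.rss_,
                    "n_obs": est.n_obs_,
                    "df_resid": est.df_resid_,
                    "rms": est.rms_,
                    "pseudo_r2": est.pseudo_r2_,
                }
            )
        self.params_ = pd.DataFrame.from_records(records).set_index("level")
        self.levels_ = list(uniques)
        self.rss_ = float(rss)
        self.n_obs_ = len(y)
        self.n_params_ = 2 * len(uniques)
        self.df_resid_ = self.n_obs_ - self.n_params_
        if self.df_resid_ <= 0:
            raise DesignError("no residual degrees of freedom in pooled fit")
        self.rms_ = rms(self.rss_, self.df_resid_)
        self.pseudo_r2_ = _pseudo_r2_or_nan(self.rss_, y)
        self.converged_ = converged
        params = {}
        ses = {}
        for rec in records:
            tag = str(rec["level"])
            params[f"y0[{tag}]"] = rec["y0"]
            params[f"beta[{tag}]"] = rec["beta"]
            ses[f"y0[{tag}]"] = rec["se_y0"]
            ses[f"beta[{tag}]"] = rec["se_beta"]
        self.result_ = FitResult(
            model_id="per_level",
            params=params,
            ses=ses,
            rss=self.rss_,
            df_resid=self.df_resid_,
            n_params=self.n_params_,
            n_obs=self.n_obs_,
            rms=self.rms_,
            pseudo_r2=self.pseudo_r2_,
            converged=self.converged_,
        )
        return self

    def predict(self, X, levels=None):
        check_is_fitted(self)
        X = check_array(X)
        codes, uniques = _resolve_levels(X, levels)
        lookup = {key: i for i, key in enumerate(self.levels_)}
        out = np.empty(len(X))
        for code, key in enumerate(uniques):
            if key not in lookup:
                raise KeyError(f"level {key!r} was not seen during fit")
            row = self.params_.iloc[lookup[key]]
            mask = codes == code
            out[mask] = hyperbola(row["y0"], row["beta"], X[mask, 1])
        return out


class _JointHyperbolaBase(RegressorMixin, BaseEstimator):
    """Shared machinery for the intermediate and combined joint fits."""

    def __init__(self, *, n_starts: int = 5, tol: float = 1e-12):
        self.n_starts = n_starts
        self.tol = tol

    def _per_level_inits(self, X, y, levels):
        """Stage-wise initial values from per-level fits; None on failure."""
        try:
            per = PerLevelHyperbola(n_starts=self.n_starts, tol=1e-10)
            per.fit(X, y, levels=levels)
            tab = per.params_
            quad = fit_stage2_quadratic(tab["gdd"], tab["y0"])
            lin = fit_stage2_linear(tab["gdd"], tab["beta"])
            return tab, quad, lin
        except Exception:
            return None, None, None

    @staticmethod
    def _generic_quad_init(X, y):
        gdd = X[:, 0]
        coef = np.polyfit(gdd, y, 2)  # crude: quadratic through all yields
        return float(coef[2]), float(coef[1]), float(coef[0])


class IntermediateHyperbola(_JointHyperbolaBase):
    """Quadratic weed-free yield with level-specific competitiveness.

    Parameters: shared (a, b, c) plus one ``beta_i`` per level, jointly
    estimated; ``n_params = 3 + #levels``.
    """

    def fit(self, X, y, levels=None):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (gdd, density)")
        codes, uniques = _resolve_levels(X, levels)
        k = len(uniques)
        if k < 4:
            raise DesignError(f"intermediate model needs >= 4 levels, got {k}")
        level_gdd = np.array(
            [np.median(X[codes == c, 0]) for c in range(k)], dtype=float
        )
        if np.unique(level_gdd).size < 3:
            raise DesignError(
                "intermediate model needs >= 3 distinct level GDDs "
                "(quadratic is rank deficient otherwise)"
            )
        g, x = X[:, 0], X[:, 1]

        def unpack(p):
            return p[0], p[1], p[2], p[3:]

        def resid(p):
            a, b, c, betas = unpack(p)
            d = _guarded(1.0 + betas[codes] * x)
            return y - (a + b * g + c * g**2) / d

        def jac(p):
            a, b, c, betas = unpack(p)
            num = a + b * g + c * g**2
            d = _guarded(1.0 + betas[codes] * x)
            J = np.zeros((len(y), 3 + k))
            J[:, 0] = -1.0 / d
            J[:, 1] = -g / d
            J[:, 2] = -(g**2) / d
            vals = num * x / d**2
            J[np.arange(len(y)), 3 + codes] = vals
            return J

        tab, quad, lin = self._per_level_inits(X, y, levels)
        starts = []
        if quad is not None:
            abc = [quad.params["a"], quad.params["b"], quad.params["c"]]
            starts.append(np.concatenate([abc, tab["beta"].to_numpy()]))
        a0, b0, c0 = self._generic_quad_init(X, y)
        starts.append(np.concatenate([[a0, b0, c0], np.full(k, 0.01)]))
        starts.append(np.concatenate([[np.mean(y), 0.0, 0.0], np.full(k, 0.005)]))
        starts = starts[: max(1, self.n_starts)]

        x_scale = np.concatenate([[10.0, 1e-2, 1e-5], np.full(k, 1e-2)])
        res = _run_nls(resid, jac, starts, x_scale=x_scale, tol=self.tol)

        self.a_, self.b_, self.c_ = (float(v) for v in res.x[:3])
        self.betas_ = pd.Series(res.x[3:], index=uniques, name="beta")
        self.levels_ = list(uniques)
        self.level_gdd_ = pd.Series(level_gdd, index=uniques, name="gdd")
        self.rss_ = float(2.0 * res.cost)
        self.n_obs_ = len(y)
        self.n_params_ = 3 + k
        self.df_resid_ = self.n_obs_ - self.n_params_
        if self.df_resid_ <= 0:
            raise DesignError("no residual degrees of freedom")
        se = _covariance_se(res.jac, self.rss_, self.df_resid_)
        self.se_a_, self.se_b_, self.se_c_ = (float(v) for v in se[:3])
        self.se_betas_ = pd.Series(se[3:], index=uniques, name="se_beta")
        self.rms_ = rms(self.rss_, self.df_resid_)
        self.pseudo_r2_ = _pseudo_r2_or_nan(self.rss_, y)
        self.converged_ = bool(res.success)
        params = {"a": self.a_, "b": self.b_, "c": self.c_}
        ses = {"a": self.se_a_, "b": self.se_b_, "c": self.se_c_}
        for key in uniques:
            params[f"beta[{key}]"] = float(self.betas_[key])
            ses[f"beta[{key}]"] = float(self.se_betas_[key])
        self.result_ = FitResult(
            model_id="intermediate",
            params=params,
            ses=ses,
            rss=self.rss_,
            df_resid=self.df_resid_,
            n_params=self.n_params_,
            n_obs=self.n_obs_,
            rms=self.rms_,
            pseudo_r2=self.pseudo_r2_,
            converged=self.converged_,
        )
        return self

    def predict(self, X, levels=None):
        check_is_fitted(self)
        X = check_array(X)
        codes, uniques = _resolve_levels(X, levels)
        lookup = {key: i for i, key in enumerate(self.levels_)}
        betas = np.empty(len(X))
        for code, key in enumerate(uniques):
            if key not in lookup:
                raise KeyError(f"level {key!r} was not seen during fit")
            betas[codes == code] = self.betas_.iloc[lookup[key]]
        g, x = X[:, 0], X[:, 1]
        return (self.a_ + self.b_ * g + self.c_ * g**2) / (1.0 + betas * x)


class CombinedHyperbola(_JointHyperbolaBase):
    """Five-parameter combined model: quadratic Y0(GDD), linear beta(GDD).

    ``X`` has two columns, (GDD to flowering, weed density).  After
    ``fit``: ``a_``..``m_`` with ``se_*_``, ``params_``
    (:class:`~weedcomp.models.CombinedParams`), ``result_``.
    """

    def fit(self, X, y, levels=None):
        X, y = check_X_y(X, y, ensure_min_samples=6)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (gdd, density)")
        g, x = X[:, 0], X[:, 1]
        if np.unique(g).size < 3:
            raise DesignError("combined model needs >= 3 distinct GDD values")

        def resid(p):
            a, b, c, l, m = p
            d = _guarded(1.0 + (l + m * g) * x)
            return y - (a + b * g + c * g**2) / d

        def jac(p):
            a, b, c, l, m = p
            num = a + b * g + c * g**2
            d = _guarded(1.0 + (l + m * g) * x)
            return np.column_stack(
                [
                    -1.0 / d,
                    -g / d,
                    -(g**2) / d,
                    num * x / d**2,
                    num * g * x / d**2,
                ]
            )

        _, quad, lin = self._per_level_inits(X, y, levels)
        starts = []
        if quad is not None and lin is not None:
            starts.append(
                [
                    quad.params["a"],
                    quad.params["b"],
                    quad.params["c"],
                    lin.params["l"],
                    lin.params["m"],
                ]
            )
        a0, b0, c0 = self._generic_quad_init(X, y)
        starts.append([a0, b0, c0, 0.005, 0.0])
        starts.append([a0, b0, c0, -0.02, 2e-5])
        starts.append([np.mean(y), 0.0, 0.0, 0.01, 0.0])
        starts = starts[: max(1, self.n_starts)]

        x_scale = [10.0, 1e-2, 1e-5, 1e-2, 1e-5]
        res = _run_nls(resid, jac, starts, x_scale=x_scale, tol=self.tol)

        self.a_, self.b_, self.c_, self.l_, self.m_ = (float(v) for v in res.x)
        self.rss_ = float(2.0 * res.cost)
        self.n_obs_ = len(y)
        self.n_params_ = 5
        self.df_resid_ = self.n_obs_ - 5
        se = _covariance_se(res.jac, self.rss_, self.df_resid_)
        self.se_a_, self.se_b_, self.se_c_, self.se_l_, self.se_m_ = (
            float(v) for v in se
        )
        self.rms_ = rms(self.rss_, self.df_resid_)
        self.pseudo_r2_ = _pseudo_r2_or_nan(self.rss_, y)
        self.converged_ = bool(res.success)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # c >= 0 concavity warning
            self.params_ = CombinedParams(
                a=self.a_,
                b=self.b_,
                c=self.c_,
                l=self.l_,
                m=self.m_,
                se_a=self.se_a_,
                se_b=self.se_b_,
                se_c=self.se_c_,
                se_l=self.se_l_,
                se_m=self.se_m_,
            )
        self.result_ = FitResult(
            model_id="combined",
            params={
                "a": self.a_,
                "b": self.b_,
                "c": self.c_,
                "l": self.l_,
                "m": self.m_,
            },
            ses={
                "a": self.se_a_,
                "b": self.se_b_,
                "c": self.se_c_,
                "l": self.se_l_,
                "m": self.se_m_,
            },
            rss=self.rss_,
            df_resid=self.df_resid_,
            n_params=5,
            n_obs=self.n_obs_,
            rms=self.rms_,
            pseudo_r2=self.pseudo_r2_,
            converged=self.converged_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return combined_yield(self.params_, X[:, 0], X[:, 1])


# ---------------------------------------------------------------------------
# stage-2 regressions (OLS of the per-level estimates on GDD)


def fit_stage2_quadratic(gdd, y0_values) -> FitResult:
    """OLS of the per-level weed-free yields on (1, GDD, GDD²)."""
    gdd = np.asarray(gdd, dtype=float)
    y0_values = np.asarray(y0_values, dtype=float)
    if gdd.size < 4:
        raise DesignError("stage-2 quadratic needs >= 4 (GDD, Y0) pairs")
    design = sm.add_constant(np.column_stack([gdd, gdd**2]))
    fit = sm.OLS(y0_values, design).fit()
    a, b, c = (float(v) for v in fit.params)
    sea, seb, sec = (float(v) for v in fit.bse)
    rss = float(fit.ssr)
    return FitResult(
        model_id="quadratic_stage2",
        params={"a": a, "b": b, "c": c},
        ses={"a": sea, "b": seb, "c": sec},
        rss=rss,
        df_resid=int(fit.df_resid),
        n_params=3,
        n_obs=int(fit.nobs),
        rms=rms(rss, int(fit.df_resid)),
        pseudo_r2=pseudo_r2(rss, y0_values),
        converged=True,
    )


def fit_stage2_linear(gdd, beta_values) -> FitResult:
    """OLS of the per-level competitiveness estimates on (1, GDD)."""
    gdd = np.asarray(gdd, dtype=float)
    beta_values = np.asarray(beta_values, dtype=float)
    if gdd.size < 3:
        raise DesignError("stage-2 linear needs >= 3 (GDD, beta) pairs")
    design = sm.add_constant(gdd)
    fit = sm.OLS(beta_values, design).fit()
    l, m = (float(v) for v in fit.params)
    sel, sem = (float(v) for v in fit.bse)
    rss = float(fit.ssr)
    return FitResult(
        model_id="linear_stage2",
        params={"l": l, "m": m},
        ses={"l": sel, "m": sem},
        rss=rss,
        df_resid=int(fit.df_resid),
        n_params=2,
        n_obs=int(fit.nobs),
        rms=rms(rss, int(fit.df_resid)),
        pseudo_r2=pseudo_r2(rss, beta_values),
        converged=True,
    )


# ---------------------------------------------------------------------------
# DataFrame-facing wrappers

OBS_COLUMNS = ("year", "regime", "gdd_flowering", "species", "density", "replicate", "yield_t_ha")


def _single_species(obs: pd.DataFrame) -> pd.DataFrame:
    if "species" in obs.columns and obs["species"].nunique() > 1:
        raise DesignError(
            "observations mix weed species; filter to one species before fitting"
        )
    return obs


def _obs_arrays(obs: pd.DataFrame):
    X = obs[["gdd_flowering", "density"]].to_numpy(dtype=float)
    y = obs["yield_t_ha"].to_numpy(dtype=float)
    levels = list(zip(obs["year"].tolist(), obs["regime"].tolist()))
    return X, y, levels


def select_levels(obs: pd.DataFrame, min_weed_free_yield: float = 1.0) -> pd.DataFrame:
    """Drop levels whose mean yield at the lowest density falls below threshold.

    A temperature level whose weed-free yield has collapsed (heat-sterile
    year) carries no information about competitiveness and destabilises
    the pooled fits; the default 1.0 t ha⁻¹ threshold removes such levels.
    """
    def keep(group: pd.DataFrame) -> bool:
        dmin = group["density"].min()
        return group.loc[group["density"] == dmin, "yield_t_ha"].mean() >= min_weed_free_yield

    mask = obs.groupby(["year", "regime"], sort=False).apply(keep, include_groups=False)
    kept = mask[mask].index
    idx = pd.MultiIndex.from_frame(obs[["year", "regime"]])
    return obs[idx.isin(kept)].copy()


def fit_hyperbola(obs: pd.DataFrame, **est_kwargs) -> FitResult:
    """Hyperbola fit for one temperature level (columns density, yield_t_ha)."""
    obs = _single_species(obs)
    est = RectangularHyperbola(**est_kwargs)
    est.fit(obs[["density"]].to_numpy(dtype=float), obs["yield_t_ha"].to_numpy(dtype=float))
    return est.result_


def fit_per_level_pooled(
    obs: pd.DataFrame, min_weed_free_yield: float = 1.0, **est_kwargs
) -> FitResult:
    """Pooled per-level fit over all included temperature levels."""
    obs = select_levels(_single_species(obs), min_weed_free_yield)
    X, y, levels = _obs_arrays(obs)
    est = PerLevelHyperbola(**est_kwargs)
    est.fit(X, y, levels=levels)
    return est.result_


def fit_intermediate(
    obs: pd.DataFrame, min_weed_free_yield: float = 1.0, **est_kwargs
) -> FitResult:
    """Joint fit of the intermediate model (shared quadratic, per-level beta)."""
    obs = select_levels(_single_species(obs), min_weed_free_yield)
    X, y, levels = _obs_arrays(obs)
    est = IntermediateHyperbola(**est_kwargs)
    est.fit(X, y, levels=levels)
    return est.result_


def fit_combined(
    obs: pd.DataFrame, min_weed_free_yield: float = 1.0, **est_kwargs
) -> FitResult:
    """Joint fit of the five-parameter combined model."""
    obs = select_levels(_single_species(obs), min_weed_free_yield)
    X, y, levels = _obs_arrays(obs)
    est = CombinedHyperbola(**est_kwargs)
    est.fit(X, y, levels=levels)
    return est.result_


def per_level_table(
    obs: pd.DataFrame, min_weed_free_yield: float | None = None, **est_kwargs
) -> pd.DataFrame:
    """Per-level parameter table (one hyperbola per year × regime level).

    Mirrors the per-level summary layout: level key, GDD, Y0 (SE),
    beta (SE), RMS and pseudo-R².  By default all levels are reported;
    pass ``min_weed_free_yield`` to apply the pooled-fit inclusion rule.
    """
    obs = _single_species(obs)
    if min_weed_free_yield is not None:
        obs = select_levels(obs, min_weed_free_yield)
    X, y, levels = _obs_arrays(obs)
    est = PerLevelHyperbola(**est_kwargs)
    est.fit(X, y, levels=levels)
    tab = est.params_.reset_index()
    tab[["year", "regime"]] = pd.DataFrame(tab["level"].tolist(), index=tab.index)
    return tab.drop(columns="level")[
        ["year", "regime", "gdd", "y0", "se_y0", "beta", "se_beta", "rms", "pseudo_r2", "n_obs"]
    ]
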