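"""Nested lack-of-fit F-testing for the competition model family.

A reduced model (fewer parameters) is tested against its predecessor by

    F = [(RSS_reduced - RSS_predecessor) / (df_reduced - df_predecessor)]
        / (RSS_full / df_full)

where the denominator is *always* the residual mean square of the full
(per-level) model, for both sequential comparisons — intermediate vs
per-level and combined vs intermediate.  The reduced model is accepted
when F falls below the upper-alpha F quantile with
(df_reduced - df_predecessor, df_full) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .exceptions import ConsistencyError, UndefinedStatisticError
from .fitting import FitResult

__all__ = ["ModelComparison", "lack_of_fit_f", "critical_f", "compare_models"]


def lack_of_fit_f(
    rss_reduced: float,
    df_reduced: int,
    rss_predecessor: float,
    df_predecessor: int,
    rss_full: float,
    df_full: int,
) -> float:
    """Lack-of-fit F statistic for one nested comparison."""
    for name, rss in (
        ("rss_reduced", rss_reduced),
        ("rss_predecessor", rss_predecessor),
        ("rss_full", rss_full),
    ):
        if rss < 0:
            raise ValueError(f"{name} must be non-negative, got {rss}")
    if df_reduced <= df_predecessor:
        raise ValueError(
            f"reduced model must have more residual df than its predecessor "
            f"({df_reduced} <= {df_predecessor})"
        )
    if df_full <= 0:
        raise ValueError("df_full must be positive")
    denom = rss_full / df_full
    if denom == 0:
        raise UndefinedStatisticError(
            "full-model residual mean square is zero; F undefined"
        )
    return ((rss_reduced - rss_predecessor) / (df_reduced - df_predecessor)) / denom


def critical_f(alpha: float, df_num: int, df_den: int) -> float:
    """Upper-alpha quantile of the F(df_num, df_den) distribution."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df_num, df_den))


@dataclass
class ModelComparison:
    """Table-style nested model comparison report for one weed species.

    ``rows`` lists (model_id, df_resid, rss, n_params) from the full
    model down to the most reduced; ``tests`` holds the sequential
    lack-of-fit results.
    """

    species: str
    rows: list[dict] = field(default_factory=list)
    tests: list[dict] = field(default_factory=list)

    def rows_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tests)

    def to_frame(self) -> pd.DataFrame:
        """Flat report: one row per model with its comparison, if any."""
        rows = pd.DataFrame(self.rows)
        tests = pd.DataFrame(self.tests)
        if not tests.empty:
            tests = tests.rename(columns={"reduced": "model_id"})
            rows = rows.merge(tests, on="model_id", how="left")
        rows.insert(0, "species", self.species)
        return rows


def compare_models(
    fit_full: FitResult,
    fit_intermediate: FitResult,
    fit_combined: FitResult,
    alpha: float = 0.05,
    species: str = "",
) -> ModelComparison:
    """Sequential lack-of-fit tests: intermediate vs full, combined vs intermediate.

    All three fits must come from the identical observation set.  The
    ``accepted`` flag follows the F-below-critical rule; a significance
    label (asterisk at the chosen alpha) and exact p-value are reported
    alongside.
    """
    fits = (fit_full, fit_intermediate, fit_combined)
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ConsistencyError(
            f"fits were computed on different observation sets (n_obs {sorted(n_obs)})"
        )
    if not fit_full.df_resid < fit_intermediate.df_resid < fit_combined.df_resid:
        raise ConsistencyError("residual df must strictly increase full -> combined")

    comparison = ModelComparison(species=species)
    for f in fits:
        comparison.rows.append(
            {
                "model_id": f.model_id,
                "df_resid": f.df_resid,
                "rss": f.rss,
                "n_params": f.n_params,
            }
        )

    pairs = [
        (fit_intermediate, fit_full, "intermediate-per_level"),
        (fit_combined, fit_intermediate, "combined-intermediate"),
    ]
    for reduced, predecessor, label in pairs:
        f_value = lack_of_fit_f(
            reduced.rss,
            reduced.df_resid,
            predecessor.rss,
            predecessor.df_resid,
            fit_full.rss,
            fit_full.df_resid,
        )
        if f_value < 0:
            if f_value < -1e-6:
                warnings.warn(
                    f"negative lack-of-fit F ({f_value:.3g}) for {label}: "
                    "a nested fit did not reach its optimum",
                    stacklevel=2,
                )
            f_value = 0.0
        df_num = reduced.df_resid - predecessor.df_resid
        df_den = fit_full.df_resid
        crit = critical_f(alpha, df_num, df_den)
        p = float(stats.f.sf(f_value, df_num, df_den))
        significant = f_value >= crit
        comparison.tests.append(
            {
                "comparison": label,
                "reduced": reduced.model_id,
                "f_value": f_value,
                "df_num": df_num,
                "df_den": df_den,
                "critical_f_05": crit,
                "alpha": alpha,
                "p_value": p,
                "significant": significant,
                "label": f"{f_value:.2f}{'*' if significant else ''}",
                "accepted": not significant,
            }
        )
    return comparison
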