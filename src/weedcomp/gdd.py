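"""Growing-degree-day (thermal time) accounting.

Daily mean air temperature is converted to accumulated growing degree
days (GDD, °C·days) above a base temperature, by default 10 °C as is
conventional for Korean paddy rice.  Accumulation is a daily sum with
per-day clamping,

    GDD = sum over days of max(T_day - T_base, 0),

over a *closed* window (both the start and the end date contribute).
For mid-summer paddy temperatures every day is above base and this
coincides with ``(mean T - T_base) * n_days``; the clamped daily sum is
the robust general form.

Stage windows all start at transplanting: to tillering, to flowering and
to maturity (defaults June 1 / Aug 10 / Aug 28 / Oct 15).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, RangeError

__all__ = [
    "TemperatureSeries",
    "StageCalendar",
    "GddValue",
    "daily_gdd",
    "accumulate_gdd",
    "stage_summary",
    "DEFAULT_T_BASE",
]

DEFAULT_T_BASE = 10.0  # °C, standard base for temperate paddy rice

#: stage-window labels, all anchored at transplanting
STAGE_LABELS = ("to_tillering", "to_flowering", "to_maturity")


@dataclass
class TemperatureSeries:
    """Daily mean air temperatures for one regime-year.

    ``dates`` must be strictly increasing, contiguous calendar days;
    ``t_mean`` one finite value (°C) per date.
    """

    regime_label: str
    year: int
    dates: pd.DatetimeIndex
    t_mean: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.t_mean = np.asarray(self.t_mean, dtype=float)
        if len(self.dates) < 1:
            raise ValueError("temperature series must contain at least one day")
        if len(self.dates) != len(self.t_mean):
            raise ValueError("dates and t_mean lengths differ")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise ValueError("dates must be strictly increasing daily steps")
        if not np.all(np.isfinite(self.t_mean)):
            raise DomainError("t_mean contains non-finite values")

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def window(self, start, end) -> np.ndarray:
        """Temperatures in the closed window [start, end]."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start > end:
            raise RangeError(f"window start {start.date()} after end {end.date()}")
        if start < self.start or end > self.end:
            raise RangeError(
                f"window [{start.date()}, {end.date()}] outside series span "
                f"[{self.start.date()}, {self.end.date()}]"
            )
        mask = (self.dates >= start) & (self.dates <= end)
        return self.t_mean[mask]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        """Build from a frame with columns date, regime, year, t_mean_c."""
        df = df.sort_values("date")
        regimes = df["regime"].unique()
        years = df["year"].unique()
        if len(regimes) != 1 or len(years) != 1:
            raise ValueError("frame must contain exactly one regime-year")
        return cls(
            regime_label=str(regimes[0]),
            year=int(years[0]),
            dates=pd.DatetimeIndex(pd.to_datetime(df["date"])),
            t_mean=df["t_mean_c"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class StageCalendar:
    """Growth-stage dates: transplanting < tillering < flowering < maturity."""

    transplanting: dt.date
    tillering: dt.date
    flowering: dt.date
    maturity: dt.date

    def __post_init__(self) -> None:
        seq = (self.transplanting, self.tillering, self.flowering, self.maturity)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"stage dates must be strictly ordered, got {seq}")

    @classmethod
    def default(cls, year: int) -> "StageCalendar":
        """June 1 / Aug 10 / Aug 28 / Oct 15 of the given year."""
        return cls(
            transplanting=dt.date(year, 6, 1),
            tillering=dt.date(year, 8, 10),
            flowering=dt.date(year, 8, 28),
            maturity=dt.date(year, 10, 15),
        )

    def stage_ends(self) -> dict[str, dt.date]:
        return {
            "to_tillering": self.tillering,
            "to_flowering": self.flowering,
            "to_maturity": self.maturity,
        }


@dataclass(frozen=True)
class GddValue:
    """Accumulated degree days for one window."""

    window_label: str
    gdd: float
    n_days: int
    t_base: float

    def __post_init__(self) -> None:
        if self.gdd < 0:
            raise ValueError("gdd must be non-negative")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


def daily_gdd(t_mean, t_base: float = DEFAULT_T_BASE):
    """Degree-day contribution of one day: ``max(t_mean - t_base, 0)``."""
    t = np.asarray(t_mean, dtype=float)
    if not np.all(np.isfinite(t)) or not np.isfinite(t_base):
        raise DomainError("temperatures must be finite")
    out = np.maximum(t - t_base, 0.0)
    return float(out) if out.ndim == 0 else out


def accumulate_gdd(
    series: TemperatureSeries,
    start,
    end,
    t_base: float = DEFAULT_T_BASE,
    window_label: str = "",
) -> GddValue:
    """Sum of daily clamped degree days over the closed window [start, end]."""
    temps = series.window(start, end)
    return GddValue(
        window_label=window_label,
        gdd=float(np.sum(daily_gdd(temps, t_base))),
        n_days=len(temps),
        t_base=t_base,
    )


def stage_summary(
    series: TemperatureSeries,
    calendar: StageCalendar,
    t_base: float = DEFAULT_T_BASE,
) -> pd.DataFrame:
    """Per-stage mean temperature and GDD, all windows from transplanting.

    Returns a frame indexed by window label (to_tillering / to_flowering /
    to_maturity) with columns ``mean_t_c``, ``gdd`` and ``n_days``.
    """
    rows = {}
    for label, end in calendar.stage_ends().items():
        temps = series.window(calendar.transplanting, end)
        g = accumulate_gdd(series, calendar.transplanting, end, t_base, label)
        rows[label] = {
            "mean_t_c": float(np.mean(temps)),
            "gdd": g.gdd,
            "n_days": g.n_days,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(STAGE_LABELS)]
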