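"""Physical-activity metrics from epoch-level wrist acceleration.

Works on epoch series in milli-g (default 5 s epochs) with a wear mask:
valid-day screening (default >= 16 worn hours, >= 2 valid days), MX metrics
(acceleration above which the most active X minutes of a day accumulate),
average acceleration (AA, a volume proxy), the intensity gradient (IG, the
log-log slope of time accumulated per intensity bin — more negative means
activity concentrated at low intensities), and time in the conventional
intensity bands.

Cut-points (milli-g): inactive < 30; light 30-100 (100 inclusive); moderate
(100, 400]; vigorous > 400; MVPA > 100.  All cross-day summaries weight
valid days equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EpochSeries",
    "PAMetrics",
    "InvalidRecordError",
    "MX_MINUTES",
    "screen_valid",
    "mx_metrics",
    "average_acceleration",
    "intensity_gradient",
    "cut_point_times",
    "pa_metrics",
]

SECONDS_PER_DAY = 86_400
MX_MINUTES = (1, 2, 5, 10, 15, 20, 30, 45, 60, 120, 240, 360, 480, 600, 720)
CUT_INACTIVE = 30.0
CUT_MODERATE = 100.0
CUT_VIGOROUS = 400.0


class InvalidRecordError(ValueError):
    """The record has fewer valid days than required."""


@dataclass
class EpochSeries:
    """Uniformly sampled epoch accelerations: ``timestamp`` (s), ``value``
    (milli-g, >= 0), ``wear`` mask, epoch length ``epoch_s``."""

    timestamp: np.ndarray
    value: np.ndarray
    wear: np.ndarray | None = None
    epoch_s: int = 5

    def __post_init__(self) -> None:
        self.timestamp = np.asarray(self.timestamp, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if (self.value < 0).any():
            raise ValueError("acceleration values must be >= 0")
        dt = np.diff(self.timestamp)
        if len(dt) and not np.allclose(dt, self.epoch_s):
            raise ValueError("timestamps must be uniform at epoch_s")
        if self.wear is None:
            self.wear = _nonwear_heuristic(self.value, self.epoch_s)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)
        if not len(self.timestamp) == len(self.value) == len(self.wear):
            raise ValueError("timestamp, value and wear misaligned")

    @property
    def day_index(self) -> np.ndarray:
        return (self.timestamp // SECONDS_PER_DAY).astype(int)


def _nonwear_heuristic(value: np.ndarray, epoch_s: int,
                       window_min: float = 60.0,
                       sd_threshold: float = 1.0) -> np.ndarray:
    # Fallback when no wear flags are supplied: a rolling 60-min window with
    # acceleration SD < 1 mg is treated as device-off.  A simplification of
    # raw-axis non-wear detection; prefer explicit flags.
    n_win = max(2, int(window_min * 60 / epoch_s))
    sd = pd.Series(value).rolling(n_win, center=True, min_periods=n_win // 2
                                  ).std(ddof=0).to_numpy()
    return ~(sd < sd_threshold)


def screen_valid(epochs: EpochSeries, min_hours_day: float = 16.0,
                 min_days: int = 2) -> pd.Series:
    """Per-day validity mask; raises :class:`InvalidRecordError` when fewer
    than ``min_days`` days reach ``min_hours_day`` worn hours."""
    worn_s = pd.Series(epochs.wear.astype(float) * epochs.epoch_s,
                       index=epochs.day_index).groupby(level=0).sum()
    valid = worn_s >= min_hours_day * 3600.0
    if int(valid.sum()) < min_days:
        raise InvalidRecordError(
            f"only {int(valid.sum())} valid day(s); {min_days} required"
        )
    return valid


def _minute_means(epochs: EpochSeries, day: int) -> np.ndarray:
    """Worn-epoch 1-min mean accelerations for one day."""
    sel = (epochs.day_index == day) & epochs.wear
    minutes = (epochs.timestamp[sel] // 60).astype(int)
    return pd.Series(epochs.value[sel]).groupby(minutes).mean().to_numpy()


def mx_metrics(epochs: EpochSeries, valid_days: pd.Series,
               x_list: tuple[int, ...] = MX_MINUTES) -> dict[int, float]:
    """M_X = acceleration of the X-th most active minute, averaged over days.

    Epochs are aggregated to 1-min means per day; within a day, M_X is the
    minimum acceleration among the top-X most active minutes (the X-th
    highest value).  The reported metric is the mean over valid days.
    """
    days = [d for d, ok in valid_days.items() if ok]
    per_day: dict[int, list[float]] = {x: [] for x in x_list}
    for day in days:
        mm = np.sort(_minute_means(epochs, day))[::-1]
        for x in x_list:
            if x > len(mm):
                raise ValueError(
                    f"M{x} requested but day {day} has only {len(mm)} worn "
                    "minutes"
                )
            per_day[x].append(float(mm[x - 1]))
    return {x: float(np.mean(v)) for x, v in per_day.items()}


def average_acceleration(epochs: EpochSeries, valid_days: pd.Series) -> float:
    """Mean worn-epoch acceleration over valid days (milli-g)."""
    days = {d for d, ok in valid_days.items() if ok}
    sel = epochs.wear & np.isin(epochs.day_index, list(days))
    if not sel.any():
        raise ValueError("no worn epochs in valid days")
    return float(np.mean(epochs.value[sel]))


def intensity_gradient(epochs: EpochSeries, valid_days: pd.Series,
                       bin_width: float = 25.0
                       ) -> tuple[float, float, float]:
    """Intensity gradient: slope of ln(minutes) on ln(bin-midpoint mg).

    Worn minutes over valid days are accumulated into ``bin_width``-mg
    intensity bins starting at 0; empty bins are dropped and an OLS fit of
    ln(total minutes) against ln(bin midpoint) yields (slope, intercept,
    R^2).  Needs >= 3 occupied bins; otherwise all three are NaN.
    """
    days = {d for d, ok in valid_days.items() if ok}
    sel = epochs.wear & np.isin(epochs.day_index, list(days))
    v = epochs.value[sel]
    if len(v) == 0:
        return math.nan, math.nan, math.nan
    edges = np.arange(0.0, v.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    minutes, _ = np.histogram(v, bins=edges)
    minutes = minutes * (epochs.epoch_s / 60.0)
    mid = 0.5 * (edges[:-1] + edges[1:])
    occupied = minutes > 0
    if occupied.sum() < 3:
        return math.nan, math.nan, math.nan
    fit = sps.linregress(np.log(mid[occupied]), np.log(minutes[occupied]))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def cut_point_times(epochs: EpochSeries, valid_days: pd.Series
                    ) -> dict[str, float]:
    """Mean minutes/day in each intensity band over valid days."""
    days = [d for d, ok in valid_days.items() if ok]
    acc = {k: [] for k in ("it", "lpa", "mpa", "vpa", "mvpa")}
    for day in days:
        sel = (epochs.day_index == day) & epochs.wear
        v = epochs.value[sel]
        mins = epochs.epoch_s / 60.0
        acc["it"].append(float((v < CUT_INACTIVE).sum() * mins))
        acc["lpa"].append(float(((v >= CUT_INACTIVE)
                                 & (v <= CUT_MODERATE)).sum() * mins))
        acc["mpa"].append(float(((v > CUT_MODERATE)
                                 & (v <= CUT_VIGOROUS)).sum() * mins))
        acc["vpa"].append(float((v > CUT_VIGOROUS).sum() * mins))
        acc["mvpa"].append(float((v > CUT_MODERATE).sum() * mins))
    return {k: float(np.mean(v)) for k, v in acc.items()}


@dataclass
class PAMetrics:
    """The full physical-activity panel for one record."""

    mx: dict[int, float]
    aa: float
    ig: float
    ig_intercept: float
    ig_r2: float
    it: float
    lpa: float
    mpa: float
    vpa: float
    mvpa: float
    n_valid_days: int

    def as_dict(self) -> dict[str, float]:
        out = {f"M{x}": v for x, v in self.mx.items()}
        out.update(AA=self.aa, IG=self.ig, IG_intercept=self.ig_intercept,
                   IG_r2=self.ig_r2, IT=self.it, LPA=self.lpa, MPA=self.mpa,
                   VPA=self.vpa, MVPA=self.mvpa,
                   n_valid_days=self.n_valid_days)
        return out


def pa_metrics(epochs: EpochSeries, min_hours_day: float = 16.0,
               min_days: int = 2,
               x_list: tuple[int, ...] = MX_MINUTES) -> PAMetrics:
    """Screen the record and compute the complete panel."""
    valid = screen_valid(epochs, min_hours_day, min_days)
    mx = mx_metrics(epochs, valid, x_list)
    aa = average_acceleration(epochs, valid)
    ig, icpt, r2 = intensity_gradient(epochs, valid)
    bands = cut_point_times(epochs, valid)
    return PAMetrics(mx=mx, aa=aa, ig=ig, ig_intercept=icpt, ig_r2=r2,
                     n_valid_days=int(valid.sum()), **bands)
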