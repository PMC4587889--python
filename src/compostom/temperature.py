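"""Pile/ambient temperature series, bio-oxidative phase end, EXothermic Index.

The EXothermic Index (EXI) summarises heat production during the
bio-oxidative phase: the summation over days of the daily pile temperature
minus the daily ambient temperature, expressed in cumulated °C. The
bio-oxidative phase is taken to end on the first day after which pile
temperature stays close to ambient (within a configurable delta for a
persistence window) without re-heating.

Day binning is half-open [d, d+1), day 0 = pile construction; daily values
are arithmetic means of all observations in the bin (reducer configurable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "daily_means",
    "detect_bio_oxidative_end",
    "exothermic_index",
    "read_series",
    "write_report",
]


@dataclass
class TemperatureSeries:
    """Paired pile/ambient temperatures over composting time (days)."""

    times: np.ndarray
    pile_temp: np.ndarray
    ambient_temp: np.ndarray
    turning_days: Optional[list[int]] = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pile_temp = np.asarray(self.pile_temp, dtype=float)
        self.ambient_temp = np.asarray(self.ambient_temp, dtype=float)
        if not (self.times.shape == self.pile_temp.shape == self.ambient_temp.shape):
            raise ValueError("times, pile_temp and ambient_temp must have equal length")
        if self.times.size == 0:
            raise ValueError("empty temperature series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        for name, arr in (("pile_temp", self.pile_temp), ("ambient_temp", self.ambient_temp)):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -20 or finite.max() > 90):
                raise ValueError(f"{name} outside the plausible [-20, 90] °C range")

    @property
    def is_daily(self) -> bool:
        return bool(np.all(self.times == np.floor(self.times)) and np.all(np.diff(self.times) >= 1))


def daily_means(
    series: TemperatureSeries,
    reducer: Callable[[np.ndarray], float] = np.mean,
) -> TemperatureSeries:
    """Collapse a (possibly sub-daily) series to one record per day.

    Observations are binned into half-open day windows [d, d+1) and reduced
    (arithmetic mean by default; e.g. ``np.max`` for a daily-maximum EXI
    variant). Days without observations are absent from the output.
    Idempotent on an already-daily series.
    """
    days = np.floor(series.times).astype(int)
    uniq = np.unique(days)
    pile = np.array([reducer(series.pile_temp[days == d]) for d in uniq], dtype=float)
    amb = np.array([reducer(series.ambient_temp[days == d]) for d in uniq], dtype=float)
    return TemperatureSeries(uniq.astype(float), pile, amb, series.turning_days)


def detect_bio_oxidative_end(
    series: TemperatureSeries,
    delta: float = 2.0,
    persistence: int = 7,
) -> Optional[int]:
    """First day d with |pile - ambient| < delta for all of [d, d+persistence).

    Requires a daily series. Returns None (end-of-series marker) with a
    warning when the pile never settles to ambient within the record.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if persistence < 1:
        raise ValueError("persistence must be at least 1 day")
    if not series.is_daily:
        raise ValueError("detect_bio_oxidative_end requires a daily series; apply daily_means first")
    days = series.times.astype(int)
    close = np.abs(series.pile_temp - series.ambient_temp) < delta
    by_day = dict(zip(days.tolist(), close.tolist()))
    for d in days:
        window = [by_day.get(d + j) for j in range(persistence)]
        if all(w is True for w in window):
            return int(d)
    warnings.warn(
        f"pile temperature never stayed within {delta} °C of ambient for "
        f"{persistence} consecutive days; bio-oxidative phase end not reached",
        stacklevel=2,
    )
    return None


def exothermic_index(
    series: TemperatureSeries,
    end_day: int,
    clip_negative: bool = False,
) -> float:
    """EXothermic Index: Σ_{d=0}^{end_day-1} (pile_d - ambient_d), cumulated °C.

    ``clip_negative`` floors each daily term at 0 (strictly exothermic
    reading of the index); by default negative daily differences are kept.
    Days with a non-finite pile or ambient value are skipped with a warning.
    """
    if not series.is_daily:
        raise ValueError("exothermic_index requires a daily series; apply daily_means first")
    days = series.times.astype(int)
    if end_day < 0 or (days.size and end_day > days[-1] + 1):
        raise ValueError(f"end_day={end_day} beyond the series (last day {days[-1]})")
    mask = days < end_day
    diffs = series.pile_temp[mask] - series.ambient_temp[mask]
    bad = ~np.isfinite(diffs)
    if bad.any():
        warnings.warn(
            f"skipping {int(bad.sum())} day(s) with missing pile/ambient readings",
            stacklevel=2,
        )
        diffs = diffs[~bad]
    if clip_negative:
        diffs = np.clip(diffs, 0.0, None)
    return float(diffs.sum())


def read_series(path) -> TemperatureSeries:
    """Read a temperature series from CSV.

    Columns: ``day`` (or ``day_or_datetime`` as fractional days),
    ``pile_temp_c``, ``ambient_temp_c``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    time_col = "day" if "day" in df.columns else "day_or_datetime"
    for col in (time_col, "pile_temp_c", "ambient_temp_c"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    return TemperatureSeries(
        df[time_col].to_numpy(float),
        df["pile_temp_c"].to_numpy(float),
        df["ambient_temp_c"].to_numpy(float),
    )


def write_report(end_day: Optional[int], exi: float, n_days: int, path) -> None:
    """JSON report {end_day, exi_cumulated_c, n_days}."""
    with open(path, "w") as fh:
        json.dump({"end_day": end_day, "exi_cumulated_c": exi, "n_days": n_days}, fh, indent=2)
        fh.write("\n")
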