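"""Minute-level MET series -> 165-point hourly MET-minutes vector.

The wearable records an activity intensity (METs) per minute; a value of
exactly zero is taken to mean the device was off (non-wear, e.g. bathing),
since even sitting quietly costs 1 MET.  The cleaning rules are:

* any maximal run of consecutive zero-MET minutes is a non-wear run;
* a run of **more than 30** consecutive minutes (>= 31) is a missing period
  and excludes the participant;
* runs of at most 30 minutes are imputed, every minute in the run, with the
  mean of the up-to-15 observed (pre-imputation, non-flagged) minutes
  immediately preceding the run;
* the cleaned minutes are summed into left-closed clock-hour bins from
  midnight of day 2 through 21:00 of day 8: 6*24 + 21 = 165 bins of
  MET-minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MinuteSeries",
    "HourlySeries",
    "ExclusionReport",
    "CoverageError",
    "MAX_SHORT_GAP_MIN",
    "WINDOW_HOURS",
    "detect_nonwear",
    "apply_exclusion_rule",
    "impute_short_gaps",
    "aggregate_hourly",
    "zero_runs",
]

logger = logging.getLogger(__name__)

#: longest non-wear run (minutes) that is still imputed rather than excluded
MAX_SHORT_GAP_MIN = 30
#: minutes of history averaged to fill a short gap
IMPUTE_WINDOW_MIN = 15
#: measurement window: midnight of day 2 to 21:00 of day 8
WINDOW_HOURS = 165


class CoverageError(ValueError):
    """Raised when a minute series does not cover the analysis window."""


@dataclass
class MinuteSeries:
    """One participant's minute-resolution MET values on a regular grid."""

    participant_id: str
    start: pd.Timestamp
    met: np.ndarray
    nonwear: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.met = np.asarray(self.met, dtype=float)
        if self.met.ndim != 1 or len(self.met) == 0:
            raise ValueError("met must be a non-empty one-dimensional array")
        if not np.all(np.isfinite(self.met)):
            raise ValueError("met contains non-finite values")
        if np.any(self.met < 0):
            raise ValueError("met values must be >= 0")
        if self.nonwear is not None:
            self.nonwear = np.asarray(self.nonwear, dtype=bool)
            if self.nonwear.shape != self.met.shape:
                raise ValueError("nonwear flags must match met in length")

    def __len__(self) -> int:
        return len(self.met)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.met), freq="min")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "met": self.met})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, participant_id: str | None = None) -> "MinuteSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        ts = pd.DatetimeIndex(df["timestamp"])
        if len(ts) > 1:
            deltas = np.diff(ts.asi8)
            if not np.all(deltas == 60_000_000_000):
                raise ValueError(f"{path}: timestamps are not a strict 1-minute grid")
        pid = participant_id if participant_id is not None else Path(path).stem
        return cls(pid, ts[0], df["met"].to_numpy())


@dataclass
class HourlySeries:
    """Hourly MET-minutes totals entering the SARIMA stage."""

    participant_id: str
    values: np.ndarray
    window_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("hourly values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("hourly MET-minutes must be >= 0")
        if self.window_start is not None:
            self.window_start = pd.Timestamp(self.window_start)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ExclusionReport:
    """Outcome of the missing-period rule for one participant."""

    participant_id: str
    excluded: bool
    longest_gap_min: int
    n_imputed_minutes: int

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "excluded": self.excluded,
            "longest_gap_min": self.longest_gap_min,
            "n_imputed_minutes": self.n_imputed_minutes,
        }


def zero_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exact zeros as (start, length) pairs."""
    is_zero = np.asarray(values) == 0
    if not is_zero.any():
        return []
    padded = np.r_[False, is_zero, False].astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_nonwear(series: MinuteSeries) -> MinuteSeries:
    """Flag every maximal run of zero-MET minutes as non-wear."""
    flags = np.zeros(len(series), dtype=bool)
    for start, length in zero_runs(series.met):
        flags[start : start + length] = True
    return MinuteSeries(series.participant_id, series.start, series.met.copy(), flags)


def _require_flags(series: MinuteSeries) -> MinuteSeries:
    return series if series.nonwear is not None else detect_nonwear(series)


def apply_exclusion_rule(series: MinuteSeries) -> ExclusionReport:
    """Excluded iff any non-wear run is strictly longer than 30 minutes."""
    series = _require_flags(series)
    runs = zero_runs(series.met)
    longest = max((length for _, length in runs), default=0)
    imputable = sum(length for _, length in runs if length <= MAX_SHORT_GAP_MIN)
    return ExclusionReport(
        participant_id=series.participant_id,
        excluded=longest > MAX_SHORT_GAP_MIN,
        longest_gap_min=longest,
        n_imputed_minutes=imputable,
    )


def impute_short_gaps(series: MinuteSeries) -> MinuteSeries:
    """Fill every non-wear run of <= 30 min with the preceding 15-min mean.

    The mean is taken over the observed, non-flagged minutes immediately
    before the run, using pre-imputation values only; with fewer than 15
    preceding observed minutes the window truncates to what exists.  A gap
    at the very start of the series (no preceding observed minute) is filled
    with the first observed value and logged as degenerate.
    """
    series = _require_flags(series)
    report = apply_exclusion_rule(series)
    if report.excluded:
        raise ValueError(
            f"participant {series.participant_id} has a missing period of "
            f"{report.longest_gap_min} min (> {MAX_SHORT_GAP_MIN}); excluded "
            "participants are not imputed"
        )
    original = series.met
    observed = ~series.nonwear
    filled = original.copy()
    for start, length in zero_runs(original):
        prev_idx = np.flatnonzero(observed[:start])[-IMPUTE_WINDOW_MIN:]
        if len(prev_idx) == 0:
            fallback_idx = np.flatnonzero(observed)
            if len(fallback_idx) == 0:
                raise ValueError(
                    f"participant {series.participant_id}: series contains no "
                    "observed minutes at all"
                )
            fill = original[fallback_idx[0]]
            logger.warning(
                "participant %s: gap at series start (length %d) filled with "
                "the first observed value %.3f (degenerate case)",
                series.participant_id, length, fill,
            )
        else:
            fill = float(original[prev_idx].mean())
        filled[start : start + length] = fill
    flags = np.zeros(len(filled), dtype=bool)
    return MinuteSeries(series.participant_id, series.start, filled, flags)


def default_window_start(series: MinuteSeries) -> pd.Timestamp:
    """Midnight of the day after the first recorded minute (day-2 midnight)."""
    first = series.timestamps[0]
    return (first.normalize() + pd.Timedelta(days=1)) if first != first.normalize() \
        else first


def aggregate_hourly(
    series: MinuteSeries,
    window_start: pd.Timestamp | None = None,
    n_hours: int = WINDOW_HOURS,
) -> HourlySeries:
    """Sum minutes into left-closed clock-hour bins of MET-minutes.

    The window must be fully covered by the series (60 minutes per bin);
    shorter coverage raises :class:`CoverageError`.
    """
    if window_start is None:
        window_start = default_window_start(series)
    window_start = pd.Timestamp(window_start)
    if window_start != window_start.floor("h"):
        raise ValueError("window_start must be aligned to a clock hour")
    offset = int((window_start - series.start) / pd.Timedelta(minutes=1))
    n_min = 60 * n_hours
    if offset < 0 or offset + n_min > len(series):
        raise CoverageError(
            f"participant {series.participant_id}: series does not cover the "
            f"window [{window_start}, {window_start + pd.Timedelta(hours=n_hours)})"
        )
    block = series.met[offset : offset + n_min]
    values = block.reshape(n_hours, 60).sum(axis=1)
    return HourlySeries(series.participant_id, values, window_start)
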