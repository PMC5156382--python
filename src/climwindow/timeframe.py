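"""Dates, climate/biological containers and the lagged climate matrix.

Everything downstream (sliding search, weighted windows, randomization)
works on a *climate matrix*: one row per biological record, column ``j``
holding the climate value ``j`` days before the (possibly
reference-adjusted) record date.  Offsets are 0-based and windows are
closed intervals ``[end, start]`` in days before the adjusted date, with
day 0 the adjusted date itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "parse_dates",
    "format_dates",
    "apply_reference",
    "ClimateSeries",
    "BiologicalTable",
    "ClimateMatrix",
    "WindowSpec",
    "build_climate_matrix",
    "block_matrix",
    "aggregate_window",
    "centre_split",
]

_STATS = ("mean", "max", "min", "sum", "slope")


class DateParseError(ValueError):
    """A date string did not match dd/mm/yyyy or names an invalid day."""


class SpanError(ValueError):
    """The climate series does not cover the span a request needs."""


def parse_dates(raw) -> np.ndarray:
    """Parse dd/mm/yyyy strings into proleptic-Gregorian ordinal day numbers.

    Parameters
    ----------
    raw : iterable of str
        Date strings, one per record, strictly in day/month/year order.

    Returns
    -------
    numpy.ndarray of int
        ``date.toordinal()`` values; calendar order is preserved and
        :func:`format_dates` round-trips exactly.
    """
    out = np.empty(len(raw), dtype=np.int64)
    for i, s in enumerate(raw):
        text = str(s).strip()
        parts = text.split("/")
        if len(parts) != 3:
            raise DateParseError(
                f"row {i}: {text!r} is not in dd/mm/yyyy format"
            )
        try:
            d, m, y = (int(p) for p in parts)
            out[i] = date(y, m, d).toordinal()
        except ValueError as exc:
            raise DateParseError(f"row {i}: invalid date {text!r} ({exc})") from exc
    return out


def format_dates(ordinals) -> list[str]:
    """Inverse of :func:`parse_dates` (dd/mm/yyyy with zero padding)."""
    return [date.fromordinal(int(o)).strftime("%d/%m/%Y") for o in ordinals]


def apply_reference(ordinals, window_type: str, refday: tuple[int, int] | None = None) -> np.ndarray:
    """Adjust biological dates for absolute- vs relative-window analysis.

    Absolute windows anchor every record to one calendar reference day: each
    date is moved to ``(refday_day, refday_month)`` of its own year, so all
    records in a year share a climate history.  Relative windows leave dates
    untouched (climate is counted back from each measurement date).

    A reference falling after the measurement date is applied verbatim but
    logged as a warning: the window then partly covers climate *after* the
    measurement, which is usually a design mistake.
    """
    ordinals = np.asarray(ordinals, dtype=np.int64)
    if window_type == "relative":
        return ordinals.copy()
    if window_type != "absolute":
        raise ValueError(f"window_type must be 'absolute' or 'relative', got {window_type!r}")
    if refday is None:
        raise ValueError("absolute windows require refday=(day, month)")
    rd, rm = int(refday[0]), int(refday[1])
    adjusted = np.empty_like(ordinals)
    n_after = 0
    for i, o in enumerate(ordinals):
        orig = date.fromordinal(int(o))
        adj = date(orig.year, rm, rd)
        if adj > orig:
            n_after += 1
        adjusted[i] = adj.toordinal()
    if n_after:
        logger.warning(
            "apply_reference: %d record(s) have the reference day %02d/%02d later "
            "in the year than the measurement itself; windows will include "
            "post-measurement climate.", n_after, rd, rm,
        )
    return adjusted


@dataclass
class ClimateSeries:
    """A daily climate series: strictly increasing dates, one value per day.

    ``dates`` are ordinal day numbers; gaps are permitted in the container but
    are a hard error if a climate matrix needs the missing days (no silent
    imputation).
    """

    dates: np.ndarray
    values: np.ndarray
    name: str = "climate"

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.dates.shape != self.values.shape or self.dates.ndim != 1:
            raise ValueError("dates and values must be 1-d arrays of equal length")
        if len(self.dates) and np.any(np.diff(self.dates) <= 0):
            raise ValueError("climate dates must be strictly increasing (one value per day)")

    def __len__(self) -> int:
        return len(self.dates)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, date_col: str = "Date", value_col: str | None = None) -> "ClimateSeries":
        """Build from a two-column table with dd/mm/yyyy dates."""
        if value_col is None:
            candidates = [c for c in frame.columns if c != date_col]
            if len(candidates) != 1:
                raise ValueError("value_col is required when the table has several non-date columns")
            value_col = candidates[0]
        ordinals = parse_dates(frame[date_col].tolist())
        order = np.argsort(ordinals)
        return cls(ordinals[order], frame[value_col].to_numpy(dtype=float)[order], name=value_col)

    def lookup(self, ordinals) -> np.ndarray:
        """Values at the requested days; raises SpanError listing any missing days."""
        ordinals = np.asarray(ordinals, dtype=np.int64)
        idx = np.searchsorted(self.dates, ordinals)
        ok = (idx < len(self.dates)) & (self.dates[np.minimum(idx, len(self.dates) - 1)] == ordinals)
        if not np.all(ok):
            missing = sorted(set(format_dates(np.unique(ordinals[~ok]))))
            head = ", ".join(missing[:10])
            more = "" if len(missing) <= 10 else f" (and {len(missing) - 10} more)"
            raise SpanError(f"climate series is missing {len(missing)} required day(s): {head}{more}")
        return self.values[idx]


@dataclass
class BiologicalTable:
    """Biological records: one response per dated record, optional covariates/group."""

    dates: np.ndarray
    response: np.ndarray
    response_name: str = "response"
    covariates: pd.DataFrame | None = None
    group: np.ndarray | None = None

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype=np.int64)
        self.response = np.asarray(self.response, dtype=float)
        if self.dates.shape != self.response.shape:
            raise ValueError("dates and response must have equal length")
        if np.any(~np.isfinite(self.response)):
            raise ValueError("response contains missing/non-finite values")
        if self.covariates is not None and len(self.covariates) != len(self.dates):
            raise ValueError("covariates must have one row per record")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != self.dates.shape:
                raise ValueError("group labels must have one entry per record")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({self.response_name: self.response})
        if self.covariates is not None:
            out = pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)
        if self.group is not None:
            out["group"] = self.group
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, response: str, date_col: str = "Date",
                   covariates: list[str] | None = None, group: str | None = None) -> "BiologicalTable":
        ordinals = parse_dates(frame[date_col].tolist())
        cov = frame[covariates].copy() if covariates else None
        grp = frame[group].to_numpy() if group else None
        return cls(ordinals, frame[response].to_numpy(dtype=float), response_name=response,
                   covariates=cov, group=grp)


@dataclass(frozen=True)
class WindowSpec:
    """A closed window [end, start] in offsets before the adjusted date."""

    start: int
    end: int
    cinterval: str = "day"

    def __post_init__(self):
        if self.end < 0 or self.start < self.end:
            raise ValueError(f"invalid window: need 0 <= end <= start, got ({self.start}, {self.end})")
        if self.cinterval not in ("day", "week", "month"):
            raise ValueError(f"cinterval must be day/week/month, got {self.cinterval!r}")

    @property
    def length(self) -> int:
        return self.start - self.end + 1


@dataclass
class ClimateMatrix:
    """Per-record lagged climate: ``values[r, j]`` = climate j units before record r."""

    values: np.ndarray            # (n_records, range_max - range_min + 1)
    adjusted_dates: np.ndarray
    range_max: int
    range_min: int = 0
    cinterval: str = "day"

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.range_min, self.range_max + 1)

    def column(self, offset: int) -> np.ndarray:
        if not (self.range_min <= offset <= self.range_max):
            raise ValueError(f"offset {offset} outside [{self.range_min}, {self.range_max}]")
        return self.values[:, offset - self.range_min]

    def window_slice(self, window: WindowSpec) -> np.ndarray:
        """Columns end..start inclusive, ordered by increasing offset."""
        if window.start > self.range_max or window.end < self.range_min:
            raise ValueError("window outside matrix bounds")
        j0 = window.end - self.range_min
        j1 = window.start - self.range_min
        return self.values[:, j0:j1 + 1]


def build_climate_matrix(series: ClimateSeries, adjusted_dates, range_max: int,
                         range_min: int = 0) -> ClimateMatrix:
    """Assemble the lagged climate matrix for daily data.

    ``values[r, j]`` is the series value on ``adjusted_dates[r] - (range_min + j)``;
    a missing day anywhere in the required span raises :class:`SpanError`
    listing the missing dates.
    """
    adjusted = np.asarray(adjusted_dates, dtype=np.int64)
    if range_max < range_min or range_min < 0:
        raise ValueError("need 0 <= range_min <= range_max")
    offsets = np.arange(range_min, range_max + 1, dtype=np.int64)
    wanted = adjusted[:, None] - offsets[None, :]
    vals = series.lookup(wanted.ravel()).reshape(wanted.shape)
    return ClimateMatrix(vals, adjusted, range_max=range_max, range_min=range_min)


def _month_back(d: date, k: int) -> date:
    """Same day-of-month k calendar months earlier, clamped to month length."""
    y, m = d.year, d.month - k
    while m <= 0:
        m += 12
        y -= 1
    day = d.day
    while True:
        try:
            return date(y, m, day)
        except ValueError:
            day -= 1


def block_matrix(matrix: ClimateMatrix, cinterval: str) -> ClimateMatrix:
    """Coarsen a daily matrix to week or month blocks counted backwards.

    Block 0 is the 7-day (or calendar-month) period ending on the adjusted
    date; a block's value is the mean of its member days.  Trailing partial
    blocks are dropped so every block is complete.
    """
    if cinterval == "day":
        return matrix
    if matrix.cinterval != "day" or matrix.range_min != 0:
        raise ValueError("block_matrix needs a daily matrix with range_min 0")
    n, c = matrix.values.shape
    if cinterval == "week":
        n_blocks = c // 7
        if n_blocks == 0:
            raise ValueError("matrix narrower than one week")
        trimmed = matrix.values[:, :n_blocks * 7]
        vals = trimmed.reshape(n, n_blocks, 7).mean(axis=2)
        return ClimateMatrix(vals, matrix.adjusted_dates, range_max=n_blocks - 1,
                             range_min=0, cinterval="week")
    if cinterval == "month":
        rows = []
        n_blocks_all = []
        for r in range(n):
            d = date.fromordinal(int(matrix.adjusted_dates[r]))
            bounds = [0]
            k = 1
            while True:
                off = (d - _month_back(d, k)).days
                if off > c - 1:
                    break
                bounds.append(off)
                k += 1
            # block b spans offsets bounds[b] .. bounds[b+1]-1
            blocks = [matrix.values[r, bounds[b]:bounds[b + 1]].mean()
                      for b in range(len(bounds) - 1)]
            rows.append(blocks)
            n_blocks_all.append(len(blocks))
        n_blocks = min(n_blocks_all)
        if n_blocks == 0:
            raise ValueError("matrix narrower than one month")
        vals = np.array([row[:n_blocks] for row in rows])
        return ClimateMatrix(vals, matrix.adjusted_dates, range_max=n_blocks - 1,
                             range_min=0, cinterval="month")
    raise ValueError(f"unknown cinterval {cinterval!r}")


def aggregate_window(matrix: ClimateMatrix, window: WindowSpec, stat: str = "mean") -> np.ndarray:
    """Row-wise aggregate of the climate inside a window.

    ``slope`` is the least-squares slope of climate against calendar time
    within the window (units: climate per day moving *forward* in time, i.e.
    the regressor is minus the offset), so a series warming toward the record
    date has positive slope.  Constant rows give slope 0.
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {_STATS}, got {stat!r}")
    sub = matrix.window_slice(window)
    if stat == "mean":
        return sub.mean(axis=1)
    if stat == "max":
        return sub.max(axis=1)
    if stat == "min":
        return sub.min(axis=1)
    if stat == "sum":
        return sub.sum(axis=1)
    # slope: regress value on t = -offset
    t = -np.arange(window.end, window.start + 1, dtype=float)
    if len(t) == 1:
        return np.zeros(sub.shape[0])
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    return (sub - sub.mean(axis=1, keepdims=True)) @ tc / denom


def centre_split(aggregate, group) -> tuple[np.ndarray, np.ndarray]:
    """Within-group centring: split an aggregate into deviations and group means.

    Returns ``(deviation, group_mean)`` with ``deviation + group_mean ==
    aggregate`` exactly and deviations summing to zero within each group.
    Separating the two lets a model estimate within- and between-group
    climate effects with distinct coefficients.
    """
    aggregate = np.asarray(aggregate, dtype=float)
    group = np.asarray(group)
    if group.shape != aggregate.shape:
        raise ValueError("each record needs a group label")
    if any(g is None or (isinstance(g, float) and np.isnan(g)) for g in group.tolist()):
        raise ValueError("missing group label")
    means = np.empty_like(aggregate)
    for g in pd.unique(group):
        mask = group == g
        means[mask] = aggregate[mask].mean()
    return aggregate - means, means
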