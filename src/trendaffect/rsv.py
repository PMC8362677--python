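"""Relative-search-volume (RSV) time-series handling.

Google Trends expresses daily search interest for a term as a relative
search volume on a [0, 100] scale, where 100 marks the day of maximum
interest within the requested window.  The analyses here compare two
matched calendar windows (e.g. Jan 1 - Apr 27 of 2019 and of 2020) per
term, so this module takes care of reading long-format exports,
validating them, aligning the two windows day-by-day (the 2020 window
contains a leap day), averaging the epidemic-related terms into a single
reference trace, and forming differential (2020 minus 2019) series and
rank-transformed variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RSVSeries",
    "DifferentialSeries",
    "IngestReport",
    "read_rsv_csv",
    "align_windows",
    "covid_rsv",
    "differential_series",
    "rank_transform",
    "minmax_rescale",
]


@dataclass
class RSVSeries:
    """One term's daily search-interest trace for one calendar window."""

    term: str
    year_window: str
    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        if len(self.dates) != len(self.values):
            raise ValueError(
                f"{self.term}/{self.year_window}: {len(self.dates)} dates "
                f"but {len(self.values)} values"
            )
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas <= 0):
            raise ValueError(f"{self.term}/{self.year_window}: dates not strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError(
                f"{self.term}/{self.year_window}: values outside [0, 100]"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DifferentialSeries:
    """Per-day 2020-minus-2019 difference of one term's aligned RSV traces."""

    term: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class IngestReport:
    """Bookkeeping of exclusions and repairs during CSV ingestion."""

    missing_terms: list = field(default_factory=list)
    excluded: dict = field(default_factory=dict)     # (term, window) -> reason
    interpolated: dict = field(default_factory=dict)  # (term, window) -> n days filled

    @property
    def clean(self) -> bool:
        return not (self.missing_terms or self.excluded)


_DEFAULT_SCHEMA = {"term": "term", "year_window": "year_window",
                   "date": "date", "value": "value"}


def read_rsv_csv(path, schema=None, expected_terms=None,
                 max_gap_days: int = 2):
    """Read a long-format RSV export into ``RSVSeries`` objects.

    Parameters
    ----------
    path : str or file-like
        CSV with (term, year_window, date, value) columns; lines starting
        with ``#`` are treated as provenance comments.
    schema : dict, optional
        Maps the canonical column names to the file's column names.
    expected_terms : iterable of str, optional
        Terms that must be present; absentees are recorded in the report
        (the deposited data lacked one word entirely), not raised.
    max_gap_days : int
        Interior gaps of at most this many consecutive missing days are
        linearly interpolated; longer gaps exclude the series.

    Returns
    -------
    (dict, IngestReport)
        Series keyed by ``(term, year_window)``, plus the exclusion report.
    """
    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, comment="#")
    for canonical, actual in cols.items():
        if actual not in df.columns:
            raise ValueError(f"missing column {actual!r} (for {canonical!r})")
    df = df.rename(columns={v: k for k, v in cols.items()})

    bad_dates = pd.to_datetime(df["date"], errors="coerce").isna()
    if bad_dates.any():
        row = int(df.index[bad_dates][0])
        raise ValueError(f"malformed date {df.loc[row, 'date']!r} at row {row}")
    df["date"] = pd.to_datetime(df["date"])

    values = pd.to_numeric(df["value"], errors="coerce")
    present = df["value"].notna()
    out_of_range = present & ((values < 0) | (values > 100))
    if out_of_range.any():
        row = int(df.index[out_of_range][0])
        raise ValueError(
            f"value {df.loc[row, 'value']!r} outside [0, 100] at row {row}"
        )
    df["value"] = values

    report = IngestReport()
    series = {}
    for (term, window), grp in df.groupby(["term", "year_window"], sort=True):
        grp = grp.sort_values("date")
        vals = grp["value"].to_numpy(dtype=float)
        dates = pd.DatetimeIndex(grp["date"])
        # reindex to a full daily grid so interior gaps become NaN
        full = pd.date_range(dates[0], dates[-1], freq="D")
        s = pd.Series(vals, index=dates).reindex(full)
        n_missing = int(s.isna().sum())
        if n_missing:
            gap_lengths = _max_gap(s.isna().to_numpy())
            if gap_lengths > max_gap_days:
                report.excluded[(term, str(window))] = (
                    f"gap of {gap_lengths} consecutive missing days"
                )
                continue
            s = s.interpolate(method="linear", limit_area="inside")
            if s.isna().any():  # missing at the edges cannot be interpolated
                report.excluded[(term, str(window))] = "missing values at window edge"
                continue
            report.interpolated[(term, str(window))] = n_missing
        series[(term, str(window))] = RSVSeries(term, str(window), full,
                                                s.to_numpy())

    if expected_terms is not None:
        have = {t for (t, _w) in series}
        report.missing_terms = sorted(set(expected_terms) - have)
    return series, report


def _max_gap(mask: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    longest = run = 0
    for m in mask:
        run = run + 1 if m else 0
        longest = max(longest, run)
    return longest


def align_windows(a: RSVSeries, b: RSVSeries, drop_leap_day: bool = True):
    """Pair two calendar windows day-by-day on month-day correspondence.

    The two windows must span the same month-day range.  When one of them
    includes Feb 29 (a leap year) that day is dropped before pairing, so
    that every remaining pair shares its month-day.  Returns the two series
    trimmed to equal length, in the argument order.
    """
    sa, sb = a, b
    if drop_leap_day:
        sa = _without_leap_day(sa)
        sb = _without_leap_day(sb)
    key_a = list(zip(sa.dates.month, sa.dates.day))
    key_b = list(zip(sb.dates.month, sb.dates.day))
    if key_a != key_b:
        if not set(key_a) & set(key_b):
            raise ValueError(
                f"windows {a.year_window} and {b.year_window} are disjoint "
                f"({sa.dates[0].date()}.. vs {sb.dates[0].date()}..)"
            )
        raise ValueError(
            f"windows {a.year_window} and {b.year_window} cover different "
            f"month-day spans ({len(sa)} vs {len(sb)} days)"
        )
    return sa, sb


def _without_leap_day(s: RSVSeries) -> RSVSeries:
    keep = ~((s.dates.month == 2) & (s.dates.day == 29))
    if keep.all():
        return s
    return RSVSeries(s.term, s.year_window, s.dates[keep], s.values[keep])


def covid_rsv(series, n_required: int = 4, label: str = "COVID-RSV") -> RSVSeries:
    """Average the epidemic-term traces of one window into a reference trace.

    The reference series ("COVID-RSV") is the pointwise arithmetic mean of
    the four epidemic-related terms' RSV traces.  A different number of
    components may be allowed via ``n_required`` (logged by the caller).
    """
    series = list(series)
    if len(series) != n_required:
        raise ValueError(
            f"expected {n_required} component series, got {len(series)}"
        )
    windows = {s.year_window for s in series}
    if len(windows) != 1:
        raise ValueError(f"components span multiple windows: {sorted(windows)}")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError("component series are not aligned (unequal lengths)")
    dates0 = series[0].dates
    for s in series[1:]:
        if not s.dates.equals(dates0):
            raise ValueError("component series dates differ")
    mean = np.mean([s.values for s in series], axis=0)
    return RSVSeries(label, series[0].year_window, dates0, mean)


def differential_series(y2020: RSVSeries, y2019: RSVSeries) -> DifferentialSeries:
    """Element-wise 2020-minus-2019 difference of two aligned traces."""
    if len(y2020) != len(y2019):
        raise ValueError(
            f"unaligned series: {len(y2020)} vs {len(y2019)} days "
            f"(align_windows first)"
        )
    return DifferentialSeries(y2020.term, y2020.values - y2019.values)


def rank_transform(values) -> np.ndarray:
    """Average ranks (ties share their mean rank), in [1, n].

    A constant vector is valid — every entry gets rank (n+1)/2 — but any
    correlation computed downstream from it is degenerate; callers flag
    that case via the correlation routines.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to rank")
    return rankdata(values, method="average")


def minmax_rescale(values) -> np.ndarray:
    """Optional [0, 1] rescale used only for visual comparison of traces."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)
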