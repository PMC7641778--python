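"""Core domain types and CSV readers/writers for daily query-fraction series.

A query fraction (QF) is the number of searches matching a term set per
10 million total searches from a geography on a calendar day.  Series live
on a strict daily grid: dates strictly increasing, spaced exactly one day.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuerySeries",
    "AnalysisWindow",
    "CovariateTable",
    "SeriesError",
    "read_series_csv",
    "write_series_csv",
    "read_covariates_csv",
    "slice_window",
    "fill_gaps",
]

LONG_HEADER = ["geography", "topic", "date", "qf"]


class SeriesError(ValueError):
    """Raised on malformed input series or CSV rows."""


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    if isinstance(x, str):
        try:
            return dt.date.fromisoformat(x)
        except ValueError as exc:
            raise SeriesError(f"malformed date {x!r}") from exc
    if isinstance(x, (np.datetime64, pd.Timestamp)):
        return pd.Timestamp(x).date()
    raise SeriesError(f"cannot interpret {x!r} as a date")


@dataclasses.dataclass(frozen=True)
class QuerySeries:
    """One geography x topic daily series of query fractions per 10 million.

    Parameters
    ----------
    geography : str
        "US" for national or a state/DC postal code.
    topic : str
        Topic label, e.g. ``"reform"`` or ``"union"``.
    dates : tuple of datetime.date
        Strictly increasing, spaced exactly one calendar day.
    values : numpy.ndarray
        Non-negative query fractions, one per date.
    """

    geography: str
    topic: str
    dates: tuple
    values: np.ndarray

    def __post_init__(self):
        dates = tuple(_as_date(d) for d in self.dates)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(dates) != values.size:
            raise SeriesError("dates and values must be 1-d and equal length")
        if values.size == 0:
            raise SeriesError("empty series")
        if np.any(values < 0):
            i = int(np.argmax(values < 0))
            raise SeriesError(
                f"negative value {values[i]} at {dates[i]} "
                f"({self.geography}/{self.topic})"
            )
        if np.any(~np.isfinite(values)):
            raise SeriesError("non-finite value in series")
        deltas = {(b - a).days for a, b in zip(dates[:-1], dates[1:])}
        if deltas - {1}:
            bad = sorted(deltas - {1})[0]
            raise SeriesError(
                f"dates must be strictly increasing with 1-day spacing; "
                f"found gap of {bad} days in {self.geography}/{self.topic}"
            )
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]

    def key(self) -> tuple:
        return (self.geography, self.topic)

    def subset(self, start: dt.date, end: dt.date) -> "QuerySeries":
        """Closed-interval slice [start, end]."""
        start, end = _as_date(start), _as_date(end)
        if start < self.start or end > self.end or start > end:
            raise SeriesError(
                f"window [{start}, {end}] outside series span "
                f"[{self.start}, {self.end}]"
            )
        i = (start - self.start).days
        j = (end - self.start).days + 1
        return QuerySeries(self.geography, self.topic, self.dates[i:j], self.values[i:j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "geography": self.geography,
                "topic": self.topic,
                "date": list(self.dates),
                "qf": self.values,
            }
        )


@dataclasses.dataclass(frozen=True)
class AnalysisWindow:
    """Baseline/post split around an event day.

    baseline = [baseline_start, event_date) — event day excluded;
    post = [event_date, post_end] — closed, the event day counts as post.
    """

    baseline_start: dt.date
    event_date: dt.date
    post_end: dt.date

    def __post_init__(self):
        object.__setattr__(self, "baseline_start", _as_date(self.baseline_start))
        object.__setattr__(self, "event_date", _as_date(self.event_date))
        object.__setattr__(self, "post_end", _as_date(self.post_end))
        if not (self.baseline_start < self.event_date <= self.post_end):
            raise SeriesError(
                "require baseline_start < event_date <= post_end, got "
                f"{self.baseline_start}, {self.event_date}, {self.post_end}"
            )

    @property
    def n_baseline(self) -> int:
        return (self.event_date - self.baseline_start).days

    @property
    def n_post(self) -> int:
        return (self.post_end - self.event_date).days + 1

    @property
    def post_dates(self) -> tuple:
        return tuple(
            self.event_date + dt.timedelta(days=i) for i in range(self.n_post)
        )


@dataclasses.dataclass(frozen=True)
class CovariateTable:
    """Per-geography 2016 vote-share covariates."""

    frame: pd.DataFrame  # columns: geography, vote_share_trump, winner

    def __post_init__(self):
        df = pd.DataFrame(self.frame).copy()
        missing = {"geography", "vote_share_trump", "winner"} - set(df.columns)
        if missing:
            raise SeriesError(f"covariate table missing columns: {sorted(missing)}")
        if df["geography"].duplicated().any():
            dup = df.loc[df["geography"].duplicated(), "geography"].iloc[0]
            raise SeriesError(f"duplicate geography in covariate table: {dup}")
        vs = df["vote_share_trump"].astype(float)
        if ((vs < 0) | (vs > 1)).any():
            raise SeriesError("vote_share_trump must lie in [0, 1]")
        bad = ~df["winner"].isin(["Trump", "Clinton"])
        if bad.any():
            raise SeriesError(
                f"unknown winner label {df.loc[bad, 'winner'].iloc[0]!r}"
            )
        df["vote_share_trump"] = vs
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def vote_share(self, geography: str) -> float:
        row = self.frame.loc[self.frame["geography"] == geography]
        if row.empty:
            raise KeyError(geography)
        return float(row["vote_share_trump"].iloc[0])

    def winners(self) -> Mapping[str, str]:
        return dict(zip(self.frame["geography"], self.frame["winner"]))


# ---------------------------------------------------------------------------
# readers / writers


def fill_gaps(
    geography: str,
    topic: str,
    dates: Sequence[dt.date],
    values: Sequence[float],
    max_gap: int = 3,
) -> QuerySeries:
    """Linearly interpolate missing days, up to ``max_gap`` consecutive.

    ARIMA fitting needs a regular daily grid; longer gaps are an error rather
    than a silent fill.
    """
    dates = [_as_date(d) for d in dates]
    idx = pd.DatetimeIndex(dates)
    s = pd.Series(np.asarray(values, dtype=float), index=idx)
    full = pd.date_range(idx[0], idx[-1], freq="D")
    gaps = len(full) - len(idx)
    if gaps:
        run = 0
        present = set(idx)
        longest = 0
        for day in full:
            run = 0 if day in present else run + 1
            longest = max(longest, run)
        if longest > max_gap:
            raise SeriesError(
                f"{geography}/{topic}: gap of {longest} missing days exceeds "
                f"max_gap={max_gap}"
            )
        s = s.reindex(full).interpolate(method="linear")
    return QuerySeries(geography, topic, [d.date() for d in s.index], s.to_numpy())


def read_series_csv(
    path,
    dialect: str = "long",
    lt_one_value: float = 0.5,
    max_gap: int = 3,
    default_geography: str = "US",
) -> list[QuerySeries]:
    """Read query-fraction series from CSV.

    dialect "long": header ``geography,topic,date,qf``, one row per day.
    dialect "trends_widetable": a public-Trends style export — one preamble
    line, one blank line, then a ``Day,<name>,...`` header where each column
    is a series.  Column names of the form ``GEO:topic`` carry the geography;
    bare names use ``default_geography``.  ``"<1"`` cells are imputed with
    ``lt_one_value`` (midpoint of the censored interval by default).
    """
    path = Path(path)
    if dialect == "long":
        return _read_long(path, max_gap)
    if dialect == "trends_widetable":
        return _read_widetable(path, lt_one_value, max_gap, default_geography)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long(path: Path, max_gap: int) -> list[QuerySeries]:
    groups: dict[tuple, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != LONG_HEADER:
            raise SeriesError(f"{path}: expected header {','.join(LONG_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise SeriesError(f"{path}:{lineno}: expected 4 columns")
            geo, topic, date_s, qf_s = (c.strip() for c in row)
            try:
                date = dt.date.fromisoformat(date_s)
            except ValueError:
                raise SeriesError(f"{path}:{lineno}: malformed date {date_s!r}")
            try:
                qf = float(qf_s)
            except ValueError:
                raise SeriesError(f"{path}:{lineno}: malformed value {qf_s!r}")
            if qf < 0:
                raise SeriesError(f"{path}:{lineno}: negative value {qf}")
            g = groups.setdefault((geo, topic), {})
            if date in g:
                raise SeriesError(
                    f"{path}:{lineno}: duplicate ({geo}, {topic}, {date})"
                )
            g[date] = qf
    out = []
    for (geo, topic), g in groups.items():
        days = sorted(g)
        out.append(fill_gaps(geo, topic, days, [g[d] for d in days], max_gap))
    return out


def _parse_series_name(name: str, default_geography: str) -> tuple[str, str]:
    if ":" in name:
        geo, topic = name.split(":", 1)
        return geo.strip(), topic.strip()
    return default_geography, name.strip()


def _read_widetable(
    path: Path, lt_one_value: float, max_gap: int, default_geography: str
) -> list[QuerySeries]:
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise SeriesError(f"{path}: widetable needs preamble, blank, header, data")
    rows = list(csv.reader(lines[2:]))
    header = rows[0]
    if not header or header[0].strip().lower() != "day":
        raise SeriesError(f"{path}: expected 'Day' header on line 3")
    names = [_parse_series_name(h, default_geography) for h in header[1:]]
    dates: list[dt.date] = []
    cols: list[list[float]] = [[] for _ in names]
    for lineno, row in enumerate(rows[1:], start=5):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            dates.append(dt.date.fromisoformat(row[0].strip()))
        except ValueError:
            raise SeriesError(f"{path}:{lineno}: malformed date {row[0]!r}")
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "<1":
                val = float(lt_one_value)
            else:
                try:
                    val = float(cell)
                except ValueError:
                    raise SeriesError(f"{path}:{lineno}: malformed value {cell!r}")
            if val < 0:
                raise SeriesError(f"{path}:{lineno}: negative value {val}")
            cols[j].append(val)
    if len(set(dates)) != len(dates):
        raise SeriesError(f"{path}: duplicate dates in widetable")
    order = np.argsort(np.array([d.toordinal() for d in dates]))
    dates = [dates[i] for i in order]
    return [
        fill_gaps(geo, topic, dates, list(np.asarray(col)[order]), max_gap)
        for (geo, topic), col in zip(names, cols)
    ]


def write_series_csv(collection: Iterable[QuerySeries], path) -> None:
    """Write a collection as long-dialect CSV (ISO dates, full float repr)."""
    collection = list(collection)
    if not collection:
        raise SeriesError("refusing to write an empty collection")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LONG_HEADER)
        for s in collection:
            for d, v in zip(s.dates, s.values):
                writer.writerow([s.geography, s.topic, d.isoformat(), repr(float(v))])


def read_covariates_csv(path) -> CovariateTable:
    df = pd.read_csv(path)
    return CovariateTable(df)


def write_covariates_csv(table: CovariateTable, path) -> None:
    table.frame.to_csv(path, index=False)


def slice_window(
    series: QuerySeries, window: AnalysisWindow
) -> tuple[QuerySeries, QuerySeries]:
    """Split a series into (baseline, post) around the event day.

    The baseline excludes the event day; the post period is the closed
    interval [event_date, post_end].  Concatenating the two restores the
    sliced range exactly.
    """
    if window.baseline_start < series.start or window.post_end > series.end:
        raise SeriesError(
            f"window [{window.baseline_start}, {window.post_end}] outside series "
            f"span [{series.start}, {series.end}]"
        )
    baseline = series.subset(
        window.baseline_start, window.event_date - dt.timedelta(days=1)
    )
    post = series.subset(window.event_date, window.post_end)
    return baseline, post
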