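"""Domain types and I/O for timestamped search-query event logs.

A search log is a flat table of ``(user_id, timestamp, query_text,
clicked_url)`` rows covering a declared half-open observation span
``[span_start, span_end)``.  Timestamps are UTC at one-second resolution
and day boundaries are UTC midnights; the on-disk format is tab-separated
with a fixed four-column header and ISO-8601 timestamps.  An empty
``clicked_url`` field means the query produced no recorded click.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

LOG_COLUMNS = ("user_id", "timestamp", "query_text", "clicked_url")
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class LogError(ValueError):
    """Base class for search-log format and validation problems."""


class LogFormatError(LogError):
    """The file is structurally wrong (missing or misnamed columns)."""


class EmptyLogError(LogError):
    """The file contains no data at all."""


class LogRowError(LogError):
    """One or more rows failed validation; carries 1-based file line numbers."""

    def __init__(self, message: str, lines: Iterable[int]):
        self.lines = sorted(int(x) for x in lines)
        shown = ", ".join(map(str, self.lines[:20]))
        if len(self.lines) > 20:
            shown += ", ..."
        super().__init__(f"{message} (line{'s' if len(self.lines) != 1 else ''} {shown})")


@dataclasses.dataclass(frozen=True)
class QueryEvent:
    """One timestamped search action by one anonymous user."""

    user_id: str
    timestamp: pd.Timestamp
    query_text: str
    clicked_url: str | None = None


def _infer_span(ts: pd.Series) -> tuple[pd.Timestamp, pd.Timestamp]:
    return ts.min().floor("D"), (ts.max() + pd.Timedelta(seconds=1)).ceil("D")


@dataclasses.dataclass
class SearchLog:
    """An event table plus its declared observation span.

    ``events`` is a DataFrame with the columns of :data:`LOG_COLUMNS`;
    row order is meaningful (ties in timestamp keep input order).  Every
    event timestamp must lie inside ``[span_start, span_end)``.
    """

    events: pd.DataFrame
    span_start: pd.Timestamp
    span_end: pd.Timestamp

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in LOG_COLUMNS if c not in ev.columns]
        if missing:
            raise LogFormatError(f"event table is missing columns: {missing}")
        ev = ev.loc[:, list(LOG_COLUMNS)].reset_index(drop=True)
        ev["timestamp"] = pd.to_datetime(ev["timestamp"]).dt.floor("s")
        ev["clicked_url"] = ev["clicked_url"].fillna("")
        self.span_start = pd.Timestamp(self.span_start)
        self.span_end = pd.Timestamp(self.span_end)
        if self.span_start >= self.span_end:
            raise LogError("span_start must precede span_end")
        if len(ev):
            if ev["query_text"].eq("").any():
                bad = ev.index[ev["query_text"].eq("")] + 2  # +1 header, +1 zero-base
                raise LogRowError("empty query_text", bad)
            lo, hi = ev["timestamp"].min(), ev["timestamp"].max()
            if lo < self.span_start or hi >= self.span_end:
                raise LogError(
                    f"event timestamps [{lo}, {hi}] fall outside the declared span "
                    f"[{self.span_start}, {self.span_end})"
                )
        self.events = ev

    @classmethod
    def from_events(
        cls,
        events: Iterable[QueryEvent],
        span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    ) -> "SearchLog":
        rows = list(events)
        df = pd.DataFrame(
            {
                "user_id": [e.user_id for e in rows],
                "timestamp": pd.to_datetime([e.timestamp for e in rows]),
                "query_text": [e.query_text for e in rows],
                "clicked_url": [e.clicked_url or "" for e in rows],
            }
        )
        if span is None:
            if not rows:
                raise EmptyLogError("cannot infer a span for an empty event list")
            span = _infer_span(df["timestamp"])
        return cls(df, span[0], span[1])

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_users(self) -> int:
        return self.events["user_id"].nunique()

    def iter_events(self) -> Iterator[QueryEvent]:
        for row in self.events.itertuples(index=False):
            yield QueryEvent(
                user_id=row.user_id,
                timestamp=row.timestamp,
                query_text=row.query_text,
                clicked_url=row.clicked_url or None,
            )


@dataclasses.dataclass
class UserHistory:
    """All events of one user, sorted ascending by timestamp (stable)."""

    user_id: str
    events: pd.DataFrame
    index_time: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev) and not ev["user_id"].eq(self.user_id).all():
            raise LogError("UserHistory events must all share user_id")
        if len(ev) and not ev["timestamp"].is_monotonic_increasing:
            raise LogError("UserHistory events must be sorted by timestamp")

    def __len__(self) -> int:
        return len(self.events)


def read_log(
    path: str | Path,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> SearchLog:
    """Read a tab-separated event log (gzip detected by extension).

    The file must carry the header ``user_id\\ttimestamp\\tquery_text\\t
    clicked_url``.  Rows with unparseable timestamps or empty query text
    raise :class:`LogRowError` naming the offending line numbers.  When
    ``span`` is omitted it is inferred as the smallest whole-day interval
    covering all events.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyLogError(f"{path} is empty") from None
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"{path} is missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad_ts = df.index[ts.isna()]
    if len(bad_ts):
        raise LogRowError("unparseable ISO-8601 timestamp", bad_ts + 2)
    bad_q = df.index[df["query_text"].str.strip().eq("")]
    if len(bad_q):
        raise LogRowError("empty query_text", bad_q + 2)
    out = df.loc[:, list(LOG_COLUMNS)].copy()
    out["timestamp"] = ts
    out["query_text"] = out["query_text"].str.strip()
    if span is None:
        if not len(out):
            # header-only file: represent an empty log over a degenerate span
            span = (pd.Timestamp("1970-01-01"), pd.Timestamp("1970-01-02"))
        else:
            span = _infer_span(out["timestamp"])
    return SearchLog(out, span[0], span[1])


def write_log(log: SearchLog, path: str | Path) -> None:
    """Write ``log`` so that :func:`read_log` round-trips it field-wise."""
    out = log.events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, sep="\t", index=False)


def user_histories(log: SearchLog) -> dict[str, UserHistory]:
    """Split a log into per-user histories sorted by time (stable ties).

    The union of all histories' events equals the log's events; the sum of
    their lengths equals ``log.n_events``.
    """
    ordered = log.events.sort_values("timestamp", kind="stable")
    return {
        uid: UserHistory(user_id=uid, events=grp.reset_index(drop=True))
        for uid, grp in ordered.groupby("user_id", sort=True)
    }
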