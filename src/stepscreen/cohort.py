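"""Seed-query discovery and target/comparison cohort assignment.

Seed queries are search queries empirically tied to 12-step resource
pages: any normalized query text issued, with a click to at least one
labelled seed URL, by at least ``min_users`` distinct users.  The target
cohort comprises users whose *first* seed-query event falls in the index
window (the final observation month) with no seed queries before it;
users with earlier seed queries are excluded from both populations so
prior treatment-seekers cannot contaminate the comparison baseline; all
remaining users form the comparison population.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lexicon import tokenize
from .log_model import SearchLog
from .synthetic_logs import final_month_start

GROUP_LABELS = ("AA", "NA", "BOTH")
MEETING_TOKENS = frozenset({"meeting", "meetings"})


class CohortError(ValueError):
    """Invalid cohort configuration or degenerate input."""


class UndefinedProportionError(CohortError):
    """A proportion was requested over zero qualifying events."""


def normalize_query(text: str) -> str:
    """Canonical query form: lowercase, punctuation stripped, single spaces."""
    return " ".join(tokenize(text))


@dataclasses.dataclass(frozen=True)
class SeedQuery:
    """A discovered 12-step seed query."""

    query_text: str  # normalized
    label: str  # AA | NA | BOTH
    n_users: int
    is_meeting: bool


def load_seed_urls(path: str | Path) -> dict[str, str]:
    """Read the two-column (url, label) seed-URL table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("url", "label"):
        if col not in df.columns:
            raise CohortError(f"{path} is missing column {col!r}")
    bad = sorted(set(df["label"]) - {"AA", "NA"})
    if bad:
        raise CohortError(f"{path} has labels other than AA/NA: {bad}")
    return dict(zip(df["url"], df["label"]))


def _normalized_texts(ev: pd.DataFrame) -> pd.Series:
    uniq = pd.unique(ev["query_text"])
    return ev["query_text"].map({t: normalize_query(t) for t in uniq})


def discover_seed_queries(
    log: SearchLog,
    seed_urls: Mapping[str, str],
    min_users: int = 50,
) -> list[SeedQuery]:
    """Find queries clicked through to seed URLs by >= ``min_users`` users.

    Each retained query is labelled AA or NA by the majority label of its
    clicked seed URLs (BOTH on a tie) and flagged as meeting-related when
    its tokens include "meeting"/"meetings".  Results are sorted by
    descending user count, then text.
    """
    if not seed_urls:
        raise CohortError("seed_urls must be non-empty")
    bad = sorted(set(seed_urls.values()) - {"AA", "NA"})
    if bad:
        raise CohortError(f"seed URL labels must be AA or NA, got {bad}")
    ev = log.events
    clicked = ev[ev["clicked_url"].isin(seed_urls.keys()) & ev["clicked_url"].ne("")]
    if not len(clicked):
        return []
    norm = _normalized_texts(clicked)
    frame = pd.DataFrame(
        {
            "norm": norm,
            "user_id": clicked["user_id"].to_numpy(),
            "label": clicked["clicked_url"].map(seed_urls).to_numpy(),
        }
    )
    out: list[SeedQuery] = []
    for text, grp in frame.groupby("norm", sort=True):
        n_users = grp["user_id"].nunique()
        if n_users < min_users:
            continue
        counts = grp["label"].value_counts()
        aa, na = int(counts.get("AA", 0)), int(counts.get("NA", 0))
        label = "AA" if aa > na else "NA" if na > aa else "BOTH"
        is_meeting = bool(MEETING_TOKENS & set(text.split()))
        out.append(SeedQuery(text, label, int(n_users), is_meeting))
    out.sort(key=lambda s: (-s.n_users, s.query_text))
    return out


def final_month_window(
    span_start: pd.Timestamp, span_end: pd.Timestamp
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """The index window: last calendar month of the span, half-open."""
    return final_month_start(span_start, span_end), pd.Timestamp(span_end)


def _seed_events(log: SearchLog, seeds: Sequence[SeedQuery]) -> pd.DataFrame:
    ev = log.events
    norm = _normalized_texts(ev)
    mask = norm.isin({s.query_text for s in seeds})
    out = ev.loc[mask, ["user_id", "timestamp"]].copy()
    out["norm"] = norm[mask]
    return out


def identify_cohort(
    log: SearchLog,
    seeds: Sequence[SeedQuery],
    index_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> pd.DataFrame:
    """Assign every distinct user a role: target, comparison, or excluded.

    Targets are users whose first seed-query event lies inside
    ``index_window`` (default: the final calendar month of the log span)
    and who have no seed queries before it; users with pre-window seed
    queries are excluded entirely; everyone else is comparison.  Returns
    a DataFrame (user_id, role, index_time) with index_time = first
    seed-query timestamp for targets, NaT otherwise.
    """
    if index_window is None:
        index_window = final_month_window(log.span_start, log.span_end)
    w0, w1 = pd.Timestamp(index_window[0]), pd.Timestamp(index_window[1])
    if w0 < log.span_start or w1 > log.span_end or w0 >= w1:
        raise CohortError(
            f"index window [{w0}, {w1}) must lie inside the log span "
            f"[{log.span_start}, {log.span_end})"
        )
    se = _seed_events(log, seeds) if seeds else pd.DataFrame(columns=["user_id", "timestamp"])
    all_users = pd.Index(sorted(log.events["user_id"].unique()), name="user_id")
    first = se.groupby("user_id")["timestamp"].min() if len(se) else pd.Series(dtype="datetime64[ns]")
    roles = pd.Series("comparison", index=all_users)
    target = first[(first >= w0) & (first < w1)]
    roles.loc[target.index] = "target"
    roles.loc[first[first < w0].index] = "excluded"
    out = pd.DataFrame({"user_id": all_users, "role": roles.to_numpy()})
    out["index_time"] = out["user_id"].map(target).astype("datetime64[ns]")
    return out


def assign_subgroups(
    assignments: pd.DataFrame,
    log: SearchLog,
    seeds: Sequence[SeedQuery],
    index_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> pd.DataFrame:
    """Fill per-target group (AA/NA/BOTH) and the meeting-subsample flag.

    A target user is AA when every index-window seed query of theirs is
    AA-labelled, NA when every one is NA-labelled, and BOTH otherwise.
    ``meeting_subsample`` is true iff the user's first seed query is
    meeting-related.
    """
    if index_window is None:
        index_window = final_month_window(log.span_start, log.span_end)
    w0, w1 = index_window
    seed_map = {s.query_text: s for s in seeds}
    se = _seed_events(log, seeds)
    se = se[(se["timestamp"] >= w0) & (se["timestamp"] < w1)]
    out = assignments.copy()
    out["group"] = ""
    out["meeting_subsample"] = False
    targets = set(out.loc[out["role"] == "target", "user_id"])
    se = se[se["user_id"].isin(targets)]
    if len(se):
        labels = se["norm"].map(lambda t: seed_map[t].label)
        per_user = pd.DataFrame({"user_id": se["user_id"].to_numpy(), "label": labels.to_numpy()})
        label_sets = per_user.groupby("user_id")["label"].agg(set)

        def _group(lbls: set) -> str:
            if lbls == {"AA"}:
                return "AA"
            if lbls == {"NA"}:
                return "NA"
            return "BOTH"

        groups = label_sets.map(_group)
        # first seed query decides the meeting flag (stable order on ties)
        se_sorted = se.sort_values("timestamp", kind="stable")
        first_norm = se_sorted.groupby("user_id")["norm"].first()
        meeting = first_norm.map(lambda t: seed_map[t].is_meeting)
        is_target = out["role"].eq("target")
        out.loc[is_target, "group"] = out.loc[is_target, "user_id"].map(groups).fillna("")
        out.loc[is_target, "meeting_subsample"] = (
            out.loc[is_target, "user_id"].map(meeting).fillna(False).astype(bool)
        )
    return out


def cohort_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Summary counts: roles, AA/NA/BOTH subgroups and the meeting subsample."""
    roles = assignments["role"].value_counts()
    counts = {
        "target": int(roles.get("target", 0)),
        "comparison": int(roles.get("comparison", 0)),
        "excluded": int(roles.get("excluded", 0)),
    }
    if "group" in assignments.columns:
        groups = assignments.loc[assignments["role"] == "target", "group"].value_counts()
        for g in GROUP_LABELS:
            counts[g] = int(groups.get(g, 0))
        counts["meeting"] = int(
            assignments.loc[assignments["role"] == "target", "meeting_subsample"].sum()
        )
    return counts


def keyword_fraction(
    log: SearchLog,
    users: Iterable[str],
    keyword: str,
    seeds: Sequence[SeedQuery],
) -> float:
    """Fraction of the users' seed-query events containing ``keyword`` as a token.

    Mirrors auditing what share of treatment-seeking queries mention a
    bystander keyword (for example "alanon", which typically indicates
    family members searching on behalf of someone else).
    """
    users = set(users)
    if not users:
        raise CohortError("users must be non-empty")
    se = _seed_events(log, seeds)
    se = se[se["user_id"].isin(users)]
    if not len(se):
        raise UndefinedProportionError("no seed-query events for the given users")
    kw = normalize_query(keyword)
    hits = se["norm"].map(lambda t: kw in t.split()).sum()
    return float(hits) / float(len(se))
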