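"""Symptom synonym lexicon and free-text query matching.

The lexicon maps canonical medical symptom names (clinical wording such
as "diaphoresis") to lists of synonym phrases (colloquial wording such
as "sweating").  A query mentions a symptom when one of its synonyms
occurs as a contiguous whole-word token sequence in the query — so
"rash" matches "skin rash cream" but not "crash".  Matching is
case-insensitive and ignores punctuation.  Each synonym phrase belongs
to exactly one canonical symptom; an ambiguous lexicon is rejected at
load time because downstream person-counting needs an unambiguous
symptom indicator.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .log_model import SearchLog, UserHistory

_TOKEN_RE = re.compile(r"[a-z0-9]+")

LEXICON_COLUMNS = ("canonical_symptom", "synonym")


class LexiconError(ValueError):
    """Structural problem in a symptom lexicon."""


class AmbiguousSynonymError(LexiconError):
    """The same synonym phrase is mapped to two canonical symptoms."""


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase, strip punctuation, and split into word tokens."""
    return tuple(_TOKEN_RE.findall(text.lower()))


@dataclasses.dataclass(frozen=True)
class SymptomAnnotation:
    """The set of canonical symptoms mentioned by one log event."""

    event_index: int
    symptoms: frozenset[str]


class SymptomLexicon:
    """Canonical symptom -> synonym phrases, with a token-phrase matcher."""

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        if not entries:
            raise LexiconError("lexicon has no symptoms")
        self._entries: dict[str, list[str]] = {}
        self._phrases: dict[tuple[str, ...], str] = {}
        for canonical, synonyms in entries.items():
            canon = " ".join(tokenize(canonical))
            if not canon:
                raise LexiconError(f"canonical symptom {canonical!r} has no word tokens")
            phrases: list[str] = []
            for syn in [canonical, *synonyms]:  # self-match is guaranteed
                norm = " ".join(tokenize(syn))
                if not norm:
                    raise LexiconError(f"empty synonym under {canonical!r}")
                if norm in phrases:
                    continue
                toks = tuple(norm.split())
                owner = self._phrases.get(toks)
                if owner is not None and owner != canon:
                    raise AmbiguousSynonymError(
                        f"synonym {norm!r} is mapped to both {owner!r} and {canon!r}"
                    )
                self._phrases[toks] = canon
                phrases.append(norm)
            self._entries[canon] = phrases
        self._lengths = sorted({len(t) for t in self._phrases})

    @property
    def entries(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self._entries.items()}

    @property
    def symptoms(self) -> tuple[str, ...]:
        return tuple(sorted(self._entries))

    @property
    def size(self) -> int:
        return len(self._entries)

    def __len__(self) -> int:
        return self.size

    def __contains__(self, symptom: str) -> bool:
        return symptom in self._entries

    def match(self, query_text: str) -> frozenset[str]:
        """Canonical symptoms whose synonyms occur contiguously in the text."""
        toks = tokenize(query_text)
        n = len(toks)
        found: set[str] = set()
        for i in range(n):
            for length in self._lengths:
                if i + length > n:
                    break
                canon = self._phrases.get(toks[i : i + length])
                if canon is not None:
                    found.add(canon)
        return frozenset(found)


def build_lexicon(entries: Mapping[str, Iterable[str]]) -> SymptomLexicon:
    """Construct a lexicon from an in-memory mapping (synonyms may omit self)."""
    return SymptomLexicon(entries)


def load_lexicon(path: str | Path) -> SymptomLexicon:
    """Load a two-column tab-separated lexicon file.

    The header must be ``canonical_symptom\\tsynonym``, one synonym per
    row.  Duplicate rows are deduplicated with a warning; a synonym
    appearing under two canonical symptoms is a hard error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise LexiconError(f"{path} is empty") from None
    missing = [c for c in LEXICON_COLUMNS if c not in df.columns]
    if missing:
        raise LexiconError(f"{path} is missing columns: {missing}")
    if not len(df):
        raise LexiconError(f"{path} contains no lexicon rows")
    norm = df.assign(
        canonical_symptom=df["canonical_symptom"].map(lambda s: " ".join(tokenize(s))),
        synonym=df["synonym"].map(lambda s: " ".join(tokenize(s))),
    )
    dup = norm.duplicated()
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate (canonical, synonym) rows deduplicated",
            stacklevel=2,
        )
        norm = norm[~dup]
    entries: dict[str, list[str]] = {}
    for canonical, syn in zip(norm["canonical_symptom"], norm["synonym"]):
        entries.setdefault(canonical, []).append(syn)
    return SymptomLexicon(entries)


def default_lexicon() -> SymptomLexicon:
    """The packaged fixture lexicon (a compact stand-in synonym list)."""
    with resources.as_file(
        resources.files("stepscreen") / "data" / "symptom_lexicon.tsv"
    ) as p:
        return load_lexicon(p)


def match_query(query_text: str, lexicon: SymptomLexicon) -> frozenset[str]:
    """Canonical symptoms mentioned in ``query_text`` (empty text -> empty set)."""
    return lexicon.match(query_text)


def _events_frame(data) -> pd.DataFrame:
    """Coerce a SearchLog, event DataFrame, or UserHistory collection to events."""
    if isinstance(data, SearchLog):
        return data.events
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, Mapping):
        data = data.values()
    frames = []
    for item in data:
        if isinstance(item, UserHistory):
            frames.append(item.events)
        else:
            raise TypeError(f"cannot interpret {type(item)!r} as log events")
    if not frames:
        return pd.DataFrame(columns=["user_id", "timestamp", "query_text", "clicked_url"])
    return pd.concat(frames, ignore_index=True)


def annotate_log(log: SearchLog | pd.DataFrame, lexicon: SymptomLexicon) -> list[SymptomAnnotation]:
    """One annotation per event, in event order, equal to per-event matching."""
    ev = _events_frame(log)
    cache: dict[str, frozenset[str]] = {}
    out = []
    for i, text in enumerate(ev["query_text"]):
        hit = cache.get(text)
        if hit is None:
            hit = lexicon.match(text)
            cache[text] = hit
        out.append(SymptomAnnotation(event_index=i, symptoms=hit))
    return out


def symptom_hits(data, lexicon: SymptomLexicon) -> pd.DataFrame:
    """Long table of symptom mentions: columns (user_id, timestamp, symptom).

    One row per (event, matched canonical symptom) pair; events matching
    no symptom contribute nothing.  Matching is cached per distinct query
    text, which keeps annotation linear in the number of distinct queries
    rather than the number of events.
    """
    ev = _events_frame(data)
    if not len(ev):
        return pd.DataFrame(columns=["user_id", "timestamp", "symptom"])
    uniq = pd.unique(ev["query_text"])
    cache = {t: tuple(sorted(lexicon.match(t))) for t in uniq}
    matched = ev["query_text"].map(cache)
    mask = matched.str.len() > 0
    sub = ev.loc[mask, ["user_id", "timestamp"]].copy()
    sub["symptom"] = matched[mask]
    return sub.explode("symptom").reset_index(drop=True)
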