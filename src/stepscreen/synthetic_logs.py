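"""Seeded generative model for search logs with planted temporal effects.

The generator emulates the data regime the screening pipeline assumes:

* a fixed observation span (default nine months);
* ``n_target_users`` who each issue exactly one first 12-step seed query
  (with a click to a seed resource URL) at a time uniform over the final
  observation month — the index event;
* ``n_comparison_users`` who never issue seed queries;
* background queries per user as a Poisson process over the span, drawn
  from a nonsense vocabulary guaranteed not to match any symptom
  synonym;
* per-symptom, per-user-day Bernoulli symptom queries at
  ``symptom_base_prob`` (at most one query per symptom per day, matching
  the person-level counting the analysis uses) for every user, so the
  between-group ratio is ~1 under the null;
* optional *planted effects* that multiply the symptom-query probability
  of target users inside one of the three pre-index windows (proximal =
  last 7 days before the index instant, middle = 7-14 days, distal =
  14-30 days).

Target users' symptom-emission days are aligned to their own index
instant (day boundaries at ``index - k * 24h``) rather than calendar
midnights; with calendar days a planted window effect would leak about
half a day of elevated rate into the neighbouring window, blurring the
planted label.  Comparison users use calendar days.

Everything is a pure function of the configuration, including its RNG
seed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .log_model import SearchLog

#: Window label -> (lo, hi) in *relative days before the index instant*:
#: relative day k covers [index - (k+1)d, index - k*d), so "proximal"
#: spans the 7 days immediately before the index event.
WINDOW_DAY_RANGES: dict[str, tuple[int, int]] = {
    "proximal": (0, 7),
    "middle": (7, 14),
    "distal": (14, 30),
}

SECONDS_PER_DAY = 86_400

#: Simulation symptom names: single-token canonical symptoms from the
#: packaged lexicon, pairwise token-disjoint so emitted queries for one
#: symptom can never register as mentions of another.
DEFAULT_SYMPTOMS: tuple[str, ...] = (
    "diaphoresis", "pyrosis", "hallucination", "impotence", "urticaria",
    "akathisia", "agoraphobia", "cataplexy", "exophthalmos", "bloating",
    "blindness", "amnesia", "dizziness", "anxiety", "blister",
    "itch", "swelling", "tinnitus", "anorexia", "cough",
    "cramp", "depression", "constipation", "fever", "rash",
    "toothache", "xerostomia", "dysphagia", "paranoia", "malaise",
)

_SYMPTOM_TEMPLATES = ("{s}", "what causes {s}", "{s} remedies", "how to treat {s}")

#: Invented-word background queries; none contains a symptom synonym,
#: a seed-query phrase, or the token "meeting".
BACKGROUND_VOCABULARY: tuple[str, ...] = (
    "glimbort recipes", "weather in zanvoria", "cheap flights to brundle",
    "voxley season 4 release date", "how tall is mount quandrix",
    "best snorfle restaurants", "plarvin league scores", "trelbo phone review",
    "directions to lake vermandy", "crontek stock price", "diy murbling ideas",
    "fastest womple in the world", "zorple translation", "gravit movie cast",
    "when is blenmas this year", "florpid chords", "used kandrel for sale",
    "history of the drombu empire", "strell pie recipe", "palvorite meaning",
    "quibnet login", "turn off veldrin notifications", "brastle vs crindle",
    "top 10 yempler songs", "is the prandle open today", "sharnel haircut styles",
    "voltrey bus schedule", "minkel puzzle answers", "ostrevan travel guide",
    "fix a squeaky jorvel", "grendip birthday ideas", "walmora opening hours",
    "plintor exchange rate", "darnish lessons online", "cromble assembly manual",
    "yarvelo 2017 highlights", "best price on tromkins", "skelver game rules",
    "hentrup wedding venues", "new flandrel update",
)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """Multiply one symptom's query probability inside one pre-index window."""

    symptom: str
    window: str  # "distal" | "middle" | "proximal"
    multiplier: float

    def __post_init__(self) -> None:
        if self.window not in WINDOW_DAY_RANGES:
            raise SimConfigError(
                f"unknown window {self.window!r}; expected one of {sorted(WINDOW_DAY_RANGES)}"
            )
        if self.multiplier < 1:
            raise SimConfigError("planted multipliers must be >= 1")


@dataclasses.dataclass(frozen=True)
class SeedQueryDef:
    """One 12-step seed query: its text, clicked resource URL, and label."""

    query_text: str
    url: str
    label: str  # "AA" | "NA"

    def __post_init__(self) -> None:
        if self.label not in ("AA", "NA"):
            raise SimConfigError(f"seed query label must be AA or NA, got {self.label!r}")


DEFAULT_SEED_VOCABULARY: tuple[SeedQueryDef, ...] = (
    SeedQueryDef("alcoholics anonymous", "https://example.org/aa/home", "AA"),
    SeedQueryDef("aa meeting near me", "https://example.org/aa/meeting-finder", "AA"),
    SeedQueryDef("alcoholic anonymous meeting directory", "https://example.org/aa/meeting-directory", "AA"),
    SeedQueryDef("aa 12 steps", "https://example.org/aa/twelve-steps", "AA"),
    SeedQueryDef("alcoholics anonymous hotline", "https://example.org/aa/contact", "AA"),
    SeedQueryDef("narcotics anonymous", "https://example.org/na/home", "NA"),
    SeedQueryDef("na meetings today", "https://example.org/na/meeting-search", "NA"),
    SeedQueryDef("narcotics anonymous helpline", "https://example.org/na/contact", "NA"),
)


def default_seed_urls() -> dict[str, str]:
    """URL -> AA/NA label for the default seed vocabulary."""
    return {d.url: d.label for d in DEFAULT_SEED_VOCABULARY}


@dataclasses.dataclass
class SimConfig:
    """Parameters of one simulated search-log study."""

    n_target_users: int = 500
    n_comparison_users: int = 5000
    span_start: pd.Timestamp = pd.Timestamp("2016-11-01")
    span_end: pd.Timestamp = pd.Timestamp("2017-08-01")
    background_query_rate: float = 0.1  # expected background queries / user-day
    symptom_base_prob: float = 0.01  # per-symptom per-user-day query probability
    symptoms: tuple[str, ...] = DEFAULT_SYMPTOMS
    planted_effects: tuple[PlantedEffect, ...] = ()
    target_history_multipliers: Mapping[str, float] = dataclasses.field(default_factory=dict)
    seed_query_vocabulary: tuple[SeedQueryDef, ...] = DEFAULT_SEED_VOCABULARY
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.span_start = pd.Timestamp(self.span_start)
        self.span_end = pd.Timestamp(self.span_end)
        self.symptoms = tuple(self.symptoms)
        self.planted_effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
            for e in self.planted_effects
        )
        self.seed_query_vocabulary = tuple(
            d if isinstance(d, SeedQueryDef) else SeedQueryDef(**d)
            for d in self.seed_query_vocabulary
        )
        self.validate()

    def validate(self) -> None:
        if self.n_target_users < 0 or self.n_comparison_users < 0:
            raise SimConfigError("user counts must be >= 0")
        if not (0.0 <= self.symptom_base_prob <= 1.0):
            raise SimConfigError("symptom_base_prob must be in [0, 1]")
        if self.background_query_rate < 0:
            raise SimConfigError("background_query_rate must be >= 0")
        if (self.span_end - self.span_start) < pd.Timedelta(days=31):
            raise SimConfigError(
                "observation span must cover at least 31 days for the "
                "30-day pre-index windows to fit"
            )
        known = set(self.symptoms)
        for eff in self.planted_effects:
            if eff.symptom not in known:
                raise SimConfigError(f"planted effect on unknown symptom {eff.symptom!r}")
        for sym, mult in self.target_history_multipliers.items():
            if sym not in known:
                raise SimConfigError(f"history multiplier on unknown symptom {sym!r}")
            if mult < 1:
                raise SimConfigError("history multipliers must be >= 1")
        if self.n_target_users and not self.seed_query_vocabulary:
            raise SimConfigError("target users need a non-empty seed query vocabulary")

    def to_dict(self) -> dict:
        return {
            "n_target_users": self.n_target_users,
            "n_comparison_users": self.n_comparison_users,
            "span_start": self.span_start.isoformat(),
            "span_end": self.span_end.isoformat(),
            "background_query_rate": self.background_query_rate,
            "symptom_base_prob": self.symptom_base_prob,
            "symptoms": list(self.symptoms),
            "planted_effects": [dataclasses.asdict(e) for e in self.planted_effects],
            "target_history_multipliers": dict(self.target_history_multipliers),
            "seed_query_vocabulary": [dataclasses.asdict(d) for d in self.seed_query_vocabulary],
            "rng_seed": int(self.rng_seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**dict(d))


@dataclasses.dataclass
class GroundTruth:
    """Per-user truth of a simulation plus the planted effects, for audits.

    ``assignments`` has one row per simulated user: user_id, role
    (target/comparison), group (AA/NA for targets), seed_query,
    is_meeting, index_time (NaT for comparison users).
    """

    assignments: pd.DataFrame
    planted_effects: tuple[PlantedEffect, ...]

    def write(self, path) -> None:
        out = self.assignments.copy()
        out["index_time"] = out["index_time"].dt.strftime("%Y-%m-%dT%H:%M:%S").fillna("")
        out.to_csv(path, sep="\t", index=False)


def final_month_start(span_start: pd.Timestamp, span_end: pd.Timestamp) -> pd.Timestamp:
    """UTC start of the last calendar month touched by the span."""
    last = pd.Timestamp(span_end) - pd.Timedelta(seconds=1)
    start = pd.Timestamp(year=last.year, month=last.month, day=1)
    return max(start, pd.Timestamp(span_start))


def lexicon_for(config: SimConfig):
    """A minimal lexicon whose canonical set is the simulated symptom list."""
    from .lexicon import build_lexicon

    return build_lexicon({s: [s] for s in config.symptoms})


def null_config(n_symptoms: int, seed: int, **overrides) -> SimConfig:
    """A no-effect configuration over the first ``n_symptoms`` default symptoms."""
    if n_symptoms < 1:
        raise SimConfigError("n_symptoms must be >= 1")
    if n_symptoms > len(DEFAULT_SYMPTOMS):
        raise SimConfigError(
            f"at most {len(DEFAULT_SYMPTOMS)} default symptoms are available"
        )
    overrides.setdefault("planted_effects", ())
    return SimConfig(
        symptoms=DEFAULT_SYMPTOMS[:n_symptoms],
        rng_seed=int(seed),
        **overrides,
    )


def _symptom_probability_grid(
    base: float,
    n_days: int,
    effects: Sequence[PlantedEffect],
    history_multiplier: float,
) -> np.ndarray:
    """Per-relative-day probability vector for one symptom of a target user."""
    p = np.full(n_days, base * history_multiplier)
    for eff in effects:
        lo, hi = WINDOW_DAY_RANGES[eff.window]
        hi = min(hi, n_days)
        p[lo:hi] = base * history_multiplier * eff.multiplier
    return np.clip(p, 0.0, 1.0)


def simulate_logs(config: SimConfig) -> tuple[SearchLog, GroundTruth]:
    """Draw one synthetic search log and its ground truth from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    start, end = config.span_start, config.span_end
    total_s = int((end - start).total_seconds())
    n_days = total_s // SECONDS_PER_DAY
    n_t, n_c = config.n_target_users, config.n_comparison_users
    t_ids = np.array([f"t{i:06d}" for i in range(n_t)], dtype=object)
    c_ids = np.array([f"c{i:06d}" for i in range(n_c)], dtype=object)

    users_col: list[np.ndarray] = []
    secs_col: list[np.ndarray] = []
    text_col: list[np.ndarray] = []
    url_col: list[np.ndarray] = []

    # --- index events (one seed query per target user, uniform over final month)
    month_lo = int((final_month_start(start, end) - start).total_seconds())
    if n_t:
        index_s = rng.integers(month_lo, total_s, size=n_t)
        vocab = config.seed_query_vocabulary
        vidx = rng.integers(0, len(vocab), size=n_t)
        users_col.append(t_ids)
        secs_col.append(index_s)
        text_col.append(np.array([vocab[i].query_text for i in vidx], dtype=object))
        url_col.append(np.array([vocab[i].url for i in vidx], dtype=object))
    else:
        index_s = np.empty(0, dtype=np.int64)
        vidx = np.empty(0, dtype=np.int64)

    all_ids = np.concatenate([t_ids, c_ids])

    # --- background queries: Poisson process over the whole span
    if config.background_query_rate > 0 and len(all_ids):
        counts = rng.poisson(config.background_query_rate * n_days, size=len(all_ids))
        n_bg = int(counts.sum())
        if n_bg:
            users_col.append(np.repeat(all_ids, counts))
            secs_col.append(rng.integers(0, total_s, size=n_bg))
            bg = np.asarray(BACKGROUND_VOCABULARY, dtype=object)
            text_col.append(bg[rng.integers(0, len(bg), size=n_bg)])
            url_col.append(np.full(n_bg, "", dtype=object))

    # --- symptom queries
    base = config.symptom_base_prob
    effects_by_symptom: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted_effects:
        effects_by_symptom.setdefault(eff.symptom, []).append(eff)
    # target users: relative-day grid anchored at each user's index instant
    k_pre = index_s // SECONDS_PER_DAY  # complete pre-index days inside the span
    k_post = (total_s - index_s) // SECONDS_PER_DAY
    kmax_pre = int(k_pre.max()) if n_t else 0
    kmax_post = int(k_post.max()) if n_t else 0
    for sym in config.symptoms:
        templates = np.array(
            [t.format(s=sym) for t in _SYMPTOM_TEMPLATES], dtype=object
        )
        effs = effects_by_symptom.get(sym, ())
        hist_mult = float(config.target_history_multipliers.get(sym, 1.0))
        if n_t and kmax_pre:
            p_rel = _symptom_probability_grid(base, kmax_pre, effs, hist_mult)
            u = rng.random((n_t, kmax_pre))
            hits = (u < p_rel[None, :]) & (np.arange(kmax_pre)[None, :] < k_pre[:, None])
            ui, ki = np.nonzero(hits)
            if len(ui):
                offs = rng.integers(0, SECONDS_PER_DAY, size=len(ui))
                users_col.append(t_ids[ui])
                secs_col.append(index_s[ui] - (ki + 1) * SECONDS_PER_DAY + offs)
                text_col.append(templates[rng.integers(0, len(templates), size=len(ui))])
                url_col.append(np.full(len(ui), "", dtype=object))
        if n_t and kmax_post:
            # post-index activity continues at the base rate
            p_post = np.clip(base * hist_mult, 0.0, 1.0)
            u = rng.random((n_t, kmax_post))
            hits = (u < p_post) & (np.arange(kmax_post)[None, :] < k_post[:, None])
            ui, ki = np.nonzero(hits)
            if len(ui):
                offs = rng.integers(0, SECONDS_PER_DAY, size=len(ui))
                users_col.append(t_ids[ui])
                secs_col.append(index_s[ui] + ki * SECONDS_PER_DAY + offs)
                text_col.append(templates[rng.integers(0, len(templates), size=len(ui))])
                url_col.append(np.full(len(ui), "", dtype=object))
        if n_c and n_days:
            u = rng.random((n_c, n_days))
            ui, di = np.nonzero(u < base)
            if len(ui):
                offs = rng.integers(0, SECONDS_PER_DAY, size=len(ui))
                users_col.append(c_ids[ui])
                secs_col.append(di * SECONDS_PER_DAY + offs)
                text_col.append(templates[rng.integers(0, len(templates), size=len(ui))])
                url_col.append(np.full(len(ui), "", dtype=object))

    if users_col:
        events = pd.DataFrame(
            {
                "user_id": np.concatenate(users_col),
                "timestamp": start
                + pd.to_timedelta(np.concatenate(secs_col).astype(np.int64), unit="s"),
                "query_text": np.concatenate(text_col),
                "clicked_url": np.concatenate(url_col),
            }
        )
        events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(
            columns=["user_id", "timestamp", "query_text", "clicked_url"]
        ).astype({"timestamp": "datetime64[ns]"})
    log = SearchLog(events, start, end)

    vocab = config.seed_query_vocabulary
    truth = pd.DataFrame(
        {
            "user_id": np.concatenate([t_ids, c_ids]),
            "role": ["target"] * n_t + ["comparison"] * n_c,
            "group": [vocab[i].label for i in vidx] + [""] * n_c,
            "seed_query": [vocab[i].query_text for i in vidx] + [""] * n_c,
            "is_meeting": [
                any(tok in ("meeting", "meetings") for tok in vocab[i].query_text.split())
                for i in vidx
            ]
            + [False] * n_c,
            "index_time": list(start + pd.to_timedelta(index_s, unit="s"))
            + [pd.NaT] * n_c,
        }
    )
    return log, GroundTruth(assignments=truth, planted_effects=config.planted_effects)
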