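"""Between-group ratio screen, time-lagged 2x2 chi-square screen, and the
persistence taxonomy.

Two complementary screens identify symptoms whose querying anticipates
12-step information seeking:

* **Between-group ratio** — for each symptom, the fraction of target
  users who ever query it divided by the same fraction among comparison
  users, ranked descending.

* **Within-person temporal screen** — for each symptom and each of three
  disjoint pre-index windows (distal = [-30, -14), middle = [-14, -7),
  proximal = [-7, 0) days relative to each user's own index instant), a
  2x2 person-count table contrasts querying inside the window against
  querying in a baseline period, tested with Pearson's chi-square on
  1 df and Bonferroni-corrected over (symptoms tested x windows).  A
  window is significant only when the window probability also exceeds
  the baseline probability.

The default baseline for each window is a *duration-matched* interval
immediately before the 30-day lead-up ([-30-L, -30) days for a window of
length L), so the two probabilities being compared refer to equal
exposure times.  ``baseline="full_history"`` instead uses all activity
strictly before index-30d, which conflates rate changes with exposure
length (a user is far more likely to have queried at least once in
eight months than in seven days) and is kept only as a sensitivity
variant.

Symptoms significant in all three windows are *persistent*; in exactly
two, *near-persistent*; in the proximal window only, *immediate*; in
the distal window only, *distal*; in the middle only, *middle_only*;
otherwise *none*.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import SymptomLexicon, symptom_hits

LEAD_UP_DAYS = 30
PERSISTENCE_CATEGORIES = (
    "persistent",
    "near_persistent",
    "immediate",
    "distal",
    "middle_only",
    "none",
)


class TemporalStatsError(ValueError):
    """Degenerate input to a screen (empty population, bad window set...)."""


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """A half-open pre-index window, in days relative to the index instant."""

    label: str
    start_days: float  # inclusive, negative
    end_days: float  # exclusive

    def __post_init__(self) -> None:
        if self.start_days >= self.end_days:
            raise TemporalStatsError("window start must precede end")

    @property
    def length_days(self) -> float:
        return self.end_days - self.start_days


DEFAULT_WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec("distal", -30, -14),
    WindowSpec("middle", -14, -7),
    WindowSpec("proximal", -7, 0),
)


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Person counts for one (symptom, window) pair.

    a = users querying the symptom in the window, c = users not;
    b = users querying it in the baseline period, d = users not.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise TemporalStatsError("contingency cells must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p_window(self) -> float:
        return self.a / (self.a + self.c) if (self.a + self.c) else float("nan")

    @property
    def p_baseline(self) -> float:
        return self.b / (self.b + self.d) if (self.b + self.d) else float("nan")


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def pearson_chi_square(table: ContingencyTable, continuity: bool = False) -> ChiSquareResult:
    """Pearson's chi-square on a 2x2 table, 1 df.

    Closed form ``n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``; with
    ``continuity`` the Yates-corrected form ``n (|ad-bc| - n/2)^2 / ...``
    (clamped at zero).  A zero margin yields statistic 0, p 1 and the
    degenerate flag.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0 or n == 0:
        return ChiSquareResult(0.0, 1.0, True)
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / denom
    return ChiSquareResult(float(stat), float(stats.chi2.sf(stat, df=1)), False)


def bonferroni_threshold(alpha: float, n_symptoms: int, n_windows: int) -> float:
    """Family-wise corrected per-test level: alpha / (symptoms x windows)."""
    if alpha <= 0 or alpha > 1:
        raise TemporalStatsError("alpha must be in (0, 1]")
    if n_symptoms <= 0 or n_windows <= 0:
        raise TemporalStatsError("test counts must be positive")
    return alpha / (n_symptoms * n_windows)


def _as_hits(data, lexicon: SymptomLexicon | None) -> pd.DataFrame:
    """Accept precomputed hits (user_id, timestamp, symptom) or raw events."""
    if isinstance(data, pd.DataFrame) and "symptom" in data.columns:
        return data
    if lexicon is None:
        raise TemporalStatsError(
            "raw events were supplied without a lexicon to match them against"
        )
    return symptom_hits(data, lexicon)


def _user_universe(data, users: Iterable[str] | None) -> pd.Index:
    if users is not None:
        return pd.Index(pd.unique(pd.Series(list(users), dtype=object)))
    from .lexicon import _events_frame  # denominator = users present in the data

    return pd.Index(_events_frame(data)["user_id"].unique())


def symptom_user_probability(
    data,
    symptom: str,
    lexicon: SymptomLexicon | None = None,
    users: Iterable[str] | None = None,
    period: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> float:
    """Fraction of users with >= 1 query mentioning ``symptom``.

    ``data`` may be a SearchLog, an event DataFrame (needs ``lexicon``),
    a UserHistory collection, or a precomputed hit table.  ``users``
    fixes the denominator; by default it is every user appearing in the
    data.  ``period`` restricts matching to ``[start, end)``.
    """
    universe = _user_universe(data, users)
    if not len(universe):
        raise TemporalStatsError("empty user set")
    hits = _as_hits(data, lexicon)
    hits = hits[hits["symptom"].eq(symptom) & hits["user_id"].isin(universe)]
    if period is not None:
        lo, hi = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        hits = hits[(hits["timestamp"] >= lo) & (hits["timestamp"] < hi)]
    return hits["user_id"].nunique() / len(universe)


def probability_ratio_screen(
    target,
    comparison,
    lexicon: SymptomLexicon | None = None,
    symptoms: Sequence[str] | None = None,
    target_users: Iterable[str] | None = None,
    comparison_users: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-symptom target/comparison probability ratios, ranked descending.

    Returns a DataFrame (symptom, p_target, p_comparison, ratio, rank)
    with one row per symptom.  Symptoms never queried by the comparison
    population get an undefined (NaN) ratio and rank and are listed after
    the ranked rows.
    """
    if symptoms is None:
        if lexicon is None:
            raise TemporalStatsError("either symptoms or a lexicon must be given")
        symptoms = lexicon.symptoms
    t_universe = _user_universe(target, target_users)
    c_universe = _user_universe(comparison, comparison_users)
    if not len(t_universe) or not len(c_universe):
        raise TemporalStatsError("both populations must be non-empty")
    t_hits = _as_hits(target, lexicon)
    c_hits = _as_hits(comparison, lexicon)
    t_hits = t_hits[t_hits["user_id"].isin(t_universe)]
    c_hits = c_hits[c_hits["user_id"].isin(c_universe)]
    t_counts = t_hits.groupby("symptom")["user_id"].nunique()
    c_counts = c_hits.groupby("symptom")["user_id"].nunique()
    rows = []
    for sym in symptoms:
        p_t = int(t_counts.get(sym, 0)) / len(t_universe)
        p_c = int(c_counts.get(sym, 0)) / len(c_universe)
        rows.append((sym, p_t, p_c, p_t / p_c if p_c > 0 else np.nan))
    df = pd.DataFrame(rows, columns=["symptom", "p_target", "p_comparison", "ratio"])
    df = df.sort_values(
        ["ratio", "symptom"], ascending=[False, True], na_position="last", kind="stable"
    ).reset_index(drop=True)
    defined = df["ratio"].notna()
    df["rank"] = np.where(defined, defined.cumsum(), np.nan)
    return df


def _baseline_interval(window: WindowSpec, baseline: str) -> tuple[float, float]:
    if baseline == "pre_leadup":
        return (-LEAD_UP_DAYS - window.length_days, -LEAD_UP_DAYS)
    if baseline == "full_history":
        return (-np.inf, -LEAD_UP_DAYS)
    raise TemporalStatsError(f"unknown baseline mode {baseline!r}")


def _eligible_users(
    index_times: pd.Series,
    windows: Sequence[WindowSpec],
    baseline: str,
    span_start: pd.Timestamp | None,
) -> pd.Series:
    """Users whose observation covers both the lead-up and the baseline."""
    if span_start is None:
        return index_times
    span_start = pd.Timestamp(span_start)
    if baseline == "pre_leadup":
        need = LEAD_UP_DAYS + max(w.length_days for w in windows)
        ok = index_times - pd.Timedelta(days=need) >= span_start
    else:  # full_history: at least one day of pre-lead-up observation
        ok = index_times - pd.Timedelta(days=LEAD_UP_DAYS + 1) >= span_start
    return index_times[ok]


def _coerce_index_times(index_times) -> pd.Series:
    if isinstance(index_times, Mapping):
        index_times = pd.Series(index_times)
    s = pd.Series(pd.to_datetime(index_times.to_numpy()), index=index_times.index)
    s.index.name = "user_id"
    return s


def build_window_table(
    data,
    index_times,
    symptom: str,
    window: WindowSpec,
    lexicon: SymptomLexicon | None = None,
    baseline: str = "pre_leadup",
    span_start: pd.Timestamp | None = None,
) -> ContingencyTable:
    """The 2x2 person-count table for one symptom and one window.

    ``index_times`` maps target user ids to their index instants; every
    mapped user who is observationally eligible contributes to exactly
    one cell of each margin, so a + c == b + d == number evaluated.
    """
    idx = _coerce_index_times(index_times)
    eligible = _eligible_users(idx, [window], baseline, span_start)
    if not len(eligible):
        raise TemporalStatsError("no evaluable users (baseline does not fit the span)")
    hits = _as_hits(data, lexicon)
    hits = hits[hits["symptom"].eq(symptom)]
    counts = _window_baseline_counts(hits, eligible, window, baseline, span_start)
    a, b = counts
    n = len(eligible)
    return ContingencyTable(a=a, b=b, c=n - a, d=n - b)


def _window_baseline_counts(
    sym_hits: pd.DataFrame,
    eligible: pd.Series,
    window: WindowSpec,
    baseline: str,
    span_start: pd.Timestamp | None,
) -> tuple[int, int]:
    """(#users with a hit in the window, #users with a hit in the baseline)."""
    h = sym_hits[sym_hits["user_id"].isin(eligible.index)]
    if not len(h):
        return 0, 0
    idx = h["user_id"].map(eligible)
    off = (h["timestamp"] - idx).dt.total_seconds() / 86_400.0
    in_w = (off >= window.start_days) & (off < window.end_days)
    b_lo, b_hi = _baseline_interval(window, baseline)
    in_b = (off >= b_lo) & (off < b_hi)
    if span_start is not None:
        in_b &= h["timestamp"] >= pd.Timestamp(span_start)
    return int(h.loc[in_w, "user_id"].nunique()), int(h.loc[in_b, "user_id"].nunique())


@dataclasses.dataclass
class TemporalScreenResult:
    """Per-(symptom, window) results plus the testing metadata.

    ``table`` columns: symptom, window, A, B, C, D, p_window, p_baseline,
    chi_square, p_value, degenerate, significant.
    """

    table: pd.DataFrame
    n_symptoms_tested: int
    n_windows: int
    alpha: float
    corrected_alpha: float
    n_users_evaluated: int
    n_users_dropped: int
    baseline: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def temporal_screen(
    data,
    index_times,
    lexicon: SymptomLexicon | None = None,
    symptoms: Sequence[str] | None = None,
    windows: Sequence[WindowSpec] = DEFAULT_WINDOWS,
    alpha: float = 0.05,
    baseline: str = "pre_leadup",
    continuity: bool = False,
    span_start: pd.Timestamp | None = None,
) -> TemporalScreenResult:
    """Chi-square screen of every (symptom, window) pair.

    A pair is significant iff the window probability exceeds the baseline
    probability *and* its p-value clears the Bonferroni threshold
    ``alpha / (n_symptoms_tested * n_windows)``, where
    ``n_symptoms_tested`` is the size of the symptom universe actually
    screened (the supplied lexicon or symptom list — never a hard-coded
    count).
    """
    if symptoms is None:
        if lexicon is None:
            raise TemporalStatsError("either symptoms or a lexicon must be given")
        symptoms = lexicon.symptoms
    if not len(symptoms):
        raise TemporalStatsError("no symptoms to test")
    if not len(windows):
        raise TemporalStatsError("no windows to test")
    idx = _coerce_index_times(index_times)
    if not len(idx):
        raise TemporalStatsError("no target users with index times")
    eligible = _eligible_users(idx, windows, baseline, span_start)
    n_eval, n_drop = len(eligible), len(idx) - len(eligible)
    if n_eval == 0:
        raise TemporalStatsError("no evaluable users (baseline does not fit the span)")
    hits = _as_hits(data, lexicon)
    hits = hits[hits["user_id"].isin(eligible.index)]
    corrected = bonferroni_threshold(alpha, len(symptoms), len(windows))
    rows = []
    by_symptom = dict(tuple(hits.groupby("symptom"))) if len(hits) else {}
    empty = hits.iloc[0:0]
    for sym in symptoms:
        sym_hits = by_symptom.get(sym, empty)
        for w in windows:
            a, b = _window_baseline_counts(sym_hits, eligible, w, baseline, span_start)
            tab = ContingencyTable(a=a, b=b, c=n_eval - a, d=n_eval - b)
            chi = pearson_chi_square(tab, continuity=continuity)
            signif = (
                not chi.degenerate
                and tab.p_window > tab.p_baseline
                and chi.p_value < corrected
            )
            rows.append(
                (
                    sym, w.label, tab.a, tab.b, tab.c, tab.d,
                    tab.p_window, tab.p_baseline,
                    chi.statistic, chi.p_value, chi.degenerate, signif,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "symptom", "window", "A", "B", "C", "D",
            "p_window", "p_baseline", "chi_square", "p_value",
            "degenerate", "significant",
        ],
    )
    return TemporalScreenResult(
        table=table,
        n_symptoms_tested=len(symptoms),
        n_windows=len(windows),
        alpha=alpha,
        corrected_alpha=corrected,
        n_users_evaluated=n_eval,
        n_users_dropped=n_drop,
        baseline=baseline,
    )


def classify_persistence(
    results: pd.DataFrame | TemporalScreenResult,
    windows: Sequence[WindowSpec] = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Assign each symptom exactly one persistence category.

    Requires exactly one result row per (symptom, window).  Returns a
    DataFrame (symptom, category, significant_windows).
    """
    table = results.table if isinstance(results, TemporalScreenResult) else results
    labels = [w.label for w in windows]
    if len(set(labels)) != 3:
        raise TemporalStatsError("persistence classification expects three distinct windows")
    distal_lbl, middle_lbl, proximal_lbl = labels
    rows = []
    for sym, grp in table.groupby("symptom", sort=True):
        if sorted(grp["window"]) != sorted(labels):
            raise TemporalStatsError(
                f"symptom {sym!r} needs exactly one result per window, got {list(grp['window'])}"
            )
        sig = set(grp.loc[grp["significant"], "window"])
        if len(sig) == 3:
            cat = "persistent"
        elif len(sig) == 2:
            cat = "near_persistent"
        elif sig == {proximal_lbl}:
            cat = "immediate"
        elif sig == {distal_lbl}:
            cat = "distal"
        elif sig == {middle_lbl}:
            cat = "middle_only"
        else:
            cat = "none"
        rows.append((sym, cat, ",".join(l for l in labels if l in sig)))
    return pd.DataFrame(rows, columns=["symptom", "category", "significant_windows"])


def compare_subgroups(
    subgroup_a,
    subgroup_b,
    symptom: str,
    lexicon: SymptomLexicon | None = None,
    users_a: Iterable[str] | None = None,
    users_b: Iterable[str] | None = None,
    continuity: bool = False,
) -> ChiSquareResult:
    """Chi-square test of symptom-querying prevalence between two subgroups.

    Builds the 2x2 (subgroup x ever-queried indicator) table and applies
    the same Pearson statistic as the temporal screen.
    """
    ua = _user_universe(subgroup_a, users_a)
    ub = _user_universe(subgroup_b, users_b)
    if not len(ua) or not len(ub):
        raise TemporalStatsError("both subgroups must be non-empty")
    ha = _as_hits(subgroup_a, lexicon)
    hb = _as_hits(subgroup_b, lexicon)
    qa = ha.loc[ha["symptom"].eq(symptom) & ha["user_id"].isin(ua), "user_id"].nunique()
    qb = hb.loc[hb["symptom"].eq(symptom) & hb["user_id"].isin(ub), "user_id"].nunique()
    tab = ContingencyTable(a=int(qa), b=int(qb), c=len(ua) - int(qa), d=len(ub) - int(qb))
    return pearson_chi_square(tab, continuity=continuity)
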