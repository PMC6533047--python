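"""The 2x2 chi-square, ratio screen, temporal screen, and persistence taxonomy."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from stepscreen import (
    DEFAULT_SYMPTOMS,
    DEFAULT_WINDOWS,
    ContingencyTable,
    PlantedEffect,
    TemporalStatsError,
    WindowSpec,
    bonferroni_threshold,
    build_window_table,
    classify_persistence,
    compare_subgroups,
    lexicon_for,
    null_config,
    pearson_chi_square,
    probability_ratio_screen,
    simulate_logs,
    symptom_hits,
    symptom_user_probability,
    temporal_screen,
    user_histories,
)


def hits_frame(rows):
    """rows: (user_id, iso_timestamp, symptom)"""
    return pd.DataFrame(
        {
            "user_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime([r[1] for r in rows]),
            "symptom": [r[2] for r in rows],
        }
    )


class TestPearsonChiSquare:
    def test_closed_form_example(self):
        res = pearson_chi_square(ContingencyTable(a=10, c=90, b=5, d=95))
        expected = 200 * (10 * 95 - 90 * 5) ** 2 / (15 * 185 * 100 * 100)
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(1.801801801, rel=1e-9)
        # p-value against a numerical-integration oracle for the chi2(1) tail
        tail, _ = integrate.quad(lambda x: stats.chi2.pdf(x, 1), res.statistic, np.inf)
        assert res.p_value == pytest.approx(tail, rel=1e-8)

    def test_identical_rows_give_zero_statistic(self):
        res = pearson_chi_square(ContingencyTable(a=5, b=5, c=5, d=5))
        assert res.statistic == 0.0 and res.p_value == 1.0 and not res.degenerate

    def test_zero_margin_is_degenerate(self):
        res = pearson_chi_square(ContingencyTable(a=0, c=0, b=3, d=7))
        assert res == (0.0, 1.0, True)

    def test_negative_cell_rejected(self):
        with pytest.raises(TemporalStatsError):
            ContingencyTable(a=-1, b=0, c=0, d=0)

    @pytest.mark.parametrize("continuity", [False, True])
    def test_matches_reference_implementation_on_random_tables(self, continuity):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 200, size=4)
            ours = pearson_chi_square(
                ContingencyTable(a=int(a), b=int(b), c=int(c), d=int(d)),
                continuity=continuity,
            )
            obs = np.array([[a, c], [b, d]])
            if ours.degenerate:
                continue
            ref_stat, ref_p, _, _ = stats.chi2_contingency(obs, correction=continuity)
            assert abs(ours.statistic - ref_stat) < 1e-9
            assert ours.p_value == pytest.approx(ref_p, abs=1e-12)


class TestBonferroni:
    def test_published_style_correction(self):
        thr = bonferroni_threshold(0.05, 152, 3)
        assert thr == pytest.approx(0.05 / 456)
        # two significant figures, as such thresholds are conventionally printed
        assert float(f"{thr:.2g}") == 0.00011

    @pytest.mark.parametrize(
        "alpha,n_sym,n_win,expected", [(0.05, 1, 1, 0.05), (0.06, 3, 2, 0.01)]
    )
    def test_arithmetic(self, alpha, n_sym, n_win, expected):
        assert bonferroni_threshold(alpha, n_sym, n_win) == pytest.approx(expected)

    def test_zero_counts_rejected(self):
        with pytest.raises(TemporalStatsError):
            bonferroni_threshold(0.05, 0, 3)


class TestSymptomUserProbability:
    def test_five_of_one_hundred(self):
        hits = hits_frame([(f"u{i}", "2017-01-01T00:00:00", "cough") for i in range(5)])
        users = [f"u{i}" for i in range(100)]
        assert symptom_user_probability(hits, "cough", users=users) == pytest.approx(0.05)

    def test_never_queried_is_zero(self):
        hits = hits_frame([("u0", "2017-01-01T00:00:00", "cough")])
        assert symptom_user_probability(hits, "fever", users=["u0", "u1"]) == 0.0

    def test_empty_user_set_rejected(self):
        with pytest.raises(TemporalStatsError):
            symptom_user_probability(hits_frame([]), "cough", users=[])

    def test_matches_bernoulli_complement_closed_form(self):
        # P(>=1 query in 30 days) = 1 - (1-p)^30 under daily Bernoulli emission
        cfg = null_config(
            5, 101, n_target_users=0, n_comparison_users=2000,
            span_start="2017-01-01", span_end="2017-03-02",
        )
        log, gt = simulate_logs(cfg)
        hits = symptom_hits(log, lexicon_for(cfg))
        period = (pd.Timestamp("2017-01-01"), pd.Timestamp("2017-01-31"))
        p_hat = symptom_user_probability(
            hits, cfg.symptoms[0], users=gt.assignments["user_id"], period=period
        )
        p_true = 1 - (1 - cfg.symptom_base_prob) ** 30
        se = np.sqrt(p_true * (1 - p_true) / 2000)
        assert abs(p_hat - p_true) < 3 * se

    def test_accepts_user_histories(self, tiny_lexicon):
        from conftest import make_log

        log = make_log(
            [
                ("u1", "2017-01-01T00:00:00", "sweating"),
                ("u2", "2017-01-01T00:00:00", "weather"),
            ]
        )
        hist = user_histories(log)
        p = symptom_user_probability(hist, "diaphoresis", lexicon=tiny_lexicon)
        assert p == pytest.approx(0.5)


class TestProbabilityRatioScreen:
    def test_ranking_and_arithmetic(self):
        t_hits = hits_frame(
            [(f"u{i}", "2017-01-01T00:00:00", "cough") for i in range(5)]
            + [(f"u{i}", "2017-01-01T00:00:00", "fever") for i in range(4)]
        )
        c_hits = hits_frame(
            [("c0", "2017-01-01T00:00:00", "cough")]
            + [(f"c{i}", "2017-01-01T00:00:00", "fever") for i in range(20)]
        )
        out = probability_ratio_screen(
            t_hits, c_hits,
            symptoms=["cough", "fever", "rash"],
            target_users=[f"u{i}" for i in range(100)],
            comparison_users=[f"c{i}" for i in range(1000)],
        )
        ranked = out.set_index("symptom")
        assert ranked.loc["cough", "ratio"] == pytest.approx(0.05 / 0.001)
        assert ranked.loc["fever", "ratio"] == pytest.approx(0.04 / 0.02)
        assert list(out["symptom"][:2]) == ["cough", "fever"]
        assert list(out["rank"][:2]) == [1, 2]
        # rash never queried by comparison users: undefined ratio, listed last
        assert np.isnan(ranked.loc["rash", "ratio"])
        assert out["symptom"].iloc[-1] == "rash"

    def test_identical_populations_have_unit_ratios(self):
        hits = hits_frame(
            [(f"u{i}", "2017-01-01T00:00:00", "cough") for i in range(7)]
        )
        users = [f"u{i}" for i in range(50)]
        out = probability_ratio_screen(
            hits, hits, symptoms=["cough"], target_users=users, comparison_users=users
        )
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_whole_history_elevation_is_ranked_first(self):
        sym = DEFAULT_SYMPTOMS[0]
        cfg = null_config(
            10, 71, n_target_users=500, n_comparison_users=5000,
            target_history_multipliers={sym: 10.0},
        )
        log, gt = simulate_logs(cfg)
        hits = symptom_hits(log, lexicon_for(cfg))
        truth = gt.assignments
        t_users = truth.loc[truth["role"] == "target", "user_id"]
        c_users = truth.loc[truth["role"] == "comparison", "user_id"]
        out = probability_ratio_screen(
            hits[hits["user_id"].isin(t_users)],
            hits[hits["user_id"].isin(c_users)],
            symptoms=cfg.symptoms,
            target_users=t_users,
            comparison_users=c_users,
        )
        assert out["symptom"].iloc[0] == sym

    def test_null_ratios_concentrate_around_one(self):
        cfg = null_config(10, 83, n_target_users=2000, n_comparison_users=20000)
        log, gt = simulate_logs(cfg)
        hits = symptom_hits(log, lexicon_for(cfg))
        truth = gt.assignments
        t_users = truth.loc[truth["role"] == "target", "user_id"]
        c_users = truth.loc[truth["role"] == "comparison", "user_id"]
        out = probability_ratio_screen(
            hits[hits["user_id"].isin(t_users)],
            hits[hits["user_id"].isin(c_users)],
            symptoms=cfg.symptoms,
            target_users=t_users,
            comparison_users=c_users,
        )
        assert 0.8 <= out["ratio"].median() <= 1.25


IDX = pd.Series(
    pd.to_datetime(["2017-07-10", "2017-07-10", "2017-07-10"]),
    index=pd.Index(["u1", "u2", "u3"], name="user_id"),
)
#: u1 queries the symptom 3 days before index, u2 33 days before, u3 never.
TOY_HITS = hits_frame(
    [
        ("u1", "2017-07-07T00:00:00", "cough"),
        ("u2", "2017-06-07T00:00:00", "cough"),
    ]
)


class TestBuildWindowTable:
    def test_hand_enumerated_proximal_table(self):
        tab = build_window_table(TOY_HITS, IDX, "cough", DEFAULT_WINDOWS[2])
        assert (tab.a, tab.c, tab.b, tab.d) == (1, 2, 1, 2)

    def test_hand_enumerated_distal_table(self):
        tab = build_window_table(TOY_HITS, IDX, "cough", DEFAULT_WINDOWS[0])
        assert (tab.a, tab.c, tab.b, tab.d) == (0, 3, 1, 2)

    def test_full_history_baseline_reaches_further_back(self):
        far = hits_frame([("u3", "2017-05-01T00:00:00", "cough")])  # 70 days out
        hits = pd.concat([TOY_HITS, far], ignore_index=True)
        matched = build_window_table(hits, IDX, "cough", DEFAULT_WINDOWS[2])
        full = build_window_table(
            hits, IDX, "cough", DEFAULT_WINDOWS[2], baseline="full_history",
            span_start=pd.Timestamp("2016-11-01"),
        )
        assert matched.b == 1  # u3's old query is outside the matched slice
        assert full.b == 2

    def test_saturated_table(self):
        rows = []
        for u in ("u1", "u2", "u3"):
            rows += [(u, "2017-07-05T00:00:00", "cough"), (u, "2017-06-08T00:00:00", "cough")]
        tab = build_window_table(hits_frame(rows), IDX, "cough", DEFAULT_WINDOWS[2])
        assert (tab.a, tab.b, tab.c, tab.d) == (3, 3, 0, 0)
        assert pearson_chi_square(tab).degenerate

    def test_margins_equal_evaluated_users(self):
        for w in DEFAULT_WINDOWS:
            tab = build_window_table(TOY_HITS, IDX, "cough", w)
            assert tab.a + tab.c == tab.b + tab.d == 3


class TestTemporalScreen:
    def test_single_user_cohort_runs_without_significance(self):
        res = temporal_screen(
            TOY_HITS[TOY_HITS["user_id"] == "u1"],
            IDX[["u1"]],
            symptoms=["cough", "fever"],
        )
        assert len(res.table) == 6
        assert not res.table["significant"].any()
        assert res.n_users_evaluated == 1

    def test_conservation_on_simulated_cohort(self):
        cfg = null_config(5, 43, n_target_users=100, n_comparison_users=0)
        log, gt = simulate_logs(cfg)
        hits = symptom_hits(log, lexicon_for(cfg))
        truth = gt.assignments.set_index("user_id")
        res = temporal_screen(
            hits, truth["index_time"].dropna(), symptoms=cfg.symptoms,
            span_start=log.span_start,
        )
        n = res.n_users_evaluated
        assert ((res.table["A"] + res.table["C"]) == n).all()
        assert ((res.table["B"] + res.table["D"]) == n).all()
        assert res.corrected_alpha == pytest.approx(0.05 / (5 * 3))

    def test_detection_rate_is_monotone_in_effect_size(self):
        from stepscreen.experiments import planted_replicate, spawn_seeds

        seeds = spawn_seeds(202, 4)
        detected = {}
        for mult in (2.0, 8.0):
            detected[mult] = sum(
                "proximal"
                in planted_replicate(
                    s, multiplier=mult, n_target=500, n_symptoms=10, n_comparison=200
                )["significant_windows"]
                for s in seeds
            )
        assert detected[8.0] >= detected[2.0]
        assert detected[8.0] == len(seeds)  # a x8 effect at n=500 is overwhelming

    def test_significance_requires_elevated_window_probability(self):
        # deflated window: many baseline hits, none in-window -> never significant
        rows = [(f"u{i}", "2017-06-08T00:00:00", "cough") for i in range(50)]
        idx = pd.Series(
            pd.to_datetime(["2017-07-10"] * 60),
            index=pd.Index([f"u{i}" for i in range(60)], name="user_id"),
        )
        res = temporal_screen(hits_frame(rows), idx, symptoms=["cough"])
        prox = res.table[res.table["window"] == "proximal"].iloc[0]
        assert prox["p_window"] < prox["p_baseline"]
        assert not prox["significant"]


class TestClassifyPersistence:
    def _table(self, sig_windows):
        rows = []
        for w in ("distal", "middle", "proximal"):
            rows.append(("s", w, w in sig_windows))
        return pd.DataFrame(rows, columns=["symptom", "window", "significant"])

    @pytest.mark.parametrize(
        "sig,expected",
        [
            ({"distal", "middle", "proximal"}, "persistent"),
            ({"middle", "proximal"}, "near_persistent"),
            ({"distal", "proximal"}, "near_persistent"),
            ({"proximal"}, "immediate"),
            ({"distal"}, "distal"),
            ({"middle"}, "middle_only"),
            (set(), "none"),
        ],
    )
    def test_taxonomy(self, sig, expected):
        out = classify_persistence(self._table(sig))
        assert out["category"].iloc[0] == expected
        assert set(out["significant_windows"].iloc[0].split(",")) >= (sig or {""})

    def test_each_symptom_appears_exactly_once(self):
        rng = np.random.default_rng(1)
        rows = []
        syms = [f"s{i}" for i in range(25)]
        for s in syms:
            for w in ("distal", "middle", "proximal"):
                rows.append((s, w, bool(rng.random() < 0.4)))
        out = classify_persistence(
            pd.DataFrame(rows, columns=["symptom", "window", "significant"])
        )
        assert sorted(out["symptom"]) == sorted(syms)
        assert out["category"].isin(
            ["persistent", "near_persistent", "immediate", "distal", "middle_only", "none"]
        ).all()

    def test_missing_window_rows_rejected(self):
        bad = pd.DataFrame(
            [("s", "proximal", True)], columns=["symptom", "window", "significant"]
        )
        with pytest.raises(TemporalStatsError):
            classify_persistence(bad)


class TestCompareSubgroups:
    def test_identical_frequencies_give_zero(self):
        h = hits_frame([(f"u{i}", "2017-01-01T00:00:00", "cough") for i in range(10)])
        res = compare_subgroups(
            h, h, "cough",
            users_a=[f"u{i}" for i in range(40)],
            users_b=[f"u{i}" for i in range(40)],
        )
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form(self):
        ha = hits_frame([(f"a{i}", "2017-01-01T00:00:00", "cough") for i in range(30)])
        hb = hits_frame([(f"b{i}", "2017-01-01T00:00:00", "cough") for i in range(10)])
        res = compare_subgroups(
            ha, hb, "cough",
            users_a=[f"a{i}" for i in range(100)],
            users_b=[f"b{i}" for i in range(100)],
        )
        # n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)] with a=30,b=10,c=70,d=90
        expected = 200 * (30 * 90 - 10 * 70) ** 2 / (40 * 160 * 100 * 100)
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(12.5)

    def test_random_subset_is_rarely_significant(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        reps = 20
        for _ in range(reps):
            queried = rng.random(400) < 0.15
            users = np.array([f"u{i}" for i in range(400)])
            sub = rng.choice(400, size=150, replace=False)
            mask = np.zeros(400, dtype=bool)
            mask[sub] = True
            ha = hits_frame(
                [(u, "2017-01-01T00:00:00", "cough") for u in users[queried & mask]]
            )
            hb = hits_frame(
                [(u, "2017-01-01T00:00:00", "cough") for u in users[queried & ~mask]]
            )
            res = compare_subgroups(
                ha, hb, "cough", users_a=users[mask], users_b=users[~mask]
            )
            n_sig += res.p_value < 0.05
        assert n_sig <= reps - int(0.9 * reps)  # >=90% non-significant


def test_window_specs_partition_the_lead_up():
    lengths = sorted((w.start_days, w.end_days) for w in DEFAULT_WINDOWS)
    assert lengths == [(-30, -14), (-14, -7), (-7, 0)]
    covered = set()
    for lo, hi in lengths:
        days = set(range(int(lo), int(hi)))
        assert not covered & days
        covered |= days
    assert covered == set(range(-30, 0))
    with pytest.raises(TemporalStatsError):
        WindowSpec("bad", 0, -7)
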