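# Methods

`stepscreen` implements a case-comparison screen over anonymized
search-engine query logs: it identifies people who transition from
querying medical symptoms to querying 12-step addiction-program
information (Alcoholics Anonymous / Narcotics Anonymous), and tests
which symptoms are queried at elevated rates, and in which pre-index
time windows. Because population-scale commercial search logs are
proprietary, the package ships a first-class synthetic log generator
that reproduces the statistical structure the screen assumes, together
with a ground-truth ledger of planted effects, so every statistical
property of the pipeline can be tested end to end.

## Data model

A log is a table of `(user_id, timestamp, query_text, clicked_url)`
events over a declared half-open observation span (default nine months,
2016-11-01 to 2017-08-01). Timestamps are UTC at one-second resolution;
day boundaries are UTC midnights. Ties in timestamp preserve input
order so every downstream computation is deterministic.

## Cohort construction

1. **Seed queries.** A curated, labelled set of 12-step resource URLs
   (AA or NA) is the anchor. Any normalized query text (lowercased,
   punctuation stripped, whitespace collapsed) issued with a click to a
   seed URL by at least `min_users` distinct users becomes a *seed
   query*. The production-scale default is `min_users = 50`; simulation
   harnesses use 10 because synthetic cohorts are orders of magnitude
   smaller. Each seed query is labelled by the majority label of its
   clicked seed URLs (BOTH on ties) and flagged as meeting-related when
   its tokens include "meeting"/"meetings".
2. **Target cohort.** The *index window* is the final calendar month of
   the span. Users whose first seed-query event falls in the index
   window, with no seed queries before it, are *targets*; their
   *index time* is that first seed-query timestamp. Users with earlier
   seed queries are excluded from both populations — they are prior
   treatment-information seekers and would contaminate the comparison
   baseline. Everyone else is the *comparison* population (the
   "all other users" reading: the comparison group excludes the
   target cohort).
3. **Subgroups.** A target is AA if all their index-window seed queries
   are AA-labelled, NA if all NA, BOTH otherwise; the pipeline asserts
   `AA + NA + BOTH == target` on every run. The *meeting subsample*
   comprises targets whose first seed query is meeting-related.

## Lexicon matching

The symptom lexicon maps canonical clinical terms to colloquial synonym
phrases ("diaphoresis" ← "sweating"). A query mentions a symptom when a
synonym occurs as a contiguous whole-word token sequence — substring
matches are rejected so "crash" never matches "rash". Each synonym
phrase belongs to exactly one canonical symptom; an ambiguous lexicon is
a load-time error because the person-level 2×2 counting below needs an
unambiguous indicator. The packaged ~40-symptom lexicon is a compact
fixture: real deployments should supply a comprehensive lexicon file
(the pipeline takes it as an input and never hard-codes its size).

## Statistical screens

**Between-group ratio.** For each symptom *s*,
`ratio(s) = P(target user ever queries s) / P(comparison user ever queries s)`,
ranked descending. Symptoms never queried by the comparison population
are reported separately with an undefined ratio.

**Within-person temporal screen.** Three disjoint windows partition the
30 days before each target's index instant:

| label    | offset interval (days) | length |
|----------|------------------------|--------|
| distal   | [−30, −14)             | 16     |
| middle   | [−14, −7)              | 7      |
| proximal | [−7, 0)                | 7      |

For each (symptom, window) pair a 2×2 person-count table is built:
A = targets with ≥ 1 symptom query in the window, C = the rest;
B = targets with ≥ 1 symptom query in the *baseline period*, D = the
rest, so A + C = B + D = number of evaluated users. The table is tested
with Pearson's chi-square (closed form
`n(AD−BC)² / [(A+B)(C+D)(A+C)(B+D)]`, 1 df, no continuity correction by
default; Yates correction available as a flag). A pair is *significant*
iff `p_window > p_baseline` **and** `p < α / (n_symptoms_tested × n_windows)`
(Bonferroni; α = .05 by default; the divisor always uses the number of
symptoms actually screened, never a fixed constant).

**Baseline choice.** The default baseline for a window of length L is
the duration-matched interval [−30−L, −30) days, immediately before the
30-day lead-up. The alternative — all activity strictly before
index−30d (`baseline="full_history"`) — is retained as a sensitivity
variant but is not the default, because the probability of *ever*
querying a symptom grows with exposure time: over a multi-month history
even a modest per-day rate makes `p_baseline` approach 1, so a genuine
pre-index surge confined to a 7-day window can never satisfy
`p_window > p_baseline`. With equal exposure durations the two
proportions are directly comparable, the screen's one-sided condition
means what it says, and simulated effects of known size are recoverable.
The run metadata records which baseline was used; under `full_history`
the output flags the exposure-duration imbalance as a known bias source.

A worry worth recording: the 2×2 treats the window and baseline
indicators of the *same* person as independent samples. A paired
(McNemar-style) test would be more appropriate in principle; the
unpaired Pearson form is implemented because it is the field-standard
screen this package reproduces, and with disjoint window/baseline
periods and rare per-day rates the dependence is weak.

**Persistence taxonomy.** Per symptom, over its three window results:
significant in all three → *persistent*; exactly two →
*near_persistent*; proximal only → *immediate*; distal only → *distal*;
middle only → *middle_only*; otherwise *none*. Categories partition the
symptom set.

## Synthetic data generator

Each simulated user emits, independently:

* **Background queries** — a Poisson process at
  `background_query_rate = 0.1` queries/user-day, drawn from an
  invented-word vocabulary that can never match a symptom synonym or a
  seed query.
* **Symptom queries** — per symptom, per day, a Bernoulli draw at
  `symptom_base_prob = 0.01` (at most one query per symptom per day,
  matching the person-level counting of the screen). Targets and
  comparison users share the base rate, so between-group ratios are ≈ 1
  under the null.
* **Index event** — each target issues exactly one seed query, with a
  click to a seed URL, at a time uniform over the final month.
  Comparison users issue none.

Planted effects multiply a target's symptom probability inside one
named window. Target users' symptom-emission days are aligned to their
own index instant (day boundaries at `index − k·24h`) rather than
calendar midnights: with calendar days, a planted window effect leaks
roughly half a day of elevated rate across each window boundary, which
at n = 2000 is enough to make a neighbouring window spuriously
significant and misclassify a proximal-only effect as near-persistent.
Comparison users use calendar days. Post-index target activity
continues at the base rate. A whole-history multiplier
(`target_history_multipliers`) is available to drive the between-group
ratio screen.

Defaults were chosen once for statistical power at desk scale (null
harness: 500 target / 5000 comparison users, 20 symptoms), not for
realism — real per-symptom query rates are far below 0.01/day and real
cohorts are far larger. Other deliberate idealizations: no seasonality
or weekday structure, no query-language variation beyond fixed
templates, no shared browsers, one seed query per target, no
demographics. Tests passing on this generator therefore demonstrate
that the *pipeline machinery and inference* behave correctly under the
model's assumptions; they say nothing about lexicon coverage or
behavioural realism in production logs.

## Numerical and degenerate-case conventions

* Chi-square on a table with any zero margin returns statistic 0,
  p = 1, and a degenerate flag (never significant).
* Targets whose index time leaves no room for the lead-up plus baseline
  inside the span are dropped from the temporal screen and counted in
  the run metadata; a screen with zero evaluable users is an error.
* Undefined ratios (comparison probability 0) are NaN, ranked last.
* Replicate seeds for Monte-Carlo studies are spawned from one master
  seed via `numpy.random.SeedSequence`; every simulation is a pure
  function of its configuration including `rng_seed`.
* Result tables are written with `%.12g` float formatting, making
  repeated runs byte-identical.

## Problem sizes used in the checks

The type-I study uses 200 replicates of the 20-symptom null at
500/5000 users (test suite) and 100 replicates in the reproduction
script; recovery studies use 50 (suite) / 30 (script) replicates at
n_target = 2000 with a ×8 effect. At these sizes the proximal-window
effect (p_window ≈ 0.44 vs matched baseline ≈ 0.07) is detected with
overwhelming power, while the family-wise false-positive rate under the
null stays near the nominal 5% bound (the one-sided
`p_window > p_baseline` condition makes it conservative).

## Known limitations

* The unpaired chi-square on paired person-level indicators (above).
* No duration normalization is needed under the matched baseline, but
  the three windows still differ in length (16/7/7 days), so per-window
  probabilities are not directly comparable *across* windows — only
  window-vs-baseline contrasts are interpreted.
* Bonferroni control is conservative for correlated symptoms; no FDR
  alternative is provided.
* The packaged lexicon and seed-URL list are fixtures, not curated
  clinical resources.
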