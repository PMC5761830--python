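# dualforage

Coordinated chick provisioning in dual-foraging seabirds: trip
classification, Monte Carlo randomization tests for pair coordination, and
chick-growth analysis.

## The scientific problem

Many pelagic seabirds provision their single chick with a *dual foraging
strategy*: short trips (ST, mean ~1.9 h) that deliver food to the chick
alternate with long trips (LT, mean ~12.8 h) that mainly serve adult
self-maintenance.  If both parents leave on long trips at the same time, the
chick faces long fasts; if their schedules are offset — one making short
provisioning trips while the other is away on a long one — food arrives
steadily.  This package implements the full analysis chain needed to test
whether breeding partners coordinate in this way, using nothing more than
binned colony attendance data: each bird of a marked pair is scored
present/absent at the colony every 10 minutes during continuous 48-h
observation sessions.

The pipeline:

1. **Trip classification.**  A foraging trip is a maximal run of colony
   absence.  Pooled log trip durations are bimodal; the ST/LT threshold *c*
   minimizes `Var(log d | d < c) + Var(log d | d ≥ c)` over all candidate
   splits (both variances with denominator *n*−1).  Trips clipped by the
   session boundaries are excluded, together with the partner's concurrent
   records, and sessions in which the female fed ≤ 1 time (brood desertion)
   are dropped.
2. **Randomization tests**, separately per pair-session.  Each bird's
   timeline is decomposed into activity *strings* (runs of CO / ST / LT
   windows).  The null shuffles trip strings uniformly over trip positions
   and colony strings over colony positions — keeping one colony string
   between consecutive trips, sampling everything without replacement — and
   rebuilds both timelines 10,000 times.  Two statistics are tested:
   the **overlap count** (windows with one bird on ST while the other is on
   LT; upper tail) and the **CV of inter-feeding intervals** (feedings pooled
   over both parents at each trip's end; lower tail).  The
   **coordination level** is `(obs − exp)/exp` with `exp` the null mean.
3. **Combination.**  Session p-values of a pair are combined with Stouffer's
   Z (`Z = Σ Φ⁻¹(1−pᵢ) / √k`); Fisher and logit methods are cross-checks.
   Study-level combinations are reported over all sessions and over per-pair
   combined values.
4. **Chick growth.**  Eight indicators per chick (mass at day 14–16, peak and
   fledging mass and day, mass recession, and two Specific Growth Rates
   `SGR = (ln m₂ − ln m₁) × ((t₂ − t₁) × 100)⁻¹`), reduced by PCA on z-scored
   variables; four ML linear mixed models with pair as random intercept
   relate coordination, feeding evenness, chick age and growth.

A seedable synthetic-data generator (`dualforage.simulate`) emulates the
study's structure — colony bouts of ~49 min (10–80 min), log-normal trip
mixtures, 48-h sessions on the 10-min grid, a tunable pair-coupling knob
`kappa`, and chick mass trajectories — so the whole pipeline runs and is
testable without any external data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
corpus (25 pairs, 1–5 sessions each, moderate coupling `kappa = 0.6`):

```bash
python analysis/01_simulate_corpus.py
python analysis/02_classify_trips.py
python analysis/03_randomization_tests.py
python analysis/04_combined_inference.py
python analysis/05_chick_growth_models.py
```

which prints (seed 0):

```
corpus: 25 pairs, 66 sessions, 1495 true trips, 49 chicks -> results/corpus
cut-off 6.42 h  (ST n=1109, mean 1.91 h; LT n=163, mean 12.69 h); 66 sessions, 0 excluded
st_lt_overlap: 65 informative sessions, mean index +0.199, median p_mid 0.362, overlap proportion 0.427 ± 0.155
interfeed_cv: study-level Z = 2.10, P = 0.0178 (k = 66 sessions)
st_lt_overlap: study-level Z = 2.91, P = 0.0018 (k = 65 sessions)
49 chicks; PC1+PC2 explain 54.9% of growth variance
b_relcv_vs_coordination      coordination_level   est  -0.4467 F(1,38) =  62.65  P = 0.0000
```

Reading: the estimated short/long cut-off (6.4 h) falls between the two trip
modes; pairs overlap ST-against-LT more often than the shuffle null expects
(positive mean coordination index, study-level Stouffer Z = 2.9); feedings
are more evenly spaced than chance (lower CV, Z = 2.1); and sessions with a
higher coordination level have lower relative interval CV (negative mixed
model slope) — while chick growth (PC1/PC2) shows no coordination effect, as
the generator builds none in by default.

The same stages are available as a console tool
(`dualforage simulate | classify | coordinate | combine | growth | report`)
and as library functions (`simulate_corpus`, `pair_sessions_from_records`,
`run_randomization`, `combine`, `growth_pca`, `run_full_pipeline`).

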