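# shuttleseq

Simulation and scoring of a touch-screen **behavioral-sequencing task with
serial reversal learning** — an operant assay of cognitive flexibility in
mice.

## The task and its metrics

Four nose-poke spots sit on a 2×2 grid. The two spots on one diagonal are
*rewarded*, the two on the other diagonal are *never-rewarded*. Of the two
rewarded spots exactly one is *active* at a time: poking it delivers a
pellet, ends the trial, and activates its diagonal partner — so sustained
reward requires shuttling along the rewarded diagonal while ignoring the
never-rewarded spots. A session is 100 such trials (45-minute cap). After
an acquisition phase, the rewarded and never-rewarded diagonals swap every
10 sessions ("serial reversal"), for 50 sessions in all.

Five per-session learning scores are computed from the poke-event log:

1. **Move-pattern rates** — each trial's first poke classified relative to
   the previous trial's correct spot as *diagonal* (its partner, the next
   correct spot), *adjacent* (either neighbour) or *re-entry* (the same
   spot). Chance: 25/50/25 %.
2. **First-choice never-rewarded rate** — % of trials whose first poke is
   at a never-rewarded spot. Chance: 50 %.
3. **Cumulative diagonal correct/error counts** over the first 150 pokes.
4. **Never-rewarded rate per 5-trial block** (all pokes, first 40 trials).
5. **First-choice re-entry rate** — the persistence metric.

Derived criteria include *sessions-to-criterion* (first session with a
first-choice never-rewarded rate below 30 %) and first-/final-three-session
stage aggregates. Group comparisons use Student's one-sample *t* against
chance, equal-variance two-sample *t*, and a group × session
repeated-measures analysis with Bonferroni-corrected per-session contrasts.

Because no animal data ship with the package, a synthetic-agent module
generates cohorts with the learning structure the analysis assumes: a
softmax policy over the four spots with a learned diagonal preference, an
acquired shuttling habit, a re-entry ("persistence") bias κ_re, and a
perseveration factor λ controlling how fast the old diagonal is unlearned
after a reversal. Two presets — `control` and `dysbiosis` (elevated κ_re,
λ < 1) — emulate the healthy and antibiotic-dysbiosis phenotypes. See
`docs/methods.md` for the model.

## Worked example

```sh
shuttleseq simulate --n-control 5 --n-dysbiosis 5 --seed 42 --out logs.csv
shuttleseq validate logs.csv
shuttleseq score logs.csv --out scores.csv
shuttleseq analyze scores.csv --out report
```

prints

```
wrote 134777 pokes (10 subjects x 50 sessions) to logs.csv
OK: 500 session log(s), 134777 pokes
wrote 2500 score rows for 500 sessions to scores.csv
wrote report/session_means.csv
wrote report/stage_aggregates.csv
wrote report/sessions_to_criterion.csv
wrote report/chance_tests.csv
```

The control group's first-choice never-rewarded rate starts near chance
(39.2 % in session 1), falls to 12.0 % by session 10, spikes above chance
after the first reversal (60.4 % in session 11), and recovers (15.2 % by
session 20). `sessions_to_criterion.csv` shows the dysbiosis group needing
more sessions than controls to fall below 30 % after reversals (e.g. 4 vs 3
in rev1), and `stage_aggregates.csv` shows its elevated re-entry rate over
the final three acquisition sessions (36.0 ± 1.7 % vs 25.6 ± 0.6 %;
two-sample *t* = −5.88, p = 0.0004 on the per-subject means):
persistence and perseveration phenotypes, respectively.

The same pipeline is available as library functions
(`shuttleseq.make_cohort`, `score_table`, `report`, …) for scripted use,
and `shuttleseq score`/`analyze` run on any poke-event CSV in the
documented schema — including logs from a real apparatus.

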