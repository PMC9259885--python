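# Methods

## Task model

The contingency engine (`shuttleseq.protocol`) is a discrete-event state
machine over four spots arranged on a 2×2 grid (spots 1, 2 on the top row,
3, 4 on the bottom; diagonal pairs {1, 4} and {2, 3}; two spots are
*adjacent* when they share a row or column). One diagonal pair is rewarded,
the other never-rewarded. Exactly one rewarded spot is active at a time;
poking it delivers a reward, ends the trial, and activates its diagonal
partner. Geometry is configurable through `SpotLayout`, but "diagonal" and
"adjacent" only have their intended meaning on a 2×2 arrangement.

Choices the apparatus description leaves open, and how they are resolved:

- **Session-start activation.** Which rewarded spot is active before the
  first reward of a session is undefined; here both rewarded spots start
  "armed" and the first poke at either is rewarded and seeds the
  alternation. This keeps "exactly one active spot" true from the first
  reward onward and avoids an arbitrary unrewardable first shuttle.
- **Time model.** All scored metrics are event-based, so the simulator
  runs without a clock by default and sessions always complete their
  trial count. Passing `mean_inter_poke_s` enables exponential inter-poke
  intervals and the 45-minute session cap (2700 s, `PhaseSpec.time_cap_s`),
  producing aborted sessions whose metrics are computed over completed
  trials only.
- **Counterbalancing.** Initial diagonal assignments alternate in subject
  order within a group (split difference ≤ 1), deterministically.
- **State across sessions.** The diagonal assignment follows the phase's
  reversal flag; the armed state resets every session.

The default schedule is acquisition plus four reversal stages, 10 sessions
per phase, 100 trials per session, with the rewarded diagonal alternating
between phases (so the second reversal stage reinstates the acquisition
diagonal).

## Scoring

All five metrics are defined in `shuttleseq.scoring` and documented there.
Conventions that required a decision:

- Trial 1 of a session has no previous correct spot and is excluded from
  the move-pattern/re-entry classification; it *is* included in the
  first-choice never-rewarded rate, whose definition does not involve the
  previous trial. On the shared window (trials ≥ 2) the adjacent-move rate
  and the first-choice never-rewarded rate are identical by construction —
  the two neighbours of a rewarded spot are exactly the two never-rewarded
  spots — and the test suite asserts this on every simulated session.
- Aborted sessions: denominators use completed trials (trials that ended
  with a reward); an unfinished tail trial is dropped. Windows ("first 100
  trials", "first 150 choices", "first 40 trials") truncate at what the
  session provides and never pad.
- The cumulative diagonal correct/error scan uses overlapping consecutive
  poke pairs and crosses trial boundaries, treating shuttling as a
  continuous movement pattern rather than a per-trial one.
- The block never-rewarded rate defaults to 5-trial blocks over the first
  40 trials (the window every subject completes); the window is a
  parameter.
- Percentages keep full floating precision internally; round only for
  display.

### Chance levels

Under a memoryless uniform policy the first poke of a trial hits a
never-rewarded spot with probability 2/4 = 50 %, and relative to the
previous correct spot the four possible first choices split 1/2/1 into
diagonal/adjacent/re-entry, i.e. 25/50/25 %. These are the reference lines
for the one-sample tests.

One subtlety: the *per-5-trial-block* never-rewarded rate is a ratio whose
denominator is a small random poke count (~20 under the uniform policy),
so the expectation of the block ratio sits below the poke-level
probability (≈ 47 % rather than 50 %, a finite-sample ratio bias). The
acceptance script therefore weights block rates by their poke counts,
which estimates the poke-level probability the 50 % chance line refers to.

## Synthetic agents

`shuttleseq.agents` provides the generative stand-in for animal behavior
(nothing is fitted to real animals). The adaptive agent keeps a signed
diagonal preference D ∈ [−1, 1] and chooses spots by softmax over

    u(s) = β·D·side(s) + κ_alt·|D|·1[s = partner(last reward)] + κ_re·1[s = last reward]

mixed with a uniform lapse ε. Updates after a poke at spot s (g = side(s),
w = 0.5 a fixed structural weight — reward is stronger evidence than its
absence):

    rewarded:    D ← D + α(g − D)
    unrewarded:  D ← D + αλw(−g − D)

Design rationale, parameter by parameter:

| parameter | meaning | control | dysbiosis |
|---|---|---|---|
| α (`learn_rate`) | preference update per poke | 0.002 | 0.002 |
| β (`inv_temp`) | choice determinism | 2.2 | 2.2 |
| κ_alt (`kappa_alt`) | shuttling-habit bonus (gated by \|D\|) | 2.2 | 2.2 |
| κ_re (`kappa_re`) | re-entry (persistence) bias | 0.25 | 1.0 |
| λ (`perseveration_decay`) | unlearning speed after nonreward | 1.0 | 0.35 |
| ε (`explore`) | uniform lapse probability | 0.25 | 0.25 |

- Gating the alternation bonus by |D| makes habit expression contingent on
  rule knowledge: a naive agent starts at chance, and after a reversal the
  habit keeps serving the old diagonal until D is unlearned, which is what
  produces the above-chance error spike at the start of each reversal
  stage. An ungated bonus would be cued entirely by the last reward and
  would be correct from the first post-reversal pellet onward, abolishing
  both the near-chance start and the spike.
- The unrewarded-update weight w = 0.5 prevents the steady stream of
  unrewarded re-entry/inactive pokes from capping D at a low value (which
  would make the control re-entry rate rise with training instead of
  fall), and slows post-reversal unlearning to a multi-session time scale.
- κ_re is *not* gated: persistence is modeled as a raw compulsion toward
  the last rewarding location, present from session 1 — matching the
  dysbiosis phenotype, whose re-entry rate is elevated from the start and
  does not resolve with training.
- Limits: ε = 1 reduces the agent to the uniform policy; large κ_re drives
  the first-choice re-entry rate toward 100 %.

Preset values were chosen once so that a 10-session acquisition run of 20
control agents reproduces the qualitative shape of the published control
learning curves — first-choice never-rewarded rate starting near chance
(high 30s %), ending well below it, a first-reversal spike above 50 % that
decays below 30 % within roughly four sessions, declining re-entry — and
the dysbiosis preset reproduces elevated, persistent re-entry with slower
reversal adaptation. The generator emulates the *structure* real data would
have (event schema, trial composition, learning dynamics, phenotype
contrasts); it does not emulate satiety or motivation drifts, inter-poke
timing (unless the optional clock is enabled), spot-specific biases, or
individual-difference distributions beyond seed noise, so passing tests
validate the pipeline, not any biological claim.

Seeding: one `numpy.random.Generator` per subject, seeded as
`base_seed + subject_index`; the same base seed reproduces a cohort bit
for bit.

## Statistics

One-sample and two-sample tests are Student's t (two-sided, equal
variance, α = 0.05) via scipy. With zero sample variance the one-sample
statistic is returned as t = 0, p = 1 at the chance mean and ±∞, p = 0
away from it. The omnibus group × session analysis is delegated to
`pingouin.mixed_anova` (session as the repeated factor); the package's own
code handles data marshaling, the per-session group contrasts, and
Bonferroni correction (corrected p = min(1, p·m) over the m sessions
tested). The exact per-session contrast behind published repeated-measures
analyses is software-dependent; here it is a two-sample t per session,
and the delegation boundary is documented rather than guessed.

## Problem sizes and numerical checks

The test suite validates chance recovery on 200 uniform sessions, scorer
equivalence against an independent brute-force implementation on 1,000
random logs (exact equality), phenotype monotonicity on a 5-point κ_re
grid with 20 agents per point, the reversal spike on 20 trained agents,
and type-I control on 500 null replicates of two 4-subject groups over
three 25-trial sessions (corrected rejection rate ≤ 0.05 plus binomial
error). These sizes keep the full suite under a minute on one CPU while
leaving Monte Carlo error well inside the asserted tolerances.

## Known limitations

- The agent family is a minimal descriptive model; its parameters are not
  identifiable from, or comparable to, real mice.
- `sessions_to_criterion` in the report applies the 30 % threshold to the
  group-mean curve, not per subject.
- The CSV validator reconstructs the diagonal assignment from observed
  spot roles; a session in which some spot never appears relies on the
  layout geometry to complete the pairs.
- The repeated-measures omnibus requires a complete subject × session
  table; missing cells are reported, not imputed.
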