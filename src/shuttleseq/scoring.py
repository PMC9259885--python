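"""The five per-session learning scores of the behavioral-sequencing task.

All metrics are computed from a :class:`~shuttleseq.events.SessionLog` and
its diagonal assignment:

1. *Move-pattern rates* — each trial's first poke, classified relative to
   the previous trial's correct (rewarded) spot as a **diagonal** move (its
   diagonal partner, i.e. the next correct spot), an **adjacent** move
   (either neighbour, necessarily a never-rewarded spot) or a **re-entry**
   (the same spot again).  Chance levels under uniform choice: 25/50/25%.
2. *First-choice never-rewarded rate* — percentage of trials whose first
   poke lands on a never-rewarded spot; chance 50%.
3. *Cumulative diagonal correct / error counts* — consecutive-poke pairs
   spanning the rewarded diagonal (correct) or the never-rewarded diagonal
   (error), accumulated over the first 150 pokes.
4. *Never-rewarded rate per 5-trial block* — share of **all** pokes landing
   on never-rewarded spots, per block of 5 trials; chance 50%.
5. *First-choice re-entry rate* — the re-entry component of (1); elevated
   re-entry is the persistence phenotype.

Trial 1 of a session has no previous correct spot, so it is excluded from
the move-pattern classification (and from re-entry), while it *is* counted
in the first-choice never-rewarded rate.  Denominators use completed trials
only; windows truncate at what the session provides, never pad.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import SessionLog
from .layout import Spot, SpotLayout


class UndefinedMetricError(ValueError):
    """The metric is undefined for this log (e.g. no eligible trials)."""


class MovePattern(enum.Enum):
    DIAGONAL = "diagonal"
    ADJACENT = "adjacent"
    RE_ENTRY = "re_entry"


def classify_first_choice(
    prev_correct: Spot, first_choice: Spot, layout: SpotLayout
) -> MovePattern:
    """Classify a trial's first poke relative to the previous correct spot."""
    if first_choice == prev_correct:
        return MovePattern.RE_ENTRY
    if first_choice == layout.diagonal_partner(prev_correct):
        return MovePattern.DIAGONAL
    if first_choice in layout.adjacency(prev_correct):
        return MovePattern.ADJACENT
    raise KeyError(f"spot {first_choice!r} is not in the layout")


def first_choice_never_rewarded_rate(
    log: SessionLog, n_trials: int = 100, include_first_trial: bool = True
) -> float:
    """Percentage of trials (within the first ``n_trials`` completed trials)
    whose first poke is at a never-rewarded spot.

    ``include_first_trial=False`` restricts to trials >= 2, the window shared
    with the move-pattern rates.
    """
    trials = log.completed_trials()[:n_trials]
    if not include_first_trial:
        trials = [t for t in trials if t[0].trial_index >= 2]
    if not trials:
        raise UndefinedMetricError("no eligible trials")
    never = log.assignment.never_rewarded_pair
    hits = sum(1 for t in trials if t[0].spot in never)
    return 100.0 * hits / len(trials)


def _classified_first_choices(
    log: SessionLog, layout: SpotLayout, n_trials: int
) -> list[MovePattern]:
    trials = log.completed_trials()[:n_trials]
    out: list[MovePattern] = []
    for prev, cur in zip(trials, trials[1:]):
        prev_correct = prev[-1].spot  # the rewarded poke that ended the trial
        out.append(classify_first_choice(prev_correct, cur[0].spot, layout))
    return out


def move_pattern_rates(
    log: SessionLog, layout: SpotLayout | None = None, n_trials: int = 100
) -> tuple[float, float, float]:
    """(diagonal%, adjacent%, re_entry%) over classifiable trials in the
    first-``n_trials`` window; the three rates sum to 100."""
    from .layout import DEFAULT_LAYOUT

    layout = layout or DEFAULT_LAYOUT
    patterns = _classified_first_choices(log, layout, n_trials)
    if not patterns:
        raise UndefinedMetricError("need >= 2 completed trials to classify moves")
    n = len(patterns)
    counts = {p: 0 for p in MovePattern}
    for p in patterns:
        counts[p] += 1
    return (
        100.0 * counts[MovePattern.DIAGONAL] / n,
        100.0 * counts[MovePattern.ADJACENT] / n,
        100.0 * counts[MovePattern.RE_ENTRY] / n,
    )


def re_entry_rate(
    log: SessionLog, layout: SpotLayout | None = None, n_trials: int = 100
) -> float:
    """First-choice re-entry percentage (the persistence metric)."""
    return move_pattern_rates(log, layout, n_trials)[2]


def cumulative_diagonal_counts(
    log: SessionLog, n_choices: int = 150
) -> list[tuple[int, int]]:
    """Cumulative (diagonal-correct, diagonal-error) counts per poke.

    Scans consecutive poke pairs — across trial boundaries — among the first
    ``n_choices`` pokes of the session.  A pair spanning the two rewarded
    spots increments the correct count; a pair spanning the two
    never-rewarded spots increments the error count.  ``series[i]`` holds
    the counts after poke ``i + 1``; both components are nondecreasing.
    """
    pokes = [ev.spot for ev in log.events[:n_choices]]
    rewarded = log.assignment.rewarded_pair
    never = log.assignment.never_rewarded_pair
    series: list[tuple[int, int]] = []
    correct = error = 0
    for i, spot in enumerate(pokes):
        if i > 0:
            pair = {pokes[i - 1], spot}
            if pair == set(rewarded):
                correct += 1
            elif pair == set(never):
                error += 1
        series.append((correct, error))
    return series


def never_rewarded_rate_blocks(
    log: SessionLog, block: int = 5, n_trials: int = 40
) -> list[float]:
    """Never-rewarded percentage of *all* pokes in consecutive ``block``-trial
    blocks, over the first ``n_trials`` completed trials (full blocks only)."""
    trials = log.completed_trials()[:n_trials]
    n_blocks = len(trials) // block
    if n_blocks == 0:
        raise UndefinedMetricError(f"fewer than {block} completed trials")
    never = log.assignment.never_rewarded_pair
    rates: list[float] = []
    for b in range(n_blocks):
        pokes = [ev for t in trials[b * block : (b + 1) * block] for ev in t]
        hits = sum(1 for ev in pokes if ev.spot in never)
        rates.append(100.0 * hits / len(pokes))
    return rates


def sessions_to_criterion(
    rates_by_session: Sequence[float], threshold: float = 30.0
) -> int | None:
    """1-based ordinal of the first session whose rate drops below
    ``threshold`` (the paper-style learning criterion), or None if never."""
    if len(rates_by_session) == 0:
        raise UndefinedMetricError("empty rate series")
    for i, rate in enumerate(rates_by_session, start=1):
        if rate < threshold:
            return i
    return None


def stage_aggregate(
    table: pd.DataFrame, sessions: Sequence[int]
) -> tuple[float, float]:
    """Group mean +/- SEM of per-subject means over selected sessions.

    ``table`` needs columns ``subject``, ``session``, ``value``.  Each
    subject's values over ``sessions`` are averaged first; the returned mean
    and standard error are across subjects (SEM is NaN for one subject).
    """
    sel = table[table["session"].isin(list(sessions))]
    if sel.empty:
        raise UndefinedMetricError("selection resolves to no sessions")
    per_subject = sel.groupby("subject")["value"].mean()
    mean = float(per_subject.mean())
    n = len(per_subject)
    sem = float(per_subject.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem


@dataclass(frozen=True)
class SessionScores:
    """All five scores of one session (None/empty where undefined)."""

    subject_id: str
    session_index: int
    phase: str
    n_trials_completed: int
    first_choice_never_rewarded_rate: float | None
    diagonal_move_rate: float | None
    adjacent_move_rate: float | None
    re_entry_rate: float | None
    cumulative_diagonal: list[tuple[int, int]]
    never_rewarded_block_rates: list[float]


def score_session(
    log: SessionLog,
    layout: SpotLayout | None = None,
    *,
    first_choice_trials: int = 100,
    cumulative_choices: int = 150,
    block: int = 5,
    block_trials: int = 40,
) -> SessionScores:
    """Compute every per-session score; metrics that are undefined for a
    short/aborted session come back as None (scalars) or empty (series)."""
    try:
        fc = first_choice_never_rewarded_rate(log, first_choice_trials)
    except UndefinedMetricError:
        fc = None
    try:
        diag, adj, re_ = move_pattern_rates(log, layout, first_choice_trials)
    except UndefinedMetricError:
        diag = adj = re_ = None
    try:
        blocks = never_rewarded_rate_blocks(log, block, block_trials)
    except UndefinedMetricError:
        blocks = []
    return SessionScores(
        subject_id=log.subject_id,
        session_index=log.session_index,
        phase=log.phase,
        n_trials_completed=log.n_trials_completed,
        first_choice_never_rewarded_rate=fc,
        diagonal_move_rate=diag,
        adjacent_move_rate=adj,
        re_entry_rate=re_,
        cumulative_diagonal=cumulative_diagonal_counts(log, cumulative_choices),
        never_rewarded_block_rates=blocks,
    )


#: Scalar metric names as they appear in score tables, with chance levels (%).
CHANCE_LEVELS = {
    "first_choice_never_rewarded": 50.0,
    "diagonal_move": 25.0,
    "adjacent_move": 50.0,
    "re_entry": 25.0,
}


def score_table(
    logs: Iterable[SessionLog],
    layout: SpotLayout | None = None,
    **windows,
) -> pd.DataFrame:
    """Tidy per-session score table: one row per subject x session x metric.

    Columns: ``subject``, ``phase``, ``session``, ``metric``, ``value``
    (value is NaN where the metric is undefined).  Scalar metrics only; the
    cumulative and block series are available via :func:`score_session`.
    """
    rows = []
    for log in logs:
        s = score_session(log, layout, **windows)
        scalars = {
            "first_choice_never_rewarded": s.first_choice_never_rewarded_rate,
            "diagonal_move": s.diagonal_move_rate,
            "adjacent_move": s.adjacent_move_rate,
            "re_entry": s.re_entry_rate,
            "n_trials_completed": float(s.n_trials_completed),
        }
        for metric, value in scalars.items():
            rows.append(
                (s.subject_id, s.phase, s.session_index, metric,
                 np.nan if value is None else value)
            )
    return pd.DataFrame(rows, columns=["subject", "phase", "session", "metric", "value"])
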