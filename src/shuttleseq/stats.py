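"""Session-level statistical comparisons for scored cohorts.

Covers the study's analysis structure: Student's one-sample t against
analytic chance levels, equal-variance two-sample t between groups, and a
group x session repeated-measures analysis (omnibus mixed ANOVA delegated
to :func:`pingouin.mixed_anova`) followed by per-session group contrasts
with Bonferroni correction over the sessions tested.  Two-sided tests
throughout; alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import ProtocolSchedule
from .scoring import CHANCE_LEVELS, sessions_to_criterion, stage_aggregate


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, df, p, optional corrected p, label."""

    statistic: float
    df: float
    pvalue: float
    pvalue_corrected: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
        if self.pvalue_corrected is not None and self.pvalue_corrected < self.pvalue:
            raise ValueError("corrected p must be >= raw p")


def one_sample_t_vs_chance(values: Sequence[float], chance: float) -> TestResult:
    """Two-sided one-sample Student's t of per-subject percentages against an
    analytic chance level.

    With zero sample variance the t statistic degenerates: at the chance
    mean the result is t = 0, p = 1; away from it, t = +/-inf, p = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t requires n >= 2")
    label = f"one-sample t vs chance {chance:g}%"
    if float(x.std(ddof=1)) == 0.0:
        if float(x.mean()) == chance:
            return TestResult(0.0, x.size - 1, 1.0, label=label)
        sign = 1.0 if float(x.mean()) > chance else -1.0
        return TestResult(sign * math.inf, x.size - 1, 0.0, label=label)
    t, p = sps.ttest_1samp(x, popmean=chance)
    return TestResult(float(t), x.size - 1, float(p), label=label)


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided equal-variance (Student's) two-sample t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t requires n >= 2 per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if math.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return TestResult(float(t), a.size + b.size - 2, float(p), label="two-sample t")


def bonferroni(pvalue: float, m: int) -> float:
    """Bonferroni-corrected p over m comparisons, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, pvalue * m)


def _check_table(table: pd.DataFrame) -> None:
    required = {"subject", "group", "session", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"score table missing column(s): {sorted(missing)}")


def between_group_session_tests(
    table: pd.DataFrame,
    metric: str,
    sessions: Sequence[int] | None = None,
    *,
    omnibus: bool = True,
) -> tuple[pd.DataFrame | None, list[TestResult]]:
    """Group x session analysis of one metric over a session window.

    ``table`` is tidy with columns subject/group/session/metric/value and
    exactly two groups.  Returns the omnibus mixed-ANOVA table (None when
    ``omnibus=False``) and one per-session two-sample t contrast with
    Bonferroni correction over the number of sessions tested.  Missing
    subject x session cells raise with the offending pairs listed.
    """
    _check_table(table)
    data = table[table["metric"] == metric].copy()
    if data.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    group_names = sorted(data["group"].unique())
    if len(group_names) != 2:
        raise ValueError(f"exactly two groups required, found {group_names}")
    if sessions is None:
        sessions = sorted(data["session"].unique())
    data = data[data["session"].isin(list(sessions))]
    counts = data.groupby("group")["subject"].nunique()
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 subjects")
    # Balanced-design check: every subject must have every session.
    missing_pairs = []
    for subject, sub in data.groupby("subject"):
        for s in sessions:
            if s not in set(sub["session"]) or sub[sub["session"] == s]["value"].isna().any():
                missing_pairs.append((subject, s))
    if missing_pairs:
        raise ValueError(f"missing subject x session value(s): {missing_pairs}")

    omnibus_table = None
    if omnibus:
        import pingouin as pg

        omnibus_table = pg.mixed_anova(
            data=data, dv="value", within="session", subject="subject", between="group"
        )

    m = len(sessions)
    results: list[TestResult] = []
    for s in sessions:
        at_s = data[data["session"] == s]
        a = at_s[at_s["group"] == group_names[0]]["value"].to_numpy()
        b = at_s[at_s["group"] == group_names[1]]["value"].to_numpy()
        res = two_sample_t(a, b)
        results.append(
            TestResult(
                statistic=res.statistic,
                df=res.df,
                pvalue=res.pvalue,
                pvalue_corrected=bonferroni(res.pvalue, m),
                label=f"{metric}: {group_names[0]} vs {group_names[1]}, session {s}",
            )
        )
    return omnibus_table, results


def session_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per group x session x metric mean, SEM and n across subjects."""
    _check_table(table)
    grouped = table.groupby(["group", "metric", "session"])["value"]
    out = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    return out


def report(
    table: pd.DataFrame,
    schedule: ProtocolSchedule,
    metrics: Sequence[str] | None = None,
    *,
    criterion_threshold: float = 30.0,
    chance_levels: Mapping[str, float] = CHANCE_LEVELS,
) -> dict[str, pd.DataFrame]:
    """Assemble the standard analysis tables for a scored cohort.

    Returns a dict of DataFrames:

    - ``session_means``: group means +/- SEM per session and metric;
    - ``stage_aggregates``: first-three and final-three session aggregates
      per phase, group and metric;
    - ``sessions_to_criterion``: per group and phase, the ordinal of the
      first session whose group-mean first-choice never-rewarded rate drops
      below ``criterion_threshold`` percent;
    - ``chance_tests``: one-sample t of per-subject first-three-session
      aggregates against each metric's chance level, per phase and group.
    """
    _check_table(table)
    if metrics is None:
        metrics = [m for m in table["metric"].unique() if m != "n_trials_completed"]
    table = table[table["metric"].isin(list(metrics))]
    if table.empty:
        empty = pd.DataFrame()
        return {
            "session_means": empty,
            "stage_aggregates": empty,
            "sessions_to_criterion": empty,
            "chance_tests": empty,
        }

    means = session_means(table)

    phase_sessions: dict[str, list[int]] = {}
    for index, phase in schedule.sessions():
        phase_sessions.setdefault(phase.name, []).append(index)

    agg_rows = []
    chance_rows = []
    crit_rows = []
    for group, group_table in table.groupby("group"):
        for phase_name, sess in phase_sessions.items():
            windows = {"first_three": sess[:3], "final_three": sess[-3:]}
            for metric in metrics:
                mt = group_table[group_table["metric"] == metric]
                if mt["value"].isna().all():
                    continue
                for window_name, window in windows.items():
                    sub = mt.rename(columns={})[mt["session"].isin(window)]
                    if sub.empty:
                        continue
                    mean, sem = stage_aggregate(
                        mt[["subject", "session", "value"]], window
                    )
                    agg_rows.append((group, phase_name, window_name, metric, mean, sem))
                if metric in chance_levels:
                    per_subject = (
                        mt[mt["session"].isin(windows["first_three"])]
                        .groupby("subject")["value"]
                        .mean()
                    )
                    if len(per_subject) >= 2:
                        res = one_sample_t_vs_chance(
                            per_subject.to_numpy(), chance_levels[metric]
                        )
                        chance_rows.append(
                            (group, phase_name, metric, chance_levels[metric],
                             res.statistic, res.df, res.pvalue)
                        )
            fc = means[
                (means["group"] == group)
                & (means["metric"] == "first_choice_never_rewarded")
                & (means["session"].isin(sess))
            ].sort_values("session")
            if not fc.empty:
                reached = sessions_to_criterion(
                    fc["mean"].tolist(), threshold=criterion_threshold
                )
                crit_rows.append((group, phase_name, reached))

    return {
        "session_means": means,
        "stage_aggregates": pd.DataFrame(
            agg_rows, columns=["group", "phase", "window", "metric", "mean", "sem"]
        ),
        "sessions_to_criterion": pd.DataFrame(
            crit_rows, columns=["group", "phase", "sessions_to_criterion"]
        ),
        "chance_tests": pd.DataFrame(
            chance_rows,
            columns=["group", "phase", "metric", "chance", "statistic", "df", "pvalue"],
        ),
    }
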