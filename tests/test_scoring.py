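"""The five learning metrics, their frozen hand-computed examples, and the
brute-force oracle equivalence."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shuttleseq as sq
from bruteforce import (
    bf_cumulative_diagonal_counts,
    bf_first_choice_never_rewarded_rate,
    bf_move_pattern_rates,
    bf_never_rewarded_rate_blocks,
)
from conftest import PerfectAlternator, build_log, random_small_log


class TestClassifyFirstChoice:
    @pytest.mark.parametrize(
        "prev,choice,expected",
        [
            (1, 4, sq.MovePattern.DIAGONAL),
            (1, 2, sq.MovePattern.ADJACENT),
            (1, 3, sq.MovePattern.ADJACENT),
            (1, 1, sq.MovePattern.RE_ENTRY),
            (3, 2, sq.MovePattern.DIAGONAL),
        ],
    )
    def test_classification(self, prev, choice, expected, layout):
        assert sq.classify_first_choice(prev, choice, layout) is expected

    def test_total_and_exclusive_over_all_spots(self, layout):
        for prev in layout.spot_ids:
            patterns = [sq.classify_first_choice(prev, c, layout) for c in layout.spot_ids]
            assert sorted(p.value for p in patterns) == [
                "adjacent", "adjacent", "diagonal", "re_entry",
            ]


class TestFirstChoiceNeverRewardedRate:
    def test_four_of_ten_trials(self):
        # trials 1-4 start at a never-rewarded spot, trials 5-10 do not
        log = build_log([2, 1, 3, 4, 2, 1, 3, 4, 1, 4, 1, 4, 1, 4])
        assert log.n_trials_completed == 10
        assert sq.first_choice_never_rewarded_rate(log) == pytest.approx(40.0)

    def test_all_first_pokes_rewarded_gives_zero(self, assignment):
        log = sq.run_session(PerfectAlternator(), assignment,
                             sq.PhaseSpec("acquisition", trials_per_session=30), seed=0)
        assert sq.first_choice_never_rewarded_rate(log) == 0.0

    def test_empty_log_signals_undefined(self, assignment):
        log = sq.SessionLog("m1", 1, "acquisition", (), assignment)
        with pytest.raises(sq.UndefinedMetricError):
            sq.first_choice_never_rewarded_rate(log)

    def test_window_truncates_to_first_n_trials(self):
        log = build_log([2, 1, 3, 4, 1, 4])  # N-starts in trials 1, 2 only
        assert sq.first_choice_never_rewarded_rate(log, n_trials=2) == pytest.approx(100.0)
        assert sq.first_choice_never_rewarded_rate(log, n_trials=100) == pytest.approx(50.0)


class TestMovePatternRates:
    def test_crafted_five_trial_log(self):
        # first choices of trials 2..5: diagonal, adjacent, re-entry, diagonal
        log = build_log([1, 4, 2, 1, 1, 4, 1])
        assert log.n_trials_completed == 5
        diag, adj, re_ = sq.move_pattern_rates(log)
        assert (diag, adj, re_) == pytest.approx((50.0, 25.0, 25.0))

    def test_perfect_alternator_is_pure_diagonal(self, assignment):
        log = sq.run_session(PerfectAlternator(), assignment,
                             sq.PhaseSpec("acquisition", trials_per_session=50), seed=0)
        assert sq.move_pattern_rates(log) == pytest.approx((100.0, 0.0, 0.0))

    def test_single_trial_undefined(self):
        log = build_log([1])
        with pytest.raises(sq.UndefinedMetricError):
            sq.move_pattern_rates(log)

    def test_rates_sum_to_100(self):
        for seed in range(30):
            log = random_small_log(seed)
            assert sum(sq.move_pattern_rates(log)) == pytest.approx(100.0, abs=1e-9)


class TestReEntryRate:
    def test_crafted_two_of_seven(self):
        # re-entries at trials 2 and 5 of 8; 7 classifiable trials
        log = build_log([1, 1, 4, 1, 4, 4, 1, 4, 1, 4])
        assert log.n_trials_completed == 8
        assert sq.re_entry_rate(log) == pytest.approx(200.0 / 7.0)

    def test_always_reenter_first_policy_hits_100(self, assignment):
        class ReEnterFirst:
            """First poke of each trial returns to the last rewarded spot,
            then the policy relents and pokes the active spot."""

            def begin_session(self, assignment):
                self._assignment = assignment
                self._last = None
                self._fresh_trial = True

            def choose(self, rng):
                if self._last is not None and self._fresh_trial:
                    return self._last
                if self._last is None:
                    return min(self._assignment.rewarded_pair)
                return self._assignment.rewarded_partner(self._last)

            def observe(self, spot, rewarded):
                self._fresh_trial = rewarded
                if rewarded:
                    self._last = spot

        log = sq.run_session(ReEnterFirst(), assignment,
                             sq.PhaseSpec("acquisition", trials_per_session=20), seed=0)
        assert sq.re_entry_rate(log) == 100.0

    def test_perfect_alternator_never_reenters(self, assignment):
        log = sq.run_session(PerfectAlternator(), assignment,
                             sq.PhaseSpec("acquisition", trials_per_session=20), seed=0)
        assert sq.re_entry_rate(log) == 0.0


class TestCumulativeDiagonalCounts:
    def test_hand_scanned_sequence(self):
        log = build_log([1, 4, 1, 4, 2, 3])
        series = sq.cumulative_diagonal_counts(log)
        assert series == [(0, 0), (1, 0), (2, 0), (3, 0), (3, 0), (3, 1)]

    def test_single_poke(self):
        log = build_log([2])
        assert sq.cumulative_diagonal_counts(log) == [(0, 0)]

    def test_perfect_alternator_150_pokes(self, assignment):
        log = sq.run_session(PerfectAlternator(), assignment,
                             sq.PhaseSpec("acquisition", trials_per_session=200), seed=0)
        series = sq.cumulative_diagonal_counts(log, n_choices=150)
        assert len(series) == 150
        assert series[-1] == (149, 0)

    def test_series_componentwise_nondecreasing(self):
        for seed in range(20):
            series = sq.cumulative_diagonal_counts(random_small_log(seed))
            for (c0, e0), (c1, e1) in zip(series, series[1:]):
                assert c1 >= c0 and e1 >= e0
            if series:
                c, e = series[-1]
                assert c + e <= len(series) - 1


class TestNeverRewardedRateBlocks:
    def test_crafted_block_three_of_eight(self):
        # one 5-trial block with poke roles [N, A, N, N, A, A, A, A]
        log = build_log([2, 1, 3, 2, 4, 1, 4, 1])
        assert sq.never_rewarded_rate_blocks(log) == [pytest.approx(37.5)]

    def test_all_rewarded_block_is_zero(self, assignment):
        log = sq.run_session(PerfectAlternator(), assignment,
                             sq.PhaseSpec("acquisition", trials_per_session=40), seed=0)
        assert sq.never_rewarded_rate_blocks(log) == [0.0] * 8

    def test_too_few_trials_undefined(self):
        log = build_log([1, 4, 1])
        with pytest.raises(sq.UndefinedMetricError):
            sq.never_rewarded_rate_blocks(log)

    def test_block_count_respects_window(self, assignment):
        log = sq.run_session(sq.uniform_agent(), assignment,
                             sq.PhaseSpec("acquisition"), seed=9)
        assert len(sq.never_rewarded_rate_blocks(log, n_trials=40)) == 8
        assert len(sq.never_rewarded_rate_blocks(log, n_trials=100)) == 20


class TestSessionsToCriterion:
    @pytest.mark.parametrize(
        "series,expected",
        [([53.6, 45.0, 29.9], 3), ([10.0], 1), ([60.0, 55.0], None), ([30.0, 29.0], 2)],
    )
    def test_first_session_below_threshold(self, series, expected):
        assert sq.sessions_to_criterion(series, threshold=30) == expected

    def test_empty_series_rejected(self):
        with pytest.raises(sq.UndefinedMetricError):
            sq.sessions_to_criterion([])


class TestStageAggregate:
    def test_single_subject_mean(self):
        table = pd.DataFrame(
            {"subject": ["s1"] * 3, "session": [1, 2, 3], "value": [20.0, 30.0, 40.0]}
        )
        mean, sem = sq.stage_aggregate(table, [1, 2, 3])
        assert mean == pytest.approx(30.0)
        assert math.isnan(sem)

    def test_two_subject_hand_computation(self):
        table = pd.DataFrame(
            {
                "subject": ["s1"] * 3 + ["s2"] * 3,
                "session": [1, 2, 3] * 2,
                "value": [20.0, 30.0, 40.0, 10.0, 20.0, 30.0],
            }
        )
        mean, sem = sq.stage_aggregate(table, [1, 2, 3])
        # per-subject means 30 and 20 -> mean 25, sd 5*sqrt(2), sem 5
        assert mean == pytest.approx(25.0)
        assert sem == pytest.approx(5.0)

    def test_identical_values_have_zero_sem(self):
        table = pd.DataFrame(
            {"subject": ["a", "b", "c"], "session": [1, 1, 1], "value": [7.0, 7.0, 7.0]}
        )
        assert sq.stage_aggregate(table, [1]) == (7.0, 0.0)

    def test_empty_selection_rejected(self):
        table = pd.DataFrame({"subject": ["a"], "session": [1], "value": [1.0]})
        with pytest.raises(sq.UndefinedMetricError):
            sq.stage_aggregate(table, [9])


class TestOracleEquivalence:
    """The production scorer (assignment/geometry based) must agree exactly
    with the naive role-based brute-force scorer."""

    @settings(max_examples=50)
    @given(seed=st.integers(min_value=0, max_value=100_000))
    def test_all_metrics_agree_on_random_logs(self, seed):
        log = random_small_log(seed)
        assert sq.first_choice_never_rewarded_rate(log) == pytest.approx(
            bf_first_choice_never_rewarded_rate(log), abs=0
        )
        assert sq.move_pattern_rates(log) == pytest.approx(
            bf_move_pattern_rates(log), abs=0
        )
        assert sq.cumulative_diagonal_counts(log) == bf_cumulative_diagonal_counts(log)
        if log.n_trials_completed >= 5:
            assert sq.never_rewarded_rate_blocks(log, n_trials=log.n_trials_completed) == pytest.approx(
                bf_never_rewarded_rate_blocks(log, n_trials=log.n_trials_completed), abs=0
            )


class TestStructuralIdentity:
    def test_adjacent_rate_equals_never_rewarded_rate_on_common_window(self, small_cohort):
        """The two spots adjacent to the previous correct spot are exactly the
        two never-rewarded spots, so on trials >= 2 the adjacent-move rate and
        the first-choice never-rewarded rate coincide."""
        cohort, _ = small_cohort
        checked = 0
        for logs in cohort.logs.values():
            for log in logs:
                _, adj, _ = sq.move_pattern_rates(log)
                nr = sq.first_choice_never_rewarded_rate(log, include_first_trial=False)
                assert adj == pytest.approx(nr, abs=1e-12)
                checked += 1
        assert checked == 6 * 8


class TestScoreTable:
    def test_tidy_shape_and_sum_invariant(self, small_cohort):
        cohort, schedule = small_cohort
        logs = [log for subject_logs in cohort.logs.values() for log in subject_logs]
        table = sq.score_table(logs)
        assert set(table.columns) == {"subject", "phase", "session", "metric", "value"}
        assert len(table) == len(logs) * 5
        wide = table.pivot_table(index=["subject", "session"], columns="metric", values="value")
        total = wide["diagonal_move"] + wide["adjacent_move"] + wide["re_entry"]
        assert np.allclose(total, 100.0)

    def test_score_session_collects_all_metrics(self, assignment):
        log = sq.run_session(sq.uniform_agent(), assignment, sq.PhaseSpec("acquisition"), seed=1)
        scores = sq.score_session(log)
        assert scores.n_trials_completed == 100
        assert 0 <= scores.first_choice_never_rewarded_rate <= 100
        assert len(scores.never_rewarded_block_rates) == 8
        assert len(scores.cumulative_diagonal) == 150
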