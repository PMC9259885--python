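import hypothesis
import pytest

import shuttleseq as sq

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def layout():
    return sq.DEFAULT_LAYOUT


@pytest.fixture(scope="session")
def assignment(layout):
    """Diagonal A ({1, 4}) rewarded."""
    return sq.DiagonalAssignment.from_layout(layout, 0)


def build_log(pokes, rewarded=frozenset({1, 4}), subject="m1", session=1, phase="acquisition"):
    """Replay a poke sequence through the contingency engine into a SessionLog."""
    assignment = sq.DiagonalAssignment(
        rewarded_pair=frozenset(rewarded),
        never_rewarded_pair=frozenset({1, 2, 3, 4} - set(rewarded)),
    )
    state = sq.ContingencyState.initial(assignment)
    events = []
    for spot in pokes:
        role = state.role_of(spot)
        rewarded_flag, _, new_state = sq.respond_to_poke(state, spot)
        events.append(
            sq.PokeEvent(
                subject_id=subject,
                phase=phase,
                session_index=session,
                trial_index=state.trial_index,
                poke_index=state.pokes_this_trial + 1,
                spot=spot,
                spot_role=role,
                rewarded=rewarded_flag,
            )
        )
        state = new_state
    return sq.SessionLog(
        subject_id=subject,
        session_index=session,
        phase=phase,
        events=tuple(events),
        assignment=assignment,
    )


class PerfectAlternator:
    """Policy that always pokes the currently active rewarded spot."""

    def begin_session(self, assignment):
        self._assignment = assignment
        self._next = min(assignment.rewarded_pair)

    def choose(self, rng):
        return self._next

    def observe(self, spot, rewarded):
        if rewarded:
            self._next = self._assignment.rewarded_partner(spot)


def random_small_log(seed, max_trials=30):
    """A short uniform-policy session for oracle-equivalence checks."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n_trials = int(rng.integers(2, max_trials + 1))
    phase = sq.PhaseSpec("acquisition", n_sessions=1, trials_per_session=n_trials)
    assignment = sq.DiagonalAssignment.from_layout(sq.DEFAULT_LAYOUT, int(rng.integers(2)))
    return sq.run_session(
        sq.uniform_agent(), assignment, phase, rng=rng,
        subject_id=f"r{seed}", session_index=1,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2x3-subject cohort over a shortened two-phase schedule."""
    schedule = sq.ProtocolSchedule(
        phases=(
            sq.PhaseSpec("acquisition", n_sessions=4, trials_per_session=40),
            sq.PhaseSpec("rev1", n_sessions=4, trials_per_session=40, reversed=True),
        )
    )
    return sq.make_cohort(3, 3, schedule, base_seed=7), schedule
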