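"""Reward-contingency engine and protocol scheduling.

The behavioral-sequencing task: of the four spots, the two on one diagonal
are *rewarded* and the two on the other are *never-rewarded*.  Of the two
rewarded spots exactly one is *active* at a time; poking the active spot
delivers a pellet, ends the trial, deactivates the spot and activates its
diagonal partner — so earning successive rewards requires shuttling along
the rewarded diagonal.  A session is a fixed number of such trials
(optionally under a wall-clock cap).  In serial reversal learning the
rewarded and never-rewarded diagonals swap between phases.

At session start neither rewarded spot has been poked yet; both are
"armed" (``active_spot is None``) and the first poke at either rewarded
spot is rewarded and seeds the alternation.  From the first reward onward
exactly one rewarded spot is active.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from os import PathLike
from typing import Iterator, Protocol, Sequence

import numpy as np
import yaml

from .events import PokeEvent, SessionLog
from .layout import DEFAULT_LAYOUT, DiagonalAssignment, Spot, SpotLayout

#: Session wall-clock cap used by the real apparatus, in seconds (45 min).
DEFAULT_TIME_CAP_S = 45 * 60.0
#: Trials per completed session.
DEFAULT_TRIALS_PER_SESSION = 100
#: Sessions per phase under the default serial-reversal schedule.
DEFAULT_SESSIONS_PER_PHASE = 10


class ProtocolError(RuntimeError):
    """An event inconsistent with the task contingencies (e.g. unknown spot)."""


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of the protocol (acquisition or a reversal stage)."""

    name: str
    n_sessions: int = DEFAULT_SESSIONS_PER_PHASE
    trials_per_session: int = DEFAULT_TRIALS_PER_SESSION
    time_cap_s: float = DEFAULT_TIME_CAP_S
    reversed: bool = False  # diagonal assignment flipped relative to acquisition

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered phases plus the spot layout; sessions are numbered globally from 1."""

    phases: tuple[PhaseSpec, ...]
    layout: SpotLayout = DEFAULT_LAYOUT

    @property
    def n_sessions(self) -> int:
        return sum(p.n_sessions for p in self.phases)

    def sessions(self) -> Iterator[tuple[int, PhaseSpec]]:
        """Yield (global 1-based session index, phase) for every session."""
        index = 1
        for phase in self.phases:
            for _ in range(phase.n_sessions):
                yield index, phase
                index += 1

    def phase_of_session(self, session_index: int) -> PhaseSpec:
        for index, phase in self.sessions():
            if index == session_index:
                return phase
        raise KeyError(f"session {session_index} is outside the schedule")


def make_default_schedule(layout: SpotLayout = DEFAULT_LAYOUT) -> ProtocolSchedule:
    """The standard serial-reversal protocol: acquisition then four reversal
    stages, 10 sessions per phase (50 total), 100 trials per session, 45-min
    cap, with the rewarded diagonal alternating between phases."""
    phases = [PhaseSpec(name="acquisition")]
    for k in range(1, 5):
        phases.append(PhaseSpec(name=f"rev{k}", reversed=(k % 2 == 1)))
    return ProtocolSchedule(phases=tuple(phases), layout=layout)


def load_schedule(path: str | PathLike) -> ProtocolSchedule:
    """Build a schedule from a flat key-value YAML config.

    Recognised keys (all optional; defaults reproduce
    :func:`make_default_schedule`)::

        sessions_per_phase: 10    # sessions in acquisition and in each reversal
        n_reversals: 4            # number of reversal stages after acquisition
        trials_per_session: 100
        time_cap_s: 2700
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - {"sessions_per_phase", "n_reversals", "trials_per_session", "time_cap_s"}
    if unknown:
        raise ValueError(f"unknown schedule config key(s): {sorted(unknown)}")
    n_sessions = int(cfg.get("sessions_per_phase", DEFAULT_SESSIONS_PER_PHASE))
    n_rev = int(cfg.get("n_reversals", 4))
    trials = int(cfg.get("trials_per_session", DEFAULT_TRIALS_PER_SESSION))
    cap = float(cfg.get("time_cap_s", DEFAULT_TIME_CAP_S))
    phases = [
        PhaseSpec(name="acquisition", n_sessions=n_sessions, trials_per_session=trials, time_cap_s=cap)
    ]
    for k in range(1, n_rev + 1):
        phases.append(
            PhaseSpec(
                name=f"rev{k}",
                n_sessions=n_sessions,
                trials_per_session=trials,
                time_cap_s=cap,
                reversed=(k % 2 == 1),
            )
        )
    return ProtocolSchedule(phases=tuple(phases))


@dataclass(frozen=True)
class ContingencyState:
    """Instantaneous contingency during a session.

    ``active_spot is None`` means the session-start armed state (no reward
    delivered yet; the first rewarded-spot poke wins and seeds alternation).
    """

    assignment: DiagonalAssignment
    active_spot: Spot | None = None
    trial_index: int = 1
    pokes_this_trial: int = 0

    @classmethod
    def initial(cls, assignment: DiagonalAssignment) -> "ContingencyState":
        return cls(assignment=assignment)

    def role_of(self, spot: Spot) -> str:
        """Role of ``spot`` under the current contingency."""
        if spot in self.assignment.never_rewarded_pair:
            return "never_rewarded"
        if self.active_spot is None or spot == self.active_spot:
            return "active_rewarded"
        return "inactive_rewarded"


def respond_to_poke(
    state: ContingencyState, spot: Spot
) -> tuple[bool, bool, ContingencyState]:
    """Apply one nose-poke to the contingency state.

    Returns ``(rewarded, trial_ended, new_state)``.  A poke at the active
    rewarded spot (or at either rewarded spot while armed) is rewarded, ends
    the trial and activates the diagonal partner; any other poke is
    unrewarded and the trial continues.
    """
    if spot not in state.assignment.spots:
        raise ProtocolError(f"unknown spot {spot!r}")
    rewarded = state.role_of(spot) == "active_rewarded"
    if rewarded:
        new = ContingencyState(
            assignment=state.assignment,
            active_spot=state.assignment.rewarded_partner(spot),
            trial_index=state.trial_index + 1,
            pokes_this_trial=0,
        )
        return True, True, new
    new = replace(state, pokes_this_trial=state.pokes_this_trial + 1)
    return False, False, new


def apply_reversal(assignment: DiagonalAssignment) -> DiagonalAssignment:
    """Swap the rewarded and never-rewarded diagonals (an involution)."""
    return DiagonalAssignment(
        rewarded_pair=assignment.never_rewarded_pair,
        never_rewarded_pair=assignment.rewarded_pair,
    )


def counterbalance(
    subject_ids: Sequence[str], layout: SpotLayout = DEFAULT_LAYOUT
) -> dict[str, DiagonalAssignment]:
    """Assign initial diagonals to subjects as evenly as possible.

    Deterministic in subject order: subjects at even positions start with
    diagonal A rewarded, odd positions with diagonal B, so the split differs
    by at most one.
    """
    if len(subject_ids) == 0:
        raise ValueError("counterbalance requires at least one subject")
    return {
        subject: DiagonalAssignment.from_layout(layout, rewarded_diagonal=i % 2)
        for i, subject in enumerate(subject_ids)
    }


class Policy(Protocol):
    """A poke generator: one spot choice per call, given what it has observed."""

    def begin_session(self, assignment: DiagonalAssignment) -> None: ...

    def choose(self, rng: np.random.Generator) -> Spot: ...

    def observe(self, spot: Spot, rewarded: bool) -> None: ...


def run_session(
    policy: Policy,
    assignment: DiagonalAssignment,
    phase: PhaseSpec,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "subject",
    session_index: int = 1,
    layout: SpotLayout = DEFAULT_LAYOUT,
    mean_inter_poke_s: float | None = None,
) -> SessionLog:
    """Run one session of a policy against the contingency engine.

    The session ends after ``phase.trials_per_session`` completed trials, or
    — when the optional clock is enabled via ``mean_inter_poke_s``
    (exponential inter-poke intervals) — as soon as the simulated clock
    would exceed ``phase.time_cap_s``.  With a fixed ``seed`` (or a caller
    supplied ``rng``) the log is reproducible bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    state = ContingencyState.initial(assignment)
    policy.begin_session(assignment)
    events: list[PokeEvent] = []
    clock = 0.0
    while state.trial_index <= phase.trials_per_session:
        spot = policy.choose(rng)
        if spot not in layout or spot not in assignment.spots:
            raise ProtocolError(
                f"policy {type(policy).__name__} emitted invalid spot {spot!r} "
                f"(session {session_index}, trial {state.trial_index})"
            )
        time_s: float | None = None
        if mean_inter_poke_s is not None:
            clock += float(rng.exponential(mean_inter_poke_s))
            if clock > phase.time_cap_s:
                break  # session aborted at the cap; the poke never happened
            time_s = clock
        role = state.role_of(spot)
        rewarded, _, new_state = respond_to_poke(state, spot)
        events.append(
            PokeEvent(
                subject_id=subject_id,
                phase=phase.name,
                session_index=session_index,
                trial_index=state.trial_index,
                poke_index=state.pokes_this_trial + 1,
                spot=spot,
                spot_role=role,
                rewarded=rewarded,
                time_s=time_s,
            )
        )
        policy.observe(spot, rewarded)
        state = new_state
    return SessionLog(
        subject_id=subject_id,
        session_index=session_index,
        phase=phase.name,
        events=tuple(events),
        assignment=assignment,
    )


def run_protocol(
    policy: Policy,
    schedule: ProtocolSchedule,
    initial_assignment: DiagonalAssignment,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "subject",
    mean_inter_poke_s: float | None = None,
) -> list[SessionLog]:
    """Run a policy through every session of a schedule.

    The diagonal assignment of each session follows the phase's ``reversed``
    flag relative to the subject's initial (acquisition) assignment; the
    armed state resets every session while the policy's internal memory
    persists across sessions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    logs: list[SessionLog] = []
    flipped = apply_reversal(initial_assignment)
    for session_index, phase in schedule.sessions():
        assignment = flipped if phase.reversed else initial_assignment
        logs.append(
            run_session(
                policy,
                assignment,
                phase,
                rng=rng,
                subject_id=subject_id,
                session_index=session_index,
                layout=schedule.layout,
                mean_inter_poke_s=mean_inter_poke_s,
            )
        )
    return logs
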