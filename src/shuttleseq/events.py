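"""Poke-event logs: in-memory containers plus CSV reading/writing/validation.

One row per nose-poke.  Column order is fixed:

    subject_id, phase, session_index, trial_index, poke_index,
    spot, spot_role, rewarded, time_s

``spot_role`` records the role of the poked spot *at the moment of the poke*
(``active_rewarded``, ``inactive_rewarded`` or ``never_rewarded``);
``rewarded`` is true exactly when the role is ``active_rewarded``.  All
indices are 1-based.  ``time_s`` is optional (empty when the simulator runs
without a clock).  Files are comma-delimited UTF-8 with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import IO, Iterable

import pandas as pd

from .layout import DEFAULT_LAYOUT, DiagonalAssignment, Spot, SpotLayout

COLUMNS = [
    "subject_id",
    "phase",
    "session_index",
    "trial_index",
    "poke_index",
    "spot",
    "spot_role",
    "rewarded",
    "time_s",
]

ROLES = ("active_rewarded", "inactive_rewarded", "never_rewarded")


class LogValidationError(ValueError):
    """A poke-event file violates the schema; ``errors`` lists (row, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "\n".join(f"  row {row}: {msg}" for row, msg in errors[:20])
        more = "" if len(errors) <= 20 else f"\n  ... and {len(errors) - 20} more"
        super().__init__(f"{len(errors)} validation error(s):\n{lines}{more}")


@dataclass(frozen=True)
class PokeEvent:
    """A single nose-poke and its outcome."""

    subject_id: str
    phase: str
    session_index: int
    trial_index: int
    poke_index: int
    spot: Spot
    spot_role: str
    rewarded: bool
    time_s: float | None = None

    def __post_init__(self) -> None:
        if self.spot_role not in ROLES:
            raise ValueError(f"unknown spot_role {self.spot_role!r}")
        if self.rewarded != (self.spot_role == "active_rewarded"):
            raise ValueError("rewarded must be true iff spot_role is active_rewarded")
        if self.session_index < 1 or self.trial_index < 1 or self.poke_index < 1:
            raise ValueError("indices are 1-based and must be positive")


@dataclass(frozen=True)
class SessionLog:
    """All pokes of one subject in one session, in order, plus the contingency."""

    subject_id: str
    session_index: int
    phase: str
    events: tuple[PokeEvent, ...]
    assignment: DiagonalAssignment

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.subject_id != self.subject_id or ev.session_index != self.session_index:
                raise ValueError("all events must share the log's subject and session")

    @property
    def n_trials_completed(self) -> int:
        """Number of trials that ended with a reward."""
        return sum(1 for ev in self.events if ev.rewarded)

    def trials(self) -> list[list[PokeEvent]]:
        """Events grouped by trial, in order."""
        out: list[list[PokeEvent]] = []
        for ev in self.events:
            if not out or ev.trial_index != out[-1][0].trial_index:
                out.append([])
            out[-1].append(ev)
        return out

    def completed_trials(self) -> list[list[PokeEvent]]:
        """Trials whose last poke was rewarded (an aborted tail trial is dropped)."""
        return [t for t in self.trials() if t[-1].rewarded]


def _events_frame(logs: Iterable[SessionLog]) -> pd.DataFrame:
    rows = [
        (
            ev.subject_id,
            ev.phase,
            ev.session_index,
            ev.trial_index,
            ev.poke_index,
            ev.spot,
            ev.spot_role,
            ev.rewarded,
            # shortest round-trip repr; empty when the clock was disabled
            "" if ev.time_s is None else repr(ev.time_s),
        )
        for log in logs
        for ev in log.events
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_log(logs: Iterable[SessionLog], path: str | PathLike | IO[str]) -> None:
    """Write session logs to a CSV file (header + one row per poke)."""
    frame = _events_frame(logs)
    frame.to_csv(path, index=False)


def _infer_assignment(
    roles_by_spot: dict[Spot, set[str]], layout: SpotLayout, errors: list[tuple[int, str]]
) -> DiagonalAssignment:
    rewarded: set[Spot] = set()
    never: set[Spot] = set()
    for spot, roles in roles_by_spot.items():
        if roles & {"active_rewarded", "inactive_rewarded"}:
            rewarded.add(spot)
        if "never_rewarded" in roles:
            never.add(spot)
    if rewarded & never:
        raise LogValidationError(
            errors + [(0, f"spots {sorted(rewarded & never)} appear with both rewarded and never-rewarded roles")]
        )
    # Complete partially observed pairs through the layout geometry.
    for spot in list(rewarded):
        rewarded.add(layout.diagonal_partner(spot))
    for spot in list(never):
        never.add(layout.diagonal_partner(spot))
    if not rewarded and never:
        rewarded = set(layout.spot_ids) - never
    if not never and rewarded:
        never = set(layout.spot_ids) - rewarded
    if len(rewarded) != 2 or len(never) != 2 or rewarded & never:
        raise LogValidationError(
            errors + [(0, "cannot reconstruct a consistent diagonal assignment from spot roles")]
        )
    return DiagonalAssignment(frozenset(rewarded), frozenset(never))


def read_log(path: str | PathLike | IO[str], layout: SpotLayout = DEFAULT_LAYOUT) -> list[SessionLog]:
    """Read and validate a poke-event CSV; returns one :class:`SessionLog` per
    (subject, session) in file order.

    Raises
    ------
    LogValidationError
        With 1-based data-row numbers, when a column is missing, a role or
        reward flag is inconsistent, indices are non-monotone, or a spot is
        not in the layout.
    """
    frame = pd.read_csv(
        path, dtype={"subject_id": str, "phase": str}, float_precision="round_trip"
    )
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise LogValidationError([(0, f"missing column(s): {', '.join(missing)}")])

    errors: list[tuple[int, str]] = []
    logs: list[SessionLog] = []
    # Preserve file order of (subject, session) groups.
    frame["rownum"] = range(1, len(frame) + 1)
    for (subject, session), grp in frame.groupby(["subject_id", "session_index"], sort=False):
        events: list[PokeEvent] = []
        roles_by_spot: dict[Spot, set[str]] = {}
        prev_trial = 0
        prev_poke = 0
        for rec in grp.itertuples(index=False):
            row = rec.rownum
            if rec.spot_role not in ROLES:
                errors.append((row, f"unknown spot_role {rec.spot_role!r}"))
                continue
            if rec.spot not in layout:
                errors.append((row, f"spot {rec.spot!r} is not in the layout"))
                continue
            rewarded = bool(rec.rewarded)
            if rewarded != (rec.spot_role == "active_rewarded"):
                errors.append(
                    (row, "rewarded must be true iff spot_role is active_rewarded")
                )
                continue
            trial = int(rec.trial_index)
            poke = int(rec.poke_index)
            if trial < prev_trial:
                errors.append((row, f"trial_index decreases ({prev_trial} -> {trial})"))
                continue
            expected_poke = 1 if trial != prev_trial else prev_poke + 1
            if poke != expected_poke:
                errors.append(
                    (row, f"poke_index must be {expected_poke} (restarts at 1 each trial), got {poke}")
                )
                continue
            prev_trial, prev_poke = trial, poke
            time_s = None if pd.isna(rec.time_s) else float(rec.time_s)
            events.append(
                PokeEvent(
                    subject_id=str(subject),
                    phase=str(rec.phase),
                    session_index=int(session),
                    trial_index=trial,
                    poke_index=poke,
                    spot=int(rec.spot),
                    spot_role=str(rec.spot_role),
                    rewarded=rewarded,
                    time_s=time_s,
                )
            )
            roles_by_spot.setdefault(int(rec.spot), set()).add(str(rec.spot_role))
        if errors:
            continue
        assignment = _infer_assignment(roles_by_spot, layout, errors)
        logs.append(
            SessionLog(
                subject_id=str(subject),
                session_index=int(session),
                phase=str(events[0].phase) if events else "",
                events=tuple(events),
                assignment=assignment,
            )
        )
    if errors:
        raise LogValidationError(errors)
    return logs
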