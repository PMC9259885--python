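"""Synthetic mouse agents for the behavioral-sequencing task.

No behavioral model is fitted to real animals here: these agents are a
generative stand-in producing poke-event logs with the learning structure
the scoring and statistics assume, so the whole pipeline can be exercised
and validated end to end.

The adaptive agent is a softmax choice policy with two "stickiness" knobs:

*   a signed diagonal preference ``D`` in [-1, 1] (positive = diagonal A),
    learned from reward feedback — the slow spatial-rule memory;
*   an alternation bonus ``kappa_alt`` for the diagonal partner of the last
    rewarded spot — the shuttling habit;
*   a re-entry bias ``kappa_re`` for the last rewarded spot itself —
    elevated ``kappa_re`` yields the *persistence* phenotype;
*   a perseveration factor ``lambda`` scaling how fast unrewarded pokes
    unlearn ``D`` — ``lambda < 1`` yields slow unlearning after a reversal,
    the *perseveration* phenotype.

Choice probabilities over the four spots s:

    u(s) = beta * D * side(s)
           + kappa_alt * |D| * 1[s = partner(last rewarded spot)]
           + kappa_re        * 1[s = last rewarded spot]
    P(s) = (1 - eps) * softmax(u)(s) + eps / 4

where ``side(s)`` is +1 on diagonal A and -1 on diagonal B.  The
alternation bonus is gated by ``|D|``: the shuttling habit is only
expressed to the extent the spatial rule has been acquired, so a naive
agent starts at chance, and after a reversal the habit keeps serving the
*old* rule until ``D`` is unlearned, producing the above-chance error
spike that serial reversal learning shows.  The re-entry bias is not
gated — persistence is modeled as a raw compulsion toward the last
rewarding location, present from the first session.

After each
poke at spot s, with g = side(s) and w = 0.5 (``UNREWARDED_SCALE``, a fixed
structural constant: a pellet is stronger evidence than its absence):

    rewarded:    D <- D + alpha * (g - D)                    (toward s's diagonal)
    unrewarded:  D <- D + alpha * lambda * w * (-g - D)      (away from it)

Both updates are convex steps toward +/-1, so ``D`` stays bounded.  With
``eps = 1`` (or ``beta = kappa_alt = kappa_re = 0``) the agent reduces to
the uniform policy, whose analytic chance levels are 50% first-choice
never-rewarded and 25/50/25% diagonal/adjacent/re-entry moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .events import SessionLog
from .layout import DEFAULT_LAYOUT, DiagonalAssignment, Spot, SpotLayout
from .protocol import ProtocolSchedule, counterbalance, make_default_schedule, run_protocol

#: Relative weight of unrewarded vs rewarded preference updates.
UNREWARDED_SCALE = 0.5


@dataclass(frozen=True)
class AgentParams:
    """Policy parameters of the adaptive agent.

    learn_rate (alpha, per poke, in (0, 1]), inv_temp (beta, >= 0),
    kappa_alt / kappa_re (additive utilities, >= 0), perseveration_decay
    (lambda, in (0, 1]; 1 = symmetric unlearning), explore (eps, lapse
    probability in [0, 1]).
    """

    learn_rate: float = 0.002
    inv_temp: float = 2.2
    kappa_alt: float = 2.2
    kappa_re: float = 0.25
    perseveration_decay: float = 1.0
    explore: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.learn_rate <= 1.0):
            raise ValueError("learn_rate must be in (0, 1]")
        if self.inv_temp < 0.0:
            raise ValueError("inv_temp must be >= 0")
        if self.kappa_alt < 0.0 or self.kappa_re < 0.0:
            raise ValueError("kappa_alt and kappa_re must be >= 0")
        if not (0.0 < self.perseveration_decay <= 1.0):
            raise ValueError("perseveration_decay must be in (0, 1]")
        if not (0.0 <= self.explore <= 1.0):
            raise ValueError("explore must be in [0, 1]")


#: Preset emulating the healthy-control phenotype: moderate re-entry bias,
#: symmetric unlearning after reversal.
CONTROL_PRESET = AgentParams()

#: Preset emulating the dysbiosis phenotype: elevated re-entry bias
#: (persistence) and slowed unlearning of the old diagonal (perseveration).
DYSBIOSIS_PRESET = AgentParams(kappa_re=1.0, perseveration_decay=0.35)

PRESETS = {"control": CONTROL_PRESET, "dysbiosis": DYSBIOSIS_PRESET}


class UniformAgent:
    """Chance-level policy: every poke uniform over the four spots,
    independent of history."""

    def __init__(self, layout: SpotLayout = DEFAULT_LAYOUT):
        self._spots = layout.spot_ids

    def begin_session(self, assignment: DiagonalAssignment) -> None:
        pass

    def choose(self, rng: np.random.Generator) -> Spot:
        return self._spots[int(rng.integers(4))]

    def observe(self, spot: Spot, rewarded: bool) -> None:
        pass


def uniform_agent(layout: SpotLayout = DEFAULT_LAYOUT) -> UniformAgent:
    return UniformAgent(layout)


class AdaptiveAgent:
    """Softmax agent with diagonal-preference learning and stickiness.

    ``D`` persists across sessions (the learned spatial rule is long-term
    memory); the last rewarded spot resets at session start (sessions are
    separate daily runs).
    """

    def __init__(self, params: AgentParams, layout: SpotLayout = DEFAULT_LAYOUT):
        self.params = params
        self.layout = layout
        self._spots = layout.spot_ids
        self._side = {s: layout.side(s) for s in self._spots}
        self._partner = {s: layout.diagonal_partner(s) for s in self._spots}
        self.diagonal_preference = 0.0
        self.last_rewarded_spot: Spot | None = None

    def begin_session(self, assignment: DiagonalAssignment) -> None:
        self.last_rewarded_spot = None

    def choice_probabilities(self) -> dict[Spot, float]:
        """Current P(spot); exposed for testing the policy in isolation."""
        p = self.params
        d = self.diagonal_preference
        util = {s: p.inv_temp * d * self._side[s] for s in self._spots}
        if self.last_rewarded_spot is not None:
            util[self._partner[self.last_rewarded_spot]] += p.kappa_alt * abs(d)
            util[self.last_rewarded_spot] += p.kappa_re
        top = max(util.values())
        exps = {s: math.exp(u - top) for s, u in util.items()}
        z = sum(exps.values())
        return {s: (1.0 - p.explore) * e / z + p.explore / 4.0 for s, e in exps.items()}

    def choose(self, rng: np.random.Generator) -> Spot:
        probs = self.choice_probabilities()
        r = float(rng.random())
        acc = 0.0
        for s in self._spots:
            acc += probs[s]
            if r < acc:
                return s
        return self._spots[-1]  # guard against rounding at r ~ 1

    def observe(self, spot: Spot, rewarded: bool) -> None:
        p = self.params
        g = float(self._side[spot])
        if rewarded:
            self.diagonal_preference += p.learn_rate * (g - self.diagonal_preference)
            self.last_rewarded_spot = spot
        else:
            self.diagonal_preference += (
                p.learn_rate * p.perseveration_decay * UNREWARDED_SCALE
                * (-g - self.diagonal_preference)
            )


def adaptive_agent(params: AgentParams, layout: SpotLayout = DEFAULT_LAYOUT) -> AdaptiveAgent:
    if not isinstance(params, AgentParams):
        raise TypeError("params must be an AgentParams")
    return AdaptiveAgent(params, layout)


class Cohort(NamedTuple):
    """Simulated cohort: event logs per subject and the subject -> group map."""

    logs: dict[str, list[SessionLog]]
    groups: dict[str, str]


def make_cohort(
    n_control: int,
    n_dysbiosis: int,
    schedule: ProtocolSchedule | None = None,
    base_seed: int = 0,
    *,
    control_params: AgentParams = CONTROL_PRESET,
    dysbiosis_params: AgentParams = DYSBIOSIS_PRESET,
    mean_inter_poke_s: float | None = None,
) -> Cohort:
    """Simulate a two-group cohort through the full schedule.

    Initial diagonal assignments are counterbalanced within each group;
    subject ``i`` (over the whole cohort, in order) uses seed
    ``base_seed + i``, so the same ``base_seed`` reproduces identical logs.
    """
    if n_control < 0 or n_dysbiosis < 0:
        raise ValueError("group sizes must be >= 0")
    schedule = schedule or make_default_schedule()
    subjects = [f"control-{i + 1}" for i in range(n_control)]
    subjects += [f"dysbiosis-{i + 1}" for i in range(n_dysbiosis)]
    groups = {s: s.rsplit("-", 1)[0] for s in subjects}
    assignments: dict[str, DiagonalAssignment] = {}
    for group in ("control", "dysbiosis"):
        members = [s for s in subjects if groups[s] == group]
        if members:
            assignments.update(counterbalance(members, schedule.layout))
    logs: dict[str, list[SessionLog]] = {}
    for index, subject in enumerate(subjects):
        params = control_params if groups[subject] == "control" else dysbiosis_params
        agent = AdaptiveAgent(params, schedule.layout)
        logs[subject] = run_protocol(
            agent,
            schedule,
            assignments[subject],
            seed=base_seed + index,
            subject_id=subject,
            mean_inter_poke_s=mean_inter_poke_s,
        )
    return Cohort(logs=logs, groups=groups)
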