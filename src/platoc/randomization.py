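"""Adaptive allocation across a shared control arm and staggered experimental arms.

Allocation starts equal across all open arms.  Once the control arm has
treated its cap (default 30 patients), the control probability drops to
1/(1 + 3m) and each open experimental arm receives 3/(1 + 3m), where m is
the number of experimental arms still accruing.  Arms that have filled
their planned sample size stop counting toward m and receive no patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Literal, Sequence

import numpy as np

__all__ = [
    "ArmSpec",
    "AllocationState",
    "ScheduleEvent",
    "allocation_probabilities",
    "assign_patient",
    "open_close_schedule",
]

ArmRole = Literal["control", "experimental"]


@dataclass(frozen=True)
class ArmSpec:
    """Specification of one arm: identity, role, true rate, size, entry time."""

    arm_id: Hashable
    role: ArmRole
    true_rate: float
    planned_n: int = 30
    open_time: float = 0.0  # months from trial start

    def __post_init__(self) -> None:
        if self.role not in ("control", "experimental"):
            raise ValueError(f"role must be control or experimental, got {self.role!r}")
        if not (0.0 <= self.true_rate <= 1.0):
            raise ValueError(f"true_rate must be in [0, 1], got {self.true_rate}")
        if self.planned_n < 0:
            raise ValueError(f"planned_n must be >= 0, got {self.planned_n}")
        if self.open_time < 0:
            raise ValueError(f"open_time must be >= 0, got {self.open_time}")


@dataclass
class AllocationState:
    """Counts that determine the current allocation vector.

    ``active_arm_ids`` lists experimental arms open to accrual and still
    below their planned size; ``m`` is their count.
    """

    control_treated: int
    active_arm_ids: list = field(default_factory=list)
    control_cap: int = 30

    @property
    def m(self) -> int:
        return len(self.active_arm_ids)


def allocation_probabilities(state: AllocationState) -> np.ndarray:
    """Allocation vector over (control, *active experimental arms*).

    Equal 1/(m+1) allocation to every open arm until the control cap is
    reached; thereafter control gets 1/(1+3m) and each experimental arm
    3/(1+3m).  Raises if no experimental arm is open (the trial cannot
    randomize).
    """
    m = state.m
    if m < 1:
        raise ValueError("no open experimental arm: cannot randomize")
    if state.control_treated < state.control_cap:
        return np.full(m + 1, 1.0 / (m + 1))
    return np.array([1.0 / (1 + 3 * m)] + [3.0 / (1 + 3 * m)] * m)


def assign_patient(state: AllocationState, rng: np.random.Generator) -> Hashable:
    """Sample one arm (the control's id is ``"control"``) for the next patient."""
    probs = allocation_probabilities(state)
    idx = int(rng.choice(len(probs), p=probs))
    return "control" if idx == 0 else state.active_arm_ids[idx - 1]


@dataclass(frozen=True)
class ScheduleEvent:
    time: float
    arm_id: Hashable
    kind: Literal["open", "close"]


def open_close_schedule(arms: Sequence[ArmSpec]) -> list[ScheduleEvent]:
    """Planned accrual timeline for a list of arms.

    Emits an ``open`` event at each arm's entry time, ordered by time.  An
    arm closes to accrual once its planned size is reached, which is
    outcome-path dependent; the only closes known in advance are degenerate
    arms with ``planned_n == 0``, which open and close at the same instant.
    """
    ids = [a.arm_id for a in arms]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate arm_ids in {ids}")
    events: list[ScheduleEvent] = []
    for arm in sorted(arms, key=lambda a: a.open_time):
        events.append(ScheduleEvent(arm.open_time, arm.arm_id, "open"))
        if arm.planned_n == 0:
            events.append(ScheduleEvent(arm.open_time, arm.arm_id, "close"))
    return events
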