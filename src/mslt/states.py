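"""Health states of the illness-death-with-recovery model.

Three states: two transient (non-disabled, disabled) and one absorbing
(dead).  Four off-diagonal transitions are modelled between the living
states and into death; remaining in a living state is the reference
("retention") outcome.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """State codes as used in panel files (1/2/3)."""

    NONDISABLED = 1
    DISABLED = 2
    DEAD = 3

    @property
    def is_absorbing(self) -> bool:
        return self is HealthState.DEAD


#: The four modelled transitions, in the canonical parameter ordering.
TRANSITIONS: tuple[tuple[HealthState, HealthState], ...] = (
    (HealthState.NONDISABLED, HealthState.DISABLED),
    (HealthState.NONDISABLED, HealthState.DEAD),
    (HealthState.DISABLED, HealthState.NONDISABLED),
    (HealthState.DISABLED, HealthState.DEAD),
)

#: Human-readable labels for the four transitions ("1->2", ...).
TRANSITION_LABELS: tuple[str, ...] = tuple(
    f"{int(i)}->{int(j)}" for i, j in TRANSITIONS
)
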