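"""Blink-timing command distributor.

Detected events become application commands: lateral movements pass through
one-to-one, while blinks are grouped by their timing to distinguish single,
double, triple and quadruple blinks.  A blink joins the open group if its
onset follows the previous member's onset by at most ``gap_s`` (0.5 s);
judgment on the group is made ``horizon_s`` (1.5 s) after the group's first
onset — except that a fourth blink closes its group immediately, so the
"go back" command is not delayed by the horizon.

Both a whole-list (:func:`group_events`) and an incremental
(:func:`stream_group`) form are provided; replaying a stream reproduces the
whole-list output exactly.  Boundary conventions: a gap of exactly
``gap_s`` still joins; a clock exactly at the horizon flushes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .detector import DetectedEvent

__all__ = [
    "DistributorConfig",
    "CommandEvent",
    "DistributorState",
    "group_events",
    "stream_group",
    "flush",
]

_BLINK_KINDS = {1: "single_blink", 2: "double_blink", 3: "triple_blink", 4: "quadruple_blink"}


@dataclass(frozen=True)
class DistributorConfig:
    """Timing rule parameters (seconds)."""

    gap_s: float = 0.5
    horizon_s: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.gap_s < self.horizon_s:
            raise ValueError(
                f"need 0 < gap_s < horizon_s, got gap_s={self.gap_s}, "
                f"horizon_s={self.horizon_s}"
            )


@dataclass(frozen=True)
class CommandEvent:
    """A command-level event with the onsets of its contributing artifacts."""

    kind: str
    decision_time: float
    member_onsets: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {v: k for k, v in _BLINK_KINDS.items()}
        n = expected.get(self.kind, 1)
        if len(self.member_onsets) != n:
            raise ValueError(
                f"{self.kind} must have {n} member(s), got {len(self.member_onsets)}"
            )
        if self.member_onsets and self.decision_time < max(self.member_onsets):
            raise ValueError("decision_time must not precede the last member onset")


@dataclass
class _Group:
    onsets: list[float]

    @property
    def first(self) -> float:
        return self.onsets[0]

    @property
    def last(self) -> float:
        return self.onsets[-1]


@dataclass
class DistributorState:
    """Pending blink groups awaiting their horizon (newest last)."""

    pending: list[_Group] = field(default_factory=list)
    clock: float = float("-inf")


def _close(group: _Group, config: DistributorConfig) -> CommandEvent:
    kind = _BLINK_KINDS[len(group.onsets)]
    return CommandEvent(
        kind=kind,
        decision_time=group.first + config.horizon_s,
        member_onsets=tuple(group.onsets),
    )


def _advance(
    state: DistributorState, clock_time: float, config: DistributorConfig
) -> list[CommandEvent]:
    """Flush every pending group whose horizon has been reached."""
    out = []
    keep = []
    for group in state.pending:
        if clock_time >= group.first + config.horizon_s:
            out.append(_close(group, config))
        else:
            keep.append(group)
    state.pending = keep
    return out


def stream_group(
    event: DetectedEvent | None,
    clock_time: float,
    state: DistributorState,
    config: DistributorConfig | None = None,
) -> list[CommandEvent]:
    """Incremental grouping: feed one event (or a bare clock tick).

    ``clock_time`` must be monotone non-decreasing across calls; pass
    ``event=None`` to only advance the clock.  Returns the commands decided
    by this call, mutating ``state`` in place.
    """
    config = config or DistributorConfig()
    if clock_time < state.clock:
        raise ValueError(
            f"clock regression: {clock_time} after {state.clock}"
        )
    state.clock = clock_time
    commands = _advance(state, clock_time, config)
    if event is None:
        return commands
    if event.label in ("look_left", "look_right"):
        commands.append(
            CommandEvent(
                kind=event.label,
                decision_time=event.onset,
                member_onsets=(event.onset,),
            )
        )
        return commands
    # Blink: join the newest pending group iff within gap of its last member.
    group = state.pending[-1] if state.pending else None
    if group is not None and event.onset - group.last <= config.gap_s:
        group.onsets.append(event.onset)
        if len(group.onsets) == 4:
            # Quadruple blinks are dispatched immediately, ahead of the horizon.
            state.pending.pop()
            commands.append(
                CommandEvent(
                    kind="quadruple_blink",
                    decision_time=event.onset,
                    member_onsets=tuple(group.onsets),
                )
            )
    else:
        state.pending.append(_Group(onsets=[event.onset]))
    return commands


def flush(
    state: DistributorState, config: DistributorConfig | None = None
) -> list[CommandEvent]:
    """Close out all pending groups (end of stream)."""
    config = config or DistributorConfig()
    out = [_close(g, config) for g in state.pending]
    state.pending = []
    return out


def group_events(
    events: Sequence[DetectedEvent], config: DistributorConfig | None = None
) -> list[CommandEvent]:
    """Whole-list form of the timing rules.

    ``events`` must be sorted by onset.  Commands are returned in decision
    order (lateral commands decide at their own onset).
    """
    config = config or DistributorConfig()
    onsets = [e.onset for e in events]
    if onsets != sorted(onsets):
        raise ValueError("events must be sorted by onset")
    state = DistributorState()
    commands: list[CommandEvent] = []
    for event in events:
        commands.extend(stream_group(event, event.onset, state, config))
    commands.extend(flush(state, config))
    commands.sort(key=lambda c: (c.decision_time, c.member_onsets))
    return commands
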