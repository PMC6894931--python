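"""Virtual pneumatic controller for a multi-pipette patch rig.

Five pressure levels are used through the patching workflow: LOW (+20 mbar)
keeps solution flowing out of idle tips, HIGH (+70 mbar) protects the tip
while advancing through tissue, PATCH is the operator-controlled line for
sealing and break-in (HIGH and PATCH share one output), ATMOSPHERE (0 mbar)
holds established whole-cell recordings, and CLEAN alternates strong suction
(-350 mbar) and pressure (+1000 mbar) for detergent cleaning of the tip.

Each pipette is routed by three two-position solenoid valves in a tree: the
root valve selects the {LOW, HIGH/PATCH} branch or the {ATMOSPHERE, CLEAN}
branch, and the corresponding branch valve picks the channel.  The routing
table is configuration, not hard-coded logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .errors import InvalidArgumentError, ProtocolViolationError

__all__ = [
    "Channel",
    "Phase",
    "ValveState",
    "ScheduleStep",
    "PressureSchedule",
    "RigEvent",
    "CleaningGeometry",
    "PressureRig",
    "cleaning_schedule",
    "las_concentration",
    "DEFAULT_LEVELS_MBAR",
    "DEFAULT_ROUTING",
]


class Channel(str, Enum):
    LOW = "LOW"
    HIGH = "HIGH"
    PATCH = "PATCH"
    ATMOSPHERE = "ATMOSPHERE"
    CLEAN = "CLEAN"


#: static regulator set-points, mbar (PATCH is operator-variable, CLEAN
#: alternates between suction and expulsion per the cleaning schedule)
DEFAULT_LEVELS_MBAR = {
    Channel.LOW: 20.0,
    Channel.HIGH: 70.0,
    Channel.ATMOSPHERE: 0.0,
}

CLEAN_SUCTION_MBAR = -350.0
CLEAN_EXPEL_MBAR = 1000.0  # 1 bar


@dataclass(frozen=True)
class ValveState:
    """Positions of the three tree valves (root, branch A, branch B)."""

    root: int
    branch_a: int
    branch_b: int

    def __post_init__(self):
        for v in (self.root, self.branch_a, self.branch_b):
            if v not in (0, 1):
                raise InvalidArgumentError("valve positions are two-state (0/1)")


#: canonical routing: root=0 selects branch A ({LOW, HIGH/PATCH}), root=1
#: branch B ({ATMOSPHERE, CLEAN}); the unused branch valve rests at 0 so the
#: map channel -> configuration is a bijection over the reachable states.
#: HIGH and PATCH share the branch-A output (selected upstream of the tree).
DEFAULT_ROUTING = {
    Channel.LOW: ValveState(0, 0, 0),
    Channel.HIGH: ValveState(0, 1, 0),
    Channel.PATCH: ValveState(0, 1, 0),
    Channel.ATMOSPHERE: ValveState(1, 0, 0),
    Channel.CLEAN: ValveState(1, 0, 1),
}


class Phase(str, Enum):
    STAGED = "staged"
    APPROACHING = "approaching"
    SEALING = "sealing"
    WHOLE_CELL = "whole_cell"
    FAILED = "failed"


_LEGAL_TRANSITIONS = {
    Phase.STAGED: {Phase.APPROACHING},
    Phase.APPROACHING: {Phase.SEALING},
    Phase.SEALING: {Phase.WHOLE_CELL, Phase.FAILED},
    Phase.WHOLE_CELL: {Phase.FAILED},  # recording deteriorates
    Phase.FAILED: {Phase.STAGED},  # after cleaning, ready for a new attempt
}

#: channel mandated while a pipette sits in each phase
PHASE_CHANNEL = {
    Phase.STAGED: Channel.LOW,
    Phase.APPROACHING: Channel.HIGH,
    Phase.SEALING: Channel.PATCH,
    Phase.WHOLE_CELL: Channel.ATMOSPHERE,
    Phase.FAILED: Channel.CLEAN,  # eligible for cleaning
}


@dataclass(frozen=True)
class ScheduleStep:
    pressure_mbar: float
    duration_s: float
    location: str  # cleaning_well | recording_well_rim | above_slice

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidArgumentError("schedule step durations must be > 0")


@dataclass(frozen=True)
class PressureSchedule:
    steps: tuple

    @property
    def total_active_s(self) -> float:
        return sum(s.duration_s for s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)


def cleaning_schedule(
    n_cycles: int = 5,
    suction_mbar: float = CLEAN_SUCTION_MBAR,
    expel_mbar: float = CLEAN_EXPEL_MBAR,
    cycle_s: float = 1.0,
    expulsion_s: float = 10.0,
) -> PressureSchedule:
    """The detergent cleaning pressure sequence.

    Five cycles of suction (-350 mbar, 1 s) then pressure (+1 bar, 1 s) in
    the cleaning well, a long expulsion (+1 bar, 10 s) still in the cleaning
    well, and a final expulsion (+1 bar, 10 s) at the recording-well rim:
    12 steps, 30 s of active pressure in total.
    """
    steps = []
    for _ in range(n_cycles):
        steps.append(ScheduleStep(suction_mbar, cycle_s, "cleaning_well"))
        steps.append(ScheduleStep(expel_mbar, cycle_s, "cleaning_well"))
    steps.append(ScheduleStep(expel_mbar, expulsion_s, "cleaning_well"))
    steps.append(ScheduleStep(expel_mbar, expulsion_s, "recording_well_rim"))
    return PressureSchedule(tuple(steps))


@dataclass(frozen=True)
class RigEvent:
    timestamp_s: float
    pipette: int
    kind: str  # channel-switch | move-start | move-end | step-start | step-end
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp_s": self.timestamp_s,
                "pipette": self.pipette,
                "kind": self.kind,
                "payload": self.payload,
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class CleaningGeometry:
    """Straight-line travel distances for one cleaning round, micrometres."""

    retract_um: float = 20000.0  # above slice -> above the cleaning well
    lower_um: float = 5000.0  # dip into the detergent
    to_rim_um: float = 15000.0  # cleaning well -> recording-well rim
    return_um: float = 10000.0  # rim -> staged position above the slice

    @property
    def total_um(self) -> float:
        return self.retract_um + self.lower_um + self.to_rim_um + self.return_um


class PressureRig:
    """Discrete-event virtual rig holding per-pipette valve and phase state."""

    def __init__(
        self,
        n_pipettes: int = 10,
        levels_mbar: dict | None = None,
        routing: dict | None = None,
        patch_mbar: float = 0.0,
    ):
        if n_pipettes < 1:
            raise InvalidArgumentError("need at least one pipette")
        self.n_pipettes = n_pipettes
        self.levels = dict(DEFAULT_LEVELS_MBAR if levels_mbar is None else levels_mbar)
        self.routing = dict(DEFAULT_ROUTING if routing is None else routing)
        self.patch_mbar = patch_mbar  # operator-scripted mouthpiece/syringe value
        self.clock_s = 0.0
        self.channel: dict[int, Channel] = {p: Channel.ATMOSPHERE for p in self.pipettes}
        self.phase: dict[int, Phase] = {p: Phase.STAGED for p in self.pipettes}
        self.events: list[RigEvent] = []
        self._last_t: dict[int, float] = {p: 0.0 for p in self.pipettes}

    @property
    def pipettes(self) -> range:
        return range(1, self.n_pipettes + 1)

    # -- helpers ---------------------------------------------------------
    def _check_pipette(self, pipette: int) -> None:
        if pipette not in self.pipettes:
            raise InvalidArgumentError(f"unknown pipette {pipette}")

    def _emit(self, t: float, pipette: int, kind: str, **payload) -> None:
        t = max(t, self._last_t[pipette])  # timestamps non-decreasing per pipette
        self._last_t[pipette] = t
        self.events.append(RigEvent(t, pipette, kind, payload))

    # -- channels --------------------------------------------------------
    def set_channel(self, pipette: int, channel: Channel) -> ValveState:
        """Route ``channel`` to ``pipette``; returns the valve configuration."""
        self._check_pipette(pipette)
        try:
            channel = Channel(channel)
        except ValueError as exc:
            raise InvalidArgumentError(f"unknown channel {channel!r}") from exc
        state = self.routing[channel]
        if self.channel[pipette] != channel:
            self._emit(
                self.clock_s,
                pipette,
                "channel-switch",
                channel=channel.value,
                valves=[state.root, state.branch_a, state.branch_b],
            )
        self.channel[pipette] = channel
        return state

    def pressure_of(self, pipette: int) -> float:
        """Current static pressure at the pipette, mbar."""
        self._check_pipette(pipette)
        ch = self.channel[pipette]
        if ch is Channel.PATCH:
            return self.patch_mbar
        if ch is Channel.CLEAN:
            return CLEAN_SUCTION_MBAR  # schedule alternates; suction is the idle side
        return self.levels[ch]

    # -- patching state machine -----------------------------------------
    def patch_phase_advance(self, pipette: int, phase: Phase) -> Channel:
        """Advance a pipette's patching phase; returns the mandated channel."""
        self._check_pipette(pipette)
        phase = Phase(phase)
        current = self.phase[pipette]
        if phase not in _LEGAL_TRANSITIONS[current]:
            raise ProtocolViolationError(
                f"pipette {pipette}: illegal transition {current.value} -> {phase.value}"
            )
        self.phase[pipette] = phase
        required = PHASE_CHANNEL[phase]
        if phase is not Phase.FAILED:  # FAILED is *eligible* for CLEAN, not switched yet
            self.set_channel(pipette, required)
        return required

    # -- cleaning --------------------------------------------------------
    def run_cleaning(
        self,
        pipettes,
        move_speed_um_s: float = 2000.0,
        geometry: CleaningGeometry | None = None,
        schedule: PressureSchedule | None = None,
    ) -> list[RigEvent]:
        """Clean the selected pipettes concurrently; returns their event log.

        Retract above the cleaning well, dip into the detergent, run the
        pressure schedule, expel at the recording-well rim and return above
        the slice on LOW.  Pipettes holding cells must not be selected and
        are never touched.  Wall time is the 30 s active schedule plus the
        movement legs at ``move_speed_um_s``.
        """
        pipettes = sorted(set(pipettes))
        for p in pipettes:
            self._check_pipette(p)
            if self.phase[p] is Phase.WHOLE_CELL:
                raise ProtocolViolationError(
                    f"pipette {p} holds a whole-cell recording and cannot be cleaned"
                )
        if move_speed_um_s <= 0:
            raise InvalidArgumentError("move_speed_um_s must be > 0")
        geometry = geometry or CleaningGeometry()
        schedule = schedule or cleaning_schedule()
        start = self.clock_s
        n_before = len(self.events)
        legs = [
            ("retract", geometry.retract_um, None),
            ("lower_into_well", geometry.lower_um, None),
            ("to_rim", geometry.to_rim_um, None),
            ("return_above_slice", geometry.return_um, None),
        ]
        # identical timeline for every selected pipette (concurrent motion)
        for p in pipettes:
            t = start
            for name, dist, _ in legs[:2]:
                self._emit(t, p, "move-start", leg=name)
                t += dist / move_speed_um_s
                self._emit(t, p, "move-end", leg=name)
            self.set_channel(p, Channel.CLEAN)
            self._last_t[p] = max(self._last_t[p], t)
            for step in schedule.steps[:-1]:  # all but the rim expulsion
                self._emit(t, p, "step-start", pressure_mbar=step.pressure_mbar,
                           location=step.location)
                t += step.duration_s
                self._emit(t, p, "step-end", pressure_mbar=step.pressure_mbar)
            name, dist, _ = legs[2]
            self._emit(t, p, "move-start", leg=name)
            t += dist / move_speed_um_s
            self._emit(t, p, "move-end", leg=name)
            rim = schedule.steps[-1]
            self._emit(t, p, "step-start", pressure_mbar=rim.pressure_mbar,
                       location=rim.location)
            t += rim.duration_s
            self._emit(t, p, "step-end", pressure_mbar=rim.pressure_mbar)
            name, dist, _ = legs[3]
            self._emit(t, p, "move-start", leg=name)
            t += dist / move_speed_um_s
            self._emit(t, p, "move-end", leg=name)
            self.set_channel(p, Channel.LOW)
            if self.phase[p] is Phase.FAILED:
                self.phase[p] = Phase.STAGED
            end = t
        if pipettes:
            self.clock_s = end
        return self.events[n_before:]


def las_concentration(
    adherent_volume_ul: float,
    bath_volume_ul: float = 1000.0,
    alconox_frac: float = 0.02,
    las_frac_of_alconox: float = 0.20,
) -> float:
    """Percent LAS in the bath after carry-over of detergent on the tip.

    Mass balance: the adherent droplet of Alconox solution (concentration
    ``alconox_frac``, of which ``las_frac_of_alconox`` is the active LAS
    surfactant) dilutes into the bath.  Receptor interference starts around
    0.001% LAS, so sub-microlitre carry-over into a 1 ml bath is ~10x below
    the critical level.
    """
    if adherent_volume_ul < 0 or bath_volume_ul <= 0:
        raise InvalidArgumentError("volumes must be positive (adherent may be 0)")
    for name, f in (("alconox_frac", alconox_frac), ("las_frac_of_alconox", las_frac_of_alconox)):
        if not 0.0 <= f <= 1.0:
            raise InvalidArgumentError(f"{name} must be in [0, 1]")
    las_ul = adherent_volume_ul * alconox_frac * las_frac_of_alconox
    return 100.0 * las_ul / (bath_volume_ul + adherent_volume_ul)
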