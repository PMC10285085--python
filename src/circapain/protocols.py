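"""Light schedules and forced-wakefulness protocols.

Conventions
-----------
Simulation time ``t`` is in minutes and ``t = 0`` corresponds to clock time
08:00 (habitual wake onset / lights-on of the baseline day).  A "sim-clock"
value is ``t mod 1440``: sim-clock 0 is 08:00, sim-clock 960 is midnight,
sim-clock 1140 is 03:00.  Negative times belong to the spin-up period, lit
by the protocol's repeating spin-up cycle.

Light is piecewise constant.  A :class:`DailyCycle` tiles one 24 h day; a
:class:`LightSchedule` is a sequence of phases, each an anchored daily
cycle, so that abrupt schedule shifts (jet lag) are exact step changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MIN_PER_DAY",
    "clock_to_sim",
    "sim_to_clock",
    "DailyCycle",
    "LightSchedule",
    "Protocol",
    "baseline_protocol",
    "daguet_cr_protocol",
    "deprivation_sweep_protocol",
    "jet_lag_protocol",
    "chronic_restriction_protocol",
]

MIN_PER_DAY = 1440.0
#: clock-time (minutes after midnight) of simulation origin: 08:00
ORIGIN_CLOCK_MIN = 480.0


def clock_to_sim(minutes_after_midnight: float) -> float:
    """Convert a wall-clock time to sim-clock minutes (0 = 08:00)."""
    return (minutes_after_midnight - ORIGIN_CLOCK_MIN) % MIN_PER_DAY


def sim_to_clock(t: float) -> float:
    """Wall-clock minutes after midnight for a simulation time."""
    return (t + ORIGIN_CLOCK_MIN) % MIN_PER_DAY


@dataclass(frozen=True)
class DailyCycle:
    """One 24 h piecewise-constant light pattern.

    ``segments`` is an ordered list of (start, end, lux) in sim-clock
    minutes that must tile [0, 1440) exactly.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("cycle needs at least one segment")
        cursor = 0.0
        for start, end, lux in self.segments:
            if start != cursor or end <= start:
                raise ValueError("segments must tile [0, 1440) without gaps")
            if lux < 0:
                raise ValueError("lux must be non-negative")
            cursor = end
        if cursor != MIN_PER_DAY:
            raise ValueError("segments must cover exactly one day")

    @classmethod
    def on_off(
        cls, on_clock: float, hours_on: float, day_lux: float, night_lux: float
    ) -> "DailyCycle":
        """Light:dark alternation with lights-on at sim-clock ``on_clock``."""
        on = on_clock % MIN_PER_DAY
        off = (on + hours_on * 60.0) % MIN_PER_DAY
        if hours_on <= 0:
            return cls(((0.0, MIN_PER_DAY, night_lux),))
        if hours_on >= 24:
            return cls(((0.0, MIN_PER_DAY, day_lux),))
        if on < off:
            segs = []
            if on > 0:
                segs.append((0.0, on, night_lux))
            segs.append((on, off, day_lux))
            if off < MIN_PER_DAY:
                segs.append((off, MIN_PER_DAY, night_lux))
        else:  # lit interval wraps midnight of the sim-clock
            segs = [(0.0, off, day_lux), (off, on, night_lux), (on, MIN_PER_DAY, day_lux)]
        return cls(tuple(segs))

    @classmethod
    def constant(cls, lux: float) -> "DailyCycle":
        return cls(((0.0, MIN_PER_DAY, lux),))

    def lux_at(self, sim_clock: float) -> float:
        c = sim_clock % MIN_PER_DAY
        for start, end, lux in self.segments:
            if start <= c < end:
                return lux
        raise AssertionError("unreachable: cycle tiles the day")

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Sim-clock times at which the lux level may step."""
        return tuple(s for s, _, _ in self.segments)


@dataclass(frozen=True)
class LightSchedule:
    """Sequence of (start time, daily cycle) phases tiling [0, duration)."""

    phases: tuple[tuple[float, DailyCycle], ...]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        starts = [s for s, _ in self.phases]
        if not starts or starts[0] != 0.0 or starts != sorted(starts):
            raise ValueError("phases must start at 0 and be sorted")

    def _phase_at(self, t: float) -> DailyCycle:
        cyc = self.phases[0][1]
        for start, cycle in self.phases:
            if t >= start:
                cyc = cycle
            else:
                break
        return cyc

    def lux_at(self, t: float) -> float:
        """Total lookup over [0, duration); the tail cycle repeats beyond."""
        if t < 0:
            raise ValueError("schedule times start at 0")
        return self._phase_at(t).lux_at(t % MIN_PER_DAY)

    def breakpoints(self, a: float, b: float) -> list[float]:
        """All times in (a, b) where the lux level may be discontinuous."""
        pts: set[float] = set()
        for start, _ in self.phases:
            if a < start < b:
                pts.add(start)
        # daily cycle boundaries of whichever phase is active
        day0 = int(a // MIN_PER_DAY)
        day1 = int(b // MIN_PER_DAY) + 1
        for day in range(day0, day1 + 1):
            base = day * MIN_PER_DAY
            for c in self._phase_at(base).boundaries + self._phase_at(
                max(base, a)
            ).boundaries:
                t = base + c
                if a < t < b:
                    pts.add(t)
        return sorted(pts)


@dataclass(frozen=True)
class Protocol:
    """A complete experiment: light schedule, forcing, duration, spin-up.

    ``forced_wake_intervals`` are half-open [start, end) windows during
    which sleep is prevented.  ``spinup_cycle`` is the repeating 24 h light
    pattern applied for ``spinup_days`` before t = 0 to entrain the model.
    """

    light: LightSchedule
    duration: float
    forced_wake_intervals: tuple[tuple[float, float], ...] = ()
    spinup_cycle: DailyCycle | None = None
    spinup_days: int = 20
    label: str = ""

    def __post_init__(self) -> None:
        last = -float("inf")
        for start, end in self.forced_wake_intervals:
            if end <= start:
                raise ValueError("forced interval must have positive length")
            if start < 0 or end > self.duration:
                raise ValueError("forced interval outside [0, duration]")
            if start < last:
                raise ValueError("forced intervals must be sorted, non-overlapping")
            last = end
        if self.spinup_cycle is None:
            object.__setattr__(self, "spinup_cycle", self.light.phases[0][1])

    def lux_at(self, t: float) -> float:
        if t < 0:
            return self.spinup_cycle.lux_at(t % MIN_PER_DAY)
        return self.light.lux_at(min(t, self.duration - 1e-9))

    def forced_at(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.forced_wake_intervals)

    def without_forcing(self) -> "Protocol":
        """Matched control: identical light and spin-up, no forcing."""
        return replace(self, forced_wake_intervals=(), label=self.label + "_control")

    def breakpoints(self, a: float, b: float) -> list[float]:
        """Discontinuities of light or forcing in (a, b)."""
        pts: set[float] = set()
        if a < 0:
            day0 = int(a // MIN_PER_DAY)
            for day in range(day0, 1):
                for c in self.spinup_cycle.boundaries:
                    t = day * MIN_PER_DAY + c
                    if a < t < min(b, 0.0):
                        pts.add(t)
            if a < 0.0 < b:
                pts.add(0.0)
        if b > 0:
            pts.update(self.light.breakpoints(max(a, 0.0), min(b, self.duration)))
        for s, e in self.forced_wake_intervals:
            for t in (s, e):
                if a < t < b:
                    pts.add(t)
        return sorted(pts)


def baseline_protocol(
    ld_split: tuple[float, float] = (14.0, 10.0),
    day_lux: float = 600.0,
    night_lux: float = 0.0,
    days: float = 10.0,
) -> Protocol:
    """Repeating light:dark day with lights-on at 08:00 and no forcing.

    ``(14, 10)`` at 600:0 lux is the reference entrained condition; the
    (12, 12) splits at 0.5 or 600 lux build the recovery and deprivation
    sweep baselines.
    """
    light_h, dark_h = ld_split
    if abs(light_h + dark_h - 24.0) > 1e-9:
        raise ValueError("light:dark split must sum to 24 h")
    cycle = DailyCycle.on_off(0.0, light_h, day_lux, night_lux)
    return Protocol(
        light=LightSchedule(((0.0, cycle),), days * MIN_PER_DAY),
        duration=days * MIN_PER_DAY,
        label=f"baseline_{light_h:g}:{dark_h:g}_{day_lux:g}lux",
    )


def daguet_cr_protocol(recovery_days: float = 4.5) -> Protocol:
    """The 34 h constant-routine deprivation protocol, with recovery tail.

    Day 1: 0.5 lux 08:00-24:00 and darkness 24:00-08:00 (16 h wake, 8 h
    sleep opportunity).  From 08:00 of day 2, 34 h of forced wakefulness at
    a constant 0.5 lux, ending 18:00 on day 3.  Then ``recovery_days`` of a
    12:12 light:dark schedule at the 0.5 lux laboratory setting.

    Spin-up uses a standard 12:12 indoor day (600:0 lux, lights-on 08:00),
    so the pacemaker enters the protocol entrained with its minimum near
    03:00.
    """
    day1 = DailyCycle.on_off(0.0, 16.0, 0.5, 0.0)
    cr = DailyCycle.constant(0.5)
    recovery = DailyCycle.on_off(0.0, 12.0, 0.5, 0.0)
    t_dep_start = MIN_PER_DAY  # 08:00 day 2
    t_dep_end = t_dep_start + 34.0 * 60.0  # 18:00 day 3
    duration = t_dep_end + recovery_days * MIN_PER_DAY
    light = LightSchedule(
        ((0.0, day1), (t_dep_start, cr), (t_dep_end, recovery)), duration
    )
    return Protocol(
        light=light,
        duration=duration,
        forced_wake_intervals=((t_dep_start, t_dep_end),),
        spinup_cycle=DailyCycle.on_off(0.0, 12.0, 600.0, 0.0),
        label="daguet_cr",
    )


def deprivation_sweep_protocol(
    total_hours_awake: float,
    wake_onset_min: float = 0.0,
    days: float = 7.0,
) -> Protocol:
    """Sleep-deprivation protocol labeled by total time awake.

    The count includes the ~12 h of habitual wake time of the 12:12
    600:0 lux baseline, so totals of 12 h or less impose no forcing.
    ``wake_onset_min`` is the entrained wake-onset time of the matched
    control (sim minutes; emergent from the model, measured by the caller),
    from which the forced window extends for ``total_hours_awake`` hours.
    """
    if total_hours_awake < 0:
        raise ValueError("total hours awake must be non-negative")
    base = baseline_protocol((12.0, 12.0), 600.0, 0.0, days)
    if total_hours_awake <= 12.0:
        return replace(base, label=f"sweep_{total_hours_awake:g}h")
    start = wake_onset_min
    end = start + total_hours_awake * 60.0
    return replace(
        base,
        forced_wake_intervals=((start, end),),
        label=f"sweep_{total_hours_awake:g}h",
    )


def jet_lag_protocol(
    direction: str,
    zones: int = 5,
    with_flight_deprivation: bool = False,
    days_before_switch: float = 2.0,
    total_days: float = 18.0,
) -> Protocol:
    """Abrupt light-schedule shift simulating travel across time zones.

    The origin keeps a 12:12 light:dark day at 600:0 lux with lights-on
    08:00.  At 08:00 origin time on the travel day (arrival time: 1 p.m.
    destination time for the 5 h eastward trip, 3 a.m. for the westward),
    the schedule steps to the destination's, which is the same 12:12 day
    shifted ``zones`` hours earlier (east) or later (west) in origin time.
    With ``with_flight_deprivation``, the flight's forced-wake interval (8 h
    east, 11 h west) ends at the switch instant.
    """
    if direction not in ("east", "west"):
        raise ValueError(f"direction must be 'east' or 'west', got {direction!r}")
    shift_min = zones * 60.0
    origin = DailyCycle.on_off(0.0, 12.0, 600.0, 0.0)
    # destination lights-on in origin sim-clock: earlier for east, later for west
    on = (-shift_min if direction == "east" else shift_min) % MIN_PER_DAY
    dest = DailyCycle.on_off(on, 12.0, 600.0, 0.0)
    t_switch = days_before_switch * MIN_PER_DAY
    duration = total_days * MIN_PER_DAY
    forced: tuple[tuple[float, float], ...] = ()
    if with_flight_deprivation:
        flight_h = 8.0 if direction == "east" else 11.0
        forced = ((t_switch - flight_h * 60.0, t_switch),)
    return Protocol(
        light=LightSchedule(((0.0, origin), (t_switch, dest)), duration),
        duration=duration,
        forced_wake_intervals=forced,
        spinup_cycle=origin,
        label=f"jetlag_{direction}{zones}"
        + ("_deprived" if with_flight_deprivation else ""),
    )


def chronic_restriction_protocol(days: int = 7) -> Protocol:
    """A week with sleep restricted to the 04:00-08:00 window nightly.

    Indoor fluorescent light (600 lux) during the 20 h of forced
    wakefulness, darkness during the 4 h sleep opportunity.  Spin-up uses
    the unrestricted 12:12 600:0 lux control day.
    """
    # 04:00 is sim-clock 1200 (20 h after the 08:00 origin)
    cycle = DailyCycle(((0.0, 1200.0, 600.0), (1200.0, MIN_PER_DAY, 0.0)))
    duration = days * MIN_PER_DAY
    forced = tuple(
        (d * MIN_PER_DAY, d * MIN_PER_DAY + 1200.0) for d in range(days)
    )
    return Protocol(
        light=LightSchedule(((0.0, cycle),), duration),
        duration=duration,
        forced_wake_intervals=forced,
        spinup_cycle=DailyCycle.on_off(0.0, 12.0, 600.0, 0.0),
        label="chronic_restriction",
    )
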