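"""Head-fixation task logic, hardware-free.

Re-implements the control logic of an automated home-cage head-fixation
rig: RFID-gated session tracking, entrance/contact/fixation reward
economics, probabilistic head-fixation, in-trial reward and flash-stimulus
scheduling, and a stochastic virtual-mouse colony that exercises the whole
state machine for testing and synthetic-data generation.

The cage holds up to five RFID-tagged mice.  A mouse entering the fixation
tube earns a small entrance reward (subject to a daily cap); touching the
contact plates with its head bar triggers, with configurable probability,
solenoid head-fixation and a fixed-duration imaging trial with water
rewards at regular intervals.  Non-fixed contact trials still dispense the
full fixation-value reward so that the contingency is not aversive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CageConfig",
    "Event",
    "EventLog",
    "TrialRecord",
    "CageState",
    "VirtualMouse",
    "LogConsistencyError",
    "ImpossibleStateError",
    "ConfigurationError",
    "step_state_machine",
    "schedule_trial_rewards",
    "schedule_stimuli",
    "associate_sessions",
    "holding_force",
    "run_virtual_colony",
    "total_dispensed_ul",
]

GRAVITY_M_S2 = 9.81

EVENT_KINDS = ("entry", "exit", "contact", "fix_start", "fix_end", "reward", "stim")
REWARD_KINDS = ("entrance", "contact", "fix")


class LogConsistencyError(ValueError):
    """An event sequence violates the cage's physical constraints."""


class ImpossibleStateError(ValueError):
    """Two mice appear to occupy the fixation tube simultaneously."""


class ConfigurationError(ValueError):
    """A cage configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CageConfig:
    """Cage task parameters.

    Volumes in microlitres, durations in seconds.  ``fix_reward_multiplier``
    is the ratio of total water per fixation trial to one entrance reward
    (deployed systems used up to 30x).  ``fix_probability`` is the chance
    that a plate contact actually engages the solenoids; non-fixed contacts
    dispense the full fixation-value reward.  ``reward_times`` overrides the
    regular ``reward_interval_s`` schedule with explicit offsets from trial
    start (e.g. rewards only at the beginning and end of a long trial).
    ``training_contact_rewards`` enables the training-phase behaviour where
    plate contact alone (solenoids off) earns the fixation-value reward.
    """

    entrance_reward_ul: float = 6.5          # ~5-8 ul drops
    fix_reward_multiplier: float = 30.0      # allowed 4-30
    entrance_reward_cap: int = 100           # per mouse per light-cycle day
    fix_probability: float = 0.65
    trial_duration_s: float = 30.0
    reward_interval_s: float = 10.0
    valve_open_ms: float = 400.0
    reward_times: tuple[float, ...] | None = None
    stim_trial_fraction: float = 0.65
    flash_interval_s: float = 5.0
    flashes_per_trial: int = 4
    first_flash_offset_s: float = 2.0
    stim_enabled: bool = False
    lights_on_hour: float = 7.0
    training_contact_rewards: bool = True
    release_latency_s: float = 0.0           # solenoid release modelled as instant

    def __post_init__(self) -> None:
        if not 0.0 <= self.fix_probability <= 1.0:
            raise ConfigurationError("fix_probability must lie in [0, 1]")
        for name in ("entrance_reward_ul", "trial_duration_s", "reward_interval_s",
                     "valve_open_ms", "flash_interval_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.entrance_reward_cap < 0:
            raise ConfigurationError("entrance_reward_cap must be >= 0")
        if not 0.0 <= self.stim_trial_fraction <= 1.0:
            raise ConfigurationError("stim_trial_fraction must lie in [0, 1]")
        if self.flashes_per_trial < 1:
            raise ConfigurationError("flashes_per_trial must be >= 1")

    @property
    def fix_trial_total_ul(self) -> float:
        """Total water dispensed over one fixation (or contact) trial."""
        return self.entrance_reward_ul * self.fix_reward_multiplier


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    """One timestamped cage event.

    ``t`` is seconds since session start; ``payload`` carries kind-specific
    fields (reward ``volume_ul`` and ``reward_kind``; stim ``flash_index``;
    fix_start ``trial_duration_s``).
    """

    t: float
    tag: str
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventLog:
    """Time-ordered cage events for one session, keyed by mouse tag.

    ``t0_iso`` anchors the relative timestamps to wall-clock time;
    ``t0_hour`` is the local hour-of-day at t=0 (needed for diurnal
    binning and the lights-cycle day boundary).
    """

    events: list[Event] = field(default_factory=list)
    t0_iso: str | None = None
    t0_hour: float = 7.0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def append(self, event: Event) -> None:
        if self.events and event.t < self.events[-1].t - 1e-9:
            raise LogConsistencyError(
                f"non-monotone timestamp {event.t} after {self.events[-1].t}")
        self.events.append(event)

    def extend(self, events) -> None:
        for e in sorted(events, key=lambda e: e.t):
            self.append(e)

    def for_tag(self, tag: str) -> list[Event]:
        return [e for e in self.events if e.tag == tag]

    def of_kind(self, *kinds: str) -> list[Event]:
        return [e for e in self.events if e.kind in kinds]

    @property
    def tags(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            if e.tag:
                seen.setdefault(e.tag, None)
        return list(seen)

    def validate(self) -> None:
        """Check ordering, entry/exit alternation and fix pairing.

        Raises :class:`LogConsistencyError` naming the first offending
        event index (0-based line number in JSONL/CSV exports).
        """
        last_t = -math.inf
        in_tube: dict[str, bool] = {}
        open_fix: dict[str, float] = {}
        for i, e in enumerate(self.events):
            if e.t < last_t - 1e-9:
                raise LogConsistencyError(
                    f"line {i}: timestamp {e.t} decreases below {last_t}")
            last_t = e.t
            if e.kind == "entry":
                if in_tube.get(e.tag):
                    raise LogConsistencyError(
                        f"line {i}: entry for {e.tag} without prior exit")
                in_tube[e.tag] = True
            elif e.kind == "exit":
                if not in_tube.get(e.tag):
                    raise LogConsistencyError(
                        f"line {i}: exit for {e.tag} without prior entry")
                in_tube[e.tag] = False
            elif e.kind == "fix_start":
                if e.tag in open_fix:
                    raise LogConsistencyError(
                        f"line {i}: nested fix_start for {e.tag}")
                if open_fix:
                    other = next(iter(open_fix))
                    raise ImpossibleStateError(
                        f"line {i}: fix_start for {e.tag} while {other} is fixed")
                open_fix[e.tag] = e.t
            elif e.kind == "fix_end":
                if e.tag not in open_fix:
                    raise LogConsistencyError(
                        f"line {i}: fix_end for {e.tag} without fix_start")
                del open_fix[e.tag]
        if open_fix:
            tag = next(iter(open_fix))
            raise LogConsistencyError(f"fix_start for {tag} never closed")

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for e in self.events:
            row = {"t": e.t, "tag": e.tag, "kind": e.kind}
            row.update(e.payload)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TrialRecord:
    """One head-fixation episode with its rewards, stimuli and linked movie."""

    mouse_tag: str
    fix_start: float
    fix_end: float
    reward_times: list[float] = field(default_factory=list)
    stim_times: list[float] = field(default_factory=list)
    movie_id: str | None = None

    def __post_init__(self) -> None:
        if self.fix_end < self.fix_start:
            raise LogConsistencyError("fix_end precedes fix_start")
        for t in list(self.reward_times) + list(self.stim_times):
            if not (self.fix_start - 1e-9 <= t <= self.fix_end + 1e-9):
                raise LogConsistencyError(
                    f"event at {t} outside trial [{self.fix_start}, {self.fix_end}]")

    @property
    def duration_s(self) -> float:
        return self.fix_end - self.fix_start


# ---------------------------------------------------------------------------
# rig analytics
# ---------------------------------------------------------------------------


def holding_force(lift_kg: float, contact_angle_deg: float) -> float:
    """Holding force (N) of the solenoid pistons on the head bar.

    A solenoid with linear lift capacity ``lift_kg`` contacting the bar at
    ``contact_angle_deg`` transfers ``m * g * sin(angle)`` newtons.
    """
    if lift_kg <= 0:
        raise ValueError("lift_kg must be positive")
    if not 0.0 < contact_angle_deg <= 90.0:
        raise ValueError("contact angle must lie in (0, 90] degrees")
    return lift_kg * GRAVITY_M_S2 * math.sin(math.radians(contact_angle_deg))


# ---------------------------------------------------------------------------
# state machine
# ---------------------------------------------------------------------------

PHASES = ("idle", "mouse_in_tube", "contact", "fixed", "releasing")


@dataclass
class CageState:
    """Mutable controller state threaded through :func:`step_state_machine`."""

    phase: str = "idle"
    current_tag: str | None = None
    fix_start_t: float | None = None
    trial_end_t: float | None = None
    pending: list[Event] = field(default_factory=list)   # scheduled future events
    entrance_rewards: dict = field(default_factory=dict)  # (tag, day) -> count
    t0_hour: float = 7.0

    def day_index(self, t: float, lights_on_hour: float) -> int:
        """Light-cycle day containing time ``t`` (day boundary at lights-on)."""
        hours = t / 3600.0 + self.t0_hour - lights_on_hour
        return int(math.floor(hours / 24.0))


def schedule_trial_rewards(fix_start: float, config: CageConfig) -> list[Event]:
    """Water-reward events for one fixation trial.

    Default schedule: one reward at trial start then every
    ``reward_interval_s`` for the trial duration (0, 10, 20 s in a 30 s
    trial), each a 400 ms valve opening; total trial volume is split
    equally across them.  ``config.reward_times`` overrides the offsets.
    """
    if config.reward_times is not None:
        offsets = [float(x) for x in config.reward_times]
    else:
        n = max(1, int(math.ceil(
            (config.trial_duration_s - 1e-9) / config.reward_interval_s)))
        offsets = [i * config.reward_interval_s for i in range(n)]
    for off in offsets:
        if not 0.0 <= off <= config.trial_duration_s:
            raise ConfigurationError(f"reward offset {off} outside trial")
    vol = config.fix_trial_total_ul / len(offsets)
    return [
        Event(fix_start + off, "", "reward",
              {"volume_ul": vol, "reward_kind": "fix",
               "valve_open_ms": config.valve_open_ms})
        for off in offsets
    ]


def schedule_stimuli(trial: TrialRecord, config: CageConfig,
                     rng: np.random.Generator) -> list[float]:
    """Flash-stimulus times for one trial.

    With probability ``stim_trial_fraction`` the trial carries
    ``flashes_per_trial`` flashes spaced exactly ``flash_interval_s`` apart,
    starting ``first_flash_offset_s`` after fixation; otherwise no flashes.
    """
    span = (config.first_flash_offset_s
            + (config.flashes_per_trial - 1) * config.flash_interval_s)
    if span > trial.duration_s + 1e-9:
        raise ConfigurationError(
            f"{config.flashes_per_trial} flashes spanning {span:.1f}s do not fit "
            f"in a {trial.duration_s:.1f}s trial")
    if rng.random() >= config.stim_trial_fraction:
        return []
    return [trial.fix_start + config.first_flash_offset_s + i * config.flash_interval_s
            for i in range(config.flashes_per_trial)]


def step_state_machine(state: CageState, sensor_event: Event,
                       config: CageConfig, rng: np.random.Generator,
                       ) -> tuple[CageState, list[Event]]:
    """Advance the controller by one sensor event; return emitted log events.

    Sensor inputs are ``entry``/``exit``/``contact`` events (from the RFID
    reader and head-bar plates) plus the synthetic kind ``fix_end`` with tag
    ``"power_loss"`` payload used to inject a power failure.  Scheduled
    in-trial events (rewards, stimuli, fix_end) are emitted immediately with
    their future timestamps; a power loss cancels any not-yet-due scheduled
    events and releases the mouse at once (spring-driven release).
    """
    t = sensor_event.t
    emitted: list[Event] = []

    # power loss: emit whatever came due, then release and cancel the rest
    if sensor_event.payload.get("power_loss"):
        emitted.extend(e for e in state.pending
                       if e.t <= t and e.kind != "fix_end")
        state.pending = []
        if state.phase == "fixed" and state.current_tag is not None:
            emitted.append(Event(t, state.current_tag, "fix_end",
                                 {"reason": "power_loss"}))
            state.phase = "mouse_in_tube"
            state.fix_start_t = None
            state.trial_end_t = None
        return state, sorted(emitted, key=lambda e: e.t)

    # release scheduled events that have come due
    due = [e for e in state.pending if e.t <= t]
    state.pending = [e for e in state.pending if e.t > t]
    emitted.extend(due)
    if state.phase == "fixed" and state.trial_end_t is not None \
            and t >= state.trial_end_t:
        state.phase = "mouse_in_tube"
        state.fix_start_t = None
        state.trial_end_t = None

    kind, tag = sensor_event.kind, sensor_event.tag

    if kind == "entry":
        if state.phase == "fixed":
            raise ImpossibleStateError(
                f"entry of {tag} at t={t} while {state.current_tag} is fixed")
        state.phase = "mouse_in_tube"
        state.current_tag = tag
        day = state.day_index(t, config.lights_on_hour)
        key = (tag, day)
        count = state.entrance_rewards.get(key, 0)
        emitted.append(sensor_event)
        if count < config.entrance_reward_cap:
            state.entrance_rewards[key] = count + 1
            emitted.append(Event(t, tag, "reward",
                                 {"volume_ul": config.entrance_reward_ul,
                                  "reward_kind": "entrance",
                                  "valve_open_ms": config.valve_open_ms}))
    elif kind == "contact":
        if state.current_tag != tag or state.phase == "idle":
            raise LogConsistencyError(
                f"contact by {tag} at t={t} with no prior entry")
        emitted.append(sensor_event)
        state.phase = "contact"
        if rng.random() < config.fix_probability:
            fix_end = t + config.trial_duration_s + config.release_latency_s
            emitted.append(Event(t, tag, "fix_start",
                                 {"trial_duration_s": config.trial_duration_s}))
            state.phase = "fixed"
            state.fix_start_t = t
            state.trial_end_t = fix_end
            schedule: list[Event] = [
                replace(e, tag=tag) for e in schedule_trial_rewards(t, config)]
            if config.stim_enabled:
                trial = TrialRecord(tag, t, fix_end)
                for i, st in enumerate(schedule_stimuli(trial, config, rng)):
                    schedule.append(Event(st, tag, "stim", {"flash_index": i}))
            schedule.append(Event(fix_end, tag, "fix_end", {}))
            state.pending.extend(sorted(schedule, key=lambda e: e.t))
        else:
            # non-fixed trial still dispenses the maximum-value reward
            emitted.append(Event(t, tag, "reward",
                                 {"volume_ul": config.fix_trial_total_ul,
                                  "reward_kind": "contact",
                                  "valve_open_ms": config.valve_open_ms}))
            state.phase = "mouse_in_tube"
    elif kind == "exit":
        if state.phase == "fixed" and state.current_tag == tag:
            raise ImpossibleStateError(f"exit of {tag} at t={t} while fixed")
        emitted.append(sensor_event)
        if state.current_tag == tag:
            state.phase = "idle"
            state.current_tag = None
    else:
        emitted.append(sensor_event)

    return state, sorted(emitted, key=lambda e: e.t)


def total_dispensed_ul(log: EventLog) -> float:
    """Total water volume recorded in a log (microlitres)."""
    return float(sum(e.payload.get("volume_ul", 0.0)
                     for e in log.events if e.kind == "reward"))


# ---------------------------------------------------------------------------
# session association
# ---------------------------------------------------------------------------


def associate_sessions(log: EventLog, movie_index,
                       ) -> tuple[list[TrialRecord], list[str]]:
    """Assign movies to mice from RFID entry/exit times.

    ``movie_index`` is an iterable of ``(movie_id, t_start, t_end)``.  A
    movie is assigned to the unique tag whose entry-exit interval contains
    its full time span; movies spanning an exit (or matching no interval)
    are returned in the unassigned list.  Fixation trials inside the log are
    linked to the movie covering them.
    """
    log.validate()
    intervals: list[tuple[float, float, str]] = []
    open_entry: dict[str, float] = {}
    for e in log.events:
        if e.kind == "entry":
            open_entry[e.tag] = e.t
        elif e.kind == "exit" and e.tag in open_entry:
            intervals.append((open_entry.pop(e.tag), e.t, e.tag))
    for tag, t_in in open_entry.items():  # still inside at end of log
        intervals.append((t_in, math.inf, tag))

    records: list[TrialRecord] = []
    open_fix: dict[str, TrialRecord] = {}
    for e in log.events:
        if e.kind == "fix_start":
            open_fix[e.tag] = TrialRecord(e.tag, e.t, e.t)
        elif e.kind == "fix_end" and e.tag in open_fix:
            r = open_fix.pop(e.tag)
            r.fix_end = e.t
            records.append(r)
        elif e.kind == "reward" and e.tag in open_fix \
                and e.payload.get("reward_kind") == "fix":
            open_fix[e.tag].reward_times.append(e.t)
        elif e.kind == "stim" and e.tag in open_fix:
            open_fix[e.tag].stim_times.append(e.t)
    records.sort(key=lambda r: r.fix_start)

    unassigned: list[str] = []
    for movie_id, m0, m1 in movie_index:
        owners = [tag for (a, b, tag) in intervals if a <= m0 and m1 <= b]
        if len(owners) != 1:
            unassigned.append(movie_id)
            continue
        tag = owners[0]
        for r in records:
            if (r.mouse_tag == tag and r.movie_id is None
                    and m0 <= r.fix_start and r.fix_end <= m1):
                r.movie_id = movie_id
                break
    return records, unassigned


# ---------------------------------------------------------------------------
# virtual colony
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VirtualMouse:
    """Fixed-propensity stochastic agent standing in for one mouse.

    ``entries_per_day`` is the mean daily tube-entry count; ``contact_prob``
    the chance a visit proceeds to plate contact; ``nocturnal_bias`` the
    night/day entry-rate ratio (>1 = nocturnal); ``dwell_s`` the mean
    non-trial visit duration.
    """

    tag: str
    entries_per_day: float = 80.0
    contact_prob: float = 0.15
    nocturnal_bias: float = 2.0
    dwell_s: float = 8.0

    def rate_per_s(self, hour_of_day: float, lights_on_hour: float) -> float:
        """Instantaneous entry rate, diurnally modulated, integrating to
        entries_per_day over 24 h."""
        night = not (lights_on_hour <= hour_of_day % 24.0
                     < lights_on_hour + 12.0)
        base = self.entries_per_day / 86400.0
        # split so that 12h day + 12h night average to the daily mean
        scale = 2.0 * self.nocturnal_bias / (1.0 + self.nocturnal_bias)
        return base * (scale if night else 2.0 - scale)


def run_virtual_colony(agents: list[VirtualMouse], config: CageConfig,
                       days: float, seed: int,
                       t0_hour: float = 7.0) -> EventLog:
    """Simulate a multi-day cage with competing virtual mice.

    Entry times are drawn per agent from a diurnally modulated Poisson
    process (thinning); only one mouse occupies the tube at a time, so an
    agent whose draw collides with an occupied tube retries after the
    occupant leaves.  Every visit runs through the same state machine the
    real cage would use, so the resulting log satisfies all EventLog
    invariants by construction.
    """
    if not agents:
        return EventLog(t0_hour=t0_hour)
    rng = np.random.default_rng(seed)
    horizon = days * 86400.0
    state = CageState(t0_hour=t0_hour)
    log = EventLog(t0_hour=t0_hour)

    max_rates = {
        a.tag: max(a.rate_per_s(h, config.lights_on_hour) for h in range(24))
        for a in agents
    }

    def next_entry(agent: VirtualMouse, after: float) -> float:
        t = after
        lam_max = max_rates[agent.tag]
        if lam_max <= 0:
            return math.inf
        while t < horizon:
            t += rng.exponential(1.0 / lam_max)
            hour = (t / 3600.0 + t0_hour) % 24.0
            if rng.random() < agent.rate_per_s(hour, config.lights_on_hour) / lam_max:
                return t
        return math.inf

    pending_entries = {a.tag: next_entry(a, 0.0) for a in agents}
    agents_by_tag = {a.tag: a for a in agents}
    busy_until = 0.0

    while True:
        tag = min(pending_entries, key=pending_entries.get)
        t = pending_entries[tag]
        if t >= horizon:
            break
        agent = agents_by_tag[tag]
        if t < busy_until:  # tube occupied; retry shortly after it frees
            pending_entries[tag] = busy_until + rng.exponential(2.0)
            continue

        emitted: list[Event] = []
        state, ev = step_state_machine(state, Event(t, tag, "entry"), config, rng)
        emitted.extend(ev)
        t_exit = t + rng.exponential(agent.dwell_s)
        if rng.random() < agent.contact_prob:
            t_contact = t + rng.uniform(1.0, 3.0)
            state, ev = step_state_machine(
                state, Event(t_contact, tag, "contact"), config, rng)
            emitted.extend(ev)
            if state.phase == "fixed":
                # trial runs to completion; exit shortly after release
                t_exit = state.trial_end_t + rng.exponential(2.0)
                state, ev = step_state_machine(
                    state, Event(t_exit, tag, "exit"), config, rng)
                emitted.extend(ev)
                busy_until = t_exit
                log.extend(emitted)
                pending_entries[tag] = next_entry(agent, t_exit)
                continue
        t_exit = max(t_exit, (emitted[-1].t if emitted else t) + 0.5)
        state, ev = step_state_machine(state, Event(t_exit, tag, "exit"), config, rng)
        emitted.extend(ev)
        busy_until = t_exit
        log.extend(emitted)
        pending_entries[tag] = next_entry(agent, t_exit)

    log.validate()
    return log
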