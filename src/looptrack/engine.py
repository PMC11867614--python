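"""Event loop and context system for closed-loop 1D track tasks.

A *context* is a group of stimuli activated together: it owns a set of track
zones (empty = global), a list of device actions to emit on activation /
deactivation edges, and an ordered stack of *decorators* — composable
conjunctive conditions (even laps only, after 5 minutes, laps 10-20,
alternating blocks) that gate the base zone check.

Each step of the loop processes inbound device messages (position deltas,
lap resets, licks, acks), updates the experiment state, evaluates every
context in settings order, and emits start/stop action messages only on
activation edges.  Every emitted message and state change yields a
timestamped behavior record.

Reward contexts support two modes: *non-operant* (reward on zone entry) and
*operant* (reward only when the animal licks inside the zone), in both
cases at most once per lap per zone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Callable, Sequence

from looptrack.behavior_log import BehaviorLogWriter, BehaviorRecord
from looptrack.messaging import (AckPolicy, Message, ParseError, decode_message,
                                 encode_message, send_with_ack)
from looptrack.tracking import (TrackConfig, TrackState, apply_lap_reset,
                                circular_distance, integrate_ticks)


class SettingsError(ValueError):
    """Settings file failed schema validation at load time."""


@dataclass(frozen=True)
class Zone:
    """Track interval defined by a location and radius (mm)."""

    center_mm: float
    radius_mm: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")

    def contains(self, position_mm: float, cfg: TrackConfig) -> bool:
        if cfg.circular:
            d = circular_distance(position_mm, self.center_mm,
                                  cfg.track_length_mm)
        else:
            d = abs(position_mm - self.center_mm)
        return d <= self.radius_mm


DECORATOR_KINDS = ("lap_parity", "time_window", "lap_range", "alternation")


@dataclass(frozen=True)
class DecoratorSpec:
    """One conjunctive activation condition.

    kinds:
      lap_parity   params: parity "even" | "odd"
      time_window  params: start_ms, end_ms (end omitted = unbounded)
      lap_range    params: min, max (inclusive)
      alternation  params: period_laps, phase — active during alternating
                   blocks of ``period_laps`` laps, starting with an active
                   block when phase = 0
    """

    kind: str
    params: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in DECORATOR_KINDS:
            raise SettingsError(f"unknown decorator kind {self.kind!r}")
        p = self.params
        if self.kind == "lap_parity":
            if p.get("parity") not in ("even", "odd"):
                raise SettingsError("lap_parity needs parity 'even' or 'odd'")
        elif self.kind == "time_window":
            start = p.get("start_ms", 0)
            end = p.get("end_ms")
            if end is not None and end < start:
                raise SettingsError("time_window end_ms before start_ms")
        elif self.kind == "lap_range":
            if p.get("min", 0) > p.get("max", float("inf")):
                raise SettingsError("lap_range min exceeds max")
        elif self.kind == "alternation":
            if p.get("period_laps", 1) < 1:
                raise SettingsError("alternation period_laps must be >= 1")

    def holds(self, s: "ExperimentState") -> bool:
        p = self.params
        if self.kind == "lap_parity":
            return (s.track.lap % 2 == 0) == (p["parity"] == "even")
        if self.kind == "time_window":
            end = p.get("end_ms")
            return s.t_ms >= p.get("start_ms", 0) and (end is None or s.t_ms <= end)
        if self.kind == "lap_range":
            return p.get("min", 0) <= s.track.lap <= p.get("max", float("inf"))
        if self.kind == "alternation":
            period = p.get("period_laps", 1)
            return (s.track.lap // period) % 2 == p.get("phase", 0)
        raise AssertionError(self.kind)


@dataclass
class ExperimentState:
    t_ms: int = 0
    track: TrackState = dc_field(default_factory=TrackState)
    licking: bool = False      # latched since last step
    reward_count: int = 0
    running: bool = False


@dataclass
class TargetSpec:
    """Device actions a context sends on its activation edges."""

    route: list[str]
    start_action: str
    stop_action: str = ""
    start_payload: dict[str, Any] = dc_field(default_factory=dict)
    stop_payload: dict[str, Any] = dc_field(default_factory=dict)


@dataclass
class ContextList:
    id: str
    zones: list[Zone] = dc_field(default_factory=list)
    targets: list[TargetSpec] = dc_field(default_factory=list)
    decorators: list[DecoratorSpec] = dc_field(default_factory=list)
    kind: str = "stimulus"              # "stimulus" | "reward"
    reward_mode: str = "non_operant"    # operant | non_operant
    valve_open_ms: int = 50
    active: bool = False
    _rewarded_lap: dict[int, int] = dc_field(default_factory=dict)

    def check(self, s: ExperimentState, cfg: TrackConfig) -> bool:
        """Full activation predicate: all decorators AND the base zone check."""
        fn: Callable[[ExperimentState], bool] = lambda st: base_check(self, st, cfg)
        for spec in self.decorators:
            fn = decorate(fn, spec)
        return fn(s)


def base_check(c: ContextList, s: ExperimentState, cfg: TrackConfig) -> bool:
    """True iff the context has no zones (global) or the animal is inside
    one of them (circular distance on circular tracks)."""
    if not c.zones:
        return True
    return any(z.contains(s.track.position_mm, cfg) for z in c.zones)


def decorate(check_fn: Callable[[ExperimentState], bool],
             spec: DecoratorSpec) -> Callable[[ExperimentState], bool]:
    """Wrap a predicate with one decorator condition (conjunction).

    All decorators are conjunctive, so composition order never changes the
    result — any permutation of the same stack yields the same trace.
    """
    def wrapped(s: ExperimentState) -> bool:
        return spec.holds(s) and check_fn(s)
    return wrapped


def evaluate_reward(c: ContextList, s: ExperimentState, cfg: TrackConfig,
                    mode: str | None = None) -> str:
    """Reward decision for one step: 'trigger', 'hold' or 'none'.

    At most one trigger per lap per zone.  Non-operant triggers on zone
    entry; operant requires a lick while inside the zone ('hold' while
    waiting for the lick).
    """
    mode = mode or c.reward_mode
    pos = s.track.position_mm
    for i, z in enumerate(c.zones):
        if not z.contains(pos, cfg):
            continue
        if c._rewarded_lap.get(i) == s.track.lap:
            return "none"
        if mode == "non_operant" or (mode == "operant" and s.licking):
            c._rewarded_lap[i] = s.track.lap
            return "trigger"
        return "hold"
    return "none"


@dataclass
class SettingsSpec:
    """Validated experiment settings (track, devices, contexts, duration)."""

    track: TrackConfig
    contexts: list[ContextList]
    devices: dict[str, tuple[str, int]] = dc_field(default_factory=dict)
    duration_ms: int = 60_000
    step_ms: int = 10

    @classmethod
    def from_dict(cls, obj: dict[str, Any]) -> "SettingsSpec":
        try:
            tr = obj["track"]
            track = TrackConfig(track_length_mm=float(tr["length_mm"]),
                                scale_mm_per_tick=float(tr["scale_mm_per_tick"]),
                                circular=bool(tr.get("circular", True)))
        except (KeyError, TypeError, ValueError) as exc:
            raise SettingsError(f"invalid track config: {exc}") from exc
        contexts: list[ContextList] = []
        seen_ids: set[str] = set()
        for c in obj.get("contexts", []):
            cid = c.get("id")
            if not cid or cid in seen_ids:
                raise SettingsError(f"missing or duplicate context id {cid!r}")
            seen_ids.add(cid)
            kind = c.get("type", "stimulus")
            if kind not in ("stimulus", "reward"):
                raise SettingsError(f"unknown context type {kind!r}")
            mode = c.get("mode", "non_operant")
            if mode not in ("operant", "non_operant"):
                raise SettingsError(f"unknown reward mode {mode!r}")
            zones = [Zone(center_mm=float(z["center_mm"]),
                          radius_mm=float(z["radius_mm"]))
                     for z in c.get("zones", [])]
            decorators = [DecoratorSpec(kind=d["kind"],
                                        params={k: v for k, v in d.items()
                                                if k != "kind"})
                          for d in c.get("decorators", [])]
            targets = [TargetSpec(route=list(t["route"]),
                                  start_action=t.get("start_action", "start"),
                                  stop_action=t.get("stop_action", ""),
                                  start_payload=dict(t.get("start_payload", {})),
                                  stop_payload=dict(t.get("stop_payload", {})))
                       for t in c.get("targets", [])]
            contexts.append(ContextList(
                id=cid, zones=zones, targets=targets, decorators=decorators,
                kind=kind, reward_mode=mode,
                valve_open_ms=int(c.get("valve_ms", 50))))
        devices = {name: (d["host"], int(d["port"]))
                   for name, d in obj.get("devices", {}).items()}
        return cls(track=track, contexts=contexts, devices=devices,
                   duration_ms=int(obj.get("duration_ms", 60_000)),
                   step_ms=int(obj.get("step_ms", 10)))

    @classmethod
    def from_json(cls, path: str | Path) -> "SettingsSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class TaskEngine:
    """The event loop: consume device messages, evaluate contexts, actuate."""

    def __init__(self, settings: SettingsSpec):
        self.settings = settings
        self.state = ExperimentState()
        self._msg_id = 0
        self._lap_seen = 0
        for c in settings.contexts:   # clear runtime state from earlier runs
            c.active = False
            c._rewarded_lap.clear()

    def next_msg_id(self) -> int:
        self._msg_id += 1
        return self._msg_id

    def step(self, now_ms: int,
             inbox: Sequence[Message | bytes]) -> tuple[list[Message],
                                                         list[BehaviorRecord]]:
        """One loop iteration: inbox -> state update -> context edges.

        Position updates are applied before context checks; licks are
        latched per step; malformed inbound messages become dead-letter
        error records and never abort the step.
        """
        s, cfg = self.state, self.settings.track
        s.t_ms = max(s.t_ms, now_ms)
        s.licking = False
        outbox: list[Message] = []
        records: list[BehaviorRecord] = []
        moved = False

        for raw in inbox:
            try:
                m = decode_message(raw) if isinstance(raw, (bytes, bytearray)) else raw
            except ParseError as exc:
                records.append(BehaviorRecord(now_ms, "error", {
                    "reason": "dead_letter",
                    "raw": exc.raw.decode("utf-8", "replace")}))
                continue
            head = m.route[0]
            if head == "position":
                if m.action == "delta":
                    s.track = integrate_ticks(s.track, cfg,
                                              int(m.payload.get("ticks", 0)),
                                              now_ms)
                    moved = True
                elif m.action == "lap_reset":
                    s.track, drift = apply_lap_reset(s.track, cfg)
                    records.append(BehaviorRecord(now_ms, "message_in", {
                        "route": m.route, "action": "lap_reset",
                        "drift_mm": round(drift, 6)}))
                    moved = True
            elif head == "lick":
                s.licking = True
                records.append(BehaviorRecord(now_ms, "lick", {}))
            elif head == "ack":
                records.append(BehaviorRecord(now_ms, "message_in", {
                    "route": m.route, "id": m.payload.get("id")}))
            else:
                records.append(BehaviorRecord(now_ms, "error", {
                    "reason": "dead_letter", "route": m.route,
                    "action": m.action}))

        if moved:
            records.append(BehaviorRecord(now_ms, "position", {
                "position_mm": round(s.track.position_mm, 6),
                "lap": s.track.lap}))
        if s.track.lap > self._lap_seen:
            for k in range(self._lap_seen + 1, s.track.lap + 1):
                records.append(BehaviorRecord(now_ms, "lap", {"lap": k}))
            self._lap_seen = s.track.lap

        for c in self.settings.contexts:
            active = c.check(s, cfg) if s.running else False
            if active != c.active:
                kind = "context_start" if active else "context_stop"
                records.append(BehaviorRecord(now_ms, kind, {"id": c.id}))
                for t in c.targets:
                    action = t.start_action if active else t.stop_action
                    if not action:
                        continue
                    payload = dict(t.start_payload if active else t.stop_payload)
                    msg = Message(route=list(t.route), action=action,
                                  payload=payload, msg_id=self.next_msg_id(),
                                  timestamp_ms=now_ms)
                    outbox.append(msg)
                    records.append(BehaviorRecord(now_ms, "message_out", {
                        "route": msg.route, "action": action, "id": msg.msg_id}))
                c.active = active
            if c.kind == "reward" and s.running and active:
                decision = evaluate_reward(c, s, cfg)
                if decision == "trigger":
                    msg = Message(route=["behavior", "valve"], action="open",
                                  payload={"duration_ms": c.valve_open_ms,
                                           "context": c.id},
                                  msg_id=self.next_msg_id(), timestamp_ms=now_ms)
                    outbox.append(msg)
                    s.reward_count += 1
                    records.append(BehaviorRecord(now_ms, "reward", {
                        "context": c.id, "lap": s.track.lap,
                        "position_mm": round(s.track.position_mm, 6)}))
                    records.append(BehaviorRecord(now_ms, "message_out", {
                        "route": msg.route, "action": "open", "id": msg.msg_id}))

        if not records:
            records.append(BehaviorRecord(now_ms, "heartbeat", {}))
        return outbox, records


def run_experiment(settings: SettingsSpec, rig, duration_ms: int | None = None,
                   seed: int = 0, out_path: str | Path = "behavior.jsonl",
                   epoch: float | None = None,
                   ack_policy: AckPolicy = AckPolicy()) -> Path:
    """Run a full closed-loop session against a rig; return the log path.

    Setup emits an acknowledged sync "start" trigger (the imaging-start
    pulse) and aborts if it cannot be delivered; then the loop steps the
    engine every ``settings.step_ms`` until the duration elapses; finally a
    stop trigger is sent and the log closed.  With an injected clock and a
    scripted rig, identical (settings, seed, epoch) produce byte-identical
    logs.
    """
    duration_ms = duration_ms if duration_ms is not None else settings.duration_ms
    engine = TaskEngine(settings)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if epoch is None:
        epoch = time.time()
    with open(out_path, "w") as fh:
        log = BehaviorLogWriter(fh)
        sync = Message(route=["behavior", "sync"], action="pulse",
                       payload={"event": "start"},
                       msg_id=engine.next_msg_id(), timestamp_ms=0)
        status = rig.send_with_ack(sync, ack_policy)
        if not status.acked:
            log.write(BehaviorRecord(0, "error", {
                "reason": "sync_start_unacked", "attempts": status.attempts}))
            raise RuntimeError("sync start trigger was not acknowledged")
        log.write(BehaviorRecord(0, "sync", {
            "event": "start", "epoch_s": epoch, "seed": seed,
            "settings": {"track_length_mm": settings.track.track_length_mm,
                         "scale_mm_per_tick": settings.track.scale_mm_per_tick,
                         "circular": settings.track.circular}}))
        engine.state.running = True
        now = 0
        while now < duration_ms:
            now += settings.step_ms
            inbox = rig.poll(now)
            outbox, records = engine.step(now, inbox)
            for r in records:
                log.write(r)
            rig.deliver(outbox)
        # termination: deactivate anything still on, then the stop pulse
        engine.state.running = False
        outbox, records = engine.step(now, [])
        for r in records:
            if r.kind != "heartbeat":
                log.write(r)
        rig.deliver(outbox)
        stop = Message(route=["behavior", "sync"], action="pulse",
                       payload={"event": "stop"},
                       msg_id=engine.next_msg_id(), timestamp_ms=now)
        rig.send_with_ack(stop, ack_policy)
        log.write(BehaviorRecord(now, "sync", {"event": "stop",
                                               "rewards": engine.state.reward_count,
                                               "laps": engine.state.track.lap}))
    return out_path
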