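"""Virtual hardware: simulated mouse, position/behavior controllers, display.

Software stand-ins for every device on the rig, sharing the wire format of
the messaging module, so that full closed-loop sessions run in-process with
known ground truth.  The simulated mouse produces a piecewise
Ornstein-Uhlenbeck speed profile with pauses; its displacement is quantized
into rotary-encoder ticks with the fractional remainder carried forward, so
the tick stream conserves distance to within one tick.  Licking is an
inhomogeneous Bernoulli process whose rate is elevated inside reward zones.

All randomness flows from one seed through independent named substreams
(motion, licks), so each component is independently reproducible.

A ``slip_mm_per_lap`` parameter models belt slip: the encoder under-reports
distance by that many mm per lap, which — without lap resets — accumulates
linearly in the integrated position.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from looptrack.engine import SettingsSpec, Zone
from looptrack.messaging import (AckPolicy, DeliveryStatus, Endpoint, Message,
                                 decode_message, encode_message, make_ack,
                                 send_with_ack)
from looptrack.tracking import TrackConfig


@dataclass(frozen=True)
class MouseModel:
    """Stochastic running/licking model for the simulated animal."""

    mean_speed_mm_s: float = 150.0
    speed_sd: float = 50.0
    pause_prob_per_s: float = 0.05
    pause_duration_s: float = 1.0
    lick_rate_base_hz: float = 0.5
    lick_rate_zone_hz: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mean_speed_mm_s", "speed_sd", "pause_prob_per_s",
                     "pause_duration_s", "lick_rate_base_hz",
                     "lick_rate_zone_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class GroundTruth:
    """Exact simulated state per transmission window, plus event times."""

    t_ms: np.ndarray            # window end times
    position_mm: np.ndarray     # true position at window end
    lap: np.ndarray             # true lap count at window end
    lick_times_ms: list[int]
    zone_entry_times_ms: list[int]
    dt_ms: int


def simulate_mouse(model: MouseModel, cfg: TrackConfig, duration_ms: int,
                   dt_ms: int = 10, zones: Sequence[Zone] = (),
                   slip_mm_per_lap: float = 0.0,
                   ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Simulate running and licking; return (ticks, licks, ground truth).

    ``ticks[i]`` is the encoder tick count transmitted for window i (the
    displacement the encoder *reports*, reduced by slip);
    ``licks[i]`` is 1 when a lick occurred in window i.  Ground truth tracks
    the real belt position.
    """
    ss = np.random.SeedSequence(model.seed)
    rng_motion, rng_lick = (np.random.default_rng(s) for s in ss.spawn(2))
    n = duration_ms // dt_ms
    dt = dt_ms / 1000.0
    L = cfg.track_length_mm
    theta = 2.0  # OU mean-reversion rate (1/s): speed decorrelates in ~0.5 s

    speed = model.mean_speed_mm_s
    pause_left = 0.0
    pos, lap = 0.0, 0
    carry = 0.0
    slip_frac = slip_mm_per_lap / L

    t_arr = np.arange(1, n + 1) * dt_ms
    pos_arr = np.empty(n)
    lap_arr = np.empty(n, dtype=int)
    ticks = np.zeros(n, dtype=int)
    licks = np.zeros(n, dtype=int)
    lick_times: list[int] = []
    entries: list[int] = []
    in_zone_prev = False

    noise = rng_motion.standard_normal(n)
    pause_draws = rng_motion.random(n)
    lick_draws = rng_lick.random(n)

    for i in range(n):
        if pause_left > 0:
            pause_left -= dt
            v = 0.0
        else:
            speed += theta * (model.mean_speed_mm_s - speed) * dt
            speed += model.speed_sd * np.sqrt(2 * theta * dt) * noise[i]
            speed = max(speed, 0.0)
            v = speed
            if pause_draws[i] < model.pause_prob_per_s * dt:
                pause_left = model.pause_duration_s
        disp = v * dt
        pos += disp
        while pos >= L:
            pos -= L
            lap += 1
        carry += disp * (1.0 - slip_frac) / cfg.scale_mm_per_tick
        k = int(carry)
        ticks[i] = k
        carry -= k
        pos_arr[i] = pos
        lap_arr[i] = lap

        in_zone = any(z.contains(pos, cfg) for z in zones)
        if in_zone and not in_zone_prev:
            entries.append(int(t_arr[i]))
        in_zone_prev = in_zone
        rate = model.lick_rate_zone_hz if in_zone else model.lick_rate_base_hz
        if lick_draws[i] < min(1.0, rate * dt):
            licks[i] = 1
            lick_times.append(int(t_arr[i]))

    truth = GroundTruth(t_ms=t_arr, position_mm=pos_arr, lap=lap_arr,
                        lick_times_ms=lick_times, zone_entry_times_ms=entries,
                        dt_ms=dt_ms)
    return ticks, licks, truth


class VirtualPositionController:
    """Movement-gated encoder reporting: a delta message only when ticks
    were counted in a window, and a lap_reset message when the belt
    completes a revolution (the physical reset sensor)."""

    def __init__(self, ticks: np.ndarray, truth: GroundTruth,
                 scale_mm_per_tick: float = 0.5):
        self._ticks = ticks
        self._lap = truth.lap
        self._pos = truth.position_mm
        self._t = truth.t_ms
        self._scale = scale_mm_per_tick

    def messages_for_window(self, i: int) -> list[Message]:
        out: list[Message] = []
        t = int(self._t[i])

        def delta(k):
            if k:
                out.append(Message(route=["position"], action="delta",
                                   payload={"ticks": int(k)}, timestamp_ms=t))

        prev_lap = self._lap[i - 1] if i > 0 else 0
        if self._lap[i] > prev_lap:
            # the reset sensor fired mid-window at the 0-crossing: report the
            # pre-crossing ticks, then the reset, then the remainder
            after = int(np.clip(self._pos[i] // self._scale, 0,
                                self._ticks[i]))
            delta(self._ticks[i] - after)
            out.append(Message(route=["position"], action="lap_reset",
                               payload={}, timestamp_ms=t))
            delta(after)
        else:
            delta(self._ticks[i])
        return out


@dataclass
class Actuation:
    t_ms: int
    action: str
    duration_ms: int
    payload: dict


class VirtualBehaviorController:
    """Virtual GPIO box: actuates valves/LEDs/tones, acks every command,
    tolerates unknown actions (ack + dead-letter), dedupes msg ids.

    Deliberately has no notion of the experiment running: commands actuate
    whether or not a session is in progress (pre-run test pulses work)."""

    def __init__(self):
        self.actuations: list[Actuation] = []
        self.dead_letters: list[Message] = []
        self._seen_ids: set[int] = set()

    def handle(self, data: bytes, now_ms: int | None = None) -> bytes:
        m = decode_message(data)
        ack = encode_message(make_ack(m.msg_id)) if m.msg_id is not None else b""
        if m.msg_id is not None:
            if m.msg_id in self._seen_ids:
                return ack  # duplicate delivery is idempotent
            self._seen_ids.add(m.msg_id)
        t = now_ms if now_ms is not None else (m.timestamp_ms or 0)
        known = {"open", "pulse", "on", "off", "tone"}
        if m.action in known:
            self.actuations.append(Actuation(
                t_ms=t, action=m.action,
                duration_ms=int(m.payload.get("duration_ms", 0)),
                payload=dict(m.payload)))
        else:
            self.dead_letters.append(m)
        return ack


@dataclass
class SceneRecord:
    send_t_ms: int
    recv_t_ms: int
    position_mm: float | None
    scene_id: str


class VirtualDisplay:
    """Protocol-level display stub: applies scene switches and records
    per-packet receive latency under a (scripted) transport delay."""

    def __init__(self, transport_delay_ms: float = 0.0):
        self.delay_ms = transport_delay_ms
        self.records: list[SceneRecord] = []
        self.scene_id: str = "default"

    def handle(self, data: bytes) -> bytes:
        m = decode_message(data)
        send_t = m.timestamp_ms or 0
        recv_t = int(send_t + self.delay_ms)
        if m.action == "scene":
            self.scene_id = str(m.payload.get("scene_id", self.scene_id))
        pos = m.payload.get("position_mm")
        self.records.append(SceneRecord(send_t_ms=send_t, recv_t_ms=recv_t,
                                        position_mm=pos, scene_id=self.scene_id))
        return encode_message(make_ack(m.msg_id)) if m.msg_id is not None else b""

    @property
    def latencies_ms(self) -> list[int]:
        return [r.recv_t_ms - r.send_t_ms for r in self.records]


class VirtualRig:
    """Everything run_experiment needs: a mouse, controllers, a display.

    ``poll(now_ms)`` returns the device messages generated in the window
    ending at now_ms; ``deliver(outbox)`` routes engine commands to the
    virtual devices (behavior box, display) with acknowledged delivery.
    """

    def __init__(self, settings: SettingsSpec, mouse: MouseModel,
                 duration_ms: int, slip_mm_per_lap: float = 0.0,
                 display_delay_ms: float = 0.0):
        zones = [z for c in settings.contexts if c.kind == "reward"
                 for z in c.zones]
        self.ticks, self.licks, self.truth = simulate_mouse(
            mouse, settings.track, duration_ms, dt_ms=settings.step_ms,
            zones=zones, slip_mm_per_lap=slip_mm_per_lap)
        self.position_controller = VirtualPositionController(
            self.ticks, self.truth, settings.track.scale_mm_per_tick)
        self.behavior = VirtualBehaviorController()
        self.display = VirtualDisplay(transport_delay_ms=display_delay_ms)
        self.step_ms = settings.step_ms
        self.behavior_ep = Endpoint("127.0.0.1", 5000)
        self.display_ep = Endpoint("127.0.0.1", 5001)

    # -- inbound (device -> engine) -------------------------------------
    def poll(self, now_ms: int) -> list[Message]:
        i = now_ms // self.step_ms - 1
        if i < 0 or i >= len(self.ticks):
            return []
        msgs = self.position_controller.messages_for_window(i)
        if self.licks[i]:
            msgs.append(Message(route=["lick"], action="event",
                                payload={}, timestamp_ms=now_ms))
        return msgs

    # -- outbound (engine -> devices) -----------------------------------
    def deliver(self, outbox: Sequence[Message]) -> None:
        for m in outbox:
            data = encode_message(m)
            if m.route[0] == "display":
                self.display.handle(data)
            else:
                self.behavior.handle(data, now_ms=m.timestamp_ms)

    def send_with_ack(self, m: Message, policy: AckPolicy) -> DeliveryStatus:
        reply = self.behavior.handle(encode_message(m), now_ms=m.timestamp_ms)
        ack = decode_message(reply)
        ok = ack.payload.get("id") == m.msg_id
        return DeliveryStatus(acked=ok, attempts=1)
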