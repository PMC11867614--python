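"""Streaming timestamped behavior log: JSON-lines writer and session reader.

Each record is one JSON object per line, appended and flushed as it happens,
so a crash loses at most the partial final line (which the reader skips with
a warning).  Times are integer milliseconds relative to the sync-start
record, which also stores the wall-clock epoch for alignment with recording
devices.

Record kinds form a closed set; timestamps are non-decreasing in file order
— a writer receiving an out-of-order record monotonizes its time and logs an
explicit error record alongside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, IO, Iterable

RECORD_KINDS = frozenset({
    "position", "lap", "lick", "reward", "context_start", "context_stop",
    "message_in", "message_out", "sync", "error", "heartbeat",
})


@dataclass
class BehaviorRecord:
    t_ms: int
    kind: str
    payload: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in RECORD_KINDS:
            raise ValueError(f"unknown record kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps({"t_ms": self.t_ms, "kind": self.kind,
                           "payload": self.payload},
                          separators=(",", ":"), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "BehaviorRecord":
        obj = json.loads(line)
        return cls(t_ms=int(obj["t_ms"]), kind=obj["kind"],
                   payload=obj.get("payload", {}))


class BehaviorLogWriter:
    """Append-only JSON-lines writer enforcing monotone timestamps."""

    def __init__(self, stream: IO[str]):
        self._stream = stream
        self._last_t: int | None = None

    def write(self, r: BehaviorRecord) -> None:
        if self._last_t is not None and r.t_ms < self._last_t:
            err = BehaviorRecord(
                t_ms=self._last_t, kind="error",
                payload={"reason": "time_regression", "original_t_ms": r.t_ms,
                         "kind": r.kind})
            self._emit(err)
            r = BehaviorRecord(t_ms=self._last_t, kind=r.kind, payload=r.payload)
        self._emit(r)

    def _emit(self, r: BehaviorRecord) -> None:
        self._stream.write(r.to_json() + "\n")
        self._stream.flush()
        self._last_t = r.t_ms


def write_record(stream: IO[str] | BehaviorLogWriter, r: BehaviorRecord) -> None:
    """Append one record; bare streams get a throwaway writer (no
    cross-call monotonization — prefer BehaviorLogWriter for sessions)."""
    if isinstance(stream, BehaviorLogWriter):
        stream.write(r)
    else:
        BehaviorLogWriter(stream).write(r)


@dataclass
class ContextInterval:
    context_id: str
    start_ms: int
    stop_ms: int
    unclosed: bool = False


@dataclass
class SessionData:
    """Full reconstruction of one behavioral session from its log."""

    records: list[BehaviorRecord]
    position: list[tuple[int, float, int]]   # (t_ms, mm, lap)
    lick_times: list[int]
    reward_times: list[int]
    lap_times: list[int]
    context_intervals: dict[str, list[ContextInterval]]
    settings: dict[str, Any]
    warnings: list[str]

    @property
    def n_laps(self) -> int:
        return len(self.lap_times)

    @property
    def reward_count(self) -> int:
        return len(self.reward_times)


def iter_records(path: str | Path) -> Iterable[tuple[BehaviorRecord | None, str]]:
    with open(path, "r") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            try:
                yield BehaviorRecord.from_json(stripped), ""
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                yield None, f"unparseable line skipped: {exc}"


def load_session(path: str | Path) -> SessionData:
    """Reconstruct a session from a behavior log file.

    A truncated final line is skipped with a warning; an unclosed context
    interval is closed at the last timestamp and flagged.
    """
    records: list[BehaviorRecord] = []
    warnings: list[str] = []
    for rec, warn in iter_records(path):
        if rec is None:
            warnings.append(warn)
        else:
            records.append(rec)
    position = []
    lick_times, reward_times, lap_times = [], [], []
    open_ctx: dict[str, int] = {}
    intervals: dict[str, list[ContextInterval]] = {}
    settings: dict[str, Any] = {}
    last_t = records[-1].t_ms if records else 0
    for r in records:
        if r.kind == "position":
            position.append((r.t_ms, float(r.payload["position_mm"]),
                             int(r.payload["lap"])))
        elif r.kind == "lick":
            lick_times.append(r.t_ms)
        elif r.kind == "reward":
            reward_times.append(r.t_ms)
        elif r.kind == "lap":
            lap_times.append(r.t_ms)
        elif r.kind == "context_start":
            open_ctx[r.payload["id"]] = r.t_ms
        elif r.kind == "context_stop":
            cid = r.payload["id"]
            start = open_ctx.pop(cid, None)
            if start is None:
                warnings.append(f"context_stop without start for {cid!r}")
            else:
                intervals.setdefault(cid, []).append(
                    ContextInterval(cid, start, r.t_ms))
        elif r.kind == "sync" and r.payload.get("event") == "start":
            settings = r.payload.get("settings", {})
    for cid, start in open_ctx.items():
        intervals.setdefault(cid, []).append(
            ContextInterval(cid, start, last_t, unclosed=True))
        warnings.append(f"context {cid!r} unclosed; closed at {last_t}")
    return SessionData(records=records, position=position,
                       lick_times=lick_times, reward_times=reward_times,
                       lap_times=lap_times, context_intervals=intervals,
                       settings=settings, warnings=warnings)
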