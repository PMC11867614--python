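"""Datagram JSON message model, routing, and acknowledged delivery.

Every component of the rig — real or virtual — speaks the same wire format:
one UTF-8 JSON object per datagram with top-level keys

    ``route``   list of route-name strings (first element selects the handler)
    ``action``  verb for the addressed device ("start", "open", "delta", ...)
    ``payload`` key-value map of scalars / strings / lists
    ``id``      per-sender monotone message id (optional)
    ``t_ms``    milliseconds since experiment start (optional, absent pre-start)

Reliability is ack-based: a receiver replies with a minimal
``{route: ["ack"], payload: {id: <msg_id>}}`` message, and senders retry the
identical ``id`` until acked or retries are exhausted.  Receivers treat a
duplicate ``id`` as idempotent.

Transports are injectable so that every test runs without a network: the
scripted transports here (lossless, drop-list, fixed-delay) share the
interface of the real UDP loopback transport.
"""

from __future__ import annotations

import json
import socket
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

MAX_DATAGRAM_BYTES = 1400  # single-MTU limit; larger messages are rejected


class MessageError(ValueError):
    """Invalid message: empty route, unserializable payload, oversized."""


class ParseError(ValueError):
    """Malformed inbound datagram; carries the raw bytes for the log."""

    def __init__(self, msg: str, raw: bytes):
        super().__init__(msg)
        self.raw = raw


@dataclass(frozen=True)
class Endpoint:
    """Static network address of one device (host, port)."""

    host: str
    port: int

    def __post_init__(self):
        if not (1 <= self.port <= 65535):
            raise ValueError(f"port {self.port} outside [1, 65535]")


@dataclass(frozen=True)
class AckPolicy:
    """Retry policy for acknowledged delivery."""

    timeout_ms: int = 100
    max_retries: int = 3

    def __post_init__(self):
        if self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be > 0")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")


@dataclass
class Message:
    """Routed key-value packet — the unit of all device communication."""

    route: list[str]
    action: str = ""
    payload: dict[str, Any] = field(default_factory=dict)
    msg_id: int | None = None
    timestamp_ms: int | None = None

    def validate(self) -> None:
        if not self.route or not all(isinstance(r, str) for r in self.route):
            raise MessageError("route must be a non-empty list of strings")


def encode_message(m: Message) -> bytes:
    """Serialize a message to a single UTF-8 JSON datagram (<= 1400 bytes)."""
    m.validate()
    obj: dict[str, Any] = {"route": list(m.route), "action": m.action,
                           "payload": m.payload}
    if m.msg_id is not None:
        obj["id"] = m.msg_id
    if m.timestamp_ms is not None:
        obj["t_ms"] = m.timestamp_ms
    try:
        data = json.dumps(obj, separators=(",", ":"), allow_nan=False).encode()
    except (TypeError, ValueError) as exc:
        raise MessageError(f"payload not JSON-serializable: {exc}") from exc
    if len(data) > MAX_DATAGRAM_BYTES:
        raise MessageError(
            f"encoded message is {len(data)} bytes, exceeds {MAX_DATAGRAM_BYTES}")
    return data


def decode_message(b: bytes) -> Message:
    """Parse one datagram back into a Message.

    Unknown top-level keys are preserved inside the payload so that newer
    senders stay compatible with older receivers.
    """
    try:
        obj = json.loads(b.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ParseError(f"malformed datagram: {exc}", raw=b) from exc
    if not isinstance(obj, dict):
        raise ParseError("datagram is not a JSON object", raw=b)
    route = obj.pop("route", None)
    if not isinstance(route, list) or not route:
        raise ParseError("missing or empty route", raw=b)
    m = Message(
        route=[str(r) for r in route],
        action=str(obj.pop("action", "")),
        payload=dict(obj.pop("payload", {}) or {}),
        msg_id=obj.pop("id", None),
        timestamp_ms=obj.pop("t_ms", None),
    )
    m.payload.update(obj)  # unknown extras retained
    return m


def make_ack(msg_id: int) -> Message:
    return Message(route=["ack"], action="ack", payload={"id": msg_id})


@dataclass
class DeadLetter:
    """Record of a message whose first route element had no handler."""

    message: Message
    reason: str


class Router:
    """First-route-element dispatch table with dead-letter capture."""

    def __init__(self):
        self._handlers: dict[str, Callable[[Message, list[str]], Any]] = {}
        self.dead_letters: list[DeadLetter] = []

    def register(self, name: str, handler: Callable[[Message, list[str]], Any]) -> None:
        self._handlers[name] = handler

    def dispatch(self, m: Message) -> Any:
        """Route ``m`` to the handler of its first route element.

        The handler receives the message and the remaining sub-route.
        Unmatched routes append a dead-letter record and return None —
        routing never raises.
        """
        head, rest = m.route[0], m.route[1:]
        handler = self._handlers.get(head)
        if handler is None:
            self.dead_letters.append(DeadLetter(m, f"no handler for {head!r}"))
            return None
        return handler(m, rest)


def dispatch(m: Message, registry: dict[str, Callable[[Message, list[str]], Any]],
             dead_letters: list[DeadLetter] | None = None) -> Any:
    """Functional form of Router.dispatch for a plain handler dict."""
    r = Router()
    for name, h in registry.items():
        r.register(name, h)
    out = r.dispatch(m)
    if dead_letters is not None:
        dead_letters.extend(r.dead_letters)
    return out


@dataclass
class DeliveryStatus:
    acked: bool
    attempts: int

    def __bool__(self) -> bool:
        return self.acked


# ---------------------------------------------------------------------------
# Transports.  A transport exposes ``request(ep, data, timeout_ms)`` which
# sends one datagram and returns the reply datagram (bytes) or None on
# timeout/loss.  Scripted transports let tests control loss and delay.
# ---------------------------------------------------------------------------

class ScriptedTransport:
    """In-process transport backed by per-endpoint responder callables.

    ``drop_first`` drops the first k outbound datagrams; ``drop_all`` drops
    every outbound datagram; ``delay_ms`` is recorded as the simulated
    one-way latency (exposed for display-latency measurements).
    """

    def __init__(self, drop_first: int = 0, drop_all: bool = False,
                 delay_ms: float = 0.0):
        self.responders: dict[Endpoint, Callable[[bytes], bytes | None]] = {}
        self.drop_first = drop_first
        self.drop_all = drop_all
        self.delay_ms = delay_ms
        self.sent: list[tuple[Endpoint, bytes]] = []
        self._dropped = 0

    def bind(self, ep: Endpoint, responder: Callable[[bytes], bytes | None]) -> None:
        self.responders[ep] = responder

    def request(self, ep: Endpoint, data: bytes, timeout_ms: int) -> bytes | None:
        self.sent.append((ep, data))
        if self.drop_all or self._dropped < self.drop_first:
            self._dropped += 1
            return None
        responder = self.responders.get(ep)
        if responder is None:
            return None
        return responder(data)


class UdpTransport:
    """Real datagram socket transport (loopback by default)."""

    def __init__(self):
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)

    def request(self, ep: Endpoint, data: bytes, timeout_ms: int) -> bytes | None:
        self._sock.settimeout(timeout_ms / 1000.0)
        self._sock.sendto(data, (ep.host, ep.port))
        try:
            reply, _ = self._sock.recvfrom(65536)
        except socket.timeout:
            return None
        return reply

    def close(self) -> None:
        self._sock.close()


def send_with_ack(transport, ep: Endpoint, m: Message,
                  policy: AckPolicy = AckPolicy()) -> DeliveryStatus:
    """Send ``m`` and wait for a matching ack, retrying the identical msg_id.

    Performs at most ``1 + max_retries`` sends; returns as soon as an ack
    whose payload id equals ``m.msg_id`` arrives.
    """
    if m.msg_id is None:
        raise MessageError("send_with_ack requires a msg_id")
    data = encode_message(m)
    attempts = 0
    for _ in range(1 + policy.max_retries):
        attempts += 1
        reply = transport.request(ep, data, policy.timeout_ms)
        if reply is None:
            continue
        try:
            ack = decode_message(reply)
        except ParseError:
            continue
        if ack.route and ack.route[0] == "ack" and ack.payload.get("id") == m.msg_id:
            return DeliveryStatus(acked=True, attempts=attempts)
    return DeliveryStatus(acked=False, attempts=attempts)
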