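"""ThingSpeak-style telemetry of diagnostic metrics.

A channel update carries an API key and up to eight numeric fields
(``field1``..``field8``), mirroring the public ThingSpeak channel-update
convention. Transports are pluggable: the in-process :class:`MockTransport`
records requests for tests, and :class:`HTTPTransport` posts form-encoded
updates with the standard library. Transmission never raises into the
pipeline — failures come back as a status — and free-tier pacing is
enforced by a minimum interval between sends (delay or reject per config).

Only scalar metrics and labels are ever transmitted; no patient-identifying
data enters an update.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .evaluate import MetricsReport

_FIELD_NAMES = tuple(f"field{i}" for i in range(1, 9))

DEFAULT_FIELD_MAPPING = {
    "accuracy": "field1",
    "sensitivity": "field2",
    "specificity": "field3",
    "precision": "field4",
    "auc": "field5",
}


@dataclass(frozen=True)
class ChannelUpdate:
    api_key: str
    fields: dict[str, float]
    created_at: float = field(default_factory=time.time)

    def __post_init__(self):
        if len(self.fields) > 8:
            raise ValueError("at most 8 fields per channel update")
        for name, value in self.fields.items():
            if name not in _FIELD_NAMES:
                raise ValueError(f"invalid field name {name!r}")
            if not (value == value and abs(value) != float("inf")):
                raise ValueError(f"non-finite value for {name}")


@dataclass(frozen=True)
class TransmitStatus:
    ok: bool
    status: str  # "sent" | "rate_limited" | "failed" | "disabled"
    entry_id: int | None = None
    detail: str = ""


def format_channel_update(
    metrics: MetricsReport,
    mapping: dict[str, str] | None = None,
    api_key: str = "",
) -> ChannelUpdate:
    """Map metrics to channel fields as percentages rounded to 2 decimals.

    ``mapping`` assigns metric names to distinct field1..field8 slots;
    metrics that are undefined (None) are simply left unmapped.
    """
    if mapping is None:
        mapping = DEFAULT_FIELD_MAPPING
    slots = list(mapping.values())
    if len(set(slots)) != len(slots):
        raise ValueError("duplicate field assignment in mapping")
    values = metrics.as_dict(percentages=True)
    fields = {}
    for metric_name, slot in mapping.items():
        if metric_name not in values:
            raise ValueError(f"unknown metric {metric_name!r}")
        if values[metric_name] is not None:
            fields[slot] = float(values[metric_name])
    return ChannelUpdate(api_key=api_key, fields=fields)


class MockTransport:
    """Records updates in memory; succeeds unless told to fail."""

    def __init__(self, fail: bool = False):
        self.requests: list[ChannelUpdate] = []
        self.fail = fail
        self._next_id = 1

    def send(self, update: ChannelUpdate) -> tuple[int, int]:
        if self.fail:
            raise ConnectionError("mock transport configured to fail")
        self.requests.append(update)
        entry_id = self._next_id
        self._next_id += 1
        return 200, entry_id


class HTTPTransport:
    """Form-encoded POST of api_key and fieldN parameters to an update URL."""

    def __init__(self, endpoint: str = "https://api.thingspeak.com/update", timeout: float = 10.0):
        self.endpoint = endpoint
        self.timeout = timeout

    def send(self, update: ChannelUpdate) -> tuple[int, int]:
        import urllib.parse
        import urllib.request

        payload = {"api_key": update.api_key, **{k: str(v) for k, v in update.fields.items()}}
        data = urllib.parse.urlencode(payload).encode()
        with urllib.request.urlopen(self.endpoint, data=data, timeout=self.timeout) as resp:
            body = resp.read().decode().strip()
            return resp.status, int(body) if body.isdigit() else 0


class Transmitter:
    """Paced, failure-isolating sender around a transport."""

    def __init__(
        self,
        transport,
        min_interval_seconds: float = 15.0,
        policy: str = "reject",
        clock=time.monotonic,
        sleep=time.sleep,
    ):
        if policy not in ("reject", "delay"):
            raise ValueError("policy must be 'reject' or 'delay'")
        self.transport = transport
        self.min_interval = min_interval_seconds
        self.policy = policy
        self._clock = clock
        self._sleep = sleep
        self._last_send: float | None = None

    def transmit(self, update: ChannelUpdate) -> TransmitStatus:
        now = self._clock()
        if self._last_send is not None and now - self._last_send < self.min_interval:
            if self.policy == "reject":
                return TransmitStatus(
                    ok=False, status="rate_limited",
                    detail=f"min interval {self.min_interval}s not elapsed",
                )
            self._sleep(self.min_interval - (now - self._last_send))
        try:
            status_code, entry_id = self.transport.send(update)
        except Exception as exc:  # failures are a status, never an exception
            return TransmitStatus(ok=False, status="failed", detail=str(exc))
        self._last_send = self._clock()
        if status_code != 200:
            return TransmitStatus(ok=False, status="failed", detail=f"HTTP {status_code}")
        return TransmitStatus(ok=True, status="sent", entry_id=entry_id)


def transmit(update: ChannelUpdate, transport, min_interval_seconds: float = 0.0) -> TransmitStatus:
    """One-shot convenience wrapper around :class:`Transmitter`."""
    return Transmitter(transport, min_interval_seconds).transmit(update)
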