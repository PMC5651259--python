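"""Shared domain model for the closed-loop engine.

Everything in the engine is clocked by a single virtual sample clock: every
timestamp anywhere in the system is an integer sample index at the session
sampling rate.  Millisecond values exist only at the API surface and are
converted immediately with :func:`ms_to_samples`.  This replaces the soft
real-time behaviour of a hardware-clocked acquisition loop with an exactly
reproducible contract — latencies become sample counts, and two runs with the
same inputs and seed are bit-identical.

The module defines the session configuration, the acquisition :class:`Block`,
the event types carried by the closed loop (spikes, digital/analog I/O, user
data, text messages), and :class:`EventRepository`, the bounded time-ordered
store shared by all pipeline stages.
"""

from __future__ import annotations

import bisect
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

__all__ = [
    "NeuroloopError",
    "OrderingError",
    "ArgumentError",
    "LayoutError",
    "StorageError",
    "SequenceError",
    "PluginLoadError",
    "ms_to_samples",
    "samples_to_ms",
    "SessionConfig",
    "Block",
    "SpikeEvent",
    "DigitalInEvent",
    "DigitalOutEvent",
    "AnalogOutEvent",
    "UserDataEvent",
    "TextEvent",
    "EventRepository",
    "RawHistory",
]


class NeuroloopError(Exception):
    """Base class for all errors raised by this package."""


class OrderingError(NeuroloopError):
    """A stage observed events out of time order.

    This always signals an engine bug (stages insert in commit order), never a
    user error.
    """


class ArgumentError(NeuroloopError, ValueError):
    """Invalid argument to an operation."""


class LayoutError(NeuroloopError):
    """Malformed channel-layout file."""


class StorageError(NeuroloopError):
    """Unreadable or unwritable session store."""


class SequenceError(NeuroloopError):
    """Malformed or over-capacity experiment sequence."""


class PluginLoadError(NeuroloopError):
    """A plugin could not be loaded or configured."""


def ms_to_samples(t_ms: float, rate_hz: float) -> int:
    """Convert milliseconds to integer samples (round half up).

    8 ms at 16 kHz gives 128 samples.  The engine never stores fractional
    time; every duration passes through this conversion exactly once.
    """
    if rate_hz <= 0:
        raise ArgumentError(f"sampling rate must be positive, got {rate_hz}")
    return int(math.floor(t_ms * rate_hz / 1000.0 + 0.5))


def samples_to_ms(n_samples: float, rate_hz: float) -> float:
    """Exact inverse scale of :func:`ms_to_samples` (derived, never stored)."""
    if rate_hz <= 0:
        raise ArgumentError(f"sampling rate must be positive, got {rate_hz}")
    return n_samples * 1000.0 / rate_hz


def _per_channel(value, n_channels: int, dtype) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    if arr.ndim == 0:
        return np.full(n_channels, arr, dtype=dtype)
    if arr.shape != (n_channels,):
        raise ArgumentError(
            f"per-channel value has shape {arr.shape}, expected ({n_channels},)"
        )
    return arr


@dataclass
class SessionConfig:
    """Static configuration of one acquisition session.

    Parameters
    ----------
    sampling_rate_hz
        Samples per second per channel.  The board this emulates runs up to
        ~46 kHz; typical MEA work uses 16 kHz.
    n_channels
        Number of analog input channels (1..64).
    block_samples
        Samples per channel per acquisition block; the completed transfer of
        one block clocks the real-time loop.  Hardware minimum is 64.
    waveform_pre_ms, waveform_post_ms
        Capture window around each threshold crossing.  A spike becomes
        visible to closed-loop code only after its full window is captured.
    threshold_volts, polarity
        Per-channel detection threshold and crossing direction (-1 = the
        extracellular convention, a downward crossing of a negative
        threshold; +1 = upward crossing).  Scalars broadcast to all channels.
    periodic_interval_ms
        Interval of the slow periodic closed-loop slot.
    raw_history_s, spike_capacity, event_capacity
        Repository bounds: raw history is a duration, the spike store and the
        other event stores are event counts (spike default 500,000).
    scale_volts_per_code
        ADC quantum used by the synthetic digitizer and the raw file format.
    """

    sampling_rate_hz: int = 16000
    n_channels: int = 60
    block_samples: int = 64
    waveform_pre_ms: float = 1.0
    waveform_post_ms: float = 7.0
    threshold_volts: Union[float, Sequence[float]] = -30e-6
    polarity: Union[int, Sequence[int]] = -1
    periodic_interval_ms: float = 1000.0
    n_digital_lines: int = 16
    n_analog_out: int = 2
    n_user_streams: int = 2
    raw_history_s: float = 10.0
    spike_capacity: int = 500_000
    event_capacity: int = 100_000
    scale_volts_per_code: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ArgumentError("sampling_rate_hz must be positive")
        if not 1 <= self.n_channels <= 64:
            raise ArgumentError("n_channels must be in 1..64")
        if self.block_samples < 64:
            raise ArgumentError("block_samples must be >= 64 (hardware minimum)")
        if self.waveform_pre_ms < 0 or self.waveform_post_ms < 0:
            raise ArgumentError("waveform window halves must be non-negative")
        if self.waveform_pre_ms + self.waveform_post_ms <= 0:
            raise ArgumentError("waveform window must have positive total length")
        if self.periodic_interval_ms <= 0:
            raise ArgumentError("periodic_interval_ms must be positive")
        if self.n_user_streams != 2:
            raise ArgumentError("exactly 2 user data streams are supported")
        if min(self.raw_history_s, self.spike_capacity, self.event_capacity) <= 0:
            raise ArgumentError("all history capacities must be positive")
        if self.scale_volts_per_code <= 0:
            raise ArgumentError("scale_volts_per_code must be positive")
        self.thresholds = _per_channel(self.threshold_volts, self.n_channels, float)
        self.polarities = _per_channel(self.polarity, self.n_channels, int)
        if not np.all(np.abs(self.polarities) == 1):
            raise ArgumentError("polarity entries must be +1 or -1")

    @property
    def n_pre(self) -> int:
        return ms_to_samples(self.waveform_pre_ms, self.sampling_rate_hz)

    @property
    def n_post(self) -> int:
        return ms_to_samples(self.waveform_post_ms, self.sampling_rate_hz)

    @property
    def periodic_interval_samples(self) -> int:
        return max(1, ms_to_samples(self.periodic_interval_ms, self.sampling_rate_hz))

    @property
    def raw_history_samples(self) -> int:
        return max(
            self.block_samples,
            ms_to_samples(self.raw_history_s * 1000.0, self.sampling_rate_hz),
        )


@dataclass
class Block:
    """One acquisition chunk: ``block_samples`` samples on every channel.

    Blocks are gapless and non-overlapping; block ``k`` covers samples
    ``[k*B, (k+1)*B)``.
    """

    index: int
    start_sample: int
    data: np.ndarray  # shape (n_channels, block_samples), volts
    digital_in: Optional[list] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ArgumentError("block data must be a channels x samples matrix")
        if self.start_sample != self.index * self.data.shape[1]:
            raise ArgumentError("start_sample must equal index * block_samples")

    @property
    def end_sample(self) -> int:
        return self.start_sample + self.data.shape[1]


@dataclass(eq=False)
class SpikeEvent:
    """A threshold crossing with its captured waveform.

    ``t_cross`` is the sample of the crossing itself; ``visible_at`` is the
    block end at which the fully captured event entered the repository (the
    earliest virtual time at which closed-loop code can react to it).
    """

    t_cross: int
    channel: int
    waveform: np.ndarray
    visible_at: int

    @property
    def timestamp(self) -> int:
        return self.t_cross

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpikeEvent)
            and (self.t_cross, self.channel, self.visible_at)
            == (other.t_cross, other.channel, other.visible_at)
            and np.array_equal(self.waveform, other.waveform)
        )


@dataclass(frozen=True)
class DigitalInEvent:
    timestamp: int
    line: int
    level: int


@dataclass(frozen=True)
class DigitalOutEvent:
    timestamp: int
    line: int
    level: int


@dataclass(frozen=True)
class AnalogOutEvent:
    timestamp: int
    channel: int
    value: float


@dataclass(frozen=True)
class UserDataEvent:
    """Plugin-generated scalar sample on one of the two user streams."""

    timestamp: int
    stream: int  # 1 or 2
    value: float


@dataclass(frozen=True)
class TextEvent:
    timestamp: int
    source: str
    text: str


#: attribute used by ``channels=`` filtering, per stream kind
_FILTER_ATTR = {
    "spikes": "channel",
    "digital_in": "line",
    "digital_out": "line",
    "analog_out": "channel",
    "user": "stream",
    "text": None,
}

STREAM_KINDS = tuple(_FILTER_ATTR)


class EventRepository:
    """Bounded, time-ordered event store for one stream.

    The engine inserts events in commit order, so timestamps are
    non-decreasing; an out-of-order insert raises :class:`OrderingError`
    (an engine bug, never a user error).  When the capacity is exceeded the
    oldest events are evicted first and the eviction counter incremented.
    Queries use half-open windows ``[t0, t1)`` over the event timestamps
    (``t_cross`` for spikes).

    Spike visibility: an event carrying ``visible_at`` is returned only if
    ``visible_at <= horizon``.  By default the horizon is the query end
    ``t1`` — a window ending before a spike's capture completed does not
    contain it.  Pass an explicit ``horizon`` (the engine passes the current
    block end) to decouple the window from visibility; window queries with a
    fixed horizon partition time exactly.
    """

    def __init__(self, kind: str, capacity: int):
        if kind not in _FILTER_ATTR:
            raise ArgumentError(f"unknown stream kind {kind!r}")
        if capacity <= 0:
            raise ArgumentError("capacity must be positive")
        self.kind = kind
        self.capacity = int(capacity)
        self._times: list[int] = []
        self._events: list = []
        self.evicted = 0

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator:
        return iter(self._events)

    @property
    def events(self) -> list:
        return list(self._events)

    def insert(self, ev) -> None:
        t = ev.timestamp
        if self._times and t < self._times[-1]:
            raise OrderingError(
                f"{self.kind}: insert at t={t} after t={self._times[-1]} "
                "(stages must insert in commit order)"
            )
        self._times.append(t)
        self._events.append(ev)
        excess = len(self._events) - self.capacity
        if excess > 0:
            del self._times[:excess]
            del self._events[:excess]
            self.evicted += excess

    def query(
        self,
        t0: int,
        t1: int,
        channels: Optional[Iterable[int]] = None,
        horizon="auto",
    ) -> list:
        """Events with timestamp in ``[t0, t1)``, time-ordered."""
        if t0 > t1:
            raise ArgumentError(f"query window [{t0}, {t1}) has t0 > t1")
        lo = bisect.bisect_left(self._times, t0)
        hi = bisect.bisect_left(self._times, t1)
        out = self._events[lo:hi]
        if horizon == "auto":
            horizon = t1
        if horizon is not None:
            out = [e for e in out if getattr(e, "visible_at", horizon) <= horizon]
        if channels is not None:
            attr = _FILTER_ATTR[self.kind]
            if attr is not None:
                wanted = set(channels)
                out = [e for e in out if getattr(e, attr) in wanted]
        return out


class RawHistory:
    """Rolling raw-voltage history with a bounded duration.

    Stores the most recent ``capacity_samples`` of the continuous trace as a
    deque of blocks; older samples are discarded.  Unlike event streams the
    raw stream is a dense matrix, so it gets its own container.
    """

    def __init__(self, n_channels: int, capacity_samples: int):
        if capacity_samples <= 0:
            raise ArgumentError("capacity must be positive")
        self.n_channels = n_channels
        self.capacity = int(capacity_samples)
        self._chunks: deque = deque()  # (start_sample, data)
        self.start = 0  # oldest retained sample
        self.end = 0  # one past newest sample

    def append(self, start_sample: int, data: np.ndarray) -> None:
        if start_sample != self.end:
            raise OrderingError(
                f"raw history: block at {start_sample} after end {self.end}"
            )
        self._chunks.append((start_sample, data))
        self.end = start_sample + data.shape[1]
        while self._chunks and self._chunks[0][0] + self._chunks[0][1].shape[1] <= (
            self.end - self.capacity
        ):
            self._chunks.popleft()
        self.start = self._chunks[0][0] if self._chunks else self.end

    def query(self, t0: int, t1: int, channel: Optional[int] = None) -> np.ndarray:
        """Dense samples for ``[t0, t1)`` clipped to the retained span."""
        if t0 > t1:
            raise ArgumentError(f"query window [{t0}, {t1}) has t0 > t1")
        t0 = max(t0, self.start)
        t1 = min(t1, self.end)
        n = max(0, t1 - t0)
        if channel is None:
            out = np.zeros((self.n_channels, n))
        else:
            out = np.zeros(n)
        if n == 0:
            return out
        for start, data in self._chunks:
            stop = start + data.shape[1]
            if stop <= t0 or start >= t1:
                continue
            a = max(start, t0)
            b = min(stop, t1)
            seg = data[:, a - start : b - start]
            if channel is None:
                out[:, a - t0 : b - t0] = seg
            else:
                out[a - t0 : b - t0] = seg[channel]
        return out

    def last_value(self, channel: int) -> float:
        """Newest retained sample on ``channel`` (0.0 before any data)."""
        if not self._chunks:
            return 0.0
        return float(self._chunks[-1][1][channel, -1])
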