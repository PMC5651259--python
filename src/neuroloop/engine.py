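"""The closed-loop pipeline: per-block stage ordering, plugin slots, output
arbitration and loop instrumentation.

Each completed acquisition block drives one pipeline pass, in a fixed order:

1. preprocessing — spike detection, capture, commit to the repositories;
2. the real-time closed-loop slot — every loaded plugin's
   ``process_realtime`` runs once per block;
3. the slow periodic slot — ``process_periodic`` runs at the first block end
   at or past each multiple of the periodic interval;
4. output arbitration and application;
5. the logging hook.

The hardware original ran these stages as threads woken in a chain; on the
virtual clock the chain becomes a deterministic per-block sequence with the
same observable semantics.  The original's shared output buffer (real-time
and periodic threads contending on a semaphore, with possible loss of the
periodic thread's output) becomes a deterministic rule: periodic *hardware*
output in a block where the real-time slot produced hardware output is
dropped and logged; user-data and text output is never dropped.

Plugins interact with the engine only through :class:`LoopContext`: read
access to the repositories clipped to the current visibility horizon, and
request sinks for digital, analog, user-data and text output.  A plugin that
raises is disabled and the session continues — an experiment must survive
its closed-loop code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AnalogOutEvent,
    ArgumentError,
    Block,
    DigitalInEvent,
    DigitalOutEvent,
    EventRepository,
    PluginLoadError,
    RawHistory,
    SessionConfig,
    SpikeEvent,
    TextEvent,
    UserDataEvent,
    samples_to_ms,
)
from .detect import SpikeDetector

__all__ = [
    "Plugin",
    "OutputRequest",
    "LoopContext",
    "Session",
    "SessionResult",
    "LoopStats",
    "arbitrate",
    "loop_interval_stats",
    "run_session",
]


class Plugin:
    """Base class for user closed-loop code: five entry points, no returns.

    ``on_load(arg)`` receives a free-text argument string; ``start()`` runs
    once before the first block; ``process_realtime(ctx)`` runs once per
    block; ``process_periodic(ctx)`` runs on the periodic slot; and
    ``on_unload()`` runs at teardown.  Implementing only one of the two
    process functions is fine.  All effects flow through the context's
    request interface — entry points return nothing.
    """

    name = "plugin"

    def on_load(self, arg: str) -> None:
        pass

    def validate(self, cfg: SessionConfig) -> None:
        """Optional hook: raise :class:`PluginLoadError` on a bad config."""

    def start(self) -> None:
        pass

    def process_realtime(self, ctx: "LoopContext") -> None:
        pass

    def process_periodic(self, ctx: "LoopContext") -> None:
        pass

    def on_unload(self) -> None:
        pass


HARDWARE_KINDS = ("digital", "analog")


@dataclass
class OutputRequest:
    """One output produced by a plugin during a loop slot."""

    kind: str  # digital | analog | user | text
    target: object  # line / channel / stream / source string
    value: object
    revert_after: Optional[int] = None  # samples; digital pulses only


class LoopContext:
    """Read-only repository views plus request sinks, for one loop slot.

    ``now`` is the current block end; no query through the context can see a
    spike whose ``visible_at`` exceeds it.
    """

    def __init__(self, session: "Session", now: int, block_index: int):
        self._s = session
        self.now = now
        self.block_index = block_index
        self.requests: List[OutputRequest] = []

    # -- read views --------------------------------------------------------

    @property
    def sampling_rate_hz(self) -> int:
        return self._s.cfg.sampling_rate_hz

    def spikes(self, t0: int = 0, t1: Optional[int] = None,
               channels: Optional[Iterable[int]] = None) -> List[SpikeEvent]:
        t1 = self.now if t1 is None else min(t1, self.now)
        return self._s.repos["spikes"].query(
            max(t0, 0), max(t1, 0), channels=channels, horizon=self.now
        )

    def new_spikes(self, since: int,
                   channels: Optional[Iterable[int]] = None) -> List[SpikeEvent]:
        """Spikes that became visible after ``since`` (scan-frontier query).

        A spike's crossing can precede its commit by up to
        ``n_post + block_samples`` samples, so a frontier over crossing
        times would miss late-committing events; this frontier is over
        ``visible_at``, which is what "newly in the repository" means.
        """
        slack = self._s.cfg.n_post + self._s.cfg.block_samples + 1
        evs = self._s.repos["spikes"].query(
            max(0, since - slack), self.now, channels=channels, horizon=self.now
        )
        return [e for e in evs if e.visible_at > since]

    def events(self, stream: str, t0: int = 0, t1: Optional[int] = None,
               channels: Optional[Iterable[int]] = None) -> list:
        t1 = self.now if t1 is None else min(t1, self.now)
        return self._s.repos[stream].query(
            max(t0, 0), max(t1, 0), channels=channels, horizon=self.now
        )

    def raw(self, t0: int, t1: int, channel: Optional[int] = None) -> np.ndarray:
        return self._s.raw.query(max(t0, 0), min(t1, self.now), channel=channel)

    def raw_last(self, channel: int) -> float:
        return self._s.raw.last_value(channel)

    def digital_level(self, line: int) -> int:
        return int(self._s.digital_levels[line])

    def analog_level(self, channel: int) -> float:
        return float(self._s.analog_levels[channel])

    # -- request sinks -----------------------------------------------------

    def request_digital(self, line: int, level: int,
                        revert_after: Optional[int] = None) -> None:
        """Set a digital line; ``revert_after`` (samples) makes it a pulse."""
        self.requests.append(
            OutputRequest("digital", int(line), 1 if level else 0, revert_after)
        )

    def request_analog(self, channel: int, value: float) -> None:
        self.requests.append(OutputRequest("analog", int(channel), float(value)))

    def request_user(self, stream: int, value: float) -> None:
        """Send a scalar to user data stream 1 or 2 (never dropped)."""
        self.requests.append(OutputRequest("user", int(stream), float(value)))

    def log(self, text: str, source: str = "plugin") -> None:
        self.requests.append(OutputRequest("text", source, str(text)))


def arbitrate(
    rt_requests: Sequence[OutputRequest],
    periodic_requests: Sequence[OutputRequest],
) -> Tuple[List[OutputRequest], List[OutputRequest]]:
    """Resolve same-block contention for the hardware output buffer.

    Real-time requests are always applied.  Periodic hardware (digital or
    analog) requests are dropped when the real-time slot produced hardware
    output in the same block; periodic user-data and text requests bypass
    the hardware buffer and are never dropped.
    """
    applied = list(rt_requests)
    dropped: List[OutputRequest] = []
    rt_hw = any(r.kind in HARDWARE_KINDS for r in rt_requests)
    for r in periodic_requests:
        if rt_hw and r.kind in HARDWARE_KINDS:
            dropped.append(r)
        else:
            applied.append(r)
    return applied, dropped


@dataclass
class _LoadedPlugin:
    plugin: Plugin
    enabled: bool = True
    arg: str = ""

    @property
    def name(self) -> str:
        return getattr(self.plugin, "name", type(self.plugin).__name__)


@dataclass
class LoopStats:
    mean_ms: float
    sd_ms: float
    min_ms: float
    max_ms: float
    rate_hz: float
    n_intervals: int


@dataclass
class SessionResult:
    """Everything a finished session produced, on the virtual clock."""

    cfg: SessionConfig
    repos: Dict[str, EventRepository]
    raw: RawHistory
    digital_timeline: Dict[int, List[Tuple[int, int]]]
    analog_timeline: Dict[int, List[Tuple[int, float]]]
    rt_times: List[int]
    periodic_times: List[int]
    dropped_periodic: int
    n_blocks: int
    end_sample: int

    @property
    def text_log(self) -> List[TextEvent]:
        return self.repos["text"].events

    def trigger_onsets(self, line: int) -> List[int]:
        """Samples at which ``line`` transitioned low → high."""
        onsets, level = [], 0
        for t, v in self.digital_timeline[line]:
            if v and not level:
                onsets.append(t)
            level = v
        return onsets

    def pulse_widths(self, line: int) -> List[int]:
        """High durations (samples) of completed pulses on ``line``."""
        widths, up = [], None
        for t, v in self.digital_timeline[line]:
            if v and up is None:
                up = t
            elif not v and up is not None:
                widths.append(t - up)
                up = None
        return widths


def loop_interval_stats(result: SessionResult) -> LoopStats:
    """Intervals between consecutive real-time invocations, reported in ms.

    Computed in sample units; on the virtual clock they equal the block size
    exactly, so the spread is zero — the statistic exists to make the loop
    rate an output of the run rather than an assumption.
    """
    if len(result.rt_times) < 2:
        raise ArgumentError("need at least 2 invocations for interval stats")
    d = np.diff(np.asarray(result.rt_times, dtype=np.int64))
    rate = result.cfg.sampling_rate_hz
    mean_samples = float(d.mean())
    return LoopStats(
        mean_ms=samples_to_ms(mean_samples, rate),
        sd_ms=samples_to_ms(float(d.std()), rate),
        min_ms=samples_to_ms(int(d.min()), rate),
        max_ms=samples_to_ms(int(d.max()), rate),
        rate_hz=rate / mean_samples,
        n_intervals=len(d),
    )


class Session:
    """A running closed-loop session over a block source.

    Parameters
    ----------
    cfg
        Session configuration.
    source
        Iterable of :class:`Block` (synthetic stream or playback).
    plugins
        Plugins to load before the first block, as instances or
        ``(instance, arg_string)`` pairs.
    store
        Optional :class:`~neuroloop.persistence.SessionStore`; when set and
        logging is enabled, raw data and committed events are appended with a
        configurable flush cadence.
    loopback
        Optional ``(analog_out_channel, input_channel)`` pair: during each
        block the input channel is overwritten with the analog output level
        held at the block start, emulating a physical wire from an analog
        output to an analog input (used by the I/O latency plugin).
    """

    def __init__(
        self,
        cfg: SessionConfig,
        source: Iterable[Block],
        plugins: Sequence = (),
        store=None,
        loopback: Optional[Tuple[int, int]] = None,
        flush_interval_ms: float = 500.0,
    ):
        self.cfg = cfg
        self._source: Iterator[Block] = iter(source)
        self.detector = SpikeDetector(cfg)
        cap = cfg.event_capacity
        self.repos: Dict[str, EventRepository] = {
            "spikes": EventRepository("spikes", cfg.spike_capacity),
            "digital_in": EventRepository("digital_in", cap),
            "digital_out": EventRepository("digital_out", cap),
            "analog_out": EventRepository("analog_out", cap),
            "user": EventRepository("user", cap),
            "text": EventRepository("text", cap),
        }
        self.raw = RawHistory(cfg.n_channels, cfg.raw_history_samples)
        self.digital_levels = np.zeros(cfg.n_digital_lines, dtype=int)
        self.analog_levels = np.zeros(cfg.n_analog_out)
        self.digital_timeline = {l: [] for l in range(cfg.n_digital_lines)}
        self.analog_timeline = {c: [] for c in range(cfg.n_analog_out)}
        self._reverts: Dict[int, int] = {}  # line -> scheduled low-edge sample
        self.rt_times: List[int] = []
        self.periodic_times: List[int] = []
        self.dropped_periodic = 0
        self._next_due = cfg.periodic_interval_samples
        self._warned_degenerate = False
        self.now = 0
        self.n_blocks = 0
        self.store = store
        self.logging_enabled = store is not None
        self._flush_samples = max(
            cfg.block_samples,
            int(round(flush_interval_ms * cfg.sampling_rate_hz / 1000.0)),
        )
        self._last_flush = 0
        self._log_raw: List[np.ndarray] = []
        self._log_events: Dict[str, list] = {k: [] for k in self.repos}
        self._loopback = loopback
        self._plugins: List[_LoadedPlugin] = []
        self._finalized = False
        for p in plugins:
            if isinstance(p, tuple):
                self.load_plugin(p[0], p[1])
            else:
                self.load_plugin(p)

    # -- plugin management -------------------------------------------------

    def load_plugin(self, plugin: Plugin, arg: str = "") -> None:
        """Load, configure and start a plugin (raises PluginLoadError)."""
        try:
            plugin.on_load(arg)
            plugin.validate(self.cfg)
            plugin.start()
        except PluginLoadError:
            raise
        except Exception as exc:  # noqa: BLE001 - plugin code is untrusted
            raise PluginLoadError(f"plugin failed to load: {exc}") from exc
        self._plugins.append(_LoadedPlugin(plugin, arg=arg))
        self.post_text(f"plugin '{self._plugins[-1].name}' loaded")

    def unload_plugin(self, name: str) -> bool:
        for i, lp in enumerate(self._plugins):
            if lp.name == name:
                try:
                    lp.plugin.on_unload()
                except Exception as exc:  # noqa: BLE001
                    self.post_text(f"plugin '{name}' error on unload: {exc}")
                del self._plugins[i]
                self.post_text(f"plugin '{name}' unloaded")
                return True
        return False

    def plugin_names(self) -> List[str]:
        return [lp.name for lp in self._plugins]

    # -- text log ----------------------------------------------------------

    def post_text(self, text: str, source: str = "system",
                  timestamp: Optional[int] = None) -> None:
        ev = TextEvent(self.now if timestamp is None else timestamp, source, text)
        self._insert("text", ev)

    def set_threshold(self, channel: int, volts: float) -> None:
        self.cfg.thresholds[channel] = volts
        self.detector._thr[channel, 0] = volts
        self.post_text(f"threshold ch{channel} set to {volts!r} V")

    # -- pipeline ----------------------------------------------------------

    def _insert(self, stream: str, ev) -> None:
        self.repos[stream].insert(ev)
        if self.logging_enabled and self.store is not None:
            self._log_events[stream].append(ev)

    def _call_slot(self, slot: str, now: int, block_index: int) -> List[OutputRequest]:
        ctx = LoopContext(self, now, block_index)
        for lp in self._plugins:
            if not lp.enabled:
                continue
            fn = (lp.plugin.process_realtime if slot == "rt"
                  else lp.plugin.process_periodic)
            try:
                fn(ctx)
            except Exception as exc:  # noqa: BLE001 - must not kill the session
                lp.enabled = False
                self.post_text(
                    f"plugin '{lp.name}' disabled after error: {exc!r}",
                    timestamp=now,
                )
        return ctx.requests

    def _apply_due_reverts(self, up_to: int) -> None:
        due = sorted((t, line) for line, t in self._reverts.items() if t <= up_to)
        for t, line in due:
            del self._reverts[line]
            self.digital_levels[line] = 0
            self.digital_timeline[line].append((t, 0))
            self._insert("digital_out", DigitalOutEvent(t, line, 0))

    def _apply(self, req: OutputRequest, now: int) -> None:
        if req.kind == "digital":
            line = req.target
            if not 0 <= line < self.cfg.n_digital_lines:
                self.post_text(f"request to nonexistent digital line {line} skipped",
                               timestamp=now)
                return
            if line in self._reverts:
                del self._reverts[line]
                self.post_text(
                    f"overlapping pulse on line {line}: later request wins",
                    timestamp=now,
                )
            self.digital_levels[line] = req.value
            self.digital_timeline[line].append((now, req.value))
            self._insert("digital_out", DigitalOutEvent(now, line, req.value))
            if req.revert_after is not None:
                self._reverts[line] = now + int(req.revert_after)
        elif req.kind == "analog":
            ch = req.target
            if not 0 <= ch < self.cfg.n_analog_out:
                self.post_text(f"request to nonexistent analog channel {ch} skipped",
                               timestamp=now)
                return
            self.analog_levels[ch] = req.value
            self.analog_timeline[ch].append((now, req.value))
            self._insert("analog_out", AnalogOutEvent(now, ch, req.value))
        elif req.kind == "user":
            if req.target not in (1, 2):
                self.post_text(f"request to nonexistent user stream {req.target} "
                               "skipped", timestamp=now)
                return
            self._insert("user", UserDataEvent(now, req.target, req.value))
        elif req.kind == "text":
            self._insert("text", TextEvent(now, req.target, req.value))

    def step(self, block: Block) -> None:
        """Run the full per-block pipeline for one acquisition block."""
        end = block.end_sample
        if self._loopback is not None:
            out_ch, in_ch = self._loopback
            block.data[in_ch, :] = self.analog_levels[out_ch]
        self.raw.append(block.start_sample, block.data)
        if self.logging_enabled and self.store is not None:
            self._log_raw.append(block.data)

        # (1) preprocessing: detect, capture, commit
        for ev in self.detector.process_block(block):
            self._insert("spikes", ev)
        if block.digital_in:
            for ev in block.digital_in:
                self._insert("digital_in", ev)

        # (2) real-time slot — one invocation slot per block, plugins or not
        rt_requests = self._call_slot("rt", end, block.index)
        self.rt_times.append(end)

        # (3) slow periodic slot
        periodic_requests: List[OutputRequest] = []
        interval = self.cfg.periodic_interval_samples
        if end >= self._next_due:
            if interval < block.data.shape[1] and not self._warned_degenerate:
                self._warned_degenerate = True
                self.post_text(
                    "periodic interval shorter than one block; firing every block",
                    timestamp=end,
                )
            periodic_requests = self._call_slot("periodic", end, block.index)
            self.periodic_times.append(end)
            self._next_due = (end // interval + 1) * interval

        # (4) arbitration + output application
        applied, dropped = arbitrate(rt_requests, periodic_requests)
        if dropped:
            self.dropped_periodic += len(dropped)
            self.post_text(
                f"periodic output dropped ({len(dropped)} request(s)): "
                "hardware buffer busy with real-time output",
                timestamp=end,
            )
        self._apply_due_reverts(end)
        for req in applied:
            self._apply(req, end)

        self.now = end
        self.n_blocks += 1

        # (5) logging hook
        if (
            self.logging_enabled
            and self.store is not None
            and end - self._last_flush >= self._flush_samples
        ):
            self.flush_log()

    def flush_log(self) -> None:
        if self.store is None:
            return
        for data in self._log_raw:
            self.store.append_raw(data)
        self._log_raw.clear()
        for stream, evs in self._log_events.items():
            if evs:
                self.store.append_events(stream, evs)
                evs.clear()
        self._last_flush = self.now

    # -- driving -----------------------------------------------------------

    def step_blocks(self, n: int) -> int:
        """Process up to ``n`` blocks; returns how many were available."""
        done = 0
        for _ in range(n):
            block = next(self._source, None)
            if block is None:
                break
            self.step(block)
            done += 1
        return done

    def run(self, max_blocks: Optional[int] = None) -> SessionResult:
        """Drain the source (or ``max_blocks``) and finalize."""
        for block in self._source:
            self.step(block)
            if max_blocks is not None and self.n_blocks >= max_blocks:
                break
        return self.finalize()

    def finalize(self) -> SessionResult:
        if not self._finalized:
            self._finalized = True
            # pending pulse reverts fall past the last block: apply them so
            # every issued pulse has its exact low edge
            self._apply_due_reverts(max(self._reverts.values(), default=0))
            for lp in self._plugins:
                try:
                    lp.plugin.on_unload()
                except Exception as exc:  # noqa: BLE001
                    self.post_text(f"plugin '{lp.name}' error on unload: {exc}")
            if self.store is not None:
                self.flush_log()
                self.store.close()
        return self.result()

    def result(self) -> SessionResult:
        return SessionResult(
            cfg=self.cfg,
            repos=self.repos,
            raw=self.raw,
            digital_timeline=self.digital_timeline,
            analog_timeline=self.analog_timeline,
            rt_times=list(self.rt_times),
            periodic_times=list(self.periodic_times),
            dropped_periodic=self.dropped_periodic,
            n_blocks=self.n_blocks,
            end_sample=self.now,
        )


def run_session(
    cfg: SessionConfig,
    source: Iterable[Block],
    plugins: Sequence = (),
    store=None,
    loopback: Optional[Tuple[int, int]] = None,
) -> SessionResult:
    """Convenience wrapper: build a :class:`Session`, drain it, finalize."""
    return Session(
        cfg, source, plugins=plugins, store=store, loopback=loopback
    ).run()
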