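"""Reference closed-loop plugins built on the plugin contract.

Four plugins exercise the engine the way a network-level MEA experiment
would:

* :class:`MotifPlugin` — real-time detector of an ordered cross-electrode
  spike motif (e.g. five spikes on electrodes 37, 26, 25, 34, 41 with every
  consecutive gap at most 10 ms); on a match it pulses a digital line
  (5 ms) and then holds a refractory period (1 s) during which further
  matches issue no triggers.
* :class:`RateMonitorPlugin` — periodic monitor sending the scaled spike
  count of the trailing window (default 60 s) to user data stream 1.
* :class:`IOLatencyPlugin` — the loop-timing probe: reads an analog input
  that is wired (via the engine's loopback) to an analog output, and toggles
  the output — below 1 V it drives 5 V, above 1 V it drives 0 V, at exactly
  1 V it holds the previous output.
* :class:`BurstDetectorPlugin` — a simple network-burst detector declaring
  an onset when the all-channel spike count in a trailing bin crosses a
  threshold from below; one onset per suprathreshold episode.

Each plugin is addressable by name through :func:`make_plugin` with a small
semicolon-separated argument-string grammar, so the CLI and the sequencer
can load them the way the original loaded DLLs with argument strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .core import ArgumentError, PluginLoadError, SessionConfig, ms_to_samples
from .engine import LoopContext, Plugin

__all__ = [
    "MotifSpec",
    "MotifPlugin",
    "RateMonitorPlugin",
    "IOLatencyPlugin",
    "BurstDetectorPlugin",
    "PLUGIN_REGISTRY",
    "make_plugin",
]

#: the demonstration motif electrodes, in firing order
DEMO_ELECTRODES = (37, 26, 25, 34, 41)


@dataclass(frozen=True)
class MotifSpec:
    """An ordered cross-electrode spike pattern and its trigger policy.

    A motif occurrence is one spike per listed electrode, in list order by
    crossing time, with every consecutive inter-spike interval at most
    ``max_interval_ms``.
    """

    electrodes: Tuple[int, ...] = DEMO_ELECTRODES
    max_interval_ms: float = 10.0
    line: int = 1
    pulse_ms: float = 5.0
    refractory_s: float = 1.0

    def __post_init__(self) -> None:
        if len(self.electrodes) < 2:
            raise ArgumentError("a motif needs at least 2 electrodes")
        if len(set(self.electrodes)) != len(self.electrodes):
            raise ArgumentError("motif electrodes must be distinct")
        if min(self.max_interval_ms, self.pulse_ms, self.refractory_s) <= 0:
            raise ArgumentError("motif durations must be positive")


class MotifPlugin(Plugin):
    """Real-time motif detector with pulse output and refractory period.

    Matching is an earliest-completion greedy scan over newly visible
    spikes: each new spike on a motif electrode extends the longest prefix
    it can legally follow (gap within bound, strictly increasing times).
    Spikes on non-motif electrodes are ignored, and an out-of-order spike on
    a motif electrode does not invalidate a match in progress — only the
    order among the five matched spikes matters.  The scan cursor advances
    monotonically, so each committed spike is examined exactly once.

    On a match: if no trigger was issued within the refractory period, the
    trigger line is pulsed for ``pulse_ms`` and the refractory clock
    restarts; matches inside the refractory period issue nothing and do not
    extend it.
    """

    name = "motif"

    def __init__(self, spec: Optional[MotifSpec] = None):
        self.spec = spec
        self._reset_state()

    def _reset_state(self) -> None:
        self.last_trigger: Optional[int] = None
        self.cursor = 0
        self._prefix: List[Optional[int]] = []
        self.n_matches = 0
        self.n_triggers = 0

    def on_load(self, arg: str) -> None:
        if arg.strip():
            self.spec = parse_motif_arg(arg)
        if self.spec is None:
            self.spec = MotifSpec()

    def validate(self, cfg: SessionConfig) -> None:
        assert self.spec is not None
        if max(self.spec.electrodes) >= cfg.n_channels or min(self.spec.electrodes) < 0:
            raise PluginLoadError(
                f"motif electrodes {self.spec.electrodes} outside channel range "
                f"0..{cfg.n_channels - 1}"
            )
        if not 0 <= self.spec.line < cfg.n_digital_lines:
            raise PluginLoadError(f"trigger line {self.spec.line} out of range")

    def start(self) -> None:
        self._reset_state()
        self._prefix = [None] * len(self.spec.electrodes)

    def process_realtime(self, ctx: LoopContext) -> None:
        spec = self.spec
        rate = ctx.sampling_rate_hz
        max_gap = ms_to_samples(spec.max_interval_ms, rate)
        refractory = ms_to_samples(spec.refractory_s * 1000.0, rate)
        pos_of = {e: i for i, e in enumerate(spec.electrodes)}
        new = ctx.new_spikes(self.cursor, channels=spec.electrodes)
        self.cursor = ctx.now
        # ties in t_cross break by electrode-list order
        new.sort(key=lambda s: (s.t_cross, pos_of[s.channel]))
        k = len(spec.electrodes)
        for s in new:
            i = pos_of[s.channel]
            t = s.t_cross
            if i == 0:
                self._prefix[0] = t
                continue
            prev = self._prefix[i - 1]
            if prev is None or t <= prev or t - prev > max_gap:
                continue
            self._prefix[i] = t
            if i == k - 1:
                self.n_matches += 1
                self._prefix = [None] * k  # consume the matched spikes
                if (
                    self.last_trigger is None
                    or ctx.now - self.last_trigger >= refractory
                ):
                    ctx.request_digital(
                        spec.line, 1,
                        revert_after=ms_to_samples(spec.pulse_ms, rate),
                    )
                    self.last_trigger = ctx.now
                    self.n_triggers += 1


class RateMonitorPlugin(Plugin):
    """Periodic spike-rate monitor: trailing-window count to user stream 1.

    With the defaults (60 s window, scale 1, called once a second) the
    emitted value is the network firing rate in spikes per minute.
    """

    name = "rate"

    def __init__(self, window_s: float = 60.0, scale: float = 1.0, stream: int = 1):
        self.window_s = window_s
        self.scale = scale
        self.stream = stream

    def on_load(self, arg: str) -> None:
        parts = [p for p in arg.strip().split(";") if p]
        if len(parts) >= 1:
            self.window_s = float(parts[0])
        if len(parts) >= 2:
            self.scale = float(parts[1])
        if self.window_s <= 0:
            raise PluginLoadError("rate window must be positive")

    def process_periodic(self, ctx: LoopContext) -> None:
        window = ms_to_samples(self.window_s * 1000.0, ctx.sampling_rate_hz)
        count = len(ctx.spikes(max(0, ctx.now - window), ctx.now))
        ctx.request_user(self.stream, self.scale * count)


class IOLatencyPlugin(Plugin):
    """Loop-timing probe over an analog output wired back to an input.

    For input values < 1 V the output is set to 5 V; for input values > 1 V
    it is set to 0 V; at exactly 1 V the previous output is held.  Run with
    ``loopback=(output_channel, input_channel)`` on the session; the output
    then flips once per loop and the flip period measures the full
    sample-analyze-output cycle.
    """

    name = "io_latency"

    def __init__(self, input_channel: int = 0, output_channel: int = 0):
        self.input_channel = input_channel
        self.output_channel = output_channel

    def on_load(self, arg: str) -> None:
        parts = [p for p in arg.strip().split(";") if p]
        if len(parts) >= 1:
            self.input_channel = int(parts[0])
        if len(parts) >= 2:
            self.output_channel = int(parts[1])

    def validate(self, cfg: SessionConfig) -> None:
        if not 0 <= self.input_channel < cfg.n_channels:
            raise PluginLoadError("io_latency input channel out of range")
        if not 0 <= self.output_channel < cfg.n_analog_out:
            raise PluginLoadError("io_latency output channel out of range")

    def process_realtime(self, ctx: LoopContext) -> None:
        v = ctx.raw_last(self.input_channel)
        if v < 1.0:
            target = 5.0
        elif v > 1.0:
            target = 0.0
        else:
            return  # exactly 1 V: hold previous output
        if ctx.analog_level(self.output_channel) != target:
            ctx.request_analog(self.output_channel, target)


class BurstDetectorPlugin(Plugin):
    """Rate-threshold network-burst detector (real-time slot).

    Declares a burst onset when the all-channel spike count in the trailing
    ``bin_ms`` window crosses ``threshold`` from below; while the count
    stays at or above threshold the episode continues and no further onsets
    are declared.  Onsets go to user stream 2 (count as value) and to the
    text log.  This is a deliberately simple stand-in for dedicated burst
    detection algorithms.
    """

    name = "burst"

    def __init__(self, bin_ms: float = 25.0, threshold: int = 20, stream: int = 2):
        self.bin_ms = bin_ms
        self.threshold = threshold
        self.stream = stream
        self._in_burst = False
        self.onsets: List[int] = []

    def on_load(self, arg: str) -> None:
        parts = [p for p in arg.strip().split(";") if p]
        if len(parts) >= 1:
            self.bin_ms = float(parts[0])
        if len(parts) >= 2:
            self.threshold = int(parts[1])
        if self.bin_ms <= 0 or self.threshold <= 0:
            raise PluginLoadError("burst bin and threshold must be positive")

    def start(self) -> None:
        self._in_burst = False
        self.onsets = []

    def process_realtime(self, ctx: LoopContext) -> None:
        bin_samples = ms_to_samples(self.bin_ms, ctx.sampling_rate_hz)
        count = len(ctx.spikes(max(0, ctx.now - bin_samples), ctx.now))
        if count >= self.threshold:
            if not self._in_burst:
                self._in_burst = True
                self.onsets.append(ctx.now)
                ctx.request_user(self.stream, float(count))
                ctx.log(f"burst onset at sample {ctx.now} ({count} spikes/bin)",
                        source="burst")
        else:
            self._in_burst = False


def parse_motif_arg(arg: str) -> MotifSpec:
    """Parse ``"electrodes;max_interval_ms;line;pulse_ms;refractory_s"``.

    Example: ``"37,26,25,34,41;10;1;5;1"`` is the demonstration setting.
    Trailing fields may be omitted and default to the demo values.
    """
    parts = [p.strip() for p in arg.strip().split(";")]
    if not parts or not parts[0]:
        raise ArgumentError("motif argument string needs an electrode list")
    try:
        electrodes = tuple(int(e) for e in parts[0].split(","))
        kwargs = {}
        if len(parts) >= 2 and parts[1]:
            kwargs["max_interval_ms"] = float(parts[1])
        if len(parts) >= 3 and parts[2]:
            kwargs["line"] = int(parts[2])
        if len(parts) >= 4 and parts[3]:
            kwargs["pulse_ms"] = float(parts[3])
        if len(parts) >= 5 and parts[4]:
            kwargs["refractory_s"] = float(parts[4])
    except ValueError as exc:
        raise ArgumentError(f"bad motif argument string {arg!r}: {exc}") from exc
    return MotifSpec(electrodes=electrodes, **kwargs)


PLUGIN_REGISTRY = {
    "motif": MotifPlugin,
    "rate": RateMonitorPlugin,
    "io_latency": IOLatencyPlugin,
    "burst": BurstDetectorPlugin,
}


def make_plugin(name: str) -> Plugin:
    """Instantiate a registered plugin by name (argument string applied by
    the session via ``on_load``)."""
    try:
        return PLUGIN_REGISTRY[name]()
    except KeyError:
        raise ArgumentError(
            f"unknown plugin {name!r}; known: {sorted(PLUGIN_REGISTRY)}"
        ) from None
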