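"""Session logging, playback reading, text export and channel layouts.

A session directory holds one file series per data stream plus a JSON
manifest, the single source of format truth:

``manifest.json``
    sampling rate, channel count, block size, ADC scale (volts per code),
    waveform window, format version and a config snapshot — everything
    needed to reopen the session without the original configuration.
``raw.NNNN.bin``
    headerless little-endian int16, channel-interleaved frames (one frame =
    one sample across all channels); volts = code × scale.
``spikes.NNNN.csv``, ``digital_in/out``, ``analog_out``, ``user``,
``text`` (``.NNNN.csv``)
    one record per row, comma separated, header row, "." decimal point, no
    quoting.  Spike waveforms are stored as integer ADC codes, so storage
    is lossless at the digitizer's resolution.

Files roll over so that no file exceeds the user-defined maximum size
(except a single oversized record); the concatenated series is gap-free and
ordered, and read-back is independent of the rollover size used at write
time.  A torn final record (partial write) is dropped with a warning on
reopen; all complete records are recovered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .core import (
    AnalogOutEvent,
    ArgumentError,
    Block,
    DigitalInEvent,
    DigitalOutEvent,
    LayoutError,
    SessionConfig,
    SpikeEvent,
    StorageError,
    TextEvent,
    UserDataEvent,
    samples_to_ms,
)
from .synth import stream_blocks

__all__ = [
    "SessionStore",
    "SessionData",
    "read_session",
    "playback_blocks",
    "export_text",
    "ChannelLayout",
    "read_layout",
]

FORMAT_VERSION = 1
EVENT_STREAMS = ("spikes", "digital_in", "digital_out", "analog_out", "user", "text")
ALL_STREAMS = ("raw",) + EVENT_STREAMS

_HEADERS = {
    "digital_in": "timestamp,line,level",
    "digital_out": "timestamp,line,level",
    "analog_out": "timestamp,channel,value",
    "user": "timestamp,stream,value",
    "text": "timestamp,source,text",
}


def _spike_header(n_wave: int) -> str:
    cols = ",".join(f"w{i}" for i in range(n_wave))
    return f"t_cross,channel,visible_at,{cols}" if n_wave else "t_cross,channel,visible_at"


class SessionStore:
    """Append-only writer for one session directory with size rollover."""

    def __init__(
        self,
        directory,
        cfg: SessionConfig,
        max_file_bytes: int = 50_000_000,
        streams: Optional[Tuple[str, ...]] = None,
    ):
        if max_file_bytes <= 0:
            raise ArgumentError("max_file_bytes must be positive")
        self.dir = Path(directory)
        try:
            self.dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise StorageError(f"cannot create session directory: {exc}") from exc
        self.cfg = cfg
        self.max_file_bytes = int(max_file_bytes)
        self.streams = tuple(streams) if streams is not None else ALL_STREAMS
        unknown = set(self.streams) - set(ALL_STREAMS)
        if unknown:
            raise ArgumentError(f"unknown streams {sorted(unknown)}")
        self.scale = cfg.scale_volts_per_code
        self._files: Dict[str, tuple] = {}  # stream -> [index, handle, size]
        self._n_wave = cfg.n_pre + cfg.n_post
        manifest = {
            "format": "neuroloop-session",
            "version": FORMAT_VERSION,
            "sampling_rate_hz": cfg.sampling_rate_hz,
            "n_channels": cfg.n_channels,
            "block_samples": cfg.block_samples,
            "scale_volts_per_code": cfg.scale_volts_per_code,
            "n_pre": cfg.n_pre,
            "n_post": cfg.n_post,
            "streams": list(self.streams),
            "config": {
                "sampling_rate_hz": cfg.sampling_rate_hz,
                "n_channels": cfg.n_channels,
                "block_samples": cfg.block_samples,
                "waveform_pre_ms": cfg.waveform_pre_ms,
                "waveform_post_ms": cfg.waveform_post_ms,
                "threshold_volts": list(map(float, cfg.thresholds)),
                "polarity": list(map(int, cfg.polarities)),
                "periodic_interval_ms": cfg.periodic_interval_ms,
                "n_digital_lines": cfg.n_digital_lines,
                "n_analog_out": cfg.n_analog_out,
                "raw_history_s": cfg.raw_history_s,
                "spike_capacity": cfg.spike_capacity,
                "event_capacity": cfg.event_capacity,
                "scale_volts_per_code": cfg.scale_volts_per_code,
                "seed": cfg.seed,
            },
        }
        try:
            (self.dir / "manifest.json").write_text(
                json.dumps(manifest, indent=1) + "\n"
            )
        except OSError as exc:
            raise StorageError(f"cannot write manifest: {exc}") from exc

    # -- low-level file series --------------------------------------------

    def _path(self, stream: str, index: int) -> Path:
        ext = "bin" if stream == "raw" else "csv"
        return self.dir / f"{stream}.{index:04d}.{ext}"

    def _open(self, stream: str, index: int):
        mode = "wb" if stream == "raw" else "w"
        try:
            fh = open(self._path(stream, index), mode, newline="" if mode == "w" else None)
        except OSError as exc:
            raise StorageError(f"cannot open {stream} file: {exc}") from exc
        size = 0
        if stream != "raw":
            header = (
                _spike_header(self._n_wave) if stream == "spikes" else _HEADERS[stream]
            )
            fh.write(header + "\n")
            size = len(header) + 1
        self._files[stream] = [index, fh, size]
        return self._files[stream]

    def _current(self, stream: str):
        return self._files.get(stream) or self._open(stream, 0)

    def _has_data(self, stream: str, entry) -> bool:
        if stream == "raw":
            return entry[2] > 0
        header = _spike_header(self._n_wave) if stream == "spikes" else _HEADERS[stream]
        return entry[2] > len(header) + 1

    # -- appending ---------------------------------------------------------

    def append_raw(self, data_volts: np.ndarray) -> None:
        """Append one block of raw volts as interleaved int16 frames."""
        if "raw" not in self.streams:
            return
        codes = np.clip(
            np.rint(data_volts / self.scale), -32768, 32767
        ).astype("<i2")
        frames = np.ascontiguousarray(codes.T)  # sample-major interleave
        frame_bytes = 2 * codes.shape[0]
        entry = self._current("raw")
        remaining = frames
        while remaining.shape[0] > 0:
            room = (self.max_file_bytes - entry[2]) // frame_bytes
            if room <= 0:
                if entry[2] == 0:
                    room = 1  # single oversized record allowed
                else:
                    entry[1].close()
                    entry = self._open("raw", entry[0] + 1)
                    continue
            chunk = remaining[:room]
            entry[1].write(chunk.tobytes())
            entry[2] += chunk.nbytes
            remaining = remaining[room:]

    def _format_event(self, stream: str, ev) -> str:
        if stream == "spikes":
            codes = np.rint(np.asarray(ev.waveform) / self.scale).astype(int)
            tail = "," + ",".join(map(str, codes)) if len(codes) else ""
            return f"{ev.t_cross},{ev.channel},{ev.visible_at}{tail}\n"
        if stream in ("digital_in", "digital_out"):
            return f"{ev.timestamp},{ev.line},{ev.level}\n"
        if stream == "analog_out":
            return f"{ev.timestamp},{ev.channel},{ev.value!r}\n"
        if stream == "user":
            return f"{ev.timestamp},{ev.stream},{ev.value!r}\n"
        if stream == "text":
            text = ev.text.replace("\n", " ")
            return f"{ev.timestamp},{ev.source},{text}\n"
        raise ArgumentError(f"unknown stream {stream!r}")

    def append_events(self, stream: str, events) -> None:
        if stream not in self.streams:
            return
        for ev in events:
            line = self._format_event(stream, ev)
            entry = self._current(stream)
            if (
                entry[2] + len(line) > self.max_file_bytes
                and self._has_data(stream, entry)
            ):
                entry[1].close()
                entry = self._open(stream, entry[0] + 1)
            entry[1].write(line)
            entry[2] += len(line)

    def close(self) -> None:
        for entry in self._files.values():
            entry[1].close()
        self._files.clear()


# -- reading ---------------------------------------------------------------


@dataclass
class SessionData:
    """A fully read session: manifest, dense raw codes, event lists."""

    manifest: dict
    raw_codes: np.ndarray  # (n_channels, n_samples) int16
    events: Dict[str, list] = field(default_factory=dict)

    @property
    def scale(self) -> float:
        return self.manifest["scale_volts_per_code"]

    def raw_volts(self) -> np.ndarray:
        return self.raw_codes.astype(np.float64) * self.scale

    def session_config(self) -> SessionConfig:
        return SessionConfig(**self.manifest["config"])


def _series(directory: Path, stream: str) -> List[Path]:
    ext = "bin" if stream == "raw" else "csv"
    return sorted(directory.glob(f"{stream}.*.{ext}"))


def _parse_event(stream: str, parts: List[str], scale: float):
    if stream == "spikes":
        t, ch, vis = int(parts[0]), int(parts[1]), int(parts[2])
        wf = np.asarray([int(p) for p in parts[3:]], dtype=float) * scale
        return SpikeEvent(t_cross=t, channel=ch, waveform=wf, visible_at=vis)
    if stream == "digital_in":
        return DigitalInEvent(int(parts[0]), int(parts[1]), int(parts[2]))
    if stream == "digital_out":
        return DigitalOutEvent(int(parts[0]), int(parts[1]), int(parts[2]))
    if stream == "analog_out":
        return AnalogOutEvent(int(parts[0]), int(parts[1]), float(parts[2]))
    if stream == "user":
        return UserDataEvent(int(parts[0]), int(parts[1]), float(parts[2]))
    if stream == "text":
        return TextEvent(int(parts[0]), parts[1], parts[2])
    raise ArgumentError(f"unknown stream {stream!r}")


def _read_event_series(paths: List[Path], stream: str, scale: float) -> list:
    events = []
    for fi, path in enumerate(paths):
        is_last_file = fi == len(paths) - 1
        text = path.read_text()
        lines = text.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
            complete_tail = True
        else:
            complete_tail = False  # file ends mid-record
        for li, line in enumerate(lines):
            if li == 0:
                continue  # header
            is_last_line = li == len(lines) - 1
            maxsplit = 2 if stream == "text" else -1
            parts = line.split(",", maxsplit) if maxsplit > 0 else line.split(",")
            try:
                if is_last_line and not complete_tail:
                    raise ValueError("torn record")
                events.append(_parse_event(stream, parts, scale))
            except (ValueError, IndexError) as exc:
                if is_last_file and is_last_line:
                    warnings.warn(
                        f"{path.name}: dropped incomplete final record ({exc})",
                        stacklevel=2,
                    )
                    break
                raise StorageError(f"{path.name} line {li + 1}: {exc}") from exc
    return events


def read_session(directory) -> SessionData:
    """Read a whole session back; round-trips what was appended exactly."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise StorageError(f"no manifest.json in {directory}: not a session")
    manifest = json.loads(mpath.read_text())
    if manifest.get("version") != FORMAT_VERSION:
        raise StorageError(
            f"session format version {manifest.get('version')} "
            f"not supported (expected {FORMAT_VERSION})"
        )
    n_ch = manifest["n_channels"]
    frame_bytes = 2 * n_ch

    chunks = []
    raw_paths = _series(directory, "raw")
    for fi, path in enumerate(raw_paths):
        buf = path.read_bytes()
        extra = len(buf) % frame_bytes
        if extra:
            if fi != len(raw_paths) - 1:
                raise StorageError(f"{path.name}: torn frame mid-series")
            warnings.warn(
                f"{path.name}: dropped {extra} trailing bytes (torn frame)",
                stacklevel=2,
            )
            buf = buf[: len(buf) - extra]
        if buf:
            chunks.append(
                np.frombuffer(buf, dtype="<i2").reshape(-1, n_ch)
            )
    if chunks:
        raw_codes = np.concatenate(chunks, axis=0).T.copy()
    else:
        raw_codes = np.zeros((n_ch, 0), dtype=np.int16)

    events = {}
    scale = manifest["scale_volts_per_code"]
    for stream in EVENT_STREAMS:
        events[stream] = _read_event_series(_series(directory, stream), stream, scale)
    return SessionData(manifest=manifest, raw_codes=raw_codes, events=events)


def playback_blocks(directory, block_samples: Optional[int] = None) -> Iterator[Block]:
    """Stream a logged session's raw data as acquisition blocks.

    Emulates live acquisition from storage; with the manifest's own block
    size the block sequence equals the original run's exactly.
    """
    data = read_session(directory)
    b = block_samples or data.manifest["block_samples"]
    return stream_blocks(data.raw_volts(), b)


# -- text export -----------------------------------------------------------


def export_text(session_dir, out_dir) -> Dict[str, Path]:
    """Convert raw input and spike events to delimited text.

    Values reproduce the stored data exactly: timestamps and channels as
    integers, voltages as the exact product of the integer code and the
    manifest scale (``repr`` round-trip).
    """
    data = read_session(session_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rate = data.manifest["sampling_rate_hz"]
    scale = data.scale
    written = {}

    spikes_path = out / "spikes.csv"
    n_wave = data.manifest["n_pre"] + data.manifest["n_post"]
    cols = ",".join(f"w{i}_volts" for i in range(n_wave))
    with open(spikes_path, "w") as fh:
        fh.write(f"timestamp_samples,timestamp_ms,channel,{cols}\n")
        for ev in data.events["spikes"]:
            wf = ",".join(repr(float(v)) for v in ev.waveform)
            fh.write(
                f"{ev.t_cross},{samples_to_ms(ev.t_cross, rate)!r},{ev.channel},{wf}\n"
            )
    written["spikes"] = spikes_path

    raw_path = out / "raw.csv"
    volts = data.raw_volts()
    with open(raw_path, "w") as fh:
        heads = ",".join(f"ch{c}_volts" for c in range(volts.shape[0]))
        fh.write(f"timestamp_samples,{heads}\n")
        for t in range(volts.shape[1]):
            row = ",".join(repr(float(v)) for v in volts[:, t])
            fh.write(f"{t},{row}\n")
    written["raw"] = raw_path
    return written


# -- channel layouts -------------------------------------------------------


@dataclass
class ChannelLayout:
    """Mapping channel id -> (row, col) grid position."""

    positions: Dict[int, Tuple[int, int]]
    n_rows: int
    n_cols: int

    def __len__(self) -> int:
        return len(self.positions)


def read_layout(path) -> ChannelLayout:
    """Parse a text grid layout: integers are channel ids, "." is empty.

    The standard 60-electrode MEA is an 8x8 grid with the four corners
    empty.  Duplicate channel ids are rejected.
    """
    positions: Dict[int, Tuple[int, int]] = {}
    rows = [
        line.split()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    n_cols = 0
    for r, tokens in enumerate(rows):
        n_cols = max(n_cols, len(tokens))
        for c, tok in enumerate(tokens):
            if tok == ".":
                continue
            try:
                ch = int(tok)
            except ValueError:
                raise LayoutError(
                    f"row {r + 1}: token {tok!r} is neither an integer nor '.'"
                ) from None
            if ch in positions:
                raise LayoutError(f"channel {ch} listed twice")
            positions[ch] = (r, c)
    return ChannelLayout(positions=positions, n_rows=len(rows), n_cols=n_cols)
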