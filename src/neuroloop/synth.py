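"""Synthetic multielectrode-array recordings with ground truth.

Stands in for the dish, amplifier and acquisition board: produces a
multichannel extracellular voltage trace as Gaussian noise plus a biphasic
spike template superimposed at known times, together with the full ground
truth (every background spike, every planted motif and burst).  Ground
truth is what makes the closed-loop engine testable — parameter-recovery
tests can demand sample-exact agreement between detected and planted
spikes on noiseless traces.

The generated trace is quantized to the ADC code grid
(``scale_volts_per_code``, default 1 µV/code) exactly as a 12-bit digitizer
would, so a logged session plays back bit-identically.

Background trains are Poisson per channel, thinned to a configurable
minimum same-channel gap (default 2 ms) against both themselves and any
planted spikes, keeping ground truth unambiguous at the price of a slight
departure from pure Poisson statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import ArgumentError, Block, ms_to_samples
from .plugins import MotifSpec

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "spike_template",
    "plant_motif",
    "generate_recording",
    "stream_blocks",
]

MIN_BLOCK_SAMPLES = 64


def spike_template(
    amplitude_v: float = -60e-6,
    width_ms: float = 1.5,
    rate_hz: int = 16000,
) -> np.ndarray:
    """Biphasic extracellular spike template.

    A sharp negative deflection (the template's first sample *is* the
    negative peak) relaxing to zero, followed by a smaller positive
    rebound — the typical extracellular shape.  Putting the peak at sample
    zero makes the threshold-crossing time of a planted spike equal its
    ground-truth time for any threshold between zero and the peak.
    """
    n = ms_to_samples(width_ms, rate_hz)
    if n < 2:
        raise ArgumentError("template width must span at least 2 samples")
    n_neg = max(1, n // 3)
    n_pos = n - n_neg
    neg = amplitude_v * np.cos(np.linspace(0.0, np.pi / 2, n_neg, endpoint=False))
    pos = (-amplitude_v / 3.0) * np.sin(np.linspace(0.0, np.pi, n_pos))
    return np.concatenate([neg, pos])


@dataclass
class GroundTruth:
    """Per-channel true spike times plus planted structure, in samples."""

    spikes: Dict[int, np.ndarray] = field(default_factory=dict)
    motifs: List[List[Tuple[int, int]]] = field(default_factory=list)  # [(ch, t)]
    bursts: List[int] = field(default_factory=list)

    def motif_last_spikes(self) -> List[int]:
        """Crossing time of the final spike of each planted motif."""
        return [max(t for _, t in m) for m in self.motifs]

    def all_times(self, channel: int) -> np.ndarray:
        return self.spikes.get(channel, np.empty(0, dtype=int))


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    Defaults emulate the reference preparation: a 60-electrode MEA sampled
    at 16 kHz with sparse background activity.  ``planted_motifs`` entries
    are ``(spec, at_sample)`` or ``(spec, at_sample, gaps_samples)`` where
    ``spec`` is a :class:`~neuroloop.plugins.MotifSpec` or a plain electrode
    tuple; ``planted_bursts`` entries are
    ``(at_sample, channels, jitter_ms)``.
    """

    duration_s: float = 10.0
    n_channels: int = 60
    sampling_rate_hz: int = 16000
    noise_sd: float = 10e-6
    template_amplitude_v: float = -60e-6
    template_width_ms: float = 1.5
    background_rate_hz: Union[float, Sequence[float]] = 1.0
    min_gap_ms: float = 2.0
    planted_motifs: List[tuple] = field(default_factory=list)
    planted_bursts: List[tuple] = field(default_factory=list)
    scale_volts_per_code: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ArgumentError("duration must be positive")
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be non-negative")
        rates = np.atleast_1d(np.asarray(self.background_rate_hz, dtype=float))
        if np.any(rates < 0):
            raise ArgumentError("background rates must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


def plant_motif(
    spec: Union[MotifSpec, Sequence[int]],
    at: int,
    rate_hz: int,
    gaps: Optional[Sequence[int]] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[int, int]]:
    """Spike times for one motif occurrence starting at sample ``at``.

    Returns one ``(channel, t)`` per motif electrode at strictly increasing
    times; every consecutive gap is at most the spec's maximum interval.
    ``gaps`` (samples, one per consecutive pair) may be given explicitly;
    otherwise they are drawn uniformly from [half the bound, the bound].
    A single-electrode "motif" degenerates to one spike.
    """
    if isinstance(spec, MotifSpec):
        electrodes = spec.electrodes
        max_gap = ms_to_samples(spec.max_interval_ms, rate_hz)
    else:
        electrodes = tuple(spec)
        max_gap = ms_to_samples(10.0, rate_hz)
    n_gaps = len(electrodes) - 1
    if gaps is None:
        if n_gaps == 0:
            gaps = ()
        else:
            rng = rng or np.random.default_rng()
            gaps = rng.integers(max(1, max_gap // 2), max_gap + 1, n_gaps)
    gaps = tuple(int(g) for g in gaps)
    if len(gaps) != n_gaps:
        raise ArgumentError(f"motif needs {n_gaps} gaps, got {len(gaps)}")
    if any(g < 1 or g > max_gap for g in gaps):
        raise ArgumentError(
            f"motif gaps {gaps} outside (0, {max_gap}] samples"
        )
    out, t = [], int(at)
    for i, e in enumerate(electrodes):
        out.append((int(e), t))
        if i < n_gaps:
            t += gaps[i]
    return out


def _thin(times: np.ndarray, keep_near: np.ndarray, gap: int) -> np.ndarray:
    """Drop background times within ``gap`` of each other or of planted ones."""
    kept: List[int] = []
    last = -gap - 1
    j = 0
    keep_near = np.sort(keep_near)
    for t in np.sort(times):
        while j < len(keep_near) and keep_near[j] < t - gap:
            j += 1
        if j < len(keep_near) and abs(int(keep_near[j]) - int(t)) <= gap:
            continue
        if t - last <= gap:
            continue
        kept.append(int(t))
        last = t
    return np.asarray(kept, dtype=int)


def generate_recording(cfg: SynthConfig) -> Tuple[np.ndarray, GroundTruth]:
    """Render a synthetic recording and its ground truth.

    The trace is ``noise + sum of templates at true spike times``, quantized
    to the ADC grid; identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.sampling_rate_hz
    n = cfg.n_samples
    template = spike_template(cfg.template_amplitude_v, cfg.template_width_ms, rate)
    if len(template) > n:
        raise ArgumentError("spike template wider than the recording")
    gap = ms_to_samples(cfg.min_gap_ms, rate)

    planted: Dict[int, List[int]] = {c: [] for c in range(cfg.n_channels)}
    truth = GroundTruth()

    for entry in cfg.planted_motifs:
        spec, at = entry[0], int(entry[1])
        gaps = entry[2] if len(entry) > 2 else None
        spikes = plant_motif(spec, at, rate, gaps=gaps, rng=rng)
        for ch, t in spikes:
            if not 0 <= t < n:
                raise ArgumentError(f"planted motif spike at {t} outside recording")
            if ch >= cfg.n_channels:
                raise ArgumentError(f"motif electrode {ch} outside channel range")
            planted[ch].append(t)
        truth.motifs.append(spikes)

    for entry in cfg.planted_bursts:
        at, channels = int(entry[0]), entry[1]
        jitter_ms = float(entry[2]) if len(entry) > 2 else 2.0
        jitter = max(1, ms_to_samples(jitter_ms, rate))
        for ch in channels:
            t = at + int(rng.integers(0, jitter))
            if not 0 <= t < n:
                raise ArgumentError(f"planted burst spike at {t} outside recording")
            planted[int(ch)].append(t)
        truth.bursts.append(at)

    rates = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.background_rate_hz, dtype=float)),
        (cfg.n_channels,),
    )

    data = np.zeros((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        bg = np.empty(0, dtype=int)
        if rates[ch] > 0:
            count = rng.poisson(rates[ch] * cfg.duration_s)
            bg = _thin(
                rng.integers(0, n, count),
                np.asarray(planted[ch], dtype=int),
                gap,
            )
        times = np.sort(np.concatenate([bg, np.asarray(planted[ch], dtype=int)]))
        truth.spikes[ch] = times.astype(int)
        for t in times:
            seg = min(len(template), n - t)
            data[ch, t : t + seg] += template[:seg]

    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)

    # quantize to the ADC grid, channel by channel to bound peak memory
    q = cfg.scale_volts_per_code
    for ch in range(cfg.n_channels):
        np.multiply(np.rint(data[ch] / q), q, out=data[ch])
    return data, truth


def stream_blocks(data: np.ndarray, block_samples: int) -> Iterator[Block]:
    """Cut a recording into gapless acquisition blocks.

    Yields ``len // block_samples`` blocks; a trailing partial block is
    discarded, mirroring a board that only signals completed transfers.
    """
    if block_samples < MIN_BLOCK_SAMPLES:
        raise ArgumentError(
            f"block_samples must be >= {MIN_BLOCK_SAMPLES}, got {block_samples}"
        )
    if data.ndim != 2 or data.shape[1] < block_samples:
        raise ArgumentError("source must hold at least one full block")
    n_blocks = data.shape[1] // block_samples
    for k in range(n_blocks):
        lo = k * block_samples
        yield Block(
            index=k,
            start_sample=lo,
            data=data[:, lo : lo + block_samples].copy(),
        )
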