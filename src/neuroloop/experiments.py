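"""End-to-end timing experiments on synthetic data.

These drive the whole stack — generator, detector, engine and the motif
plugin — to measure the quantities the closed-loop design promises:

* the real-time loop repetition rate (sampling rate / block size);
* the motif-to-trigger delay, which on the virtual clock decomposes
  exactly into the post-crossing waveform-capture wait plus alignment to
  the next block boundary;
* refractory enforcement and trigger pulse width.

Problem sizes are desk scale: traces are noiseless, use 42 channels (the
demo motif's highest electrode is 41) and run a few virtual minutes; the
quantities measured are timing mechanics, which do not depend on noise or
on silent extra channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .core import SessionConfig, ms_to_samples, samples_to_ms
from .engine import Plugin, Session, loop_interval_stats
from .plugins import DEMO_ELECTRODES, MotifPlugin, MotifSpec
from .sequencer import MAX_ACTIONS, SequenceError, parse_sequence
from .synth import SynthConfig, generate_recording, stream_blocks

__all__ = [
    "loop_rate_experiment",
    "motif_latency_experiment",
    "refractory_experiment",
    "sequencer_capacity_experiment",
    "MotifLatencyResult",
]


def loop_rate_experiment(
    duration_s: float = 10.0,
    sampling_rate_hz: int = 45000,
    block_samples: int = 64,
    seed: int = 0,
) -> dict:
    """Measure the real-time loop rate of a simulated session.

    Runs a quiet single-channel session with a no-op real-time plugin and
    divides the number of real-time invocations by the virtual time
    processed.  On the virtual clock this equals sampling_rate / block_size
    exactly (e.g. 45000/64 = 703.125 Hz), with zero jitter.
    """
    scfg = SynthConfig(
        duration_s=duration_s,
        n_channels=1,
        sampling_rate_hz=sampling_rate_hz,
        noise_sd=0.0,
        background_rate_hz=0.0,
        seed=seed,
    )
    data, _ = generate_recording(scfg)
    cfg = SessionConfig(
        sampling_rate_hz=sampling_rate_hz,
        n_channels=1,
        block_samples=block_samples,
        seed=seed,
    )
    result = Session(
        cfg, stream_blocks(data, block_samples), plugins=[Plugin()]
    ).run()
    stats = loop_interval_stats(result)
    measured_s = result.end_sample / sampling_rate_hz
    return {
        "rate_hz": len(result.rt_times) / measured_s,
        "n_invocations": len(result.rt_times),
        "duration_s": measured_s,
        "interval_stats": stats,
    }


@dataclass
class MotifLatencyResult:
    delays_ms: np.ndarray  # trigger onset minus last motif spike crossing
    n_planted: int
    n_triggers: int
    pulse_widths_ms: np.ndarray
    intertrigger_s: np.ndarray


def _run_motif_session(
    planted,
    duration_s: float,
    spec: MotifSpec,
    sampling_rate_hz: int,
    block_samples: int,
    waveform_post_ms: float,
    seed: int,
) -> tuple:
    n_channels = max(spec.electrodes) + 1
    scfg = SynthConfig(
        duration_s=duration_s,
        n_channels=n_channels,
        sampling_rate_hz=sampling_rate_hz,
        noise_sd=0.0,
        background_rate_hz=0.0,
        planted_motifs=planted,
        seed=seed,
    )
    data, truth = generate_recording(scfg)
    cfg = SessionConfig(
        sampling_rate_hz=sampling_rate_hz,
        n_channels=n_channels,
        block_samples=block_samples,
        waveform_pre_ms=0.0,
        waveform_post_ms=waveform_post_ms,
        threshold_volts=-30e-6,
        seed=seed,
    )
    result = Session(
        cfg, stream_blocks(data, block_samples), plugins=[MotifPlugin(spec)]
    ).run()
    return result, truth


def motif_latency_experiment(
    n_motifs: int = 100,
    spacing_s: float = 2.0,
    sampling_rate_hz: int = 16000,
    block_samples: int = 64,
    waveform_post_ms: float = 8.0,
    seed: int = 0,
) -> MotifLatencyResult:
    """Motif-to-trigger delays over many planted motifs at random phases.

    Plants ``n_motifs`` full five-electrode motifs (consecutive gaps drawn
    from 5–10 ms), spaced ``spacing_s`` apart so every one falls outside
    the previous trigger's refractory period, with the start offset
    uniformly random relative to the 64-sample block grid.  The
    post-crossing capture wait is set to the full 8 ms demonstration
    waveform window, so each delay is the capture wait plus block
    alignment: between 8 ms and 8 ms + one loop period.
    """
    rng = np.random.default_rng(seed)
    spec = MotifSpec(electrodes=DEMO_ELECTRODES)
    rate = sampling_rate_hz
    gap_lo = ms_to_samples(5.0, rate)
    gap_hi = ms_to_samples(10.0, rate)
    spacing = int(round(spacing_s * rate))
    t0 = ms_to_samples(500.0, rate)
    planted = []
    last_spikes: List[int] = []
    for k in range(n_motifs):
        offset = int(rng.integers(0, block_samples))
        at = t0 + k * spacing + offset
        gaps = tuple(int(g) for g in rng.integers(gap_lo, gap_hi + 1, 4))
        planted.append((spec, at, gaps))
        last_spikes.append(at + sum(gaps))
    duration_s = (t0 + n_motifs * spacing + rate) / rate
    result, _ = _run_motif_session(
        planted, duration_s, spec, rate, block_samples, waveform_post_ms, seed
    )
    onsets = np.asarray(result.trigger_onsets(spec.line))
    # pair each trigger with the motif completion that caused it
    last = np.asarray(last_spikes)
    idx = np.searchsorted(last, onsets) - 1
    delays = samples_to_ms(onsets - last[idx], rate)
    return MotifLatencyResult(
        delays_ms=np.asarray(delays, dtype=float),
        n_planted=n_motifs,
        n_triggers=len(onsets),
        pulse_widths_ms=samples_to_ms(
            np.asarray(result.pulse_widths(spec.line), dtype=float), rate
        ),
        intertrigger_s=np.diff(onsets) / rate,
    )


def refractory_experiment(
    duration_s: float = 30.0,
    period_ms: float = 200.0,
    sampling_rate_hz: int = 16000,
    block_samples: int = 64,
    seed: int = 0,
) -> MotifLatencyResult:
    """Motifs recurring every ``period_ms`` under the 1-s demo refractory.

    Full motifs complete five times per refractory period; only every
    fifth completion may trigger, so consecutive trigger onsets are at
    least 1 s apart — exactly 1 s when the period divides the refractory.
    """
    spec = MotifSpec(electrodes=DEMO_ELECTRODES)
    rate = sampling_rate_hz
    period = ms_to_samples(period_ms, rate)
    gaps = (ms_to_samples(6.0, rate),) * 4
    t0 = ms_to_samples(500.0, rate)
    span = int(duration_s * rate) - rate  # leave tail room for capture
    planted = [
        (spec, at, gaps) for at in range(t0, span, period)
    ]
    last_spikes = [at + sum(gaps) for (_, at, _) in planted]
    result, _ = _run_motif_session(
        planted, duration_s, spec, rate, block_samples, 8.0, seed
    )
    onsets = np.asarray(result.trigger_onsets(spec.line))
    last = np.asarray(last_spikes)
    idx = np.searchsorted(last, onsets) - 1
    return MotifLatencyResult(
        delays_ms=np.asarray(samples_to_ms(onsets - last[idx], rate), dtype=float),
        n_planted=len(planted),
        n_triggers=len(onsets),
        pulse_widths_ms=samples_to_ms(
            np.asarray(result.pulse_widths(spec.line), dtype=float), rate
        ),
        intertrigger_s=np.diff(onsets) / rate,
    )


def sequencer_capacity_experiment() -> dict:
    """Largest accepted sequence length (and that one more is rejected)."""
    lines_200 = "\n".join("marker 0 tick" for _ in range(MAX_ACTIONS)) + "\n"
    seq = parse_sequence(lines_200)
    accepted = len(seq)
    rejected_201 = False
    try:
        parse_sequence(lines_200 + "marker 0 one-too-many\n")
    except SequenceError:
        rejected_201 = True
    return {"max_accepted": accepted, "rejects_201": rejected_201}
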