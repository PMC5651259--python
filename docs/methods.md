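# Methods

## The virtual sample clock

The engine models a block-clocked acquisition system: a data acquisition
board samples `C` channels at rate `f` and raises an interrupt every time a
block of `B` samples per channel has been transferred, and each interrupt
drives one pass of a fixed pipeline. Instead of emulating threads and
wall-clock scheduling, `neuroloop` replaces time itself: the only clock is
the integer sample index, a block "arrives" when the previous pipeline pass
finishes, and every stage runs to completion in a fixed order within each
pass:

1. preprocessing — spike detection, waveform capture, commit;
2. real-time plugin slot (once per block);
3. periodic plugin slot (at the first block end ≥ each multiple of the
   configured interval; intervals shorter than one block fire every block
   and log a warning);
4. output arbitration and application;
5. logging.

This preserves the observable semantics of the hardware original — what a
plugin can see when, and when its outputs take effect — while discarding
what cannot be a portable contract (preemption, jitter, CPU load). All
latencies are defined in sample units; millisecond values are derived at
the API surface with round-half-up conversion and never stored.
Consequences used throughout the tests: the loop rate is exactly `f/B`;
inter-invocation jitter is exactly zero; and identical inputs and seed give
bit-identical sessions.

Output application time is the end of the invoking block (zero virtual
processing time), since actual compute time is hardware-dependent and
outside the contract. Digital pulse reverts are the one exception to
block-aligned timestamps: a pulse of `d` samples requested at block end `t`
goes low at exactly `t + d`, applied when the covering block completes (or
at session finalization), so pulse widths are exact.

## Spike detection and deferred commit

Detection is a per-channel threshold crossing with a Schmitt-style
re-trigger rule at zero hysteresis: a crossing fires on the first sample on
the triggered side after at least one sample on the non-triggered side.
Polarity is configurable per channel; the default is negative-going, the
extracellular convention. One wide spike produces one event; genuinely
separate crossings each produce an event, even when their capture windows
overlap — overlapping events are stored separately, not lumped.

Each event's waveform covers `[t_cross − n_pre, t_cross + n_post)`
(defaults 1 ms / 7 ms of the 8-ms demonstration window; crossings within
`n_pre` of the recording start are zero-padded). A crossing stays pending
until the first completed block end ≥ `t_cross + n_post`; only then is the
event committed with `visible_at` set to that block end. For `n_post ≥ 1`
this equals `⌈(t_cross + n_post)/B⌉·B`; with `n_post = 0` a boundary
crossing still commits at the end of the block that contains it, since it
cannot be detected earlier. Detection and waveforms are therefore invariant
to block size; only `visible_at` depends on `B`, and
`visible_at − t_cross ∈ [n_post, n_post + B]` always. This is the entire
timing story of the trigger-latency results: an 8-ms post-crossing window
and 4-ms blocks give delays uniform on ≈[8 ms, 12 ms], mean ≈ 10 ms.

No filter stage runs by default; the detector exposes a causal `prefilter`
hook for users who want a streaming high-pass, but thresholds the raw
trace otherwise.

## Repositories and visibility

All streams (spikes, digital in/out, analog out, two user-data streams,
text) are bounded, time-ordered FIFO stores; eviction removes oldest first
and is counted. Queries are half-open `[t0, t1)` over 0-based sample
indices, so adjacent windows partition time. Spike queries additionally
respect visibility: by default a window ending at `t1` only returns spikes
with `visible_at ≤ t1`, and the engine's plugin context pins the horizon to
the current block end, so no plugin can ever observe a spike before its
capture completed. The spike store defaults to 500,000 events ("several
hundred thousand" is the design envelope; the exact figure is
configurable); raw history is a rolling duration (default 10 s) rather
than a count, and both styles are supported.

## Arbitration

The hardware original shared one output buffer between the real-time and
periodic threads behind a semaphore, and documented that periodic output
*may* be lost when the buffer is busy. A testable engine needs a
deterministic rule, so the engine adopts the strictest reading: in any
block where the real-time slot produced hardware output (digital or
analog), periodic hardware output is dropped, counted and logged as a text
message. User-data and text requests bypass the hardware buffer and are
never dropped. Overlapping pulses on one line resolve last-writer-wins
with a logged warning. Requests to nonexistent lines/channels are logged
and skipped. A plugin that raises is disabled and the session continues;
an experiment must survive its closed-loop code.

## Motif matching

A motif is an ordered electrode list with a bound on consecutive
inter-spike gaps. Matching is an earliest-completion greedy automaton over
newly *visible* spikes (the scan frontier is over `visible_at`, not
`t_cross`, because a spike's commit can trail its crossing by up to
`n_post + B` samples): a spike on motif electrode `i` extends the prefix
when it strictly follows the current prefix-`i−1` spike within the gap
bound; completing the last position is a match, which consumes the matched
spikes. Spikes on non-motif electrodes are ignored; an out-of-order spike
on a motif electrode does not invalidate a match in progress — only the
order among the matched spikes matters. Whether the original demonstration
required the five spikes to be consecutive is not recoverable; this rule
is ours and is documented as such. On a match, a trigger fires only if the
last trigger is at least one refractory period old; matches inside the
refractory period are detected (counted) but signal nothing and do not
extend the refractory clock.

## Synthetic recordings

The generator stands in for dish, amplifier and digitizer. A recording is
Gaussian noise plus a biphasic template at known times, quantized to the
ADC grid. Choices, none of which the original constrains:

* **Template** — negative peak of −60 µV at the template's first sample,
  relaxing over ~0.5 ms, then a +20 µV rebound; total width 1.5 ms.
  Putting the peak at sample zero makes a planted spike's threshold
  crossing equal its ground-truth time for any threshold between 0 and the
  peak, which is what lets recovery tests demand sample-exact agreement.
* **Noise floor** — default 10 µV rms (8 µV in the README example);
  detection thresholds default to −30 µV, half the template amplitude.
* **Background activity** — per-channel Poisson (default 1 Hz, the order
  of spontaneous culture activity), thinned to a 2-ms minimum same-channel
  gap against itself and against planted spikes so ground truth stays
  unambiguous. Thinning makes counts slightly sub-Poisson; the
  consistency test uses a 4·√(rT) band.
* **Quantization** — 1 µV/code, int16 storage. This mirrors a 12-bit
  converter behind a ×1000-class amplifier, keeps the template exact on
  the grid, makes text export exactly decimal, and — because the generator
  itself snaps to the grid — makes log → playback bit-identical.

What the generator does *not* emulate: field potentials, electrode drift,
waveform variability across units, bursts with realistic intraburst
structure, artifacts. Tests passing on this data therefore validate the
*engine's* timing, ordering and bookkeeping contracts, not detection
performance on real recordings.

## Persistence

Formats are this package's own (the original's binary formats are
unpublished; no compatibility is claimed): a JSON manifest plus headerless
int16 little-endian interleaved raw files and per-stream CSVs, rolled over
so no file exceeds the configured size (a single oversized record is
allowed). Events are logged with a 500-ms virtual-time flush cadence.
Read-back is independent of the rollover size; a torn final record (raw
frame or CSV row) is dropped with a warning and everything before it is
recovered; a torn record anywhere else is a hard error. Playback streams a
logged session's raw data as blocks; with the same configuration and
plugins it reproduces the original run's event streams exactly.

## Sequencer

Experiment sequences are plain-text action lists (≤ 200 actions):
`run`, `marker`, `load_plugin`, `unload_plugin`, `start_logging`,
`stop_logging`, `set_threshold`, `stop`. Each action performs its effect
and then advances the virtual clock by its stated duration (`run` is a
pure advance), so durations sum to the log span; unknown plugin names are
logged and skipped; `stop` or source exhaustion ends the sequence early.
The grammar and the uniform duration rule are this package's choices — the
original exposed only a dialog box.

## Problem sizes

The timing experiments in `neuroloop.experiments` (used by the test suite
and `scripts/acceptance.py`) run noiseless traces with 42 channels (the
demonstration motif's highest electrode is 41) rather than a full
60-channel noisy preparation: the measured quantities — loop rate, capture
wait, block alignment, refractory floor, pulse width — are properties of
the clocking arithmetic and are unaffected by noise or by silent extra
channels, while the smaller traces keep a full 100-motif experiment at
about 200 virtual seconds and ~1 GB of trace. The delay experiment plants
motifs 2 s apart (outside the 1-s refractory) with start phases uniform
over the 64-sample block grid; the refractory experiment plants a full
motif every 200 ms for 30 s.

## Known limitations

* No wall-clock pacing: the engine runs as fast as it computes; there is
  deliberately no real-time guarantee to inherit or violate.
* Single-threaded by design; the original's concurrency is modelled as
  ordering contracts, not reproduced.
* The burst detector is a simple rate-threshold stand-in, not a published
  burst-detection algorithm.
* No spike sorting; a "spike" is a threshold crossing.
* Raw storage is int16 at a fixed linear scale; signals beyond ±32.767 mV
  at the default 1 µV/code would clip.
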