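# neuroloop

A deterministic closed-loop multichannel electrophysiology engine on a
virtual sample clock.

Closed-loop experiments with spiking neuronal networks — e.g. cortical
cultures on a 60-electrode multielectrode array (MEA) — need a
sample-analyze-output loop fast enough to react within the duration of a
single action potential (~1–2 ms), plus spike detection, event histories,
logging and experiment automation around it. Systems that do this on real
hardware are clocked by the acquisition board: an interrupt fires every time
a block of `B` samples per channel lands in memory, and each interrupt
drives one pass of a pipeline (preprocess → real-time closed-loop code →
output). `neuroloop` re-implements that engine with the wall clock replaced
by a **virtual sample clock**: every timestamp is an integer sample index at
the session sampling rate, every latency is a sample count, and two runs
with the same inputs and seed are bit-identical. That turns soft real-time
behaviour into a testable contract and makes the engine a simulation and
prototyping tool for closed-loop protocols.

## The timing model

With sampling rate `f` and block size `B` (hardware minimum 64 samples),
the real-time loop runs at exactly

```
loop rate = f / B          (45 kHz, B = 64  →  703.125 Hz, period 1.42 ms)
```

Spikes are detected as threshold crossings (per-channel threshold and
polarity; negative-going by default), and each spike carries a waveform
covering `n_pre` samples before and `n_post` samples after the crossing.
Because the post-window extends past the current block, a spike enters the
event repository only at the first block end that covers its full window —
so closed-loop code reacts to a spike with a delay of

```
delay ∈ [n_post, n_post + B]  samples
```

With the 8-ms capture window and 64-sample blocks at 16 kHz this is
8–12 ms, mean ≈ 10 ms for uniformly random spike phases — the waveform
capture wait plus 0–4 ms of loop alignment.

Two closed-loop slots host user plugins: a real-time slot invoked once per
block and a slow periodic slot invoked at a configurable interval. Plugins
see read-only views of all event repositories (raw, spikes, digital I/O,
analog out, two user-data streams, text messages) and emit output requests;
periodic *hardware* output is dropped (and logged) when the real-time slot
produced hardware output in the same block, mirroring the contended output
buffer of the hardware original.

Reference plugins implement the classic demonstration protocol: a motif
detector that watches for an ordered five-electrode spike sequence
(consecutive gaps ≤ 10 ms), pulses a digital line for 5 ms on a match and
enforces a 1-s refractory period; a 60-s spike-rate monitor; an I/O-latency
probe; and a simple rate-threshold network-burst detector.

## Worked example

`config.yml`:

```yaml
session:
  sampling_rate_hz: 16000
  n_channels: 60
  block_samples: 64
  threshold_volts: -30.0e-6      # volts; half the synthetic spike amplitude
  periodic_interval_ms: 1000.0
synth:
  duration_s: 20
  noise_sd: 8.0e-6               # volts rms
  background_rate_hz: 0.5        # Poisson, per channel
  motifs:
    - electrodes: [37, 26, 25, 34, 41]
      at_s: [2.0, 2.4, 6.0, 11.5, 18.0]
      gap_ms: 6
plugins:
  - name: motif
    args: "37,26,25,34,41;10;1;5;1"   # electrodes; max gap ms; line; pulse ms; refractory s
  - name: rate
    args: "60;1"                      # window s; scale
```

```
$ neuroloop run -c config.yml -o session --seed 1
blocks processed: 5000
spikes committed: 2077
loop interval: 4.000 ms (rate 250.0 Hz, sd 0.000 ms)
digital triggers issued: 4
```

20 s at 16 kHz is 5000 blocks of 64 samples; the loop period is
64/16000 = 4 ms exactly, with zero jitter on the virtual clock. The 2077
committed events are the ~625 true (background + planted) spikes plus
noise crossings — the −30 µV threshold sits at 3.75 σ of the 8 µV noise
floor, which at 16 kHz still crosses about once per channel-second, just
as it would on a real rig. The motif plugin fires **4** triggers from **5**
planted motifs: the motif at 2.4 s completes 0.4 s after the 2.0 s trigger
and falls inside the 1-s refractory period, so it is detected but not
signalled. The session directory holds the manifest, raw int16 data,
per-stream event CSVs and a timestamped `log.txt`; `neuroloop export`
converts raw data and spikes to plain text, `neuroloop playback` re-runs
the logged session through the same pipeline (bit-identically), and
`neuroloop sequence` executes a timed experiment script (up to 200
actions).

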