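"""Per-block spike detection with deferred waveform commit.

A spike is a threshold crossing: the first sample on the triggered side of
the per-channel threshold after at least one sample on the non-triggered
side (Schmitt-style with zero hysteresis — one wide spike yields one
crossing, while genuinely re-crossing signals yield one event per
crossing, stored as separate, possibly overlapping events).

The captured waveform spans ``[t_cross - n_pre, t_cross + n_post)``.  Since
the post-window usually extends past the current block, detected crossings
stay *pending* until the block whose end covers the full window completes;
only then is the event committed with ``visible_at`` set to that block end.
Closed-loop code therefore reacts to a spike no earlier than
``t_cross + n_post`` and no later than ``t_cross + n_post + B`` samples
after the crossing — the waveform-capture wait plus loop alignment that
dominates trigger latency.

Detection itself is block-size invariant: crossing times and waveforms are
identical for any block size; only ``visible_at`` depends on it.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np

from .core import ArgumentError, Block, OrderingError, SessionConfig, SpikeEvent

__all__ = ["SpikeDetector"]


class SpikeDetector:
    """Streaming detector fed one :class:`Block` at a time.

    Parameters
    ----------
    cfg
        Session configuration (thresholds, polarities, waveform window).

    Attributes
    ----------
    prefilter
        Optional causal preprocessing hook ``f(data) -> data`` applied to each
        block before thresholding (e.g. a streaming high-pass).  Disabled by
        default; the detector then thresholds the raw trace.
    """

    def __init__(self, cfg: SessionConfig):
        self.cfg = cfg
        self.n_pre = cfg.n_pre
        self.n_post = cfg.n_post
        self._thr = cfg.thresholds[:, None]
        self._neg = (cfg.polarities < 0)[:, None]
        # ring buffer deep enough to cut any pending spike's full window
        self._depth = self.n_pre + self.n_post + 2 * cfg.block_samples
        self._buf = np.zeros((cfg.n_channels, self._depth))
        self._buf_end = 0
        self._trig = np.zeros(cfg.n_channels, dtype=bool)
        self._pending: List[Tuple[int, int]] = []  # (t_cross, channel), sorted
        self._next_index = 0
        self.prefilter: Optional[Callable[[np.ndarray], np.ndarray]] = None

    # -- detection ---------------------------------------------------------

    def _triggered(self, data: np.ndarray) -> np.ndarray:
        return np.where(self._neg, data < self._thr, data > self._thr)

    def detect_block(self, block: Block) -> List[Tuple[int, int]]:
        """Record ``block`` and return its new crossings as (t_cross, channel).

        Blocks must arrive in order.  A crossing exactly at a block boundary
        belongs to the block containing the first triggered sample.  Detection
        continues while capture windows are open, so overlapping same-channel
        events are each reported.
        """
        if block.index != self._next_index:
            raise OrderingError(
                f"block {block.index} arrived, expected {self._next_index}"
            )
        self._next_index += 1
        data = block.data if self.prefilter is None else self.prefilter(block.data)
        b = data.shape[1]
        if b >= self._depth:
            self._buf[:] = data[:, -self._depth :]
        else:
            self._buf[:, :-b] = self._buf[:, b:]
            self._buf[:, -b:] = data
        self._buf_end = block.start_sample + b

        trig = self._triggered(data)
        prev = np.empty_like(trig)
        prev[:, 0] = self._trig
        prev[:, 1:] = trig[:, :-1]
        rising = trig & ~prev
        self._trig = trig[:, -1].copy()
        ch, off = np.nonzero(rising)
        crossings = sorted(
            (block.start_sample + int(o), int(c)) for c, o in zip(ch, off)
        )
        self._pending.extend(crossings)
        return crossings

    # -- capture + commit --------------------------------------------------

    def pending(self) -> List[Tuple[int, int]]:
        """Crossings whose capture window is still open."""
        return list(self._pending)

    def capture_waveform(self, t_cross: int, channel: int) -> np.ndarray:
        """Cut ``[t_cross - n_pre, t_cross + n_post)`` from the ring buffer.

        Samples before the recording start are zero-padded (the buffer is
        zero-initialized, so the pre-session region reads as zeros).
        """
        lo = t_cross - self.n_pre
        buf_start = self._buf_end - self._depth
        if lo < buf_start or t_cross + self.n_post > self._buf_end:
            raise ArgumentError(
                f"capture window for t_cross={t_cross} outside buffered span"
            )
        i = lo - buf_start
        return self._buf[channel, i : i + self.n_pre + self.n_post].copy()

    def commit_ready(self, completed_block_end: int) -> List[SpikeEvent]:
        """Commit pending spikes whose capture window is complete.

        Exactly those with ``t_cross + n_post <= completed_block_end`` are
        committed (once each), with ``visible_at = completed_block_end``.
        """
        ready = [p for p in self._pending if p[0] + self.n_post <= completed_block_end]
        if ready:
            self._pending = [
                p for p in self._pending if p[0] + self.n_post > completed_block_end
            ]
        return [
            SpikeEvent(
                t_cross=t,
                channel=c,
                waveform=self.capture_waveform(t, c),
                visible_at=completed_block_end,
            )
            for t, c in ready
        ]

    def process_block(self, block: Block) -> List[SpikeEvent]:
        """detect → capture → commit for one block; returns committed events."""
        self.detect_block(block)
        return self.commit_ready(block.end_sample)
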