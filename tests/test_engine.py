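"""Pipeline ordering, plugin slots, arbitration and output application."""

import numpy as np
import pytest

from neuroloop import (
    ArgumentError,
    OutputRequest,
    Plugin,
    Session,
    SessionConfig,
    SynthConfig,
    arbitrate,
    generate_recording,
    loop_interval_stats,
    run_session,
    stream_blocks,
)


def _cfg(**kw):
    base = dict(sampling_rate_hz=16000, n_channels=1, block_samples=64,
                threshold_volts=-50e-6)
    base.update(kw)
    return SessionConfig(**base)


def _blocks(n_blocks, n_channels=1, block_samples=64):
    return stream_blocks(np.zeros((n_channels, n_blocks * block_samples)),
                         block_samples)


class _Recorder(Plugin):
    """Runs a callback in a chosen slot."""

    name = "recorder"

    def __init__(self, realtime=None, periodic=None):
        self._rt = realtime
        self._p = periodic
        self.rt_calls = 0
        self.periodic_calls = 0

    def process_realtime(self, ctx):
        self.rt_calls += 1
        if self._rt:
            self._rt(ctx)

    def process_periodic(self, ctx):
        self.periodic_calls += 1
        if self._p:
            self._p(ctx)


def test_noop_session_has_one_rt_slot_per_block():
    result = run_session(_cfg(), _blocks(10))
    assert result.n_blocks == 10
    assert result.rt_times == [64 * (k + 1) for k in range(10)]
    assert all(not tl for tl in result.digital_timeline.values())
    assert all(not tl for tl in result.analog_timeline.values())


def test_realtime_invocations_equal_block_count():
    plugin = _Recorder()
    run_session(_cfg(), _blocks(37), plugins=[plugin])
    assert plugin.rt_calls == 37


class TestPeriodicSlot:
    def test_one_second_interval_two_second_run(self):
        cfg = _cfg(periodic_interval_ms=1000.0)
        result = run_session(cfg, _blocks(500))  # 2 s at 16 kHz
        assert result.periodic_times == [16000, 32000]

    def test_scaled_long_run_count(self):
        # one invocation per interval: a 124-s run at 1 Hz fires 124 times
        cfg = _cfg(periodic_interval_ms=1000.0)
        result = run_session(cfg, _blocks(124 * 250))
        assert len(result.periodic_times) == 124

    def test_non_block_multiple_interval_fires_at_next_block_end(self):
        cfg = _cfg(periodic_interval_ms=6.25)  # 100 samples, B = 64
        result = run_session(cfg, _blocks(16))
        assert result.periodic_times == [128, 256, 320, 448, 512, 640, 704,
                                         832, 960, 1024]

    def test_degenerate_interval_fires_every_block_with_warning(self):
        cfg = _cfg(periodic_interval_ms=2.0)  # 32 samples < one block
        plugin = _Recorder()
        result = run_session(cfg, _blocks(10), plugins=[plugin])
        assert plugin.periodic_calls == 10
        assert any("periodic interval shorter" in ev.text
                   for ev in result.text_log)


class TestArbitration:
    def test_periodic_alone_is_applied(self):
        applied, dropped = arbitrate([], [OutputRequest("digital", 1, 1)])
        assert len(applied) == 1 and dropped == []

    def test_same_block_hardware_contention_drops_periodic(self):
        rt = [OutputRequest("digital", 0, 1)]
        periodic = [OutputRequest("digital", 1, 1)]
        applied, dropped = arbitrate(rt, periodic)
        assert applied == rt
        assert len(dropped) == 1

    def test_user_data_bypasses_hardware_buffer(self):
        rt = [OutputRequest("analog", 0, 2.0)]
        periodic = [OutputRequest("user", 1, 3.5), OutputRequest("text", "p", "m")]
        applied, dropped = arbitrate(rt, periodic)
        assert dropped == []
        assert len(applied) == 3

    def test_engine_logs_and_counts_drops(self):
        cfg = _cfg(periodic_interval_ms=100.0)
        rt = _Recorder(realtime=lambda ctx: ctx.request_digital(0, 1))
        per = _Recorder(periodic=lambda ctx: (ctx.request_digital(1, 1),
                                              ctx.request_user(1, 7.0)))
        result = run_session(cfg, _blocks(50), plugins=[rt, per])
        n_periodic = len(result.periodic_times)
        assert n_periodic > 0
        assert result.dropped_periodic == n_periodic  # digital dropped each slot
        assert len(result.repos["user"]) == n_periodic  # user data never dropped
        assert any("periodic output dropped" in ev.text for ev in result.text_log)


class TestOutputApplication:
    def test_pulse_exact_edges(self):
        def fire(ctx):
            if ctx.block_index == 17:  # block end 1152
                ctx.request_digital(3, 1, revert_after=80)

        result = run_session(_cfg(), _blocks(30),
                             plugins=[_Recorder(realtime=fire)])
        assert result.digital_timeline[3] == [(1152, 1), (1232, 0)]
        assert result.pulse_widths(3) == [80]

    def test_pulse_revert_beyond_session_end_still_applied(self):
        def fire(ctx):
            if ctx.block_index == 28:
                ctx.request_digital(0, 1, revert_after=800)

        result = run_session(_cfg(), _blocks(30),
                             plugins=[_Recorder(realtime=fire)])
        assert result.digital_timeline[0] == [(1856, 1), (2656, 0)]

    def test_overlapping_pulses_later_request_wins(self):
        def fire(ctx):
            if ctx.block_index in (10, 11):  # 64 samples apart, pulses of 80
                ctx.request_digital(0, 1, revert_after=80)

        result = run_session(_cfg(), _blocks(30),
                             plugins=[_Recorder(realtime=fire)])
        # second request cancels the first revert; single low edge at 768+80
        assert result.digital_timeline[0] == [(704, 1), (768, 1), (848, 0)]
        assert sum("overlapping pulse" in ev.text for ev in result.text_log) == 1

    def test_analog_holds_last_value(self):
        def fire(ctx):
            if ctx.block_index == 2:
                ctx.request_analog(1, 2.5)

        result = run_session(_cfg(), _blocks(5),
                             plugins=[_Recorder(realtime=fire)])
        assert result.analog_timeline[1] == [(192, 2.5)]

    def test_request_to_nonexistent_line_logged_and_skipped(self):
        result = run_session(
            _cfg(), _blocks(3),
            plugins=[_Recorder(realtime=lambda ctx: ctx.request_digital(99, 1))],
        )
        assert any("nonexistent digital line 99" in ev.text
                   for ev in result.text_log)
        assert len(result.repos["digital_out"]) == 0


class TestLoopStats:
    def test_virtual_clock_intervals_are_exact(self):
        cfg = _cfg(sampling_rate_hz=45000)
        result = run_session(cfg, _blocks(100))
        stats = loop_interval_stats(result)
        assert stats.mean_ms == pytest.approx(64 / 45000 * 1000)
        assert stats.sd_ms == 0.0
        assert stats.rate_hz == pytest.approx(703.125)

    def test_16khz_interval_is_4ms(self):
        result = run_session(_cfg(), _blocks(10))
        assert loop_interval_stats(result).mean_ms == 4.0

    def test_requires_two_invocations(self):
        result = run_session(_cfg(), _blocks(1))
        with pytest.raises(ArgumentError):
            loop_interval_stats(result)


class _Exploder(Plugin):
    name = "exploder"

    def __init__(self, fail_at=5):
        self.fail_at = fail_at
        self.calls = 0

    def process_realtime(self, ctx):
        self.calls += 1
        ctx.request_user(1, float(self.calls))
        if self.calls == self.fail_at:
            raise RuntimeError("boom")


def test_failing_plugin_is_disabled_session_survives():
    plugin = _Exploder(fail_at=5)
    result = run_session(_cfg(), _blocks(20), plugins=[plugin])
    assert result.n_blocks == 20  # session completed
    assert plugin.calls == 5  # never called again after the error
    assert any("disabled after error" in ev.text for ev in result.text_log)
    # requests made during the failing invocation are still collected
    assert len(result.repos["user"]) == 5


def test_plugins_cannot_see_uncommitted_spikes():
    """Stage ordering: no realtime slot observes a spike with
    visible_at beyond the current block end."""
    scfg = SynthConfig(duration_s=1.0, n_channels=1, noise_sd=0.0,
                       background_rate_hz=20.0, seed=3)
    data, _ = generate_recording(scfg)
    seen = []

    def peek(ctx):
        for s in ctx.spikes(0, ctx.now):
            seen.append((s.visible_at, ctx.now))

    cfg = _cfg(threshold_volts=-30e-6)
    run_session(cfg, stream_blocks(data, 64),
                plugins=[_Recorder(realtime=peek)])
    assert seen, "expected some spikes to be observed"
    assert all(vis <= now for vis, now in seen)


def test_same_seed_same_result():
    scfg = SynthConfig(duration_s=1.5, n_channels=2, noise_sd=10e-6,
                       background_rate_hz=8.0, seed=21)
    outs = []
    for _ in range(2):
        data, _ = generate_recording(scfg)
        cfg = _cfg(n_channels=2, threshold_volts=-30e-6,
                   periodic_interval_ms=250.0)
        plugin = _Recorder(
            realtime=lambda ctx: None,
            periodic=lambda ctx: ctx.request_user(1, float(len(ctx.spikes()))),
        )
        result = run_session(cfg, stream_blocks(data, 64), plugins=[plugin])
        outs.append(result)
    a, b = outs
    assert [(e.t_cross, e.channel) for e in a.repos["spikes"]] == [
        (e.t_cross, e.channel) for e in b.repos["spikes"]
    ]
    assert a.repos["user"].events == b.repos["user"].events
    assert a.rt_times == b.rt_times and a.periodic_times == b.periodic_times


def test_loopback_feeds_output_to_next_block_input():
    cfg = _cfg()

    def drive(ctx):
        if ctx.block_index == 0:
            ctx.request_analog(0, 3.0)

    session = Session(cfg, _blocks(3), plugins=[_Recorder(realtime=drive)],
                      loopback=(0, 0))
    result = session.run()
    # block 0 saw the initial 0 V; blocks 1+ see the driven 3 V
    np.testing.assert_array_equal(result.raw.query(0, 64, channel=0), 0.0)
    np.testing.assert_array_equal(result.raw.query(64, 192, channel=0), 3.0)
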