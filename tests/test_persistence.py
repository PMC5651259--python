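"""Session store round-trips, rollover, playback equivalence, layouts."""

import json
import warnings

import numpy as np
import pytest

from neuroloop import (
    LayoutError,
    MotifPlugin,
    MotifSpec,
    RateMonitorPlugin,
    SessionConfig,
    SessionStore,
    StorageError,
    SynthConfig,
    export_text,
    generate_recording,
    playback_blocks,
    read_layout,
    read_session,
    run_session,
    stream_blocks,
)

SPEC = MotifSpec(electrodes=(0, 1, 2, 3, 4))


def _cfg(**kw):
    base = dict(sampling_rate_hz=16000, n_channels=5, block_samples=64,
                waveform_pre_ms=1.0, waveform_post_ms=7.0,
                threshold_volts=-30e-6, periodic_interval_ms=250.0)
    base.update(kw)
    return SessionConfig(**base)


def _recording(duration_s=1.5, seed=13, background=6.0):
    scfg = SynthConfig(duration_s=duration_s, n_channels=5, noise_sd=0.0,
                       background_rate_hz=background,
                       planted_motifs=[(SPEC, 4000, (96,) * 4)], seed=seed)
    return generate_recording(scfg)


def _logged_session(tmp_path, max_file_bytes=50_000_000, plugins=None):
    data, truth = _recording()
    cfg = _cfg()
    store = SessionStore(tmp_path / "session", cfg, max_file_bytes=max_file_bytes)
    plugins = plugins if plugins is not None else [
        MotifPlugin(SPEC), RateMonitorPlugin(window_s=1.0)
    ]
    result = run_session(cfg, stream_blocks(data, 64), plugins=plugins,
                         store=store)
    return data, truth, cfg, result, tmp_path / "session"


def _event_key(ev):
    return (ev.timestamp, tuple(sorted(vars(ev).items())) if hasattr(ev, "__dict__")
            else ev)


class TestRoundTrip:
    def test_raw_and_events_read_back_identically(self, tmp_path):
        data, _, cfg, result, sdir = _logged_session(tmp_path)
        back = read_session(sdir)
        n_logged = result.n_blocks * 64
        np.testing.assert_array_equal(back.raw_volts(), data[:, :n_logged])
        # spikes: timestamps, channels, visibility and waveforms all survive
        orig = result.repos["spikes"].events
        assert len(back.events["spikes"]) == len(orig)
        for a, b in zip(orig, back.events["spikes"]):
            assert (a.t_cross, a.channel, a.visible_at) == (
                b.t_cross, b.channel, b.visible_at
            )
            np.testing.assert_array_equal(a.waveform, b.waveform)
        for stream in ("digital_out", "user", "text"):
            assert back.events[stream] == result.repos[stream].events

    def test_raw_frame_count_matches_blocks(self, tmp_path):
        _, _, _, result, sdir = _logged_session(tmp_path)
        back = read_session(sdir)
        assert back.raw_codes.shape[1] == result.n_blocks * 64

    def test_manifest_suffices_to_rebuild_config(self, tmp_path):
        _, _, cfg, _, sdir = _logged_session(tmp_path)
        rebuilt = read_session(sdir).session_config()
        assert rebuilt.sampling_rate_hz == cfg.sampling_rate_hz
        assert rebuilt.n_channels == cfg.n_channels
        np.testing.assert_array_equal(rebuilt.thresholds, cfg.thresholds)


class TestRollover:
    def test_tiny_files_roll_and_concatenate(self, tmp_path):
        _, _, _, result, sdir = _logged_session(tmp_path, max_file_bytes=4096)
        assert len(list(sdir.glob("raw.*.bin"))) > 1
        assert all(
            p.stat().st_size <= 4096 for p in sdir.glob("*.bin")
        )
        back = read_session(sdir)
        assert len(back.events["spikes"]) == len(result.repos["spikes"])

    def test_read_back_independent_of_rollover_size(self, tmp_path):
        outs = []
        for name, size in (("small", 2048), ("big", 10**8)):
            data, _, cfg, _, _ = _logged_session(tmp_path / name,
                                                 max_file_bytes=size)
            outs.append(read_session(tmp_path / name / "session"))
        a, b = outs
        np.testing.assert_array_equal(a.raw_codes, b.raw_codes)
        assert a.events == b.events

    def test_no_events_no_file_growth(self, tmp_path):
        cfg = _cfg(n_channels=1)
        store = SessionStore(tmp_path / "s", cfg, streams=("spikes",))
        store.append_events("spikes", [])
        store.close()
        files = list((tmp_path / "s").glob("spikes.*.csv"))
        # at most the header exists; no records were written
        assert all(len(p.read_text().splitlines()) == 1 for p in files)


class TestTornTails:
    def test_truncated_raw_file_recovers_complete_frames(self, tmp_path):
        data, _, _, _, sdir = _logged_session(tmp_path)
        raw_files = sorted(sdir.glob("raw.*.bin"))
        last = raw_files[-1]
        last.write_bytes(last.read_bytes()[:-3])  # tear mid-frame
        with pytest.warns(UserWarning, match="torn frame"):
            back = read_session(sdir)
        np.testing.assert_array_equal(
            back.raw_volts(), data[:, : back.raw_codes.shape[1]]
        )

    def test_truncated_event_file_drops_only_final_record(self, tmp_path):
        _, _, _, result, sdir = _logged_session(tmp_path)
        spike_files = sorted(sdir.glob("spikes.*.csv"))
        text = spike_files[-1].read_text()
        spike_files[-1].write_text(text[:-20])  # cut into the last record
        with pytest.warns(UserWarning, match="incomplete final record"):
            back = read_session(sdir)
        assert len(back.events["spikes"]) == len(result.repos["spikes"]) - 1

    def test_missing_manifest_rejected(self, tmp_path):
        with pytest.raises(StorageError, match="manifest"):
            read_session(tmp_path)

    def test_version_mismatch_rejected(self, tmp_path):
        _, _, _, _, sdir = _logged_session(tmp_path)
        manifest = json.loads((sdir / "manifest.json").read_text())
        manifest["version"] = 99
        (sdir / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(StorageError, match="version"):
            read_session(sdir)


def test_playback_blocks_equal_original_blocks(tmp_path):
    data, _, cfg, _, sdir = _logged_session(tmp_path)
    played = list(playback_blocks(sdir))
    original = list(stream_blocks(data, 64))[: len(played)]
    for a, b in zip(played, original):
        assert a.index == b.index
        np.testing.assert_array_equal(a.data, b.data)


def test_playback_rerun_reproduces_session_result(tmp_path):
    """Log a closed-loop run, play it back through the same pipeline with
    the same plugins: every event stream is identical."""
    data, _, cfg, live, sdir = _logged_session(tmp_path)
    replay = run_session(
        cfg, playback_blocks(sdir),
        plugins=[MotifPlugin(SPEC), RateMonitorPlugin(window_s=1.0)],
    )
    assert [(e.t_cross, e.channel, e.visible_at)
            for e in live.repos["spikes"]] == [
        (e.t_cross, e.channel, e.visible_at) for e in replay.repos["spikes"]
    ]
    assert live.digital_timeline == replay.digital_timeline
    assert live.repos["user"].events == replay.repos["user"].events
    assert live.rt_times == replay.rt_times


class TestExportText:
    def test_spike_rows_and_exact_values(self, tmp_path):
        _, _, _, result, sdir = _logged_session(tmp_path)
        out = export_text(sdir, tmp_path / "txt")
        lines = out["spikes"].read_text().splitlines()
        assert len(lines) == 1 + len(result.repos["spikes"])
        back = read_session(sdir)
        row = lines[1].split(",")
        ev = back.events["spikes"][0]
        assert int(row[0]) == ev.t_cross
        assert float(row[1]) == ev.t_cross * 1000.0 / 16000
        assert int(row[2]) == ev.channel
        parsed = np.array([float(x) for x in row[3:]])
        np.testing.assert_array_equal(parsed, ev.waveform)

    def test_raw_export_lossless_at_code_resolution(self, tmp_path):
        data, _, _, _, sdir = _logged_session(tmp_path)
        out = export_text(sdir, tmp_path / "txt")
        lines = out["raw"].read_text().splitlines()
        back = read_session(sdir)
        assert len(lines) == 1 + back.raw_codes.shape[1]
        t, *volts = lines[5].split(",")
        np.testing.assert_array_equal(
            np.array([float(v) for v in volts]), back.raw_volts()[:, 5]
        )

    def test_empty_session_exports_headers_only(self, tmp_path):
        cfg = _cfg(n_channels=1)
        store = SessionStore(tmp_path / "s", cfg)
        store.close()
        out = export_text(tmp_path / "s", tmp_path / "txt")
        for path in out.values():
            assert len(path.read_text().splitlines()) == 1


class TestChannelLayout:
    def test_standard_mea_grid(self, tmp_path):
        rows = []
        ch = 0
        for r in range(8):
            toks = []
            for c in range(8):
                if (r, c) in ((0, 0), (0, 7), (7, 0), (7, 7)):
                    toks.append(".")
                else:
                    toks.append(str(ch))
                    ch += 1
            rows.append(" ".join(toks))
        path = tmp_path / "layout.txt"
        path.write_text("\n".join(rows) + "\n")
        layout = read_layout(path)
        assert len(layout) == 60
        assert layout.positions[0] == (0, 1)

    def test_single_row(self, tmp_path):
        path = tmp_path / "l.txt"
        path.write_text("1 2 3\n")
        assert len(read_layout(path)) == 3

    def test_duplicate_channel_rejected(self, tmp_path):
        path = tmp_path / "l.txt"
        path.write_text("1 2\n3 1\n")
        with pytest.raises(LayoutError, match="twice"):
            read_layout(path)

    def test_bad_token_rejected(self, tmp_path):
        path = tmp_path / "l.txt"
        path.write_text("1 x 3\n")
        with pytest.raises(LayoutError):
            read_layout(path)
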