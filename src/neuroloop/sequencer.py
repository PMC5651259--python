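"""Timed experiment sequences.

A sequence file is plain text, one action per line:

    # kind   duration_s   argument...
    load_plugin 0 motif 37,26,25,34,41;10;1;5;1
    start_logging 0
    run 120
    marker 0 drug added
    stop 0

Fields are whitespace separated; everything after the second field is the
free-text argument.  Lines starting with ``#`` and blank lines are ignored.
A sequence holds at most 200 actions.  Every action performs its effect and
then advances the virtual clock by its duration (a ``run`` action is a pure
advance), so the sum of durations equals the span of the execution log.

Unknown plugin names are logged and skipped — a typo must not abort an
experiment; an explicit ``stop`` or source exhaustion ends the sequence
early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

from .core import PluginLoadError, SequenceError, ms_to_samples
from .engine import Session
from .plugins import PLUGIN_REGISTRY, make_plugin

__all__ = [
    "ACTION_KINDS",
    "MAX_ACTIONS",
    "ExperimentAction",
    "ExperimentSequence",
    "LogEntry",
    "parse_sequence",
    "run_sequence",
]

MAX_ACTIONS = 200

ACTION_KINDS = (
    "run",
    "marker",
    "load_plugin",
    "unload_plugin",
    "start_logging",
    "stop_logging",
    "set_threshold",
    "stop",
)


@dataclass(frozen=True)
class ExperimentAction:
    kind: str
    duration_s: float
    arg: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ACTION_KINDS:
            raise SequenceError(f"unknown action kind {self.kind!r}")
        if self.duration_s < 0:
            raise SequenceError("action duration must be >= 0")


@dataclass
class ExperimentSequence:
    actions: List[ExperimentAction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.actions) > MAX_ACTIONS:
            raise SequenceError(
                f"sequence holds {len(self.actions)} actions; limit is {MAX_ACTIONS}"
            )

    def __len__(self) -> int:
        return len(self.actions)


def parse_sequence(source: Union[str, Path]) -> ExperimentSequence:
    """Parse a sequence file (path or literal text) into validated actions."""
    path = Path(source) if not isinstance(source, str) or "\n" not in source else None
    text = path.read_text() if path is not None else str(source)
    actions: List[ExperimentAction] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 2)
        kind = parts[0]
        if kind not in ACTION_KINDS:
            raise SequenceError(f"line {ln}: unknown action kind {kind!r}")
        try:
            duration = float(parts[1]) if len(parts) > 1 else 0.0
        except ValueError:
            raise SequenceError(f"line {ln}: bad duration {parts[1]!r}") from None
        arg = parts[2] if len(parts) > 2 else ""
        try:
            actions.append(ExperimentAction(kind, duration, arg))
        except SequenceError as exc:
            raise SequenceError(f"line {ln}: {exc}") from None
        if len(actions) > MAX_ACTIONS:
            raise SequenceError(
                f"line {ln}: sequence exceeds {MAX_ACTIONS} actions"
            )
    return ExperimentSequence(actions)


@dataclass
class LogEntry:
    index: int
    kind: str
    start_sample: int
    end_sample: int
    status: str  # "ok" | "skipped" | "stopped" | "exhausted"
    message: str = ""


def _advance(session: Session, duration_s: float) -> bool:
    """Step the engine for ``duration_s`` of virtual time; False if the
    source ran out first."""
    rate = session.cfg.sampling_rate_hz
    n_blocks = ms_to_samples(duration_s * 1000.0, rate) // session.cfg.block_samples
    return session.step_blocks(n_blocks) == n_blocks


def run_sequence(seq: ExperimentSequence, session: Session) -> List[LogEntry]:
    """Execute actions in order against a session; returns the execution log.

    The session is finalized when the sequence completes (or terminates
    early on ``stop`` or source exhaustion).
    """
    log: List[LogEntry] = []
    stopped = False
    for i, act in enumerate(seq.actions):
        start = session.now
        status, msg = "ok", ""
        if act.kind == "run":
            pass  # pure advance below
        elif act.kind == "marker":
            session.post_text(act.arg, source="sequence")
        elif act.kind == "load_plugin":
            name, _, parg = act.arg.partition(" ")
            if name not in PLUGIN_REGISTRY:
                status, msg = "skipped", f"unknown plugin {name!r}"
                session.post_text(f"sequence: {msg}")
            else:
                try:
                    session.load_plugin(make_plugin(name), parg)
                except PluginLoadError as exc:
                    status, msg = "skipped", f"plugin {name!r} failed to load: {exc}"
                    session.post_text(f"sequence: {msg}")
        elif act.kind == "unload_plugin":
            if not session.unload_plugin(act.arg.strip()):
                status, msg = "skipped", f"plugin {act.arg.strip()!r} not loaded"
                session.post_text(f"sequence: {msg}")
        elif act.kind == "start_logging":
            if session.store is None:
                status, msg = "skipped", "no session store attached"
                session.post_text(f"sequence: {msg}")
            else:
                session.logging_enabled = True
        elif act.kind == "stop_logging":
            session.flush_log()
            session.logging_enabled = False
        elif act.kind == "set_threshold":
            try:
                ch_s, v_s = act.arg.split()
                session.set_threshold(int(ch_s), float(v_s))
            except (ValueError, IndexError) as exc:
                status, msg = "skipped", f"bad set_threshold argument: {exc}"
                session.post_text(f"sequence: {msg}")
        elif act.kind == "stop":
            stopped = True

        completed = True
        if not stopped and act.duration_s > 0:
            completed = _advance(session, act.duration_s)
        if stopped:
            status = "stopped"
        elif not completed:
            status, msg = "exhausted", "data source exhausted"
        log.append(LogEntry(i, act.kind, start, session.now, status, msg))
        if stopped or not completed:
            break
    session.finalize()
    return log
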