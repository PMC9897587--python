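"""Construction of the five rhythmic-task stimulus patterns.

All tasks are built on a quadruple-metered 8-beat cycle: metrically "strong"
beats fall on cycle positions 1 and 5, the remaining integer positions are
"weak", and events midway between two pulses are "half"-beat events.  The
isochronous tasks use a 500 ms inter-stimulus onset interval (IOI, 120 BPM)
by default.  A pattern is an explicit, ordered grid of labeled events: each
grid position exists even when no sound is played there (unmarked positions
are what taps are matched against in the sparse-metronome task).

Tasks
-----
ISO_SYNC_1_1   synchronization with a full isochronous pattern: a click on
               every beat plus a short beep on beats 1-7 of each cycle.
ISO_REPRO      reproduction from memory: same pattern during the two
               passive-listening cycles, then a silent grid while tapping.
ISO_SYNC_1_4   synchronization where only the strong beats (1 and 5) are
               marked during tapping; listen cycles play the full pattern.
NONISO_SYNC    synchronization with a non-isochronous 7-note pattern per
               cycle (5 on-beat notes, 2 half-beat notes) over full clicks.
REACT          reaction task: aperiodic beeps with IOIs drawn uniformly
               from [200, 800] ms over one minute; no listen phase.

Times are in milliseconds, zero at the first click of the first listen cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "Task",
    "Strength",
    "StimulusEvent",
    "StimulusPattern",
    "DEFAULT_IOI_MS",
    "DEFAULT_NONISO_POSITIONS",
    "make_iso_sync_pattern",
    "make_iso_repro_pattern",
    "make_one_in_four_pattern",
    "make_noniso_pattern",
    "make_react_sequence",
    "pattern_to_frame",
    "pattern_from_frame",
    "write_pattern_csv",
    "read_pattern_csv",
    "render_stimulus_audio",
]

DEFAULT_IOI_MS = 500.0
BEATS_PER_CYCLE = 8
#: Default 7-note non-isochronous cycle: 5 on-beat + 2 half-beat positions.
#: The exact positions are a documented, overridable package default.
DEFAULT_NONISO_POSITIONS = (1.0, 2.0, 3.5, 4.0, 5.0, 6.5, 7.0)


class Task(str, Enum):
    ISO_SYNC_1_1 = "ISO_SYNC_1_1"
    ISO_REPRO = "ISO_REPRO"
    ISO_SYNC_1_4 = "ISO_SYNC_1_4"
    NONISO_SYNC = "NONISO_SYNC"
    REACT = "REACT"


class Strength(str, Enum):
    STRONG = "strong"
    WEAK = "weak"
    HALF = "half"


def _strength_for(beat_position: float) -> Strength:
    if beat_position != int(beat_position):
        return Strength.HALF
    return Strength.STRONG if int(beat_position) in (1, 5) else Strength.WEAK


@dataclass(frozen=True)
class StimulusEvent:
    """One labeled grid position of a stimulus pattern."""

    time_ms: float
    cycle_index: int  # 1-based 8-beat-cycle counter
    beat_position: float  # 1..8, half-beats at k + 0.5
    strength: Strength
    has_click: bool
    has_beep: bool
    listen_phase: bool = False

    def __post_init__(self) -> None:
        if self.strength != _strength_for(self.beat_position):
            raise InvalidArgumentError(
                f"strength {self.strength} inconsistent with beat position "
                f"{self.beat_position}"
            )


@dataclass
class StimulusPattern:
    """Ordered event grid for one task trial."""

    task: Task
    ioi_ms: float | None
    events: list[StimulusEvent] = field(default_factory=list)
    n_listen_cycles: int = 0
    n_tap_cycles: int = 0

    def __post_init__(self) -> None:
        times = [e.time_ms for e in self.events]
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise InvalidArgumentError("event times must be strictly increasing")

    @property
    def tempo_bpm(self) -> float | None:
        """Tempo implied by the IOI (60000 / IOI); None for REACT."""
        return None if self.ioi_ms is None else 60000.0 / self.ioi_ms

    @property
    def listen_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.listen_phase]

    @property
    def tap_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if not e.listen_phase]

    @property
    def tap_phase_start_ms(self) -> float:
        """Onset of the first grid position of the first tapping cycle."""
        tap = self.tap_events
        if not tap:
            raise InvalidArgumentError("pattern has no tapping phase")
        return min(e.time_ms for e in tap)

    def click_times(self, include_listen: bool = True) -> np.ndarray:
        return np.array(
            [e.time_ms for e in self.events
             if e.has_click and (include_listen or not e.listen_phase)]
        )

    def beep_times(self, include_listen: bool = True) -> np.ndarray:
        return np.array(
            [e.time_ms for e in self.events
             if e.has_beep and (include_listen or not e.listen_phase)]
        )

    def reference_events(self) -> list[StimulusEvent]:
        """Tapping-phase events a tap can be matched against.

        For the isochronous tasks every integer grid position is a valid
        reference (in the sparse 1:4 task the unmarked weak positions are
        "internalized" beats).  For the non-isochronous task the references
        are the 7 beeped note positions, so half-beat taps get half-beat
        references.  REACT has no reference grid.
        """
        if self.task is Task.REACT:
            raise InvalidArgumentError("REACT pattern has no reference grid")
        tap = self.tap_events
        if self.task is Task.NONISO_SYNC:
            return [e for e in tap if e.has_beep]
        return [e for e in tap if e.beat_position == int(e.beat_position)]


def _check_grid_args(ioi_ms: float, n_tap_cycles: int, n_listen_cycles: int) -> None:
    if ioi_ms <= 0:
        raise InvalidArgumentError(f"ioi_ms must be positive, got {ioi_ms}")
    if n_tap_cycles < 1:
        raise InvalidArgumentError(f"n_tap_cycles must be >= 1, got {n_tap_cycles}")
    if n_listen_cycles < 0:
        raise InvalidArgumentError(
            f"n_listen_cycles must be >= 0, got {n_listen_cycles}"
        )


def _iso_cycle(
    cycle: int, ioi_ms: float, listen: bool, marked_positions: Iterable[float] | None,
    beep_positions: Iterable[float],
) -> list[StimulusEvent]:
    """Build one 8-beat cycle of integer grid positions.

    marked_positions: positions that carry a click (None = all 8).
    beep_positions: positions that carry a beep.
    """
    marked = set(range(1, 9)) if marked_positions is None else set(marked_positions)
    beeps = set(beep_positions)
    t0 = (cycle - 1) * BEATS_PER_CYCLE * ioi_ms
    return [
        StimulusEvent(
            time_ms=t0 + (b - 1) * ioi_ms,
            cycle_index=cycle,
            beat_position=float(b),
            strength=_strength_for(b),
            has_click=b in marked,
            has_beep=b in beeps,
            listen_phase=listen,
        )
        for b in range(1, 9)
    ]


def _full_listen_cycles(n_listen_cycles: int, ioi_ms: float) -> list[StimulusEvent]:
    """Listen cycles always present the full 1:1 pattern (click on every beat,
    beep on beats 1-7)."""
    ev: list[StimulusEvent] = []
    for c in range(1, n_listen_cycles + 1):
        ev.extend(_iso_cycle(c, ioi_ms, True, None, range(1, 8)))
    return ev


def make_iso_sync_pattern(
    ioi_ms: float = DEFAULT_IOI_MS,
    n_tap_cycles: int = 3,
    n_listen_cycles: int = 2,
) -> StimulusPattern:
    """Full isochronous synchronization pattern (1:1).

    A click marks every beat; a beep additionally marks beats 1-7 of each
    cycle (the 8th beat carries no beep, which keeps the cycle boundary
    audible).  Listen cycles precede tapping cycles.
    """
    _check_grid_args(ioi_ms, n_tap_cycles, n_listen_cycles)
    ev = _full_listen_cycles(n_listen_cycles, ioi_ms)
    for c in range(n_listen_cycles + 1, n_listen_cycles + n_tap_cycles + 1):
        ev.extend(_iso_cycle(c, ioi_ms, False, None, range(1, 8)))
    return StimulusPattern(Task.ISO_SYNC_1_1, ioi_ms, ev, n_listen_cycles, n_tap_cycles)


def make_iso_repro_pattern(
    ioi_ms: float = DEFAULT_IOI_MS,
    n_tap_cycles: int = 3,
    n_listen_cycles: int = 2,
) -> StimulusPattern:
    """Reproduction-from-memory pattern: full 1:1 listen cycles, then a
    silent grid (no clicks, no beeps) while the participant taps the
    internalized pulse."""
    _check_grid_args(ioi_ms, n_tap_cycles, n_listen_cycles)
    ev = _full_listen_cycles(n_listen_cycles, ioi_ms)
    for c in range(n_listen_cycles + 1, n_listen_cycles + n_tap_cycles + 1):
        ev.extend(_iso_cycle(c, ioi_ms, False, (), ()))
    return StimulusPattern(Task.ISO_REPRO, ioi_ms, ev, n_listen_cycles, n_tap_cycles)


def make_one_in_four_pattern(
    ioi_ms: float = DEFAULT_IOI_MS,
    n_tap_cycles: int = 3,
    n_listen_cycles: int = 2,
) -> StimulusPattern:
    """Sparse synchronization pattern (1:4): during tapping only the strong
    beats (positions 1 and 5) are marked with click + beep; the weak beats
    remain as unmarked grid positions the participant internalizes.  Listen
    cycles play the full 1:1 pattern first."""
    _check_grid_args(ioi_ms, n_tap_cycles, n_listen_cycles)
    ev = _full_listen_cycles(n_listen_cycles, ioi_ms)
    for c in range(n_listen_cycles + 1, n_listen_cycles + n_tap_cycles + 1):
        ev.extend(_iso_cycle(c, ioi_ms, False, (1, 5), (1, 5)))
    return StimulusPattern(
        Task.ISO_SYNC_1_4, ioi_ms, ev, n_listen_cycles, n_tap_cycles
    )


def make_noniso_pattern(
    ioi_ms: float = DEFAULT_IOI_MS,
    n_tap_cycles: int = 3,
    n_listen_cycles: int = 2,
    note_positions: Sequence[float] = DEFAULT_NONISO_POSITIONS,
) -> StimulusPattern:
    """Non-isochronous synchronization pattern: clicks on all 8 beats, beeps
    on 7 note positions per cycle of which 5 are on-beat and 2 half-beat."""
    _check_grid_args(ioi_ms, n_tap_cycles, n_listen_cycles)
    pos = sorted(float(p) for p in note_positions)
    if len(pos) != 7:
        raise InvalidArgumentError(f"need exactly 7 note positions, got {len(pos)}")
    n_int = sum(p == int(p) for p in pos)
    n_half = sum(p - int(p) == 0.5 for p in pos)
    if n_int != 5 or n_half != 2:
        raise InvalidArgumentError(
            "note positions must be 5 on-beat + 2 half-beat, got "
            f"{n_int} on-beat / {n_half} half-beat"
        )
    if len(set(pos)) != 7 or pos[0] < 1 or pos[-1] >= 8.5:
        raise InvalidArgumentError("note positions must be distinct and in [1, 8.5)")

    ev: list[StimulusEvent] = []
    for c in range(1, n_listen_cycles + n_tap_cycles + 1):
        listen = c <= n_listen_cycles
        t0 = (c - 1) * BEATS_PER_CYCLE * ioi_ms
        grid = sorted(set(range(1, 9)) | set(pos))
        for b in grid:
            ev.append(
                StimulusEvent(
                    time_ms=t0 + (b - 1) * ioi_ms,
                    cycle_index=c,
                    beat_position=float(b),
                    strength=_strength_for(b),
                    has_click=b == int(b),
                    has_beep=b in pos,
                    listen_phase=listen,
                )
            )
    return StimulusPattern(Task.NONISO_SYNC, ioi_ms, ev, n_listen_cycles, n_tap_cycles)


def make_react_sequence(
    duration_ms: float = 60000.0,
    ioi_min_ms: float = 200.0,
    ioi_max_ms: float = 800.0,
    seed: int = 0,
) -> StimulusPattern:
    """Aperiodic reaction-task sequence.

    Beep onsets start at 0 and accumulate inter-onset intervals drawn
    uniformly from [ioi_min_ms, ioi_max_ms] until duration_ms is reached.
    There is no listen phase and no periodic reference grid, so the pattern
    carries no IOI; cycle/beat labels are placeholders (events are treated
    as an unstructured onset list).
    """
    if not 0 < ioi_min_ms < ioi_max_ms:
        raise InvalidArgumentError(
            f"need 0 < ioi_min_ms < ioi_max_ms, got {ioi_min_ms}, {ioi_max_ms}"
        )
    if duration_ms <= ioi_max_ms:
        raise InvalidArgumentError("duration_ms must exceed ioi_max_ms")
    rng = np.random.default_rng(seed)
    times = [0.0]
    while True:
        t = times[-1] + rng.uniform(ioi_min_ms, ioi_max_ms)
        if t > duration_ms:
            break
        times.append(t)
    ev = [
        StimulusEvent(
            time_ms=t,
            cycle_index=1,
            beat_position=float(i + 1),
            strength=_strength_for(i + 1),
            has_click=False,
            has_beep=True,
            listen_phase=False,
        )
        for i, t in enumerate(times)
    ]
    return StimulusPattern(Task.REACT, None, ev, 0, 1)


# ---------------------------------------------------------------------------
# export / import

_CSV_COLUMNS = [
    "time_ms", "cycle_index", "beat_position", "strength",
    "has_click", "has_beep", "listen_phase",
]


def pattern_to_frame(pattern: StimulusPattern) -> pd.DataFrame:
    rows = [
        (e.time_ms, e.cycle_index, e.beat_position, e.strength.value,
         e.has_click, e.has_beep, e.listen_phase)
        for e in pattern.events
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def pattern_from_frame(
    frame: pd.DataFrame, task: Task, ioi_ms: float | None,
    n_listen_cycles: int, n_tap_cycles: int,
) -> StimulusPattern:
    events = [
        StimulusEvent(
            time_ms=float(r.time_ms),
            cycle_index=int(r.cycle_index),
            beat_position=float(r.beat_position),
            strength=Strength(r.strength),
            has_click=bool(r.has_click),
            has_beep=bool(r.has_beep),
            listen_phase=bool(r.listen_phase),
        )
        for r in frame.itertuples()
    ]
    return StimulusPattern(task, ioi_ms, events, n_listen_cycles, n_tap_cycles)


def write_pattern_csv(pattern: StimulusPattern, path: str | Path) -> None:
    """Write the event grid plus a '# key=value' header line of metadata."""
    path = Path(path)
    meta = (
        f"# task={pattern.task.value} ioi_ms={pattern.ioi_ms} "
        f"n_listen_cycles={pattern.n_listen_cycles} "
        f"n_tap_cycles={pattern.n_tap_cycles}\n"
    )
    with open(path, "w") as fh:
        fh.write(meta)
        pattern_to_frame(pattern).to_csv(fh, index=False)


def read_pattern_csv(path: str | Path) -> StimulusPattern:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        frame = pd.read_csv(fh)
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    ioi = None if meta["ioi_ms"] == "None" else float(meta["ioi_ms"])
    return pattern_from_frame(
        frame, Task(meta["task"]), ioi,
        int(meta["n_listen_cycles"]), int(meta["n_tap_cycles"]),
    )


# ---------------------------------------------------------------------------
# audio rendering

CLICK_DURATION_MS = 5.0
BEEP_FREQ_HZ = 1100.0
BEEP_DURATION_MS = 20.0


def render_stimulus_audio(
    pattern: StimulusPattern,
    fs_hz: float,
    duration_ms: float | None = None,
    click_amp: float = 1.0,
    beep_amp: float = 0.7,
) -> np.ndarray:
    """Render the pattern's sounds to one mono channel.

    Clicks are short Hann-windowed broadband bursts; beeps are 1100 Hz,
    20 ms tones.  Returned as float samples in [-1, 1].
    """
    if fs_hz <= 0:
        raise InvalidArgumentError("fs_hz must be positive")
    if duration_ms is None:
        last = pattern.events[-1].time_ms if pattern.events else 0.0
        duration_ms = last + 2 * BEEP_DURATION_MS + (pattern.ioi_ms or 500.0)
    n = int(round(duration_ms * fs_hz / 1000.0))
    out = np.zeros(n)

    def add_burst(t_ms: float, dur_ms: float, amp: float, freq: float | None) -> None:
        i0 = int(round(t_ms * fs_hz / 1000.0))
        ns = max(int(round(dur_ms * fs_hz / 1000.0)), 2)
        if i0 >= n:
            return
        tt = np.arange(ns) / fs_hz
        win = np.hanning(ns)
        carrier = np.sin(2 * np.pi * freq * tt) if freq else np.ones(ns)
        seg = amp * win * carrier
        i1 = min(i0 + ns, n)
        out[i0:i1] += seg[: i1 - i0]

    for e in pattern.events:
        if e.has_click:
            add_burst(e.time_ms, CLICK_DURATION_MS, click_amp, None)
        if e.has_beep:
            add_burst(e.time_ms, BEEP_DURATION_MS, beep_amp, BEEP_FREQ_HZ)
    peak = np.abs(out).max()
    if peak > 1.0:
        out /= peak
    return out
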