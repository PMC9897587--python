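"""Per-tap and per-train synchronization descriptors.

Per-tap measures
----------------
Asynchrony    signed tap-minus-reference time (ms), wrapped to the half-open
              interval [-IOI/2, +IOI/2); negative = tap leads the pulse
              (the classic negative mean asynchrony of paced tapping).
Phase Angle   the asynchrony as an angle of the beat cycle:
              PA = asynchrony * 360 / IOI, in [-180, +180) degrees.
Reaction Time tap minus closest *preceding* stimulus (aperiodic task only);
              always non-negative.
Tapping Force normalized peak force amplitude (arbitrary units).

Per-train measures
------------------
PLV           phase-locking value, the length of the mean unit vector of
              the train's phase angles: |sum_k e^{i PA_k}| / N in [0, 1].
              1 means a perfectly consistent tap-stimulus phase.
CV            coefficient of variation of inter-tap intervals, in percent
              (sample SD / mean * 100); inverse index of isochrony.
PE            periodicity error, |mean ITI - target period| in ms.
Drift         OLS slope of ITI against interval index (ms per tap) with its
              two-sided p-value.  A positive slope means the train slows
              down over time, a negative slope that it speeds up.
RT_Var/TF_Var sample SDs of reaction time / tapping force over the window.

Windows: the first 8-beat cycle of tapping ("first_cycle", taps 1-8) is
analyzed separately from the stabilized phase ("stabilized", taps 9-24,
i.e. cycles 2-3).  Which descriptor applies to which task and window
follows the study design matrix in TASK_WINDOW_DESCRIPTORS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sstats

from .errors import (
    InvalidArgumentError,
    ShortTrainWarning,
    UndefinedStatisticError,
    UnsupportedCombinationError,
    UnsupportedTaskError,
)
from .signal import TapEvent
from .stimuli import StimulusPattern, Strength, Task

__all__ = [
    "Window",
    "MatchedTap",
    "TrainSummary",
    "TASK_WINDOW_DESCRIPTORS",
    "match_nearest_pulse",
    "phase_angle",
    "plv",
    "reaction_times",
    "inter_tap_intervals",
    "coefficient_of_variation",
    "periodicity_error",
    "drift_slope",
    "select_window",
    "summarize_train",
]


class Window(str, Enum):
    FIRST_CYCLE = "first_cycle"
    STABILIZED = "stabilized"


@dataclass(frozen=True)
class MatchedTap:
    """A tap joined to its reference stimulus event."""

    tap_index: int  # 1-based position in the train
    tap_time_ms: float
    ref_time_ms: float
    ref_cycle: int  # tapping-phase cycle of the reference (1-based)
    asynchrony_ms: float
    phase_angle_deg: float
    force_au: float
    strength: Strength


def phase_angle(asynchrony_ms: float, ioi_ms: float) -> float:
    """Angular conversion of a tap asynchrony: asynchrony * 360 / IOI."""
    if ioi_ms <= 0:
        raise InvalidArgumentError("ioi_ms must be positive")
    if abs(asynchrony_ms) > ioi_ms / 2:
        raise InvalidArgumentError(
            f"|asynchrony| = {abs(asynchrony_ms)} ms exceeds IOI/2 = {ioi_ms / 2} ms"
        )
    return asynchrony_ms * 360.0 / ioi_ms


def _wrap_asynchrony(delta_ms: float, ioi_ms: float) -> float:
    """Wrap a tap-minus-pulse difference into [-IOI/2, +IOI/2).

    A tap exactly midway between two pulses is treated as leading the later
    pulse: asynchrony -IOI/2, so -180 deg is attainable and +180 excluded.
    """
    half = ioi_ms / 2.0
    wrapped = (delta_ms + half) % ioi_ms - half
    return wrapped if wrapped < half else -half


def match_nearest_pulse(
    taps: list[TapEvent], pattern: StimulusPattern
) -> list[MatchedTap]:
    """Join each tap to the reference event minimizing |tap - reference|.

    Matching is tap-driven: every tap is matched, reference pulses may go
    unmatched (missed beats) or be matched more than once (extra taps).
    The asynchrony is wrapped to [-IOI/2, +IOI/2); metrical strength is
    copied from the matched event.
    """
    if pattern.ioi_ms is None:
        raise UnsupportedTaskError(
            f"{pattern.task.value} has no inter-stimulus interval to match against"
        )
    if not taps:
        return []
    refs = pattern.reference_events()
    ref_times = np.array([e.time_ms for e in refs])
    tap_cycle0 = min(e.cycle_index for e in pattern.tap_events)
    out: list[MatchedTap] = []
    for i, tap in enumerate(sorted(taps, key=lambda t: t.time_ms), start=1):
        deltas = tap.time_ms - ref_times
        j = int(np.argmin(np.abs(deltas)))
        asyn = _wrap_asynchrony(deltas[j], pattern.ioi_ms)
        # midpoint tie: reassign to the later pulse (negative asynchrony)
        if deltas[j] > 0 and asyn < 0 and j + 1 < len(refs):
            j += 1
        ref = refs[j]
        out.append(
            MatchedTap(
                tap_index=i,
                tap_time_ms=tap.time_ms,
                ref_time_ms=ref.time_ms,
                ref_cycle=ref.cycle_index - tap_cycle0 + 1,
                asynchrony_ms=asyn,
                phase_angle_deg=phase_angle(asyn, pattern.ioi_ms),
                force_au=tap.amplitude,
                strength=ref.strength,
            )
        )
    return out


def plv(phase_angles_deg: np.ndarray | list[float]) -> float:
    """Phase-locking value: norm of the mean unit vector of the angles."""
    ang = np.asarray(phase_angles_deg, dtype=float)
    if ang.size == 0:
        raise UndefinedStatisticError("PLV of an empty angle set is undefined")
    rad = np.deg2rad(ang)
    return float(np.abs(np.mean(np.exp(1j * rad))))


def reaction_times(
    taps: list[TapEvent], pattern: StimulusPattern
) -> tuple[np.ndarray, int]:
    """Reaction time of each tap to its closest preceding stimulus.

    Only defined for the aperiodic reaction task.  Taps occurring before
    the first stimulus have no defined RT; they are dropped and counted in
    the second return value.
    """
    if pattern.task is not Task.REACT:
        raise UnsupportedTaskError(
            f"reaction times are defined for REACT only, not {pattern.task.value}"
        )
    stim_times = np.array([e.time_ms for e in pattern.events if e.has_beep])
    rts: list[float] = []
    n_dropped = 0
    for tap in sorted(taps, key=lambda t: t.time_ms):
        preceding = stim_times[stim_times <= tap.time_ms]
        if preceding.size == 0:
            n_dropped += 1
            continue
        rts.append(tap.time_ms - preceding[-1])
    return np.asarray(rts), n_dropped


def inter_tap_intervals(taps: list[TapEvent]) -> np.ndarray:
    """Consecutive tap-to-tap intervals (ms); length N-1."""
    if len(taps) < 2:
        raise UndefinedStatisticError("need at least 2 taps for intervals")
    times = np.array([t.time_ms for t in taps])
    if np.any(np.diff(times) <= 0):
        raise InvalidArgumentError("tap times must be strictly increasing")
    return np.diff(times)


def coefficient_of_variation(itis: np.ndarray | list[float]) -> float:
    """Sample SD of the intervals relative to their mean, in percent."""
    x = np.asarray(itis, dtype=float)
    if x.size < 2:
        raise UndefinedStatisticError("CV needs at least 2 intervals")
    m = x.mean()
    if m <= 0:
        raise UndefinedStatisticError("CV undefined for non-positive mean interval")
    return float(100.0 * x.std(ddof=1) / m)


def periodicity_error(itis: np.ndarray | list[float], target_ms: float) -> float:
    """|mean produced interval - target period|, in ms."""
    x = np.asarray(itis, dtype=float)
    if x.size == 0:
        raise UndefinedStatisticError("periodicity error needs at least 1 interval")
    return float(abs(x.mean() - target_ms))


def drift_slope(itis: np.ndarray | list[float]) -> tuple[float, float]:
    """OLS slope of interval duration against interval index (1-based).

    Returns (slope in ms per tap, two-sided p-value of the t-test on the
    slope).  Positive slope = intervals lengthen = the train decelerates.
    """
    y = np.asarray(itis, dtype=float)
    if y.size < 3:
        raise UndefinedStatisticError("drift regression needs at least 3 intervals")
    x = np.arange(1, y.size + 1, dtype=float)
    res = sstats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), p


def select_window(
    taps: list,
    window: Window | str,
    pattern: StimulusPattern,
) -> list:
    """Restrict a train to the analysis window.

    For paced (synchronization) tasks with matched taps, membership follows
    the matched reference's tapping-phase cycle: first_cycle = cycle 1,
    stabilized = cycles 2-3.  For unpaced trains (reproduction, reaction)
    or plain tap events, membership is ordinal: taps 1-8 vs taps 9-24.
    Short trains emit ShortTrainWarning with the available count and return
    the partial window.
    """
    window = Window(window)
    taps = sorted(taps, key=lambda t: getattr(t, "tap_time_ms", None)
                  if hasattr(t, "tap_time_ms") else t.time_ms)
    paced = pattern.task in (Task.ISO_SYNC_1_1, Task.ISO_SYNC_1_4, Task.NONISO_SYNC)
    use_cycles = paced and taps and isinstance(taps[0], MatchedTap)
    if use_cycles:
        cycles = (1,) if window is Window.FIRST_CYCLE else (2, 3)
        out = [t for t in taps if t.ref_cycle in cycles]
        expected = 8 * len(cycles)
    else:
        lo, hi = (0, 8) if window is Window.FIRST_CYCLE else (8, 24)
        out = taps[lo:hi]
        expected = hi - lo
        if window is Window.STABILIZED and len(taps) <= lo:
            out = []
    if len(out) < expected:
        warnings.warn(
            f"window {window.value} expected {expected} taps, got {len(out)}",
            ShortTrainWarning,
            stacklevel=2,
        )
    return out


@dataclass
class TrainSummary:
    """Per-train descriptor values for one task x window combination.

    Fields not part of the design matrix for the combination stay None.
    """

    task: Task
    window: Window
    n_taps: int
    plv: float | None = None
    plv_by_strength: dict[str, float] = field(default_factory=dict)
    pa_circmean_deg: float | None = None
    pa_circmean_by_strength: dict[str, float] = field(default_factory=dict)
    n_by_strength: dict[str, int] = field(default_factory=dict)
    cv_percent: float | None = None
    pe_ms: float | None = None
    mean_iti_ms: float | None = None
    drift_slope_ms_per_tap: float | None = None
    drift_p: float | None = None
    rt_mean_ms: float | None = None
    rt_sd_ms: float | None = None
    tf_mean_au: float | None = None
    tf_sd_au: float | None = None
    tf_by_strength: dict[str, float] = field(default_factory=dict)


#: Which per-train descriptors the study design defines for each
#: task x window cell.  Combinations absent here are not analyzed.
TASK_WINDOW_DESCRIPTORS: dict[tuple[Task, Window], frozenset[str]] = {
    (Task.ISO_SYNC_1_1, Window.FIRST_CYCLE): frozenset({"pa", "plv"}),
    (Task.ISO_SYNC_1_1, Window.STABILIZED): frozenset(
        {"pa", "plv", "pa_strength", "plv_strength", "cv", "tf", "tf_strength",
         "tf_var"}
    ),
    (Task.ISO_SYNC_1_4, Window.STABILIZED): frozenset(
        {"pa_strength", "plv_strength", "tf_strength"}
    ),
    (Task.NONISO_SYNC, Window.STABILIZED): frozenset(
        {"pa_strength", "plv_strength", "tf", "tf_strength", "tf_var"}
    ),
    (Task.ISO_REPRO, Window.FIRST_CYCLE): frozenset({"cv", "pe", "drift"}),
    (Task.ISO_REPRO, Window.STABILIZED): frozenset(
        {"cv", "pe", "drift", "tf", "tf_var"}
    ),
    (Task.REACT, Window.STABILIZED): frozenset({"rt", "rt_var"}),
}


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    z = np.mean(np.exp(1j * rad))
    mean = np.rad2deg(np.angle(z))
    return float(mean if mean < 180.0 else -180.0)


def summarize_train(
    matched: list,
    task: Task,
    window: Window | str,
    pattern: StimulusPattern | None = None,
    target_ms: float = 500.0,
) -> TrainSummary:
    """Compute the per-train descriptors defined for a task x window cell.

    ``matched`` is the full train of one trial: MatchedTap objects for the
    paced tasks, TapEvent objects for reproduction and reaction trains
    (``pattern`` is then required for window selection, and for the RT
    computation in the reaction task).  Drift in the reproduction task is
    evaluated over the whole train (taps 1-24) regardless of window.
    """
    window = Window(window)
    fields = TASK_WINDOW_DESCRIPTORS.get((task, window))
    if fields is None:
        raise UnsupportedCombinationError(
            f"no descriptors defined for {task.value} x {window.value}"
        )
    if pattern is None and (task is Task.REACT or not (
        matched and isinstance(matched[0], MatchedTap)
    )):
        raise InvalidArgumentError(
            "pattern is required for unpaced or reaction trains"
        )

    if pattern is not None:
        win_taps = select_window(matched, window, pattern)
    else:  # paced matched taps: cycle-based selection needs only ref_cycle
        cycles = (1,) if window is Window.FIRST_CYCLE else (2, 3)
        win_taps = [t for t in matched if t.ref_cycle in cycles]

    s = TrainSummary(task=task, window=window, n_taps=len(win_taps))

    def times(ts):
        return [TapEvent(t.tap_time_ms, t.force_au) if isinstance(t, MatchedTap)
                else t for t in ts]

    if "pa" in fields or "pa_strength" in fields or "plv" in fields \
            or "plv_strength" in fields:
        ang = np.array([t.phase_angle_deg for t in win_taps])
        if "plv" in fields and ang.size:
            s.plv = plv(ang)
        if "pa" in fields and ang.size:
            s.pa_circmean_deg = _circular_mean_deg(ang)
        by_str = {}
        for t in win_taps:
            by_str.setdefault(t.strength.value, []).append(t.phase_angle_deg)
        s.n_by_strength = {k: len(v) for k, v in by_str.items()}
        if "plv_strength" in fields:
            s.plv_by_strength = {k: plv(np.array(v)) for k, v in by_str.items()}
        if "pa_strength" in fields:
            s.pa_circmean_by_strength = {
                k: _circular_mean_deg(np.array(v)) for k, v in by_str.items()
            }

    if "cv" in fields or "pe" in fields:
        if len(win_taps) >= 2:
            itis = inter_tap_intervals(times(win_taps))
            s.mean_iti_ms = float(np.mean(itis))
            if "cv" in fields:
                s.cv_percent = coefficient_of_variation(itis)
            if "pe" in fields:
                s.pe_ms = periodicity_error(itis, target_ms)

    if "drift" in fields and len(matched) >= 4:
        itis_all = inter_tap_intervals(times(sorted(
            matched, key=lambda t: t.tap_time_ms
            if isinstance(t, MatchedTap) else t.time_ms)))
        s.drift_slope_ms_per_tap, s.drift_p = drift_slope(itis_all)

    if "rt" in fields or "rt_var" in fields:
        rts, _ = reaction_times(times(win_taps), pattern)
        if rts.size:
            s.rt_mean_ms = float(rts.mean())
        if rts.size >= 2:
            s.rt_sd_ms = float(rts.std(ddof=1))

    if "tf" in fields or "tf_var" in fields or "tf_strength" in fields:
        forces = np.array([
            t.force_au if isinstance(t, MatchedTap) else t.amplitude
            for t in win_taps
        ])
        if ("tf" in fields or "tf_var" in fields) and forces.size:
            s.tf_mean_au = float(forces.mean())
            if "tf_var" in fields and forces.size >= 2:
                s.tf_sd_au = float(forces.std(ddof=1))
        if "tf_strength" in fields:
            by_str_f: dict[str, list[float]] = {}
            for t in win_taps:
                if isinstance(t, MatchedTap):
                    by_str_f.setdefault(t.strength.value, []).append(t.force_au)
            s.tf_by_strength = {
                k: float(np.mean(v)) for k, v in by_str_f.items()
            }

    return s
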