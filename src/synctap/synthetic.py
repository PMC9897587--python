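"""Virtual-participant tapping simulator.

Generates event-level taps and rendered force recordings with the
statistical structure the analysis pipeline assumes, so every stage can be
validated end-to-end without human data.

Generative models
-----------------
Paced tapping (synchronization tasks): each reference event elicits a tap
whose asynchrony is drawn from a wrapped normal in ms,
``N(pa_mean_deg * IOI/360, (pa_sd_deg * IOI/360)^2)`` wrapped into
[-IOI/2, +IOI/2).  A negative mean phase angle reproduces the negative
mean asynchrony (anticipation) typical of paced tapping.  Lapses: a tap is
omitted with probability ``p_miss``; an extra tap is inserted between two
references with probability ``p_extra``.

Unpaced tapping (reproduction): the two-level central-clock / motor model.
The n-th inter-tap interval is

    ITI_n = target + drift * n + C_n + M_{n+1} - M_n,

with clock noise ``C_n ~ N(0, clock_sd^2)`` and motor delays
``M_n ~ N(0, motor_sd^2)``.  The motor terms telescope, which yields the
model's signature negative lag-1 ITI autocovariance of ``-motor_sd^2``
(lag-1 autocorrelation -motor_sd^2 / (clock_sd^2 + 2 motor_sd^2)).

Reaction task: each stimulus elicits a tap after
``RT = max(0, N(rt_mean, rt_sd^2))`` ms; a response that would land after
the next stimulus onset is skipped (the participant misses that beep).

Force model: tap amplitude = base + strength-dependent offset (strong
beats are hit harder, half-beat notes softer) + normal noise, floored at a
small positive value.  Rendered pulses are Hann-windowed bumps, smooth and
band-limited well below the 100 Hz analysis cutoff.

Presets encode the published group-level behavior of adults who stutter
(PWS-like), matched fluent adults (PNS-like), and the pooled sample; see
``PRESETS``.  All randomness flows from a single seed through
``numpy.random.SeedSequence`` spawning, so every output is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, OverlapWarning, UnsupportedTaskError
from .signal import ForceRecording, TapEvent
from .stimuli import StimulusPattern, Strength, Task, render_stimulus_audio

import warnings

__all__ = [
    "ParticipantParams",
    "PRESETS",
    "pooled_preset",
    "pns_like_preset",
    "pws_like_preset",
    "simulate_paced",
    "simulate_unpaced",
    "simulate_react",
    "render_force",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters of one virtual tapper.

    Timing parameters are in ms except the phase-angle pair (degrees of the
    beat cycle); forces are arbitrary units matching the normalized scale.
    """

    pa_mean_deg: float = -29.4  # mean phase angle, paced tasks
    pa_sd_deg: float = 25.0  # within-train phase-angle dispersion
    clock_sd_ms: float = 20.0  # central-timer SD, unpaced tapping
    motor_sd_ms: float = 10.0  # motor-implementation SD, unpaced tapping
    target_iti_ms: float = 500.0  # internalized period
    drift_ms_per_tap: float = 0.0  # deterministic ITI trend
    rt_mean_ms: float = 232.0  # reaction-time mean
    rt_sd_ms: float = 40.0  # reaction-time SD (truncated at 0)
    force_base_au: float = 0.70  # weak-beat force level
    force_strong_delta_au: float = 0.019  # strong-beat increment
    force_half_delta_au: float = -0.073  # half-beat decrement
    force_sd_au: float = 0.05  # tap-to-tap force noise
    p_miss: float = 0.02  # probability a reference elicits no tap
    p_extra: float = 0.01  # probability of an inserted extra tap

    def __post_init__(self) -> None:
        for name in ("pa_sd_deg", "clock_sd_ms", "motor_sd_ms", "rt_sd_ms",
                     "force_sd_au"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        for name in ("p_miss", "p_extra"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        if self.target_iti_ms <= 0:
            raise InvalidArgumentError("target_iti_ms must be positive")


# Group presets.  Pooled mean phase angle -29.4 deg; the group split applies
# the published PWS-minus-PNS difference of -10.8 deg symmetrically around
# the pooled mean (PNS -24.0, PWS -34.8).  Reaction-time mean 232 ms for
# both groups.  PWS unpaced timing SDs are scaled by exp(0.24) so the
# log-CV group difference equals 0.24.  Dispersions not published (pa_sd,
# rt_sd, clock/motor split) are package modeling choices, documented in the
# methods note.
_CV_SCALE = math.exp(0.24)

PRESETS: dict[str, ParticipantParams] = {
    "POOLED": ParticipantParams(),
    "PNS_like": ParticipantParams(
        pa_mean_deg=-24.0, clock_sd_ms=20.0, motor_sd_ms=10.0
    ),
    "PWS_like": ParticipantParams(
        pa_mean_deg=-34.8,
        clock_sd_ms=20.0 * _CV_SCALE,
        motor_sd_ms=10.0 * _CV_SCALE,
    ),
}


def pooled_preset(**overrides) -> ParticipantParams:
    return replace(PRESETS["POOLED"], **overrides)


def pns_like_preset(**overrides) -> ParticipantParams:
    return replace(PRESETS["PNS_like"], **overrides)


def pws_like_preset(**overrides) -> ParticipantParams:
    return replace(PRESETS["PWS_like"], **overrides)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _draw_force(rng: np.random.Generator, params: ParticipantParams,
                strength: Strength) -> float:
    delta = {
        Strength.STRONG: params.force_strong_delta_au,
        Strength.WEAK: 0.0,
        Strength.HALF: params.force_half_delta_au,
    }[strength]
    f = params.force_base_au + delta + rng.normal(0.0, params.force_sd_au)
    return max(f, 0.05)


def simulate_paced(
    pattern: StimulusPattern,
    params: ParticipantParams,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[TapEvent], pd.DataFrame]:
    """Simulate one synchronization train against a paced pattern.

    Returns the tap events (time + force amplitude) and a ground-truth
    frame recording, per reference event, the drawn asynchrony, force and
    lapse outcome.
    """
    if pattern.task not in (Task.ISO_SYNC_1_1, Task.ISO_SYNC_1_4,
                            Task.NONISO_SYNC):
        raise UnsupportedTaskError(
            f"simulate_paced needs a synchronization pattern, got "
            f"{pattern.task.value}"
        )
    rng = _rng(seed)
    ioi = pattern.ioi_ms
    assert ioi is not None
    asyn_mean = params.pa_mean_deg * ioi / 360.0
    asyn_sd = params.pa_sd_deg * ioi / 360.0
    half = ioi / 2.0

    refs = pattern.reference_events()
    taps: list[TapEvent] = []
    rows = []
    for k, ref in enumerate(refs):
        missed = rng.random() < params.p_miss
        asyn = float(rng.normal(asyn_mean, asyn_sd))
        asyn = (asyn + half) % ioi - half  # wrapped normal on [-IOI/2, IOI/2)
        force = _draw_force(rng, params, ref.strength)
        if not missed:
            taps.append(TapEvent(ref.time_ms + asyn, min(force, 1.0)))
        rows.append(
            dict(ref_time_ms=ref.time_ms, strength=ref.strength.value,
                 asynchrony_ms=asyn, force_au=force, missed=missed,
                 extra=False)
        )
        if rng.random() < params.p_extra and k + 1 < len(refs):
            t_extra = ref.time_ms + asyn + rng.uniform(0.35, 0.65) * ioi
            f_extra = _draw_force(rng, params, Strength.WEAK)
            taps.append(TapEvent(t_extra, min(f_extra, 1.0)))
            rows.append(
                dict(ref_time_ms=ref.time_ms, strength="weak",
                     asynchrony_ms=t_extra - ref.time_ms, force_au=f_extra,
                     missed=False, extra=True)
            )
    taps.sort(key=lambda t: t.time_ms)
    return taps, pd.DataFrame(rows)


def simulate_unpaced(
    params: ParticipantParams,
    n_taps: int = 24,
    seed: int | np.random.SeedSequence = 0,
    t0_ms: float = 0.0,
) -> tuple[list[TapEvent], pd.DataFrame]:
    """Simulate a continuation train with the two-level clock/motor model."""
    if n_taps < 2:
        raise InvalidArgumentError("n_taps must be >= 2")
    rng = _rng(seed)
    clock = rng.normal(0.0, params.clock_sd_ms, size=n_taps - 1)
    motor = rng.normal(0.0, params.motor_sd_ms, size=n_taps)
    n = np.arange(1, n_taps)
    itis = (params.target_iti_ms + params.drift_ms_per_tap * n
            + clock + motor[1:] - motor[:-1])
    times = t0_ms + np.concatenate([[0.0], np.cumsum(itis)])
    taps = []
    rows = []
    for i, t in enumerate(times):
        force = _draw_force(rng, params, Strength.WEAK)
        taps.append(TapEvent(float(t), min(force, 1.0)))
        rows.append(dict(tap_index=i + 1, time_ms=float(t), force_au=force))
    gt = pd.DataFrame(rows)
    gt.attrs["itis_ms"] = itis
    return taps, gt


def simulate_react(
    pattern: StimulusPattern,
    params: ParticipantParams,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[TapEvent], pd.DataFrame]:
    """Simulate reaction-task tapping: one truncated-normal RT per stimulus.

    A response whose tap would land at or after the next stimulus onset is
    skipped, emulating a missed fast-following beep.
    """
    if pattern.task is not Task.REACT:
        raise UnsupportedTaskError("simulate_react needs a REACT pattern")
    rng = _rng(seed)
    stim = np.array([e.time_ms for e in pattern.events if e.has_beep])
    taps = []
    rows = []
    for i, t_stim in enumerate(stim):
        rt = max(0.0, float(rng.normal(params.rt_mean_ms, params.rt_sd_ms)))
        t_tap = t_stim + rt
        next_stim = stim[i + 1] if i + 1 < len(stim) else np.inf
        skipped = t_tap >= next_stim
        force = _draw_force(rng, params, Strength.WEAK)
        if not skipped:
            taps.append(TapEvent(t_tap, min(force, 1.0)))
        rows.append(dict(stim_time_ms=t_stim, rt_ms=rt, force_au=force,
                         skipped=skipped))
    return taps, pd.DataFrame(rows)


def render_force(
    taps: list[TapEvent],
    pattern: StimulusPattern | None,
    fs_hz: float = 2000.0,
    pulse_width_ms: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    duration_ms: float | None = None,
) -> ForceRecording:
    """Render tap events to a sampled force channel (+ stimulus channel).

    Each tap becomes a Hann-windowed bump peaking at the tap instant with
    height equal to its force amplitude.  If a pattern is given, its
    clicks/beeps are rendered on the stimulus channel.
    """
    if fs_hz < 10.0 / (pulse_width_ms / 1000.0) / 1000.0:
        raise InvalidArgumentError("sampling rate too low for the pulse width")
    if fs_hz * pulse_width_ms / 1000.0 < 10:
        raise InvalidArgumentError(
            f"need >= 10 samples per pulse: fs {fs_hz} Hz, width "
            f"{pulse_width_ms} ms"
        )
    if duration_ms is None:
        t_last_tap = max((t.time_ms for t in taps), default=0.0)
        t_last_ev = pattern.events[-1].time_ms if pattern and pattern.events else 0.0
        duration_ms = max(t_last_tap, t_last_ev) + 2 * pulse_width_ms + 500.0
    n = int(round(duration_ms * fs_hz / 1000.0))
    force = np.zeros(n)
    half_w = pulse_width_ms / 2.0

    times = sorted(t.time_ms for t in taps)
    if any(b - a < pulse_width_ms for a, b in zip(times, times[1:])):
        warnings.warn(
            "tap pulses overlap closer than the pulse width; rendering anyway",
            OverlapWarning,
            stacklevel=2,
        )

    ns = int(round(pulse_width_ms * fs_hz / 1000.0))
    ns += 1 - ns % 2  # odd length so the window peaks on one sample
    bump = np.hanning(ns)
    for tap in taps:
        center = int(round(tap.time_ms * fs_hz / 1000.0))
        i0 = center - ns // 2
        j0, j1 = max(i0, 0), min(i0 + ns, n)
        if j1 <= j0:
            continue
        force[j0:j1] += tap.amplitude * bump[j0 - i0: j1 - i0]

    if noise_sd > 0:
        force += _rng(seed).normal(0.0, noise_sd, size=n)

    stim = None
    if pattern is not None:
        stim = render_stimulus_audio(pattern, fs_hz, duration_ms=duration_ms)
    return ForceRecording(fs_hz=fs_hz, force=force, stim=stim, t0_ms=0.0)


def ground_truth_csv(gt: pd.DataFrame, params: ParticipantParams,
                     path) -> None:
    """Write a ground-truth table with the injected parameters as header."""
    with open(path, "w") as fh:
        for k, v in asdict(params).items():
            fh.write(f"# {k}={v}\n")
        gt.to_csv(fh, index=False)
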