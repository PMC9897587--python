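"""Force-signal conditioning and tap-event extraction.

The acquisition chain records two synchronized channels: the strain-gauge
force signal under the tapping finger and the audio stimulus mix.  Tap
instants are recovered from the force channel in three steps that mirror
standard practice for unipolar force pulses:

1. envelope extraction — zero-phase low-pass filtering (Chebyshev type I,
   100 Hz cutoff by default, applied forward-backward so pulse peaks are
   not delayed) of the rectified signal;
2. normalization by the task-wise maximum, so amplitudes are comparable
   within a trial and the detection threshold is a fixed fraction;
3. peak picking with an amplitude threshold (20 % of the maximum) and a
   minimum inter-peak distance (200 ms), with amplitude-priority
   suppression; each surviving peak is then shifted to the earliest
   above-threshold local maximum it suppressed, so that the reported
   instant is the first sharp peak of the strike rather than a later
   rebound.

Force amplitudes are arbitrary units (the sensor is not calibrated in
Newtons); only within- and between-trial comparisons are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "ForceRecording",
    "TapEvent",
    "lowpass_envelope",
    "normalize_force",
    "detect_taps",
    "detect_stimulus_onsets",
    "extract_taps",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_MIN_DISTANCE_MS",
    "DEFAULT_HEIGHT_FRAC",
]

DEFAULT_CUTOFF_HZ = 100.0
DEFAULT_MIN_DISTANCE_MS = 200.0
DEFAULT_HEIGHT_FRAC = 0.2
#: Chebyshev type I design defaults (order, passband ripple in dB).
DEFAULT_FILTER_ORDER = 4
DEFAULT_FILTER_RIPPLE_DB = 0.5


@dataclass
class ForceRecording:
    """Sampled force (+ optional stimulus) channels of one trial.

    t0_ms is the time of the first sample relative to the stimulus-pattern
    origin (the first click of the first listen cycle).
    """

    fs_hz: float
    force: np.ndarray
    stim: np.ndarray | None = None
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.fs_hz <= 0:
            raise InvalidArgumentError("fs_hz must be positive")
        if self.force.size == 0:
            raise InvalidArgumentError("force channel is empty")
        if self.stim is not None:
            self.stim = np.asarray(self.stim, dtype=float)
            if self.stim.shape != self.force.shape:
                raise InvalidArgumentError(
                    "stim channel length must match force channel"
                )

    @property
    def duration_ms(self) -> float:
        return self.force.size / self.fs_hz * 1000.0

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.force.size) / self.fs_hz * 1000.0


@dataclass(frozen=True)
class TapEvent:
    """A detected tap: instant (ms) and normalized peak force in [0, 1]."""

    time_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0 + 1e-9:
            raise InvalidArgumentError(
                f"amplitude must be in [0, 1], got {self.amplitude}"
            )


def _design_lowpass(fs_hz: float, cutoff_hz: float,
                    order: int, ripple_db: float) -> np.ndarray:
    if not 0 < cutoff_hz < fs_hz / 2:
        raise InvalidArgumentError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs_hz / 2} Hz)"
        )
    sos = sps.cheby1(order, ripple_db, cutoff_hz, btype="low",
                     fs=fs_hz, output="sos")
    # even-order Chebyshev I sits at the ripple floor at DC; renormalize to
    # unity DC gain so a constant force level passes through unchanged
    dc = np.prod(np.sum(sos[:, :3], axis=1) / np.sum(sos[:, 3:], axis=1))
    sos[0, :3] /= dc
    return sos


def lowpass_envelope(
    rec: ForceRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    ripple_db: float = DEFAULT_FILTER_RIPPLE_DB,
) -> np.ndarray:
    """Zero-phase low-pass envelope of the rectified force channel.

    Forward-backward filtering (sosfiltfilt) doubles the attenuation and
    cancels the phase response, so pulse peaks keep their sample position.
    Rectification is a no-op on clean unipolar force but guards against
    baseline noise excursions below zero.
    """
    sos = _design_lowpass(rec.fs_hz, cutoff_hz, order, ripple_db)
    x = np.abs(rec.force)
    padlen = min(3 * (2 * len(sos) + 1), x.size - 1)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def normalize_force(signal: np.ndarray) -> np.ndarray:
    """Scale a force trace by its task-wise maximum so the peak is 1."""
    x = np.asarray(signal, dtype=float)
    m = x.max() if x.size else 0.0
    if m <= 0:
        raise DegenerateInputError("cannot normalize: maximum is not positive")
    return x / m


def detect_taps(
    signal: np.ndarray,
    fs_hz: float,
    min_distance_ms: float = DEFAULT_MIN_DISTANCE_MS,
    height_frac: float = DEFAULT_HEIGHT_FRAC,
    t0_ms: float = 0.0,
) -> list[TapEvent]:
    """Pick tap peaks from a normalized envelope.

    Local maxima below ``height_frac`` are ignored; the minimum inter-peak
    distance is enforced greedily by amplitude priority.  Each surviving
    peak is then moved to the earliest above-threshold local maximum inside
    its left suppression half-window (rebound bounces trail the strike, so
    the first sharp peak is the tap instant), provided the move keeps the
    inter-tap spacing guarantee intact.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return []
    if min_distance_ms <= 0:
        raise InvalidArgumentError("min_distance_ms must be positive")
    if not 0 < height_frac < 1:
        raise InvalidArgumentError("height_frac must be in (0, 1)")
    dist = int(round(min_distance_ms * fs_hz / 1000.0))
    if dist < 1:
        raise InvalidArgumentError(
            f"min distance {min_distance_ms} ms is below one sample at {fs_hz} Hz"
        )

    # all candidate maxima above threshold, then amplitude-priority selection
    cand, _ = sps.find_peaks(x, height=height_frac)
    if cand.size == 0:
        return []
    kept, _ = sps.find_peaks(x, height=height_frac, distance=dist)

    final: list[int] = []
    for k in kept:
        # candidates suppressed by k: within dist, nearer to k than to other kept
        lo = k - dist
        window = cand[(cand >= lo) & (cand <= k)]
        others = kept[kept != k]
        if others.size:
            window = window[
                np.abs(window - k) <= np.min(np.abs(window[:, None] - others), axis=1)
            ]
        idx = int(window.min()) if window.size else int(k)
        if final and idx - final[-1] < dist:
            idx = int(k)  # keep the spacing guarantee
        final.append(idx)

    return [
        TapEvent(time_ms=t0_ms + i / fs_hz * 1000.0, amplitude=min(float(x[i]), 1.0))
        for i in final
    ]


def detect_stimulus_onsets(
    stim: np.ndarray,
    fs_hz: float,
    threshold: float = 0.3,
    refractory_ms: float = 100.0,
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Onset times (ms) of stimulus bursts on the recorded stimulus channel.

    Rising crossings of ``threshold`` on the normalized rectified channel,
    debounced by a refractory window so one burst yields one onset.
    """
    x = np.abs(np.asarray(stim, dtype=float))
    if x.size == 0 or x.max() <= 0:
        return np.array([])
    x = x / x.max()
    above = x >= threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.insert(rising, 0, 0)
    refr = int(round(refractory_ms * fs_hz / 1000.0))
    onsets: list[int] = []
    for i in rising:
        if not onsets or i - onsets[-1] >= refr:
            onsets.append(int(i))
    return t0_ms + np.asarray(onsets, dtype=float) / fs_hz * 1000.0


def extract_taps(
    rec: ForceRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    min_distance_ms: float = DEFAULT_MIN_DISTANCE_MS,
    height_frac: float = DEFAULT_HEIGHT_FRAC,
    order: int = DEFAULT_FILTER_ORDER,
    ripple_db: float = DEFAULT_FILTER_RIPPLE_DB,
) -> list[TapEvent]:
    """Full conditioning chain: envelope -> normalize -> peak picking."""
    env = lowpass_envelope(rec, cutoff_hz, order, ripple_db)
    norm = normalize_force(env)
    return detect_taps(norm, rec.fs_hz, min_distance_ms, height_frac, rec.t0_ms)
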