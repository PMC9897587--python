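"""File formats, run configuration and the end-to-end pipeline driver.

Formats
-------
Recordings   two-channel WAV (channel 1 force, channel 2 stimulus; PCM
             16-bit) or CSV with columns time_ms, force[, stim].
Tap instants Praat TextGrid point tier "taps" (times in seconds, long
             format) and tidy CSV (times in ms).
Summaries    tidy CSV: one row per tap and one row per train x window.

Every pipeline artifact embeds the resolved configuration and seed, so a
run is reproducible byte-for-byte from its config file.
"""

from __future__ import annotations

import dataclasses
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import descriptors as desc
from . import synthetic
from .errors import FormatError, InvalidArgumentError
from .signal import ForceRecording, TapEvent, extract_taps
from .stimuli import (
    StimulusPattern,
    Task,
    make_iso_repro_pattern,
    make_iso_sync_pattern,
    make_noniso_pattern,
    make_one_in_four_pattern,
    make_react_sequence,
)

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording_wav",
    "write_recording_csv",
    "write_taps_textgrid",
    "read_taps_textgrid",
    "taps_to_frame",
    "matched_to_frame",
    "summary_to_frame",
    "build_pattern",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# recordings

def write_recording_wav(rec: ForceRecording, path: str | Path) -> None:
    """Write force (+ stimulus) channels as PCM 16-bit WAV.

    Channels are scaled jointly by the overall absolute maximum so relative
    amplitudes survive the round trip.
    """
    stim = rec.stim if rec.stim is not None else np.zeros_like(rec.force)
    data = np.stack([rec.force, stim], axis=1)
    peak = np.abs(data).max()
    scale = 32767.0 / peak if peak > 0 else 1.0
    wavfile.write(str(path), int(rec.fs_hz),
                  np.round(data * scale).astype(np.int16))


def write_recording_csv(rec: ForceRecording, path: str | Path) -> None:
    frame = pd.DataFrame({"time_ms": rec.times_ms(), "force": rec.force})
    if rec.stim is not None:
        frame["stim"] = rec.stim
    frame.to_csv(path, index=False)


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs_hz: float | None = None,
    require_stim: bool = False,
) -> ForceRecording:
    """Read a recording from WAV (2-channel) or CSV.

    format is inferred from the extension when not given ("wav2ch"/"csv").
    For CSV the sampling rate comes from the time column unless fs_hz is
    supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = format or ("wav2ch" if path.suffix.lower() == ".wav" else "csv")
    if fmt == "wav2ch":
        try:
            fs, data = wavfile.read(str(path))
        except Exception as e:  # noqa: BLE001 - map to package error
            raise FormatError(f"{path}: unreadable WAV ({e})") from e
        if data.ndim == 1:
            if require_stim:
                raise FormatError(
                    f"{path}: stimulus channel required but WAV has 1 channel"
                )
            force, stim = data.astype(float), None
        elif data.shape[1] >= 2:
            force = data[:, 0].astype(float)
            stim = data[:, 1].astype(float)
        else:
            raise FormatError(f"{path}: unsupported channel layout {data.shape}")
        return ForceRecording(fs_hz=float(fs), force=force, stim=stim)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except Exception as e:  # noqa: BLE001
            raise FormatError(f"{path}: unreadable CSV ({e})") from e
        if "force" not in frame.columns:
            raise FormatError(f"{path}: CSV needs a 'force' column")
        if fs_hz is None:
            if "time_ms" not in frame.columns or len(frame) < 2:
                raise FormatError(
                    f"{path}: need a time_ms column (or explicit fs_hz)"
                )
            dt = np.diff(frame["time_ms"].to_numpy())
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise FormatError(f"{path}: time_ms is not uniformly sampled")
            fs_hz = 1000.0 / float(dt.mean())
        stim = frame["stim"].to_numpy(float) if "stim" in frame.columns else None
        if require_stim and stim is None:
            raise FormatError(f"{path}: stimulus column required but absent")
        t0 = float(frame["time_ms"].iloc[0]) if "time_ms" in frame.columns else 0.0
        return ForceRecording(fs_hz=fs_hz, force=frame["force"].to_numpy(float),
                              stim=stim, t0_ms=t0)
    raise InvalidArgumentError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Praat TextGrid (long format, point tier)

def write_taps_textgrid(taps: list[TapEvent], path: str | Path,
                        tier_name: str = "taps",
                        xmax_s: float | None = None) -> None:
    """Write tap instants as a Praat TextGrid point tier (times in seconds)."""
    times_s = [t.time_ms / 1000.0 for t in taps]
    if xmax_s is None:
        xmax_s = (max(times_s) + 1.0) if times_s else 1.0
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax_s:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "TextTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax_s:.6f}",
        f"        points: size = {len(times_s)}",
    ]
    for i, (t, tap) in enumerate(zip(times_s, taps), start=1):
        lines += [
            f"        points [{i}]:",
            f"            number = {t:.6f}",
            f'            mark = "{tap.amplitude:.4f}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_taps_textgrid(path: str | Path) -> list[TapEvent]:
    """Read back a point tier written by write_taps_textgrid."""
    text = Path(path).read_text()
    if "TextGrid" not in text:
        raise FormatError(f"{path}: not a TextGrid file")
    numbers = re.findall(r"number = ([0-9.eE+-]+)", text)
    marks = re.findall(r'mark = "([^"]*)"', text)
    taps = []
    for i, num in enumerate(numbers):
        amp = 1.0
        if i < len(marks):
            try:
                amp = float(marks[i])
            except ValueError:
                pass
        taps.append(TapEvent(time_ms=float(num) * 1000.0,
                             amplitude=min(max(amp, 0.0), 1.0)))
    return taps


# ---------------------------------------------------------------------------
# tidy tables

def taps_to_frame(taps: list[TapEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i + 1, t.time_ms, t.amplitude) for i, t in enumerate(taps)],
        columns=["tap_index", "time_ms", "amplitude"],
    )


def matched_to_frame(matched: list[desc.MatchedTap]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.tap_index, m.tap_time_ms, m.ref_time_ms, m.ref_cycle,
             m.asynchrony_ms, m.phase_angle_deg, m.force_au, m.strength.value)
            for m in matched
        ],
        columns=[
            "tap_index", "tap_time_ms", "ref_time_ms", "ref_cycle",
            "asynchrony_ms", "phase_angle_deg", "force_au", "strength",
        ],
    )


def summary_to_frame(summaries: list[desc.TrainSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "task": s.task.value, "window": s.window.value, "n_taps": s.n_taps,
            "plv": s.plv, "pa_circmean_deg": s.pa_circmean_deg,
            "cv_percent": s.cv_percent, "pe_ms": s.pe_ms,
            "mean_iti_ms": s.mean_iti_ms,
            "drift_slope_ms_per_tap": s.drift_slope_ms_per_tap,
            "drift_p": s.drift_p,
            "rt_mean_ms": s.rt_mean_ms, "rt_sd_ms": s.rt_sd_ms,
            "tf_mean_au": s.tf_mean_au, "tf_sd_au": s.tf_sd_au,
        }
        for k, v in s.plv_by_strength.items():
            row[f"plv_{k}"] = v
        for k, v in s.pa_circmean_by_strength.items():
            row[f"pa_{k}"] = v
        for k, v in s.tf_by_strength.items():
            row[f"tf_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration + pipeline

@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    task: str = "ISO_SYNC_1_1"
    ioi_ms: float = 500.0
    n_tap_cycles: int = 3
    n_listen_cycles: int = 2
    fs_hz: float = 2000.0
    cutoff_hz: float = 100.0
    filter_order: int = 4
    filter_ripple_db: float = 0.5
    min_distance_ms: float = 200.0
    height_frac: float = 0.2
    windows: list[str] = field(default_factory=lambda: ["stabilized"])
    seed: int = 0
    preset: str = "POOLED"
    input_path: str | None = None  # read a recording instead of simulating
    output_dir: str | None = None
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def build_pattern(config: RunConfig) -> StimulusPattern:
    task = Task(config.task)
    if task is Task.ISO_SYNC_1_1:
        return make_iso_sync_pattern(config.ioi_ms, config.n_tap_cycles,
                                     config.n_listen_cycles)
    if task is Task.ISO_REPRO:
        return make_iso_repro_pattern(config.ioi_ms, config.n_tap_cycles,
                                      config.n_listen_cycles)
    if task is Task.ISO_SYNC_1_4:
        return make_one_in_four_pattern(config.ioi_ms, config.n_tap_cycles,
                                        config.n_listen_cycles)
    if task is Task.NONISO_SYNC:
        return make_noniso_pattern(config.ioi_ms, config.n_tap_cycles,
                                   config.n_listen_cycles)
    return make_react_sequence(seed=config.seed)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run stimuli -> (simulate | read) -> detect -> match -> summarize.

    Returns the tidy tables; when config.output_dir is set they are also
    written as CSV together with the resolved config, so a fixed seed and
    fixed inputs reproduce the outputs byte-for-byte.
    """
    task = Task(config.task)
    pattern = build_pattern(config)
    params = synthetic.PRESETS[config.preset]

    if config.input_path is not None:
        rec = read_recording(config.input_path, fs_hz=config.fs_hz)
    else:
        if task is Task.REACT:
            taps_true, _ = synthetic.simulate_react(pattern, params, config.seed)
        elif task is Task.ISO_REPRO:
            n = 8 * config.n_tap_cycles
            taps_true, _ = synthetic.simulate_unpaced(
                params, n_taps=n, seed=config.seed,
                t0_ms=pattern.tap_phase_start_ms)
        else:
            taps_true, _ = synthetic.simulate_paced(pattern, params, config.seed)
        rec = synthetic.render_force(taps_true, pattern, fs_hz=config.fs_hz)

    taps = extract_taps(
        rec, cutoff_hz=config.cutoff_hz,
        min_distance_ms=config.min_distance_ms,
        height_frac=config.height_frac, order=config.filter_order,
        ripple_db=config.filter_ripple_db,
    )
    # ignore anything detected during the passive-listening phase
    if task is not Task.REACT:
        t_start = pattern.tap_phase_start_ms - (pattern.ioi_ms or 0) / 2
        taps = [t for t in taps if t.time_ms >= t_start]

    tables: dict[str, pd.DataFrame] = {"taps": taps_to_frame(taps)}

    if task in (Task.ISO_SYNC_1_1, Task.ISO_SYNC_1_4, Task.NONISO_SYNC):
        matched = desc.match_nearest_pulse(taps, pattern)
        tables["matched"] = matched_to_frame(matched)
        train: list = matched
    else:
        train = taps

    summaries = []
    for w in config.windows:
        window = desc.Window(w)
        if (task, window) not in desc.TASK_WINDOW_DESCRIPTORS:
            continue
        summaries.append(
            desc.summarize_train(train, task, window, pattern=pattern,
                                 target_ms=config.ioi_ms)
        )
    tables["summary"] = summary_to_frame(summaries)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())
        for name, frame in tables.items():
            buf = _io.StringIO()
            frame.to_csv(buf, index=False, float_format="%.6f",
                         lineterminator="\n")
            (out / f"{name}.csv").write_text(buf.getvalue())
    return tables
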