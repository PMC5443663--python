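"""Plain-text and WAV import/export for traces, spike trains and configs.

Formats:
  * pressure / vibration traces: 2-column delimited text (time_s, amplitude)
    or 16-bit PCM WAV (sample rate in the header);
  * two-channel tympanal traces: 3-column text (time_s, left, right);
  * spike trains: one event time per line;
  * treadmill traces: 3-column text (sample_index, dx_px, dy_px);
  * directionality tables: 2-column text (azimuth_deg, ivad_db);
  * configs: JSON key-value files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
from scipy.io import wavfile

from .ear import SpikeTrain, TympanalTraces
from .kinematics import TreadmillTrace
from .stimuli import PressureTrace

PathLike = Union[str, Path]


def save_trace_text(trace: PressureTrace, path: PathLike) -> None:
    t = np.arange(len(trace.samples)) / trace.fs_hz
    np.savetxt(path, np.column_stack((t, trace.samples)),
               header="time_s\tamplitude", delimiter="\t", comments="")


def load_trace_text(path: PathLike) -> PressureTrace:
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    t, x = data[:, 0], data[:, 1]
    fs = 1.0 / np.median(np.diff(t))
    return PressureTrace(samples=x, fs_hz=float(round(fs)))


def save_trace_wav(trace: PressureTrace, path: PathLike,
                   full_scale_amplitude: float | None = None) -> None:
    """16-bit PCM WAV; ``full_scale_amplitude`` maps to digital full scale
    (defaults to the trace's own peak)."""
    peak = full_scale_amplitude or float(np.max(np.abs(trace.samples))) or 1.0
    scaled = np.clip(trace.samples / peak, -1.0, 1.0)
    wavfile.write(str(path), int(round(trace.fs_hz)),
                  (scaled * 32767).astype(np.int16))


def load_trace_wav(path: PathLike) -> PressureTrace:
    fs, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return PressureTrace(samples=np.asarray(data, dtype=float), fs_hz=float(fs))


def save_tympanal_text(traces: TympanalTraces, path: PathLike) -> None:
    t = np.arange(len(traces.left)) / traces.fs_hz
    np.savetxt(path, np.column_stack((t, traces.left, traces.right)),
               header="time_s\tleft\tright", delimiter="\t", comments="")


def load_tympanal_text(path: PathLike) -> TympanalTraces:
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    fs = 1.0 / np.median(np.diff(data[:, 0]))
    return TympanalTraces(left=data[:, 1], right=data[:, 2], fs_hz=float(round(fs)))


def save_spike_train(train: SpikeTrain, path: PathLike) -> None:
    np.savetxt(path, train.times_s, header="time_s", comments="")


def load_spike_train(path: PathLike, channel: str = "unspecified") -> SpikeTrain:
    times = np.atleast_1d(np.loadtxt(path, skiprows=1))
    return SpikeTrain(times_s=times, channel=channel)


def save_treadmill_text(trace: TreadmillTrace, path: PathLike) -> None:
    idx = np.arange(len(trace))
    np.savetxt(path, np.column_stack((idx, trace.dx, trace.dy)),
               header="sample_index\tdx_px\tdy_px", delimiter="\t", comments="")


def load_treadmill_text(path: PathLike, fs_hz: float = 2160.0,
                        cal_cm_per_px: float = 0.0028) -> TreadmillTrace:
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    return TreadmillTrace(dx=data[:, 1], dy=data[:, 2], fs_hz=fs_hz,
                          cal_cm_per_px=cal_cm_per_px)


def load_directionality_table(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth-vs-IVAD calibration table: 2 columns (azimuth_deg, ivad_db)."""
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected a 2-column azimuth/IVAD table")
    return data[:, 0], data[:, 1]


def save_config(config: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def load_config(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
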