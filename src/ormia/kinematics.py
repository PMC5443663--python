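"""Treadmill (trackball) phonotaxis kinematics.

An optical sensor under the ball reports per-sample x/y pixel increments at
2160 Hz.  Increments are calibrated to cm, converted to steering (x) and
forward (y) velocity components, integrated into a virtual walking
trajectory, and reduced to the scalar response measures used throughout:
response latency, total distance walked, angular heading (right-positive,
0 deg = toward the frontal speaker), and a validity flag (total translation
> 1 cm counts as a behavioural response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TreadmillTrace",
    "TrialKinematics",
    "velocities",
    "trajectory_and_scalars",
    "mirror_and_average",
    "synthetic_walk",
]

DEFAULT_FS_HZ = 2160.0
DEFAULT_CAL_CM_PER_PX = 0.0028
VALID_DISTANCE_CM = 1.0


@dataclass
class TreadmillTrace:
    """Per-sample pixel increments: dx = lateral (steering), dy = forward."""

    dx: np.ndarray
    dy: np.ndarray
    fs_hz: float = DEFAULT_FS_HZ
    cal_cm_per_px: float = DEFAULT_CAL_CM_PER_PX

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValueError("dx and dy must be equal-length 1-D arrays")
        if self.fs_hz <= 0 or self.cal_cm_per_px <= 0:
            raise ValueError("fs_hz and cal_cm_per_px must be positive")

    def __len__(self) -> int:
        return len(self.dx)


@dataclass
class TrialKinematics:
    forward_v: np.ndarray  # cm/s
    steering_v: np.ndarray  # cm/s
    path_xy: np.ndarray  # (n, 2) cumulative trajectory, cm
    latency_ms: Optional[float]
    total_distance_cm: float
    angular_heading_deg: Optional[float]
    valid: bool
    heading_mode: str = "mid"
    smooth_window_s: Optional[float] = None


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrink-to-valid edges."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(len(x))
    half_lo = (window - 1) // 2
    half_hi = window // 2
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, len(x))
    return (c[hi] - c[lo]) / (hi - lo)


def velocities(trace: TreadmillTrace,
               smooth_window_s: Optional[float] = 0.050) -> tuple[np.ndarray, np.ndarray]:
    """Forward and steering velocity (cm/s) from pixel increments.

    v[i] = increment * calibration * fs; forward from y, steering from x
    (positive = rightward).  A centred moving average (default 50 ms) smooths
    both components; pass None to disable.
    """
    scale = trace.cal_cm_per_px * trace.fs_hz
    fwd = trace.dy * scale
    steer = trace.dx * scale
    if smooth_window_s is not None and len(fwd) > 1:
        win = max(1, int(round(smooth_window_s * trace.fs_hz)))
        if win > 1:
            fwd = _moving_average(fwd, win)
            steer = _moving_average(steer, win)
    return fwd, steer


def _detect_latency(forward_v: np.ndarray, fs_hz: float, onset_idx: int,
                    sustain_s: float = 0.020,
                    sd_factor: float = 3.0,
                    min_floor_cm_s: float = 0.05) -> Optional[int]:
    """Response onset: first post-stimulus sample where forward velocity
    exceeds ``sd_factor`` times its pre-stimulus SD for at least ``sustain_s``.

    The SD criterion gets an absolute floor so a perfectly quiescent baseline
    (SD = 0, as in synthetic traces) does not trigger on numerical dust.
    """
    pre = forward_v[:onset_idx]
    sd = float(np.std(pre)) if pre.size else 0.0
    thresh = max(sd_factor * sd, min_floor_cm_s)
    n_sustain = max(1, int(round(sustain_s * fs_hz)))
    above = forward_v[onset_idx:] > thresh
    if not np.any(above):
        return None
    # first run of >= n_sustain consecutive suprathreshold samples
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_sustain:
            return onset_idx + i - n_sustain + 1
    return None


def trajectory_and_scalars(trace: TreadmillTrace,
                           signal_onset_s: float,
                           signal_offset_s: Optional[float] = None,
                           heading_mode: str = "mid",
                           smooth_window_s: Optional[float] = 0.050) -> TrialKinematics:
    """Integrate a treadmill trace into a trajectory and the scalar measures.

    path = cumulative sum of calibrated increments; total distance = sum of
    per-sample step lengths; latency = time from signal onset to detected
    response onset; angular heading = atan2(net_x, net_y) of the displacement
    accumulated from response onset to either the temporal midpoint between
    response onset and signal offset (``heading_mode="mid"``, the
    mid-response angular heading) or the end of the trial ("whole").
    """
    if heading_mode not in ("mid", "whole"):
        raise ValueError("heading_mode must be 'mid' or 'whole'")
    steps = np.column_stack((trace.dx, trace.dy)) * trace.cal_cm_per_px
    path = np.cumsum(steps, axis=0)
    total_dist = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    fwd, steer = velocities(trace, smooth_window_s)
    # latency detection runs on the raw (unsmoothed) velocity: a centred
    # smoothing window would pull the detected onset earlier by half a window
    fwd_raw, _ = velocities(trace, None)
    onset_idx = int(round(signal_onset_s * trace.fs_hz))
    resp_idx = _detect_latency(fwd_raw, trace.fs_hz, onset_idx)
    valid = total_dist > VALID_DISTANCE_CM
    latency_ms: Optional[float] = None
    heading: Optional[float] = None
    if resp_idx is not None:
        latency_ms = (resp_idx - onset_idx) / trace.fs_hz * 1000.0
        if heading_mode == "mid":
            if signal_offset_s is None:
                raise ValueError("heading_mode='mid' requires signal_offset_s")
            off_idx = min(int(round(signal_offset_s * trace.fs_hz)), len(trace))
            end_idx = resp_idx + (off_idx - resp_idx) // 2
        else:
            end_idx = len(trace)
        end_idx = max(end_idx, resp_idx + 1)
        start_xy = path[resp_idx - 1] if resp_idx > 0 else np.zeros(2)
        net = path[min(end_idx, len(path)) - 1] - start_xy
        if np.hypot(*net) > 0:
            heading = math.degrees(math.atan2(net[0], net[1]))
    if not valid:
        heading = None
    return TrialKinematics(
        forward_v=fwd, steering_v=steer, path_xy=path,
        latency_ms=latency_ms, total_distance_cm=total_dist,
        angular_heading_deg=heading, valid=valid,
        heading_mode=heading_mode, smooth_window_s=smooth_window_s)


def mirror_and_average(headings_deg: Sequence[float],
                       masker_sides: Sequence[str],
                       subject_ids: Optional[Sequence] = None) -> dict:
    """Pool trials across mirror-image speaker layouts.

    Left-masker trials are mirrored about the 0 deg midline (heading sign
    negated) before pooling, so all trials share a right-masker frame.  When
    ``subject_ids`` are given, per-subject means are computed first and the
    cross-subject mean +/- SEM is reported; otherwise trials pool directly.
    """
    if len(headings_deg) != len(masker_sides):
        raise ValueError("need one masker side label per trial")
    mirrored = []
    for h, side in zip(headings_deg, masker_sides):
        if side == "right":
            mirrored.append(float(h))
        elif side == "left":
            mirrored.append(-float(h))
        else:
            raise ValueError(f"masker side must be 'left' or 'right', got {side!r}")
    mirrored_arr = np.array(mirrored)
    if subject_ids is not None:
        if len(subject_ids) != len(mirrored_arr):
            raise ValueError("need one subject id per trial")
        ids = np.asarray(subject_ids)
        per_subject = np.array([np.mean(mirrored_arr[ids == s])
                                for s in np.unique(ids)])
    else:
        per_subject = mirrored_arr
    mean = float(np.mean(per_subject))
    sem = float(np.std(per_subject, ddof=1) / np.sqrt(len(per_subject))) \
        if len(per_subject) > 1 else 0.0
    return {"mean_deg": mean, "sem_deg": sem,
            "per_subject_deg": per_subject, "mirrored_deg": mirrored_arr}


def synthetic_walk(heading_deg: float,
                   speed_cm_s: float = 6.0,
                   latency_s: float = 0.056,
                   signal_onset_s: float = 1.5,
                   duration_s: float = 5.0,
                   fs_hz: float = DEFAULT_FS_HZ,
                   cal_cm_per_px: float = DEFAULT_CAL_CM_PER_PX,
                   speed_jitter_cm_s: float = 0.0,
                   seed: Optional[int] = None) -> TreadmillTrace:
    """Synthetic responder: quiescent until ``signal_onset + latency``, then a
    straight walk at ``speed_cm_s`` along ``heading_deg`` until the end.

    Used to exercise the analysis chain with known ground truth; optional
    Gaussian jitter on the per-sample speed emulates gait noise.
    """
    n = int(round(duration_s * fs_hz))
    dx = np.zeros(n)
    dy = np.zeros(n)
    start = int(round((signal_onset_s + latency_s) * fs_hz))
    if start < n:
        step_cm = speed_cm_s / fs_hz
        m = n - start
        speeds = np.full(m, step_cm)
        if speed_jitter_cm_s > 0:
            rng = np.random.default_rng(seed)
            speeds = speeds + rng.normal(0.0, speed_jitter_cm_s / fs_hz, m)
            speeds = np.clip(speeds, 0.0, None)
        h = math.radians(heading_deg)
        dx[start:] = speeds * math.sin(h) / cal_cm_per_px
        dy[start:] = speeds * math.cos(h) / cal_cm_per_px
    return TreadmillTrace(dx=dx, dy=dy, fs_hz=fs_hz, cal_cm_per_px=cal_cm_per_px)
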