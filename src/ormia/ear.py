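"""Generative model of the mechanically coupled ears and auditory afferents.

The fly's paired tympana act as a single mechanically coupled directional
receiver: the interaural vibration amplitude difference (IVAD) grows as an
antisymmetric, saturating sigmoid of source azimuth.  This module renders
per-ear vibration traces for a multi-source scene by applying a
direction-dependent gain per source and ear, adds a measurement-noise floor,
and converts traces into onset-phasic afferent spike trains (one — or a few —
spikes at each suprathreshold envelope onset, followed by a ~4 ms refractory
dead time).  An asymmetrically placed masker raises the noise floor more in
the masker-ipsilateral ear; the resulting interaural difference in *effective*
signal amplitude mimics the binaural cue of a laterally displaced source and
is what drives the simulated heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stimuli import PressureTrace, SceneSpec, assemble_scene, db_to_amplitude

__all__ = [
    "DirectionalityCurve",
    "EarGainModel",
    "TympanalTraces",
    "AfferentSpec",
    "SpikeTrain",
    "render_tympanal",
    "render_scene",
    "spikes_from_trace",
    "simulate_heading",
]


@dataclass(frozen=True)
class DirectionalityCurve:
    """Antisymmetric sigmoid IVAD(theta) = max_ivad_db * (2/(1+exp(-theta/slope)) - 1).

    Equivalently max_ivad_db * tanh(theta / (2 * slope_deg)).  IVAD(0) = 0,
    IVAD(-theta) = -IVAD(theta), monotone increasing, |IVAD| < max_ivad_db.
    """

    max_ivad_db: float = 10.0
    slope_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.max_ivad_db <= 0 or self.slope_deg <= 0:
            raise ValueError("max_ivad_db and slope_deg must be positive")

    def ivad_db(self, azimuth_deg) -> np.ndarray | float:
        theta = np.asarray(azimuth_deg, dtype=float)
        out = self.max_ivad_db * (2.0 / (1.0 + np.exp(-theta / self.slope_deg)) - 1.0)
        return float(out) if out.ndim == 0 else out

    def inverse_deg(self, ivad_db) -> np.ndarray | float:
        """Azimuth producing a given IVAD; clamps to the open saturation range."""
        r = np.asarray(ivad_db, dtype=float) / self.max_ivad_db
        r = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
        out = 2.0 * self.slope_deg * np.arctanh(r)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EarGainModel:
    """Per-ear gains from the directionality curve, split symmetrically.

    Right-ear gain +IVAD(theta)/2 dB, left-ear gain -IVAD(theta)/2 dB, so the
    interaural difference equals IVAD(theta) exactly; only the difference is
    constrained by tympanal physiology, and only differences enter any
    analysis.  ``meas_noise_db`` is the level (dB re the digital reference) of
    the additive Gaussian measurement-noise floor per ear; None disables it.
    """

    curve: DirectionalityCurve = DirectionalityCurve()
    meas_noise_db: Optional[float] = 36.0

    def gain_db(self, azimuth_deg: float, ear: str) -> float:
        half = 0.5 * self.curve.ivad_db(azimuth_deg)
        if ear == "right":
            return half
        if ear == "left":
            return -half
        raise ValueError("ear must be 'left' or 'right'")


@dataclass
class TympanalTraces:
    left: np.ndarray
    right: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right traces must have equal length")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("non-finite samples in tympanal traces")

    def ear(self, which: str) -> np.ndarray:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError("ear must be 'left' or 'right'")


def render_tympanal(source_traces: Sequence[PressureTrace],
                    azimuths_deg: Sequence[float],
                    model: EarGainModel,
                    seed: Optional[int] = None) -> TympanalTraces:
    """Render left/right tympanal vibration traces for an assembled scene.

    Each ear's trace is the sum over sources of the source waveform scaled by
    that ear's direction-dependent linear gain, plus an independent Gaussian
    measurement-noise floor at ``model.meas_noise_db``.
    """
    if len(source_traces) != len(azimuths_deg):
        raise ValueError("need one azimuth per source trace")
    if len(source_traces) == 0:
        raise ValueError("empty scene")
    fs = source_traces[0].fs_hz
    n = len(source_traces[0].samples)
    left = np.zeros(n)
    right = np.zeros(n)
    for trace, az in zip(source_traces, azimuths_deg):
        if len(trace.samples) != n or trace.fs_hz != fs:
            raise ValueError("source traces must share length and sample rate")
        left += 10.0 ** (model.gain_db(az, "left") / 20.0) * trace.samples
        right += 10.0 ** (model.gain_db(az, "right") / 20.0) * trace.samples
    if model.meas_noise_db is not None:
        rng = np.random.default_rng(seed)
        sigma = db_to_amplitude(model.meas_noise_db)
        left = left + sigma * rng.standard_normal(n)
        right = right + sigma * rng.standard_normal(n)
    return TympanalTraces(left=left, right=right, fs_hz=fs)


def render_scene(spec: SceneSpec, model: EarGainModel,
                 seed: Optional[int] = None) -> TympanalTraces:
    """Convenience: assemble a :class:`SceneSpec` and render both ears."""
    traces = assemble_scene(spec)
    azimuths = [src.azimuth_deg for src in spec.sources]
    return render_tympanal(traces, azimuths, model, seed=seed)


# ---------------------------------------------------------------------------
# Afferent spiking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AfferentSpec:
    """Onset-phasic afferent: Type I fires a single spike per pulse onset,
    Type II a short burst; both then go refractory for ~4 ms."""

    type: str = "I"
    refractory_ms: float = 4.0
    n_onset_spikes: int = 1
    threshold_factor: float = 3.0  # multiple of quiet-epoch envelope RMS
    jitter_ms: float = 0.0
    burst_isi_ms: float = 0.8  # spacing of within-burst spikes (Type II)
    onset_ratio: float = 1.8  # envelope increment over the running baseline
    baseline_s: float = 0.2  # trailing-average window for the adaptive floor
    baseline_lag_s: float = 0.01  # gap so a pulse does not inflate its own floor

    def __post_init__(self) -> None:
        if self.type not in ("I", "II"):
            raise ValueError("afferent type must be 'I' or 'II'")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.n_onset_spikes < 1:
            raise ValueError("n_onset_spikes must be >= 1")
        if self.type == "I" and self.n_onset_spikes != 1:
            raise ValueError("Type I afferents fire a single onset spike")


@dataclass
class SpikeTrain:
    times_s: np.ndarray
    channel: str = "unspecified"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    def count_in(self, t0: float, t1: float) -> int:
        return int(np.sum((self.times_s >= t0) & (self.times_s < t1)))


def envelope(trace: np.ndarray, fs_hz: float, window_s: float = 0.001) -> np.ndarray:
    """Amplitude envelope: full-wave rectification + 1 ms sliding RMS."""
    from .vibrometry import sliding_rms

    win = max(2, int(round(window_s * fs_hz)))
    return sliding_rms(np.abs(np.asarray(trace, dtype=float)), win)


def _trailing_baseline(env: np.ndarray, fs_hz: float,
                       baseline_s: float, lag_s: float) -> np.ndarray:
    """Trailing mean of the envelope over [t - lag - baseline, t - lag].

    Serves as the adaptive noise floor for onset detection; the lag keeps a
    rising pulse from raising its own floor.  Early samples shrink to the
    available history; the very start falls back to the first sample.
    """
    n = len(env)
    c = np.concatenate(([0.0], np.cumsum(env)))
    idx = np.arange(n)
    hi = np.maximum(idx - int(round(lag_s * fs_hz)), 0)
    lo = np.maximum(hi - int(round(baseline_s * fs_hz)), 0)
    width = np.maximum(hi - lo, 1)
    out = (c[hi] - c[lo]) / width
    out[hi == 0] = env[0]
    return out


def spikes_from_trace(trace: np.ndarray, fs_hz: float,
                      quiet_epoch: tuple[float, float],
                      spec: AfferentSpec = AfferentSpec(),
                      seed: Optional[int] = None,
                      channel: str = "unspecified") -> SpikeTrain:
    """Generate an onset-phasic spike train from a vibration/voltage trace.

    The unit is phasic: it detects envelope *onsets*, not absolute level.
    The detection threshold at time t is the larger of a static floor
    (``spec.threshold_factor`` times the quiet-epoch envelope RMS) and an
    adaptive floor (``spec.onset_ratio`` times a trailing-average of the
    envelope), so a sound pulse is marked only where it rises sufficiently
    above the running background.  Each upward threshold crossing triggers
    ``n_onset_spikes`` spikes followed by a ``refractory_ms`` dead time.
    Envelope fluctuations of a sustained noise masker occasionally cross the
    adaptive floor, producing the irregular masker-driven spikes seen in
    multi-unit recordings.
    """
    x = np.asarray(trace, dtype=float)
    if not np.any(x):
        return SpikeTrain(times_s=np.empty(0), channel=channel)
    q0 = int(round(quiet_epoch[0] * fs_hz))
    q1 = int(round(quiet_epoch[1] * fs_hz))
    if q1 <= q0:
        raise ValueError("empty quiet epoch: cannot calibrate threshold")
    env = envelope(x, fs_hz)
    quiet = env[q0:q1]
    if quiet.size == 0:
        raise ValueError("quiet epoch lies outside the trace")
    static = spec.threshold_factor * float(np.sqrt(np.mean(quiet ** 2)))
    if static <= 0:
        static = spec.threshold_factor * float(np.finfo(float).tiny)
    baseline = _trailing_baseline(env, fs_hz, spec.baseline_s, spec.baseline_lag_s)
    thresh = np.maximum(static, spec.onset_ratio * baseline)
    above = env > thresh
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    refractory_s = spec.refractory_ms / 1000.0
    rng = np.random.default_rng(seed) if spec.jitter_ms > 0 else None
    times: list[float] = []
    t_dead = -np.inf
    for idx in crossings:
        t = idx / fs_hz
        if t < t_dead:
            continue
        for k in range(spec.n_onset_spikes):
            tk = t + k * spec.burst_isi_ms / 1000.0
            if rng is not None:
                tk += rng.normal(0.0, spec.jitter_ms / 1000.0)
            times.append(tk)
        t_dead = t + refractory_s + (spec.n_onset_spikes - 1) * spec.burst_isi_ms / 1000.0
    times_arr = np.array(sorted(times))
    # enforce strict ordering under jitter
    if times_arr.size > 1:
        keep = np.concatenate(([True], np.diff(times_arr) > 0))
        times_arr = times_arr[keep]
    return SpikeTrain(times_s=times_arr, channel=channel)


def simulate_heading(ivad_effective_db: float,
                     curve: Optional[DirectionalityCurve] = None,
                     gain_deg_per_db: Optional[float] = None) -> float:
    """Map an effective interaural amplitude difference to a walking heading.

    The fly orients toward the ear with the larger effective amplitude: the
    heading is the azimuth whose directionality-curve IVAD equals the measured
    effective difference (curve inversion), or a linear mapping when
    ``gain_deg_per_db`` is given instead.  heading(0) = 0 and the map is
    antisymmetric; sign convention is right-positive, with
    ``ivad_effective_db`` = right-ear minus left-ear effective amplitude.
    """
    if not math.isfinite(ivad_effective_db):
        raise ValueError("ivad_effective_db must be finite")
    if gain_deg_per_db is not None:
        return gain_deg_per_db * ivad_effective_db
    if curve is None:
        curve = DirectionalityCurve()
    return float(curve.inverse_deg(ivad_effective_db))
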