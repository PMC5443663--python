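"""Acoustic stimulus synthesis: pulsed trills, band-limited noise maskers, scenes.

The target signal emulates a synthetic field-cricket trill: tonal 5 kHz pulses
of 10 ms with 1 ms linear on/off ramps, repeated at 50 pulses/s.  Maskers are
band-limited (~2-7 kHz) Gaussian noise bursts.  Levels are expressed in dB re
an arbitrary digital reference: a waveform of RMS amplitude 1.0 is defined to
be ``REF_DB`` (60 dB).  Only dB *differences* enter any downstream analysis,
so the reference convention is immaterial as long as it is used consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "REF_DB",
    "SPEED_OF_SOUND_M_S",
    "PulseTrainSpec",
    "NoiseSpec",
    "SourceSpec",
    "SceneSpec",
    "PressureTrace",
    "db_to_amplitude",
    "amplitude_to_db",
    "best_itd_us",
    "wavelength_cm",
    "synth_pulse_train",
    "synth_noise",
    "set_level",
    "assemble_scene",
    "default_scene",
]

#: dB level assigned to a waveform whose reference RMS amplitude is 1.0.
REF_DB = 60.0

#: Speed of sound in air (m/s) used by the geometry helpers.
SPEED_OF_SOUND_M_S = 344.0

DEFAULT_FS_HZ = 44100.0


def db_to_amplitude(level_db: float) -> float:
    """Linear RMS amplitude corresponding to ``level_db`` (re the 60 dB = 1.0 convention)."""
    return 10.0 ** ((level_db - REF_DB) / 20.0)


def amplitude_to_db(amplitude: float) -> float:
    """Inverse of :func:`db_to_amplitude`."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive for dB conversion")
    return REF_DB + 20.0 * math.log10(amplitude)


def best_itd_us(ear_separation_m: float = 500e-6,
                speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S) -> float:
    """Best-possible acoustic interaural time difference, in microseconds.

    For two ears separated by ``ear_separation_m`` the arrival-time difference
    is maximal for a source at 90 deg azimuth, where the extra path length
    equals the full ear separation.  The fly's 500 um separation yields ~1.45 us.
    """
    if ear_separation_m <= 0 or speed_of_sound_m_s <= 0:
        raise ValueError("separation and speed of sound must be positive")
    return ear_separation_m / speed_of_sound_m_s * 1e6


def wavelength_cm(frequency_hz: float,
                  speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S) -> float:
    """Acoustic wavelength in cm (a 5 kHz cricket-song carrier is ~7 cm)."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return speed_of_sound_m_s / frequency_hz * 100.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrainSpec:
    """Pulsed tonal trill: ``carrier_hz`` tone gated into ramped pulses."""

    carrier_hz: float = 5000.0
    pulse_ms: float = 10.0
    ramp_ms: float = 1.0
    rate_pps: float = 50.0
    total_s: float = 2.0

    def __post_init__(self) -> None:
        if min(self.carrier_hz, self.pulse_ms, self.rate_pps, self.total_s) <= 0:
            raise ValueError("carrier_hz, pulse_ms, rate_pps, total_s must be positive")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be non-negative")
        if self.pulse_ms > 1000.0 / self.rate_pps:
            raise ValueError("pulse_ms exceeds the inter-pulse period")
        if self.ramp_ms > self.pulse_ms / 2:
            raise ValueError("ramp_ms exceeds half the pulse duration")

    @property
    def n_pulses(self) -> int:
        return int(math.floor(self.total_s * self.rate_pps + 1e-9))


@dataclass(frozen=True)
class NoiseSpec:
    """Band-limited stationary Gaussian noise burst."""

    band_lo_hz: float = 2000.0
    band_hi_hz: float = 7000.0
    total_s: float = 4.0
    rng_seed: int = 0
    edge_hz: float = 200.0  # raised-cosine transition width at each band edge

    def __post_init__(self) -> None:
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("require 0 < band_lo_hz < band_hi_hz")
        if self.total_s <= 0:
            raise ValueError("total_s must be positive")


WaveformSpec = Union[PulseTrainSpec, NoiseSpec]


@dataclass(frozen=True)
class SourceSpec:
    """One loudspeaker in the arena.

    azimuth_deg: signed azimuth, 0 = frontal midline, positive = fly's right.
    coherent_group: sources sharing a label share one noise realization
    (Experiment 3's mirror-symmetric identical maskers).
    """

    azimuth_deg: float
    level_db: float
    onset_s: float
    waveform: WaveformSpec
    coherent_group: Optional[str] = None
    level_mode: str = "auto"  # auto: peak_rms for pulse trains, longterm_rms for noise

    def __post_init__(self) -> None:
        if not -180.0 <= self.azimuth_deg <= 180.0:
            raise ValueError("azimuth_deg must lie in [-180, 180]")
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    sources: tuple[SourceSpec, ...]
    fs_hz: float = DEFAULT_FS_HZ
    record_s: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.fs_hz <= 0 or self.record_s <= 0:
            raise ValueError("fs_hz and record_s must be positive")
        for src in self.sources:
            dur = src.waveform.total_s
            if src.onset_s >= self.record_s:
                raise ValueError("source onset beyond end of recording")
            if src.onset_s + dur > self.record_s + 1e-9:
                raise ValueError("source waveform does not fit within record_s")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_s * self.fs_hz))


@dataclass
class PressureTrace:
    """Sampled pressure waveform (dimensionless amplitude re reference)."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def synth_pulse_train(spec: PulseTrainSpec, fs_hz: float = DEFAULT_FS_HZ) -> PressureTrace:
    """Synthesize a pulsed trill; inter-pulse samples are exactly zero.

    Each pulse is a ``carrier_hz`` sinusoid of ``pulse_ms`` with linear on/off
    ramps of ``ramp_ms``; pulses start at multiples of the pulse period.
    """
    if fs_hz <= 2 * spec.carrier_hz:
        raise ValueError("fs_hz must exceed twice the carrier frequency")
    n_total = int(round(spec.total_s * fs_hz))
    out = np.zeros(n_total)
    n_pulse = int(round(spec.pulse_ms / 1000.0 * fs_hz))
    n_ramp = int(round(spec.ramp_ms / 1000.0 * fs_hz))
    env = np.ones(n_pulse)
    if n_ramp > 0:
        # linear ramps from/to zero over ramp_ms
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[n_pulse - n_ramp:] = ramp[::-1]
    t = np.arange(n_pulse) / fs_hz
    period_s = 1.0 / spec.rate_pps
    for k in range(spec.n_pulses):
        i0 = int(round(k * period_s * fs_hz))
        if i0 + n_pulse > n_total:
            break
        out[i0:i0 + n_pulse] = env * np.sin(2 * np.pi * spec.carrier_hz * t)
    return PressureTrace(out, fs_hz)


def synth_noise(spec: NoiseSpec, fs_hz: float = DEFAULT_FS_HZ) -> PressureTrace:
    """Band-limited Gaussian noise by spectral shaping.

    White Gaussian noise is transformed to the frequency domain; bins outside
    [band_lo, band_hi] are zeroed with raised-cosine transitions of
    ``edge_hz`` centred on the band edges, guaranteeing deep (>40 dB)
    out-of-band rejection.  The same seed always yields the same samples,
    which is what makes "coherent" maskers possible.
    """
    nyq = fs_hz / 2.0
    if spec.band_hi_hz >= nyq:
        raise ValueError("band_hi_hz must be below the Nyquist frequency")
    n = int(round(spec.total_s * fs_hz))
    rng = np.random.default_rng(spec.rng_seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    gain = _band_gain(freqs, spec.band_lo_hz, spec.band_hi_hz, spec.edge_hz)
    shaped = np.fft.irfft(spectrum * gain, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    if rms > 0:
        shaped = shaped / rms
    return PressureTrace(shaped, fs_hz)


def _band_gain(freqs: np.ndarray, lo: float, hi: float, edge: float) -> np.ndarray:
    """Raised-cosine band-pass gain: 1 inside [lo, hi], 0 beyond edge widths."""
    gain = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    gain[inside] = 1.0
    if edge > 0:
        lo_t = (freqs > lo - edge) & (freqs < lo)
        gain[lo_t] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[lo_t]) / edge))
        hi_t = (freqs > hi) & (freqs < hi + edge)
        gain[hi_t] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_t] - hi) / edge))
    return gain


def sliding_rms_max(trace: PressureTrace, window_s: float = 0.005) -> float:
    """Maximum sliding RMS of the trace (peak-RMS calibration measure)."""
    from .vibrometry import sliding_rms

    win = max(2, int(round(window_s * trace.fs_hz)))
    return float(np.max(sliding_rms(trace.samples, win)))


def set_level(trace: PressureTrace, level_db: float, mode: str = "longterm_rms") -> PressureTrace:
    """Rescale a trace to ``level_db``.

    mode="peak_rms": the maximum 5 ms sliding RMS (the pulse-interior plateau)
    is brought to the reference amplitude for ``level_db`` — the convention
    used to calibrate pulsed signals.  mode="longterm_rms": the whole-trace
    RMS is brought to that amplitude — the convention for continuous maskers.
    """
    if mode not in ("peak_rms", "longterm_rms"):
        raise ValueError(f"unknown level mode: {mode!r}")
    if mode == "peak_rms":
        current = sliding_rms_max(trace)
    else:
        current = trace.rms()
    if current <= 0:
        raise ValueError("cannot scale an all-zero trace")
    target = db_to_amplitude(level_db)
    return PressureTrace(trace.samples * (target / current), trace.fs_hz)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def _render_source(src: SourceSpec, fs_hz: float,
                   noise_cache: dict[str, np.ndarray]) -> PressureTrace:
    wf = src.waveform
    if isinstance(wf, PulseTrainSpec):
        trace = synth_pulse_train(wf, fs_hz)
        mode = "peak_rms" if src.level_mode == "auto" else src.level_mode
    elif isinstance(wf, NoiseSpec):
        if src.coherent_group is not None and src.coherent_group in noise_cache:
            trace = PressureTrace(noise_cache[src.coherent_group].copy(), fs_hz)
        else:
            trace = synth_noise(wf, fs_hz)
            if src.coherent_group is not None:
                noise_cache[src.coherent_group] = trace.samples.copy()
        mode = "longterm_rms" if src.level_mode == "auto" else src.level_mode
    else:  # pragma: no cover - guarded by SourceSpec typing
        raise TypeError(f"unsupported waveform spec: {type(wf)!r}")
    return set_level(trace, src.level_db, mode=mode)


def assemble_scene(spec: SceneSpec) -> list[PressureTrace]:
    """Render every source, calibrated and zero-padded onto the common timeline.

    Returns one full-length :class:`PressureTrace` per source, in the order of
    ``spec.sources``; the acoustic mixture at any point in space is a gain-
    weighted sum of these (done per ear by the ear model).
    """
    n_total = spec.n_samples
    noise_cache: dict[str, np.ndarray] = {}
    out: list[PressureTrace] = []
    for src in spec.sources:
        trace = _render_source(src, spec.fs_hz, noise_cache)
        padded = np.zeros(n_total)
        i0 = int(round(src.onset_s * spec.fs_hz))
        seg = trace.samples[: n_total - i0]
        padded[i0:i0 + len(seg)] = seg
        out.append(PressureTrace(padded, spec.fs_hz))
    return out


def default_scene(signal_azimuth_deg: float = 0.0,
                  signal_db: float = 76.0,
                  masker_azimuths_deg: tuple[float, ...] = (),
                  masker_db: float = 76.0,
                  coherent_maskers: bool = True,
                  masker_seed: int = 0,
                  fs_hz: float = DEFAULT_FS_HZ,
                  signal: bool = True) -> SceneSpec:
    """Standard trial timing: 4 s masker at 0.5 s, 2 s trill at 1.5 s, 5 s record.

    The trill is embedded symmetrically in the masker — it begins 1 s after
    masker onset and ends 1 s before masker offset.  Multiple maskers share
    one coherent noise waveform when ``coherent_maskers`` is set; each masker
    is individually calibrated to ``masker_db`` (two coherent maskers at 70 dB
    each sum in phase to an overall 76 dB at a symmetric point).
    """
    sources: list[SourceSpec] = []
    if signal:
        sources.append(SourceSpec(
            azimuth_deg=signal_azimuth_deg, level_db=signal_db, onset_s=1.5,
            waveform=PulseTrainSpec()))
    group = "masker" if coherent_maskers else None
    for i, az in enumerate(masker_azimuths_deg):
        seed = masker_seed if coherent_maskers else masker_seed + i
        sources.append(SourceSpec(
            azimuth_deg=az, level_db=masker_db, onset_s=0.5,
            waveform=NoiseSpec(rng_seed=seed), coherent_group=group))
    return SceneSpec(sources=tuple(sources), fs_hz=fs_hz, record_s=5.0)
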