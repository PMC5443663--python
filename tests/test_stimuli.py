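"""Stimulus synthesis: pulse trains, band-limited noise, levels, scenes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ormia.stimuli import (NoiseSpec, PressureTrace, PulseTrainSpec, SceneSpec,
                           SourceSpec, amplitude_to_db, assemble_scene,
                           best_itd_us, db_to_amplitude, default_scene,
                           set_level, synth_noise, synth_pulse_train,
                           wavelength_cm)

FS = 44100.0


def _count_pulses(trace: PressureTrace) -> int:
    """Envelope-threshold pulse counter (independent of the synthesis path)."""
    env = np.abs(trace.samples) > 1e-6
    onsets = np.flatnonzero(env[1:] & ~env[:-1]) + 1
    return len(onsets) + int(env[0])


class TestPulseTrain:
    def test_standard_trill_pulse_count_and_duty_cycle(self):
        trace = synth_pulse_train(PulseTrainSpec(), FS)
        assert _count_pulses(trace) == 100
        duty = np.mean(np.abs(trace.samples) > 1e-6)
        assert duty == pytest.approx(0.5, abs=0.02)

    def test_two_pulse_stimulus(self):
        # a 40 ms trill at 50 pulses/s contains exactly two pulses
        trace = synth_pulse_train(PulseTrainSpec(total_s=0.04), FS)
        assert _count_pulses(trace) == 2

    def test_interpulse_samples_exactly_zero(self):
        trace = synth_pulse_train(PulseTrainSpec(total_s=0.1), FS)
        gap = trace.samples[int(0.012 * FS):int(0.019 * FS)]
        assert np.all(gap == 0.0)

    def test_unramped_pulse_interior_rms_is_sine_rms(self):
        spec = PulseTrainSpec(ramp_ms=0.0, total_s=0.02)
        trace = synth_pulse_train(spec, FS)
        pulse = trace.samples[: int(0.010 * FS)]
        assert np.sqrt(np.mean(pulse ** 2)) == pytest.approx(1 / np.sqrt(2),
                                                             rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"pulse_ms": 25.0, "rate_pps": 50.0},   # pulse longer than period
        {"ramp_ms": 6.0},                        # ramp > half pulse
        {"carrier_hz": -5.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PulseTrainSpec(**kwargs)

    def test_undersampled_carrier_rejected(self):
        with pytest.raises(ValueError):
            synth_pulse_train(PulseTrainSpec(), fs_hz=8000.0)


class TestNoise:
    def test_deterministic_under_fixed_seed(self):
        a = synth_noise(NoiseSpec(rng_seed=7), FS)
        b = synth_noise(NoiseSpec(rng_seed=7), FS)
        assert np.array_equal(a.samples, b.samples)

    @given(seed=st.integers(0, 10 ** 6))
    def test_out_of_band_rejection_at_least_40_db(self, seed):
        trace = synth_noise(NoiseSpec(total_s=1.0, rng_seed=seed), FS)
        spectrum = np.abs(np.fft.rfft(trace.samples)) ** 2
        freqs = np.fft.rfftfreq(len(trace.samples), 1 / FS)
        in_band = (freqs >= 2000) & (freqs <= 7000)
        out_band = (freqs < 1700) | (freqs > 7300)
        ratio = np.mean(spectrum[in_band]) / max(np.mean(spectrum[out_band]),
                                                 1e-300)
        assert 10 * np.log10(ratio) >= 40.0

    def test_band_covers_5khz_carrier(self):
        # the masker's passband overlaps the song carrier frequency
        spec = NoiseSpec()
        assert spec.band_lo_hz < 5000.0 < spec.band_hi_hz

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            synth_noise(NoiseSpec(band_hi_hz=30000.0), FS)


class TestLevels:
    def test_6db_doubles_amplitude(self):
        trace = synth_noise(NoiseSpec(total_s=0.5, rng_seed=0), FS)
        lo = set_level(trace, 60.0)
        hi = set_level(trace, 66.02)
        assert np.max(np.abs(hi.samples / lo.samples - 2.0)) < 1e-3

    def test_snr_labels_from_level_difference(self):
        # 70 dB signal against a 76 dB masker is the -6 dB SNR condition
        assert 70.0 - 76.0 == -6.0
        assert amplitude_to_db(db_to_amplitude(70.0)) == pytest.approx(70.0)

    def test_coherent_sum_of_two_70db_maskers_is_76db(self):
        noise = synth_noise(NoiseSpec(total_s=0.5, rng_seed=3), FS)
        each = set_level(noise, 70.0)
        combined = PressureTrace(each.samples + each.samples, FS)
        assert amplitude_to_db(combined.rms()) == pytest.approx(76.02, abs=0.01)

    def test_set_level_idempotent(self):
        trill = synth_pulse_train(PulseTrainSpec(total_s=0.2), FS)
        once = set_level(trill, 76.0, mode="peak_rms")
        twice = set_level(once, 76.0, mode="peak_rms")
        assert np.allclose(once.samples, twice.samples, rtol=1e-9)

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            set_level(PressureTrace(np.zeros(1000), FS), 70.0)


class TestSceneAssembly:
    def test_default_timing_embeds_signal_symmetrically(self):
        spec = default_scene(masker_azimuths_deg=(90.0,))
        traces = assemble_scene(spec)
        sig, mask = traces[0].samples, traces[1].samples
        sig_on = np.flatnonzero(np.abs(sig) > 1e-9)[0] / FS
        mask_on = np.flatnonzero(np.abs(mask) > 1e-9)[0] / FS
        sig_off = np.flatnonzero(np.abs(sig) > 1e-9)[-1] / FS
        mask_off = np.flatnonzero(np.abs(mask) > 1e-9)[-1] / FS
        assert sig_on - mask_on == pytest.approx(1.0, abs=0.01)
        assert mask_off - sig_off == pytest.approx(1.0, abs=0.02)

    def test_empty_scene_is_silent(self):
        spec = SceneSpec(sources=(), fs_hz=FS, record_s=1.0)
        assert assemble_scene(spec) == []
        assert spec.n_samples == 44100

    def test_coherent_group_shares_waveform_across_azimuths(self):
        spec = default_scene(signal=False, masker_azimuths_deg=(90.0, -90.0),
                             masker_db=70.0)
        m1, m2 = assemble_scene(spec)
        assert np.array_equal(m1.samples, m2.samples)
        assert spec.sources[0].azimuth_deg != spec.sources[1].azimuth_deg

    def test_source_beyond_record_rejected(self):
        src = SourceSpec(azimuth_deg=0, level_db=70, onset_s=4.0,
                         waveform=NoiseSpec(total_s=4.0))
        with pytest.raises(ValueError):
            SceneSpec(sources=(src,), fs_hz=FS, record_s=5.0)


class TestGeometry:
    def test_best_itd_for_fly_ear_separation(self):
        # 500 um separation at 344 m/s: ~1.45 us at 90 deg incidence
        assert best_itd_us(500e-6) == pytest.approx(1.45, abs=0.005)

    def test_wavelength_of_cricket_song_carrier(self):
        assert wavelength_cm(5000.0) == pytest.approx(7.0, abs=0.2)
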