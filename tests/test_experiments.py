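"""End-to-end experiment replicas: determinism, directionality, outputs."""

import json

import numpy as np
import pandas as pd
import pytest

from ormia.experiments import (ExperimentConfig, ModelObserver,
                               compare_masked_thresholds, run_experiment,
                               trill_window_schedule)

SMALL = dict(n_flies=3, repeats=2)


@pytest.fixture(scope="module")
def exp2_result():
    return run_experiment(ExperimentConfig(experiment="exp2_snr_separation",
                                           seed=5, **SMALL))


class TestObserver:
    def test_quiet_floor_is_measurement_noise(self):
        obs = ModelObserver(ExperimentConfig().model())
        # response probability rises monotonically with level
        levels = np.linspace(20, 76, 15)
        probs = [obs.response_probability(l) for l in levels]
        assert np.all(np.diff(probs) >= 0)
        assert probs[0] < 0.01 and probs[-1] > 0.99

    def test_masker_raises_detection_level(self):
        model = ExperimentConfig().model()
        quiet = ModelObserver(model)
        masked = ModelObserver(model, masker_azimuths_deg=(90.0,),
                               masker_db=76.0)
        assert masked.response_probability(60.0) < quiet.response_probability(60.0)

    def test_better_ear_is_masker_contralateral(self):
        model = ExperimentConfig().model()
        obs = ModelObserver(model, masker_azimuths_deg=(90.0,), masker_db=76.0)
        assert obs.effective_amplitude_db(76.0, "left") > \
            obs.effective_amplitude_db(76.0, "right")


class TestExp1:
    def test_quiet_threshold_below_masked(self):
        res = run_experiment(ExperimentConfig(experiment="exp1_thresholds",
                                              n_flies=4, seed=2))
        s = res["summary"]
        assert s["threshold_quiet_db"] < s["threshold_masked_6deg_db"]
        assert s["threshold_quiet_db"] < s["threshold_masked_90deg_db"]

    def test_azimuth_independent_masking_yields_no_srm(self):
        # with a flat directionality curve the 90-6 contrast vanishes
        table = pd.DataFrame([
            {"fly": f, "condition": c, "threshold_db": 60.0 + f}
            for f in range(5) for c in ("quiet", "masked_6deg", "masked_90deg")])
        out = compare_masked_thresholds(table)
        assert out["srm_large_minus_small_db"] == pytest.approx(0.0)


class TestExp2(object):
    def test_heading_away_from_masker(self, exp2_result):
        summary = exp2_result["tables"]["condition_summary"]
        # all pooled headings negative: diverted contralateral to the masker
        assert (summary["heading_mean_deg"] < 0).all()

    def test_larger_separation_larger_deviation(self, exp2_result):
        summary = exp2_result["tables"]["condition_summary"]
        for snr in (-6.0, 0.0, 6.0):
            h6 = summary.query("separation_deg == 6 and snr_db == @snr")
            h90 = summary.query("separation_deg == 90 and snr_db == @snr")
            assert abs(float(h90["heading_mean_deg"].iloc[0])) >= \
                abs(float(h6["heading_mean_deg"].iloc[0]))

    def test_distance_grows_with_snr(self, exp2_result):
        summary = exp2_result["tables"]["condition_summary"]
        for sep in (6.0, 90.0):
            d = summary[summary["separation_deg"] == sep] \
                .sort_values("snr_db")["distance_cm"].to_numpy()
            assert np.all(np.diff(d) > 0)


class TestExp3:
    def test_symmetric_maskers_restore_forward_heading(self):
        res = run_experiment(ExperimentConfig(experiment="exp3_symmetry",
                                              seed=3, **SMALL))
        means = res["summary"]["mean_heading_deg"]
        assert abs(means["sym_6deg"]) < 5.0
        assert abs(means["sym_90deg"]) < 5.0
        assert means["asym_90deg"] < -10.0  # diverted away from right masker


class TestDeterminismAndOutput:
    def test_same_seed_byte_identical_manifest(self, tmp_path):
        cfg = ExperimentConfig(experiment="exp1_thresholds", n_flies=2, seed=9)
        for sub in ("a", "b"):
            run_experiment(cfg, outdir=tmp_path / sub)
        m1 = (tmp_path / "a" / "exp1_thresholds_manifest.json").read_bytes()
        m2 = (tmp_path / "b" / "exp1_thresholds_manifest.json").read_bytes()
        assert m1 == m2

    def test_tables_and_manifest_written(self, tmp_path):
        cfg = ExperimentConfig(experiment="exp1_thresholds", n_flies=2, seed=9)
        res = run_experiment(cfg, outdir=tmp_path)
        csv = tmp_path / "exp1_thresholds_thresholds.csv"
        assert csv.exists()
        manifest = json.loads(
            (tmp_path / "exp1_thresholds_manifest.json").read_text())
        assert manifest["experiment"] == "exp1_thresholds"
        assert manifest["config"]["seed"] == 9

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(experiment="exp9")


class TestWindowSchedule:
    def test_trill_schedule_trims_edges_and_tiles_floor(self):
        fs = 44100.0
        sig, floor = trill_window_schedule(1.5, fs)
        # 2 s trill at 50 pps minus 100 ms at each edge: 90 pulse windows
        assert len(sig) == 90
        assert len(floor) == len(sig)
        # first signal window begins 100 ms into the trill
        assert sig[0][0] == int(round(1.6 * fs))
        # floor windows live strictly before signal onset
        assert max(w[1] for w in floor) <= int(round(1.5 * fs))


class TestCli:
    def test_cli_runs_experiment_and_writes_outputs(self, tmp_path):
        from click.testing import CliRunner

        from ormia.cli import main

        runner = CliRunner()
        res = runner.invoke(main, ["run", "exp1_thresholds", "--seed", "4",
                                   "--n-flies", "2",
                                   "--outdir", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "exp1_thresholds_manifest.json").exists()

    def test_cli_synth_writes_wav(self, tmp_path):
        from click.testing import CliRunner

        from ormia.cli import main

        out = tmp_path / "trill.wav"
        res = CliRunner().invoke(main, ["synth", "--kind", "trill",
                                        "--duration-s", "0.2",
                                        "--out", str(out)])
        assert res.exit_code == 0, res.output
        from scipy.io import wavfile

        fs, data = wavfile.read(out)
        assert fs == 44100 and len(data) == int(0.2 * 44100)
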