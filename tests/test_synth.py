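import numpy as np
import pytest
from scipy import signal as sg

from bgosc import synth
from bgosc.io import assign_structures, derive_bipolar
from bgosc.synth import CohortConfig, GroundTruth, SeverityModel, generate_cohort, generate_hemisphere


class TestGroundTruthValidation:
    def test_lf_peak_outside_band_rejected(self):
        with pytest.raises(ValueError, match="lf_peak"):
            GroundTruth(subject_id="s", hemisphere="left", lf_peak_hz=2.0)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            GroundTruth(subject_id="s", hemisphere="left",
                        coupling_gain={"str_gpi": -0.1, "str_gpe": 0, "gpe_gpi": 0})

    def test_zero_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            GroundTruth(subject_id="s", hemisphere="left", coupling_lag_ms=0.0)

    def test_negative_severity_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            SeverityModel(noise_sd=-1.0)


class TestGenerateHemisphere:
    def test_three_minutes_at_1khz(self, default_truth):
        rec = generate_hemisphere(default_truth, duration_s=180.0, fs=1000.0, seed=0)
        assert rec.samples.shape == (8, 180_000)
        assert rec.fs == 1000.0

    def test_nonpositive_duration_rejected(self, default_truth):
        with pytest.raises(ValueError, match="duration"):
            generate_hemisphere(default_truth, duration_s=0.0, fs=1000.0)

    def test_sub_sample_lag_rejected(self):
        truth = GroundTruth(subject_id="s", hemisphere="left", coupling_lag_ms=0.5,
                            line_noise_amp=0.0, beta_peak_hz=None)
        with pytest.raises(ValueError, match="lag"):
            generate_hemisphere(truth, duration_s=10.0, fs=250.0)

    def test_bipolar_montage_recovers_three_structures(self, small_recording):
        retained = assign_structures(derive_bipolar(small_recording))
        assert set(retained) == {"STR", "GPe", "GPi"}

    def test_lf_band_power_monotone_in_gain(self):
        """Generated 3-12 Hz power grows with lf_power_gain (fixed seed)."""
        powers = []
        for gain in (0.25, 0.75, 1.5, 3.0):
            truth = GroundTruth(subject_id="s", hemisphere="left", lf_peak_hz=8.0,
                                beta_peak_hz=None,
                                lf_power_gain={"STR": gain, "GPe": 1.0, "GPi": 1.0},
                                coupling_gain={"str_gpi": 0, "str_gpe": 0, "gpe_gpi": 0})
            rec = generate_hemisphere(truth, duration_s=40.0, fs=250.0, seed=11)
            x = assign_structures(derive_bipolar(rec))["STR"].samples
            f, p = sg.welch(x, fs=250.0, nperseg=512)
            powers.append(p[(f >= 3) & (f <= 12)].mean())
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_coupling_lag_recovered_by_cross_correlation(self):
        """STR and GPi low-frequency components peak at the configured lag."""
        fs, lag_ms = 250.0, 24.0
        truth = GroundTruth(subject_id="s", hemisphere="left", lf_peak_hz=8.0,
                            beta_peak_hz=None, coupling_lag_ms=lag_ms,
                            lf_power_gain={"STR": 1.0, "GPe": 0.1, "GPi": 0.0},
                            coupling_gain={"str_gpi": 1.0, "str_gpe": 0, "gpe_gpi": 0},
                            common_source_gain=0.0, line_noise_amp=0.0, background_gain=0.1)
        rec = generate_hemisphere(truth, duration_s=60.0, fs=fs, seed=3)
        ch = assign_structures(derive_bipolar(rec))
        sos = sg.butter(4, [6 / 125, 10 / 125], btype="bandpass", output="sos")
        a = sg.sosfiltfilt(sos, ch["STR"].samples)
        b = sg.sosfiltfilt(sos, ch["GPi"].samples)
        xc = sg.correlate(b, a, mode="full")
        lag = np.argmax(xc) - (len(a) - 1)
        assert abs(lag - round(lag_ms * fs / 1000)) <= 1


class TestGenerateCohort:
    def test_default_cohort_has_19_hemispheres(self):
        cohort = generate_cohort(10, 2, seed=0)
        assert len(cohort.recordings) == 19
        assert len(cohort.truths) == 19
        assert cohort.severity.shape[0] == 10

    def test_same_seed_is_bit_identical(self):
        cfg = CohortConfig(duration_s=5.0, fs=250.0)
        c1 = generate_cohort(3, 2, cfg, seed=42)
        c2 = generate_cohort(3, 2, cfg, seed=42)
        for r1, r2 in zip(c1.recordings, c2.recordings):
            np.testing.assert_array_equal(r1.samples, r2.samples)
        assert c1.severity.equals(c2.severity)

    def test_noiseless_severity_is_affine_in_gpi_gain(self):
        cfg = CohortConfig(duration_s=5.0, fs=250.0,
                           severity=SeverityModel(w_str_gpi_coupling=0.0, noise_sd=0.0))
        cohort = generate_cohort(8, 2, cfg, seed=1)
        sev = cohort.severity
        pred = cfg.severity.intercept + cfg.severity.w_gpi_power * sev["true_gpi_lf_gain"]
        np.testing.assert_allclose(sev["severity"], np.maximum(pred, 0.0), rtol=1e-12)

    def test_severity_is_clamped_non_negative(self):
        cfg = CohortConfig(duration_s=5.0, fs=250.0,
                           severity=SeverityModel(intercept=-100.0, w_gpi_power=0.0,
                                                  w_str_gpi_coupling=0.0, noise_sd=0.0))
        cohort = generate_cohort(3, 2, cfg, seed=1)
        assert (cohort.severity["severity"] >= 0).all()

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(jitter_sd=-0.1)

    def test_excluded_hemisphere_not_generated(self):
        cfg = CohortConfig(duration_s=5.0, fs=250.0, exclude=(("sub-02", "right"),))
        cohort = generate_cohort(3, 2, cfg, seed=0)
        keys = {(r.subject_id, r.hemisphere) for r in cohort.recordings}
        assert ("sub-02", "right") not in keys
        assert len(cohort.recordings) == 5

    def test_write_cohort_round_trips(self, tmp_path):
        from bgosc.io import read_recording

        cfg = CohortConfig(duration_s=5.0, fs=250.0)
        cohort = generate_cohort(2, 2, cfg, seed=0)
        outdir = synth.write_cohort(cohort, tmp_path / "cohort")
        assert (outdir / "ground_truth.csv").exists()
        assert (outdir / "generator_config.yaml").exists()
        rec = cohort.recordings[0]
        back = read_recording(outdir / f"{rec.subject_id}_{rec.hemisphere}.dat")
        np.testing.assert_array_equal(back.samples, rec.samples)
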