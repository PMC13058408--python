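"""HRF, trial-wise GLM, fNIRS classification and EEG band power."""

import numpy as np
import pandas as pd
import pytest

from nfpredict.neurophys import (EegSession, FnirsSession, HrfParams,
                                 average_channels, band_power,
                                 build_trial_design, classify_trial,
                                 eeg_predictors, fit_trial_glm,
                                 fnirs_predictors, hrf_regressor, trial_betas,
                                 two_gamma_hrf)


def simple_schedule(onsets, duration=30.0, types=None):
    types = types or ["regulation"] * len(onsets)
    return pd.DataFrame({"trial_id": range(len(onsets)), "type": types,
                         "onset_s": onsets, "duration_s": duration})


class TestTwoGammaHrf:
    def test_kernel_zero_at_origin_and_unit_peak(self):
        h = two_gamma_hrf(fs=20.0)
        assert h.kernel[0] == 0.0
        assert h.kernel.max() == pytest.approx(1.0)
        assert abs(h.kernel[-1]) < 0.01  # decayed by the grid end

    def test_peak_latency_matches_default_delay(self):
        # numerical maximisation of the sampled kernel
        h = two_gamma_hrf(fs=100.0)
        t_peak = h.times[np.argmax(h.kernel)]
        assert 5.0 <= t_peak <= 7.0

    def test_doubling_fs_keeps_unit_peak(self):
        h1 = two_gamma_hrf(fs=10.0)
        h2 = two_gamma_hrf(fs=20.0)
        assert h2.kernel.max() == pytest.approx(h1.kernel.max()) == 1.0
        # coarse samples interleave into the fine grid
        np.testing.assert_allclose(h2.kernel[::2][:len(h1.kernel)],
                                   h1.kernel, atol=1e-12)

    @pytest.mark.parametrize("bad", [
        HrfParams(peak_delay=-1), HrfParams(dispersion_1=0),
        HrfParams(undershoot_ratio=0)])
    def test_nonpositive_params_rejected(self, bad):
        with pytest.raises(ValueError):
            two_gamma_hrf(10.0, params=bad)

    def test_short_kernel_rejected(self):
        with pytest.raises(ValueError):
            two_gamma_hrf(10.0, length_s=10.0)


class TestBuildTrialDesign:
    def test_regressor_zero_before_onset(self, hrf10):
        sched = simple_schedule([50.0])
        design = build_trial_design(sched, 0, 10.0, 2000, hrf10)
        assert (design["trial"].to_numpy()[:500] == 0).all()
        assert design["trial"].to_numpy()[520] > 0

    def test_long_boxcar_plateaus_at_kernel_sum(self, hrf10):
        sched = simple_schedule([10.0], duration=300.0)
        reg = hrf_regressor(sched, [0], 10.0, 4000, hrf10)
        assert reg[2000] == pytest.approx(hrf10.kernel.sum(), rel=1e-10)

    def test_disjoint_trials_sum_to_union(self, hrf10):
        sched = simple_schedule([30.0, 400.0])
        a = hrf_regressor(sched, [0], 10.0, 6000, hrf10)
        b = hrf_regressor(sched, [1], 10.0, 6000, hrf10)
        both = hrf_regressor(sched, [0, 1], 10.0, 6000, hrf10)
        np.testing.assert_allclose(a + b, both, atol=1e-12)

    def test_unknown_trial_id_rejected(self, hrf10):
        with pytest.raises(KeyError):
            build_trial_design(simple_schedule([10.0]), 99, 10.0, 1000, hrf10)


class TestFitTrialGlm:
    def test_exact_recovery_in_noiseless_model(self, hrf10):
        sched = simple_schedule([20.0])
        design = build_trial_design(sched, 0, 10.0, 1000, hrf10)
        t = np.arange(1000) / 10.0
        series = 3.0 * design["trial"].to_numpy() + 0.5 + 0.01 * t
        assert fit_trial_glm(series, design) == pytest.approx(3.0, abs=1e-8)

    def test_pure_drift_yields_zero_beta(self, hrf10):
        sched = simple_schedule([20.0])
        design = build_trial_design(sched, 0, 10.0, 1000, hrf10)
        series = 0.2 + 0.05 * np.arange(1000) / 10.0
        assert fit_trial_glm(series, design) == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, hrf10, rng):
        # independently coded (X'X)^-1 X'y on 100 random instances
        sched = simple_schedule([5.0], duration=8.0)
        design = build_trial_design(sched, 0, 10.0, 200, hrf10)
        X = design.to_numpy()
        keep = [i for i in range(X.shape[1]) if np.any(X[:, i] != 0)]
        Xk = X[:, keep]
        for _ in range(100):
            y = rng.standard_normal(200)
            oracle = np.linalg.solve(Xk.T @ Xk, Xk.T @ y)[0]
            assert fit_trial_glm(y, design) == pytest.approx(oracle, abs=1e-8)

    def test_rank_deficient_design_rejected(self, hrf10):
        design = pd.DataFrame({"trial": np.ones(50), "others": np.zeros(50),
                               "intercept": np.ones(50),
                               "drift": np.zeros(50)})
        with pytest.raises(np.linalg.LinAlgError):
            fit_trial_glm(np.random.default_rng(0).standard_normal(50), design)


class TestClassification:
    @pytest.mark.parametrize("pair,expected", [
        ((0.3, 0.1), 0.2), ((0.7, 0.7), 0.7), ((0.25, -0.05), 0.10)])
    def test_average_channels(self, pair, expected):
        assert average_channels(*pair) == pytest.approx(expected)

    @pytest.mark.parametrize("beta,label", [
        (0.25, "oxygenation"), (-0.25, "deoxygenation"),
        (0.2, "neither"), (-0.2, "neither"), (0.0, "neither")])
    def test_classify_trial_thresholds(self, beta, label):
        assert classify_trial(beta) == label

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            classify_trial(float("nan"))


def synthetic_session(amplitudes_by_type, fs=10.0, hrf=None):
    """Noiseless two-channel session with preset per-trial amplitudes."""
    from nfpredict.cohort import generate_fnirs_session
    amp = []
    spec_types = []
    # default schedule order: regulation/passive alternating then transfer
    order = []
    for i in range(12):
        order += ["regulation", "passive_viewing"]
    order += ["transfer"] * 12
    counters = {t: 0 for t in amplitudes_by_type}
    for t in order:
        amp.append(amplitudes_by_type[t][counters[t]])
        counters[t] += 1
    traits = pd.Series({"attention": 0.0, "regulation": 0.0, "control": 0.0})
    return generate_fnirs_session(traits, noise_sd=0.0, drift_slope=0.0,
                                  fs=fs, seed=0, amplitudes=np.array(amp),
                                  hrf=hrf)


class TestFnirsPredictors:
    def test_preset_amplitudes_enumerate_to_50_25(self, hrf10):
        amps = [0.5] * 6 + [-0.5] * 3 + [0.0] * 3
        ses = synthetic_session({t: list(amps) for t in
                                 ("passive_viewing", "regulation", "transfer")},
                                hrf=hrf10)
        out = fnirs_predictors(ses, hrf10)
        for key in ("passive", "regulation", "transfer"):
            assert out[f"fnirs_oxy_{key}"] == pytest.approx(50.0)
            assert out[f"fnirs_deoxy_{key}"] == pytest.approx(25.0)

    def test_all_zero_betas_give_zero_percentages(self, hrf10):
        ses = synthetic_session({t: [0.0] * 12 for t in
                                 ("passive_viewing", "regulation", "transfer")},
                                hrf=hrf10)
        out = fnirs_predictors(ses, hrf10)
        assert all(v == 0.0 for v in out.values())

    def test_percentages_conserve_to_100(self, default_cohort, hrf10):
        from nfpredict.cohort import generate_fnirs_session
        _, traits = default_cohort
        ses = generate_fnirs_session(traits.iloc[30], seed=77)
        betas = trial_betas(ses, hrf10)
        for ttype in ("passive_viewing", "regulation", "transfer"):
            tb = [b.beta for b in betas if b.type == ttype]
            labels = [classify_trial(b) for b in tb]
            total = sum(100.0 * labels.count(c) / len(tb)
                        for c in ("oxygenation", "deoxygenation", "neither"))
            assert total == pytest.approx(100.0)

    def test_channel_scaling_scales_betas(self, hrf10):
        ses = synthetic_session({t: [0.4] * 12 for t in
                                 ("passive_viewing", "regulation", "transfer")},
                                hrf=hrf10)
        scaled = FnirsSession(fs=ses.fs, series=ses.series * 3.0,
                              schedule=ses.schedule)
        b0 = trial_betas(ses, hrf10)[0].beta
        b1 = trial_betas(scaled, hrf10)[0].beta
        assert b1 == pytest.approx(3.0 * b0, rel=1e-9)

    def test_recovery_error_nondecreasing_in_noise(self, default_cohort, hrf10):
        from nfpredict.cohort import generate_fnirs_session
        _, traits = default_cohort
        amps = np.full(36, 0.4)
        maes = []
        for noise in (0.0, 0.1, 0.5):
            errs = []
            for seed in range(3):
                ses = generate_fnirs_session(traits.iloc[25], noise_sd=noise,
                                             drift_slope=0.0, seed=seed,
                                             amplitudes=amps)
                errs += [abs(b.beta - 0.4) for b in trial_betas(ses, hrf10)]
            maes.append(np.mean(errs))
        assert maes[0] <= maes[1] <= maes[2]


class TestBandPower:
    def test_sinusoid_power_concentrates_in_band(self):
        fs = 250.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 25.0 * t)
        inband = band_power(x, fs, (23, 28))
        total = np.var(x)  # Parseval: integrated PSD equals the variance
        assert inband / total >= 0.95

    def test_out_of_band_sinusoid_contributes_little(self):
        fs = 250.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        assert band_power(x, fs, (23, 28)) / np.var(x) < 0.01

    def test_white_noise_flat_spectrum_share(self, rng):
        fs = 200.0
        sigma = 1.5
        x = rng.normal(0, sigma, int(600 * fs))
        expected = sigma ** 2 * 5.0 / (fs / 2)
        assert band_power(x, fs, (23, 28)) == pytest.approx(expected, rel=0.10)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(500), fs=50.0, band=(23, 28))


class TestEegPredictors:
    def test_means_per_trial_type(self):
        ses = EegSession(powers={"passive_viewing": [4.0, 5.0, 6.0],
                                 "regulation": [5.2, 4.8, 4.7],
                                 "transfer": [5.1, 5.3]})
        out = eeg_predictors(ses)
        assert out["eeg_passive"] == pytest.approx(5.0)
        assert out["eeg_regulation"] == pytest.approx(4.9)
        assert out["eeg_transfer"] == pytest.approx(5.2)

    def test_single_trial_is_identity(self):
        ses = EegSession(powers={"passive_viewing": [7.3]})
        assert eeg_predictors(ses)["eeg_passive"] == pytest.approx(7.3)

    def test_missing_type_marked_absent(self):
        ses = EegSession(powers={"regulation": [5.0]})
        out = eeg_predictors(ses)
        assert np.isnan(out["eeg_passive"])
        assert np.isnan(out["eeg_transfer"])
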