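"""Synthetic experiments: staircase, trial tables, spectral-mixture EEG, TRFs."""

import numpy as np
import pandas as pd
import pytest

from apertrack.specfit import PRESETS, parameterize, welch_psd
from apertrack.synthexp import (
    EEGGenParams,
    ObserverModel,
    StaircaseState,
    bin_exponent_model,
    canonical_trf,
    envelope_onsets,
    estimate_trf,
    gen_spectral_eeg,
    reconstruct_stimulus_loso,
    run_staircase_session,
    simulate_experiment,
    staircase_update,
    trf_forward_simulate,
)


class TestStaircase:
    def test_ideal_observer_drives_depth_to_floor(self):
        obs = ObserverModel(threshold=1e-6, slope=1000, lapse=0.0, guess=0.0)
        depths, _ = run_staircase_session(obs, 300, seed=0)
        assert depths[-1] == pytest.approx(StaircaseState().depth_floor, abs=0.02)

    def test_accuracy_converges_to_seventy_percent(self):
        obs = ObserverModel(threshold=0.2, slope=10, lapse=0.02, guess=0.05)
        accs = [run_staircase_session(obs, 432, seed=s)[1][216:].mean()
                for s in range(10)]
        assert np.mean(accs) == pytest.approx(0.70, abs=0.05)

    @pytest.mark.parametrize("threshold", [0.05, 0.2, 0.5])
    def test_convergence_across_observer_thresholds(self, threshold):
        obs = ObserverModel(threshold=threshold, slope=15, lapse=0.02, guess=0.05)
        accs = [run_staircase_session(obs, 432, seed=s)[1][216:].mean()
                for s in range(6)]
        assert abs(np.mean(accs) - 0.70) < 0.05

    def test_update_rule_and_determinism(self):
        st = StaircaseState(depth=0.5)
        up = staircase_update(st, correct=False)
        down = staircase_update(st, correct=True)
        assert up.depth == pytest.approx(0.5 + st.step_up)
        assert down.depth == pytest.approx(0.5 - st.step_down)
        # weighted up-down ratio targets 70 %
        assert st.step_down / st.step_up == pytest.approx(0.3 / 0.7)
        a = run_staircase_session(ObserverModel(), 100, seed=3)
        b = run_staircase_session(ObserverModel(), 100, seed=3)
        np.testing.assert_array_equal(a[0], b[0])

    def test_invalid_observer(self):
        with pytest.raises(ValueError):
            ObserverModel(lapse=1.5)
        with pytest.raises(ValueError):
            ObserverModel(slope=-1)


class TestSimulateExperiment:
    def test_session_structure(self, coupled_experiment):
        t = coupled_experiment
        assert (t.groupby("subject").size() == 432).all()
        # attention constant within block, alternating across blocks
        per_block = t.groupby(["subject", "block"])["attention"].nunique()
        assert (per_block == 1).all()
        one = t[t.subject == 0].groupby("block")["attention"].first()
        assert (one.iloc[::2] != one.iloc[1::2].to_numpy()).all()

    def test_stimulus_exponents_uncorrelated(self, coupled_experiment):
        for _, sub in coupled_experiment.groupby("subject"):
            r = np.corrcoef(sub.chi_aud, sub.chi_vis)[0, 1]
            assert abs(r) < 0.1

    def test_rt_present_iff_response(self, coupled_experiment):
        t = coupled_experiment
        assert t.loc[t.correct == 1, "rt_s"].notna().all()
        assert t.loc[t.correct == 0, "rt_s"].isna().all()

    def test_planted_coupling_recovered(self, coupled_experiment):
        from apertrack.stats import tracking_beta
        betas = [tracking_beta(sub, "auditory").beta
                 for _, sub in coupled_experiment.groupby("subject")]
        assert np.mean(betas) == pytest.approx(0.3, abs=0.05)

    def test_full_fidelity_tier_roundtrip(self):
        gen = EEGGenParams(b_aud=0.0, b_vis=0.0, noise_sd=0.05, subject_sd=0.0)
        t = simulate_experiment(1, n_blocks=2, trials_per_block=6, gen=gen,
                                electrodes=("Cz",), fidelity="full", seed=2)
        # estimated exponents cluster near the generator's base exponent
        assert t["exp_Cz"].mean() == pytest.approx(gen.base_exponent, abs=0.2)


class TestGenSpectralEEG:
    def test_mixture_recovery(self):
        x = gen_spectral_eeg(2.0, 1.0, [(10, 0.5, 1.5)], 0.0, 60, 250, seed=0)
        fit = parameterize(welch_psd(x, 250, 0.5), PRESETS["eeg_trial"])
        assert fit.exponent == pytest.approx(2.0, abs=0.1)
        assert any(abs(p.center_hz - 10) <= 0.5 for p in fit.peaks)

    def test_flat_when_exponent_zero(self):
        x = gen_spectral_eeg(0.0, 1.0, [], 0.0, 60, 250, seed=1)
        fit = parameterize(welch_psd(x, 250, 0.5), PRESETS["eeg_trial"])
        assert abs(fit.exponent) < 0.1

    def test_determinism_and_errors(self):
        a = gen_spectral_eeg(1.0, 0.0, [], 0.1, 5, 250, seed=7)
        b = gen_spectral_eeg(1.0, 0.0, [], 0.1, 5, 250, seed=7)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            gen_spectral_eeg(-1.0, 0.0, [], 0.0, 5, 250)
        with pytest.raises(ValueError):
            gen_spectral_eeg(1.0, 0.0, [], 0.0, 0.5, 250)


class TestEnvelopeOnsets:
    def test_constant_signal_gives_zeros(self):
        out = envelope_onsets(np.ones(5000), 1000.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        out = envelope_onsets(rng.standard_normal(8000), 1000.0)
        assert (out >= 0).all()

    def test_step_produces_bump_at_step_time(self):
        fs, t0 = 1000.0, 2.0
        t = np.arange(0, 4, 1 / fs)
        x = np.sin(2 * np.pi * 300 * t) * np.where(t < t0, 0.2, 1.0)
        out = envelope_onsets(x, fs)
        peak_t = np.argmax(out) / 250.0
        assert abs(peak_t - t0) <= 0.008


class TestEstimateTRF:
    fs = 250.0

    def _onset_trains(self, n_trials, n=800, seed=0):
        rng = np.random.default_rng(seed)
        return [np.clip(rng.normal(0, 1, n), 0, None) * (rng.random(n) < 0.05)
                for _ in range(n_trials)]

    def test_kernel_recovery(self):
        kern = canonical_trf(self.fs)
        ons = self._onset_trains(25)
        eeg = trf_forward_simulate(
            {"auditory": kern},
            [{"onsets_aud": o, "onsets_vis": np.zeros_like(o), "attention": "auditory"}
             for o in ons], noise_sd=0.1, seed=1)
        est, _ = estimate_trf(ons, eeg, self.fs)
        r = np.corrcoef(est.weights, kern.weights)[0, 1]
        assert r > 0.9

    def test_noise_eeg_reconstructs_nothing(self):
        rng = np.random.default_rng(5)
        ons = self._onset_trains(50, seed=6)
        noise = [rng.standard_normal(800) for _ in range(50)]
        _, cv = estimate_trf(ons, noise, self.fs)
        assert abs(cv) < 0.1

    def test_lambda_grid_and_singularity(self):
        assert np.allclose(np.logspace(-3, 3, 7)[[0, -1]], [1e-3, 1e3])
        ons = [np.zeros(500), np.zeros(500)]
        eeg = [np.random.default_rng(0).standard_normal(500) for _ in range(2)]
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            estimate_trf(ons, eeg, self.fs, lambdas=[0.0])

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            estimate_trf([np.zeros(100)], [np.zeros(100)], self.fs)


class TestLOSOReconstruction:
    fs = 250.0

    def _subject(self, kern, seed, n_trials=15, strong=True):
        rng = np.random.default_rng(seed)
        ons = [np.clip(rng.normal(0, 1, 800), 0, None) * (rng.random(800) < 0.05)
               for _ in range(n_trials)]
        eeg = trf_forward_simulate(
            {"auditory": kern},
            [{"onsets_aud": o, "onsets_vis": np.zeros_like(o), "attention": "auditory"}
             for o in ons], noise_sd=0.3 if strong else 5.0, seed=seed)
        bk, _ = estimate_trf(ons, eeg, self.fs, mode="backward")
        return bk, eeg, ons

    def test_strong_coupling_all_subjects_significant(self):
        kern = canonical_trf(self.fs)
        subs = [self._subject(kern, s) for s in range(3)]
        df = reconstruct_stimulus_loso([s[0] for s in subs], [s[1] for s in subs],
                                       [s[2] for s in subs], self.fs)
        assert len(df) == 3
        assert (df["p"] < 0.05).all() and (df["t"] > 0).all()

    def test_shuffled_pairing_kills_reconstruction(self):
        kern = canonical_trf(self.fs)
        subs = [self._subject(kern, s + 10) for s in range(2)]
        shuffled = [s[2][1:] + s[2][:1] for s in subs]
        df = reconstruct_stimulus_loso([s[0] for s in subs], [s[1] for s in subs],
                                       shuffled, self.fs)
        assert np.abs(df["mean_r"]).max() < 0.1

    def test_single_subject_rejected(self):
        kern = canonical_trf(self.fs)
        with pytest.raises(ValueError):
            reconstruct_stimulus_loso([kern], [[]], [[]], self.fs)


class TestForwardSimulation:
    fs = 250.0

    def test_impulse_reproduces_kernel(self):
        kern = canonical_trf(self.fs)
        onset = np.zeros(500)
        onset[100] = 1.0
        eeg = trf_forward_simulate(
            {"auditory": kern},
            [{"onsets_aud": onset, "onsets_vis": np.zeros(500), "attention": "auditory"}],
            noise_sd=0.0)[0]
        lag0 = int(round(-kern.lags_s[0] * self.fs))
        seg = eeg[100 - lag0: 100 - lag0 + kern.weights.size]
        np.testing.assert_allclose(seg, kern.weights, atol=1e-12)

    def test_determinism(self):
        kern = canonical_trf(self.fs)
        trials = [{"onsets_aud": np.random.default_rng(0).random(500),
                   "onsets_vis": np.zeros(500), "attention": "auditory"}]
        a = trf_forward_simulate({"auditory": kern}, trials, noise_sd=0.5, seed=3)
        b = trf_forward_simulate({"auditory": kern}, trials, noise_sd=0.5, seed=3)
        np.testing.assert_array_equal(a[0], b[0])


class TestBinExponentModel:
    def _planted(self, slope, n=400, seed=0):
        rng = np.random.default_rng(seed)
        chi = rng.uniform(0, 3, n)
        att = np.where(rng.random(n) < 0.5, "auditory", "visual")
        y = 1.5 + slope * chi + rng.normal(0, 0.3, n)
        return y, chi, att

    def test_report_fields_and_planted_trend(self):
        y, chi, att = self._planted(0.2)
        rep = bin_exponent_model(y, chi, att)
        assert set(rep.columns) == {"term", "beta", "se", "t", "p"}
        row = rep[rep.term == "stim_exponent_bin"].iloc[0]
        assert row.beta > 0 and row.p < 0.001

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(4)
        y, chi, att = self._planted(0.3, seed=2)
        ts = []
        for _ in range(50):
            perm = rng.permutation(len(y))
            rep = bin_exponent_model(y[perm], chi, att)
            ts.append(abs(rep[rep.term == "stim_exponent_bin"].iloc[0].t))
        assert np.median(ts) < 2

    def test_degenerate_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_exponent_model(np.ones(40), np.repeat([1.0, 2.0], 20),
                               np.repeat(["auditory", "visual"], 20))
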