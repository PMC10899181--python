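import numpy as np
import pytest
from scipy import signal as sp_signal
from scipy import stats

import reachbci as rb
from reachbci.paradigm import (ERROR_ONSET_RANGE_S, START_POSITIONS,
                               SynthConfig, TemplateSpec, build_schedule,
                               detect_saccade, generate_snake,
                               simulate_mrcp_epochs, simulate_tracking_eeg,
                               topography)
from reachbci.session import default_montage
from reachbci.trajectory import build_lag_matrix, fit_pls, pls_predict


class TestSnake:
    def test_duration_and_sampling(self):
        snake = generate_snake(0)
        assert snake.n_samples == 460
        assert snake.fs == 20.0

    def test_components_decorrelated(self):
        for seed in range(5):
            s = generate_snake(seed)
            assert abs(np.corrcoef(s.px, s.py)[0, 1]) < 0.1
            assert abs(np.corrcoef(s.vx, s.vy)[0, 1]) < 0.1

    def test_spectral_mass_in_band(self):
        # independent oracle: periodogram power fraction inside [0.15, 0.45] Hz
        s = generate_snake(3, duration_s=60.0)
        f, p = sp_signal.periodogram(s.px, fs=s.fs)
        inside = (f >= 0.15) & (f <= 0.45)
        assert p[inside].sum() / p[f > 0].sum() > 0.9

    def test_velocity_is_position_derivative(self):
        s = generate_snake(4)
        np.testing.assert_allclose(s.vx, np.gradient(s.px) * s.fs)

    def test_reproducible_and_unreachable_bound(self):
        a, b = generate_snake(7), generate_snake(7)
        np.testing.assert_array_equal(a.px, b.px)
        with pytest.raises(RuntimeError, match="attempts"):
            generate_snake(0, decorrelation_bound=1e-9, max_attempts=3)


class TestSchedule:
    def test_default_counts(self):
        sch = build_schedule(0)
        mov = sch.trials_of("movlook", "calibration")
        assert len(mov) == 72
        assert len(sch.trials_of("onlylook")) == 60
        assert sum(t.error for t in mov) == 22  # round(0.30 * 72)

    def test_counterbalanced_starts(self):
        sch = build_schedule(1)
        for run in sch.runs_of("movlook") + sch.runs_of("onlylook"):
            counts = {p: sum(t.start_pos == p for t in run.trials)
                      for p in START_POSITIONS}
            assert all(c == 3 for c in counts.values())

    def test_error_onsets_in_range(self):
        sch = build_schedule(2)
        for t in sch.trials_of("movlook"):
            if t.error:
                assert ERROR_ONSET_RANGE_S[0] <= t.error_onset_s <= ERROR_ONSET_RANGE_S[1]

    def test_bit_reproducible(self):
        a, b = build_schedule(5), build_schedule(5)
        ta = [(t.condition, t.start_pos, t.snake_seed, t.error, t.error_onset_s)
              for r in a.runs for t in r.trials]
        tb = [(t.condition, t.start_pos, t.snake_seed, t.error, t.error_onset_s)
              for r in b.runs for t in r.trials]
        assert ta == tb

    def test_online_alpha_schedule(self):
        sch = build_schedule(0)
        alphas = [r.alpha for r in sch.runs_of("movlook", "online")]
        assert alphas == [0.5, 0.5, 0.5, 1.0, 1.0, 1.0]

    def test_uncounterbalanceable_trials_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_schedule(0, trials_per_run=10)


def _noise_free_cfg(**kw):
    return SynthConfig(noise_scale_uv=0.0, eog_noise_uv=0.0, **kw)


class TestReachingTemplates:
    def test_movlook_negativity_peaks_100ms_before_saccade(self, montage):
        sch = build_schedule(3, n_movlook_runs=1, n_onlylook_runs=1,
                             n_online_runs=0, include_eyeblocks=False)
        runs = simulate_mrcp_epochs(_noise_free_cfg(eog_mix_scale=0.0), sch, 3)
        run = runs[[k for k in runs if "movlook" in k][0]]
        cz = montage.index("Cz")
        sacc = run.events_of("saccade")
        fs = run.fs
        for _, ev in sacc.iterrows():
            k = int(round(ev.onset * fs))
            seg = run.eeg[cz, k - 200:k + 200]
            t_min = (np.argmin(seg) - 200) / fs
            assert abs(t_min - (-0.1)) < 0.05

    def test_onlylook_has_no_motor_component(self, montage):
        sch = build_schedule(3, n_movlook_runs=1, n_onlylook_runs=1,
                             n_online_runs=0, include_eyeblocks=False)
        runs = simulate_mrcp_epochs(_noise_free_cfg(eog_mix_scale=0.0), sch, 3)
        mov = runs[[k for k in runs if "movlook" in k][0]]
        onl = runs[[k for k in runs if "onlylook" in k][0]]
        cz = default_montage().index("Cz")
        # motor negativity present only in movlook
        assert mov.eeg[cz].min() < -3.0
        assert onl.eeg[cz].min() > -3.0

    def test_condition_difference_recovers_template_under_noise(self, montage):
        cfg = SynthConfig()
        sch = build_schedule(4, n_movlook_runs=4, n_onlylook_runs=4,
                             n_online_runs=0, include_eyeblocks=False)
        runs = simulate_mrcp_epochs(cfg, sch, 4)
        cz = montage.index("Cz")
        fs = cfg.fs

        def epochs(keyword):
            out = []
            for name, run in runs.items():
                if keyword not in name:
                    continue
                for _, ev in run.events_of("saccade").iterrows():
                    k = int(round(ev.onset * fs))
                    out.append(run.eeg[cz, k - 100:k + 100])
            return np.asarray(out)

        mov, onl = epochs("movlook"), epochs("onlylook")
        assert len(mov) >= 40
        diff = mov.mean(axis=0) - onl.mean(axis=0)
        t = (np.arange(-100, 100)) / fs
        template = cfg.mrcp.amplitude_uv * np.exp(
            -0.5 * ((t - cfg.mrcp.latency_s) / cfg.mrcp.temporal_sigma_s) ** 2)
        sem = mov.std(axis=0).mean() / np.sqrt(len(mov)) * 2
        assert np.max(np.abs(diff - template)) < 4 * sem + 1.0


class TestErrpTemplates:
    def test_pe_and_ern_latencies(self, montage):
        cfg = _noise_free_cfg(eog_mix_scale=0.0)
        sch = build_schedule(5, n_movlook_runs=1, n_onlylook_runs=0,
                             n_online_runs=0, include_eyeblocks=False)
        runs = rb.simulate_session(cfg, sch, 5)
        run = runs[[k for k in runs if "movlook" in k][0]]
        fs = cfg.fs
        cpz, fcz = montage.index("CPz"), montage.index("FCz")
        errors = run.events_of("error_onset")
        assert len(errors)
        for _, ev in errors.iterrows():
            k = int(round(ev.onset * fs))
            seg_pe = run.eeg[cpz, k:k + 200]
            seg_ern = run.eeg[fcz, k:k + 200]
            assert abs(np.argmax(seg_pe) / fs - 0.44) < 0.05
            assert abs(np.argmin(seg_ern) / fs - 0.77) < 0.05

    def test_correct_trials_average_to_noise(self):
        cfg = SynthConfig()
        sch = build_schedule(6, n_movlook_runs=2, n_onlylook_runs=0,
                             n_online_runs=0, include_eyeblocks=False,
                             error_fraction=0.0)
        runs = rb.simulate_session(cfg, sch, 6)
        montage = default_montage()
        fcz = montage.index("FCz")
        epochs = []
        for run in runs.values():
            for _, ev in run.events_of("tracking_start").iterrows():
                k = int(round((ev.onset + 18.0) * cfg.fs))
                epochs.append(run.eeg[fcz, k:k + 100])
        epochs = np.asarray(epochs)
        grand = epochs.mean(axis=0)
        sem = epochs.std(axis=0, ddof=1) / np.sqrt(len(epochs))
        assert np.mean(np.abs(grand) < 3 * sem) > 0.9


class TestTrackingEncoding:
    def test_infinite_snr_decodes_nearly_perfectly(self, montage):
        cfg = SynthConfig(kin_snr=np.inf, noise_scale_uv=0.0)
        train, test = generate_snake(10, duration_s=120.0), generate_snake(11)
        keep = ~montage.is_af_row
        Xtr_raw, Ytr = simulate_tracking_eeg(cfg, train, 1, montage)
        Xte_raw, Yte = simulate_tracking_eeg(cfg, test, 2, montage)
        # decode at 20 Hz with the lag model
        Xtr = build_lag_matrix(Xtr_raw[keep][:, ::10])
        Xte = build_lag_matrix(Xte_raw[keep][:, ::10])
        W, b = fit_pls(Xtr, Ytr[:, ::10][:, 6:], n_components=30)
        pred = pls_predict(W, b, Xte)
        truth = Yte[:, ::10][:, 6:]
        for i in range(4):
            assert np.corrcoef(pred[i], truth[i])[0, 1] > 0.99

    def test_velocity_rows_are_position_derivatives(self):
        snake = generate_snake(12)
        _, kin = simulate_tracking_eeg(SynthConfig(), snake, 3)
        # the upsampled velocity rows match the upsampled position gradient
        # to within interpolation error
        v_est = np.gradient(kin[0]) * 200.0
        mask = slice(50, -50)
        assert np.corrcoef(v_est[mask], kin[2][mask])[0, 1] > 0.98

    def test_pure_noise_decodes_at_chance(self, montage):
        cfg = SynthConfig(kin_snr=0.0)
        snake = generate_snake(13, duration_s=60.0)
        keep = ~montage.is_af_row
        X_raw, Y = simulate_tracking_eeg(cfg, snake, 4, montage)
        X = build_lag_matrix(X_raw[keep][:, ::10])
        Y20 = Y[:, ::10][:, 6:]
        half = X.shape[1] // 2
        W, b = fit_pls(X[:, :half], Y20[:, :half], n_components=10)
        pred = pls_predict(W, b, X[:, half:])
        r = abs(np.corrcoef(pred[0], Y20[0, half:])[0, 1])
        assert r < 0.3


class TestSaccadeDetector:
    def _eog_with_step(self, n=1000, fs=200.0, amp=100.0, at=2.5):
        rng = np.random.default_rng(0)
        eog = 0.5 * rng.standard_normal((4, n))
        t = np.arange(n) / fs
        eog[0] += amp * (t >= at)
        return eog, fs

    def test_single_step_single_detection(self):
        eog, fs = self._eog_with_step()
        times = detect_saccade(eog, fs, threshold_mads=20)
        assert len(times) == 1
        assert abs(times[0] - 2.5) <= 2 / fs

    def test_flat_eog_no_detections(self):
        rng = np.random.default_rng(1)
        eog = 0.1 * rng.standard_normal((4, 2000))
        assert len(detect_saccade(eog, 200.0, threshold_mads=20)) == 0

    @pytest.mark.parametrize("gap,expected", [(1.0, 2), (0.2, 1)])
    def test_refractory_period(self, gap, expected):
        fs = 200.0
        n = int(6 * fs)
        rng = np.random.default_rng(2)
        eog = 0.5 * rng.standard_normal((4, n))
        t = np.arange(n) / fs
        eog[0] += 100.0 * ((t >= 2.0).astype(float) + (t >= 2.0 + gap))
        times = detect_saccade(eog, fs, threshold_mads=20)
        assert len(times) == expected

    def test_zero_mad_baseline_rejected(self):
        eog = np.zeros((4, 1000))
        eog[0, 500:] = 100.0
        with pytest.raises(ValueError, match="MAD"):
            detect_saccade(eog, 200.0)


class TestSessionRoundTrip:
    def test_simulated_session_roundtrips_losslessly(self, small_session, tmp_path):
        _, runs = small_session
        name = next(iter(runs))
        rb.save_session(tmp_path / "s.h5", {name: runs[name]})
        back = rb.load_session(tmp_path / "s.h5")[name]
        np.testing.assert_array_equal(back.eeg, runs[name].eeg)
        np.testing.assert_array_equal(back.eog, runs[name].eog)

    def test_template_latency_validation(self):
        with pytest.raises(ValueError, match="latency"):
            SynthConfig(pe=TemplateSpec(latency_s=2.0, amplitude_uv=5.0,
                                        center="CPz", temporal_sigma_s=0.08))

    def test_topography_peaks_at_center(self, montage):
        w = topography(montage, "Cz", 0.05)
        assert np.argmax(w) == montage.index("Cz")
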