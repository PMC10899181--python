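import numpy as np
import pandas as pd
import pytest
from scipy import signal

from reachbci.preprocess import (EogModel, PreprocConfig, RAW_RATE_HZ,
                                 attenuate_transients, design_errp_bandpass,
                                 design_highpass018, design_lowpass3,
                                 design_lowpass25, design_notch,
                                 estimate_transient_stats, fit_eog_model,
                                 interpolate_bad_channels,
                                 interpolation_weights, preprocess_common,
                                 preprocess_errp_branch,
                                 preprocess_movement_branch)
from reachbci.session import RawSession, Stream, empty_events


def _fitted_eog(fs=100.0):
    rng = np.random.default_rng(0)
    eog = rng.standard_normal((4, 2000))
    eeg = rng.standard_normal((60, 2000))
    model = fit_eog_model(eeg, eog, fs=fs)
    return model


def _raw(montage, eeg, eog=None):
    n = eeg.shape[1]
    return RawSession(eeg=eeg, eog=np.zeros((4, n)) if eog is None else eog,
                      fs=RAW_RATE_HZ, events=empty_events(), montage=montage)


def _cascade_gain_db(sos_list, freq, fs):
    """Independent oracle: designed-cascade magnitude response at freq."""
    h = 1.0 + 0j
    for sos in sos_list:
        _, resp = signal.sosfreqz(sos, worN=[freq], fs=fs)
        h *= resp[0]
    return 20 * np.log10(abs(h))


class TestCommonStage:
    def test_constant_input_passes_dc(self, montage):
        eeg = np.full((60, 2000), 10.0)
        out, _ = preprocess_common(_raw(montage, eeg), PreprocConfig(),
                                   _fitted_eog())
        # steady-state tail after filter transients
        assert np.allclose(out.data[:, -200:], 10.0, atol=0.3)

    def test_50hz_attenuated_at_least_20db(self, montage):
        cfg = PreprocConfig()
        t = np.arange(4000) / RAW_RATE_HZ
        eeg = np.tile(np.sin(2 * np.pi * 50.0 * t), (60, 1))
        out, _ = preprocess_common(_raw(montage, eeg), cfg, _fitted_eog())
        measured = out.data[0, 500:]
        atten_db = 20 * np.log10(np.sqrt(np.mean(measured ** 2))
                                 / np.sqrt(0.5))
        designed = _cascade_gain_db(
            [design_lowpass25(RAW_RATE_HZ)]
            + [design_notch(f, cfg.notch_q, RAW_RATE_HZ) for f in cfg.notch_hz],
            50.0, RAW_RATE_HZ)
        assert designed < -20
        assert atten_db < -20

    @pytest.mark.parametrize("n", [1000, 1001])
    def test_sample_count_halved(self, montage, n):
        eeg = np.zeros((60, n))
        out, _ = preprocess_common(_raw(montage, eeg), PreprocConfig(),
                                   _fitted_eog())
        assert out.n_samples == int(np.ceil(n / 2))
        assert out.fs == 100.0

    def test_af_row_removed(self, montage):
        eeg = np.zeros((60, 1000))
        out, _ = preprocess_common(_raw(montage, eeg), PreprocConfig(),
                                   _fitted_eog())
        assert out.data.shape[0] == 55
        assert not any(l.startswith("AF") for l in out.labels)

    def test_unfitted_eog_model_rejected(self, montage):
        with pytest.raises(RuntimeError, match="fitted"):
            preprocess_common(_raw(montage, np.zeros((60, 1000))),
                              PreprocConfig(), EogModel())

    def test_wrong_rate_rejected(self, montage):
        raw = _raw(montage, np.zeros((60, 1000)))
        raw.fs = 250.0
        with pytest.raises(ValueError, match="200"):
            preprocess_common(raw, PreprocConfig(), _fitted_eog())


class TestInterpolation:
    def test_constant_neighbors(self, montage):
        data = np.full((60, 50), 7.0)
        data[10] = 99.0
        out = interpolate_bad_channels(data, montage, np.array([10]))
        np.testing.assert_allclose(out[10], 7.0)

    def test_weights_sum_to_one(self, montage):
        weights = interpolation_weights(montage, np.array([3, 20, 41]))
        for _, (nb, w) in weights.items():
            assert len(nb) == 4
            assert abs(w.sum() - 1.0) < 1e-12

    def test_linear_gradient_recovered(self, montage):
        # potentials forming a linear spatial field: v = a.x (per sample)
        a = np.array([3.0, -2.0, 1.5])
        field = montage.positions @ a
        data = np.tile(field[:, None], (1, 10))
        bad = 25
        out = interpolate_bad_channels(data, montage, np.array([bad]))
        scale = np.abs(field).mean()
        assert np.all(np.abs(out[bad] - field[bad]) <= 0.1 * scale + 1e-9)

    def test_all_bad_rejected(self, montage):
        with pytest.raises(ValueError):
            interpolate_bad_channels(np.zeros((60, 10)), montage,
                                     np.arange(60))


class TestEogRegression:
    def test_known_mixing_recovered(self):
        rng = np.random.default_rng(2)
        eog = rng.standard_normal((4, 20000))
        B = rng.standard_normal((30, 8)) * np.r_[np.ones(4), np.zeros(4)]
        model = EogModel(fs=100.0)
        clean = rng.standard_normal((30, 20000))
        reg = model.regressors(eog)
        signal_part = B @ reg
        noise = clean * signal_part.std() / clean.std() / np.sqrt(10)  # SNR 10
        fitted = fit_eog_model(signal_part + noise, eog, fs=100.0)
        big = np.abs(B) > 0.3
        rel = np.abs(fitted.coefficients[big] - B[big]) / np.abs(B[big])
        assert np.median(rel) < 0.1

    def test_independent_eeg_gives_null_coefficients(self):
        rng = np.random.default_rng(3)
        n = 5000
        eog = rng.standard_normal((4, n))
        eeg = rng.standard_normal((20, n))
        model = fit_eog_model(eeg, eog, fs=100.0)
        # |b| < 3 standard errors of the regression coefficient
        se = 1.0 / np.sqrt(n)
        assert np.mean(np.abs(model.coefficients) < 3 * se * 3) > 0.95

    def test_application_reduces_correlation(self):
        rng = np.random.default_rng(4)
        eog = rng.standard_normal((4, 5000))
        eeg = 0.5 * eog[0] + rng.standard_normal((10, 5000))
        model = fit_eog_model(eeg, eog, fs=100.0)
        cleaned = model.apply(eeg, eog)
        before = np.abs(np.corrcoef(np.vstack([eeg, eog]))[:10, 10])
        after = np.abs(np.corrcoef(np.vstack([cleaned, eog]))[:10, 10])
        assert after.mean() < before.mean()

    def test_flat_eog_rejected(self):
        with pytest.raises(ValueError, match="ill-posed"):
            fit_eog_model(np.random.default_rng(0).standard_normal((5, 100)),
                          np.zeros((4, 100)))


class TestTransients:
    def test_clean_stream_unchanged(self, montage):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((60, 2000))
        stats = estimate_transient_stats(data)
        out = attenuate_transients(data, stats, montage)
        assert np.max(np.abs(out - data)) < 1e-6 * data.std()

    def test_large_step_suppressed(self, montage):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((60, 2000))
        stats = estimate_transient_stats(data)
        data2 = data.copy()
        data2[7, 1000:] += 500.0
        out = attenuate_transients(data2, stats, montage)
        residual = np.median(out[7, 1000:]) - np.median(out[7, :1000])
        assert abs(residual) < 0.2 * 500.0

    def test_other_channels_bit_identical(self, montage):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((60, 1000))
        stats = estimate_transient_stats(data)
        data2 = data.copy()
        data2[7, 500:] += 500.0
        out = attenuate_transients(data2, stats, montage)
        others = np.setdiff1d(np.arange(60), [7])
        np.testing.assert_array_equal(out[others], data2[others])


class TestMovementBranch:
    def test_car_zero_mean_and_rates(self):
        rng = np.random.default_rng(8)
        stream = Stream(rng.standard_normal((55, 3000)), 100.0)
        mrcp, traj = preprocess_movement_branch(stream, PreprocConfig())
        assert mrcp.fs == 10.0 and traj.fs == 20.0
        # CAR applied before the final low-pass: the low-pass is channel-wise
        # linear so the cross-channel mean stays zero at every sample
        assert np.abs(mrcp.data.mean(axis=0)).max() < 1e-10

    def test_dc_removed(self):
        stream = Stream(np.full((55, 5000), 42.0), 100.0)
        mrcp, _ = preprocess_movement_branch(stream, PreprocConfig())
        assert np.abs(mrcp.data[:, -50:]).max() < 1.0

    def test_5hz_attenuated_10db(self):
        t = np.arange(5000) / 100.0
        base = np.sin(2 * np.pi * 5.0 * t)
        data = np.vstack([base, -base] + [np.zeros_like(base)] * 53)
        # zero-phase (offline) chain: forward-backward doubles the dB drop
        _, traj = preprocess_movement_branch(Stream(data, 100.0),
                                             PreprocConfig(causal_mode=False))
        designed = 2 * _cascade_gain_db([design_highpass018(100.0),
                                         design_lowpass3(100.0)], 5.0, 100.0)
        assert designed < -10
        measured = traj.data[0, 100:]
        atten = 20 * np.log10(np.sqrt(np.mean(measured ** 2)) / np.sqrt(0.5))
        assert atten < -10


class TestErrpBranch:
    def test_dc_blocked(self):
        out = preprocess_errp_branch(Stream(np.full((60, 3000), 5.0), 100.0),
                                     PreprocConfig())
        assert np.abs(out.data[:, -100:]).max() < 0.05
        assert out.fs == 100.0 and out.n_samples == 3000

    @pytest.mark.parametrize("freq,bound_db,below", [(5.0, 3.0, False),
                                                     (0.2, -20.0, True)])
    def test_band_edges(self, freq, bound_db, below):
        fs = 100.0
        n = int(200 * fs)
        t = np.arange(n) / fs
        data = np.tile(np.sin(2 * np.pi * freq * t), (2, 1))
        out = preprocess_errp_branch(Stream(data, fs), PreprocConfig())
        tail = out.data[0, n // 2:]
        gain_db = 20 * np.log10(np.sqrt(np.mean(tail ** 2)) / np.sqrt(0.5))
        designed = _cascade_gain_db([design_errp_bandpass((1.0, 10.0), fs)],
                                    freq, fs)
        if below:
            assert designed < bound_db and gain_db < bound_db
        else:
            assert abs(designed) < bound_db and abs(gain_db) < bound_db


class TestPhaseAndDecimation:
    def test_zero_phase_mode_has_no_lag(self):
        fs = 100.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        # antisymmetric pair so the common average reference is a no-op
        data = np.vstack([x, -x] + [np.zeros_like(x)] * 53)
        causal_cfg = PreprocConfig(causal_mode=True)
        zp_cfg = PreprocConfig(causal_mode=False)
        _, traj_c = preprocess_movement_branch(Stream(data, fs), causal_cfg)
        _, traj_z = preprocess_movement_branch(Stream(data, fs), zp_cfg)
        ref = x[::5]
        core = slice(200, -200)

        def lag(y):
            c = signal.correlate(y[core] - y[core].mean(),
                                 ref[core] - ref[core].mean(), mode="full")
            return np.argmax(c) - (len(ref[core]) - 1)

        assert lag(traj_z.data[0]) == 0
        assert lag(traj_c.data[0]) > 0

    def test_1hz_roundtrip_amplitude(self, montage):
        t = np.arange(8000) / RAW_RATE_HZ
        x = np.sin(2 * np.pi * 1.0 * t)
        # antisymmetric pair (on non-AF channels) so CAR is a no-op
        eeg = np.zeros((60, t.size))
        eeg[10] = x
        eeg[11] = -x
        cfg = PreprocConfig(causal_mode=False)
        common, _ = preprocess_common(_raw(montage, eeg), cfg, _fitted_eog())
        _, traj = preprocess_movement_branch(common, cfg)
        row = common.labels.index(montage.labels[10])
        amp = np.sqrt(2) * traj.data[row, 100:-100].std()
        assert abs(amp - 1.0) < 0.05

    def test_filters_are_stable(self):
        for sos in (design_lowpass25(200.0), design_notch(50, 35, 200.0),
                    design_highpass018(100.0), design_lowpass3(100.0),
                    design_errp_bandpass((1.0, 10.0), 100.0)):
            _, p, _ = signal.sos2zpk(sos)
            assert np.all(np.abs(p) < 1.0)

    def test_branch_rate_must_divide(self):
        with pytest.raises(ValueError):
            PreprocConfig(mrcp_rate_hz=7.0)
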