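import numpy as np
import pytest
from scipy import signal as sp_signal

import gaitsurf as g
from gaitsurf.core import Site, Surface
from gaitsurf.preprocess import (
    NotFittedError,
    ScalerState,
    TooShortTrialError,
    UnrepairableChannelError,
    apply_scaler,
    butterworth_lowpass,
    drop_unusable,
    fill_missing,
    fit_scaler,
    segment_matrix,
    segment_trial,
)

from conftest import quiet_config


def _sine(freq, n=2000, fs=100.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


def _filter_gain(freq, fs=100.0, cutoff=6.0, order=2, passes=2):
    """Independent oracle: magnitude of the digital filter response at freq."""
    sos = sp_signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    _w, h = sp_signal.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** passes


class TestButterworth:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        assert np.allclose(butterworth_lowpass(x), x, atol=1e-9)

    @pytest.mark.parametrize("freq, comparator", [(20.0, "stop"), (0.5, "pass")])
    def test_band_gains_match_frequency_response(self, freq, comparator):
        x = _sine(freq)
        y = butterworth_lowpass(x)
        ratio = np.sqrt(np.mean(y[200:-200] ** 2) / np.mean(x[200:-200] ** 2))
        expected = _filter_gain(freq)
        assert ratio == pytest.approx(expected, rel=0.05)
        if comparator == "stop":
            assert ratio < 0.05
        else:
            assert ratio > 0.99

    def test_passband_idempotence(self):
        x = _sine(0.5)
        once = butterworth_lowpass(x)
        twice = butterworth_lowpass(once)
        rms = lambda a: np.sqrt(np.mean(a[200:-200] ** 2))
        assert abs(rms(twice) - rms(once)) / rms(once) < 0.01

    def test_single_pass_variant_has_phase_lag(self):
        x = _sine(2.0)
        causal = butterworth_lowpass(x, zero_phase=False)
        zero = butterworth_lowpass(x, zero_phase=True)
        # zero-phase output stays aligned with the input; causal lags
        assert np.corrcoef(x[200:-200], zero[200:-200])[0, 1] > 0.999
        assert np.corrcoef(x[200:-200], causal[200:-200])[0, 1] < 0.999

    def test_too_short_series_rejected(self):
        with pytest.raises(TooShortTrialError):
            butterworth_lowpass(np.zeros(4))

    def test_nan_spans_left_in_place(self):
        x = _sine(1.0, n=400)
        x[100:150] = np.nan
        y = butterworth_lowpass(x)
        assert np.isnan(y[100:150]).all()
        assert np.isfinite(y[:100]).all() and np.isfinite(y[150:]).all()


class TestFillMissing:
    def test_forward_fill(self):
        out = fill_missing(np.array([1.0, np.nan, 3.0]))
        assert out.tolist() == [1.0, 1.0, 3.0]

    def test_leading_run_takes_subsequent_value(self):
        out = fill_missing(np.array([np.nan, np.nan, 2.0]))
        assert out.tolist() == [2.0, 2.0, 2.0]

    def test_no_missing_is_identity(self):
        x = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(fill_missing(x), x)

    def test_entirely_missing_channel_signals_unrepairable(self):
        x = np.ones((5, 2))
        x[:, 1] = np.nan
        with pytest.raises(UnrepairableChannelError):
            fill_missing(x)


class TestDropUnusable:
    def test_missing_required_sensor_drops_trials(self):
        cfg = quiet_config(n_participants=2, trials_per_condition=2,
                           missing_sensor_trials=14)
        # 36 trials, 14 with thighL missing
        ds = g.simulate_cohort(cfg)
        kept, dropped = drop_unusable(ds, [Site.thighL])
        assert len(dropped) == 14
        assert len(kept) == len(ds) - 14

    def test_unused_sensor_missing_causes_no_drops(self):
        cfg = quiet_config(n_participants=1, trials_per_condition=2,
                           missing_sensor_trials=5)
        ds = g.simulate_cohort(cfg)
        kept, dropped = drop_unusable(ds, [Site.shankL, Site.shankR])
        assert dropped == []
        assert len(kept) == len(ds)

    def test_empty_dataset_passes_through(self):
        kept, dropped = drop_unusable(g.GaitDataset(trials=[]), [Site.trunk])
        assert len(kept) == 0 and dropped == []


class TestSegmentation:
    @pytest.mark.parametrize("n, L, expected", [
        (1640, 400, 4), (1640, 500, 3), (99, 100, 0), (400, 400, 1)])
    def test_floor_window_counts(self, n, L, expected):
        windows = segment_matrix(np.zeros((n, 3)), L)
        assert windows.shape[0] == expected

    def test_windows_are_consecutive_disjoint_from_zero(self):
        x = np.arange(10.0)[:, None]
        w = segment_matrix(x, 3)
        assert w[:, :, 0].tolist() == [[0, 1, 2], [3, 4, 5], [6, 7, 8]]

    def test_segment_trial_stacks_present_sensors(self, quiet_trial):
        windows = segment_trial(quiet_trial, 100)
        assert windows[0].shape == (100, 6 * 22)
        assert len(windows) == quiet_trial.n_samples // 100


class TestScaler:
    def _set(self, X, sources=None):
        n = X.shape[0]
        layout = [("Acc", Site.trunk, f"c{i}") for i in range(X.shape[2])]
        return g.SegmentSet(
            X=X.astype(np.float32),
            y=np.zeros(n, dtype=np.int64),
            sources=sources or [(1, Surface.FE, 1)] * n,
            window_ordinals=np.arange(n),
            channel_layout=layout,
            window_length=X.shape[1],
        )

    def test_midpoint_maps_to_half(self):
        X = np.array([[[-2.0], [2.0], [0.0]]])
        out = apply_scaler(fit_scaler(self._set(X)), self._set(X))
        assert out.X[0, 2, 0] == pytest.approx(0.5)

    def test_out_of_range_test_value_not_clipped(self):
        train = self._set(np.array([[[-2.0], [2.0]]]))
        state = fit_scaler(train)
        test = self._set(np.array([[[3.0], [0.0]]]))
        out = apply_scaler(state, test)
        assert out.X[0, 0, 0] == pytest.approx(1.25)

    def test_training_data_lands_in_unit_interval(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 5, size=(20, 7, 4))
        out = apply_scaler(fit_scaler(self._set(X)), self._set(X))
        assert out.X.min() >= 0.0 and out.X.max() <= 1.0

    def test_constant_channel_maps_to_zero(self):
        X = np.full((3, 5, 1), 7.0)
        out = apply_scaler(fit_scaler(self._set(X)), self._set(X))
        assert np.all(out.X == 0.0)

    def test_unfitted_state_rejected(self):
        with pytest.raises(NotFittedError):
            apply_scaler(None, self._set(np.zeros((1, 2, 1))))

    def test_provenance_records_training_trials_only(self):
        train = self._set(np.zeros((2, 3, 1)), sources=[(1, Surface.FE, 1)] * 2)
        state = fit_scaler(train)
        assert state.fitted_from == {(1, Surface.FE, 1)}
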