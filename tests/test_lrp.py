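"""Filtering, artifact rejection, LRP computation and scalar measures."""

import numpy as np
import pandas as pd
import pytest

from lrpddm.lrp import (EEGEpochs, LRPWaveform, area_between, compute_lrp,
                        grand_average, lowpass, neural_t0, onset_1df,
                        peak_measures, reject_artifacts)

from conftest import make_epochs

SFREQ = 250.0


def sine_epochs(freq_hz: float, amp: float = 10.0, n_samp: int = 1000):
    t = np.arange(n_samp) / SFREQ
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(sig, (2, 3, 1))
    return make_epochs(data, sfreq=SFREQ, tmin_ms=0.0)


class TestLowpass:
    def test_slow_component_passes(self):
        out = lowpass(sine_epochs(1.0), cutoff_hz=4.0)
        mid = slice(250, 750)  # avoid filter edges
        ratio = out.data[0, 0, mid].std() / sine_epochs(1.0).data[0, 0, mid].std()
        assert ratio > 0.99

    def test_fast_component_attenuated(self):
        out = lowpass(sine_epochs(20.0), cutoff_hz=4.0)
        mid = slice(250, 750)
        ratio = out.data[0, 0, mid].std() / sine_epochs(20.0).data[0, 0, mid].std()
        assert ratio < 0.10

    def test_dc_preserved(self):
        epochs = make_epochs(np.full((1, 3, 500), 7.0), tmin_ms=0.0)
        out = lowpass(epochs, cutoff_hz=4.0)
        assert np.allclose(out.data, 7.0, atol=1e-9)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(sine_epochs(1.0), cutoff_hz=200.0)


class TestRejectArtifacts:
    def _clean_data(self, rng, n_trials=6, n_samp=500):
        # modest white noise: comfortably inside every threshold
        return 3.0 * rng.standard_normal((n_trials, 3, n_samp))

    def test_clean_trials_survive(self):
        rng = np.random.default_rng(0)
        epochs = make_epochs(self._clean_data(rng), tmin_ms=0.0)
        kept, report = reject_artifacts(epochs)
        assert report.n_rejected == 0
        assert kept.n_trials == epochs.n_trials

    def test_blink_rule_flags_exactly_that_trial(self):
        rng = np.random.default_rng(1)
        data = self._clean_data(rng)
        bump = 120.0 * np.exp(-0.5 * ((np.arange(500) - 250) / 12.0) ** 2)
        data[2, 2, :] += bump  # EOG channel
        kept, report = reject_artifacts(make_epochs(data, tmin_ms=0.0))
        assert report.by_rule["blink"] == [2]
        assert list(report.rejected) == [2]

    def test_flat_trial_caught_by_low_variance(self):
        rng = np.random.default_rng(2)
        data = self._clean_data(rng)
        data[4, 0, :] = 0.0
        kept, report = reject_artifacts(make_epochs(data, tmin_ms=0.0))
        assert report.by_rule["variance_low"] == [4]

    def test_all_rejected_is_an_error(self):
        data = np.zeros((3, 3, 500))
        with pytest.raises(ValueError, match="every trial"):
            reject_artifacts(make_epochs(data, tmin_ms=0.0))


class TestComputeLRP:
    def _epochs_with_template(self, template, hand, n_trials=8, n_samp=500,
                              tmin_ms=-200.0):
        data = np.zeros((n_trials, 3, n_samp))
        for i in range(n_trials):
            sign = 1.0 if hand[i] == "left" else -1.0
            data[i, 1] += sign * template / 2.0   # C4
            data[i, 0] -= sign * template / 2.0   # C3
        return make_epochs(data, sfreq=SFREQ, hand=hand, tmin_ms=tmin_ms)

    def test_identical_channels_give_flat_zero(self):
        rng = np.random.default_rng(3)
        same = rng.standard_normal((5, 1, 400))
        data = np.concatenate([same, same,
                               rng.standard_normal((5, 1, 400))], axis=1)
        lrp = compute_lrp(make_epochs(data, tmin_ms=-200.0), "stimulus",
                          window=(-200.0, 1000.0))
        assert np.allclose(lrp.amplitude_uv, 0.0, atol=1e-12)

    def test_template_recovered_for_left_hand_trials(self):
        n_samp = 500
        t = -200.0 + np.arange(n_samp) * 1000.0 / SFREQ
        template = np.where((t > 100) & (t < 500),
                            3.0 * np.sin(np.pi * (t - 100) / 400.0), 0.0)
        epochs = self._epochs_with_template(template, ["left"] * 8,
                                            n_samp=n_samp)
        lrp = compute_lrp(epochs, "stimulus", window=(-200.0, 1200.0))
        recovered = np.interp(t, lrp.time_ms, lrp.amplitude_uv)
        assert np.allclose(recovered, template, atol=1e-9)

    def test_hand_swap_flips_sign_exactly(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 3, 500))
        hands = np.array(["left", "right"] * 5)
        e1 = make_epochs(data, hand=hands, tmin_ms=-200.0)
        e2 = make_epochs(data, hand=np.where(hands == "left", "right",
                                             "left"), tmin_ms=-200.0)
        l1 = compute_lrp(e1, "stimulus", window=(-200.0, 1000.0))
        l2 = compute_lrp(e2, "stimulus", window=(-200.0, 1000.0))
        assert np.array_equal(l1.amplitude_uv, -l2.amplitude_uv)

    def test_baseline_window_mean_is_zero(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((1, 3, 500)) + 5.0
        lrp = compute_lrp(make_epochs(data, tmin_ms=-200.0), "stimulus",
                          window=(-200.0, 1000.0))
        bl = (lrp.time_ms >= -200.0) & (lrp.time_ms <= 0.0)
        assert abs(lrp.amplitude_uv[bl].mean()) < 1e-12

    def test_incorrect_trials_are_excluded(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((6, 3, 500))
        epochs = make_epochs(data, correct=[True, False] * 3, tmin_ms=-200.0)
        lrp = compute_lrp(epochs, "stimulus", window=(-200.0, 1000.0))
        assert lrp.n == 3

    def test_grand_average_is_unweighted_mean(self):
        t = np.arange(0.0, 100.0, 4.0)
        w1 = LRPWaveform("response", t, np.ones_like(t), n=10)
        w2 = LRPWaveform("response", t, 3.0 * np.ones_like(t), n=1000)
        ga = grand_average([w1, w2])
        assert np.allclose(ga.amplitude_uv, 2.0)


class TestOnset1DF:
    def _wave(self, y, dt=4.0, t0=-100.0):
        t = t0 + np.arange(len(y)) * dt
        return LRPWaveform("stimulus", t, np.asarray(y, float), n=10)

    def test_exact_piecewise_linear_recovered(self):
        t = -100.0 + np.arange(200) * 4.0
        y = np.where(t < 300.0, 0.0, 0.01 * (t - 300.0))
        assert onset_1df(self._wave(y), (-100.0, 696.0)) == pytest.approx(
            300.0, abs=1e-9)

    def test_noisy_ramp_median_within_one_sample(self):
        """SNR 10 ramp: the onset estimate is median-unbiased to within one
        sample over 100 seeded replicates."""
        rng = np.random.default_rng(42)
        t = -100.0 + np.arange(200) * 4.0
        clean = np.where(t < 300.0, 0.0, 0.01 * (t - 300.0))
        scale = clean.max() / 10.0
        estimates = [
            onset_1df(self._wave(clean + scale * rng.standard_normal(len(t))),
                      (-100.0, 696.0))
            for _ in range(100)
        ]
        assert abs(np.median(estimates) - 300.0) <= 4.0

    def test_flat_input_reports_no_rise(self):
        with pytest.raises(ValueError, match="no rise"):
            onset_1df(self._wave(np.zeros(100)), (-100.0, 295.0))


class TestPeakMeasures:
    def _resp_wave(self, y, dt=4.0):
        t = -600.0 + np.arange(len(y)) * dt
        return LRPWaveform("response", t, np.asarray(y, float), n=10)

    def test_single_bump_latency_and_height(self):
        t = -600.0 + np.arange(200) * 4.0
        y = 2.0 * np.exp(-0.5 * ((t + 90.0) / 40.0) ** 2)
        lat, height = peak_measures(self._resp_wave(y))
        assert lat == pytest.approx(-90.0, abs=4.0)
        assert height == pytest.approx(2.0, abs=0.05)

    def test_last_peak_before_response_wins(self):
        t = -600.0 + np.arange(200) * 4.0
        y = (1.0 * np.exp(-0.5 * ((t + 400.0) / 30.0) ** 2)
             + 2.0 * np.exp(-0.5 * ((t + 100.0) / 30.0) ** 2))
        lat, _ = peak_measures(self._resp_wave(y))
        assert lat == pytest.approx(-100.0, abs=4.0)

    def test_height_invariant_to_constant_offset(self):
        t = -600.0 + np.arange(200) * 4.0
        y = 2.0 * np.exp(-0.5 * ((t + 90.0) / 40.0) ** 2)
        _, h0 = peak_measures(self._resp_wave(y))
        _, h1 = peak_measures(self._resp_wave(y + 11.0))
        assert h1 == pytest.approx(h0, abs=1e-12)

    def test_no_peak_raises(self):
        t = -600.0 + np.arange(100) * 4.0
        y = 0.001 * t  # monotone, no local max before 0
        with pytest.raises(ValueError):
            peak_measures(self._resp_wave(y))


class TestAreaAndNeuralT0:
    def test_identical_curves_area_zero(self):
        t = -600.0 + np.arange(200) * 4.0
        w = LRPWaveform("response", t, np.sin(t / 100.0), n=5)
        assert area_between(w, w, (-250.0, -150.0)) == 0.0

    def test_constant_offset_area_analytic(self):
        t = -600.0 + np.arange(200) * 4.0
        w1 = LRPWaveform("response", t, np.full_like(t, 1.5), n=5)
        w2 = LRPWaveform("response", t, np.zeros_like(t), n=5)
        assert area_between(w1, w2, (-250.0, -150.0)) == pytest.approx(
            1.5 * 100.0, rel=1e-9)

    def test_window_outside_overlap_raises(self):
        t = np.arange(0.0, 100.0, 4.0)
        w = LRPWaveform("response", t, np.zeros_like(t), n=5)
        with pytest.raises(ValueError):
            area_between(w, w, (-50.0, 50.0))

    def test_neural_t0_is_onset_plus_peak_distance(self):
        ts = -100.0 + np.arange(200) * 4.0
        ys = np.where(ts < 200.0, 0.0, 0.01 * (ts - 200.0))
        stim = LRPWaveform("stimulus", ts, ys, n=10)
        tr = -600.0 + np.arange(200) * 4.0
        yr = 2.0 * np.exp(-0.5 * ((tr + 90.0) / 40.0) ** 2)
        resp = LRPWaveform("response", tr, yr, n=10)
        est = neural_t0(stim, resp, (-100.0, 500.0))
        assert est == pytest.approx(200.0 + 90.0, abs=6.0)


class TestEpochsContainer:
    def test_hdf5_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        epochs = make_epochs(rng.standard_normal((4, 3, 300)), tmin_ms=-200.0)
        path = tmp_path / "epochs.h5"
        epochs.save(path)
        back = EEGEpochs.load(path)
        assert np.array_equal(back.data, epochs.data)
        assert back.ch_names == epochs.ch_names
        assert back.sfreq == epochs.sfreq
        pd.testing.assert_frame_equal(
            back.trials, epochs.trials, check_dtype=False)

    def test_missing_required_channel_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="C4"):
            EEGEpochs(data=rng.standard_normal((2, 2, 100)), sfreq=250.0,
                      ch_names=["C3", "EOG"], tmin_ms=0.0,
                      trials=pd.DataFrame({
                          "stim_ms": [0.0, 0.0], "resp_ms": [100.0, 100.0],
                          "hand": ["left", "left"], "condition": ["c", "c"],
                          "correct": [True, True]}))

    def test_event_outside_epoch_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="resp_ms"):
            make_epochs(rng.standard_normal((2, 3, 100)), tmin_ms=0.0,
                        resp_ms=[100.0, 10_000.0])
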