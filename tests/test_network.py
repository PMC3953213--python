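"""Bistable switch units, three-layer dynamics, and layer-shape comparison."""

from dataclasses import replace

import numpy as np
import pytest

from lrpddm.ddm import choice_probability
from lrpddm.fitting import FitDesign, fit
from lrpddm.network import (NetworkParams, layer_average, rmsd_layer_fit,
                            simulate_network_trial, simulate_network_trials,
                            simulated_lrp, switch_equilibria,
                            threshold_tipping_input)
import pandas as pd


@pytest.fixture(scope="module")
def params():
    return NetworkParams()


class TestSwitchEquilibria:
    def test_no_self_excitation_is_linear(self, params):
        p = replace(params, self_excitation=1e-12)
        eq = switch_equilibria(p, 0.3)
        assert len(eq) == 1
        u, kind = eq[0]
        assert kind == "stable"
        assert u == pytest.approx(0.3 / p.leak_thr, abs=1e-6)

    def test_far_below_critical_input_single_low_state(self, params):
        eq = switch_equilibria(params, -1.0)
        assert len(eq) == 1 and eq[0][1] == "stable"
        assert eq[0][0] < params.sigmoid_offset

    def test_intermediate_input_is_bistable(self, params):
        """Brute-force sign scan of the fixed-point map is the oracle."""
        I = 0.05
        eq = switch_equilibria(params, I)
        assert [k for _, k in eq] == ["stable", "unstable", "stable"]

        # independent oracle: sign changes of the map on a fine grid
        grid = np.linspace(-1.0, 2.5, 200_001)
        f = (-params.leak_thr * grid + params.self_excitation
             / (1.0 + np.exp(-params.sigmoid_slope
                             * (grid - params.sigmoid_offset))) + I)
        crossings = np.flatnonzero(np.sign(f[:-1]) != np.sign(f[1:]))
        assert len(crossings) == 3
        for (root, _), i in zip(eq, crossings):
            assert root == pytest.approx(grid[i], abs=1e-3)

    def test_tipping_input_separates_regimes(self, params):
        tip = threshold_tipping_input(params)
        assert 0 < tip < 1
        below = switch_equilibria(params, tip - 0.01)
        above = switch_equilibria(params, tip + 0.01)
        assert sum(1 for _, k in below if k == "stable") == 2
        assert sum(1 for _, k in above if k == "stable") == 1


class TestDynamics:
    def test_zero_input_zero_noise_stays_quiescent(self, params):
        p = replace(params, noise_acc=0.0, input_baseline=0.0)
        tr = simulate_network_trial(p, 0.0, seed=1, max_time=1.5)
        assert not tr.responded
        base = tr.thr[:, 0]
        assert np.max(np.abs(tr.thr - base[:, None])) < 1e-6
        assert np.max(tr.acc) == 0.0

    def test_same_seed_reproducible(self, params):
        a = simulate_network_trials(params, 0.05, 3, seed=4)
        b = simulate_network_trials(params, 0.05, 3, seed=4)
        for x, y in zip(a, b):
            assert np.array_equal(x.thr, y.thr) and x.rt == y.rt

    def test_bias_raises_baseline_without_response(self, params):
        """Pre-stimulus biasing pushes the threshold unit toward (but not
        past) its tipping point."""
        p = replace(params, noise_acc=0.0, input_baseline=0.0,
                    bias=(0.15, 0.0))
        tr = simulate_network_trial(p, 0.0, seed=1, max_time=1.0)
        assert not tr.responded
        p0 = replace(params, noise_acc=0.0, input_baseline=0.0)
        tr0 = simulate_network_trial(p0, 0.0, seed=1, max_time=1.0)
        assert tr.thr[0, -1] > tr0.thr[0, -1] + 0.05

    def test_balanced_accumulator_difference_grows_at_net_drift(self, params):
        """With leak equal to lateral inhibition the mean accumulator
        difference grows linearly at coherence_drive/tau (regression over an
        ensemble, early window before rectification binds)."""
        coh = 0.04
        traces = simulate_network_trials(params, coh, 400, seed=8,
                                         max_time=0.5)
        t = traces[0].time
        mask = (t >= 0.05) & (t <= 0.3)
        diffs = np.mean([tr.acc[0] - tr.acc[1] for tr in traces], axis=0)
        slope = np.polyfit(t[mask], diffs[mask], 1)[0]
        expect = coh * params.input_gain / params.tau_acc
        assert slope == pytest.approx(expect, rel=0.15)

    def test_hysteresis_loop(self, params):
        """Quasi-static input sweep: the up-switch happens at a higher input
        than the down-switch (positive loop area)."""
        p = params
        dt = 1e-3
        u = 0.0
        inputs = np.concatenate([np.linspace(-0.4, 0.4, 4000),
                                 np.linspace(0.4, -0.4, 4000)])
        us = np.empty_like(inputs)
        for i, I in enumerate(inputs):
            for _ in range(20):  # settle at each level
                s = 1.0 / (1.0 + np.exp(-p.sigmoid_slope
                                        * (u - p.sigmoid_offset)))
                u += (-p.leak_thr * u + p.self_excitation * s + I) \
                    * (dt / p.tau_thr)
            us[i] = u
        half = len(inputs) // 2
        up_switch = inputs[:half][np.argmax(us[:half] > 0.7)]
        down_switch = inputs[half:][np.argmax(us[half:] < 0.3)]
        assert up_switch > down_switch + 0.1

    def test_reset_returns_to_baseline_before_next_trial(self, params):
        p = replace(params, noise_acc=0.0)
        tr = simulate_network_trial(p, 0.2, seed=1, max_time=2.5)
        assert tr.responded
        baseline = tr.thr[0, 0]
        peak = tr.thr[0].max()
        # one second after the response the unit is back near baseline
        i = np.searchsorted(tr.time, tr.rt + 1.0)
        assert abs(tr.thr[0, i] - baseline) < 0.05 * (peak - baseline)

    def test_choice_probability_matches_fitted_ddm(self, params):
        """Network behavior is DDM-like: accuracy over a large ensemble
        agrees with the closed form of a pure DDM fitted to the same
        trials (within 3 binomial SE)."""
        n = 6000
        rt, choice = simulate_network_trials(params, 0.03, n, seed=15,
                                             record=False)
        ok = np.isfinite(rt)
        tab = pd.DataFrame({
            "condition": "net",
            "choice": np.where(choice[ok] == 0, "upper", "lower"),
            "hand": np.where(choice[ok] == 0, "right", "left"),
            "rt": rt[ok],
            "correct": choice[ok] == 0,
        })
        res = fit(tab, FitDesign(conditions=("net",)), seed=5)
        p_fit = choice_probability(res.params["net"])
        acc = tab.correct.mean()
        se = np.sqrt(acc * (1 - acc) / len(tab))
        assert abs(acc - p_fit) < 3 * se


class TestSimulatedLRP:
    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            simulated_lrp([], "response")

    def test_average_covers_axis_and_counts_trials(self, params):
        traces = simulate_network_trials(params, 0.06, 50, seed=22)
        lrp = simulated_lrp(traces, "response")
        assert lrp.n > 0
        assert lrp.time.shape == lrp.amplitude.shape

    def test_rmsd_self_consistency_both_directions(self, params):
        """The layer that generated a waveform must win the RMSD comparison
        for most of the plausible grid, in both directions."""
        traces = simulate_network_trials(params, 0.05, 250, seed=99)
        grid = [params, replace(params, feedforward=1.5)]
        cohs = [0.03, 0.06]
        t_thr, thr_avg = layer_average(traces, "thr", "response",
                                       window=(-0.5, 0.05))
        res = rmsd_layer_fit(t_thr, thr_avg, grid, cohs, seed=5, n_trials=120)
        assert res["threshold_win_fraction"] > 0.5
        t_acc, acc_avg = layer_average(traces, "acc", "response",
                                       window=(-0.5, 0.05))
        res2 = rmsd_layer_fit(t_acc, acc_avg, grid, cohs, seed=5,
                              n_trials=120)
        assert res2["threshold_win_fraction"] < 0.5

    def test_rmsd_identical_layers_tie_rule(self, params, monkeypatch):
        """When both layers produce the same trace the tie rule assigns half
        a win each, so the fraction is exactly one half."""
        import lrpddm.network as net

        traces = simulate_network_trials(params, 0.05, 60, seed=7)
        t_thr, thr_avg = layer_average(traces, "thr", "response",
                                       window=(-0.4, 0.0))

        real = net.layer_average

        def same_for_both(trs, layer, **kw):
            return real(trs, "thr", **kw)

        monkeypatch.setattr(net, "layer_average", same_for_both)
        res = net.rmsd_layer_fit(t_thr, thr_avg, [params], [0.05], seed=3,
                                 n_trials=60)
        assert res["threshold_win_fraction"] == 0.5
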