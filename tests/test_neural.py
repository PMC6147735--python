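"""Spike-train analyses on synthetic neurons with known encodings."""

import numpy as np
import pytest

import clickddm as cd
from clickddm.likelihood import GridConfig
from clickddm.neural import (
    NeuronRecording,
    classify_side_selective,
    click_triggered_average,
    compute_psth,
    compute_tuning_curve,
    fit_tuning_sigmoid,
    model_joint_distributions,
    predict_cta_linear_encoding,
    smoothed_rates,
    tuning_sigmoid,
)
from clickddm.synthetic import EncodingSpec, generate_spikes


@pytest.fixture(scope="module")
def spiking_dataset(symmetric_params):
    """One session + linear, step and constant synthetic neurons."""
    sess = cd.generate_stimulus_session(250, seed=201, motor_fraction=0.0)
    encs = [
        EncodingSpec("linear", k1=3.0, k2=20.0),
        EncodingSpec("step", threshold=0.0, low=10.0, high=30.0),
        EncodingSpec("constant", rate=12.0),
    ]
    recs, paths = generate_spikes(sess, symmetric_params, encs, seed=202)
    return sess, recs, paths


def _poisson_recording(rate, n_trials, duration, seed):
    rng = np.random.default_rng(seed)
    st, ids = [], []
    for i in range(n_trials):
        n = rng.poisson(rate * duration)
        st.append(np.sort(rng.uniform(0, duration, n)))
        ids.append(np.full(n, i, dtype=np.int64))
    return NeuronRecording(np.concatenate(st), np.concatenate(ids), n_trials,
                           t_stop=np.full(n_trials, duration))


class TestSmoothingAndPSTH:
    def test_causality_single_spike(self):
        rec = NeuronRecording(np.array([0.5]), np.array([0]), 1, t_stop=np.array([1.0]))
        sm, time = smoothed_rates(rec, None, dt=0.01, sigma=0.1)
        assert np.all(sm[0][time < 0.5] == 0.0)
        assert sm[0][time >= 0.5][0] > 0

    def test_flat_poisson_psth(self, trial_factory):
        trials = [trial_factory([0.1], [0.2], 1.0) for _ in range(300)]
        for t in trials:
            t.choice = "R"
        rec = _poisson_recording(10.0, 300, 1.0, seed=1)
        sm, time = smoothed_rates(rec, trials)
        mid = np.nanmean(sm[:, time > 0.4], axis=0)
        assert np.nanmean(mid) == pytest.approx(10.0, rel=0.05)
        psth = compute_psth(rec, trials, preferred_side="R", normalize=False)
        g = int(np.argmax(psth.group_sizes))
        assert np.nanstd(psth.rates[g][time > 0.4]) < 1.5

    def test_ramp_slope_orders_with_stimulus_strength(self, spiking_dataset):
        """Linear-encoding neurons show steeper ramps for stronger stimuli."""
        sess, recs, _ = spiking_dataset
        psth = compute_psth(recs[0], sess.trials, preferred_side="R", normalize=False)
        t = psth.time
        win = (t > 0.1) & (t < 0.6)
        slopes = [np.polyfit(t[win], psth.rates[g][win], 1)[0] for g in range(4)]
        assert slopes[3] > slopes[0]
        assert slopes[3] > 0


class TestSideSelectivity:
    def test_type_one_error_calibrated(self, trial_factory):
        """Choice-independent neurons are called selective in ~5% of cases."""
        rng = np.random.default_rng(5)
        trials = []
        for _ in range(80):
            t = trial_factory([0.1], [0.2], 0.8)
            t.choice = "R" if rng.random() < 0.5 else "L"
            trials.append(t)
        hits = 0
        n_sim = 400
        for s in range(n_sim):
            rec = _poisson_recording(8.0, 80, 0.8, seed=1000 + s)
            sel, _, _ = classify_side_selective(rec, trials, window=(0.0, 0.5))
            hits += bool(sel)
        rate = hits / n_sim
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01

    def test_strong_selectivity_detected_with_correct_side(self, trial_factory):
        rng = np.random.default_rng(6)
        trials, st, ids = [], [], []
        for i in range(100):
            t = trial_factory([0.1], [0.2], 0.8)
            t.choice = "R" if i % 2 else "L"
            trials.append(t)
            rate = 20.0 if t.choice == "R" else 5.0
            n = rng.poisson(rate * 0.8)
            st.append(np.sort(rng.uniform(0, 0.8, n)))
            ids.append(np.full(n, i, dtype=np.int64))
        rec = NeuronRecording(np.concatenate(st), np.concatenate(ids), 100)
        sel, pref, p = classify_side_selective(rec, trials)
        assert sel and pref == "R" and p < 1e-6

    def test_silent_neuron_undetermined(self, trial_factory):
        trials = [trial_factory([0.1], [0.2], 0.5) for _ in range(40)]
        for i, t in enumerate(trials):
            t.choice = "R" if i % 2 else "L"
        rec = NeuronRecording(np.zeros(0), np.zeros(0, np.int64), 40)
        sel, pref, _ = classify_side_selective(rec, trials)
        assert sel is None and pref is None


class TestCTA:
    def test_click_independent_neuron_is_null(self, trial_factory):
        rng = np.random.default_rng(7)
        trials = []
        for _ in range(400):
            tr = cd.generate_click_trains(*cd.sample_difficulty(seed=rng), 1.0, rng)
            trials.append(tr)
        rec = _poisson_recording(15.0, 400, 1.0, seed=8)
        cta = click_triggered_average(rec, trials, preferred_side="R")
        ok = np.isfinite(cta.mean)
        assert np.mean(np.abs(cta.mean[ok]) < 3 * cta.se[ok]) > 0.95

    def test_zero_gain_prediction_is_flat_zero(self, symmetric_params):
        pred = predict_cta_linear_encoding(symmetric_params, k1=0.0, k2=20.0,
                                           n_trials=300, seed=9)
        np.testing.assert_allclose(np.nan_to_num(pred.mean), 0.0, atol=1e-9)

    def test_prediction_scales_linearly_with_gain(self, symmetric_params):
        p1 = predict_cta_linear_encoding(symmetric_params, k1=2.0, k2=30.0,
                                         n_trials=400, seed=10)
        p2 = predict_cta_linear_encoding(symmetric_params, k1=4.0, k2=60.0,
                                         n_trials=400, seed=10)
        ok = np.isfinite(p1.mean) & np.isfinite(p2.mean) & (p1.lags > 0.05)
        np.testing.assert_allclose(p2.mean[ok], 2.0 * p1.mean[ok], rtol=0.15, atol=0.05)

    def test_small_bound_attenuates_sustained_response(self, symmetric_params):
        tight = symmetric_params.replace(bound_B=2.0)
        loose = symmetric_params.replace(bound_B=25.0)
        pt = predict_cta_linear_encoding(tight, k1=3.0, k2=20.0, n_trials=1500, seed=11)
        pl = predict_cta_linear_encoding(loose, k1=3.0, k2=20.0, n_trials=1500, seed=11)
        late = pt.lags > 0.2
        assert np.nanmean(pt.mean[late]) < np.nanmean(pl.mean[late])


class TestTuning:
    def test_exact_sigmoid_recovery(self):
        a = np.linspace(-6, 6, 13)
        r = tuning_sigmoid(a, 2.0, 10.0, 0.8, 0.0)
        fit = fit_tuning_sigmoid(a, r)
        assert (fit.k1, fit.k2, fit.k3, fit.k4) == pytest.approx((2.0, 10.0, 0.8, 0.0), abs=1e-3)
        assert fit.slope_at_zero == pytest.approx(2.0, abs=1e-3)

    def test_flat_curve_degenerate_zero_slope(self):
        a = np.linspace(-5, 5, 11)
        fit = fit_tuning_sigmoid(a, np.full(11, 7.0))
        assert fit.degenerate
        assert fit.slope_at_zero == pytest.approx(0.0, abs=1e-3)

    def test_linear_input_small_k3_regime(self):
        a = np.linspace(-4, 4, 17)
        fit = fit_tuning_sigmoid(a, 20.0 + 1.5 * a)
        assert fit.slope_at_zero == pytest.approx(1.5, rel=0.1)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            fit_tuning_sigmoid(np.arange(4), np.arange(4.0))

    def test_constant_neuron_flat_tuning(self, spiking_dataset, symmetric_params):
        sess, recs, _ = spiking_dataset
        curve = compute_tuning_curve(recs[2], sess.trials, symmetric_params,
                                     grid=GridConfig(dt=0.02, n_bins=61))
        ok = np.isfinite(curve.summary)
        assert ok.sum() >= 5
        assert np.nanstd(curve.summary) < 2.0
        assert np.nanmean(curve.summary) == pytest.approx(12.0, rel=0.15)

    def test_lag_contract_shift_invariance(self, spiking_dataset, symmetric_params):
        """Shifting all spikes by +delta and the lag by +delta leaves the
        tuning curve unchanged."""
        sess, recs, _ = spiking_dataset
        rec = recs[0]
        delta = 0.1
        shifted = NeuronRecording(rec.spike_times + delta, rec.trial_ids, rec.n_trials,
                                  t_stop=rec.t_stop + delta)
        grid = GridConfig(dt=0.02, n_bins=61)
        joints = model_joint_distributions(sess.trials, symmetric_params, grid)
        c1 = compute_tuning_curve(rec, sess.trials, symmetric_params, lag=0.15,
                                  grid=grid, joints=joints)
        c2 = compute_tuning_curve(shifted, sess.trials, symmetric_params, lag=0.25,
                                  grid=grid, joints=joints)
        np.testing.assert_allclose(np.nan_to_num(c1.summary), np.nan_to_num(c2.summary),
                                   rtol=1e-9, atol=1e-9)

    def test_population_curve_within_neuron_hull(self, spiking_dataset, symmetric_params):
        sess, recs, _ = spiking_dataset
        grid = GridConfig(dt=0.02, n_bins=61)
        joints = model_joint_distributions(sess.trials, symmetric_params, grid)
        curves = [compute_tuning_curve(r, sess.trials, symmetric_params, grid=grid, joints=joints)
                  for r in recs[:2]]
        pooled = compute_tuning_curve(recs[:2], sess.trials, symmetric_params, grid=grid,
                                      joints=joints)
        stack = np.stack([c.summary for c in curves])
        lo = np.nanmin(stack, axis=0) - 1e-9
        hi = np.nanmax(stack, axis=0) + 1e-9
        ok = np.isfinite(pooled.summary) & np.isfinite(lo) & np.isfinite(hi)
        assert np.all(pooled.summary[ok] >= lo[ok]) and np.all(pooled.summary[ok] <= hi[ok])


class TestLatencyEstimation:
    def test_recovers_injected_latency(self, spiking_dataset, symmetric_params):
        """Spikes generated with a 0.15 s encoding lag show their first
        stimulus-strength modulation near 0.15 s."""
        from clickddm.neural import estimate_latency

        sess, recs, _ = spiking_dataset
        lat = estimate_latency(recs[0], sess.trials, preferred_side="R", alpha=0.01)
        assert 0.05 <= lat <= 0.3

    def test_unmodulated_neuron_has_no_latency(self, trial_factory):
        from clickddm.neural import estimate_latency

        rng = np.random.default_rng(44)
        trials = []
        for _ in range(120):
            trials.append(cd.generate_click_trains(*cd.sample_difficulty(seed=rng), 0.8, rng))
        rec = _poisson_recording(12.0, 120, 0.8, seed=45)
        lat = estimate_latency(rec, trials, alpha=0.001)
        assert np.isnan(lat)
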