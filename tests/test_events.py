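"""The 3x-SD transient detector: noise-floor estimators, the acceptance
boundary, rates, and trapezoidal AUC windows."""

import numpy as np
import pytest

from abquant.errors import DetectionError, InsufficientDataError, InvalidConfigError, WindowError
from abquant.events import (
    DetectionConfig,
    compute_auc,
    detect_transients,
    estimate_baseline_sd,
    transient_rate,
)
from abquant.simulate import SimulationConfig, generate_calcium_trace
from abquant.traces import compute_dff, lowpass_filter
from conftest import kernel_signal, make_dff

FS = 40.0


def noise_free_config(sd=0.05):
    """Detection settings for synthetic noise-free traces: the noise floor is
    supplied explicitly because any estimator returns 0 on a flat baseline."""
    return DetectionConfig(baseline_sd=sd, subtract_baseline=False)


class TestBaselineSd:
    def test_mad_consistent_on_gaussian_noise(self):
        rng = np.random.default_rng(42)
        dff = make_dff(0.05 * rng.standard_normal(10_000))
        est = estimate_baseline_sd(dff, estimator="mad")
        assert est == pytest.approx(0.05, rel=0.05)

    def test_constant_trace_zero_sd(self):
        assert estimate_baseline_sd(make_dff(np.ones(500)), estimator="mad") == 0.0

    def test_mad_robust_to_sparse_events(self):
        rng = np.random.default_rng(7)
        t = np.arange(10_000) / FS  # 250 s, ~6% of samples contaminated
        noise = 0.05 * rng.standard_normal(t.size)
        events = kernel_signal(t, np.linspace(5, 245, 10), amplitude=1.0)
        clean = estimate_baseline_sd(make_dff(noise), estimator="mad")
        dirty = estimate_baseline_sd(make_dff(noise + events), estimator="mad")
        assert abs(dirty - clean) / clean < 0.10

    def test_residual_mad_tracks_noise_on_busy_traces(self):
        # at hyperactive rates transients occupy most samples and plain MAD
        # saturates; the residual estimator must stay near the true floor
        cfg = SimulationConfig()
        ests = []
        for s in range(5):
            tr, _ = generate_calcium_trace(cfg, 40.0, seed=s)
            dff = compute_dff(lowpass_filter(tr, 10.0))
            ests.append(estimate_baseline_sd(dff, estimator="residual-mad"))
        # true filtered-noise SD ~ 0.028 for noise_sd 0.04 at 10/40 Hz
        assert np.mean(ests) == pytest.approx(0.028, rel=0.25)

    def test_quiet_window_sd(self):
        rng = np.random.default_rng(3)
        x = 0.04 * rng.standard_normal(4000)
        dff = make_dff(x)
        est = estimate_baseline_sd(dff, estimator="quiet-window", quiet_window=(10.0, 60.0))
        assert est == pytest.approx(x[400:2400].std(), rel=1e-9)

    def test_quiet_window_outside_trace_rejected(self):
        dff = make_dff(np.zeros(400))
        with pytest.raises(WindowError):
            estimate_baseline_sd(dff, estimator="quiet-window", quiet_window=(5.0, 30.0))

    def test_mad_needs_enough_samples(self):
        with pytest.raises(InsufficientDataError):
            estimate_baseline_sd(make_dff(np.zeros(50)), estimator="mad")


class TestDetect:
    def test_flat_zero_trace_no_events(self):
        assert detect_transients(make_dff(np.zeros(400)), noise_free_config()) == []

    def test_zero_sd_with_signal_demands_noise_floor(self):
        t = np.arange(400) / FS
        dff = make_dff(kernel_signal(t, [5.0], 1.0))
        with pytest.raises(DetectionError, match="noise floor"):
            detect_transients(dff, DetectionConfig(baseline_sd=0.0, subtract_baseline=False))

    @pytest.mark.parametrize("mult,expected", [(4.0, 1), (2.0, 0)])
    def test_three_sigma_rule_in_gaussian_noise(self, mult, expected):
        from abquant.traces import Trace

        rng = np.random.default_rng(19)
        t = np.arange(2400) / FS
        noise = 0.03 * rng.standard_normal(t.size)
        filtered_noise = lowpass_filter(Trace(noise, FS), 10.0).values
        sd = float(filtered_noise.std())
        signal = kernel_signal(t, [30.0], mult * sd)
        dff = make_dff(lowpass_filter(Trace(noise + signal, FS), 10.0).values)
        events = detect_transients(
            dff, DetectionConfig(baseline_sd=sd, subtract_baseline=False))
        assert len(events) == expected

    def test_exact_count_and_peak_times_noise_free(self):
        times = np.arange(2.0, 57.0, 2.2)[:25]
        t = np.arange(2400) / FS
        dff = make_dff(kernel_signal(t, times, 0.5))
        events = detect_transients(dff, noise_free_config())
        assert len(events) == 25
        peaks = np.array([e.peak_time for e in events])
        # kernel peaks one rise time after onset
        assert np.all(np.abs(peaks - (times + 0.05)) <= 2 / FS)

    def test_adding_one_event_increases_count_by_one(self):
        t = np.arange(2400) / FS
        base_times = [5.0, 15.0, 25.0]
        cfg = noise_free_config()
        n0 = len(detect_transients(make_dff(kernel_signal(t, base_times, 0.5)), cfg))
        n1 = len(detect_transients(make_dff(kernel_signal(t, base_times + [45.0], 0.5)), cfg))
        assert n0 == 3 and n1 == 4

    def test_threshold_sweep_flips_exactly_once(self):
        t = np.arange(1200) / FS
        cfg = noise_free_config(sd=0.05)
        detected = []
        for mult in np.arange(2.0, 4.01, 0.05):
            dff = make_dff(kernel_signal(t, [15.0], mult * 0.05))
            detected.append(len(detect_transients(dff, cfg)) > 0)
        flips = np.diff(np.asarray(detected).astype(int))
        assert np.sum(flips != 0) == 1
        boundary = np.arange(2.0, 4.01, 0.05)[int(np.argmax(detected))]
        assert boundary == pytest.approx(3.05, abs=0.051)

    def test_matches_brute_force_on_noise_free_trace(self):
        t = np.arange(2400) / FS
        x = kernel_signal(t, [4.0, 11.0, 19.5, 33.0, 50.0], 0.4)
        cfg = noise_free_config(sd=0.02)
        events = detect_transients(make_dff(x), cfg)
        thr = 3 * 0.02
        # brute force: suprathreshold strict local maxima, well separated here
        brute = [i for i in range(1, x.size - 1)
                 if x[i] > thr and x[i] >= x[i - 1] and x[i] > x[i + 1]]
        assert len(events) == len(brute)
        assert np.allclose([e.peak_time for e in events], t[brute], atol=1 / FS)


class TestRate:
    def test_rate_arithmetic(self):
        t = np.arange(2400) / FS
        cfg = noise_free_config()
        events = detect_transients(
            make_dff(kernel_signal(t, np.linspace(2, 56, 25), 0.5)), cfg)
        assert transient_rate(events, 60.0) == pytest.approx(25.0)
        assert transient_rate([], 60.0) == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidConfigError):
            transient_rate([], 0.0)

    def test_detected_rate_recovers_poisson_rate(self):
        # full pipeline at 10/min, SNR ~ 10: detected rate within 3 SE
        cfg = SimulationConfig()
        rates, true_rates = [], []
        for s in range(60):
            tr, gt = generate_calcium_trace(cfg, 10.0, seed=100 + s)
            dff = compute_dff(lowpass_filter(tr, 10.0))
            rates.append(transient_rate(detect_transients(dff), 60.0))
            true_rates.append(gt.true_rate_per_neuron[0])
        se = np.sqrt(10.0 / 60)
        assert abs(np.mean(rates) - np.mean(true_rates)) < 3 * se

    def test_hyperactive_rate_undercount_bounded(self):
        # at 30/min events closer than the 0.2 s separation merge; the
        # systematic undercount stays below ~12%
        cfg = SimulationConfig()
        det, true = 0.0, 0.0
        for s in range(30):
            tr, gt = generate_calcium_trace(cfg, 30.0, seed=200 + s)
            dff = compute_dff(lowpass_filter(tr, 10.0))
            det += len(detect_transients(dff))
            true += gt.event_times_per_neuron[0].size
        assert 0.88 * true <= det <= 1.02 * true


class TestAuc:
    def test_rectangle_area_in_glutamate_window(self):
        fs = 200.0
        t = np.arange(int(1.0 * fs)) / fs
        x = np.where((t >= 0.1) & (t < 0.35), 1.0, 0.0)
        dff = make_dff(x, sampling_rate=fs, channel="glutamate")
        auc = compute_auc(dff, 0.0, noise_free_config())
        assert auc == pytest.approx(0.25, abs=0.01)

    def test_signal_after_window_ignored(self):
        fs = 200.0
        t = np.arange(int(2.0 * fs)) / fs
        x = np.where((t >= 0.1) & (t < 0.35), 1.0, 0.0)
        late = x + np.where((t >= 0.8) & (t < 1.2), 5.0, 0.0)
        cfg = noise_free_config()
        a = compute_auc(make_dff(x, fs, channel="glutamate"), 0.0, cfg)
        b = compute_auc(make_dff(late, fs, channel="glutamate"), 0.0, cfg)
        assert a == b

    def test_triangle_matches_closed_form(self):
        fs = 200.0
        t = np.arange(int(0.6 * fs)) / fs
        x = np.clip(1.0 - np.abs(t - 0.25) / 0.15, 0.0, None)  # area 0.15
        dff = make_dff(x, fs, channel="glutamate")
        auc = compute_auc(dff, 0.0, noise_free_config())
        assert auc == pytest.approx(0.15, rel=0.01)

    def test_calcium_window_is_forty_seconds(self):
        t = np.arange(4000) / FS  # 100 s
        x = kernel_signal(t, [20.0], 0.5) + kernel_signal(t, [70.0], 5.0)
        cfg = noise_free_config()
        auc_early = compute_auc(make_dff(x), 0.0, cfg)
        only_early = kernel_signal(t, [20.0], 0.5)
        assert auc_early == pytest.approx(
            compute_auc(make_dff(only_early), 0.0, cfg), rel=1e-9)

    def test_window_past_trace_end_is_explicit_error(self):
        dff = make_dff(np.zeros(400))  # 10 s of calcium
        with pytest.raises(WindowError):
            compute_auc(dff, 0.0, noise_free_config())  # needs 40 s
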