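"""Generator oracles: determinism, Poisson rate calibration, paired sessions,
glutamate train additivity, movie consistency, and the biophysical inputs."""

import numpy as np
import pytest

from abquant.errors import InvalidConfigError
from abquant.simulate import (
    ConditionEpoch,
    SimulationConfig,
    generate_calcium_trace,
    generate_chromatogram,
    generate_dose_response,
    generate_glutamate_trace,
    generate_movie,
    generate_sensorgram,
    generate_session,
    generate_tht_curve,
)
from abquant.biophys import find_peak_volume, kav, normalize_tht


class TestCalciumTrace:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig()
        t1, g1 = generate_calcium_trace(cfg, 30.0, seed=7)
        t2, g2 = generate_calcium_trace(cfg, 30.0, seed=7)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(g1.event_times_per_neuron[0], g2.event_times_per_neuron[0])

    def test_zero_rate_noise_free_is_flat(self, quiet_config):
        trace, truth = generate_calcium_trace(quiet_config, 0.0, seed=0)
        assert truth.event_times_per_neuron[0].size == 0
        assert np.allclose(trace.values, quiet_config.baseline_f)

    def test_poisson_event_count_calibration(self):
        # 30/min for 60 s, thinned at one 50 ms rise time: survival ~ exp(-lam*tau)
        cfg = SimulationConfig()
        counts = [
            generate_calcium_trace(cfg, 30.0, seed=s)[1].event_times_per_neuron[0].size
            for s in range(200)
        ]
        expected = 30.0 * np.exp(-(30.0 / 60.0) * cfg.rise_time)
        se = np.sqrt(30.0 / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_refractory_thinning_enforced(self):
        cfg = SimulationConfig()
        for s in range(20):
            times = generate_calcium_trace(cfg, 60.0, seed=s)[1].event_times_per_neuron[0]
            if times.size > 1:
                assert np.diff(times).min() >= cfg.rise_time

    def test_condition_factor_scales_epoch_rate(self, application_schedule):
        cfg = SimulationConfig(conditions=application_schedule)
        app_rates = [
            generate_calcium_trace(cfg, 30.0, seed=s)[1].condition_rates[0]["application"]
            for s in range(300)
        ]
        # thinned-Poisson oracle: 30/min x 0.2 = 6/min in the application epoch
        se = np.sqrt(6.0 / 300)
        assert abs(np.mean(app_rates) - 6.0) < 3 * se + 0.2  # small thinning bias

    def test_invalid_configuration_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(frame_rate=0.0)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(duration=0.01)
        with pytest.raises(InvalidConfigError):
            generate_calcium_trace(SimulationConfig(), -1.0, seed=0)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(conditions=(
                ConditionEpoch("a", 0, 60, 1.0), ConditionEpoch("b", 50, 120, 0.5),
            ))


class TestSession:
    def test_fraction_zero_all_quiet(self):
        cfg = SimulationConfig(n_neurons=20, fraction_hyperactive=0.0)
        _, truth = generate_session(cfg, seed=0, make_traces=False)
        assert not any(truth.true_class_per_neuron)

    def test_binomial_hyperactive_assignment(self):
        cfg = SimulationConfig(n_neurons=100, fraction_hyperactive=0.12)
        fracs = [
            np.mean(generate_session(cfg, seed=s, make_traces=False)[1].true_class_per_neuron)
            for s in range(500)
        ]
        se = np.sqrt(0.12 * 0.88 / (100 * 500))
        assert abs(np.mean(fracs) - 0.12) < 3 * se

    def test_same_seed_identical_sessions(self):
        cfg = SimulationConfig(n_neurons=5, duration=10.0,
                               conditions=(ConditionEpoch("baseline", 0, 10),))
        s1, g1 = generate_session(cfg, seed=3)
        s2, g2 = generate_session(cfg, seed=3)
        for a, b in zip(s1.traces, s2.traces):
            assert np.array_equal(a.values, b.values)
        assert g1.true_class_per_neuron == g2.true_class_per_neuron

    def test_empty_schedule_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_session(SimulationConfig(conditions=()), seed=0)

    def test_needs_at_least_one_neuron(self):
        with pytest.raises(InvalidConfigError):
            generate_session(SimulationConfig(n_neurons=0), seed=0)


class TestGlutamate:
    def test_single_pulse_unit_peak(self):
        trace, truth = generate_glutamate_trace([0.5], n_pulses=1,
                                                per_pulse_amplitude=1.0, noise_sd=0.0,
                                                duration=2.0)
        dff = (trace.values - 100.0) / 100.0
        assert truth.event_times_per_neuron[0].size == 1
        assert dff.max() == pytest.approx(1.0, abs=1e-9)

    def test_linear_train_auc_additivity(self):
        kw = dict(per_pulse_amplitude=0.5, noise_sd=0.0, frame_rate=200.0,
                  duration=4.0, disease_gain=1.0)
        t1, _ = generate_glutamate_trace([0.5], n_pulses=1, **kw)
        t10, _ = generate_glutamate_trace([0.5], n_pulses=10, **kw)
        auc1 = np.trapezoid(t1.values - 100.0, dx=1 / 200)
        auc10 = np.trapezoid(t10.values - 100.0, dx=1 / 200)
        assert auc10 == pytest.approx(10 * auc1, rel=0.01)

    def test_disease_gain_scales_long_train_auc(self):
        kw = dict(per_pulse_amplitude=0.5, noise_sd=0.0, duration=4.0)
        ctrl, _ = generate_glutamate_trace([0.5], n_pulses=10, disease_gain=1.0, **kw)
        dis, _ = generate_glutamate_trace([0.5], n_pulses=10, disease_gain=1.5, **kw)
        r = np.trapezoid(dis.values - 100.0) / np.trapezoid(ctrl.values - 100.0)
        assert r == pytest.approx(1.5, rel=1e-9)

    def test_gain_spares_short_trains(self):
        kw = dict(per_pulse_amplitude=0.5, noise_sd=0.0, duration=2.0)
        ctrl, _ = generate_glutamate_trace([0.5], n_pulses=2, disease_gain=1.0, **kw)
        dis, _ = generate_glutamate_trace([0.5], n_pulses=2, disease_gain=1.5, **kw)
        assert np.array_equal(ctrl.values, dis.values)

    def test_subsample_pulse_spacing_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_glutamate_trace([0.5], n_pulses=2, inter_pulse=0.001,
                                     frame_rate=200.0, duration=2.0)


class TestMovie:
    def test_noise_free_roi_means_reproduce_traces(self, quiet_config):
        traces = [generate_calcium_trace(quiet_config, r, seed=s)[0]
                  for s, r in enumerate((10.0, 40.0))]
        movie, rois = generate_movie(traces)
        for label, tr in zip((1, 2), traces):
            roi_mean = movie[:, rois == label].mean(axis=1)
            assert np.allclose(roi_mean, tr.values, rtol=1e-13, atol=0)

    def test_bad_roi_labels_rejected(self, quiet_config):
        traces = [generate_calcium_trace(quiet_config, 10.0, seed=0)[0]]
        rois = np.zeros((32, 32), dtype=int)
        rois[0:3, 0:3] = 5  # labels must be 1..n_traces
        with pytest.raises(InvalidConfigError):
            generate_movie(traces, rois=rois)


class TestDoseResponse:
    def test_half_response_at_ic50(self):
        df = generate_dose_response(75.0, [75.0], noise_sd=0.0, replicates=3)
        assert df["mean"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        df = generate_dose_response(75.0, [1e-6, 1e9], noise_sd=0.0, replicates=2,
                                    floor=0.2)
        assert df["mean"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert df["mean"].iloc[1] == pytest.approx(0.2, abs=1e-6)

    def test_sem_matches_noise_over_replicates(self):
        sems = [generate_dose_response(75.0, [75.0], noise_sd=0.05, replicates=5,
                                       seed=s)["sem"].iloc[0] for s in range(300)]
        # E[SEM] ~ c4 * sd/sqrt(n) with c4(5) ~ 0.94
        assert np.mean(sems) == pytest.approx(0.94 * 0.05 / np.sqrt(5), rel=0.05)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_dose_response(0.0, [10.0])


class TestBiophysInputs:
    def test_sensorgram_plateau_half_rmax_at_kd(self):
        kd = 1e-8
        df = generate_sensorgram(k_on=1e6, k_off=1e-2, rmax=100.0, conc=kd,
                                 t_assoc=2000.0, t_dissoc=10.0, dt=1.0)
        end_assoc = df.loc[df["phase"] == "association", "response_RU"].iloc[-1]
        assert end_assoc == pytest.approx(50.0, rel=1e-6)

    def test_chromatogram_peak_at_void_gives_kav_zero(self):
        chrom = generate_chromatogram([(8.0, 50.0, 0.2)], v0=8.0, vt=24.0)
        ve = find_peak_volume(chrom)
        assert kav(ve, 8.0, 24.0) == pytest.approx(0.0, abs=0.01)

    def test_tht_co_incubation_suppresses_plateau(self):
        free = generate_tht_curve("free")
        scav = generate_tht_curve("co_incubation")
        free_asym = free.fluorescence[-12:].mean()
        n_free = normalize_tht(free)
        n_scav = normalize_tht(scav, asymptote=free_asym)
        assert n_free.fluorescence[-1] == pytest.approx(100.0, abs=1.0)
        assert n_scav.fluorescence[-1] < 5.0

    def test_tht_determinism(self):
        a = generate_tht_curve("free", noise_sd=5.0, seed=2)
        b = generate_tht_curve("free", noise_sd=5.0, seed=2)
        assert np.array_equal(a.fluorescence, b.fluorescence)
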