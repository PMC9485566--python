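"""Generator-level tests: spike-train statistics, fluorescence forward model,
membrane simulation and AP waveform synthesis."""

from __future__ import annotations

import numpy as np
import pytest

from cinpop import ephys_features as ef
from cinpop import synthgen as sg


class TestSpikeTrains:
    def test_zero_cv_renewal_is_periodic(self):
        train = sg.make_spike_train("tonic", rate=2.0, cv=0.0, duration=10.0,
                                    seed=123)
        assert train.n_spikes == 20
        assert np.allclose(train.isis, 0.5)

    @pytest.mark.parametrize("cv", [1.0, 0.5])
    def test_gamma_isi_cv_recovery(self, cv):
        # closed form: gamma-renewal ISI CV = 1/sqrt(shape)
        train = sg.make_spike_train("irregular", rate=4.0, cv=cv,
                                    duration=600.0, seed=7)
        assert train.cv_isi == pytest.approx(cv, rel=0.05)

    @pytest.mark.parametrize("pattern,rate,cv", [
        ("tonic", 2.0, 0.1), ("irregular", 5.0, 1.0), ("irregular", 8.0, 0.5),
    ])
    def test_rate_recovery_within_3_se(self, pattern, rate, cv):
        duration = 100.0
        train = sg.make_spike_train(pattern, rate, cv, duration, seed=5)
        # SE of the renewal count over T is ~ sqrt(rate*T)*cv (plus edge
        # effects); use a floor so the tonic case is not over-tight
        se = np.sqrt(rate * duration) * max(cv, 0.35) / duration
        assert abs(train.mean_rate - rate) < 3 * se

    def test_burst_pause_respects_overall_rate(self):
        train = sg.make_spike_train("burst_pause", rate=4.0, duration=600.0,
                                    seed=3)
        assert 3.0 < train.mean_rate < 5.0
        # pauses produce long ISIs that a rate-matched tonic train never has
        assert np.percentile(train.isis, 99) > 1.0

    def test_spike_times_sorted_within_bounds(self):
        for seed in range(5):
            t = sg.make_spike_train("burst_pause", 3.0, duration=60.0,
                                    seed=seed)
            assert np.all(np.diff(t.spike_times) > 0)
            assert t.spike_times.min() >= 0
            assert t.spike_times.max() <= 60.0

    def test_seed_determinism(self):
        a = sg.make_spike_train("irregular", 3.0, 1.0, 60.0, seed=9)
        b = sg.make_spike_train("irregular", 3.0, 1.0, 60.0, seed=9)
        c = sg.make_spike_train("irregular", 3.0, 1.0, 60.0, seed=10)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert not np.array_equal(a.spike_times, c.spike_times)

    @pytest.mark.parametrize("kwargs", [
        {"rate": 0.0}, {"rate": -1.0}, {"rate": 2.0, "duration": 0.0},
        {"rate": 2.0, "cv": -0.5},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            sg.make_spike_train("tonic", duration=kwargs.pop("duration", 10.0),
                                **kwargs)

    def test_enforce_min_isi(self):
        t = sg.make_spike_train("irregular", 8.0, 1.0, 60.0, seed=2)
        thinned = sg.enforce_min_isi(t, 0.3)
        assert np.all(thinned.isis >= 0.3)


class TestFluorescence:
    def test_zero_spikes_noiseless_traces_constant(self):
        sc = sg.ImagingScenario(3, 20.0, 10.0,
                                trains=[sg.SpikeTrain(np.empty(0), 20.0,
                                                      "tonic")] * 3,
                                noise_sd=0.0, baseline_F0=80.0)
        traces, truth = sg.render_fluorescence(sc)
        assert np.allclose(traces.F, 80.0)
        assert truth.total_events() == 0

    def test_single_spike_kernel_timing(self):
        train = sg.SpikeTrain(np.array([5.05]), 20.0, "tonic")
        sc = sg.ImagingScenario(1, 20.0, 10.0, trains=[train], noise_sd=0.0)
        traces, truth = sg.render_fluorescence(sc)
        assert truth.total_events() == 1
        assert truth.event_frames(0)[0] == 50
        peak_time = np.argmax(traces.F[0]) / 10.0
        # kernel peaks within ~2 rise times of the spike at this frame rate
        assert 5.0 < peak_time < 5.4

    def test_poisson_event_counts(self):
        trains = [sg.make_spike_train("irregular", 3.0, 1.0, 100.0,
                                      seed=100 + i) for i in range(10)]
        sc = sg.ImagingScenario(10, 100.0, 10.0, trains, noise_sd=0.0,
                                seed=1)
        _, truth = sg.render_fluorescence(sc)
        counts = truth.A.sum(axis=1).astype(int)
        # a frame holds >=1 Poisson spike with p = 1 - exp(-rate/fps);
        # occupied-frame counts are Binomial(C, p)
        p = 1 - np.exp(-3.0 / 10.0)
        expected = 1000 * p
        se = np.sqrt(1000 * p * (1 - p))
        assert np.all(np.abs(counts - expected) < 3 * se)

    def test_seed_determinism_bit_identical(self):
        trains = [sg.make_spike_train("irregular", 2.0, 1.0, 30.0, seed=4)]
        a, _ = sg.render_fluorescence(
            sg.ImagingScenario(1, 30.0, 10.0, trains, seed=77))
        b, _ = sg.render_fluorescence(
            sg.ImagingScenario(1, 30.0, 10.0, trains, seed=77))
        assert np.array_equal(a.F, b.F)

    def test_invalid_scenarios_raise(self):
        with pytest.raises(ValueError):
            sg.ImagingScenario(2, 10.0, 10.0, rise_tau=0.6, decay_tau=0.5)
        with pytest.raises(ValueError):
            sg.ImagingScenario(2, 0.1, 10.0)
        with pytest.raises(ValueError):
            sg.ImagingScenario(2, 10.0, 10.0,
                               ensemble_events=[(5.0, [0, 7])])


class TestMovie:
    def test_constant_trace_constant_disk(self):
        sc = sg.ImagingScenario(1, 5.0, 10.0,
                                trains=[sg.SpikeTrain(np.empty(0), 5.0,
                                                      "tonic")],
                                noise_sd=0.0, baseline_F0=120.0)
        movie, rois, traces, _ = sg.render_movie(sc, roi_radius=5,
                                                 field=(64, 64))
        assert np.all(movie == movie[0])
        y, x = int(rois.loc[0, "y"]), int(rois.loc[0, "x"])
        assert movie[0, y, x] == 120

    def test_roundtrip_roi_extraction_correlation(self):
        from cinpop import imaging_events as ie

        trains = [sg.make_spike_train("irregular", 1.0, 1.0, 60.0,
                                      seed=i) for i in range(4)]
        sc = sg.ImagingScenario(4, 60.0, 10.0, trains, noise_sd=0.01,
                                seed=3)
        movie, rois, traces, _ = sg.render_movie(sc, roi_radius=5,
                                                 field=(96, 96))
        extracted = ie.extract_roi_traces(movie, rois, fps=10.0)
        for i in range(4):
            r = np.corrcoef(extracted.F[i], traces.F[i])[0, 1]
            assert r > 0.99

    def test_empty_scenario_blank_movie(self):
        sc = sg.ImagingScenario(0, 5.0, 10.0, trains=[], noise_sd=0.0)
        movie, rois, _, _ = sg.render_movie(sc, field=(32, 32))
        assert len(rois) == 0
        assert np.all(movie == 50)

    def test_overlapping_rois_raise(self):
        sc = sg.ImagingScenario(2, 5.0, 10.0,
                                trains=[sg.SpikeTrain(np.empty(0), 5.0,
                                                      "tonic")] * 2,
                                noise_sd=0.0)
        with pytest.raises(ValueError, match="overlap"):
            sg.render_movie(sc, roi_radius=6, field=(64, 64),
                            centers=[(20, 20), (25, 20)])


class TestMembrane:
    def test_subthreshold_steady_state_exact(self):
        ms = sg.MembraneScenario(R_m=235.6, tau_m=30.0)
        sweep = sg.simulate_current_step(ms, -100.0, 0.2, 1.2, 20_000.0)
        i_off = int(1.2 * 20_000)
        deflection = ms.E_L - sweep.V[i_off - 1]
        assert deflection == pytest.approx(23.56, abs=1e-6)

    def test_subthreshold_matches_rc_closed_form(self):
        # independent closed form: V = E_L + R*I*(1 - exp(-t/tau)) / 1000
        ms = sg.MembraneScenario(R_m=300.0, tau_m=25.0, sag_fraction=0.0)
        fs = 20_000.0
        sweep = sg.simulate_current_step(ms, -80.0, 0.2, 1.2, fs)
        on = (sweep.t >= 0.2) & (sweep.t < 1.2)
        te = sweep.t[on] - 0.2
        expected = ms.E_L + 300.0 * (-80.0) / 1000.0 * (
            1 - np.exp(-te / 0.025))
        assert np.max(np.abs(sweep.V[on] - expected)) < 0.1

    @pytest.mark.parametrize("ratio", [1.019, 1.053])
    def test_sag_construction_hits_requested_ratio(self, ratio):
        ms = sg.MembraneScenario(
            sag_fraction=sg.sag_fraction_for_ratio(ratio))
        sweep = sg.simulate_current_step(ms, -100.0, 0.2, 1.2, 20_000.0)
        assert ef.sag_ratio(sweep) == pytest.approx(ratio, abs=1e-3)

    def test_analytic_lif_rheobase(self):
        # I = dV / (R * (1 - exp(-T/tau))): 15 mV, 300 MOhm -> 50 pA
        ms = sg.MembraneScenario(R_m=300.0, tau_m=30.0, E_L=-60.0,
                                 V_th=-45.0)
        assert sg.lif_rheobase(ms) == pytest.approx(50.0, rel=1e-3)

    def test_suprathreshold_step_fires(self):
        ms = sg.MembraneScenario(R_m=300.0, tau_m=30.0, E_L=-60.0,
                                 V_th=-45.0)
        sweep = sg.simulate_current_step(ms, 80.0, 0.2, 1.2, 20_000.0)
        assert len(ef.detect_spikes(sweep)) >= 1

    def test_invalid_step_raises(self):
        ms = sg.MembraneScenario()
        with pytest.raises(ValueError):
            sg.simulate_current_step(ms, -100.0, t_on=1.0, t_off=0.5)


class TestAPWaveform:
    def test_max_depolarization_rate_by_construction(self):
        p = sg.APShapeParams(max_depol_rate=40.0)
        fs = 50_000.0
        w = sg.make_ap_waveform(p, fs)
        dvdt = np.gradient(w) * fs / 1000.0
        assert dvdt.max() == pytest.approx(40.0, rel=0.02)

    def test_notch_creates_single_rising_limb_minimum(self):
        p = sg.APShapeParams(indented=True, notch_depth=0.3)
        fs = 50_000.0
        w = sg.make_ap_waveform(p, fs)
        dvdt = np.gradient(w) * fs / 1000.0
        rise = dvdt[: int(np.argmax(w))]
        from scipy.signal import find_peaks

        troughs, props = find_peaks(-rise, prominence=0.1 * rise.max())
        assert len(troughs) == 1

    def test_no_mahp_means_no_undershoot(self):
        p = sg.APShapeParams(mahp_amplitude=0.0)
        w = sg.make_ap_waveform(p, 50_000.0)
        assert w.min() >= p.threshold - 1e-9

    def test_unresolvable_half_width_raises(self):
        p = sg.APShapeParams(half_width=1.0)
        with pytest.raises(ValueError):
            sg.make_ap_waveform(p, 5_000.0)

    def test_half_width_below_limb_floor_raises(self):
        floor = sg.min_half_width(sg.APShapeParams(), 50_000.0)
        with pytest.raises(ValueError):
            sg.make_ap_waveform(
                sg.APShapeParams(half_width=0.55 * floor), 50_000.0)

    def test_shape_param_invariants(self):
        with pytest.raises(ValueError):
            sg.APShapeParams(indented=True, notch_depth=0.0)
        with pytest.raises(ValueError):
            sg.APShapeParams(indented=False, notch_depth=0.3)
        with pytest.raises(ValueError):
            sg.APShapeParams(half_width=-1.0)
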