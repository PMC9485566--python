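"""Current-clamp feature battery: spikes, passive properties, phase plots."""

from __future__ import annotations

import numpy as np
import pytest

from cinpop import ephys_features as ef
from cinpop import synthgen as sg
from cinpop.containers import StepProtocol, SweepRecording

from conftest import spontaneous_sweep

FS = 20_000.0


def flat_sweep(duration=1.0, level=-60.0, fs=FS, noise=0.0, seed=0):
    n = int(duration * fs)
    rng = np.random.default_rng(seed)
    V = np.full(n, level) + (rng.normal(0, noise, n) if noise else 0.0)
    return SweepRecording(np.arange(n) / fs, V, np.zeros(n), fs)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        assert ef.detect_spikes(flat_sweep()).size == 0

    def test_noise_only_trace_no_spikes(self):
        assert ef.detect_spikes(flat_sweep(noise=0.3, seed=1)).size == 0

    def test_five_inserted_aps_detected_at_times(self):
        times = np.array([0.1, 0.35, 0.6, 0.85, 1.1])
        sweep = spontaneous_sweep(sg.APShapeParams(mahp_half_width=60.0),
                                  times, 1.4)
        detected = ef.detect_spikes(sweep)
        assert len(detected) == 5
        assert np.all(np.abs(detected - times) < 1e-3)


class TestPassiveProperties:
    @pytest.mark.parametrize("R", [235.6, 363.2])
    def test_linear_iv_recovers_input_resistance(self, R):
        ms = sg.MembraneScenario(R_m=R, tau_m=30.0, E_L=-60.0)
        sweeps = [sg.simulate_current_step(ms, a, 0.2, 1.2, FS)
                  for a in (-100, -80, -60, -40, -20, 0, 20)]
        iv = ef.fit_iv(sweeps, eval_at=-60.0)
        assert iv.R_N == pytest.approx(R, abs=0.1)
        # linear membrane: the cubic's higher-order terms vanish
        assert abs(iv.cubic_coeffs[0]) < 1e-8
        assert abs(iv.cubic_coeffs[1]) < 1e-6

    def test_cubic_iv_derivative_matches_analytic(self):
        # synthesize steady-state points from a known cubic and check dV/dI
        coeffs = np.array([2e-6, -1e-4, 0.25, -60.0])  # V(I), I in pA
        amps = np.linspace(-100, 60, 9)
        sweeps = []
        for a in amps:
            v_ss = np.polyval(coeffs, a)
            n = int(1.4 * FS)
            t = np.arange(n) / FS
            V = np.full(n, -60.0)
            on = (t >= 0.2) & (t < 1.2)
            V[on] = -60.0 + (v_ss + 60.0) * (1 - np.exp(-(t[on] - 0.2)
                                                        / 0.02))
            step = StepProtocol(a, 0.2, 1.2)
            sweeps.append(SweepRecording(t, V, step.current(t), FS, step))
        iv = ef.fit_iv(sweeps, eval_at=-60.0)
        expected = np.polyval(np.polyder(coeffs), iv.eval_I) * 1000.0
        assert iv.R_N == pytest.approx(expected, rel=0.005)

    def test_rheobase_matches_analytic_lif(self):
        ms = sg.MembraneScenario(R_m=300.0, tau_m=30.0, E_L=-60.0,
                                 V_th=-45.0)
        amps = np.arange(5.0, 105.0, 5.0)
        rheo, res = ef.rheobase(
            runner=lambda a: sg.simulate_current_step(ms, a, 0.2, 1.2, FS),
            amplitudes=amps)
        assert res == 5.0
        assert abs(rheo - sg.lif_rheobase(ms)) <= 5.0

    def test_rheobase_scales_with_threshold_distance(self):
        amps = np.arange(5.0, 305.0, 5.0)

        def measured(v_th):
            ms = sg.MembraneScenario(R_m=300.0, tau_m=30.0, E_L=-60.0,
                                     V_th=v_th)
            rheo, _ = ef.rheobase(
                runner=lambda a: sg.simulate_current_step(ms, a, 0.2, 1.2,
                                                          FS),
                amplitudes=amps)
            return rheo

        assert abs(measured(-30.0) - 2 * measured(-45.0)) <= 5.0

    def test_rheobase_all_subthreshold_raises(self):
        ms = sg.MembraneScenario(R_m=300.0, V_th=-20.0)
        with pytest.raises(ValueError, match="max tested"):
            ef.rheobase(
                runner=lambda a: sg.simulate_current_step(ms, a, 0.2, 1.2,
                                                          FS),
                amplitudes=np.arange(5.0, 30.0, 5.0))

    def test_sag_free_rc_response_ratio_one(self):
        ms = sg.MembraneScenario(sag_fraction=0.0)
        sweep = sg.simulate_current_step(ms, -100.0, 0.2, 1.2, FS)
        assert ef.sag_ratio(sweep) == pytest.approx(1.0, abs=0.002)

    @pytest.mark.parametrize("ratio", [1.019, 1.053])
    def test_sag_ratio_recovery(self, ratio):
        ms = sg.MembraneScenario(
            sag_fraction=sg.sag_fraction_for_ratio(ratio))
        sweep = sg.simulate_current_step(ms, -100.0, 0.2, 1.2, FS)
        assert ef.sag_ratio(sweep) == pytest.approx(ratio, abs=1e-3)

    def test_depolarizing_step_rejected(self):
        ms = sg.MembraneScenario(V_th=0.0)
        sweep = sg.simulate_current_step(ms, 20.0, 0.2, 1.2, FS)
        with pytest.raises(ValueError, match="hyperpolarizing"):
            ef.sag_ratio(sweep)


class TestPhasePlots:
    def test_max_dvdt_by_construction(self):
        sweep = spontaneous_sweep(sg.APShapeParams(max_depol_rate=40.0),
                                  [0.1], 1.0)
        pp = ef.phase_plot(sweep)
        assert pp.dVdt_mean.max() == pytest.approx(40.0, rel=0.02)

    def test_sinusoid_phase_plot_is_ellipse(self):
        f, amp, fs = 5.0, 10.0, 50_000.0
        t = np.arange(int(fs)) / fs
        V = amp * np.sin(2 * np.pi * f * t)
        d = ef.dvdt(V, fs)
        expected_max = 2 * np.pi * f * amp / 1000.0  # mV/ms
        assert d.max() == pytest.approx(expected_max, rel=0.01)

    def test_two_identical_spikes_zero_sem(self):
        sweep = spontaneous_sweep(sg.APShapeParams(mahp_half_width=60.0),
                                  [0.2, 0.7], 1.2)
        pp = ef.phase_plot(sweep)
        assert len(pp.V) == 2
        assert np.max(pp.dVdt_sem) < 1e-9

    def test_phase_plot_invariant_to_offset_and_shift(self):
        sweep = spontaneous_sweep(sg.APShapeParams(), [0.3], 1.0)
        shifted = SweepRecording(sweep.t + 5.0, sweep.V + 7.0, sweep.I,
                                 sweep.fs)
        a = ef.phase_plot(sweep)
        b = ef.phase_plot(shifted)
        assert b.dVdt_mean.max() == pytest.approx(a.dVdt_mean.max(),
                                                  rel=1e-9)


class TestApFeatures:
    def test_table_regime_round_trip(self):
        p = sg.APShapeParams(threshold=-41.2, amplitude_from_threshold=56.08,
                             half_width=5.0, max_depol_rate=40.0,
                             max_repol_rate=12.0, mahp_amplitude=8.0,
                             mahp_half_width=216.9)
        sweep = spontaneous_sweep(p, [0.2], 1.2)
        f = ef.ap_features(sweep, ef.detect_spikes(sweep)[0])
        assert f.amplitude_from_threshold == pytest.approx(56.08, rel=0.05)
        assert f.half_width == pytest.approx(5.0, rel=0.05)
        assert f.threshold_V == pytest.approx(-41.2, rel=0.05)
        assert f.mahp_half_width == pytest.approx(216.9, rel=0.05)

    def test_parameter_recovery_sweep(self):
        """Round trip over random AP shapes: all features within 5%,
        indentation flag exact."""
        rng = np.random.default_rng(2024)
        n_correct = 0
        for k in range(12):
            indented = k % 2 == 0
            p = sg.APShapeParams(
                threshold=rng.uniform(-45, -38),
                amplitude_from_threshold=rng.uniform(45, 60),
                max_depol_rate=rng.uniform(30, 55),
                max_repol_rate=rng.uniform(9, 16),
                mahp_amplitude=rng.uniform(4, 10),
                mahp_half_width=rng.uniform(100, 220),
                indented=indented,
                notch_depth=rng.uniform(0.25, 0.45) if indented else 0.0,
                half_width=1.0,
            )
            floor = sg.min_half_width(p, 50_000.0)
            p = sg.APShapeParams(**{**p.__dict__,
                                    "half_width": floor
                                    + rng.uniform(0.3, 1.5)})
            sweep = spontaneous_sweep(p, [0.2], 1.2)
            f = ef.ap_features(sweep, ef.detect_spikes(sweep)[0])
            assert f.amplitude_from_threshold == pytest.approx(
                p.amplitude_from_threshold, rel=0.05)
            assert f.half_width == pytest.approx(p.half_width, rel=0.05)
            assert f.max_depol_rate == pytest.approx(p.max_depol_rate,
                                                     rel=0.05)
            assert abs(f.max_repol_rate) == pytest.approx(p.max_repol_rate,
                                                          rel=0.05)
            assert f.mahp_amplitude == pytest.approx(p.mahp_amplitude,
                                                     rel=0.05)
            n_correct += f.indented == p.indented
        assert n_correct == 12

    def test_indentation_boundary(self):
        for depth, expected in [(0.3, True), (0.05, False)]:
            p = sg.APShapeParams(indented=True, notch_depth=depth)
            sweep = spontaneous_sweep(p, [0.2], 1.0)
            f = ef.ap_features(sweep, ef.detect_spikes(sweep)[0])
            assert f.indented is expected

    def test_smooth_rise_not_indented(self):
        sweep = spontaneous_sweep(sg.APShapeParams(), [0.2], 1.0)
        f = ef.ap_features(sweep, ef.detect_spikes(sweep)[0])
        assert not f.indented


class TestAhp:
    def test_triangular_ahp_half_width(self):
        fs = 20_000.0
        base, depth, width_ms = -50.0, 10.0, 200.0
        n = int(width_ms / 1000 * fs)
        down = np.linspace(base, base - depth, n // 2)
        up = np.linspace(base - depth, base, n - n // 2)
        trace = np.concatenate([[base], down, up, [base]])
        assert ef.ahp_half_width(trace, fs) == pytest.approx(100.0, rel=0.02)

    @pytest.mark.parametrize("hw", [130.0, 216.9])
    def test_synthetic_mahp_half_width_recovery(self, hw):
        p = sg.APShapeParams(mahp_half_width=hw)
        sweep = spontaneous_sweep(p, [0.2], 1.2)
        f = ef.ap_features(sweep, ef.detect_spikes(sweep)[0])
        assert f.mahp_half_width == pytest.approx(hw, rel=0.05)

    def test_too_shallow_ahp_raises(self):
        with pytest.raises(ValueError, match="1 mV"):
            ef.ahp_half_width(np.full(1000, -50.0), 20_000.0)


class TestFiringStats:
    def test_periodic_train(self):
        times = np.arange(0.25, 10.0, 0.5)
        sweep = spontaneous_sweep(sg.APShapeParams(mahp_half_width=100.0),
                                  times, 10.0)
        stats = ef.firing_stats(sweep, window=10.0)
        assert stats.mean_rate == pytest.approx(2.0, abs=0.11)
        assert stats.cv_isi == pytest.approx(0.0, abs=0.01)
        assert stats.spontaneous

    def test_gamma_isi_cv_recovery_through_detection(self):
        train = sg.make_spike_train("irregular", 4.0, 0.5, 130.0, seed=8)
        sweep = spontaneous_sweep(
            sg.APShapeParams(mahp_half_width=20.0, mahp_amplitude=2.0),
            train.spike_times, 130.0, fs=20_000.0)
        stats = ef.firing_stats(sweep, window=120.0)
        assert stats.cv_isi == pytest.approx(0.5, rel=0.10)

    def test_empty_trace(self):
        stats = ef.firing_stats(flat_sweep(duration=2.0), window=2.0)
        assert stats.mean_rate == 0.0 and stats.cv_isi is None


class TestIfCurve:
    def test_subthreshold_amplitudes_are_zero(self):
        ms = sg.MembraneScenario(R_m=300.0, V_th=-45.0)
        sweeps = [sg.simulate_current_step(ms, a, 0.2, 1.2, FS)
                  for a in (10.0, 20.0, 30.0)]
        curve = ef.if_curve(sweeps)
        assert all(f == 0.0 for _, f in curve)

    def test_frequency_nondecreasing_in_current(self):
        ms = sg.MembraneScenario(
            R_m=300.0, V_th=-50.0,
            ap_shape=sg.APShapeParams(mahp_half_width=80.0))
        sweeps = [sg.simulate_current_step(ms, a, 0.2, 1.2, FS)
                  for a in (20.0, 40.0, 80.0, 120.0)]
        freqs = [f for _, f in ef.if_curve(sweeps)]
        assert freqs == sorted(freqs)
        assert freqs[-1] > 0
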