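"""Gating statistics, I-V extraction, response times, step detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photopore as pp
from photopore.photochemistry import H7

from conftest import GREEN, UV


def make_trace(x, fs, protocol=None):
    x = np.asarray(x, dtype=float)
    return pp.Trace(np.arange(x.size) / fs, x, fs, protocol=protocol)


class TestGatingScalars:
    def test_gating_percent_on_printed_ensemble_currents(self):
        # I_ON = 11.4 nA, I_OFF = 1.8 nA
        assert pp.gating_percent(11_400.0, 1_800.0) == pytest.approx(84.2, abs=0.05)

    @pytest.mark.parametrize("i_off,expected", [(0.0, 100.0), (10.0, 0.0)])
    def test_gating_percent_limits(self, i_off, expected):
        assert pp.gating_percent(10.0, i_off) == pytest.approx(expected)

    def test_zero_i_on_rejected(self):
        with pytest.raises(ValueError):
            pp.gating_percent(0.0, 1.0)

    @pytest.mark.parametrize("gate,fold", [(95.0, 20.0), (0.0, 1.0), (50.0, 2.0)])
    def test_fold_change_values(self, gate, fold):
        assert pp.fold_change_from_gating(gate) == pytest.approx(fold)

    def test_full_gating_overflows_to_infinity(self):
        assert pp.fold_change_from_gating(100.0) == math.inf

    @given(gate=st.floats(0.0, 99.5))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_gating_and_fold_change_are_inverses(self, gate):
        fold = pp.fold_change_from_gating(gate)
        assert pp.gating_percent(1.0, 1.0 / fold) == pytest.approx(gate, abs=1e-9)

    @pytest.mark.parametrize("args,raw,rounded", [
        ((85.0, 0.3), 283.3, 300.0),
        ((100.0, 50.0), 2.0, 2.0),
    ])
    def test_level_capacity(self, args, raw, rounded):
        cap = pp.level_capacity(*args)
        assert cap.raw == pytest.approx(raw, abs=0.05)
        assert cap.rounded == rounded

    def test_level_capacity_monotone_in_fluctuation(self):
        raws = [pp.level_capacity(85.0, f).raw for f in (0.1, 0.3, 1.0, 5.0)]
        assert np.all(np.diff(raws) < 0)

    def test_level_capacity_zero_fluctuation_rejected(self):
        with pytest.raises(ValueError):
            pp.level_capacity(85.0, 0.0)

    def test_estimate_pz_endpoints_midpoint_and_clipping(self):
        assert pp.estimate_pz_from_ensemble(64.0, 64.0, 3.2) == (1.0, False)
        p, clipped = pp.estimate_pz_from_ensemble((64.0 + 3.2) / 2, 64.0, 3.2)
        assert p == pytest.approx(0.5) and not clipped
        p, clipped = pp.estimate_pz_from_ensemble(70.0, 64.0, 3.2)
        assert p == 1.0 and clipped
        with pytest.raises(ValueError):
            pp.estimate_pz_from_ensemble(1.0, 5.0, 5.0)

    def test_pz_recovery_from_simulated_equilibrium(self):
        """Ensemble equilibrium current at the 455 nm PSS inverts back to
        p_Z = 0.45 within 3 s.e. of the binomial composition noise."""
        n = 2000
        model = pp.EnsembleModel(n_pores=n, noise_fraction=0.0)
        blue = pp.LightField.single(455, 56.3)
        proto = pp.Protocol.light_cycle([(blue, 30.0)], voltage=100.0)
        tr = pp.simulate(model, proto, seed=21, sample_rate=100,
                         initial_state=0.45)
        i_eq = tr.i_pA[-200:].mean()
        p_hat, clipped = pp.estimate_pz_from_ensemble(
            i_eq, n * 64.0, n * 3.2)
        se = math.sqrt(0.45 * 0.55 / (7 * n))
        assert not clipped
        assert abs(p_hat - 0.45) < 3 * se


class TestIVExtraction:
    def test_noiseless_resistor_recovers_straight_line_through_origin(self):
        model = pp.EnsembleModel(
            n_pores=1, noise_fraction=0.0,
            conductance=pp.ConductanceModel(mode="resistor"))
        ramp = pp.RampVoltage(dwell_s=0.05)
        proto = pp.Protocol(duration_s=float(ramp.edges[-1]), voltage=ramp)
        tr = pp.simulate(model, proto, seed=0, sample_rate=2000,
                         initial_state="Z")
        iv = pp.extract_iv(tr)
        slope = np.polyfit(iv.voltage_mV, iv.current_pA, 1)
        assert slope[0] == pytest.approx(0.64, rel=1e-6)
        assert abs(slope[1]) < 1e-6
        assert iv.current_at(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_on_state_conductance_recovered_within_error(self):
        """Parameter recovery: simulated noisy single-pore ramp returns the
        configured ON conductance at +100 mV within 3 s.e."""
        model = pp.EnsembleModel(n_pores=1, noise_fraction=0.003)
        ramp = pp.RampVoltage(dwell_s=0.2)
        proto = pp.Protocol(duration_s=float(ramp.edges[-1]), voltage=ramp)
        tr = pp.simulate(model, proto, seed=4, sample_rate=25_000,
                         initial_state="Z")
        iv = pp.extract_iv(pp.standard_chain(tr))
        idx = np.nonzero(iv.voltage_mV == 100.0)[0][0]
        se = max(iv.ci95_pA[idx] / 1.96, 1e-3)
        assert abs(iv.current_pA[idx] - 64.0) < max(3 * se, 0.3)

    def test_off_state_passes_almost_no_positive_current(self):
        model = pp.EnsembleModel(n_pores=1, noise_fraction=0.0)
        ramp = pp.RampVoltage(dwell_s=0.05)
        proto = pp.Protocol(duration_s=float(ramp.edges[-1]), voltage=ramp)
        tr = pp.simulate(model, proto, seed=0, sample_rate=2000,
                         initial_state="E")
        iv = pp.extract_iv(tr)
        pos = iv.current_pA[iv.voltage_mV > 0]
        assert np.all(pos <= 0.05 * 64.0 * 2 + 1e-9)
        assert iv.current_at(-100.0) == pytest.approx(-32.0, rel=1e-6)

    def test_missing_protocol_rejected(self):
        tr = make_trace(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            pp.extract_iv(tr)


class TestRectificationRatio:
    def test_symmetric_curve_gives_one(self):
        v = np.arange(-100.0, 101.0, 10.0)
        iv = pp.IVCurve(v, 0.5 * v)
        assert pp.rectification_ratio(iv, 100.0) == pytest.approx(1.0)

    def test_iv_and_trace_paths_agree(self):
        """The ratio computed from a model I-V curve equals the one measured
        from a simulated voltage-step trace of the same model."""
        model = pp.EnsembleModel(n_pores=1, noise_fraction=0.001)
        v_grid, i_model = pp.iv_curve_points(model.conductance, 0)
        iv_model = pp.IVCurve(v_grid, i_model)
        ramp = pp.RampVoltage(dwell_s=0.1)
        proto = pp.Protocol(duration_s=float(ramp.edges[-1]), voltage=ramp)
        tr = pp.simulate(model, proto, seed=8, sample_rate=5000,
                         initial_state="E")
        r_trace = pp.rectification_ratio(pp.extract_iv(tr), 100.0)
        r_model = pp.rectification_ratio(iv_model, 100.0)
        assert r_trace == pytest.approx(r_model, rel=0.1)

    def test_missing_voltage_rejected(self):
        iv = pp.IVCurve(np.array([-50.0, 50.0]), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError):
            pp.rectification_ratio(iv, 100.0)


class TestResponseTime:
    def test_instantaneous_step_detected_within_one_sample(self):
        fs = 1000.0
        x = np.concatenate([np.zeros(500), np.ones(1500)])
        tr = make_trace(x, fs)
        t = pp.response_time(tr, onset_s=0.5, from_level=0.0, to_level=1.0,
                             smooth_window_s=0.0)
        assert t <= 1.0 / fs + 1e-12

    def test_no_crossing_returns_nan(self):
        tr = make_trace(np.zeros(1000), 1000.0)
        assert math.isnan(pp.response_time(tr, 0.1, 0.0, 1.0,
                                           smooth_window_s=0.0))

    def test_uv_transition_time_consistent_with_calibration(self):
        """Mean simulated single-pore 365 nm switching time should sit near
        the 1.8 s used to calibrate the rate scale (within 30%)."""
        model = pp.EnsembleModel(n_pores=1, noise_fraction=0.003)
        proto = pp.Protocol.light_cycle([(pp.DARK, 1.0), (UV, 12.0)])
        times = []
        for seed in range(25):
            tr = pp.simulate(model, proto, seed=seed, sample_rate=1000,
                             initial_state="E")
            tr = pp.bessel_lowpass(tr, 20.0)
            t = pp.response_time(tr, onset_s=1.0, from_level=3.2,
                                 to_level=64.0, smooth_window_s=0.05)
            times.append(t)
        mean_t = float(np.mean(times))
        assert mean_t == pytest.approx(1.8, rel=0.30)

    def test_ensemble_off_to_on_times_ordered_across_irradiances(self):
        """Lower 365 nm irradiance slows the OFF->ON transition
        monotonically across the 36.2 / 28.2 / 13.4 mW cm^-2 series."""
        times = []
        model = pp.EnsembleModel(n_pores=64, noise_fraction=0.003)
        for q in (36.2, 28.2, 13.4):
            fld = pp.LightField.single(365, q)
            proto = pp.Protocol.light_cycle([(pp.DARK, 0.5), (fld, 20.0)])
            tr = pp.simulate(model, proto, seed=17, sample_rate=500,
                             initial_state="E")
            tr = pp.bessel_lowpass(tr, 20.0)
            times.append(pp.response_time(
                tr, onset_s=0.5, from_level=64 * 3.2, to_level=64 * 61.57,
                smooth_window_s=0.05))
        assert times[0] < times[1] < times[2]

    def test_expfit_method_agrees_with_threshold_on_clean_exponential(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = 10.0 * (1 - np.exp(-t / 1.5))
        tr = make_trace(x, fs)
        t_thr = pp.response_time(tr, 0.0, 0.0, 10.0, smooth_window_s=0.0)
        t_fit = pp.response_time(tr, 0.0, 0.0, 10.0, method="expfit")
        assert t_fit == pytest.approx(1.5 * math.log(10), rel=0.02)
        assert t_thr == pytest.approx(t_fit, rel=0.05)


class TestStepDetection:
    def test_noiseless_staircase_recovered_exactly(self):
        fs = 1000.0
        x = np.concatenate([np.full(1000, 64.0), np.full(1000, 40.0),
                            np.full(1000, 10.0)])
        tr = make_trace(x, fs)
        steps = pp.detect_steps(tr, smooth_window_s=0.0)
        assert len(steps) == 3
        times = [s[0] for s in steps]
        levels = [s[1] for s in steps]
        assert times[0] == 0.0
        assert times[1] == pytest.approx(1.0, abs=1.5 / fs)
        assert times[2] == pytest.approx(2.0, abs=1.5 / fs)
        assert levels == pytest.approx([64.0, 40.0, 10.0], abs=1e-9)

    def test_single_pore_green_transition_levels_lie_on_the_nZ_lattice(self):
        """Stepwise current changes of one pore under green light land on
        the 8-level configuration lattice: at most 8 distinct levels, each
        close to a multiple of one-switch conductance above the OFF level."""
        model = pp.EnsembleModel(n_pores=1, noise_fraction=0.003)
        proto = pp.Protocol.light_cycle([(GREEN, 60.0)])
        lattice = 3.2 + np.arange(8) / 7 * 60.8
        for seed in (1, 2, 3):
            tr = pp.simulate(model, proto, seed=seed, sample_rate=2000,
                             initial_state="Z")
            tr = pp.decimate(pp.bessel_lowpass(tr, 20.0), 4)
            steps = pp.detect_steps(tr, min_dwell_s=0.2)
            assert len(steps) >= 3  # the descent is resolved into steps
            levels = np.array([s[1] for s in steps])
            nearest = lattice[np.abs(levels[:, None] - lattice).argmin(axis=1)]
            # levels sit on the lattice (transition-straddling windows may
            # blur a level partway between two rungs)
            assert np.median(np.abs(levels - nearest)) < 60.8 / 7 / 3
            assert len(set(np.round(levels / (60.8 / 7)).astype(int))) <= 8

    def test_pure_noise_yields_no_steps(self, rng):
        fs = 1000.0
        false_positive_runs = 0
        for _ in range(30):
            tr = make_trace(rng.normal(0.0, 0.2, size=8000), fs)
            steps = pp.detect_steps(tr)
            if len(steps) > 1:
                false_positive_runs += 1
        assert false_positive_runs <= 1


class TestHalfCycleRectification:
    def test_requires_protocol(self):
        tr = make_trace(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            pp.half_cycle_rectification(tr)
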