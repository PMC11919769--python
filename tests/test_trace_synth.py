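"""Stochastic trace synthesis: switching statistics, census, AC response."""

import math

import numpy as np
import pytest
from scipy import stats

import photopore as pp
from photopore.photochemistry import relax_fraction_Z

from conftest import GREEN, UV


def quiet_model(n_pores=1, **kw):
    kw.setdefault("noise_fraction", 0.0)
    return pp.EnsembleModel(n_pores=n_pores, **kw)


class TestSwitchingStatistics:
    def test_dark_protocol_has_no_transitions_and_flat_current(self):
        model = quiet_model()
        proto = pp.Protocol(duration_s=5.0)
        trace, events = pp.simulate(model, proto, seed=1, sample_rate=1000,
                                    initial_state="Z", return_states=True)
        assert events.times.size == 0
        assert np.allclose(trace.i_pA, trace.i_pA[0])

    def test_terminal_Z_fraction_matches_uv_pss(self):
        """After long 365 nm exposure the per-switch Z fraction across
        >= 10^4 switches sits within 3 s.e. of the 96% photostationary
        value."""
        n_pores = 1500  # 10,500 switches
        model = quiet_model(n_pores)
        proto = pp.Protocol.light_cycle([(UV, 8.0)])  # ~12 equilibration times
        events = pp.simulate_switching(model, proto, seed=7, initial_state="E")
        frac = events.final_states.mean()
        p = 0.96
        se = math.sqrt(p * (1 - p) / (n_pores * 7))
        assert abs(frac - p) < 3 * se

    def test_green_switching_passes_through_intermediate_plateaus(self):
        """A single pore leaving the fully-ON state under green light steps
        down through resolvable intermediate configurations (>= 2 levels
        dwelling > 50 ms between the end states) in nearly every run."""
        model = quiet_model()
        proto = pp.Protocol.light_cycle([(GREEN, 120.0)])
        good = 0
        n_runs = 40
        for seed in range(n_runs):
            events = pp.simulate_switching(model, proto, seed, initial_state="Z")
            tt, nz = events.n_Z_trajectory(0)
            dwell = np.diff(np.concatenate([tt, [proto.duration_s]]))
            resolvable = {int(n) for n, d in zip(nz, dwell)
                          if d > 0.05 and 0 < n < 7}
            if len(resolvable) >= 2:
                good += 1
        assert good >= int(0.95 * n_runs) - 1

    def test_event_driven_mean_matches_master_equation(self):
        """The Gillespie ensemble mean current tracks the closed-form
        two-state master-equation solution within Monte-Carlo error."""
        n_pores = 400
        model = quiet_model(n_pores)
        proto = pp.Protocol.light_cycle([(UV, 3.0)], voltage=100.0)
        trace = pp.simulate(model, proto, seed=11, sample_rate=200,
                            initial_state="E")
        cond = model.conductance
        i_on, i_off = float(cond.i_on(100.0)), float(cond.i_off(100.0))
        p_t = np.array([relax_fraction_Z(model.photoswitch, UV, 0.0, t)
                        for t in trace.t])
        expected = n_pores * (i_off + p_t * (i_on - i_off))
        # binomial fluctuation of the ensemble composition
        sd = np.sqrt(n_pores * 7 * p_t * (1 - p_t)) * (i_on - i_off) / 7
        resid = trace.i_pA - expected
        assert np.all(np.abs(resid) < 5 * np.maximum(sd, 1e-9) + 1e-6)

    def test_same_seed_is_bit_identical_different_seed_is_not(self):
        model = pp.EnsembleModel(n_pores=20)
        proto = pp.Protocol.light_cycle([(UV, 2.0), (GREEN, 2.0)])
        a = pp.simulate(model, proto, seed=5, sample_rate=2000)
        b = pp.simulate(model, proto, seed=5, sample_rate=2000)
        c = pp.simulate(model, proto, seed=6, sample_rate=2000)
        assert np.array_equal(a.i_pA, b.i_pA)
        assert not np.array_equal(a.i_pA, c.i_pA)

    def test_equilibrium_current_is_irradiance_invariant(self):
        """Reducing the light intensity after equilibrium does not move the
        current level (PSS invariance), only the approach kinetics."""
        model = quiet_model(800)
        means = []
        for scale in (1.0, 0.3):
            proto = pp.Protocol.light_cycle([(UV.scaled(scale), 25.0)])
            trace = pp.simulate(model, proto, seed=3, sample_rate=200)
            means.append(trace.i_pA[-500:].mean())
        assert means[1] == pytest.approx(means[0], rel=0.01)

    def test_relative_fluctuation_scales_as_inverse_sqrt_pores(self):
        def rel_fluct(n_pores, seed):
            model = quiet_model(n_pores)
            proto = pp.Protocol.light_cycle([(GREEN, 60.0)], voltage=100.0)
            tr = pp.simulate(model, proto, seed, sample_rate=50,
                             initial_state=0.07)
            x = tr.i_pA[tr.t > 30.0]
            return x.std() / x.mean()

        r_small = np.mean([rel_fluct(64, s) for s in range(3)])
        r_big = np.mean([rel_fluct(1024, s) for s in range(3)])
        assert r_small / r_big == pytest.approx(4.0, rel=0.5)

    def test_drift_adds_linear_baseline(self):
        model = quiet_model(drift_pA_per_s=2.0)
        proto = pp.Protocol(duration_s=4.0)
        tr = pp.simulate(model, proto, seed=0, sample_rate=100,
                         initial_state="Z")
        fit = np.polyfit(tr.t, tr.i_pA, 1)
        assert fit[0] == pytest.approx(2.0, abs=1e-6)

    def test_asymmetric_salt_emf_drives_current_at_zero_applied_volts(self):
        # 0.2/2 M KCl decade: ~59 mV Nernstian driving force
        model = quiet_model(10)
        proto = pp.Protocol(duration_s=1.0, voltage=pp.ConstantVoltage(0.0),
                            emf_offset_mV=59.0)
        tr = pp.simulate(model, proto, seed=0, sample_rate=100,
                         initial_state="Z")
        assert tr.i_pA.mean() == pytest.approx(10 * 0.64 * 59.0, rel=1e-6)


class TestStateCensus:
    def test_zero_pz_puts_all_pores_fully_off(self, pzme):
        model = pp.EnsembleModel(n_pores=500, photoswitch=pzme)
        census = pp.state_census(model, GREEN, t_s=0.0, seed=1,
                                 initial_p_Z=0.0)
        assert census[0] == 500 and census[1:].sum() == 0

    def test_green_equilibrium_fully_off_fraction_near_0p602(self, pzme):
        """At the 530 nm PSS (93% E) the fully-OFF pore fraction is the
        binomial point mass 0.93^7 ~ 0.602."""
        n = 20_000
        model = pp.EnsembleModel(n_pores=n, photoswitch=pzme)
        census = pp.state_census(model, GREEN, seed=2)
        frac = census[0] / n
        p_expect = 0.93**7
        se = math.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(frac - p_expect) < 3 * se

    def test_gillespie_census_fits_binomial(self, pzme):
        """Chi-square goodness of fit of the event-driven simulator's
        terminal composition against Binomial(7, 0.96), alpha = 0.01."""
        n = 10_000
        model = pp.EnsembleModel(n_pores=n, photoswitch=pzme,
                                 noise_fraction=0.0)
        proto = pp.Protocol.light_cycle([(UV, 10.0)])
        events = pp.simulate_switching(model, proto, seed=13,
                                       initial_state="E")
        counts = np.bincount(events.final_n_Z, minlength=8)
        expected = stats.binom.pmf(np.arange(8), 7, 0.96) * n
        # merge low-expectation bins (n_Z <= 4) into one class
        obs = np.array([counts[:5].sum(), counts[5], counts[6], counts[7]])
        exp = np.array([expected[:5].sum(), expected[5], expected[6],
                        expected[7]])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p_value = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p_value > 0.01


class TestAcResponse:
    def test_off_state_half_wave_rectifies(self):
        model = quiet_model(100)
        tr = pp.ac_response(model, 100.0, 0.03, "off", seed=1)
        assert pp.half_cycle_rectification(tr, resistive_only=True) >= 5.0

    def test_zero_amplitude_gives_zero_current(self):
        model = quiet_model(100)
        tr = pp.ac_response(model, 0.0, 0.03, "off", seed=1)
        assert np.allclose(tr.i_pA, 0.0)

    def test_on_state_is_weakly_rectified(self):
        model = quiet_model(100)
        tr = pp.ac_response(model, 100.0, 0.03, "on", seed=1)
        r = pp.half_cycle_rectification(tr, resistive_only=True)
        assert 1.0 < r < 2.0  # 0.58/0.46 branch asymmetry, far from diode

    def test_capacitive_current_degrades_rectification_at_high_frequency(self):
        model = quiet_model(20, capacitance_pF=100.0)
        slow = pp.ac_response(model, 100.0, 0.03, "off", seed=1)
        fast = pp.ac_response(model, 100.0, 3.0, "off", seed=1,
                              sample_rate=20_000)
        assert pp.half_cycle_rectification(fast) < \
            pp.half_cycle_rectification(slow)

    def test_uncompensated_capacitance_follows_dv_dt(self):
        model = quiet_model(1, capacitance_pF=200.0)
        tr = pp.ac_response(model, 50.0, 1.0, "off", seed=0,
                            sample_rate=10_000)
        cap = 200.0 * tr.protocol.voltage.dvdt(tr.t) * 1e-3
        resistive = tr.i_pA - cap
        # capacitive peak (~63 pA) dominates the off-state resistive current
        assert np.abs(cap).max() > np.abs(resistive).max()


class TestProtocolValidation:
    def test_overlapping_light_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pp.Protocol(duration_s=10.0, light_segments=(
                pp.LightSegment(0.0, 5.0, UV),
                pp.LightSegment(4.0, 5.0, GREEN)))

    def test_segment_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            pp.Protocol(duration_s=3.0,
                        light_segments=(pp.LightSegment(0.0, 5.0, UV),))

    def test_gaps_between_segments_are_dark(self):
        proto = pp.Protocol(duration_s=10.0, light_segments=(
            pp.LightSegment(2.0, 3.0, UV),))
        intervals = proto.intervals()
        assert [iv[:2] for iv in intervals] == [(0.0, 2.0), (2.0, 5.0),
                                                (5.0, 10.0)]
        assert intervals[0][2].is_dark and intervals[2][2].is_dark

    def test_protocol_round_trips_through_dict(self):
        proto = pp.Protocol.light_cycle(
            [(UV, 5.0), (pp.DARK, 2.0), (GREEN, 8.0)],
            voltage=pp.SineVoltage(100.0, 0.03), emf_offset_mV=59.0)
        again = pp.Protocol.from_dict(proto.to_dict())
        assert again == proto
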