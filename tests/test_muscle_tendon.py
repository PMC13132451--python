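import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from neuromuscle import muscle_tendon as mt
from neuromuscle import signals as sg


class TestCalciumRelease:
    def test_empty_train_stays_at_baseline(self):
        ca = mt.calcium_release(sg.SpikeTrain(np.empty(0)), 25.0, 90.0,
                                T_ms=200.0)
        assert np.all(ca.values == 0.0)

    def test_single_transient_peaks_at_closed_form_time(self):
        tau_1, tau_2 = 25.0, 90.0
        ca = mt.calcium_release(sg.SpikeTrain(np.array([0.0])), tau_1, tau_2,
                                T_ms=600.0, dt_ms=0.05)
        t_star = mt.ca_peak_time(tau_1, tau_2)
        i_pk = int(np.argmax(ca.values))
        assert i_pk * 0.05 == pytest.approx(t_star, abs=0.2)
        assert ca.values[i_pk] == pytest.approx(1.0, rel=1e-3)

    def test_length_factor_unity_at_intermediate_length(self):
        xm = sg.gen_constant(-8.0, 400.0, 0.1)
        ca = mt.calcium_release(sg.SpikeTrain(np.array([0.0])), 25.0, 90.0,
                                phi_1=0.05, phi_3=0.03, x_m=xm, T_ms=400.0)
        assert ca.values.max() == pytest.approx(1.0, rel=1e-3)

    def test_length_factor_scales_amplitude(self):
        for x, rate, expect in ((-16.0, 0.05, np.exp(-0.4)),
                                (0.0, 0.03, np.exp(0.24))):
            xm = sg.gen_constant(x, 400.0, 0.1)
            ca = mt.calcium_release(sg.SpikeTrain(np.array([0.0])), 25.0,
                                    90.0, phi_1=0.05, phi_3=0.03, x_m=xm,
                                    T_ms=400.0)
            assert ca.values.max() == pytest.approx(expect, rel=1e-3)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            mt.calcium_release(sg.SpikeTrain(np.array([0.0])), 50.0, 50.0)


class TestActivationDynamics:
    def _rmp(self, **kw):
        base = dict(tau_1=25.0, tau_2=90.0, phi_1=0.05, phi_3=0.03,
                    c1i=1.5, c1n1=1.5, c1n4=200.0, c2i=2.5, c2n1=2.5,
                    c2n4=200.0, alpha_i=0.3, beta=0.01, gamma=0.02,
                    p0_5=0.15, g_1=-1.0, g_2=18.0, a_0=0.25, b_0=30.0,
                    c_0=5.0, d_0=1.5, k_se=0.1)
        base.update(kw)
        return mt.MuscleTendonRMP(**base)

    def test_zero_calcium_zero_activation(self):
        ca = sg.gen_constant(0.0, 100.0, 0.1)
        assert np.all(mt.activation_dynamics(ca, self._rmp()) == 0.0)

    def test_saturating_calcium_drives_activation_to_one(self, sol_fiber):
        rmp, _ = sol_fiber
        spikes = sg.gen_spike_train(100.0, 0.0, 3000.0)
        ca = mt.calcium_release(spikes, rmp.tau_1, rmp.tau_2, T_ms=3000.0)
        a = mt.activation_dynamics(ca, rmp)
        tail = a[int(2000 / 0.1):]
        assert tail.min() > 0.95
        # non-decreasing after the transient (fused plateau)
        assert np.all(np.diff(tail) > -1e-4)

    def test_mechanics_invariance_without_movement_coupling(self):
        rmp = self._rmp(beta=0.0, gamma=0.0)
        ca = mt.calcium_release(sg.gen_spike_train(20.0, 0.0, 500.0),
                                rmp.tau_1, rmp.tau_2, T_ms=800.0)
        n = ca.values.size
        a1 = mt.activation_dynamics(ca, rmp, x_ce=np.zeros(n),
                                    v_ce=np.zeros(n))
        a2 = mt.activation_dynamics(ca, rmp,
                                    x_ce=np.linspace(0, -10, n),
                                    v_ce=np.full(n, -20.0))
        assert np.array_equal(a1, a2)

    def test_negative_calcium_rejected(self):
        bad = sg.Signal(0.0, 0.1, np.array([0.0, 1.0]))
        bad.values[0] = -0.1
        with pytest.raises(ValueError):
            mt.activation_dynamics(bad, self._rmp())


class TestForceLength:
    def test_peak_at_g1(self):
        assert mt.fl_factor(-1.0, -1.0, 18.0) == 1.0

    def test_even_symmetry_about_peak(self):
        for d in (1.0, 5.0, 12.0):
            assert mt.fl_factor(-1.0 + d, -1.0, 18.0) == \
                pytest.approx(mt.fl_factor(-1.0 - d, -1.0, 18.0))

    def test_half_maximum_width_scales_with_g2(self):
        g_1 = -1.0
        for g_2 in (10.0, 18.0):
            x_half = brentq(lambda x: mt.fl_factor(x, g_1, g_2) - 0.5,
                            g_1, g_1 + 5 * g_2)
            assert x_half - g_1 == pytest.approx(g_2 * np.sqrt(np.log(2.0)),
                                                 rel=1e-6)


class TestForceVelocity:
    A = dict(a_0=0.25, b_0=30.0, c_0=5.0, d_0=1.5)

    def test_isometric_normalization(self):
        assert mt.fv_factor(0.0, **self.A) == pytest.approx(1.0)

    def test_branch_monotonicity(self):
        v = np.linspace(-119.0, 0.0, 50)
        short = mt.fv_factor(v, **self.A)
        assert np.all(np.diff(short) > 0)       # less shortening -> more force
        v = np.linspace(0.0, 200.0, 50)
        length = mt.fv_factor(v, **self.A)
        assert np.all(length >= 1.0 - 1e-12)
        assert np.all(np.diff(length) > 0)

    def test_zero_force_at_maximal_shortening_velocity(self):
        vmax = self.A["b_0"] / self.A["a_0"]
        assert mt.fv_factor(-vmax, **self.A) == pytest.approx(0.0, abs=1e-12)
        # and the closed-form root of the Hill branch agrees
        root = brentq(lambda v: mt.fv_factor(v, **self.A), -vmax - 1e-9,
                      -1.0)
        assert root == pytest.approx(-vmax, rel=1e-6)

    def test_inversion_round_trip(self):
        from neuromuscle import _mt_core as core
        for r in (0.05, 0.4, 0.9, 1.0, 1.2, 1.45):
            v = core.fv_invert(r, self.A["a_0"], self.A["b_0"],
                               self.A["c_0"], self.A["d_0"], 1e4)
            assert mt.fv_factor(v, **self.A) == pytest.approx(r, abs=1e-12)


class TestHillMechanics:
    def test_inactive_fiber_produces_no_force(self, sol_fiber):
        rmp, _ = sol_fiber
        f, x, v = mt.hill_step(0.0, -8.0, -8.0, rmp, 0.1)
        assert f == 0.0 and v == 0.0

    def test_fused_tetanus_matches_algebraic_fixed_point(self, sol_fiber):
        rmp, _ = sol_fiber
        f_eq, x_eq = mt.hill_equilibrium(1.0, -8.0, rmp)
        f_sim = mt.tetanus_force(rmp, 100.0, -8.0)
        assert f_sim == pytest.approx(f_eq, rel=0.05)

    def test_isometric_calibration_yields_p05(self, sol_fiber):
        rmp, _ = sol_fiber
        f_eq, _ = mt.hill_equilibrium(1.0, -8.0, rmp)
        assert f_eq == pytest.approx(rmp.p0_5, rel=1e-6)

    def test_quick_release_drops_then_recovers(self, sol_fiber):
        rmp, _ = sol_fiber
        xm = sg.gen_length_profile("step_shortening",
                                   {"start": -8.0, "step": -3.0,
                                    "t_step": 2000.0}, 4000.0, 0.1)
        tr = mt.simulate_mt(rmp, sg.gen_spike_train(100.0, 10.0, 3900.0),
                            x_m=xm)
        before = tr.force[int(1990 / 0.1)]
        just_after = tr.force[int(2005 / 0.1)]
        recovered = tr.force[int(3800 / 0.1)]
        assert just_after < 0.3 * before
        assert recovered > 0.6 * before


class TestProtocolBattery:
    def test_twitches_isolated_at_1hz(self, sol_fiber):
        rmp, _ = sol_fiber
        tr = mt.simulate_mt(rmp, sg.gen_spike_train(1.0, 10.0, 2500.0),
                            T_ms=2990.0)
        # force returns to baseline between stimuli
        between = tr.force[int(900 / 0.1): int(1000 / 0.1)]
        assert between.max() < 0.05 * tr.force.max()

    @pytest.mark.parametrize("fiber", ["sol_fiber", "mg_fiber"])
    def test_force_frequency_monotone(self, fiber, request):
        rmp, _ = request.getfixturevalue(fiber)
        means = []
        for hz in (1.0, 10.0, 20.0, 40.0, 100.0):
            tr = mt.simulate_mt(rmp, sg.gen_spike_train(hz, 10.0, 2800.0),
                                T_ms=3000.0)
            means.append(tr.force[int(500 / 0.1): int(2800 / 0.1)].mean())
        assert np.all(np.diff(means) > 0)

    def test_twitch_tetanus_ratio_below_one(self, sol_fiber, mg_fiber):
        for rmp, _ in (sol_fiber, mg_fiber):
            peak, _, _ = mt.twitch_metrics(rmp)
            assert peak / mt.tetanus_force(rmp, 100.0) < 1.0

    def test_isokinetic_ordering(self, sol_fiber):
        rmp, _ = sol_fiber
        T = 3000.0
        spikes = sg.gen_spike_train(100.0, 10.0, T - 100.0)

        def force_at_25(xm):
            return mt.simulate_mt(rmp, spikes, x_m=xm).force[int(2500 / 0.1)]

        iso = force_at_25(sg.gen_length_profile("isometric",
                                                {"length": -8.0}, T, 0.1))
        shortening = force_at_25(sg.gen_length_profile(
            "isokinetic_ramp", {"start": 0.0, "end": -12.0,
                                "t_start": 1000.0, "t_end": 4000.0}, T, 0.1))
        lengthening = force_at_25(sg.gen_length_profile(
            "isokinetic_ramp", {"start": -16.0, "end": -4.0,
                                "t_start": 1000.0, "t_end": 4000.0}, T, 0.1))
        assert shortening < iso < lengthening

    def test_tetanic_force_ordered_by_length(self, sol_fiber):
        rmp, _ = sol_fiber
        forces = [mt.tetanus_force(rmp, 100.0, x) for x in
                  (0.0, -8.0, -16.0, -24.0)]
        assert np.all(np.diff(forces) < 0)


class TestMUAP:
    def test_empty_train_zero_signal(self):
        s = mt.muap_train(sg.SpikeTrain(np.empty(0)), 0.0, 0.3, 10.0, 0.1,
                          100.0)
        assert np.all(s.values == 0.0)

    def test_waveform_is_zero_mean_biphasic(self):
        w = mt.muap_waveform(0.01, 0.3, 10.0)
        assert abs(w.sum() * 0.01) < 1e-6 * np.abs(w).sum()
        assert w.max() == pytest.approx(0.3)
        assert w.min() == pytest.approx(-0.3)

    def test_superposition_is_exact(self):
        t1 = sg.SpikeTrain(np.array([20.0]))
        t2 = sg.SpikeTrain(np.array([60.0]))
        both = sg.SpikeTrain(np.array([20.0, 60.0]))
        a = mt.muap_train(t1, 0.0, 0.3, 10.0, 0.1, 100.0).values
        b = mt.muap_train(t2, 0.0, 0.3, 10.0, 0.1, 100.0).values
        c = mt.muap_train(both, 0.0, 0.3, 10.0, 0.1, 100.0).values
        assert np.array_equal(c, a + b)

    def test_delay_shifts_waveform(self):
        s0 = mt.muap_train(sg.SpikeTrain(np.array([10.0])), 0.0, 0.3, 10.0,
                           0.1, 100.0)
        s5 = mt.muap_train(sg.SpikeTrain(np.array([10.0])), 5.0, 0.3, 10.0,
                           0.1, 100.0)
        assert np.array_equal(s5.values[50:], s0.values[:-50])


def test_fast_fiber_twitch_faster_than_slow(sol_fiber, mg_fiber):
    _, ct_slow, _ = mt.twitch_metrics(sol_fiber[0])
    _, ct_fast, _ = mt.twitch_metrics(mg_fiber[0])
    assert ct_fast < 0.5 * ct_slow
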