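import dataclasses

import numpy as np
import pytest

from neuromuscle import inverse as inv
from neuromuscle import io as nio
from neuromuscle import motoneuron as mn


class TestInvertPassive:
    def test_round_trip_random_feasible_sets(self, fr_cell):
        base, cmp = fr_cell
        rng = np.random.default_rng(0)
        for _ in range(20):
            rmp = dataclasses.replace(
                base, g_m_s=rng.uniform(0.1, 0.4),
                g_m_d=rng.uniform(0.05, 0.3), g_c=rng.uniform(0.08, 0.4),
                c_m_s=rng.uniform(0.5, 2.0), c_m_d=rng.uniform(0.5, 2.0))
            cp = mn.passive_cp_closed_form(rmp, cmp)
            got = inv.invert_passive(cp.r_n, cp.tau_m, cp.va_sd_dc,
                                     cp.va_ds_dc, cp.va_sd_ac, cmp)
            for k, v in got.items():
                assert v == pytest.approx(getattr(rmp, k), rel=1e-6)

    def test_symmetric_attenuation_balances_absolute_leaks(self, fr_cell):
        _, cmp = fr_cell
        got = inv.invert_passive(2.0, 9.0, 0.8, 0.8, 0.4, cmp)
        assert got["g_m_s"] * cmp.area_s == \
            pytest.approx(got["g_m_d"] * cmp.area_d, rel=1e-9)

    def test_unity_sd_attenuation_means_no_dendritic_leak(self, fr_cell):
        _, cmp = fr_cell
        got = inv.invert_passive(2.0, 30.0, 1.0, 0.9, 0.5, cmp)
        assert got["g_m_d"] == pytest.approx(0.0, abs=1e-12)

    def test_ac_above_dc_is_infeasible(self, fr_cell):
        _, cmp = fr_cell
        with pytest.raises(ValueError, match="infeasible"):
            inv.invert_passive(2.0, 9.0, 0.6, 0.9, 0.7, cmp)


@pytest.fixture(scope="module")
def small_lookup(fr_cell):
    return inv.build_mn_active_lookup(*fr_cell, n_grid=5)


@pytest.fixture(scope="module")
def pic_lookup(fr_cell):
    return inv.build_pic_lookup(*fr_cell, n_grid=7)


class TestActiveLookup:
    def test_rheobase_monotone_in_sodium(self, small_lookup):
        assert np.all(np.diff(small_lookup.values[:, :, 0], axis=0) < 0.5)

    def test_ahp_monotone_in_calcium_fraction(self, small_lookup):
        assert np.all(np.diff(small_lookup.values[:, :, 1], axis=1) < 0)

    def test_empty_grid_rejected(self, fr_cell):
        with pytest.raises(ValueError, match="empty"):
            inv.build_mn_active_lookup(*fr_cell,
                                       g_naf_grid=np.array([]),
                                       f_s_grid=np.array([1.0]))

    def test_node_target_returns_node_parameters(self, small_lookup,
                                                 fr_cell):
        i, j = 2, 3
        target = small_lookup.values[i, j]
        g, fs = inv.invert_active(target[0], target[1], small_lookup,
                                  *fr_cell, refine=False)
        assert g == pytest.approx(small_lookup.grids[0][i], abs=0.5)
        assert fs == pytest.approx(small_lookup.grids[1][j], rel=0.05)

    def test_in_hull_target_round_trips_within_tolerance(self, small_lookup,
                                                         fr_cell):
        base, cmp = fr_cell
        truth = dataclasses.replace(base, g_naf_s=44.0, f_s=0.025)
        ir, ahp = mn.measure_rheobase_ahp(truth, cmp, upper_na=80.0)
        g, fs = inv.invert_active(ir, ahp, small_lookup, base, cmp,
                                  refine=True)
        got = dataclasses.replace(base, g_naf_s=g, f_s=fs)
        ir2, ahp2 = mn.measure_rheobase_ahp(got, cmp, upper_na=80.0)
        assert ir2 == pytest.approx(ir, rel=0.01)
        assert ahp2 == pytest.approx(ahp, rel=0.01)

    def test_out_of_hull_refused_without_refinement(self, small_lookup,
                                                    fr_cell):
        with pytest.raises(ValueError, match="hull"):
            inv.invert_active(1.0, 40.0, small_lookup, *fr_cell,
                              refine=False)

    def test_pic_inversion_round_trip(self, pic_lookup, fr_cell):
        base, cmp = fr_cell
        g, s_nm = inv.invert_pic(15.0, pic_lookup, base, cmp)
        assert s_nm == 1.0
        got = dataclasses.replace(base, g_cal_d=g, g_kca_d=0.0, s_nm=1.0)
        pm, _, _ = mn.measure_pic(got, cmp)
        assert pm == pytest.approx(15.0, rel=0.01)

    def test_pic_amplification_splits_conductance_and_scaling(self,
                                                              pic_lookup,
                                                              fr_cell):
        base, cmp = fr_cell
        g, s_nm = inv.invert_pic(18.0, pic_lookup, base, cmp, pic_amp=1.5)
        assert s_nm > 1.0
        # the effective conductance is preserved
        g1, _ = inv.invert_pic(18.0, pic_lookup, base, cmp)
        assert g * s_nm == pytest.approx(g1, rel=1e-6)


class TestInvertMT:
    def test_round_trip_recovers_generating_parameters(self, sol_fiber):
        rmp, _ = sol_fiber
        cp = inv.measure_mt_cp(rmp)
        got = inv.invert_mt(cp)
        assert got.tau_1 == pytest.approx(rmp.tau_1, rel=0.02)
        assert got.tau_2 == pytest.approx(rmp.tau_2, rel=0.02)
        assert got.phi_1 == pytest.approx(rmp.phi_1, rel=0.05, abs=1e-3)
        assert got.phi_3 == pytest.approx(rmp.phi_3, rel=0.05, abs=1e-3)

    def test_force_length_parameters_invert_in_closed_form(self, sol_fiber):
        rmp, _ = sol_fiber
        cp = inv.measure_mt_cp(rmp)
        got = inv.invert_mt(cp, validate=False)
        assert got.g_1 == pytest.approx(rmp.g_1)
        assert got.g_2 == pytest.approx(rmp.g_2, rel=1e-9)

    def test_velocity_parameters_invert_in_closed_form(self, mg_fiber):
        rmp, _ = mg_fiber
        cp = inv.measure_mt_cp(rmp)
        got = inv.invert_mt(cp, validate=False)
        for name in ("a_0", "b_0", "c_0", "d_0"):
            assert getattr(got, name) == \
                pytest.approx(getattr(rmp, name), rel=1e-9)

    def test_stiffness_assigned_directly(self, sol_fiber):
        rmp, _ = sol_fiber
        cp = inv.measure_mt_cp(rmp)
        assert inv.invert_mt(cp, validate=False).k_se == rmp.k_se

    def test_infeasible_velocity_features_rejected(self, sol_fiber):
        cp = inv.measure_mt_cp(sol_fiber[0])
        bad = dataclasses.replace(cp, fv_slope_short=1e-4)
        with pytest.raises(ValueError, match="FV"):
            inv.invert_mt(bad, validate=False)


class TestCorrelationCurves:
    def test_tabulated_exact_at_abscissae(self):
        c = inv.CorrelationCurve("x", "tabulated",
                                 np.array([1.0, 10.0, 2.0, 20.0, 3.0, 15.0]),
                                 (1.0, 3.0))
        assert c(2.0) == 20.0
        assert c(1.0) == 10.0

    def test_exponential_decay_monotone(self):
        c = inv.CorrelationCurve("x", "exponential_decay",
                                 np.array([100.0, 1.5, 10.0]), (0.0, 5.0))
        xs = np.linspace(0.0, 5.0, 50)
        ys = [c(x) for x in xs]
        assert np.all(np.diff(ys) < 0)

    def test_piecewise_jump_at_type_boundary(self):
        corr = inv.load_default_correlations("MN")
        ahp = corr.curves["t_ahp_half"]
        assert ahp(2.2001) - ahp(2.1999) > 10.0  # fast/slow discontinuity

    def test_domain_violation_raises(self):
        corr = inv.load_default_correlations("MN")
        with pytest.raises(ValueError, match="domain"):
            corr(0.1)

    def test_csv_round_trip(self, tmp_path):
        corr = inv.load_default_correlations("MT")
        p = tmp_path / "corr.csv"
        corr.to_csv(p)
        back = inv.CorrelationSet.from_csv(p)
        for ci in (0.2, 0.4, 0.6):
            a, b = corr(ci), back(ci)
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_override_replaces_curve(self):
        corr = inv.load_default_correlations("MT")
        corr.override("twitch_ct", inv.CorrelationCurve(
            "twitch_ct", "constant", np.array([33.0]), (0.1, 0.7)))
        assert corr(0.3)["twitch_ct"] == 33.0


class TestBuildPopulation:
    def test_homogeneous_spec_gives_identical_cells(self):
        pool = inv.build_population(inv.PopulationSpec(
            "MT", np.full(3, 0.3)))
        r0, _ = pool.cells[0]
        for rmp, _ in pool.cells[1:]:
            assert rmp == r0

    def test_deterministic_construction(self, small_mu_pool):
        ci = inv.ci_rank_distribution(4, 1.4, 3.0, gamma=1.0)
        again = inv.build_population(inv.PopulationSpec("MU", ci,
                                                        lookup_n_grid=7))
        assert small_mu_pool.provenance.equals(again.provenance)

    def test_inverse_rn_p05_relationship(self, small_mu_pool):
        prov = small_mu_pool.provenance
        order = np.argsort(prov.ci.values)
        assert np.all(np.diff(prov.p0_5.values[order]) < 0)

    def test_default_pic_values_without_pic_targets(self, fr_cell):
        corr = inv.load_default_correlations("MN")
        corr.curves.pop("pic_mag")
        corr.curves.pop("pic_amp")
        pool = inv.build_population(inv.PopulationSpec(
            "MN", np.array([2.0]), correlations=corr, lookup_n_grid=4))
        rmp, _ = pool.cells[0]
        assert rmp.g_cal_d == 0.0
        assert rmp.g_kca_d == 0.0
        assert rmp.s_nm == 1.0

    def test_pool_cells_reproduce_assigned_cps(self, small_mu_pool):
        prov = small_mu_pool.provenance
        for i in (0, len(small_mu_pool) - 1):
            cell = small_mu_pool.cells[i]
            cp = mn.measure_passive_cp(cell.mn_rmp, cell.mn_cmp)
            assert cp.r_n == pytest.approx(prov.ci[i], rel=1e-6)
            ir, ahp = mn.measure_rheobase_ahp(cell.mn_rmp, cell.mn_cmp,
                                              upper_na=80.0)
            assert ir == pytest.approx(prov.i_rheo[i], rel=0.02)
            assert ahp == pytest.approx(prov.t_ahp_half[i], rel=0.02)

    def test_bell_shaped_sodium_profile_under_parabolic_rheobase(self,
                                                                 fr_cell):
        # a parabolic R_N-I_rheo correlation (minimum inside the range)
        # must produce a peaked (bell-shaped) R_N-G_Naf profile
        corr = inv.load_default_correlations("MN")
        rn = np.linspace(1.35, 3.15, 9)
        i_rheo = 4.014 * rn ** 2 - 21.59 * rn + 44.36
        pts = np.empty(18)
        pts[0::2], pts[1::2] = rn, i_rheo
        corr.override("i_rheo", inv.CorrelationCurve(
            "i_rheo", "tabulated", pts, (1.3, 3.2)))
        pool = inv.build_population(inv.PopulationSpec(
            "MN", np.linspace(1.4, 3.1, 5), correlations=corr,
            lookup_n_grid=6))
        g_naf = pool.provenance.g_naf_s.values
        k = int(np.argmax(g_naf))
        assert 0 < k < g_naf.size - 1

    def test_failure_reports_cell_index(self):
        corr = inv.load_default_correlations("MT")
        corr.override("twitch_ct", inv.CorrelationCurve(
            "twitch_ct", "constant", np.array([0.5]), (0.1, 0.7)))
        with pytest.raises(RuntimeError, match="cell 0"):
            inv.build_population(inv.PopulationSpec("MT",
                                                    np.array([0.3]),
                                                    correlations=corr))


def test_ci_rank_distribution_shapes():
    s_dom = inv.ci_rank_distribution(101, 1.0, 3.0, gamma=0.25)
    lin = inv.ci_rank_distribution(101, 1.0, 3.0, gamma=1.0)
    f_dom = inv.ci_rank_distribution(101, 1.0, 3.0, gamma=4.0)
    assert np.median(s_dom) > np.median(lin) > np.median(f_dom)
    assert s_dom[0] == lin[0] == f_dom[0] == 1.0
    assert s_dom[-1] == lin[-1] == f_dom[-1] == 3.0
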