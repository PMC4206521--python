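import numpy as np
import pytest

import hifshuttle as hs
from hifshuttle import KineticParameters, OxygenSchedule, SystemState
from hifshuttle.simulate import NoStationaryStateError


class TestOxygenSchedule:
    def test_constant_and_step_lookup(self):
        s = OxygenSchedule.step(1.0, 30.0, 1000.0)
        assert s.k_form_at(0.0) == 1.0
        assert s.k_form_at(29.999) == 1.0
        assert s.k_form_at(30.0) == 1000.0  # right-continuous
        assert list(s.segments(40.0)) == [(0.0, 30.0, 1.0), (30.0, 40.0, 1000.0)]

    @pytest.mark.parametrize("breakpoints", [
        (),                              # empty
        ((1.0, 5.0),),                   # does not start at 0
        ((0.0, 5.0), (0.0, 2.0)),        # not strictly increasing
        ((0.0, -1.0),),                  # negative rate
    ])
    def test_invalid_schedules_rejected(self, breakpoints):
        with pytest.raises(ValueError):
            OxygenSchedule(breakpoints)


class TestIntegrate:
    def test_empty_cell_without_synthesis_stays_empty(self):
        p = KineticParameters(k_syn_hif=0.0)
        traj = hs.integrate(p, SystemState(), OxygenSchedule.constant(1000.0),
                            t_end=2.0, dt_out=0.1)
        assert np.abs(traj.states).max() == 0.0

    def test_regular_grid_and_initial_state(self, default_params, normoxic_eq):
        eq = normoxic_eq.require()
        traj = hs.integrate(default_params, eq, OxygenSchedule.constant(1000.0),
                            t_end=1.0, dt_out=0.25)
        np.testing.assert_allclose(traj.times, [0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_array_equal(traj.states[0], eq.to_array())

    def test_long_relaxation_reaches_the_steady_state(self, default_params,
                                                      normoxic_eq):
        traj = hs.integrate(default_params, SystemState.uniform(1e-3),
                            OxygenSchedule.constant(1000.0),
                            t_end=2000.0, dt_out=100.0)
        final_total = traj.hif_total[-1]
        assert final_total == pytest.approx(normoxic_eq.total_hif, rel=0.01)

    def test_invalid_horizon_rejected(self, default_params):
        with pytest.raises(ValueError):
            hs.integrate(default_params, SystemState(), OxygenSchedule.constant(1.0),
                         t_end=-1.0, dt_out=0.1)

    def test_series_accessor_names(self, default_params, normoxic_eq):
        traj = hs.integrate(default_params, normoxic_eq.require(),
                            OxygenSchedule.constant(1000.0), 0.5, 0.25)
        assert np.array_equal(traj.series("nuclear_hif"),
                              traj.states[:, 0] + traj.states[:, 5])
        assert np.array_equal(traj.series("hif_cyt"), traj.states[:, 1])
        with pytest.raises(KeyError):
            traj.series("mystery_protein")


class TestSteadyState:
    def test_no_sources_gives_the_empty_cell(self):
        res = hs.steady_state(KineticParameters(k_syn_hif=0.0), 1000.0)
        assert res.converged
        assert np.abs(res.require().to_array()).max() < 1e-9

    def test_residual_below_contract(self, normoxic_eq, default_params):
        assert normoxic_eq.converged
        assert normoxic_eq.residual_norm < 1e-9
        d = hs.derivative_field(normoxic_eq.require(), default_params, 1000.0)
        assert np.abs(d.to_array()).max() < 1e-9

    def test_is_a_fixed_point_of_integrate(self, default_params, normoxic_eq):
        traj = hs.integrate(default_params, normoxic_eq.require(),
                            OxygenSchedule.constant(1000.0), 100.0, 50.0)
        drift = abs(traj.hif_total[-1] / traj.hif_total[0] - 1.0)
        assert drift < 1e-3

    def test_oscillatory_attractor_reported_not_raised(self):
        """A strongly driven variant with the free-pVHL shuttle settles into a
        limit cycle; the search reports it as a distinct status."""
        p = KineticParameters(free_pvhl_shuttles=True, k_feedback=0.15,
                              k_syn_hif=5000.0)
        res = hs.steady_state(p, 1000.0)
        assert res.status == "oscillatory"
        assert not res.converged
        with pytest.raises(NoStationaryStateError, match="oscillatory"):
            res.require()

    def test_negative_k_form_rejected(self, default_params):
        with pytest.raises(ValueError):
            hs.steady_state(default_params, -1.0)


class TestChase:
    def test_starts_at_hundred_percent_of_equilibrium(self, chase_traj,
                                                      normoxic_eq):
        assert chase_traj.hif_total[0] == pytest.approx(normoxic_eq.total_hif,
                                                        rel=1e-9)

    def test_total_hif_is_monotone_non_increasing(self, chase_traj):
        assert np.all(np.diff(chase_traj.hif_total) <= 1e-12)

    def test_grid_matches_protocol_defaults(self, chase_traj):
        assert chase_traj.times[-1] == pytest.approx(6.0)
        assert np.diff(chase_traj.times)[0] == pytest.approx(1 / 60)


class TestHypoxiaStep:
    def test_unchanged_rate_gives_a_flat_trajectory(self, default_params):
        with pytest.warns(UserWarning, match="not below"):
            traj = hs.hypoxia_step(default_params, hs.NORMOXIC_K_FORM,
                                   t_end=5.0, dt_out=0.1)
        nuc = traj.nuclear_hif
        assert np.abs(nuc / nuc[0] - 1.0).max() < 1e-5

    def test_warns_when_not_hypoxic(self, default_params):
        with pytest.warns(UserWarning, match="not below"):
            hs.hypoxia_step(default_params, 2000.0, t_end=0.5, dt_out=0.1)

    def test_initial_condition_is_the_normoxic_equilibrium(self, default_params,
                                                           normoxic_eq):
        traj = hs.hypoxia_step(default_params, 1.0, t_end=0.5, dt_out=0.1)
        np.testing.assert_allclose(traj.states[0],
                                   normoxic_eq.require().to_array(), rtol=1e-9)


class TestReoxygenation:
    def test_composition_with_hypoxia_step(self, default_params, reox_traj):
        """The hypoxic phase of the protocol is exactly a hypoxia step."""
        hyp = hs.hypoxia_step(default_params, 1.0, t_end=30.0, dt_out=0.01)
        n = hyp.times.size
        np.testing.assert_allclose(reox_traj.states[:n], hyp.states, rtol=1e-9,
                                   atol=1e-12)

    def test_event_marker_recorded(self, reox_traj):
        assert reox_traj.events["reoxygenation"] == 30.0
        assert reox_traj.schedule.k_form_at(29.99) == 1.0
        assert reox_traj.schedule.k_form_at(30.0) == hs.NORMOXIC_K_FORM

    def test_vanishing_hypoxia_duration_leaves_baseline(self, default_params):
        traj = hs.reoxygenation_protocol(default_params, 1.0,
                                         hypoxia_duration=1e-6,
                                         t_end_after=2.0, dt_out=0.01)
        nuc = traj.nuclear_hif
        assert np.abs(nuc / nuc[0] - 1.0).max() < 0.01

    def test_invalid_duration_rejected(self, default_params):
        with pytest.raises(ValueError):
            hs.reoxygenation_protocol(default_params, 1.0, hypoxia_duration=0.0)


class TestSingleCompartmentControl:
    def test_cytoplasm_stays_identically_empty(self, default_params):
        traj = hs.single_compartment_control(default_params, 1.0,
                                             hypoxia_duration=2.0,
                                             t_end_after=2.0, dt_out=0.05)
        assert np.abs(traj.states[:, [1, 3, 6]]).max() == 0.0

    def test_equals_reduced_nuclear_subsystem(self, default_params):
        """With the shuttle removed, the model collapses to the 5-species
        nuclear subsystem; an independently coded reduced system must
        reproduce the control run."""
        from scipy.integrate import solve_ivp

        p = default_params

        def reduced(t, y, kf):
            hn, vn, m, cn = y
            a, b = p.alpha_deg_hif, p.beta_deg_vhl
            fn = kf * hn * vn
            return [
                p.k_syn_hif - a * hn - fn + p.k_dis * cn + b * cn,
                p.k_transl * m - b * vn - fn + p.k_dis * cn
                + (p.gamma_nuc + a) * cn,
                p.k_feedback * hn - p.beta_deg_mrna * m,
                fn - (p.k_dis + a + b + p.gamma_nuc) * cn,
            ]

        traj = hs.single_compartment_control(p, 1.0, hypoxia_duration=2.0,
                                             t_end_after=0.0, dt_out=0.05)
        y0 = traj.states[0][[0, 2, 4, 5]]
        sol = solve_ivp(reduced, (0.0, 2.0), y0, args=(1.0,), method="LSODA",
                        rtol=1e-10, atol=1e-12, t_eval=traj.times)
        np.testing.assert_allclose(traj.states[:, [0, 2, 4, 5]], sol.y.T,
                                   rtol=1e-5, atol=1e-8)
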