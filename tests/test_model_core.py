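"""Forcing function, geometry, ODE right-hand sides and the Euler integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacuodyn import (
    DEFAULT_HYPER_PROTOCOL,
    IntegrationError,
    ModelParameters,
    OsmoticProtocol,
    VacuoleGeometry,
    area_from_volume,
    external_osmolality,
    model_rhs,
    simulate,
    ws_steady_state,
)
from vacuodyn.model_core import MOSM_TO_MOL_CM3


class TestExternalOsmolality:
    def test_plateau_before_switch(self, protocol):
        assert external_osmolality(100.0, protocol) == pytest.approx(450.0)
        assert external_osmolality(0.0, protocol) == pytest.approx(450.0)

    def test_decay_value_at_record_end(self, protocol):
        # direct evaluation of the exponential at t = 900 s
        expected = 731.5 * np.exp(-900.0 / 237.2) + 258.8
        assert external_osmolality(900.0, protocol) == pytest.approx(expected)
        assert expected == pytest.approx(275.258, abs=1e-3)

    def test_asymptote(self, protocol):
        assert external_osmolality(1e7, protocol) == pytest.approx(258.8)

    def test_clamped_just_after_switch(self, protocol):
        # the raw exponential exceeds C0 right after the switch (~465);
        # the forcing is clamped to the iso-osmotic plateau value
        assert external_osmolality(300.0, protocol) == pytest.approx(450.0)
        t = np.array([0.0, 300.0, 310.0, 900.0])
        vals = external_osmolality(t, protocol)
        assert np.all(vals <= 450.0) and np.all(vals >= 258.8)

    def test_negative_time_rejected(self, protocol):
        with pytest.raises(ValueError):
            external_osmolality(-1.0, protocol)

    def test_hyper_clamped_between_c0_and_target(self):
        p = DEFAULT_HYPER_PROTOCOL
        t = np.linspace(0, p.t_end, 181)
        vals = external_osmolality(t, p)
        assert np.all(vals >= 450.0) and np.all(vals <= 660.0)
        assert external_osmolality(1e7, p) == pytest.approx(660.0)


class TestGeometry:
    def test_sphere_area_of_10um_radius(self):
        V = 4.18879e-9  # 10-um-radius sphere, cm^3
        geom = VacuoleGeometry(V0=V)
        assert area_from_volume(V, geom) == pytest.approx(1.25664e-5, rel=1e-5)

    def test_fixed_mode_ignores_volume(self, geometry):
        fixed = VacuoleGeometry(V0=geometry.V0, area_mode="fixed")
        a0 = area_from_volume(geometry.V0, fixed)
        assert area_from_volume(5 * geometry.V0, fixed) == pytest.approx(a0)

    def test_scaling_law(self, geometry):
        V = geometry.V0
        assert area_from_volume(8 * V, geometry) == pytest.approx(
            4 * area_from_volume(V, geometry)
        )

    def test_nonpositive_volume_rejected(self, geometry):
        with pytest.raises(ValueError):
            area_from_volume(0.0, geometry)


class TestModelParameters:
    def test_unused_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(model_id="W", Pf=1e-3, Ps=1e-3)
        with pytest.raises(ValueError):
            ModelParameters(model_id="WS", Pf=1e-3, Ps=1e-3, eps_star=1.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(model_id="X", Pf=1e-3)


class TestModelRhs:
    def test_ws_zero_gradient_is_stationary(self, protocol, geometry):
        params = ModelParameters(model_id="WS", Pf=1e-2, Ps=1e-3)
        Ce = external_osmolality(500.0, protocol) * MOSM_TO_MOL_CM3
        V = geometry.V0
        dV, dM = model_rhs((V, Ce * V), 500.0, params, protocol, geometry)
        assert dV == pytest.approx(0.0, abs=1e-30)
        assert dM == pytest.approx(0.0, abs=1e-30)

    def test_wme_without_elasticity_reduces_to_w(self, protocol, geometry):
        state = (1.02 * geometry.V0, geometry.V0 * 450e-6)
        w = ModelParameters(model_id="W", Pf=5e-3)
        wme = ModelParameters(model_id="WME", Pf=5e-3, eps_star=0.0)
        assert model_rhs(state, 400.0, wme, protocol, geometry) == model_rhs(
            state, 400.0, w, protocol, geometry
        )

    def test_wsnov_without_dead_volume_reduces_to_ws(self, protocol, geometry):
        state = (1.02 * geometry.V0, geometry.V0 * 450e-6)
        ws = ModelParameters(model_id="WS", Pf=5e-3, Ps=1e-3)
        wsnov = ModelParameters(model_id="WSNOV", Pf=5e-3, Ps=1e-3, Vb=0.0)
        assert model_rhs(state, 400.0, wsnov, protocol, geometry) == model_rhs(
            state, 400.0, ws, protocol, geometry
        )

    def test_singular_state_rejected(self, protocol, geometry):
        params = ModelParameters(model_id="WNOV", Pf=5e-3, Vb=0.5 * geometry.V0)
        with pytest.raises(IntegrationError):
            model_rhs((0.4 * geometry.V0, 1e-11), 400.0, params, protocol, geometry)


class TestSimulate:
    def test_zero_pf_is_static(self, protocol, geometry):
        traj = simulate(ModelParameters(model_id="WS", Pf=0.0, Ps=1e-3), protocol, geometry)
        assert np.allclose(traj.V, traj.V0)
        assert np.allclose(traj.M, traj.M0)

    @pytest.mark.parametrize("model_id", ["W", "WNOV", "WME"])
    def test_water_only_models_conserve_mass(self, model_id, protocol, geometry):
        kwargs = {"Pf": 5e-3}
        if model_id == "WNOV":
            kwargs["Vb"] = 0.2 * geometry.V0
        if model_id == "WME":
            kwargs["eps_star"] = 1e7 / geometry.V0
        traj = simulate(ModelParameters(model_id=model_id, **kwargs), protocol, geometry)
        assert np.all(traj.M == traj.M0)
        if model_id != "WNOV":
            assert traj.M0 == pytest.approx(geometry.V0 * 450e-6)

    def test_ws_conservation_line_machine_precision(self, ws_ph70, protocol, geometry):
        traj = simulate(ws_ph70, protocol, geometry)
        resid = ws_ph70.Ps * (traj.V - traj.V0) + ws_ph70.Pf * 18.0 * (traj.M - traj.M0)
        assert np.max(np.abs(resid)) / (ws_ph70.Ps * traj.V0) < 1e-12

    def test_euler_first_order_convergence(self, ws_ph70, protocol, geometry):
        finals = {
            dt: simulate(ws_ph70, protocol, geometry, dt=dt).V[-1]
            for dt in (0.1, 0.05, 0.025)
        }
        # halving dt changes the final volume by < 1e-4 relative
        assert abs(finals[0.05] / finals[0.1] - 1) < 1e-4
        # and the change scales like the first-order Euler error
        r = (finals[0.1] - finals[0.05]) / (finals[0.05] - finals[0.025])
        assert 1.5 < r < 3.0

    def test_printed_steady_volumes_at_condition_mean_parameters(self, protocol, geometry):
        # WS forward simulation at the per-pH mean Pf with Ps from the
        # paired mean Pf/Ps ratio reproduces the recorded steady relative
        # volumes within their SEM
        cases = {  # pH: (Pf, ratio, Vf/V0 +- SEM)
            7.6: (9e-3, 27.68, 1.073, 0.008),
            7.0: (27e-3, 14.04, 1.040, 0.004),
            6.8: (7e-3, 8.19, 1.023, 0.004),
        }
        for _, (pf, ratio, vf, sem) in cases.items():
            params = ModelParameters(model_id="WS", Pf=pf, Ps=pf / ratio)
            traj = simulate(params, protocol, geometry, dt=0.1)
            assert traj.rel_volume[-1] == pytest.approx(vf, abs=sem)

    def test_steady_volume_at_mean_pf_and_mean_ps(self, protocol, geometry):
        # with Ps taken as its own condition mean (instead of pairing the
        # mean ratio) the pH 7.6 simulation still lands within the SEM
        traj = simulate(
            ModelParameters(model_id="WS", Pf=9e-3, Ps=0.35e-3), protocol, geometry
        )
        assert traj.rel_volume[-1] == pytest.approx(1.073, abs=0.008)

    def test_hyper_osmotic_protocol_shrinks_all_models(self, geometry):
        p = DEFAULT_HYPER_PROTOCOL
        V0 = geometry.V0
        for params in (
            ModelParameters(model_id="W", Pf=5e-3),
            ModelParameters(model_id="WNOV", Pf=5e-3, Vb=0.2 * V0),
            ModelParameters(model_id="WME", Pf=5e-3, eps_star=1e7 / V0),
            ModelParameters(model_id="WS", Pf=9e-3, Ps=0.35e-3),
            ModelParameters(model_id="WSNOV", Pf=9e-3, Ps=0.35e-3, Vb=0.2 * V0),
        ):
            traj = simulate(params, p, geometry)
            assert np.all(traj.V <= V0 * (1 + 1e-12))
            assert np.all(traj.V > 0)

    def test_fixed_area_changes_little(self, ws_ph70, protocol, geometry):
        fixed = VacuoleGeometry(V0=geometry.V0, area_mode="fixed")
        v_rec = simulate(ws_ph70, protocol, geometry).rel_volume[-1]
        v_fix = simulate(ws_ph70, protocol, fixed).rel_volume[-1]
        assert v_fix == pytest.approx(v_rec, abs=1e-3)

    def test_nesting_identities_along_trajectories(self, protocol, geometry):
        V0 = geometry.V0
        ref_w = simulate(ModelParameters(model_id="W", Pf=5e-3), protocol, geometry)
        for params in (
            ModelParameters(model_id="WME", Pf=5e-3, eps_star=0.0),
            ModelParameters(model_id="WNOV", Pf=5e-3, Vb=0.0),
            ModelParameters(model_id="WS", Pf=5e-3, Ps=0.0),
        ):
            traj = simulate(params, protocol, geometry)
            assert np.array_equal(traj.V, ref_w.V)
        ref_ws = simulate(ModelParameters(model_id="WS", Pf=9e-3, Ps=1e-3), protocol, geometry)
        wsnov = simulate(
            ModelParameters(model_id="WSNOV", Pf=9e-3, Ps=1e-3, Vb=0.0), protocol, geometry
        )
        assert np.array_equal(wsnov.V, ref_ws.V)
        assert np.array_equal(wsnov.M, ref_ws.M)

    def test_blowup_raises_integration_error(self, geometry):
        # a huge elastic-free Pf under a hyper gradient cannot blow up, but a
        # dead volume close to V0 with a strong hyper gradient collapses V
        params = ModelParameters(model_id="WNOV", Pf=0.1, Vb=0.97 * geometry.V0)
        with pytest.raises(IntegrationError):
            simulate(params, DEFAULT_HYPER_PROTOCOL, geometry)


class TestWsSteadyState:
    def test_limits(self):
        assert ws_steady_state(0.0, 450.0, 258.8) == pytest.approx(1.0)
        assert ws_steady_state(25.0, 450.0, 450.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # (1 + k*C0) / (1 + k*Ce) with k = 14.04 * 18 and mol/cm^3 units
        k = 14.04 * 18.0
        expected = (1 + k * 450e-6) / (1 + k * 258.8e-6)
        got = ws_steady_state(14.04, 450.0, 258.8)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1.0453, abs=2e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ws_steady_state(-1.0, 450.0, 258.8)
        with pytest.raises(ValueError):
            ws_steady_state(1.0, -450.0, 258.8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r1=st.floats(0.0, 100.0),
        dr=st.floats(1e-3, 50.0),
        ce=st.floats(100.0, 440.0),
    )
    def test_monotone_increasing_in_ratio_for_hypo(self, r1, dr, ce):
        assert ws_steady_state(r1 + dr, 450.0, ce) > ws_steady_state(r1, 450.0, ce)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r=st.floats(0.1, 100.0), ce=st.floats(460.0, 900.0))
    def test_shrinkage_for_hyper(self, r, ce):
        assert ws_steady_state(r, 450.0, ce) < 1.0
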