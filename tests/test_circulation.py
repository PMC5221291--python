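"""Valve laws, LVAD plumbing, mass balance and closed-loop integration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cvloop import (CirculationState, LvadConfig, ModelConfig, aortic_flow,
                    baseline_config, compliance_pressure, initial_state,
                    lvad_flows, mitral_flow, network_rhs, simulate,
                    ventricular_pressure)
from cvloop.circulation import STATE_FIELDS, _make_rhs, _suction_factor


class TestValveLaws:
    def test_mitral_forward_hand_value(self):
        assert mitral_flow(10, 4, 0.05, 5) == pytest.approx(120.0)

    def test_mitral_backward_is_sf_percent_of_forward_law(self):
        assert mitral_flow(8, 88, 0.05, 5) == pytest.approx(-80.0)

    def test_competent_valve_blocks_backflow(self):
        assert mitral_flow(4, 10, 0.05, 0) == 0.0
        assert aortic_flow(10, 90, 0.1, 0) == 0.0

    def test_aortic_forward_hand_value(self):
        assert aortic_flow(100, 80, 0.1, 5) == pytest.approx(200.0)

    def test_aortic_backward_hand_value(self):
        assert aortic_flow(10, 90, 0.1, 5) == pytest.approx(-40.0)

    def test_continuity_at_zero_gradient(self):
        assert mitral_flow(50, 50, 0.05, 5) == 0.0
        assert aortic_flow(50, 50, 0.1, 5) == 0.0

    @given(st.floats(min_value=0.0, max_value=150.0),
           st.floats(min_value=0.0, max_value=150.0),
           st.floats(min_value=0.0, max_value=100.0))
    def test_backward_flux_ratio_and_sign(self, p1, p2, sf):
        """Backward magnitude is exactly sf% of the forward law at equal |dP|."""
        q = mitral_flow(p1, p2, 0.04, sf)
        assert q == 0 or (q > 0) == (p1 > p2)
        if p1 < p2:
            q_fwd = mitral_flow(p2, p1, 0.04, sf)
            assert abs(q) == pytest.approx(sf / 100.0 * q_fwd, rel=1e-12)

    def test_invalid_resistance_and_sf_rejected(self):
        with pytest.raises(ValueError):
            mitral_flow(10, 5, 0.0, 5)
        with pytest.raises(ValueError):
            aortic_flow(10, 5, 0.1, 101)


class TestLvadPlumbing:
    @pytest.mark.parametrize("mode, flow, expected", [
        ("none", 0.0, (0.0, 0.0, 0.0)),
        ("laao", 40.0, (40.0, 0.0, 40.0)),
        ("lvao", 40.0, (0.0, 40.0, 40.0)),
    ])
    def test_cannulation_topologies(self, mode, flow, expected):
        assert lvad_flows(LvadConfig(mode, flow)) == expected

    def test_pump_conserves_volume(self):
        w_la, w_lv, inj = lvad_flows(LvadConfig("laao", 40.0))
        assert w_la + w_lv == inj

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LvadConfig("aoda", 40.0)
        with pytest.raises(ValueError):
            LvadConfig("none", 40.0)
        with pytest.raises(ValueError):
            LvadConfig("laao", -1.0)

    def test_suction_factor_derates_linearly_below_threshold(self):
        assert _suction_factor(10.0, 5.0) == 1.0
        assert _suction_factor(0.5, 5.0) == 1.0     # exactly at 10% threshold
        assert _suction_factor(0.25, 5.0) == 0.5
        assert _suction_factor(0.0, 5.0) == 0.0


def _random_state(rng) -> CirculationState:
    vols = dict(zip(STATE_FIELDS[:8], rng.uniform(20, 150, size=8)))
    return CirculationState(a_lv=rng.uniform(0, 1), a_rv=rng.uniform(0, 1), **vols)


class TestNetworkMassBalance:
    @pytest.mark.parametrize("mode, flow", [("none", 0.0), ("laao", 40.0), ("lvao", 40.0)])
    @pytest.mark.parametrize("sf_mi, sf_ao", [(0, 0), (5, 0), (0, 5)])
    def test_volume_derivatives_sum_to_zero(self, mode, flow, sf_mi, sf_ao):
        from dataclasses import replace
        cfg = baseline_config()
        cfg = cfg.with_(circ=replace(cfg.circ, sf_mi=sf_mi, sf_ao=sf_ao),
                        lvad=LvadConfig(mode, flow))
        rng = np.random.default_rng(7)
        for _ in range(10):
            state = _random_state(rng)
            dy = network_rhs(0.123, state, cfg)
            assert abs(dy[:8].sum()) < 1e-10 * max(1.0, np.abs(dy[:8]).max())

    def test_hydrostatic_equilibrium_is_stationary(self):
        """Equal pressures, no activation, no pump: every volume is constant."""
        cfg = baseline_config()
        c = cfg.circ
        p = 5.0
        v_lv = cfg.lv.v0 + math.log(p / (cfg.lv.passive_scale * cfg.lv.beta) + 1) / cfg.lv.kappa
        v_rv = cfg.rv.v0 + math.log(p / (cfg.rv.passive_scale * cfg.rv.beta) + 1) / cfg.rv.kappa
        state = CirculationState(
            v_lv=v_lv, v_rv=v_rv,
            v_la=c.v0_la + p * c.c_la, v_ra=c.v0_ra + p * c.c_ra,
            v_sa=c.v0_sa + p * c.c_sa, v_sv=c.v0_sv + p * c.c_sv,
            v_pa=c.v0_pa + p * c.c_pa, v_pv=c.v0_pv + p * c.c_pv,
            a_lv=0.0, a_rv=0.0)
        dy = network_rhs(0.0, state, cfg)
        assert np.allclose(dy[:8], 0.0, atol=1e-9)

    def test_rhs_matches_flow_by_flow_hand_composition(self):
        """Each compartment's rate equals the independently summed valve,
        vascular and pump flows computed from the audited operations."""
        cfg = baseline_config().with_(lvad=LvadConfig("laao", 40.0))
        from dataclasses import replace
        cfg = cfg.with_(circ=replace(cfg.circ, sf_mi=5.0))
        state = initial_state(cfg)
        c = cfg.circ
        p_lv = ventricular_pressure(state.v_lv, state.a_lv, cfg.lv, cfg.myofilament)
        p_rv = ventricular_pressure(state.v_rv, state.a_rv, cfg.rv, cfg.myofilament)
        p_la = compliance_pressure(state.v_la, c.c_la, c.v0_la)
        p_ra = compliance_pressure(state.v_ra, c.c_ra, c.v0_ra)
        p_sa = compliance_pressure(state.v_sa, c.c_sa, c.v0_sa)
        p_sv = compliance_pressure(state.v_sv, c.c_sv, c.v0_sv)
        p_pa = compliance_pressure(state.v_pa, c.c_pa, c.v0_pa)
        p_pv = compliance_pressure(state.v_pv, c.c_pv, c.v0_pv)
        q_mi = mitral_flow(p_la, p_lv, c.r_mi, c.sf_mi)
        q_ao = aortic_flow(p_lv, p_sa, c.r_ao, c.sf_ao)
        q_tr = max(0.0, (p_ra - p_rv) / c.r_tr)
        q_pu = max(0.0, (p_rv - p_pa) / c.r_pu)
        q_sa = (p_sa - p_sv) / c.r_sa
        q_sv = (p_sv - p_ra) / c.r_sv
        q_pa = (p_pa - p_pv) / c.r_pa
        q_pv = (p_pv - p_la) / c.r_pv
        w_la, _, inj = lvad_flows(cfg.lvad)
        expected = {
            "v_lv": q_mi - q_ao, "v_la": q_pv - q_mi - w_la,
            "v_rv": q_tr - q_pu, "v_ra": q_sv - q_tr,
            "v_sa": q_ao + inj - q_sa, "v_sv": q_sa - q_sv,
            "v_pa": q_pu - q_pa, "v_pv": q_pa - q_pv,
        }
        dy = network_rhs(0.05, state, cfg)
        for i, name in enumerate(STATE_FIELDS[:8]):
            assert dy[i] == pytest.approx(expected[name], rel=1e-12, abs=1e-12)

    def test_fast_closure_agrees_with_public_rhs(self):
        """The optimized integrator right-hand side equals the composed one."""
        from dataclasses import replace
        rng = np.random.default_rng(11)
        for mode, flow in [("none", 0.0), ("laao", 40.0), ("lvao", 40.0)]:
            cfg = baseline_config().with_(
                circ=replace(baseline_config().circ, sf_mi=5.0, sf_ao=0.0),
                lvad=LvadConfig(mode, flow))
            fast = _make_rhs(cfg)
            for t in rng.uniform(0, 2, size=5):
                state = _random_state(rng)
                np.testing.assert_allclose(
                    np.asarray(fast(t, state.as_array())),
                    network_rhs(t, state, cfg), rtol=1e-12, atol=1e-12)

    def test_invalid_states_rejected_with_diagnostic(self):
        cfg = baseline_config()
        state = initial_state(cfg).as_array()
        state[1] = -1.0
        with pytest.raises(ValueError, match="v_la"):
            network_rhs(0.0, state, cfg)
        state[1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            network_rhs(0.0, state, cfg)


class TestSimulate:
    def test_total_volume_conserved(self):
        cfg = baseline_config()
        res = simulate(cfg, duration=3.0)
        vol = res.data[[f"v_{x}" for x in
                        ("lv", "la", "rv", "ra", "sa", "sv", "pa", "pv")]].sum(axis=1)
        assert np.max(np.abs(vol - cfg.total_blood_volume)) / cfg.total_blood_volume < 1e-6

    def test_undriven_system_relaxes_to_rest(self):
        """With the calcium drive amplitude zeroed the loop settles into a
        stationary state with no valve flow."""
        from dataclasses import replace
        cfg = baseline_config()
        cfg = cfg.with_(calcium=replace(cfg.calcium, hf_amplitude_factor=0.0))
        # the venous reservoir drains with a ~2 min time constant, so give
        # the dissipative relaxation several of those
        res = simulate(cfg, duration=500.0, dt_out=0.1, max_step=0.5)
        tail = res.data.iloc[-1]
        for q in ("q_mi", "q_ao", "q_tr", "q_pu"):
            assert abs(tail[q]) < 1e-2
        state = CirculationState.from_array(
            res.data.iloc[-1][list(STATE_FIELDS)].to_numpy())
        dy = network_rhs(res.data.iloc[-1]["time_s"], state, cfg)
        assert np.max(np.abs(dy[:8])) < 1e-2

    def test_output_grid_and_positivity(self):
        res = simulate(baseline_config(), duration=2.0)
        t = res.data["time_s"].to_numpy()
        assert t[0] == 0.0
        assert np.allclose(np.diff(t), 1e-3)
        assert (res.data[[f"v_{x}" for x in
                          ("lv", "la", "rv", "ra", "sa", "sv", "pa", "pv")]] > 0).all().all()

    def test_steady_state_periodicity_of_baseline(self, calibrated):
        """The last two cycles of the 20 s baseline run agree within 0.5%."""
        res = simulate(calibrated)
        assert res.periodicity_defect < 0.005

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate(baseline_config(), duration=0.0)
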