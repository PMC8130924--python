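"""Coupled engine: assembly, conservation audits, steady states and
scenario protocols (small networks keep these fast)."""
import dataclasses

import numpy as np
import pytest

from conftest import make_chain_tree, uniform_zones
from vqsim.config import GasParams, HPVParams, SimConfig
from vqsim.engine import (AssembledModel, pressure_flow_experiment,
                          run_scenario, ventilation_weights)
from vqsim.mechanics import linear_steady_state


@pytest.fixture(scope="module")
def small_model(small_network):
    _, tree, zones = small_network
    cfg = SimConfig(mode="no_hpv", n_cycles=30, min_cycles=6)
    return AssembledModel(tree, zones, config=cfg)


class TestAssembly:
    def test_single_unit_state_dimension(self):
        # one arterial + one capillary + one venous segment, one zone, two
        # airway pressures, tones in hpv mode: 3*2 + 1 + 1 + 2 + 2 + 1 = 13
        tree = make_chain_tree([500.0], radii=[100.0])
        tree.flow = np.array([1e10])
        zones = uniform_zones(tree)
        m = AssembledModel(tree, zones, config=SimConfig(mode="hpv"))
        assert m.n_states == 13

    def test_mode_toggles_tone_states(self, small_network):
        _, tree, zones = small_network
        S = tree.n_segments
        m_no = AssembledModel(tree, zones, config=SimConfig(mode="no_hpv"))
        m_uvc = AssembledModel(tree, zones,
                               config=SimConfig(mode="uvc", T_star=0.8))
        m_hpv = AssembledModel(tree, zones, config=SimConfig(mode="hpv"))
        assert m_hpv.n_states - m_no.n_states == S
        assert m_uvc.n_states == m_no.n_states
        assert m_uvc.T_art_static == 0.8
        assert m_uvc.T_ven_static == 0.8

    def test_junction_residuals_zero_in_rhs(self, small_model):
        """Assembled-system audit: flow conservation at bifurcations and
        confluences holds identically at every RHS evaluation."""
        m = small_model
        rng = np.random.default_rng(7)
        y = m.initial_state() * rng.uniform(0.9, 1.1, m.n_states)
        qa = y[m.sl["qa"]]
        qc = y[m.sl["qc"]]
        # arterial: q_out(parent) - sum(q_in daughters) is zero by
        # construction; audit the confluence algebra via a re-derivation
        Pv = y[m.sl["Pv"]]
        qv = y[m.sl["qv"]]
        C_v = m.net.C0 / m.T_ven_static
        RD_v = m.net.wall.v / C_v
        for k, j in enumerate(m.internal):
            c1, c2 = m.c1[k], m.c2[k]
            num = (Pv[c1] - Pv[c2] + RD_v[c2] * qv[j]
                   + RD_v[c1] * qv[c1] - RD_v[c2] * qv[c2])
            qa_out = num / (RD_v[c1] + RD_v[c2])
            qb_out = qv[j] - qa_out
            assert qa_out + qb_out == pytest.approx(qv[j], abs=1e-14)
            # outlet-pressure balance between partners
            Pa_out = Pv[c1] + RD_v[c1] * (qv[c1] - qa_out)
            Pb_out = Pv[c2] + RD_v[c2] * (qv[c2] - qb_out)
            assert Pa_out == pytest.approx(Pb_out, rel=1e-10)

    def test_symmetric_network_symmetric_derivatives(self):
        # hand-built 2-zone symmetric tree: mirrored states give mirrored
        # derivatives component-wise
        from vqsim.netgen import SegmentTree
        coords = np.array([[0.0, 0.0], [0.0, 500.0], [-400.0, 900.0],
                           [400.0, 900.0]])
        tree = SegmentTree(nodes=[np.array([0, 1]), np.array([1, 2]),
                                  np.array([1, 3])],
                           parent=np.array([-1, 0, 0]),
                           length=np.array([500.0, 640.0, 640.0]),
                           coords=coords)
        tree.radius = np.array([200.0, 120.0, 120.0])
        tree.flow = np.array([2e10, 1e10, 1e10])
        zones = uniform_zones(tree)
        m = AssembledModel(tree, zones, config=SimConfig(mode="hpv"))
        y = m.initial_state()
        d = m.rhs(0.2, y)

        def pairs(name, idx1, idx2):
            block = d[m.sl[name]]
            np.testing.assert_allclose(block[idx1], block[idx2], rtol=1e-9,
                                       atol=1e-8, err_msg=name)
        for name in ("Pa", "qa", "Pv", "qv", "Cv", "T"):
            pairs(name, 1, 2)
        for name in ("Pc", "qc", "Cc", "Valv", "Malv"):
            pairs(name, 0, 1)


class TestVentilationWeights:
    def test_uniform_weights_are_area_fractions(self, small_network):
        _, tree, zones = small_network
        np.testing.assert_allclose(ventilation_weights(zones), zones.a)

    def test_occlusion_renormalizes_exactly(self, small_network):
        _, tree, zones = small_network
        occ = (0, 2)
        w = ventilation_weights(zones, occ)
        f = zones.a[list(occ)].sum()
        keep = np.setdiff1d(np.arange(zones.n_zones), occ)
        np.testing.assert_allclose(w[keep], zones.a[keep] / (1 - f))
        assert w[list(occ)].sum() == 0.0
        assert w.sum() == pytest.approx(1.0)

    def test_all_occluded_rejected(self, small_network):
        _, tree, zones = small_network
        with pytest.raises(ValueError, match="all zones"):
            ventilation_weights(zones, tuple(range(zones.n_zones)))


class TestSteadyStates:
    def test_passive_steady_matches_linear_network(self, small_network):
        """The dynamic model's periodic mean under constant boundary
        conditions matches the independent resistor-network reduction when
        the resistance is linearized at the reference volume."""
        _, tree, zones = small_network
        gas = GasParams(Palv_star=1e-9)  # constant external pressure
        cfg = SimConfig(mode="no_hpv", n_cycles=12, min_cycles=4,
                        gas_transport=False, volume_resistance=False,
                        T_baseline=1.0, converge_tol=1e-7)
        m = AssembledModel(tree, zones, gas=gas, config=cfg)
        res = m.run()
        ss = linear_steady_state(tree, zones, m.net.R0, m.net.cap_R0,
                                 m.net.R0, dp=25.0)
        np.testing.assert_allclose(res.seg_flow_art, ss["q"], rtol=1e-4)
        np.testing.assert_allclose(res.total_flow, ss["q"][0], rtol=1e-4)

    def test_blood_volume_conservation(self, small_model):
        """d/dt(total blood volume) equals inflow minus outflow: audit the
        assembled RHS directly."""
        m = small_model
        y = m.initial_state()
        rng = np.random.default_rng(3)
        y = y * rng.uniform(0.95, 1.05, len(y))
        d = m.rhs(0.1, y)
        C_a = m.net.C0 / m.T_art_static
        C_v = m.net.C0 / m.T_ven_static
        dV_total = (np.sum(d[m.sl["Pa"]] * C_a)
                    + np.sum(d[m.sl["Pc"]] * m.net.cap_C)
                    + np.sum(d[m.sl["Pv"]] * C_v))
        # inflow - outflow from the same state
        qa = y[m.sl["qa"]]
        Pv = y[m.sl["Pv"]]
        qv = y[m.sl["qv"]]
        RD0 = m.net.wall.v / C_v[0]
        _, Palv = (0.0, 0.0)
        from vqsim.gas_transport import ventilation_waveforms
        _, Palv = ventilation_waveforms(0.1, m.gas)
        q_out_root = qv[0] + (Palv + Pv[0] - m.config.venous_pressure) / RD0
        assert dV_total == pytest.approx(qa[0] - q_out_root, rel=1e-9)

    def test_o2_mass_balance_at_steady_state(self, small_network):
        """Cycle-averaged venous O2 export minus arterial import equals the
        summed alveolar-capillary diffusive flux (global conservation)."""
        _, tree, zones = small_network
        cfg = SimConfig(mode="no_hpv", n_cycles=60, min_cycles=40,
                        converge_tol=None)
        m = AssembledModel(tree, zones, config=cfg)
        res = m.run()
        t = res.window["t"]
        Y = res.window["y"]
        qv0 = Y[m.sl["qv"]][0]
        Cv0 = Y[m.sl["Cv"]][0]
        Pv0 = Y[m.sl["Pv"]][0]
        C_v0 = m.net.C0[0] / m.T_ven_static
        RD0 = m.net.wall.v / C_v0
        from vqsim.gas_transport import ventilation_waveforms
        _, Palv = ventilation_waveforms(t, m.gas)
        qout0 = qv0 + (Palv + Pv0 - cfg.venous_pressure) / RD0
        span = t[-1] - t[0]
        export = np.trapezoid(qout0 * Cv0 * 1e-3, t) / span
        qa0 = Y[m.sl["qa"]][0]
        imprt = np.trapezoid(qa0 * m.gas.C_O2_input * 1e-3, t) / span
        assert export - imprt == pytest.approx(res.total_o2_flux,
                                               rel=5e-3, abs=1e-12)

    def test_no_diffusion_blood_stays_at_input(self, small_network):
        _, tree, zones = small_network
        gas = dataclasses.replace(GasParams(), D_O2=1e-12)
        cfg = SimConfig(mode="no_hpv", n_cycles=25, min_cycles=20,
                        converge_tol=None)
        res = AssembledModel(tree, zones, gas=gas, config=cfg).run()
        from vqsim.gas_transport import o2_partial_pressure
        P_in = o2_partial_pressure(gas.C_O2_input, gas)
        assert res.venous_P_O2 == pytest.approx(P_in, abs=0.5)


class TestScenarios:
    def test_steady_tone_independent_of_tau(self, small_network):
        # the tone fixed point does not depend on the relaxation time; run
        # each tau for ~30 relaxation times with no early stopping
        _, tree, zones = small_network
        tones = {}
        for tau, cycles in ((2.0, 70), (6.0, 210)):
            cfg = SimConfig(mode="hpv", tau=tau, n_cycles=cycles,
                            converge_tol=None)
            res = run_scenario(tree, zones, cfg)
            tones[tau] = res.tone
        np.testing.assert_allclose(tones[2.0], tones[6.0], atol=3e-3)

    def test_occlusion_without_hpv_leaves_flows_unchanged(self, small_network):
        _, tree, zones = small_network
        base = run_scenario(tree, zones,
                            SimConfig(mode="no_hpv", n_cycles=16,
                                      min_cycles=6))
        occ = run_scenario(tree, zones,
                           SimConfig(mode="no_hpv", occluded_zones=(0, 1),
                                     n_cycles=16, min_cycles=6))
        np.testing.assert_allclose(occ.zone_flow, base.zone_flow, rtol=2e-3)

    def test_doubling_cycles_after_convergence_stable(self, small_network):
        _, tree, zones = small_network
        r1 = run_scenario(tree, zones,
                          SimConfig(mode="no_hpv", n_cycles=40,
                                    min_cycles=30, converge_tol=None))
        r2 = run_scenario(tree, zones,
                          SimConfig(mode="no_hpv", n_cycles=80,
                                    min_cycles=60, converge_tol=None))
        assert abs(r2.venous_P_O2 - r1.venous_P_O2) / r1.venous_P_O2 < 1e-2


class TestPressureFlow:
    def test_dp_increases_with_flow_and_tone(self, small_network):
        _, tree, zones = small_network
        flows = [0.0, 0.5, 1.0]
        lo = pressure_flow_experiment(tree, zones, T_star=0.5, flows=flows,
                                      n_cycles=8)
        hi = pressure_flow_experiment(tree, zones, T_star=0.8, flows=flows,
                                      n_cycles=8)
        assert lo.dp_mmHg.iloc[0] == 0.0
        assert np.all(np.diff(lo.dp_mmHg) > 0)
        assert np.all(hi.dp_mmHg.iloc[1:].to_numpy()
                      > lo.dp_mmHg.iloc[1:].to_numpy())
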