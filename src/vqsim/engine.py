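"""Assembly and integration of the coupled lobe model.

The full state couples, per vessel segment, the (P_v, q_in) pair of the
lumped mechanics on the arterial, capillary and venous sides; per perfusion
zone, the alveolar (volume, O2 moles) pair and the capillary O2
concentration; per venous segment, its O2 concentration; two airway O2
partial pressures; and, with HPV active, one tone state per arterial
segment.  All couplings (bifurcation, arteriole-capillary-venule chains,
venous confluences, outlet closure) are resolved algebraically inside the
right-hand side, so the system integrates as plain ODEs with a stiff (BDF)
method and a sparse finite-difference Jacobian.

Scenario protocols: fixed arterial-venous pressure drop or prescribed root
inflow; uniform (area-proportional) ventilation with optional airway
occlusions (bulk airflow held, weights renormalized); HPV on/off or uniform
vasoconstriction (global tone T*).  Runs proceed cycle by cycle to a
periodic steady state and summarize over the final two respiratory cycles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate._ivp.bdf import BDF

from .config import GasParams, HPVParams, SimConfig
from .gas_transport import HillInverter, o2_saturation, ventilation_waveforms
from .hpv_control import signal_weight_matrix
from .mechanics import NetworkParams, build_network_params, linear_steady_state, set_reference_volumes
from .netgen import SegmentTree, ZoneMap
from .units import L_PER_ML

__all__ = ["AssembledModel", "SimResult", "run_scenario",
           "pressure_flow_experiment", "ventilation_weights"]

V_FLOOR_FRAC = 1e-3


def ventilation_weights(zones: ZoneMap, occluded=()):
    """Zone airflow weights: area-proportional, occlusions renormalized.

    Occluded zones receive zero airflow while the bulk airflow is held, so
    the remaining weights scale by 1/(1 - occluded area fraction).
    """
    w = zones.a.copy()
    occluded = np.asarray(list(occluded), dtype=int)
    if len(occluded):
        if np.any((occluded < 0) | (occluded >= zones.n_zones)):
            raise ValueError("occluded zone index out of range")
        w[occluded] = 0.0
    tot = w.sum()
    if tot <= 0:
        raise ValueError("all zones occluded")
    return w / tot


@dataclass
class SimResult:
    """Cycle-averaged summaries over the final two respiratory cycles."""
    config: SimConfig
    n_cycles_run: int
    converged: bool
    # per-zone (cycle-averaged magnitudes)
    zone_flow: np.ndarray          # capillary blood flow, ml/s
    zone_ventilation: np.ndarray   # ml/s (mean-of-half-sine convention)
    zone_vq: np.ndarray
    zone_o2_flux: np.ndarray       # mol/s
    zone_P_alv_O2: np.ndarray      # mmHg
    zone_P_cap_O2: np.ndarray      # mmHg
    # whole-organ
    total_flow: float              # ml/s
    total_resistance: float        # mmHg s/ml
    venous_P_O2: float             # mmHg, primary vein
    venous_saturation: float
    total_o2_flux: float           # mol/s
    arterial_pressure: float       # mean inlet pressure, mmHg
    # per-segment window means (for transit-time analysis)
    seg_flow_art: np.ndarray
    seg_flow_ven: np.ndarray
    seg_vol_art: np.ndarray
    seg_vol_ven: np.ndarray
    cap_vol: np.ndarray
    tone: np.ndarray | None = None
    clamp_events: int = 0
    window: dict = field(default_factory=dict, repr=False)

    def zone_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "flow_ml_s": self.zone_flow,
            "ventilation_ml_s": self.zone_ventilation,
            "vq_ratio": self.zone_vq,
            "o2_flux_mol_s": self.zone_o2_flux,
            "P_alv_O2_mmHg": self.zone_P_alv_O2,
            "P_cap_O2_mmHg": self.zone_P_cap_O2,
        })


class AssembledModel:
    """Coupled ODE system for one network under one scenario."""

    def __init__(self, tree: SegmentTree, zones: ZoneMap,
                 net: NetworkParams | None = None,
                 gas: GasParams | None = None,
                 hpv: HPVParams | None = None,
                 config: SimConfig | None = None):
        self.tree = tree
        self.zones = zones
        self.gas = gas or GasParams()
        self.hpv = hpv or HPVParams()
        self.config = config or SimConfig()
        self.net = net or build_network_params(tree, zones)
        if self.net.V0_art is None:
            set_reference_volumes(self.net, tree, zones)

        cfg = self.config
        S = tree.n_segments
        Z = zones.n_zones
        self.S, self.Z = S, Z
        terms = zones.terminal_segment
        self.terms = terms
        child1 = np.full(S, -1, dtype=int)
        child2 = np.full(S, -1, dtype=int)
        for j, ch in enumerate(tree.children):
            if len(ch) == 2:
                child1[j], child2[j] = ch
            elif len(ch) not in (0, 2):
                raise ValueError(f"segment {j} has {len(ch)} daughters")
        self.internal = np.flatnonzero(child1 >= 0)
        self.c1 = child1[self.internal]
        self.c2 = child2[self.internal]
        self.child1, self.child2 = child1, child2
        self.nonroot = np.arange(1, S)
        self.parent_of = tree.parent

        self.w = ventilation_weights(zones, cfg.occluded_zones)
        gas_params = self.gas
        if gas_params.fio2 != cfg.fio2:
            import dataclasses as _dc
            gas_params = _dc.replace(gas_params, fio2=cfg.fio2)
            self.gas = gas_params
        self.hill = HillInverter(self.gas)
        self.W_sig, self.N_zones = signal_weight_matrix(tree, zones, self.hpv)
        self.tau = cfg.tau if cfg.tau is not None else self.hpv.tau

        # static tone factors: the unregulated state is the dilated
        # (papaverine-like) baseline T_baseline; UVC replaces it globally
        # with T_star; HPV modulates the arterial side only, leaving the
        # venous side at baseline
        if cfg.mode == "uvc":
            self.T_art_static = cfg.T_star
            self.T_ven_static = cfg.T_star
        elif cfg.mode == "no_hpv":
            self.T_art_static = cfg.T_baseline
            self.T_ven_static = cfg.T_baseline
        else:
            self.T_art_static = 1.0  # tones are dynamic states
            self.T_ven_static = cfg.T_baseline
        self.dynamic_tone = cfg.mode == "hpv"
        if self.dynamic_tone and not cfg.gas_transport:
            raise ValueError("hpv mode requires gas transport")

        # state layout
        self.has_gas = cfg.gas_transport
        off = 0
        self.sl = {}
        for name, size in [("Pa", S), ("qa", S), ("Pc", Z), ("qc", Z),
                           ("Pv", S), ("qv", S)]:
            self.sl[name] = slice(off, off + size)
            off += size
        if self.has_gas:
            for name, size in [("Cc", Z), ("Cv", S), ("Valv", Z),
                               ("Malv", Z), ("Paw", 2)]:
                self.sl[name] = slice(off, off + size)
                off += size
        if self.dynamic_tone:
            self.sl["T"] = slice(off, off + S)
            off += S
        self.n_states = off
        self.clamp_events = 0

        # fixed venous-side effective parameters
        w0 = self.net.wall
        self.v_wall = w0.v
        self._beta_ml = self.gas.beta * L_PER_ML
        self._aD = self.gas.alpha * self.gas.D_O2 * L_PER_ML  # mol/(mmHg s)

    # ------------------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        net, cfg, gas = self.net, self.config, self.gas
        S, Z = self.S, self.Z
        sl = self.sl
        Pa, qa = y[sl["Pa"]], y[sl["qa"]]
        Pc, qc = y[sl["Pc"]], y[sl["qc"]]
        Pv, qv = y[sl["Pv"]], y[sl["qv"]]

        Qair, Palv_ext = ventilation_waveforms(t, gas)
        Qair = float(Qair)
        Palv_ext = float(Palv_ext)

        if self.dynamic_tone:
            Ta = np.maximum(y[sl["T"]], 1e-2)
        else:
            Ta = self.T_art_static
        Tv = self.T_ven_static

        C_a = net.C0 / Ta
        RD_a = self.v_wall / C_a
        C_v = net.C0 / Tv
        RD_v = self.v_wall / C_v
        C_c = net.cap_C
        RD_c = self.v_wall / C_c

        Va = C_a * Pa
        Vv = C_v * Pv
        Vc = C_c * Pc
        fla = V_FLOOR_FRAC * net.V0_art
        flv = V_FLOOR_FRAC * net.V0_ven
        flc = V_FLOOR_FRAC * net.V0_cap
        if (Va < fla).any() or (Vv < flv).any() or (Vc < flc).any():
            self.clamp_events += 1
        Va = np.maximum(Va, fla)
        Vv = np.maximum(Vv, flv)
        Vc = np.maximum(Vc, flc)
        if cfg.volume_resistance:
            Ra = net.R0 * Ta * (net.V0_art / Va) ** 2
            Rv = net.R0 * Tv * (net.V0_ven / Vv) ** 2
            Rc = net.cap_R0 * (net.V0_cap / Vc) ** 2
        else:
            Ra = net.R0 * Ta
            Rv = net.R0 * Tv + 0.0 * Vv
            Rc = net.cap_R0 + 0.0 * Vc

        # outflows
        qouta = np.empty(S)
        qouta[self.terms] = qc
        qouta[self.internal] = qa[self.c1] + qa[self.c2]
        qoutc = qv[self.terms]
        qoutv = np.empty(S)
        num = (Pv[self.c1] - Pv[self.c2] + RD_v[self.c2] * qv[self.internal]
               + RD_v[self.c1] * qv[self.c1] - RD_v[self.c2] * qv[self.c2])
        qa_c1 = num / (RD_v[self.c1] + RD_v[self.c2])
        qoutv[self.c1] = qa_c1
        qoutv[self.c2] = qv[self.internal] - qa_c1
        qoutv[0] = qv[0] + (Palv_ext + Pv[0] - cfg.venous_pressure) / RD_v[0]

        # outlet pressures
        Pouta = Palv_ext + Pa + RD_a * (qa - qouta)
        Poutc = Palv_ext + Pc + RD_c * (qc - qoutc)
        Poutv = Palv_ext + Pv + RD_v * (qv - qoutv)

        # inlet pressures
        Pina = np.empty(S)
        if cfg.dp_mmHg is not None:
            Pina[0] = cfg.venous_pressure + cfg.dp_mmHg
        else:
            Pina[0] = Pouta[0]  # placeholder; root flow is prescribed
        Pina[self.c1] = Pouta[self.internal]
        Pina[self.c2] = Pouta[self.internal]
        Pinc = Pouta[self.terms]
        Pinv = np.empty(S)
        Pinv[self.terms] = Poutc
        Pinv[self.internal] = Poutv[self.c1]

        dy = np.empty_like(y)
        dy[sl["Pa"]] = (qa - qouta) / C_a
        dy[sl["qa"]] = (Pina - Pouta - Ra * qa) / net.L
        dy[sl["Pc"]] = (qc - qoutc) / C_c
        dy[sl["qc"]] = (Pinc - Poutc - Rc * qc) / net.cap_L
        dy[sl["Pv"]] = (qv - qoutv) / C_v
        dy[sl["qv"]] = (Pinv - Poutv - Rv * qv) / net.L
        if cfg.root_flow is not None:
            dy[sl["qa"]][0] = 0.0

        if self.has_gas:
            Cc_ = y[sl["Cc"]]
            Cv_ = y[sl["Cv"]]
            Valv = np.maximum(y[sl["Valv"]], 1e-6)
            Malv = np.maximum(y[sl["Malv"]], 0.0)
            Paw1, Paw2 = y[sl["Paw"]]
            q_i = self.w * Qair
            P_alv_O2 = Malv / (self._beta_ml * Valv)
            P_O2c = self.hill(Cc_)
            flux = self._aD * (P_alv_O2 - P_O2c)  # mol/s per zone
            # smooth inspiration/expiration blend: the hard switch at
            # Q_air = 0 stalls the stiff integrator; blending over a band of
            # 1e-3 QV* is physically negligible
            s = 0.5 * (1.0 + np.tanh(Qair / (1e-3 * gas.QV_star)))
            dPaw1 = (s * Qair * (gas.P_air_O2 - Paw1)
                     - (1.0 - s) * Qair * (Paw2 - Paw1)) / gas.V_airway1
            dPaw2 = (s * Qair * (Paw1 - Paw2)
                     - (1.0 - s) * float(np.sum(q_i * (P_alv_O2 - Paw2)))
                     ) / gas.V_airway2
            dMalv = q_i * self._beta_ml * (s * Paw2 + (1.0 - s) * P_alv_O2) - flux
            dy[sl["Valv"]] = q_i
            dy[sl["Malv"]] = dMalv
            dy[sl["Paw"]] = (dPaw1, dPaw2)
            # advection is upwind: brief reversed-flow excursions must not
            # anti-diffuse the concentration equations
            qc_adv = np.maximum(qc, 0.0)
            qoutc_adv = np.maximum(qoutc, 0.0)
            qoutv_adv = np.maximum(qoutv, 0.0)
            dy[sl["Cc"]] = (qc_adv * (gas.C_O2_input - Cc_)
                            + gas.alpha * gas.D_O2 * (P_alv_O2 - P_O2c)) / Vc
            # mixing volume: the anatomical blood volume pi r^2 l bounds the
            # (much smaller) compliance-distension volume of stiff veins
            Vv_mix = np.maximum(Vv, net.V_geo)
            dCv = np.empty(S)
            dCv[self.terms] = qoutc_adv * (Cc_ - Cv_[self.terms]) \
                / Vv_mix[self.terms]
            dCv[self.internal] = (
                qoutv_adv[self.c1] * (Cv_[self.c1] - Cv_[self.internal])
                + qoutv_adv[self.c2] * (Cv_[self.c2] - Cv_[self.internal])
            ) / Vv_mix[self.internal]
            dy[sl["Cv"]] = dCv

        if self.dynamic_tone:
            sig = np.exp(-P_alv_O2 / self.hpv.P_HPV)
            T_inf = (self.W_sig @ sig) * (self.hpv.T_max - self.hpv.T_min) \
                + self.hpv.T_min
            if self.hpv.aggregation == "sum_clamped":
                T_inf = np.clip(T_inf, self.hpv.T_min, self.hpv.T_max)
            dy[sl["T"]] = (T_inf - y[sl["T"]]) / self.tau
        return dy

    # ------------------------------------------------------------------
    def jac_sparsity(self) -> sparse.csr_matrix:
        """Structural Jacobian (weak tone<-gas and airway2<-alveoli
        couplings deliberately omitted; they are slow relative to the stiff
        mechanics and only serve the Newton iteration)."""
        S, Z = self.S, self.Z
        sl = self.sl
        idx = {k: np.arange(v.start, v.stop) for k, v in self.sl.items()}
        rows, cols = [], []

        def add(r, cs):
            for c in cs:
                rows.append(r)
                cols.append(c)

        iPa, iqa = idx["Pa"], idx["qa"]
        iPc, iqc = idx["Pc"], idx["qc"]
        iPv, iqv = idx["Pv"], idx["qv"]
        cap_of = {int(t): i for i, t in enumerate(self.terms)}

        def qouta_deps(j):
            if self.child1[j] >= 0:
                return [iqa[self.child1[j]], iqa[self.child2[j]]]
            return [iqc[cap_of[j]]]

        def qoutv_deps(j):
            if j == 0:
                return [iPv[0], iqv[0]]
            p = int(self.parent_of[j])
            sib = self.child2[p] if self.child1[p] == j else self.child1[p]
            return [iPv[j], iPv[sib], iqv[j], iqv[sib], iqv[p]]

        tone = idx.get("T")
        for j in range(S):
            tdep = [tone[j]] if self.dynamic_tone else []
            # dPa_j, dqa_j
            add(iPa[j], [iqa[j], *qouta_deps(j), *tdep])
            pouta_j = [iPa[j], iqa[j], *qouta_deps(j), *tdep]
            deps = list(pouta_j)
            if j > 0:
                p = int(self.parent_of[j])
                ptdep = [tone[p]] if self.dynamic_tone else []
                deps += [iPa[p], iqa[p], *qouta_deps(p), *ptdep]
            add(iqa[j], deps)
            # dPv_j, dqv_j
            add(iPv[j], [iqv[j], *qoutv_deps(j)])
            poutv_j = [iPv[j], iqv[j], *qoutv_deps(j)]
            if self.child1[j] >= 0:
                c1 = self.child1[j]
                pinv = [iPv[c1], iqv[c1], *qoutv_deps(c1)]
            else:
                i = cap_of[j]
                pinv = [iPc[i], iqc[i], iqv[j]]
            add(iqv[j], poutv_j + pinv)
        for i, t in enumerate(self.terms):
            t = int(t)
            add(iPc[i], [iqc[i], iqv[t]])
            ttdep = [tone[t]] if self.dynamic_tone else []
            add(iqc[i], [iPc[i], iqc[i], iqv[t], iPa[t], iqa[t], *ttdep])

        if self.has_gas:
            iCc, iCv = idx["Cc"], idx["Cv"]
            iV, iM = idx["Valv"], idx["Malv"]
            iPw = idx["Paw"]
            for i, t in enumerate(self.terms):
                t = int(t)
                add(iCc[i], [iCc[i], iqc[i], iM[i], iV[i], iPc[i]])
                add(iM[i], [iM[i], iV[i], iCc[i], iPw[1]])
                add(iV[i], [iV[i]])
                add(iCv[t], [iCv[t], iCc[i], iPv[t], iPc[i], iqc[i], iqv[t]])
            for j in self.internal:
                c1, c2 = self.child1[j], self.child2[j]
                add(iCv[j], [iCv[j], iCv[c1], iCv[c2], iPv[j],
                             *qoutv_deps(c1), *qoutv_deps(c2)])
            add(iPw[0], [iPw[0], iPw[1]])
            # dead-space balance advects every zone's alveolar gas during
            # expiration; the entries are large in raw units (M in mol)
            add(iPw[1], [iPw[0], iPw[1], *iM, *iV])
        if self.dynamic_tone:
            iV, iM = idx["Valv"], idx["Malv"]
            for j in range(S):
                add(tone[j], [tone[j]])
            # target tone senses every downstream zone's alveolar O2; these
            # entries are large in raw units (M is in mol) and Newton
            # diverges without them
            for k, t in enumerate(self.terms):
                j = int(t)
                while j >= 0:
                    add(tone[j], [iM[k], iV[k]])
                    j = int(self.parent_of[j])
        data = np.ones(len(rows))
        J = sparse.coo_matrix((data, (rows, cols)),
                              shape=(self.n_states, self.n_states))
        return J.tocsr()

    # ------------------------------------------------------------------
    def initial_state(self, n_iter: int = 30) -> np.ndarray:
        """Steady-state initialization from the resistor-network reduction.

        The nonlinear volume-resistance coupling is resolved by damped fixed
        point iteration around the linear solve; gas states start at inspired
        alveolar O2 and mixed-venous blood O2, tones at neutral (1)."""
        net, cfg = self.net, self.config
        _, Palv0 = ventilation_waveforms(0.0, self.gas)
        Ta = self.T_art_static
        Tv = self.T_ven_static
        Ra = net.R0 * Ta
        Rv = net.R0 * Tv
        Rc = net.cap_R0.copy()
        kw = dict(dp=cfg.dp_mmHg, root_flow=cfg.root_flow,
                  venous_pressure=cfg.venous_pressure, P_alv_ext=float(Palv0))
        ss = None
        if not cfg.volume_resistance:
            n_iter = 1
        for _ in range(n_iter):
            ss = linear_steady_state(self.tree, self.zones, Ra, Rc, Rv, **kw)
            if not cfg.volume_resistance:
                break
            Va = np.maximum((net.C0 / Ta) * ss["Pv_art"],
                            V_FLOOR_FRAC * net.V0_art)
            Vv = np.maximum((net.C0 / Tv) * ss["Pv_ven"],
                            V_FLOOR_FRAC * net.V0_ven)
            Vc = np.maximum(net.cap_C * ss["Pv_cap"],
                            V_FLOOR_FRAC * net.V0_cap)
            Ra_new = net.R0 * Ta * (net.V0_art / Va) ** 2
            Rv_new = net.R0 * Tv * (net.V0_ven / Vv) ** 2
            Rc_new = net.cap_R0 * (net.V0_cap / Vc) ** 2
            if (np.allclose(Ra_new, Ra, rtol=1e-10)
                    and np.allclose(Rv_new, Rv, rtol=1e-10)
                    and np.allclose(Rc_new, Rc, rtol=1e-10)):
                Ra, Rv, Rc = Ra_new, Rv_new, Rc_new
                break
            Ra = 0.5 * Ra + 0.5 * Ra_new
            Rv = 0.5 * Rv + 0.5 * Rv_new
            Rc = 0.5 * Rc + 0.5 * Rc_new
        y = np.zeros(self.n_states)
        sl = self.sl
        y[sl["Pa"]] = ss["Pv_art"]
        y[sl["qa"]] = ss["q"]
        y[sl["Pc"]] = ss["Pv_cap"]
        y[sl["qc"]] = ss["q_cap"]
        y[sl["Pv"]] = ss["Pv_ven"]
        y[sl["qv"]] = ss["q"]
        if self.has_gas:
            gas = self.gas
            V0 = self.zones.a * gas.V_alv_total
            P_alv, Cc, P2 = self._steady_gas_guess(ss["q_cap"])
            y[sl["Valv"]] = V0
            y[sl["Malv"]] = self._beta_ml * P_alv * V0
            y[sl["Paw"]] = (gas.P_air_O2, P2)
            y[sl["Cc"]] = Cc
            # venous: flow-weighted mix propagated to the root
            Cv = np.empty(self.S)
            Cv[self.terms] = Cc
            q = ss["q"]
            for j in self.internal[::-1]:
                c1, c2 = self.child1[j], self.child2[j]
                tot = q[c1] + q[c2]
                Cv[j] = (q[c1] * Cv[c1] + q[c2] * Cv[c2]) / tot \
                    if tot > 0 else gas.C_O2_input
            y[sl["Cv"]] = Cv
        if self.dynamic_tone:
            y[sl["T"]] = 1.0
        return y

    def _steady_gas_guess(self, q_cap: np.ndarray):
        """Cycle-averaged algebraic steady state of the gas-exchange chain.

        Per zone, the breath-averaged ventilation supply
        qbar_i beta (P2 - P_alv) balances the diffusive flux
        alpha D (P_alv - P_cap), with the capillary concentration solving
        its own advection-diffusion balance; the dead-space O2 level P2 is
        iterated as a rebreathing mixture.  Used only to initialize the
        integrator near the periodic steady state (the slow alveolar-store
        transient would otherwise dominate run time).
        """
        from scipy.optimize import brentq

        gas = self.gas
        aD = gas.alpha * gas.D_O2
        Cin = gas.C_O2_input
        qbar = self.w * gas.QV_star / np.pi  # cycle-mean inspiratory flow
        VT = 2.0 * gas.QV_star / (2.0 * np.pi * gas.R_R)  # tidal volume
        f_ds = min(0.9, (gas.V_airway1 + gas.V_airway2) / max(VT, 1e-9))
        P2 = gas.P_air_O2
        P_alv = np.full(self.Z, gas.P_air_O2)
        Cc = np.full(self.Z, Cin)
        C_hi = self.hill.C_max * (1 - 1e-9)
        for _ in range(4):
            for i in range(self.Z):
                q = max(q_cap[i], 0.0)

                def cc_of(Palv):
                    def h(C):
                        return (q * (Cin - C)
                                + aD * (Palv - float(self.hill(C))))
                    lo, hi = 0.0, C_hi
                    if h(lo) <= 0:
                        return 0.0
                    if h(hi) >= 0:
                        return hi
                    return brentq(h, lo, hi, xtol=1e-14)

                def g(Palv):
                    C = cc_of(Palv)
                    return (qbar[i] * gas.beta * (P2 - Palv)
                            - aD * (Palv - float(self.hill(C))))

                lo, hi = 1e-3, max(P2, 1.0)
                if g(hi) >= 0:
                    P_alv[i] = hi
                elif g(lo) <= 0:
                    P_alv[i] = lo
                else:
                    P_alv[i] = brentq(g, lo, hi, xtol=1e-10)
                Cc[i] = cc_of(P_alv[i])
            P2 = (1.0 - f_ds) * gas.P_air_O2 + f_ds * float(
                np.sum(self.w * P_alv))
        return P_alv, Cc, P2

    # ------------------------------------------------------------------
    def run(self, n_cycles: int | None = None, y0: np.ndarray | None = None,
            atol=None) -> SimResult:
        """Integrate to a periodic steady state, cycle by cycle.

        A single stiff solver instance persists across cycle boundaries
        (restarted only on stall/failure); per-cycle samples feed the
        periodic-steady-state diagnostic (cycle-to-cycle change of
        primary-vein O2, plus tone drift in hpv mode), which allows early
        termination well before the configured cycle budget.
        """
        cfg = self.config
        n_cycles = n_cycles or cfg.n_cycles
        Tc = 1.0 / self.gas.R_R
        y = self.initial_state() if y0 is None else y0.copy()
        sparsity = self.jac_sparsity()
        if atol is None:
            atol = self._default_atol()
        grid = np.linspace(0.0, Tc, cfg.samples_per_cycle + 1)
        t_end = n_cycles * Tc

        solver = BDF(self.rhs, 0.0, y, t_end, rtol=cfg.rtol, atol=atol,
                     jac_sparsity=sparsity)
        # the multistep history reliably wedges when it spans a breath
        # reversal; schedule a cheap fresh start just after each half-cycle
        next_restart = 0.5 * Tc
        prev_metric = None
        prev_tone = None
        windows = []
        converged = False
        cyc = 0
        cur = np.empty((len(grid), self.n_states))
        cur[0] = y
        si = 1
        nsteps = 0
        mark_t, mark_steps = 0.0, 0
        fail_t = None
        max_steps = 400_000
        self.stats = {"steps": 0, "stall_restarts": 0, "fail_restarts": 0}

        def finalize_cycle():
            nonlocal cyc, si, prev_metric, prev_tone, converged
            t_grid = cyc * Tc + grid
            Y = cur.T.copy()
            windows.append((t_grid, Y))
            if len(windows) > 2:
                windows.pop(0)
            if self.has_gas:
                metric = float(np.trapezoid(self.hill(Y[self.sl["Cv"], :][0]),
                                            t_grid)) / Tc
            else:
                metric = float(np.trapezoid(Y[self.sl["qa"], :][0],
                                            t_grid)) / Tc
            tone_now = (Y[self.sl["T"], -1].copy()
                        if self.dynamic_tone else None)
            if (cfg.converge_tol is not None and prev_metric is not None
                    and cyc + 1 >= cfg.min_cycles):
                rel = abs(metric - prev_metric) / max(abs(prev_metric), 1e-12)
                tone_ok = (not self.dynamic_tone
                           or np.max(np.abs(tone_now - prev_tone)) < 2e-3)
                if rel < cfg.converge_tol and tone_ok:
                    converged = True
            prev_metric = metric
            prev_tone = tone_now
            cyc += 1
            cur[0] = cur[-1]
            si = 1

        while cyc < n_cycles:
            msg = solver.step()
            if solver.status == "failed":
                # a multistep solver can wedge itself (step size driven to
                # eps by its own history); retry from a clean start unless
                # it makes no forward progress at all
                if fail_t is not None and solver.t - fail_t < 1e-9:
                    raise RuntimeError(
                        f"stiff solver failed at t={solver.t}: {msg}")
                fail_t = solver.t
                self.stats["fail_restarts"] += 1
                solver = BDF(self.rhs, solver.t, solver.y, t_end,
                             rtol=cfg.rtol, atol=atol, jac_sparsity=sparsity)
                continue
            nsteps += 1
            if nsteps > max_steps:
                raise RuntimeError(
                    f"stiff solver exceeded {max_steps} steps at t={solver.t}")
            if cyc * Tc + grid[si] <= solver.t:
                dense = solver.dense_output()
                while cyc < n_cycles and cyc * Tc + grid[si] <= solver.t:
                    cur[si] = dense(cyc * Tc + grid[si])
                    si += 1
                    if si == len(grid):
                        finalize_cycle()
                        if converged and cyc >= 2:
                            break
                if converged and cyc >= 2:
                    break
            if solver.status == "running" and solver.t >= next_restart:
                solver = BDF(self.rhs, solver.t, solver.y, t_end,
                             rtol=cfg.rtol, atol=atol, jac_sparsity=sparsity)
                while next_restart <= solver.t:
                    next_restart += 0.5 * Tc
            if nsteps - mark_steps >= 30:
                if solver.t - mark_t < 0.008 * Tc:
                    self.stats["stall_restarts"] += 1
                    solver = BDF(self.rhs, solver.t, solver.y, t_end,
                                 rtol=cfg.rtol, atol=atol,
                                 jac_sparsity=sparsity)
                mark_t, mark_steps = solver.t, nsteps
            if solver.status == "finished":
                while cyc < n_cycles:  # numerical edge at t_end
                    cur[si] = solver.y
                    si += 1
                    if si == len(grid):
                        finalize_cycle()
                break
        self.stats["steps"] = nsteps
        return self._summarize(windows, cyc, converged)

    def _default_atol(self) -> np.ndarray:
        atol = np.empty(self.n_states)
        sl = self.sl
        atol[sl["Pa"]] = 1e-7
        atol[sl["Pc"]] = 1e-7
        atol[sl["Pv"]] = 1e-7
        atol[sl["qa"]] = 1e-10
        atol[sl["qc"]] = 1e-10
        atol[sl["qv"]] = 1e-10
        if self.has_gas:
            atol[sl["Cc"]] = 1e-11
            atol[sl["Cv"]] = 1e-11
            atol[sl["Valv"]] = 1e-9
            atol[sl["Malv"]] = 1e-14
            atol[sl["Paw"]] = 1e-7
        if self.dynamic_tone:
            atol[sl["T"]] = 1e-8
        return atol

    # ------------------------------------------------------------------
    def _summarize(self, windows, cycles_run: int, converged: bool) -> SimResult:
        cfg, gas = self.config, self.gas
        sl = self.sl
        t = np.concatenate([w[0] for w in windows])
        Y = np.concatenate([w[1] for w in windows], axis=1)
        t, uniq = np.unique(t, return_index=True)
        Y = Y[:, uniq]
        span = t[-1] - t[0]

        def tmean(arr):
            return np.trapezoid(arr, t, axis=-1) / span

        Pa, qa = Y[sl["Pa"]], Y[sl["qa"]]
        Pc, qc = Y[sl["Pc"]], Y[sl["qc"]]
        Pv, qv = Y[sl["Pv"]], Y[sl["qv"]]
        if self.dynamic_tone:
            Ta = np.maximum(Y[sl["T"]], 1e-2)
            tone_final = Y[sl["T"], -1].copy()
        else:
            Ta = np.full_like(Pa, self.T_art_static)
            tone_final = None
        Va = (self.net.C0[:, None] / Ta) * Pa
        Vv = (self.net.C0[:, None] / self.T_ven_static) * Pv
        Vc = self.net.cap_C[:, None] * Pc

        zone_flow = tmean(qc)
        total_flow = float(tmean(qa[0]))
        vent = self.w * gas.QV_star * (2.0 / np.pi)
        with np.errstate(divide="ignore", invalid="ignore"):
            vq = np.where(zone_flow > 0, vent / zone_flow, np.inf)

        if self.has_gas:
            Malv = np.maximum(Y[sl["Malv"]], 0.0)
            Valv = np.maximum(Y[sl["Valv"]], 1e-9)
            P_alv = Malv / (self._beta_ml * Valv)
            P_capO2 = self.hill(Y[sl["Cc"]])
            flux = self._aD * (P_alv - P_capO2)
            zone_flux = tmean(flux)
            zone_Palv = tmean(P_alv)
            zone_Pcap = tmean(P_capO2)
            PvenO2 = float(tmean(self.hill(Y[sl["Cv"]][0])))
            sat = float(o2_saturation(PvenO2, gas))
        else:
            zone_flux = np.zeros(self.Z)
            zone_Palv = np.zeros(self.Z)
            zone_Pcap = np.zeros(self.Z)
            PvenO2 = float("nan")
            sat = float("nan")

        if cfg.dp_mmHg is not None:
            p_art = cfg.venous_pressure + cfg.dp_mmHg
        else:
            # inlet pressure reconstructed from the root segment balance
            RD0 = self.v_wall * Ta[0] / self.net.C0[0]
            qout0 = qa[self.child1[0]] + qa[self.child2[0]] \
                if self.child1[0] >= 0 else qc[0]
            _, Palv_t = ventilation_waveforms(t, gas)
            V0r = np.maximum(Va[0], V_FLOOR_FRAC * self.net.V0_art[0])
            R0r = self.net.R0[0] * Ta[0] * (self.net.V0_art[0] / V0r) ** 2
            p_out = Palv_t + Pa[0] + RD0 * (qa[0] - qout0)
            p_art = float(tmean(p_out + R0r * qa[0]))
        dp_eff = p_art - cfg.venous_pressure
        resistance = dp_eff / total_flow if total_flow > 0 else float("inf")

        return SimResult(
            config=cfg, n_cycles_run=cycles_run, converged=converged,
            zone_flow=zone_flow, zone_ventilation=vent, zone_vq=vq,
            zone_o2_flux=zone_flux, zone_P_alv_O2=zone_Palv,
            zone_P_cap_O2=zone_Pcap, total_flow=total_flow,
            total_resistance=float(resistance), venous_P_O2=PvenO2,
            venous_saturation=sat, total_o2_flux=float(np.sum(zone_flux)),
            arterial_pressure=float(p_art),
            seg_flow_art=tmean(qa), seg_flow_ven=tmean(qv),
            seg_vol_art=tmean(np.maximum(Va, self.net.V_geo[:, None])),
            seg_vol_ven=tmean(np.maximum(Vv, self.net.V_geo[:, None])),
            cap_vol=tmean(Vc),
            tone=tone_final, clamp_events=self.clamp_events,
            window={"t": t, "y": Y},
        )


def run_scenario(tree: SegmentTree, zones: ZoneMap, config: SimConfig,
                 net: NetworkParams | None = None,
                 gas: GasParams | None = None,
                 hpv: HPVParams | None = None) -> SimResult:
    """Assemble and integrate one scenario; returns its SimResult."""
    model = AssembledModel(tree, zones, net=net, gas=gas, hpv=hpv,
                           config=config)
    return model.run()


def pressure_flow_experiment(tree: SegmentTree, zones: ZoneMap,
                             T_star: float, flows,
                             net: NetworkParams | None = None,
                             venous_pressure: float = 7.0,
                             alveolar_pressure: float = 6.0,
                             n_cycles: int = 40) -> pd.DataFrame:
    """Whole-organ pressure-flow relationship under Zone 3 conditions.

    For each prescribed total inflow the passive network (global tone
    T_star on arterial and venous segments, constant alveolar pressure,
    fixed venous outlet pressure) is integrated to steady state; the mean
    arterial-venous pressure drop is reported.
    """
    import dataclasses as _dc
    gas = GasParams(Palv_star=1e-9, Palv_offset=alveolar_pressure)
    rows = []
    for q in np.asarray(flows, dtype=float):
        cfg = SimConfig(mode="uvc", T_star=T_star, dp_mmHg=None,
                        root_flow=float(q), venous_pressure=venous_pressure,
                        gas_transport=False, n_cycles=n_cycles, min_cycles=3,
                        converge_tol=1e-5)
        if q == 0.0:
            rows.append({"flow_ml_s": 0.0, "dp_mmHg": 0.0, "T_star": T_star})
            continue
        try:
            res = run_scenario(tree, zones, cfg, net=net, gas=gas)
            rows.append({"flow_ml_s": q,
                         "dp_mmHg": res.arterial_pressure - venous_pressure,
                         "T_star": T_star})
        except RuntimeError as err:
            rows.append({"flow_ml_s": q, "dp_mmHg": float("nan"),
                         "T_star": T_star, "error": str(err)})
    return pd.DataFrame(rows)
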