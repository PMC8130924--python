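"""Lumped-parameter (0D) vessel-segment mechanics.

Each vessel segment is a two-state RLC element: wall pressure P_v and inlet
flow q_in evolve as

    C dP_v/dt = q_in - q_out
    L dq_in/dt = P_in - P_out - R q_in
    P_out = P_alv + P_v + R_D (q_in - q_out)

with a volume-dependent resistance R = R0 (V0/V)^2, V = C P_v.  Anatomical
parameters are estimated from segment geometry: Poiseuille resistance with
the Pries viscosity law, thin-walled elastic compliance, inertance, and a
visco-elastic wall resistance R_D = v/C.  Bifurcation and confluence
couplings close the tree; capillary parameters come from the unstressed
capillary volume budget (70% of total capillary volume at a 1 mmHg design
drop).

Internal units: mmHg, ml, s, cm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WallConstants
from .netgen import SegmentTree, ZoneMap, blood_viscosity_mmhg_s
from .units import CM_PER_UM, MM_PER_CM, density_si_to_internal

__all__ = [
    "wall_thickness",
    "segment_parameters",
    "capillary_parameters",
    "NetworkParams",
    "build_network_params",
    "vessel_rhs",
    "bifurcation_coupling",
    "confluence_coupling",
    "linear_steady_state",
    "equivalent_resistance",
]


def wall_thickness(r_mm):
    """Vessel wall thickness h = r (a e^{b r} + c e^{d r}), r and h in mm."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    w = WallConstants()
    return r * (w.a * np.exp(w.b * r) + w.c * np.exp(w.d * r))


def segment_parameters(r_um, l_um, wall: WallConstants | None = None):
    """Anatomical estimators for one or more segments.

    Returns a dict of arrays in internal units: R0 (Poiseuille with the
    diameter-dependent apparent viscosity), C0 = 2 pi r^3 l/(h E), inertance
    L = rho l/(pi r^2), wall resistance RD = v/C0, geometric volume
    V_geo = pi r^2 l, and h (mm).
    """
    wall = wall or WallConstants()
    r_um = np.asarray(r_um, dtype=float)
    l_um = np.asarray(l_um, dtype=float)
    if np.any(r_um <= 0) or np.any(l_um <= 0):
        raise ValueError("radius and length must be positive")
    r = r_um * CM_PER_UM
    l = l_um * CM_PER_UM
    h_mm = wall_thickness(r * MM_PER_CM)
    h = h_mm / MM_PER_CM
    mu = blood_viscosity_mmhg_s(2.0 * r_um, wall.hct)
    R0 = 8.0 * mu * l / (np.pi * r ** 4)
    C0 = wall.compliance_factor * np.pi * r ** 3 * l / (h * wall.E)
    L = density_si_to_internal(wall.rho) * l / (np.pi * r ** 2)
    return {
        "R0": R0,
        "C0": C0,
        "L": L,
        "RD": wall.v / C0,
        "V_geo": np.pi * r ** 2 * l,
        "h_mm": h_mm,
    }


def capillary_parameters(tree: SegmentTree, zones: ZoneMap,
                         wall: WallConstants | None = None):
    """Per-capillary lumped parameters from the capillary volume budget.

    One capillary per terminal segment.  The total capillary volume equals
    the summed arterial + venous geometric volume (half of pulmonary blood
    is capillary): V_cap,Total = 2 pi sum(r_i^2 l_i).  Each zone's
    unstressed volume is 0.7 a_j V_cap,Total and its compliance is that
    volume per 1 mmHg design drop.  R0 and L copy the upstream arterial
    terminal segment; RD = v/C.
    """
    wall = wall or WallConstants()
    if tree.radius is None:
        raise ValueError("tree needs radii")
    r = tree.radius * CM_PER_UM
    l = tree.length * CM_PER_UM
    V_cap_total = 2.0 * np.pi * float(np.sum(r ** 2 * l))  # ml
    a = zones.a
    V_un = 0.7 * a * V_cap_total
    # empty zones would give zero compliance; floor at the smallest non-empty
    floor = 1e-6 * V_cap_total
    C = np.maximum(V_un, floor) / 1.0  # DP = 1 mmHg
    art = segment_parameters(tree.radius[zones.terminal_segment],
                             tree.length[zones.terminal_segment], wall)
    return {
        "C": C,
        "R0": art["R0"].copy(),
        "L": art["L"].copy(),
        "RD": wall.v / C,
        "V_un": V_un,
        "V_cap_total": V_cap_total,
    }


@dataclass
class NetworkParams:
    """Nominal mechanics parameters for the full arterial/capillary/venous
    network.  Venous segments mirror arterial geometry; reference volumes
    V0 (for the R = R0 (V0/V)^2 nonlinearity) are set by
    :func:`set_reference_volumes`."""
    wall: WallConstants
    # arterial == venous geometry (mirror)
    R0: np.ndarray
    C0: np.ndarray
    L: np.ndarray
    V_geo: np.ndarray
    cap_R0: np.ndarray
    cap_C: np.ndarray
    cap_L: np.ndarray
    cap_V_un: np.ndarray
    V_cap_total: float
    V0_art: np.ndarray | None = None
    V0_ven: np.ndarray | None = None
    V0_cap: np.ndarray | None = None


def build_network_params(tree: SegmentTree, zones: ZoneMap,
                         wall: WallConstants | None = None) -> NetworkParams:
    wall = wall or WallConstants()
    seg = segment_parameters(tree.radius, tree.length, wall)
    cap = capillary_parameters(tree, zones, wall)
    net = NetworkParams(wall=wall, R0=seg["R0"], C0=seg["C0"], L=seg["L"],
                        V_geo=seg["V_geo"], cap_R0=cap["R0"], cap_C=cap["C"],
                        cap_L=cap["L"], cap_V_un=cap["V_un"],
                        V_cap_total=cap["V_cap_total"])
    return net


# ---------------------------------------------------------------------------
# single-segment dynamics and junction algebra (reference scalar forms)
# ---------------------------------------------------------------------------

def vessel_rhs(P_v: float, q_in: float, P_in: float, q_out: float,
               P_alv: float, R0: float, C0: float, L: float, v: float,
               V0: float, T: float = 1.0, V_floor_frac: float = 1e-3):
    """Right-hand side of one vessel segment; returns (dP_v, dq_in, P_out).

    Tone multiplies the nominal resistance and divides the compliance;
    the wall resistance R_D = v/C is recomputed from the effective
    compliance.  Volume is floored at ``V_floor_frac * V0`` to keep the
    (V0/V)^2 resistance finite.
    """
    if T <= 0:
        raise ValueError("tone must be positive")
    C = C0 / T
    RD = v / C
    V = max(C * P_v, V_floor_frac * V0)
    R = R0 * T * (V0 / V) ** 2
    P_out = P_alv + P_v + RD * (q_in - q_out)
    dP_v = (q_in - q_out) / C
    dq_in = (P_in - P_out - R * q_in) / L
    return dP_v, dq_in, P_out


def bifurcation_coupling(P_out_parent: float, q_in_d1: float, q_in_d2: float):
    """Arterial bifurcation: daughters share the parent outlet pressure and
    the parent outflow is the sum of daughter inflows."""
    return {"P_in_d1": P_out_parent, "P_in_d2": P_out_parent,
            "q_out_parent": q_in_d1 + q_in_d2}


def confluence_coupling(P_v_a: float, P_v_b: float, RD_a: float, RD_b: float,
                        q_in_a: float, q_in_b: float, q_in_c: float):
    """Venous confluence: split the confluent inflow between partners.

    Solves the flow-conservation + outlet-pressure-balance pair for
    (q_out_a, q_out_b); their sum equals q_in_c identically.
    """
    denom = RD_a + RD_b
    if denom == 0:
        raise ZeroDivisionError("RD_a + RD_b must be positive")
    q_out_a = (P_v_a - P_v_b + RD_b * q_in_c + RD_a * q_in_a
               - RD_b * q_in_b) / denom
    q_out_b = q_in_c - q_out_a
    return q_out_a, q_out_b


# ---------------------------------------------------------------------------
# steady linear network reduction
# ---------------------------------------------------------------------------

def equivalent_resistance(tree: SegmentTree, R_art: np.ndarray,
                          R_cap: np.ndarray, R_ven: np.ndarray,
                          zones: ZoneMap) -> np.ndarray:
    """Series-parallel equivalent resistance of each subtree.

    R_eq[j] covers arterial segment j, its venous mirror and everything in
    between; R_eq[0] is the whole-network resistance.
    """
    S = tree.n_segments
    cap_of_term = {int(t): i for i, t in enumerate(zones.terminal_segment)}
    R_eq = np.zeros(S)
    for j in range(S - 1, -1, -1):
        ch = tree.children[j]
        if not ch:
            R_eq[j] = R_art[j] + R_cap[cap_of_term[j]] + R_ven[j]
        else:
            inv = sum(1.0 / R_eq[c] for c in ch)
            R_eq[j] = R_art[j] + R_ven[j] + 1.0 / inv
    return R_eq


def linear_steady_state(tree: SegmentTree, zones: ZoneMap,
                        R_art: np.ndarray, R_cap: np.ndarray,
                        R_ven: np.ndarray, dp: float | None = None,
                        root_flow: float | None = None,
                        venous_pressure: float = 7.0,
                        P_alv_ext: float = 0.0) -> dict:
    """Steady flows and pressures of the resistor-network reduction.

    Exactly one of ``dp`` (arterial-venous drop) or ``root_flow`` fixes the
    boundary.  Returns per-segment flows and lumenal inlet/outlet pressures
    for the arterial, capillary and venous sides plus mid-segment wall
    pressures (lumenal midpoint minus the external alveolar pressure).
    """
    if (dp is None) == (root_flow is None):
        raise ValueError("exactly one of dp and root_flow must be given")
    S = tree.n_segments
    terms = zones.terminal_segment
    R_eq = equivalent_resistance(tree, R_art, R_cap, R_ven, zones)
    q = np.zeros(S)
    q[0] = dp / R_eq[0] if dp is not None else root_flow
    for j in range(S):
        ch = tree.children[j]
        if len(ch) == 2:
            c1, c2 = ch
            g1, g2 = 1.0 / R_eq[c1], 1.0 / R_eq[c2]
            q[c1] = q[j] * g1 / (g1 + g2)
            q[c2] = q[j] * g2 / (g1 + g2)
        elif len(ch) == 1:
            q[ch[0]] = q[j]

    P_art_in = np.zeros(S)
    P_art_out = np.zeros(S)
    dp_total = q[0] * R_eq[0]
    P_art_in[0] = venous_pressure + dp_total
    for j in range(S):
        P_art_out[j] = P_art_in[j] - q[j] * R_art[j]
        for c in tree.children[j]:
            P_art_in[c] = P_art_out[j]
    q_cap = q[terms]
    P_cap_in = P_art_out[terms]
    P_cap_out = P_cap_in - q_cap * R_cap
    P_ven_in = np.zeros(S)
    P_ven_out = np.zeros(S)
    P_ven_in[terms] = P_cap_out
    for j in range(S - 1, -1, -1):
        P_ven_out[j] = P_ven_in[j] - q[j] * R_ven[j]
        p = tree.parent[j]
        if p >= 0:
            P_ven_in[p] = P_ven_out[j]  # partners share the confluent inlet
    return {
        "q": q,
        "q_cap": q_cap,
        "R_total": R_eq[0],
        "dp_total": dp_total,
        "P_art_in": P_art_in, "P_art_out": P_art_out,
        "P_cap_in": P_cap_in, "P_cap_out": P_cap_out,
        "P_ven_in": P_ven_in, "P_ven_out": P_ven_out,
        # wall pressures consistent with the lumped element (compliance at
        # the outlet node: P_out = P_alv + P_v at steady state)
        "Pv_art": P_art_out - P_alv_ext,
        "Pv_cap": P_cap_out - P_alv_ext,
        "Pv_ven": P_ven_out - P_alv_ext,
    }


def set_reference_volumes(net: NetworkParams, tree: SegmentTree,
                          zones: ZoneMap, dp: float = 25.0,
                          venous_pressure: float = 7.0) -> None:
    """Fix the resistance reference volumes V0.

    Under the default "equilibrium" convention V0 is the segment volume
    C * P_v at the baseline (tone = 1) steady state of the resistor
    reduction, so the nonlinear resistance equals R0 exactly at baseline and
    constriction (C -> C0/T at fixed wall pressure) raises R by ~T^3.  The
    "geometric" convention uses pi r^2 l instead.  Capillary V0 is the
    unstressed volume (compliance times the 1 mmHg design drop).
    """
    if net.wall.v0_convention == "geometric":
        net.V0_art = net.V_geo.copy()
        net.V0_ven = net.V_geo.copy()
    else:
        ss = linear_steady_state(tree, zones, net.R0, net.cap_R0, net.R0,
                                 dp=dp, venous_pressure=venous_pressure)
        net.V0_art = net.C0 * np.maximum(ss["Pv_art"], 0.5)
        net.V0_ven = net.C0 * np.maximum(ss["Pv_ven"], 0.5)
    net.V0_cap = net.cap_C * 1.0
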