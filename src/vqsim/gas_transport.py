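"""Airway, alveolar, capillary and venous oxygen mass balances.

Two fixed-volume airway compartments (proximal airway and a dead-space
mixing chamber) are driven by a sinusoidal bulk airflow; each perfusion zone
holds a variable-volume alveolar compartment exchanging O2 with its
capillary through an apparent diffusivity D_O2.  Blood oxygen combines
dissolved O2 (Henry's law) with hemoglobin-bound O2 (Hill binding); the
arterial tree carries the mixed-venous input concentration unchanged, and
venous segments mix their upstream inflows.

Alveolar O2 partial pressure is the gas-capacitance relation
P = M/(beta*V) with beta ~ 1/RT in mol/(L*mmHg); airflow-times-pressure
terms convert to mol/s through the same beta.  An explicit 1e-3 L/ml factor
bridges ml-based flows/volumes with mol/L concentrations.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .config import GasParams
from .units import L_PER_ML

__all__ = [
    "ventilation_waveforms",
    "o2_content",
    "o2_saturation",
    "o2_partial_pressure",
    "HillInverter",
    "airway_rhs",
    "alveolar_rhs",
    "alveolar_volume_closed_form",
    "capillary_o2_rhs",
    "venous_o2_rhs",
]


def ventilation_waveforms(t, params: GasParams):
    """Bulk airflow and external alveolar pressure at time t.

    Q_air(t) = QV* sin(2 pi R_R t) (tidal, zero net flow per cycle) and
    P_alv(t) = Palv* sin(2 pi R_R t) + offset.
    """
    phase = np.sin(2.0 * np.pi * params.R_R * np.asarray(t, dtype=float))
    return params.QV_star * phase, params.Palv_star * phase + params.Palv_offset


def o2_content(P, params: GasParams | None = None):
    """Blood O2 concentration (mol/L): dissolved + Hill-bound.

    C = alpha P + Hct C_Hb P^n/(P^n + P50^n); strictly increasing in P and
    saturating at Hct*C_Hb.
    """
    params = params or GasParams()
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("partial pressure must be non-negative")
    Pn = P ** params.n
    return params.alpha * P + params.hct * params.C_Hb * Pn / (Pn + params.P50 ** params.n)


def o2_saturation(P, params: GasParams | None = None):
    """Fractional hemoglobin saturation P^n/(P^n + P50^n)."""
    params = params or GasParams()
    P = np.asarray(P, dtype=float)
    Pn = P ** params.n
    return Pn / (Pn + params.P50 ** params.n)


def o2_partial_pressure(C: float, params: GasParams | None = None,
                        P_max: float = 1500.0) -> float:
    """Invert the content curve: the unique P with o2_content(P) = C.

    Bracketed Brent iteration to |dP| < 1e-9 mmHg; valid for
    0 <= C < o2_content(P_max).
    """
    params = params or GasParams()
    if C < 0 or C >= float(o2_content(P_max, params)):
        raise ValueError(f"concentration {C} outside invertible range")
    if C == 0.0:
        return 0.0
    return brentq(lambda P: float(o2_content(P, params)) - C, 0.0, P_max,
                  xtol=1e-9)


class HillInverter:
    """Fast vectorized inverse of the O2 content curve.

    A monotone interpolant of P(C) on a dense grid provides the initial
    guess; two Newton polishing steps on the analytic derivative bring the
    residual below ~1e-10 mmHg over the physiological range.  Used inside
    the ODE right-hand side where scalar root finding would dominate the
    run time.
    """

    def __init__(self, params: GasParams, P_max: float = 1500.0,
                 grid: int = 4000):
        self.params = params
        self.P_max = P_max
        Pg = np.linspace(0.0, P_max, grid)
        Cg = o2_content(Pg, params)
        self._interp = PchipInterpolator(Cg, Pg, extrapolate=False)
        self.C_max = float(Cg[-1])

    def _dCdP(self, P):
        p = self.params
        Pn = P ** p.n
        P50n = p.P50 ** p.n
        with np.errstate(divide="ignore", invalid="ignore"):
            dsat = np.where(P > 0.0,
                            p.n * Pn / P * P50n / (Pn + P50n) ** 2, 0.0)
        return p.alpha + p.hct * p.C_Hb * dsat

    def __call__(self, C):
        C = np.clip(np.asarray(C, dtype=float), 0.0, self.C_max * (1 - 1e-12))
        P = self._interp(C)
        for _ in range(2):
            P = np.clip(P - (o2_content(P, self.params) - C) / self._dCdP(np.maximum(P, 1e-12)),
                        0.0, self.P_max)
        return P


def alveolar_volume_closed_form(t, V0_i, q_amp_i, R_R: float):
    """Closed-form alveolar volume V0 + q/(2 pi R_R) (1 - cos(2 pi R_R t))
    for a sinusoidal zone airflow of amplitude q_amp_i; periodic with the
    breath."""
    w = 2.0 * np.pi * R_R
    return V0_i + np.asarray(q_amp_i) / w * (1.0 - np.cos(w * np.asarray(t)))


def airway_rhs(P_aw1: float, P_aw2: float, Q_air: float, q_i, P_alv_O2,
               params: GasParams):
    """Airway partial-pressure balances (piecewise in flow direction).

    Inspiration advects atmosphere -> airway1 -> airway2; expiration advects
    the alveolar mixture back through airway2 -> airway1.  ``q_i`` are the
    (signed) zone airflows with sum Q_air.
    """
    if Q_air >= 0.0:
        dP1 = Q_air / params.V_airway1 * (params.P_air_O2 - P_aw1)
        dP2 = Q_air / params.V_airway2 * (P_aw1 - P_aw2)
    else:
        dP1 = -Q_air / params.V_airway1 * (P_aw2 - P_aw1)
        dP2 = -float(np.sum(np.asarray(q_i) * (np.asarray(P_alv_O2) - P_aw2))
                     ) / params.V_airway2
    return dP1, dP2


def alveolar_rhs(V_alv, M_alv, q_i, Q_air: float, P_aw2: float, P_cap_O2,
                 params: GasParams):
    """Alveolar volume/mass balances; returns (dV, dM, P_alv_O2).

    dV/dt = q_i(t); dM/dt advects airway2 gas on inspiration and the zone's
    own alveolar gas on expiration, minus the alveolar-capillary diffusive
    flux alpha D_O2 (P_alv - P_cap) (in mol/s with the L/ml bridge).
    """
    V_alv = np.asarray(V_alv, dtype=float)
    M = np.maximum(np.asarray(M_alv, dtype=float), 0.0)
    beta_ml = params.beta * L_PER_ML              # mol/(ml*mmHg)
    P_alv_O2 = M / (beta_ml * V_alv)
    flux = params.alpha * params.D_O2 * L_PER_ML * (P_alv_O2 - np.asarray(P_cap_O2))
    if Q_air >= 0.0:
        dM = np.asarray(q_i) * beta_ml * P_aw2 - flux
    else:
        dM = np.asarray(q_i) * beta_ml * P_alv_O2 - flux
    return np.asarray(q_i, dtype=float), dM, P_alv_O2


def capillary_o2_rhs(C_O2, q_in, P_alv_O2, P_O2, V_cap, params: GasParams):
    """Capillary O2 concentration balance.

    dC/dt = [q_in (C_in - C) + alpha D_O2 (P_alv - P_O2)]/V_cap with V_cap
    in ml and flows in ml/s (the L/ml factors cancel).  ``P_O2`` is the
    partial pressure corresponding to C (supplied by the caller so the
    inversion strategy is its choice).
    """
    adv = np.asarray(q_in) * (params.C_O2_input - np.asarray(C_O2))
    diff = params.alpha * params.D_O2 * (np.asarray(P_alv_O2) - np.asarray(P_O2))
    return (adv + diff) / np.asarray(V_cap)


def venous_o2_rhs(C_j, C_a, C_b, q_out_a, q_out_b, V_ven):
    """Venous mixing: dC_j/dt = [q_a (C_a - C_j) + q_b (C_b - C_j)]/V_ven.

    For a terminal venule (single capillary upstream) pass the capillary as
    partner ``a`` and zero flow for ``b``.
    """
    return (np.asarray(q_out_a) * (np.asarray(C_a) - np.asarray(C_j))
            + np.asarray(q_out_b) * (np.asarray(C_b) - np.asarray(C_j))
            ) / np.asarray(V_ven)
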