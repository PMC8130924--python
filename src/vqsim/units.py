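"""Unit conventions and physical constants.

The hemodynamic and gas-transport equations are integrated in a single
internal unit system: pressure in mmHg, volume in ml, time in s, length in
cm (so that cm^3 == ml), oxygen amount in mol and concentration in mol/L.
Network geometry is generated and stored in micrometres and converted once
when anatomical parameters are estimated.  Conversions are centralised here
because mixed-unit source data (Pa, cP, um, mm, L) is the main numerical
hazard in this kind of model.
"""

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

UM_PER_CM = 1e4
CM_PER_UM = 1e-4
MM_PER_CM = 10.0
L_PER_ML = 1e-3

#: plasma viscosity in centipoise used to scale the relative in vitro
#: viscosity law to an absolute viscosity
PLASMA_VISCOSITY_CP = 1.2


def viscosity_cp_to_mmhg_s(mu_cp: float) -> float:
    """Convert a viscosity in centipoise to mmHg*s (1 cP = 1e-3 Pa*s)."""
    return mu_cp * 1e-3 * MMHG_PER_PA


def density_si_to_internal(rho_kg_m3: float) -> float:
    """Convert a density in kg/m^3 to the inertance unit system.

    The hydraulic inertance L = rho*l/(pi r^2) must come out in
    mmHg*s^2/ml when l, r are in cm.  rho[kg/m^3] = rho[Pa*s^2/m^2] so
    rho_internal = rho * (1 mmHg/133.322 Pa) * (1 m^2 / 1e4 cm^2) * (1e6 ml/m^3) ...
    Dimensionally: L[SI, Pa*s^2/m^3] * (mmHg/Pa) / (ml/m^3) gives
    1 Pa*s^2/m^3 = 7.5006e-9 mmHg*s^2/ml, and rho*l/(pi r^2) with l, r in m.
    Working directly: with l, r in cm, L = rho_int * l / (pi r^2) where
    rho_int = rho_SI [kg/m^3] * 1e-2 [m/cm] * MMHG_PER_PA / 1e6 [ml/m^3] ...

    Derivation: L_SI = rho*l_m/(pi r_m^2) [Pa s^2 m^-3].  Substituting
    l_m = 1e-2 l_cm, r_m = 1e-2 r_cm gives L_SI = rho*1e2*l_cm/(pi r_cm^2).
    Then L_int = L_SI * MMHG_PER_PA / 1e6.  Hence
    rho_int = rho * 1e2 * MMHG_PER_PA * 1e-6.
    """
    return rho_kg_m3 * 1e2 * MMHG_PER_PA * 1e-6
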