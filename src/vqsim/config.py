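"""Model parameters and scenario configuration.

Defaults reproduce the published rat-lobe parameterization: wall-mechanics
constants from the Blanco thickness fit, the Safaei-style lumped estimators,
blood-gas constants (Hill hemoglobin binding), breathing waveform magnitudes
re-scaled from human to rat by the cardiac-output ratio, and the empirical
HPV controller constants (P_HPV = 80/ln 2, lambda = 100 mm, tau = 30 s).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "WallConstants",
    "GasParams",
    "HPVParams",
    "SimConfig",
    "hpv_sensitivity_constant",
    "inspired_o2_partial_pressure",
    "load_config",
    "save_config",
]


def hpv_sensitivity_constant(half_signal_po2_mmhg: float = 80.0) -> float:
    """O2-sensitivity constant of the HPV signal.

    Solves S = exp(-P_alv/P_HPV) = 1/2 at the alveolar oxygen tension below
    which HPV appreciably raises pulmonary resistance (80 mmHg), giving
    P_HPV = 80/ln 2 = 115.42 mmHg.
    """
    return half_signal_po2_mmhg / math.log(2.0)


def inspired_o2_partial_pressure(fio2: float, barometric_mmhg: float = 760.0,
                                 water_vapor_mmhg: float = 47.0) -> float:
    """Inspired O2 partial pressure: FiO2*(P_B - P_H2O); 0.21 -> 149.7 mmHg."""
    if not 0.0 < fio2 <= 1.0:
        raise ValueError(f"FiO2 must be in (0, 1], got {fio2}")
    return fio2 * (barometric_mmhg - water_vapor_mmhg)


@dataclass
class WallConstants:
    """Vessel-wall mechanics constants (mmHg-ml-s internal units).

    The thickness law h = r*(a e^{b r} + c e^{d r}) takes r in mm and
    returns h in mm.
    """
    E: float = 10000.0          # elastic modulus, mmHg
    a: float = 0.2802           # thickness-fit constants, r in mm
    b: float = -0.5053
    c: float = 0.1324
    d: float = -0.01114
    v: float = 0.01             # wall stress-relaxation speed, s
    rho: float = 1060.0         # blood density, kg/m^3 (converted internally)
    hct: float = 0.4            # hematocrit entering the viscosity law
    compliance_factor: float = 2.0   # C0 = factor*pi*r^3*l/(h*E)
    #: reference-volume convention for the nonlinear resistance R=R0(V0/V)^2:
    #: "equilibrium" sets V0 to the baseline steady-state volume C*P_v,ref;
    #: "geometric" sets V0 = pi r^2 l.
    v0_convention: str = "equilibrium"

    def __post_init__(self) -> None:
        if self.E <= 0 or self.v <= 0 or self.rho <= 0:
            raise ValueError("E, v and rho must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hct}")
        if self.v0_convention not in ("equilibrium", "geometric"):
            raise ValueError(f"unknown v0_convention {self.v0_convention!r}")


@dataclass
class GasParams:
    """Oxygen-transport constants.

    ``beta`` is the gas-phase O2 capacitance in mol/(L*mmHg) -- approximately
    1/RT -- so alveolar partial pressure is P = M/(beta*V).  ``alpha`` is the
    Henry solubility of O2 in plasma.  Airflow and alveolar-pressure
    waveforms are sinusoids at the respiratory rate R_R.
    """
    alpha: float = 1.3e-6        # mol/L/mmHg
    beta: float = 5.95e-5        # mol/(L*mmHg)
    D_O2: float = 3.36           # apparent alveolar-capillary diffusivity, ml/s
    C_Hb: float = 0.0213         # heme-site concentration, mol/L
    hct: float = 0.4
    n: float = 2.6               # Hill exponent
    P50: float = 36.0            # mmHg
    #: mixed-venous O2 concentration entering the lung (mol/L).  The default
    #: is the Hill-curve content at a 40 mmHg mixed-venous tension (~11 vol%);
    #: an arterial-level content (~7.8e-3, >86 mmHg) would put the inflow
    #: above every achievable alveolar tension under hypoxia and forbid any
    #: venous oxygenation below it.
    C_O2_input: float = 4.8924e-3
    R_R: float = 1.17            # breaths per second
    QV_star: float = 2.97        # ventilation magnitude, ml/s
    Palv_star: float = 0.75      # alveolar pressure amplitude, mmHg
    Palv_offset: float = 0.0     # mean external alveolar pressure, mmHg
    fio2: float = 0.21
    #: airway compartment volumes (ml): total ~0.3 ml anatomical dead space
    #: of an adult rat, well below the ~1.6 ml tidal volume
    V_airway1: float = 0.15
    V_airway2: float = 0.15
    V_alv_total: float = 4.0     # ml, summed resting alveolar volume

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "D_O2", "C_Hb", "n", "P50",
                     "C_O2_input", "R_R", "QV_star", "V_airway1",
                     "V_airway2", "V_alv_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hct}")
        if not 0.0 < self.fio2 <= 1.0:
            raise ValueError(f"FiO2 must be in (0, 1], got {self.fio2}")

    @property
    def P_air_O2(self) -> float:
        return inspired_o2_partial_pressure(self.fio2)


@dataclass
class HPVParams:
    """Empirical HPV controller constants.

    The alveolar signal S = exp(-P_alv,O2/P_HPV) is aggregated over the
    perfusion zones downstream of each arterial segment with exponential
    spatial decay exp(-l/lambda) and mapped onto a target tone in
    [T_min, T_max]; instantaneous tone relaxes toward the target with time
    constant tau.  ``aggregation`` is "mean" (bounded by construction) or
    "sum_clamped" (raw sum clamped to the tone bounds).
    """
    P_HPV: float = field(default_factory=hpv_sensitivity_constant)  # mmHg
    lam_mm: float = 100.0        # conducted-response decay length, mm
    tau: float = 30.0            # tone relaxation time, s
    T_max: float = 1.49
    T_min: float = 0.49
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if not (self.T_max > self.T_min > 0):
            raise ValueError("require T_max > T_min > 0")
        if self.lam_mm <= 0 or self.tau <= 0 or self.P_HPV <= 0:
            raise ValueError("P_HPV, lambda and tau must be positive")
        if self.aggregation not in ("mean", "sum_clamped"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class SimConfig:
    """Scenario descriptor for the coupled engine.

    Exactly one of the boundary modes is active: a fixed arterial-venous
    pressure drop (``dp_mmHg``, applied above ``venous_pressure``) or a
    prescribed constant root inflow (``root_flow`` in ml/s).
    """
    mode: str = "no_hpv"             # no_hpv | hpv | uvc
    T_star: float = 0.8              # global tone for uvc mode
    #: global tone of the unregulated (maximally dilated, papaverine-like)
    #: state from the pressure-flow calibration; applied to arterial and
    #: venous segments in no_hpv mode and to the venous side in hpv mode
    T_baseline: float = 0.5
    dp_mmHg: float | None = 25.0
    root_flow: float | None = None
    venous_pressure: float = 7.0     # mmHg, outlet reference
    fio2: float = 0.21
    occluded_zones: tuple[int, ...] = ()
    n_cycles: int = 120
    min_cycles: int = 8
    #: stop early once the cycle-to-cycle relative change of primary-vein O2
    #: (and of tone, in hpv mode) falls below this; None disables
    converge_tol: float | None = 3e-4
    tau: float | None = None         # override HPVParams.tau when set
    rtol: float = 1e-6
    samples_per_cycle: int = 32
    gas_transport: bool = True
    #: volume-dependent resistance R = R0 T (V0/V)^2; False freezes R at
    #: R0 T (linearized at the reference volume)
    volume_resistance: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("no_hpv", "hpv", "uvc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.dp_mmHg is None) == (self.root_flow is None):
            raise ValueError("exactly one of dp_mmHg and root_flow must be set")
        if not 0.0 < self.fio2 <= 1.0:
            raise ValueError(f"FiO2 must be in (0, 1], got {self.fio2}")
        if self.T_star <= 0:
            raise ValueError("T_star must be positive")
        self.occluded_zones = tuple(int(z) for z in self.occluded_zones)


_SECTIONS = {
    "wall": WallConstants,
    "gas": GasParams,
    "hpv": HPVParams,
    "sim": SimConfig,
}


def load_config(path) -> dict:
    """Load a YAML config with sections wall/gas/hpv/sim.

    Missing sections or keys fall back to the published defaults; unknown
    keys are rejected with a field-level message.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ValueError(f"{path}: section {name!r} has unknown keys {sorted(bad)}")
        if "occluded_zones" in section and section["occluded_zones"] is not None:
            section["occluded_zones"] = tuple(section["occluded_zones"])
        out[name] = cls(**section)
    return out


def save_config(cfg: dict, path) -> None:
    """Write a config dict (as returned by load_config) back to YAML."""
    raw = {}
    for name, obj in cfg.items():
        d = dataclasses.asdict(obj)
        if "occluded_zones" in d:
            d["occluded_zones"] = list(d["occluded_zones"])
        raw[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
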