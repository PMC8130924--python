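"""Genetic-algorithm calibration of (D_O2, T_max, T_min).

The three empirical, non-measurable parameters — apparent alveolar-capillary
O2 diffusivity and the HPV tone bounds — are fitted so the model's
primary-vein O2 tension matches measured systemic arterial blood gases under
normoxia (FiO2 0.21) and hypoxia (FiO2 0.10).  Cardiac output and
ventilation boundary values are re-scaled from human measurements to a 350 g
rat by the basal cardiac-output ratio (80 ml/min over 5 L/min).  Because
T_max and T_min enter the controller only through differences, the fit is
ill-conditioned along their sum; a population method (real-coded GA with
tournament selection, blend crossover, Gaussian mutation and elitism) is
used, and the spread of the final population provides the uncertainty
summary.
"""
from __future__ import annotations

import dataclasses as _dc
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GasParams, HPVParams, SimConfig
from .engine import run_scenario

__all__ = [
    "CalibrationTarget",
    "GAConfig",
    "scale_boundary_conditions",
    "objective",
    "fit_parameters",
    "population_uncertainty",
]

CO_RAT_REF_ML_MIN = 80.0
CO_HUMAN_REF_ML_MIN = 5000.0


def scale_boundary_conditions(human_cardiac_output_ml_min: float,
                              human_ventilation_ml_min: float):
    """Re-scale human cardiac output/ventilation to rat magnitudes (ml/s).

    Multiplies by CO_rat,ref/CO_human,ref = 80/5000 = 0.016 and converts
    per-minute values to per-second.
    """
    f = CO_RAT_REF_ML_MIN / CO_HUMAN_REF_ML_MIN
    return (human_cardiac_output_ml_min * f / 60.0,
            human_ventilation_ml_min * f / 60.0)


@dataclass
class CalibrationTarget:
    """Two-condition venous O2 targets with per-condition boundary values.

    Condition 1 is normoxia, condition 2 hypoxia.  The published human blood
    gases give venous O2 tensions of 98.31 and 49.09 mmHg; the normoxia
    boundary magnitudes are the standard QP* = 0.66 and QV* = 2.97 ml/s.
    The hypoxia magnitudes are configurable (only normoxia values are
    tabulated upstream; hypoxia raises cardiac output via reflexes outside
    this model, so equal magnitudes are the conservative default).
    """
    fio2: tuple[float, float] = (0.21, 0.10)
    venous_o2_mmHg: tuple[float, float] = (98.31, 49.09)
    QP_star: tuple[float, float] = (0.66, 0.66)
    QV_star: tuple[float, float] = (2.97, 2.97)

    def __post_init__(self) -> None:
        if len(self.fio2) != 2:
            raise ValueError("exactly two conditions (normoxia, hypoxia)")


@dataclass
class GAConfig:
    generations: int = 30
    population: int = 100
    seed: int = 0
    bounds: dict = field(default_factory=lambda: {
        "D_O2": (0.01, 100.0),
        "T_max": (1.0, 3.0),
        "T_min": (0.05, 1.0),
    })
    tau_override: float = 2.0
    mutation_prob: float = 0.25
    mutation_sigma_frac: float = 0.1
    blend_alpha: float = 0.5
    tournament: int = 3
    elite: int = 2
    n_cycles: int = 120
    log_D: bool = True        # search D_O2 on a log scale (spans 4 decades)
    penalty: float = 1e6


def _decode(genes, cfg: GAConfig):
    """Genes -> (D_O2, T_max, T_min) with T_max > T_min enforced."""
    D, Tmax, Tmin = genes
    if cfg.log_D:
        D = 10.0 ** D
    Tmin = min(Tmin, Tmax - 1e-3)
    return float(D), float(Tmax), float(Tmin)


def objective(params, tree, zones, target: CalibrationTarget,
              gas: GasParams | None = None, hpv: HPVParams | None = None,
              net=None, tau: float = 2.0, n_cycles: int = 120,
              venous_pressure: float = 7.0) -> float:
    """Sum of squared venous-O2 residuals over the two FiO2 conditions.

    Each condition runs with its prescribed root inflow to periodic steady
    state (tone time constant shortened to ``tau``; the steady tone field is
    tau-independent) and the primary-vein O2 tension is averaged over the
    final two respiratory cycles.
    """
    D_O2, T_max, T_min = params
    if not T_max > T_min > 0:
        raise ValueError("require T_max > T_min > 0")
    gas = gas or GasParams()
    hpv = hpv or HPVParams()
    J = 0.0
    for i in range(2):
        g = _dc.replace(gas, D_O2=D_O2, fio2=target.fio2[i],
                        QV_star=target.QV_star[i])
        h = _dc.replace(hpv, T_max=T_max, T_min=T_min)
        cfg = SimConfig(mode="hpv", dp_mmHg=None,
                        root_flow=target.QP_star[i], fio2=target.fio2[i],
                        venous_pressure=venous_pressure, tau=tau,
                        n_cycles=n_cycles, min_cycles=8, converge_tol=1e-3)
        res = run_scenario(tree, zones, cfg, net=net, gas=g, hpv=h)
        J += (target.venous_o2_mmHg[i] - res.venous_P_O2) ** 2
    return float(J)


def fit_parameters(tree, zones, target: CalibrationTarget | None = None,
                   ga: GAConfig | None = None, gas=None, hpv=None, net=None,
                   verbose: bool = False):
    """Real-coded GA minimization of the two-condition objective.

    Returns a dict with the best decoded parameters, the best J, the decoded
    final population and the per-generation best-J trace (non-increasing:
    elitism keeps the incumbent).
    """
    target = target or CalibrationTarget()
    ga = ga or GAConfig()
    rng = np.random.default_rng(ga.seed)
    names = ("D_O2", "T_max", "T_min")
    lo = np.array([ga.bounds[n][0] for n in names])
    hi = np.array([ga.bounds[n][1] for n in names])
    if ga.log_D:
        lo[0], hi[0] = np.log10(lo[0]), np.log10(hi[0])

    def evaluate(genes):
        try:
            return objective(_decode(genes, ga), tree, zones, target,
                             gas=gas, hpv=hpv, net=net, tau=ga.tau_override,
                             n_cycles=ga.n_cycles)
        except Exception:  # noqa: BLE001 - failed individuals are penalized
            return ga.penalty

    pop = rng.uniform(lo, hi, size=(ga.population, 3))
    fit = np.array([evaluate(g) for g in pop])
    if np.all(fit >= ga.penalty):
        raise RuntimeError("every individual of the initial generation failed")
    trace = [float(fit.min())]
    for gen in range(ga.generations):
        order = np.argsort(fit)
        new = [pop[order[i]].copy() for i in range(ga.elite)]
        while len(new) < ga.population:
            # tournament parents
            picks = rng.integers(0, ga.population, size=(2, ga.tournament))
            p1 = pop[picks[0][np.argmin(fit[picks[0]])]]
            p2 = pop[picks[1][np.argmin(fit[picks[1]])]]
            # BLX-alpha blend crossover
            span = np.abs(p1 - p2)
            cl = np.minimum(p1, p2) - ga.blend_alpha * span
            ch = np.maximum(p1, p2) + ga.blend_alpha * span
            child = rng.uniform(cl, ch)
            mut = rng.random(3) < ga.mutation_prob
            child[mut] += rng.normal(0.0, ga.mutation_sigma_frac
                                     * (hi - lo))[mut]
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fit = np.concatenate([fit[order[:ga.elite]],
                              [evaluate(g) for g in pop[ga.elite:]]])
        trace.append(float(fit.min()))
        if verbose:
            print(f"generation {gen + 1}: best J = {fit.min():.4g}")
    best = int(np.argmin(fit))
    decoded = np.array([_decode(g, ga) for g in pop])
    return {
        "best_params": dict(zip(names, _decode(pop[best], ga))),
        "best_J": float(fit[best]),
        "population": pd.DataFrame(decoded, columns=names).assign(J=fit),
        "trace": np.array(trace),
    }


def population_uncertainty(population: pd.DataFrame):
    """Per-parameter SD and Pearson correlations over a GA population.

    Degenerate (zero-variance) parameters yield NaN correlations, reported
    as such.
    """
    cols = [c for c in ("D_O2", "T_max", "T_min") if c in population]
    if len(population) < 10:
        raise ValueError("population too small for uncertainty summary")
    sub = population[cols]
    sd = sub.std(ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = sub.corr()
    return {"sd": sd, "correlation": corr}
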