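"""Post-processing metrics for scenario results.

Heterogeneity is summarized by the coefficient of variation (sigma/mu) of
per-zone quantities; ventilation-perfusion matching by per-zone V/Q ratios
and their Pearson correlation; hemodynamics by red-blood-cell transit-time
distributions computed from per-path volume/flow ratios (the quantity an
indicator-dilution experiment deconvolves); gas exchange by per-zone
alveolar-capillary O2 fluxes.  Distributions are reported as Gaussian
kernel density estimates (Silverman bandwidth, support clipped at zero).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, pearsonr

from .engine import SimResult
from .netgen import SegmentTree, ZoneMap

__all__ = [
    "coefficient_of_variation",
    "vq_ratios",
    "kde_density",
    "transit_time_distribution",
    "zone_o2_flux",
    "ventilation_perfusion_correlation",
    "metric_table",
    "sensitivity_analysis",
    "SENSITIVITY_PARAMETERS",
]


def coefficient_of_variation(values) -> float:
    """Population sigma over mu; scale-invariant heterogeneity index."""
    values = np.asarray(values, dtype=float)
    mu = values.mean()
    if mu == 0:
        raise ZeroDivisionError("CV undefined for zero-mean values")
    return float(values.std() / mu)


def kde_density(values, weights=None, grid=None, n_grid: int = 256):
    """Gaussian KDE with Silverman bandwidth, clipped to non-negative
    support and renormalized to integrate to 1 on the returned grid."""
    values = np.asarray(values, dtype=float)
    if grid is None:
        hi = values.max() * 1.3 + 1e-12
        grid = np.linspace(0.0, hi, n_grid)
    if len(values) < 2 or np.ptp(values) == 0.0:
        # degenerate sample: narrow Gaussian spike at the common value
        mu = float(values.mean())
        sig = max(abs(mu) * 1e-3, 1e-12)
        dens = np.exp(-0.5 * ((grid - mu) / sig) ** 2)
    else:
        kde = gaussian_kde(values, weights=weights)
        dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density support does not overlap the grid")
    return grid, dens / area


def vq_ratios(ventilation, perfusion):
    """Per-zone V/Q ratios plus a KDE over the finite ones.

    Zones with zero perfusion have infinite V/Q and are excluded from the
    density (their count is reported); zero-ventilation zones contribute
    V/Q = 0.
    """
    v = np.asarray(ventilation, dtype=float)
    q = np.asarray(perfusion, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(q > 0, v / q, np.inf)
    finite = np.isfinite(ratios)
    grid, dens = kde_density(ratios[finite])
    return {
        "ratios": ratios,
        "n_unperfused": int(np.sum(~finite)),
        "grid": grid,
        "density": dens,
        "cv": coefficient_of_variation(ratios[finite]),
    }


def transit_time_distribution(tree: SegmentTree, zones: ZoneMap,
                              result: SimResult):
    """RBC transit-time distribution h(t) from root-to-root path times.

    Each perfusion zone defines one arterial->capillary->venous path; the
    path time sums segment volume/flow along it and paths are weighted by
    the flow they carry.  Also returns the mean transit time, which by
    Little's law approximates total perfused volume over total flow.
    """
    qa = result.seg_flow_art
    qv = result.seg_flow_ven
    Va = result.seg_vol_art
    Vv = result.seg_vol_ven
    qcap = result.zone_flow
    Vcap = result.cap_vol
    total = qa[0]
    if total <= 0:
        raise ValueError("zero total flow")
    times, weights = [], []
    for i, t_seg in enumerate(zones.terminal_segment):
        if qcap[i] <= 0:
            continue
        path = tree.path_to_root(int(t_seg))
        tt = Vcap[i] / qcap[i]
        for j in path:
            if qa[j] > 0:
                tt += Va[j] / qa[j]
            if qv[j] > 0:
                tt += Vv[j] / qv[j]
        times.append(tt)
        weights.append(qcap[i])
    times = np.asarray(times)
    weights = np.asarray(weights) / np.sum(weights)
    mean_t = float(np.sum(times * weights))
    grid, dens = kde_density(times, weights=weights)
    return {"times": times, "weights": weights, "mean": mean_t,
            "grid": grid, "density": dens}


def zone_o2_flux(result: SimResult):
    """Per-zone cycle-averaged alveolar-capillary O2 flux and summaries."""
    flux = result.zone_o2_flux
    total = float(np.sum(flux))
    cv = coefficient_of_variation(flux)
    return {"flux": flux, "total": total, "cv": cv,
            "cv_over_total": cv / total if total else float("inf")}


def ventilation_perfusion_correlation(ventilation, perfusion) -> float:
    """Pearson correlation of per-zone ventilation and perfusion."""
    v = np.asarray(ventilation, dtype=float)
    q = np.asarray(perfusion, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 zones")
    if v.std() == 0 or q.std() == 0:
        raise ValueError("zero variance in ventilation or perfusion")
    return float(pearsonr(v, q).statistic)


def metric_table(results: dict[str, SimResult]) -> pd.DataFrame:
    """Whole-organ summary table (one column per scenario)."""
    rows = {}
    for name, r in results.items():
        flux = zone_o2_flux(r)
        rows[name] = {
            "total_flow_ml_s": r.total_flow,
            "total_resistance_mmHg_s_ml": r.total_resistance,
            "flow_cv": coefficient_of_variation(r.zone_flow),
            "vq_cv": vq_ratios(r.zone_ventilation, r.zone_flow)["cv"],
            "total_o2_flux_mol_s": flux["total"],
            "o2_flux_cv": flux["cv"],
            "o2_flux_cv_over_total": flux["cv_over_total"],
            "venous_o2_mmHg": r.venous_P_O2,
            "venous_o2_saturation": r.venous_saturation,
        }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity
# ---------------------------------------------------------------------------

#: parameter name -> (config section, attribute); "Hct" perturbs the
#: hematocrit seen by both the viscosity law and the O2 content curve
SENSITIVITY_PARAMETERS = {
    "E": ("wall", "E"),
    "v": ("wall", "v"),
    "Hct": ("hct", None),
    "n": ("gas", "n"),
    "P50": ("gas", "P50"),
    "C_O2_input": ("gas", "C_O2_input"),
    "R_R": ("gas", "R_R"),
    "QV_star": ("gas", "QV_star"),
    "Palv_star": ("gas", "Palv_star"),
    "P_HPV": ("hpv", "P_HPV"),
    "lambda": ("hpv", "lam_mm"),
    "D_O2": ("gas", "D_O2"),
    "T_max": ("hpv", "T_max"),
    "T_min": ("hpv", "T_min"),
}


def sensitivity_analysis(tree, zones, config, parameters=None,
                         pct: float = 10.0, gas=None, hpv=None, wall=None):
    """One-at-a-time +-pct% sensitivity of primary-vein O2 tension.

    The index is the percent change relative to the unperturbed run,
    S_i = 100 (P_O2,i - P_O2,ref)/P_O2,ref.  Wall/viscosity parameters force
    a re-estimation of the network mechanics parameters.  Returns a tidy
    DataFrame (parameter, direction, S); failures are flagged per cell.
    """
    import dataclasses as _dc

    from .config import GasParams, HPVParams, WallConstants
    from .engine import run_scenario
    from .mechanics import build_network_params

    gas = gas or GasParams()
    hpv = hpv or HPVParams()
    wall = wall or WallConstants()
    parameters = list(parameters or SENSITIVITY_PARAMETERS)

    def run_with(wall_p, gas_p, hpv_p):
        net = build_network_params(tree, zones, wall_p)
        return run_scenario(tree, zones, config, net=net, gas=gas_p,
                            hpv=hpv_p).venous_P_O2

    ref = run_with(wall, gas, hpv)
    rows = []
    for name in parameters:
        section, attr = SENSITIVITY_PARAMETERS[name]
        for sign in (+1.0, -1.0):
            factor = 1.0 + sign * pct / 100.0
            w, g, h = wall, gas, hpv
            if section == "wall":
                w = _dc.replace(wall, **{attr: getattr(wall, attr) * factor})
            elif section == "gas":
                g = _dc.replace(gas, **{attr: getattr(gas, attr) * factor})
            elif section == "hpv":
                h = _dc.replace(hpv, **{attr: getattr(hpv, attr) * factor})
            elif section == "hct":
                w = _dc.replace(wall, hct=wall.hct * factor)
                g = _dc.replace(gas, hct=gas.hct * factor)
            try:
                po2 = run_with(w, g, h)
                S = 100.0 * (po2 - ref) / ref
                rows.append({"parameter": name,
                             "direction": "+" if sign > 0 else "-",
                             "venous_o2_mmHg": po2, "S": S})
            except Exception as err:  # noqa: BLE001 - reported per cell
                rows.append({"parameter": name,
                             "direction": "+" if sign > 0 else "-",
                             "venous_o2_mmHg": float("nan"),
                             "S": float("nan"), "error": str(err)})
    table = pd.DataFrame(rows)
    table.attrs["reference_venous_o2"] = ref
    return table
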