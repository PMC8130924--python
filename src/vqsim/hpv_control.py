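"""Empirical hypoxic pulmonary vasoconstriction (HPV) controller.

Each perfusion zone emits an oxygen signal S = exp(-P_alv,O2/P_HPV) that is
conducted upstream along the arterial wall with exponential spatial decay
exp(-l/lambda).  The aggregated signal sets a target tone in
[T_min, T_max] toward which each arterial segment's instantaneous tone
relaxes with first-order kinetics; tone multiplies the segment's nominal
resistance and divides its compliance (the wall resistance v/C follows).
Venous and capillary segments carry no tone.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse

from .config import HPVParams
from .netgen import SegmentTree, ZoneMap

__all__ = [
    "hpv_signal",
    "arterial_path_lengths",
    "signal_weight_matrix",
    "target_tone",
    "tone_rate",
    "apply_tone",
]


def hpv_signal(P_alv_O2, params: HPVParams | None = None):
    """Alveolar oxygen signal S = exp(-P_alv,O2/P_HPV), in (0, 1].

    Strictly decreasing in alveolar O2; equals 1/2 at 80 mmHg for the
    default sensitivity P_HPV = 80/ln 2.
    """
    params = params or HPVParams()
    P = np.asarray(P_alv_O2, dtype=float)
    if np.any(P < 0):
        raise ValueError("alveolar O2 tension must be non-negative")
    return np.exp(-P / params.P_HPV)


def arterial_path_lengths(tree: SegmentTree, zones: ZoneMap) -> sparse.csr_matrix:
    """Conduction path lengths l_jk (mm) from zone k to segment j's midline.

    Defined for zones downstream of j only: the full lengths of the
    segments from the zone's terminal up to (but excluding) j, plus half of
    j's own length.  Stored sparse with an explicit entry per (j, k) pair.
    """
    S, Z = tree.n_segments, zones.n_zones
    rows, cols, vals = [], [], []
    for k, t in enumerate(zones.terminal_segment):
        cum = 0.0
        j = int(t)
        while j >= 0:
            rows.append(j)
            cols.append(k)
            vals.append((cum + 0.5 * tree.length[j]) * 1e-3)  # um -> mm
            cum += tree.length[j]
            j = int(tree.parent[j])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(S, Z))


def signal_weight_matrix(tree: SegmentTree, zones: ZoneMap,
                         params: HPVParams) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Spatial-decay weights W[j, k] = exp(-l_jk/lambda) and zone counts N_j.

    Under "mean" aggregation each row is divided by its downstream-zone
    count so the aggregate stays in (0, 1] for signals in (0, 1].
    """
    lengths = arterial_path_lengths(tree, zones)
    W = lengths.copy()
    W.data = np.exp(-lengths.data / params.lam_mm)
    N = np.asarray((lengths != 0).sum(axis=1)).ravel().astype(float)
    # l_jk can legitimately be 0 only for zero-length segments (excluded by
    # construction), so the structural count equals the downstream-zone count
    if params.aggregation == "mean":
        D = sparse.diags(1.0 / np.maximum(N, 1.0))
        W = D @ W
    return W.tocsr(), N


def target_tone(signals, W: sparse.csr_matrix, params: HPVParams):
    """Target tone T_inf = agg_j(S_k e^{-l/lambda}) (T_max - T_min) + T_min.

    With mean aggregation the result lies in [T_min, T_max] by construction;
    with the raw-sum variant it is clamped to those bounds.
    """
    agg = W @ np.asarray(signals, dtype=float)
    T_inf = agg * (params.T_max - params.T_min) + params.T_min
    if params.aggregation == "sum_clamped":
        T_inf = np.clip(T_inf, params.T_min, params.T_max)
    return T_inf


def tone_rate(T, T_inf, tau: float):
    """First-order relaxation dT/dt = (T_inf - T)/tau."""
    return (np.asarray(T_inf) - np.asarray(T)) / tau


def apply_tone(R0, C0, v: float, T):
    """Effective arterial parameters R = R0 T, C = C0/T, RD = v/C."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("tone must be positive")
    C = np.asarray(C0) / T
    return np.asarray(R0) * T, C, v / C
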