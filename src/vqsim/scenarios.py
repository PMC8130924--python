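"""Scenario protocol helpers.

Occlusion series start at the most southwestern perfusion zone and spread
along the vascular topology (zones whose terminals are fewest tree hops
from the seed zone are occluded first), accumulating zones until the
requested occluded area fraction is reached.
"""
from __future__ import annotations

import numpy as np

from .netgen import SegmentTree, ZoneMap

__all__ = ["occlusion_zone_sets", "occlusion_series"]


def _topology_distance_order(tree: SegmentTree, zones: ZoneMap,
                             seed_zone: int) -> np.ndarray:
    """Zones ordered by tree-path hop count from the seed zone's terminal."""
    # hop distance between terminals = path length through common ancestor
    paths = {}
    for z, t in enumerate(zones.terminal_segment):
        paths[z] = tree.path_to_root(int(t))
    seed_path = {seg: depth for depth, seg in enumerate(paths[seed_zone])}
    dist = np.empty(zones.n_zones)
    for z, path in paths.items():
        for depth, seg in enumerate(path):
            if seg in seed_path:
                dist[z] = depth + seed_path[seg]
                break
    order = np.lexsort((np.arange(zones.n_zones), dist))
    return order


def occlusion_zone_sets(tree: SegmentTree, zones: ZoneMap,
                        area_fraction: float) -> tuple[int, ...]:
    """Zones to occlude for a target occluded area fraction.

    Starts at the most southwestern zone (smallest x + y of its terminal
    node) and follows the network structure outward, adding whole zones
    until their summed area fraction reaches ``area_fraction``.
    """
    if not 0.0 <= area_fraction < 1.0:
        raise ValueError("area fraction must be in [0, 1)")
    if area_fraction == 0.0:
        return ()
    tcoords = tree.coords[tree.distal_node[zones.terminal_segment]]
    seed_zone = int(np.argmin(tcoords.sum(axis=1)))
    order = _topology_distance_order(tree, zones, seed_zone)
    chosen: list[int] = []
    acc = 0.0
    for z in order:
        chosen.append(int(z))
        acc += zones.a[z]
        if acc >= area_fraction:
            break
    if len(chosen) >= zones.n_zones:
        raise ValueError("occlusion fraction would occlude every zone")
    return tuple(chosen)


def occlusion_series(tree: SegmentTree, zones: ZoneMap, fractions):
    """Occluded-zone sets for a monotone series of area fractions."""
    return [occlusion_zone_sets(tree, zones, f) for f in fractions]
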