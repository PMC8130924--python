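import numpy as np
import pytest

from vqsim.netgen import (SegmentTree, ZoneMap, generate_network,
                          sample_lobe_mesh)


def make_chain_tree(lengths, radii=None):
    """A single chain of segments (each a straight unit in x)."""
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    coords = np.zeros((n + 1, 2))
    coords[1:, 0] = np.cumsum(lengths)
    nodes = [np.array([i, i + 1]) for i in range(n)]
    parent = np.arange(-1, n - 1)
    tree = SegmentTree(nodes=nodes, parent=parent, length=lengths,
                       coords=coords)
    if radii is not None:
        tree.radius = np.asarray(radii, dtype=float)
    return tree


def make_binary_tree(depth, seg_length=100.0, radii_by_level=None):
    """Perfect binary SegmentTree of the given depth (root segment at top).

    Segment j has children 2j+1, 2j+2; coordinates are laid out on a fan so
    lengths are exact.
    """
    n = 2 ** (depth + 1) - 1
    parent = np.array([-1] + [(j - 1) // 2 for j in range(1, n)])
    coords = np.zeros((n + 1, 2))
    # node i is the distal node of segment i-1 ... build simple chain coords
    nodes = []
    coords = np.zeros((n + 1, 2))
    for j in range(n):
        level = int(np.floor(np.log2(j + 1)))
        coords[j + 1] = (seg_length * (level + 1), j)  # geometry is nominal
    for j in range(n):
        pnode = 0 if j == 0 else parent[j] + 1
        nodes.append(np.array([pnode, j + 1]))
    lengths = np.full(n, seg_length)
    tree = SegmentTree(nodes=nodes, parent=parent, length=lengths,
                       coords=coords)
    if radii_by_level is not None:
        r = np.empty(n)
        for j in range(n):
            r[j] = radii_by_level[int(np.floor(np.log2(j + 1)))]
        tree.radius = r
    return tree


def uniform_zones(tree, a=None):
    """ZoneMap with prescribed (or equal) area fractions for the tree's
    terminals; mesh-point bookkeeping is synthetic."""
    terms = tree.terminal_segments
    Z = len(terms)
    if a is None:
        a = np.full(Z, 1.0 / Z)
    a = np.asarray(a, dtype=float)
    area = a * 1e6
    return ZoneMap(terminal_segment=terms,
                   zone_of_point=np.repeat(np.arange(Z), 2),
                   area=area, a=a)


@pytest.fixture(scope="session")
def small_network():
    """~120-node lobe network: fast enough for coupled-engine tests."""
    return generate_network(seed=3, K=120, width_um=5000.0, spacing=350.0)


@pytest.fixture(scope="session")
def unit_square_mesh():
    from shapely.geometry import Polygon
    boundary = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
    return sample_lobe_mesh(boundary, spacing=250.0, seed=11)
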