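"""Model network generators.

Three families:

* binary and weighted ring lattices with Watts–Strogatz weight-preserving
  rewiring — the theoretical small-world transition,
* hierarchical modular networks (HN): nested power-of-two blocks whose
  connection probability and weight halve at each hierarchical level,
* modular networks (MN): fully connected modules plus random moderate-weight
  inter-module shortcuts.

The HN/MN families are the standard benchmarks for small-world statistics:
both are highly clustered, but only the MN has short weighted paths.  Both
are built as directed random matrices and symmetrized by keeping the strict
upper triangle, so realized densities fluctuate around their analytic
expectations.

All stochastic generators take an explicit ``seed`` (an int, SeedSequence or
Generator accepted by ``numpy.random.default_rng``).
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np

from .graph_core import WeightedNetwork, make_network, symmetrize_upper

logger = logging.getLogger(__name__)

__all__ = [
    "ring_distances",
    "generate_ring_lattice",
    "default_weight_fn",
    "generate_weighted_lattice",
    "rewire",
    "generate_weighted_ws",
    "generate_hn",
    "generate_mn",
]


def ring_distances(n_nodes: int) -> np.ndarray:
    """Circular lattice distance matrix: d_ij = min(|i-j|, n-|i-j|)."""
    idx = np.arange(n_nodes)
    diff = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(diff, n_nodes - diff)


def _check_lattice_params(n_nodes: int, radius: int) -> None:
    if radius < 1 or n_nodes <= 2 * radius:
        raise ValueError(
            f"ring lattice requires N > 2r >= 2, got N={n_nodes}, r={radius}"
        )


def generate_ring_lattice(n_nodes: int, radius: int) -> WeightedNetwork:
    """Binary 1-D ring lattice: each node linked to all neighbours within
    ring distance ``radius``.  Every node has degree ``2*radius`` and the
    network has exactly ``n_nodes * radius`` edges."""
    _check_lattice_params(n_nodes, radius)
    d = ring_distances(n_nodes)
    w = ((d >= 1) & (d <= radius)).astype(float)
    return make_network(w)


def default_weight_fn(radius: int, epsilon: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Default distance-decaying weight rule ``w(d) = (D_max - d)/D_max``.

    ``D_max = radius + epsilon`` is the largest lattice distance spanned by
    an edge plus one unit of lattice spacing; the ``epsilon`` margin
    guarantees every edge a strictly positive weight.  For r=5 this yields
    weights 5/6, 4/6, ..., 1/6 over distances 1..5.
    """
    d_max = radius + epsilon

    def weight_fn(d: np.ndarray) -> np.ndarray:
        return (d_max - d) / d_max

    return weight_fn


def generate_weighted_lattice(
    n_nodes: int,
    radius: int,
    weight_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    epsilon: float = 1.0,
) -> WeightedNetwork:
    """Ring lattice whose edge weights decay with lattice distance.

    Same topology as :func:`generate_ring_lattice`; the weight of edge
    ``(i, j)`` is ``weight_fn(ring_distance(i, j))``.  The default rule is
    :func:`default_weight_fn`, which is strictly decreasing and positive on
    1..radius; any strictly decreasing positive rule may be substituted.
    """
    _check_lattice_params(n_nodes, radius)
    if weight_fn is None:
        weight_fn = default_weight_fn(radius, epsilon)
    d = ring_distances(n_nodes)
    mask = (d >= 1) & (d <= radius)
    w = np.zeros((n_nodes, n_nodes))
    w[mask] = weight_fn(d[mask].astype(float))
    if np.any(w[mask] <= 0):
        raise ValueError("weight_fn must be strictly positive on 1..radius")
    return make_network(w)


def rewire(net: WeightedNetwork, p: float, seed) -> WeightedNetwork:
    """Watts–Strogatz rewiring that carries edge weights along.

    Each undirected edge ``(i, j)`` (``i < j``, visited in fixed order) is
    independently selected with probability ``p``; a selected edge is
    detached at ``j`` and reattached to a new endpoint drawn uniformly among
    nodes that are neither ``i``, nor ``j``, nor current neighbours of ``i``,
    keeping its weight.  Edge count and the multiset of edge weights are
    conserved exactly for every ``p``.  If a node's neighbourhood is
    saturated the edge is left in place (with a log warning).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    w = net.weights.copy()
    iu, ju, _ = net.edge_list()
    selected = rng.random(len(iu)) < p
    for i, j in zip(iu[selected], ju[selected]):
        i, j = int(i), int(j)
        # candidates: not self, not the old endpoint, not already linked to i
        blocked = w[i] > 0
        blocked[i] = True
        blocked[j] = True
        candidates = np.flatnonzero(~blocked)
        if candidates.size == 0:
            logger.warning("node %d saturated; edge (%d, %d) left in place", i, i, j)
            continue
        jp = int(rng.choice(candidates))
        weight = w[i, j]
        w[i, j] = w[j, i] = 0.0
        w[i, jp] = w[jp, i] = weight
    return make_network(w)


def generate_weighted_ws(
    n_nodes: int,
    radius: int,
    p: float,
    seed,
    weight_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    epsilon: float = 1.0,
) -> WeightedNetwork:
    """Weighted small-world network: distance-weighted lattice, then rewiring.

    At ``p = 0`` this is the weighted lattice exactly; at ``p = 1`` it is a
    random topology carrying the lattice's weight multiset.
    """
    lattice = generate_weighted_lattice(n_nodes, radius, weight_fn, epsilon)
    return rewire(lattice, p, seed)


def _hn_level_matrix(mx_lv: int, sz_cl: int) -> np.ndarray:
    """Levels-above-base for every node pair of the hierarchical network.

    Nodes live in aligned power-of-two blocks; the smallest block containing
    both ``i`` and ``j`` has size ``2**bit_length(i ^ j)``, so the pair sits
    ``m = max(0, bit_length(i ^ j) - sz_cl)`` levels above the fully
    connected base modules of size ``2**sz_cl``.
    """
    n = 2**mx_lv
    idx = np.arange(n)
    xor = idx[:, None] ^ idx[None, :]
    # bit_length via log2 on positive entries
    bl = np.zeros_like(xor)
    nz = xor > 0
    bl[nz] = np.floor(np.log2(xor[nz])).astype(int) + 1
    return np.maximum(0, bl - sz_cl)


def generate_hn(
    mx_lv: int = 10,
    sz_cl: int = 5,
    e_base: float = 2.0,
    seed=0,
) -> WeightedNetwork:
    """Hierarchical modular benchmark network on ``2**mx_lv`` nodes.

    Base modules of size ``2**sz_cl`` are fully connected with weight 1.  A
    directed connection between nodes whose lowest common block sits ``m``
    levels above the base is placed with probability ``e_base**-m`` and, when
    placed, carries weight equal to that probability — weak long-range ties
    between strongly clustered blocks.  The directed matrix is symmetrized by
    keeping its strict upper triangle.

    With ``mx_lv=10, e_base=2`` and ``sz_cl = 5, 6, 7`` the expected weighted
    (binary) densities are 4.5(10.9)%, 9.1(18.7)% and 17.9(31.2)%.
    """
    if not (mx_lv > sz_cl >= 1):
        raise ValueError(f"need mx_lv > sz_cl >= 1, got mx_lv={mx_lv}, sz_cl={sz_cl}")
    rng = np.random.default_rng(seed)
    levels = _hn_level_matrix(mx_lv, sz_cl)
    prob = float(e_base) ** (-levels.astype(float))
    np.fill_diagonal(prob, 0.0)
    directed = np.where(rng.random(prob.shape) < prob, prob, 0.0)
    return symmetrize_upper(directed)


def generate_mn(
    k_total: int = 65000,
    sz_cl: int = 6,
    n_nodes: int = 1024,
    seed=0,
) -> WeightedNetwork:
    """Modular benchmark network: full modules plus random shortcuts.

    ``n_nodes / 2**sz_cl`` fully connected modules (weight 1) account for a
    fixed budget of within-module directed edges; the remaining
    ``k_total - within`` directed edges are placed uniformly at random,
    without duplication, between modules with weight 0.5, then the matrix is
    symmetrized by its strict upper triangle.  The defaults give 16 modules
    of 64 nodes, i.e. 64512 within-module directed edges.
    """
    module_size = 2**sz_cl
    if n_nodes % module_size != 0:
        raise ValueError("n_nodes must be a multiple of the module size")
    n_modules = n_nodes // module_size
    within_directed = n_modules * module_size * (module_size - 1)
    e_extra = k_total - within_directed
    if e_extra <= 0:
        raise ValueError(
            f"k_total must exceed the {within_directed} within-module directed edges"
        )
    inter_capacity = n_nodes * (n_nodes - 1) - within_directed
    if e_extra > inter_capacity:
        raise ValueError(f"k_total exceeds capacity ({inter_capacity} inter-module slots)")
    rng = np.random.default_rng(seed)
    module = np.arange(n_nodes) // module_size
    same = module[:, None] == module[None, :]
    directed = np.where(same, 1.0, 0.0)
    np.fill_diagonal(directed, 0.0)
    inter_slots = np.flatnonzero(~same)
    chosen = rng.choice(inter_slots, size=e_extra, replace=False)
    flat = directed.ravel()
    flat[chosen] = 0.5
    return symmetrize_upper(flat.reshape(n_nodes, n_nodes))
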