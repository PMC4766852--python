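"""Clustering coefficients and characteristic path lengths.

These are the two raw statistics from which the small-world propensity is
built.  Clustering comes in a binary flavour and three weighted extensions
(Onnela, Barrat, Zhang), all of which reduce exactly to the binary local
coefficient on binary networks.  Path length treats an edge of weight ``w``
as having traversal cost ``1/w`` — strong connections are cheap to cross —
which is the natural cost function when weights encode connection density or
functional similarity rather than physical length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph_core import DegenerateNetworkError, WeightedNetwork

__all__ = [
    "CLUSTERING_VARIANTS",
    "PathStats",
    "local_clustering",
    "clustering_coefficient",
    "shortest_path_matrix",
    "char_path_length",
]

#: Recognised clustering variants.  "onnela" is the default throughout the
#: package; the others are exposed for sensitivity analyses.
CLUSTERING_VARIANTS = ("binary", "onnela", "barrat", "zhang")


@dataclass(frozen=True)
class PathStats:
    """Characteristic path length plus reachability bookkeeping.

    ``char_path_length`` is the mean shortest-path distance over ordered node
    pairs with a finite distance; ``n_unreachable_pairs`` counts the ordered
    pairs with no connecting path (0 for connected networks).
    """

    char_path_length: float
    n_unreachable_pairs: int


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out


def _triangle_sums(m: np.ndarray) -> np.ndarray:
    """diag(M^3) for symmetric M, i.e. sum_{j,h} m_ij m_jh m_hi per node."""
    return ((m @ m) * m).sum(axis=1)


def local_clustering(net: WeightedNetwork, variant: str = "onnela") -> np.ndarray:
    """Per-node local clustering coefficients ``c_i``.

    Parameters
    ----------
    net
        The network under evaluation.
    variant
        One of ``"binary"``, ``"onnela"``, ``"barrat"``, ``"zhang"``.

        * binary — fraction of pairs of neighbours of ``i`` that are
          themselves connected.
        * onnela — geometric-mean triangle intensity,
          ``c_i = (1/(k_i(k_i-1))) * sum_{j,h} (ŵ_ij ŵ_jh ŵ_hi)^(1/3)``
          with ``ŵ = w / max(w)``.
        * barrat — degree- and strength-aware,
          ``c_i = (1/(s_i(k_i-1))) * sum_{j,h} ((w_ij + w_ih)/2) a_ij a_ih a_jh``.
        * zhang — purely weight based,
          ``c_i = sum_{j,h} ŵ_ij ŵ_jh ŵ_hi / ((sum_j ŵ_ij)^2 - sum_j ŵ_ij^2)``.

    Nodes with fewer than two neighbours (or a zero denominator) get
    ``c_i = 0``.  The ``ŵ`` normalisation uses the global maximum of the
    matrix under evaluation, so each network is normalised in isolation.
    """
    w = net.weights
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    kk = k * (k - 1)

    if variant == "binary":
        # 2*T_i = number of ordered neighbour pairs of i that are connected
        tri2 = _triangle_sums(a)
        return _safe_div(tri2, kk)
    if variant == "onnela":
        wmax = w.max()
        if wmax <= 0:
            return np.zeros(net.n_nodes)
        cube = np.cbrt(w / wmax)
        tri2 = _triangle_sums(cube)
        return _safe_div(tri2, kk)
    if variant == "barrat":
        s = w.sum(axis=1)
        # sum over ordered (j, h): (w_ij + w_ih)/2 * [i,j,h triangle]
        #   = sum_j w_ij * a_ij * (A^2)_ij   by symmetry of the half-sum
        paths2 = a @ a
        num = (w * paths2 * a).sum(axis=1)
        return _safe_div(num, s * (k - 1))
    if variant == "zhang":
        wmax = w.max()
        if wmax <= 0:
            return np.zeros(net.n_nodes)
        wh = w / wmax
        tri2 = _triangle_sums(wh)
        denom = wh.sum(axis=1) ** 2 - (wh**2).sum(axis=1)
        return _safe_div(tri2, denom)
    raise ValueError(
        f"unknown clustering variant {variant!r}; expected one of {CLUSTERING_VARIANTS}"
    )


def clustering_coefficient(net: WeightedNetwork, variant: str = "onnela") -> float:
    """Network clustering coefficient ``C``: the mean of the local ``c_i``.

    The mean runs over all nodes; nodes with degree < 2 contribute 0, which
    keeps ``C`` comparable across networks with leaves.
    """
    return float(local_clustering(net, variant).mean())


def shortest_path_matrix(net: WeightedNetwork, weighted: bool = True) -> np.ndarray:
    """All-pairs shortest-path distance matrix.

    Weighted mode assigns each edge the traversal cost ``d_ij = 1/w_ij`` and
    returns minimal path costs (Dijkstra); binary mode returns minimal hop
    counts.  The diagonal is 0 and unreachable pairs are ``inf``.
    """
    w = net.weights
    if weighted:
        cost = np.zeros_like(w)
        mask = w > 0
        cost[mask] = 1.0 / w[mask]
        graph = csr_matrix(cost)
        return shortest_path(graph, method="D", directed=False)
    graph = csr_matrix((w > 0).astype(np.int8))
    return shortest_path(graph, method="D", directed=False, unweighted=True)


def char_path_length(net: WeightedNetwork, weighted: bool = True) -> PathStats:
    """Characteristic path length ``L``: mean distance over reachable pairs.

    ``L`` averages ``d_ij`` over ordered pairs ``i != j`` with a finite
    distance; unreachable pairs are excluded from the mean and reported in
    ``n_unreachable_pairs`` so callers can decide how strict to be.

    Raises
    ------
    DegenerateNetworkError
        If no off-diagonal distance is finite.
    """
    d = shortest_path_matrix(net, weighted=weighted)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise DegenerateNetworkError("no finite path between any pair of nodes")
    return PathStats(
        char_path_length=float(d[finite].mean()),
        n_unreachable_pairs=n_unreachable,
    )
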