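"""Canonical network representation and elementary graph quantities.

Every statistic in this package operates on a :class:`WeightedNetwork`: an
undirected graph carried as a dense symmetric matrix of nonnegative edge
weights with a zero diagonal.  Brain networks analysed with these tools are
small (tens to ~1000 nodes), so a dense representation is both simpler and
faster than a sparse one; sparsity is treated as an optimisation concern,
never a semantic one.

An entry is an edge iff its weight is strictly positive — no epsilon
thresholding is applied, weights read from files are taken at face value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "DensityReport",
    "NetworkError",
    "ShapeError",
    "SymmetryError",
    "DegenerateNetworkError",
    "make_network",
    "symmetrize_upper",
    "density",
    "max_normalize",
]


class NetworkError(ValueError):
    """Base class for invalid network construction or use."""


class ShapeError(NetworkError):
    """Input matrix is not square (or not 2-D)."""


class SymmetryError(NetworkError):
    """Input matrix is asymmetric and no symmetrization policy was requested."""


class DegenerateNetworkError(NetworkError):
    """Network has no edges (or no finite paths where some are required)."""


@dataclass(frozen=True)
class WeightedNetwork:
    """An undirected, nonnegatively weighted network.

    Attributes
    ----------
    weights
        Dense ``(n, n)`` float array; symmetric, zero diagonal, entries >= 0.
        An edge exists between ``i`` and ``j`` iff ``weights[i, j] > 0``.
    """

    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def is_binary(self) -> bool:
        """True iff every nonzero weight equals 1 exactly."""
        nz = self.weights[self.weights > 0]
        return bool(np.all(nz == 1.0))

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def degrees(self) -> np.ndarray:
        """Binary degree k_i of every node."""
        return np.count_nonzero(self.weights, axis=1)

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths s_i = sum_j w_ij."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(i, j, w)`` arrays over undirected edges with ``i < j``."""
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        return iu, ju, self.weights[iu, ju]

    def binarized(self) -> "WeightedNetwork":
        """Topology-preserving binary copy (all edge weights set to 1)."""
        return WeightedNetwork((self.weights > 0).astype(float))


@dataclass(frozen=True)
class DensityReport:
    """Binary and weighted edge densities of a network.

    ``binary_density`` is the realized fraction of the ``n(n-1)/2`` possible
    undirected edges; ``weighted_density`` is the sum of edge weights over the
    same denominator.  For binary networks the two coincide; whenever all
    weights are <= 1, ``weighted_density <= binary_density``.
    """

    binary_density: float
    weighted_density: float


def _check_square(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {m.shape}")
    return m


def make_network(
    matrix,
    *,
    atol: float = 0.0,
    allow_degenerate: bool = False,
) -> WeightedNetwork:
    """Validate a square matrix and wrap it as a :class:`WeightedNetwork`.

    The matrix must be symmetric (within ``atol``; exact by default), finite
    and nonnegative.  Self-loops (diagonal entries) are stripped silently with
    a log warning, since none of the network models here admit them.  For
    asymmetric input with an explicit symmetrization policy, use
    :func:`symmetrize_upper` instead.

    Raises
    ------
    ShapeError
        Non-square input.
    NetworkError
        Non-finite or negative entries.
    SymmetryError
        Asymmetry beyond ``atol``.
    DegenerateNetworkError
        No edges at all (unless ``allow_degenerate``).
    """
    m = _check_square(matrix)
    if not np.all(np.isfinite(m)):
        raise NetworkError("adjacency matrix contains non-finite entries")
    if np.any(m < 0):
        raise NetworkError("adjacency matrix contains negative weights")
    if not np.allclose(m, m.T, rtol=0.0, atol=atol):
        raise SymmetryError(
            "adjacency matrix is asymmetric; use symmetrize_upper() to apply "
            "an explicit symmetrization policy"
        )
    w = (m + m.T) / 2.0 if atol > 0 else m.copy()
    # exact symmetry guaranteed from here on
    w = np.triu(w, k=1)
    w = w + w.T
    if np.any(np.diagonal(m) != 0):
        logger.warning("self-loops on the diagonal were stripped")
    if not allow_degenerate and not np.any(w > 0):
        raise DegenerateNetworkError("network has no edges")
    w.setflags(write=False)
    return WeightedNetwork(w)


def symmetrize_upper(matrix) -> WeightedNetwork:
    """Build an undirected network from the strict upper triangle of a matrix.

    ``weights[i, j] = weights[j, i] = matrix[i, j]`` for ``i < j``; the lower
    triangle of the input is discarded.  This is the symmetrization policy
    used for the directed hierarchical/modular benchmark matrices.
    """
    m = _check_square(matrix)
    if np.any(m < 0):
        raise NetworkError("adjacency matrix contains negative weights")
    upper = np.triu(m, k=1)
    return make_network(upper + upper.T, allow_degenerate=True)


def density(net: WeightedNetwork) -> DensityReport:
    """Binary and weighted density of a network (n_nodes >= 2)."""
    n = net.n_nodes
    if n < 2:
        raise NetworkError("density requires at least two nodes")
    n_pairs = n * (n - 1) / 2.0
    upper = np.triu(net.weights, k=1)
    return DensityReport(
        binary_density=float(np.count_nonzero(upper) / n_pairs),
        weighted_density=float(upper.sum() / n_pairs),
    )


def max_normalize(net: WeightedNetwork) -> WeightedNetwork:
    """Rescale weights into [0, 1] by dividing by the maximum weight.

    Optional preprocessing for observed matrices whose weights live on an
    arbitrary scale; never applied implicitly by any statistic here.
    """
    wmax = net.weights.max()
    if wmax <= 0:
        raise DegenerateNetworkError("cannot normalize a network with no edges")
    return WeightedNetwork(net.weights / wmax)
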