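"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive: clustering by explicit triple enumeration and
shortest paths by Floyd–Warshall over the cost matrix, written without any
of the package's own code paths (and without scipy's graph routines, which
the implementation uses).
"""

import itertools
import math

import numpy as np


def brute_local_clustering(w: np.ndarray, variant: str) -> np.ndarray:
    """Per-node clustering by explicit enumeration of ordered triples."""
    n = w.shape[0]
    a = (w > 0).astype(float)
    wmax = w.max() if w.max() > 0 else 1.0
    wh = w / wmax
    c = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        s = w[i].sum()
        num = 0.0
        for j, h in itertools.permutations(range(n), 2):
            if j == i or h == i:
                continue
            if variant == "binary":
                num += a[i, j] * a[j, h] * a[h, i]
            elif variant == "onnela":
                num += (wh[i, j] * wh[j, h] * wh[h, i]) ** (1.0 / 3.0)
            elif variant == "barrat":
                num += ((w[i, j] + w[i, h]) / 2.0) * a[i, j] * a[i, h] * a[j, h]
            elif variant == "zhang":
                num += wh[i, j] * wh[j, h] * wh[h, i]
            else:
                raise ValueError(variant)
        if variant in ("binary", "onnela"):
            den = k * (k - 1)
        elif variant == "barrat":
            den = s * (k - 1)
        else:
            den = wh[i].sum() ** 2 - (wh[i] ** 2).sum()
        c[i] = num / den if den > 0 else 0.0
    return c


def brute_shortest_paths(w: np.ndarray, weighted: bool) -> np.ndarray:
    """All-pairs shortest paths via Floyd–Warshall on the cost matrix."""
    n = w.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_char_path_length(w: np.ndarray, weighted: bool) -> float:
    d = brute_shortest_paths(w, weighted)
    vals = [
        d[i, j]
        for i in range(len(w))
        for j in range(len(w))
        if i != j and math.isfinite(d[i, j])
    ]
    return sum(vals) / len(vals)


def random_symmetric_weights(n: int, p_edge: float, rng: np.random.Generator,
                             binary: bool = False) -> np.ndarray:
    """Random symmetric nonnegative test matrix with zero diagonal."""
    upper = np.triu((rng.random((n, n)) < p_edge).astype(float), k=1)
    if not binary:
        upper *= rng.uniform(0.1, 2.0, size=(n, n))
    w = upper + upper.T
    return w
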