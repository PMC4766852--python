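"""Ensemble experiment runners for the Watts–Strogatz transition and the
benchmark families.

The WS sweep reproduces the canonical small-world transition curve: for each
rewiring probability on a (log-spaced) grid, an ensemble of networks is
generated and the mean φ, δ, Δ_C, Δ_L and σ are computed against the
family's theoretical anchors — the lattice endpoint supplies C_latt and
L_latt (p = 0 is deterministic) and a p = 1 ensemble supplies C_rand and
L_rand.  Per-replicate seeds are derived from the master seed with
``numpy.random.SeedSequence``, so every sweep is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import generators, metrics
from .swp_stats import (
    compute_deviations,
    contribution_to_deviation,
    small_world_index,
    small_world_propensity,
)

__all__ = ["WSAnchors", "ws_anchors", "ws_phi_curve", "ws_peak", "default_p_grid"]


@dataclass(frozen=True)
class WSAnchors:
    """Theoretical null anchors of a Watts–Strogatz family.

    C_latt and L_latt come from the p = 0 lattice (deterministic); C_rand
    and L_rand are ensemble means over fully rewired (p = 1) networks.
    """

    c_latt: float
    c_rand: float
    l_latt: float
    l_rand: float


def default_p_grid(n_points: int = 13) -> np.ndarray:
    """Log-spaced rewiring-probability grid over [1e-4, 1]."""
    return np.logspace(-4, 0, n_points)


def _make_net(n_nodes, radius, p, seed, weighted):
    if weighted:
        return generators.generate_weighted_ws(n_nodes, radius, p, seed)
    lattice = generators.generate_ring_lattice(n_nodes, radius)
    return generators.rewire(lattice, p, seed)


def ws_anchors(
    n_nodes: int,
    radius: int,
    n_seeds: int,
    master_seed: int = 0,
    weighted: bool = False,
    clustering_variant: str = "onnela",
) -> WSAnchors:
    """Compute the C/L anchors for a WS family (binary or weighted)."""
    variant = clustering_variant if weighted else "binary"
    if weighted:
        lattice = generators.generate_weighted_lattice(n_nodes, radius)
    else:
        lattice = generators.generate_ring_lattice(n_nodes, radius)
    c_latt = metrics.clustering_coefficient(lattice, variant)
    l_latt = metrics.char_path_length(lattice, weighted).char_path_length
    seeds = np.random.SeedSequence(master_seed).spawn(n_seeds)
    c_rand, l_rand = [], []
    for s in seeds:
        rnd = generators.rewire(lattice, 1.0, s)
        c_rand.append(metrics.clustering_coefficient(rnd, variant))
        l_rand.append(metrics.char_path_length(rnd, weighted).char_path_length)
    return WSAnchors(c_latt, float(np.mean(c_rand)), l_latt, float(np.mean(l_rand)))


def ws_phi_curve(
    n_nodes: int = 1000,
    radius: int = 5,
    p_grid: np.ndarray | None = None,
    n_seeds: int = 50,
    master_seed: int = 0,
    weighted: bool = False,
    clustering_variant: str = "onnela",
) -> pd.DataFrame:
    """Ensemble-mean small-world transition curve over a p grid.

    Returns a DataFrame with one row per grid probability and columns
    ``p, phi_mean, phi_sem, delta_mean, delta_c, delta_l, sigma, c_mean,
    l_mean`` (deviation and σ columns are ensemble means; sem is the
    standard error over seeds).
    """
    if p_grid is None:
        p_grid = default_p_grid()
    variant = clustering_variant if weighted else "binary"
    anchors = ws_anchors(
        n_nodes, radius, n_seeds, master_seed, weighted, clustering_variant
    )
    rows = []
    for gi, p in enumerate(p_grid):
        seeds = np.random.SeedSequence((master_seed, gi)).spawn(n_seeds)
        phis, deltas, dcs, dls, sigmas, cs, ls = [], [], [], [], [], [], []
        for s in seeds:
            net = _make_net(n_nodes, radius, float(p), s, weighted)
            c = metrics.clustering_coefficient(net, variant)
            l = metrics.char_path_length(net, weighted).char_path_length
            dev = compute_deviations(
                c, l, anchors.c_latt, anchors.c_rand, anchors.l_latt, anchors.l_rand
            )
            phis.append(small_world_propensity(dev))
            deltas.append(contribution_to_deviation(dev)[0])
            dcs.append(dev.delta_c)
            dls.append(dev.delta_l)
            sigmas.append(small_world_index(c, anchors.c_rand, l, anchors.l_rand))
            cs.append(c)
            ls.append(l)
        rows.append(
            {
                "p": float(p),
                "phi_mean": float(np.mean(phis)),
                "phi_sem": float(np.std(phis, ddof=1) / np.sqrt(len(phis)))
                if len(phis) > 1
                else 0.0,
                "delta_mean": float(np.mean(deltas)),
                "delta_c": float(np.mean(dcs)),
                "delta_l": float(np.mean(dls)),
                "sigma": float(np.mean(sigmas)),
                "c_mean": float(np.mean(cs)),
                "l_mean": float(np.mean(ls)),
            }
        )
    return pd.DataFrame(rows)


def ws_peak(curve: pd.DataFrame) -> tuple[float, float]:
    """Grid probability and value of the maximal ensemble-mean φ."""
    idx = int(curve["phi_mean"].idxmax())
    return float(curve.loc[idx, "p"]), float(curve.loc[idx, "phi_mean"])
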