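# Methods

## The model and its statistics

A network is an undirected graph on `n` nodes carried as a dense symmetric
matrix `W` of nonnegative weights with zero diagonal; an edge exists iff
`w_ij > 0` (no epsilon thresholding). Self-loops are stripped at
construction. The framework assumes nonnegative weights; signed functional
networks must be transformed before use.

**Clustering.** The network coefficient `C` is the plain mean of per-node
local coefficients `c_i`, including degree-<2 nodes as 0 so that `C` stays
comparable across networks with leaves. Four local variants are provided:

* binary — fraction of connected neighbour pairs;
* Onnela — `c_i = (1/(k_i(k_i−1))) Σ_{j,h} (ŵ_ij ŵ_jh ŵ_hi)^{1/3}`;
* Barrat — `c_i = (1/(s_i(k_i−1))) Σ_{j,h} ((w_ij+w_ih)/2) a_ij a_ih a_jh`;
* Zhang — `c_i = Σ_{j,h} ŵ_ij ŵ_jh ŵ_hi / ((Σ_j ŵ_ij)² − Σ_j ŵ_ij²)`,

with `ŵ = w / max(W)` taken over the matrix under evaluation, so every
network is normalised in isolation. All weighted variants reduce exactly to
the binary coefficient on binary input (asserted in tests), and Onnela is
the default everywhere. Triangle sums are computed as `diag(M³)` via two
dense matrix products; the implementation is validated against exhaustive
triple enumeration on networks of up to 8 nodes at 1e−12.

**Path length.** Edge traversal cost is `d_ij = 1/w_ij` (hop count in
binary mode); all-pairs distances come from Dijkstra
(`scipy.sparse.csgraph`). `L` averages distances over ordered pairs with a
finite distance — for symmetric networks ordered and unordered averaging
coincide. Disconnected pairs are excluded from the mean and reported in
`n_unreachable_pairs`; a network with no finite path at all raises. This
finite-pairs policy keeps null-model comparisons well-defined for
fragmented observed networks while leaving the strictness decision to the
caller.

**Deviations, φ, δ.** `Δ_C = (C_latt − C_obs)/(C_latt − C_rand)` and
`Δ_L = (L_obs − L_rand)/(L_latt − L_rand)`, each clamped to [0, 1] with the
raw values and a clamp flag retained (real networks can out-cluster their
lattice null or out-shorten their random null); clamping is what bounds
`φ = 1 − sqrt((Δ_C² + Δ_L²)/2)` in [0, 1]. `δ = 4θ/π − 1` with
`θ = arctan(Δ_L/Δ_C)` (θ = π/2 when Δ_C = 0). At the origin both
deviations vanish, the angle is undefined, and δ is set to 0 by the
symmetry of equal contribution, with a degeneracy flag. Degenerate
normalisation ranges (`C_latt = C_rand` or `L_latt = L_rand`) raise rather
than divide by zero. The sign convention ties δ = +1 to a purely
path-length-driven deficit; only the sign, never |δ|, depends on this
choice. φ_T defaults to 0.6 and σ_T to 1; both are overridable.

## Generators

**Ring lattices.** `N` nodes on a 1-D ring with unit spacing, every node
linked to all neighbours within radius `r` (requires `N > 2r`); edge count
is exactly `N·r`. The weighted lattice assigns edge weights by ring
distance with the default rule `w(d) = (D_max − d)/D_max`, where
`D_max = r + ε` is the largest distance spanned by an edge plus one unit of
lattice spacing (`ε = 1`). The ε margin keeps the farthest edge strictly
positive; the rule is strictly decreasing and dimensionless, and any other
strictly decreasing positive rule can be passed as `weight_fn`. For data on
a measured lattice, ε would be the measurement precision.

**Rewiring.** Each undirected edge `(i, j)` with `i < j`, visited in fixed
order, is independently selected with probability `p`; a selected edge is
detached at `j` and reattached to a uniform draw among nodes that are not
`i`, not `j`, and not already neighbours of `i`, carrying its weight
unchanged. Collisions are excluded by construction; if a node's
neighbourhood is saturated the edge stays in place with a log warning.
Edge count, total weight and the exact weight multiset are invariants for
every `p` and seed (property-tested).

**Hierarchical modular networks (HN).** `2^mx_lv` nodes in aligned
power-of-two blocks. Base modules of size `2^sz_cl` are fully connected
with weight 1; a directed connection between nodes whose lowest common
block sits `m ≥ 1` levels above the base is placed with probability `2^−m`
and carries weight equal to that probability. The level of a pair is
`max(0, bit_length(i XOR j) − sz_cl)`. The directed matrix is symmetrized
by keeping its strict upper triangle. The probability indexing is anchored
so the base has p = 1 and the first cross level p = 1/2 — the anchoring
that reproduces the families' published densities analytically (expected
weighted/binary densities 4.5/10.9, 9.1/18.7 and 17.9/31.2 % for
`sz_cl` = 5, 6, 7 at `mx_lv` = 10).

**Modular networks (MN).** 16 fully connected 64-node modules (weight 1)
account for 64512 within-module directed edges; the remaining
`K − 64512` directed edges are sampled uniformly without replacement from
the inter-module slots with weight 0.5, then the matrix is symmetrized by
its upper triangle (in expectation half the inter-module edges survive).
The within-module undirected edge count, `16·C(64,2) = 32256`, is exact.

## Null models

Both weighted nulls conserve node count, edge count and the exact
edge-weight multiset.

* **Lattice null** — observed weights ranked in decreasing order fill ring
  distance shells in increasing distance order (shell `d` holds `N` pairs
  for `d < N/2`, `N/2` at `d = N/2`); slots within a shell, and runs of
  equal weights, are assigned randomly under the seed, making the
  construction bitwise reproducible yet unbiased. Real networks carry no
  canonical 1-D layout; the default identity ring ordering is justified
  because placement depends only on the distance shell, not node identity.
  User-supplied orderings or full distance matrices (e.g. Euclidean
  distances between regions) are accepted via `LatticeSpec`.
* **Random null** — the weights land on pairs drawn uniformly without
  replacement from all `n(n−1)/2` slots.
* **Degree-preserving null** (binary) — `Q·E` double-edge-swap *attempts*
  with `Q = 10`; the degree sequence is an exact invariant, and degenerate
  sequences (a star) that admit no swap return the input unchanged.

The weighted pipeline defaults to the weight-shuffling random null and the
binary pipeline to the degree-preserving one — each matching the practice
its literature expects — and a config switch overrides either.
`null_reference_stats` averages C and L over `n_realizations` independent
draws of each null (default 10) and reports standard errors. For generated
Watts–Strogatz families the sweep runner instead uses the family's
theoretical anchors — `C_latt, L_latt` from the deterministic p = 0
lattice and `C_rand, L_rand` from a p = 1 ensemble — which is both cheaper
and closer to the model's definition of the transition.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; ensembles derive
per-replicate seeds from a master seed through `numpy.random.SeedSequence`,
so configuration plus master seed reproduce any result exactly (reports are
byte-identical across runs). The transition experiments use the study
conditions N = 1000, r = 5 with 50 seeds per grid point on a 13-point
log-spaced grid over [1e−4, 1]; benchmark densities average 10 seeds. The
test suite exercises the same conditions, except that benchmark SWP
classification uses 3 null realizations per model and the density-robustness
comparison (r = 5 vs r = 33) uses 5 seeds on an 8-point grid — both
qualitative orderings that are insensitive to ensemble size.

## What the synthetic families do and do not emulate

The weighted-lattice model encodes the empirical regularity that spatially
embedded brain networks link nearby nodes more strongly than distant ones;
the HN/MN families contrast clustered-but-long against clustered-and-short
weighted architectures. None of them reproduce degree heterogeneity,
hemispheric symmetry, measurement noise or the negative correlations of
functional connectivity, so passing benchmarks demonstrates that the
statistic orders architectures correctly — not that any particular observed
connectome will score high or low. Matrices whose weights live on an
arbitrary scale can be max-normalised into [0, 1] via an explicit
preprocessing call; no statistic rescales implicitly (Onnela/Zhang
clustering are scale-invariant by construction, weighted path lengths scale
as 1/λ under `W → λW`).

## Known limitations

Directed networks, multigraphs and signed weights are out of scope. The
lattice null's statistics depend (weakly) on the assumed node layout; for
strongly non-ring geometries supply a distance matrix. δ is reported even
when φ is low, where the angle is dominated by whichever deviation was
clamped. Dense matrices bound practical size to a few thousand nodes.
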