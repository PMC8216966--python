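"""Minimum spanning trees, the raw FEE0 statistic, and abundance adjustment.

The raw functional extension-and-evenness statistic of a community is
computed from the minimum spanning tree (MST) of its points in trait
space.  Writing ``l`` for the vector of the n-1 MST branch lengths and
``lbar`` for their mean,

    FEE0 = sum_i min(l_i, lbar)
         = sum(l) * sum_i min(l_i / sum(l), 1 / (n - 1))

so FEE0 factorizes into total MST length (extension) times a branch
evenness term in (0, 1] that equals 1 exactly when all branches are equal.

Abundance is brought in by shrinking pairwise distances for abundant,
evenly-matched species pairs before the MST is recomputed:

    dist_a = min(K1 * K2, 1) * dist
    K1 = (2 / n) / (w_i + w_j)          # summed-abundance coefficient
    K2 = 2 k / (k + 1),  k = max(w_i, w_j) / min(w_i, w_j)

The cap at 1 guarantees an adjusted distance never exceeds the raw one,
and equal abundances (all w_i = 1/n) leave every distance unchanged.
Each pair is adjusted independently: the adjusted matrix may be
non-metric, which is fine because the MST needs only a complete symmetric
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .traitspace import Community, DistanceMatrix, relative_abundances

__all__ = [
    "MinimumSpanningTree",
    "compute_mst",
    "mst_branch_lengths",
    "fee0",
    "evenness_component",
    "adjust_distances",
    "fee0_for_community",
]


@dataclass(frozen=True)
class MinimumSpanningTree:
    """An MST over a community's points: n-1 edges and their lengths.

    ``branch_lengths`` is sorted ascending for deterministic output;
    ``edges`` are (label_i, label_j, length) triples.
    """

    edges: tuple
    branch_lengths: np.ndarray
    total_length: float

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)


def _prim(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prim's algorithm on a dense symmetric matrix.

    Returns (lengths, i, j) in discovery order.  Ties are broken by the
    first minimum in index order, so the result is deterministic.
    Zero-length edges (coincident species) are ordinary edges.
    """
    n = values.shape[0]
    mind = values[0].copy()
    mind[0] = np.inf
    parent = np.zeros(n, dtype=int)
    visited = np.zeros(n, dtype=bool)
    visited[0] = True
    lengths = np.empty(n - 1)
    ii = np.empty(n - 1, dtype=int)
    jj = np.empty(n - 1, dtype=int)
    for k in range(n - 1):
        j = int(np.argmin(mind))
        lengths[k] = mind[j]
        ii[k] = parent[j]
        jj[k] = j
        visited[j] = True
        closer = values[j] < mind
        parent[closer] = j
        np.minimum(mind, values[j], out=mind)
        mind[visited] = np.inf
    return lengths, ii, jj


def compute_mst(d: DistanceMatrix) -> MinimumSpanningTree:
    """Minimum spanning tree of a distance matrix.

    Total length is the global minimum over all spanning trees (verified
    against exhaustive enumeration in the test suite for small n).  When
    tied distances admit several MSTs the algorithm's index-order
    tie-break picks one deterministically; the total length is unaffected
    by the choice.
    """
    if d.n < 2:
        raise ValueError("MST undefined below two species")
    lengths, ii, jj = _prim(d.values)
    order = np.argsort(lengths, kind="stable")
    edges = tuple(
        (d.labels[ii[k]], d.labels[jj[k]], float(lengths[k])) for k in order
    )
    return MinimumSpanningTree(
        edges=edges,
        branch_lengths=lengths[order],
        total_length=float(lengths.sum()),
    )


def mst_branch_lengths(values: np.ndarray) -> np.ndarray:
    """Branch lengths only (unsorted), for hot loops."""
    if values.shape[0] == 2:
        return values[0, 1:2].copy()
    return _prim(values)[0]


def fee0(l: np.ndarray) -> float:
    """Raw extension-and-evenness statistic sum_i min(l_i, mean(l)).

    Bounded above by sum(l), with equality exactly when all branches are
    equal — the most even partition of a given total MST length.
    """
    l = np.asarray(l, dtype=float)
    if l.size == 0:
        raise ValueError(
            "empty branch-length vector: single-species communities have "
            "no MST and no FEE0"
        )
    if (l < 0).any():
        raise ValueError("branch lengths must be nonnegative")
    return float(np.minimum(l, l.mean()).sum())


def evenness_component(l: np.ndarray) -> float:
    """Branch-evenness factor sum_i min(l_i/sum(l), 1/(n-1)), in (0, 1].

    Equals 1 iff all branches are equal.  A degenerate all-coincident
    community (sum(l) = 0) returns 1 by convention, the limit of equal
    branches; FEE0 is 0 regardless so the convention is inert.
    """
    l = np.asarray(l, dtype=float)
    if l.size == 0:
        raise ValueError("empty branch-length vector")
    if (l < 0).any():
        raise ValueError("branch lengths must be nonnegative")
    total = l.sum()
    if total == 0:
        return 1.0
    return float(np.minimum(l / total, 1.0 / l.size).sum())


def adjustment_factors(w: np.ndarray, n: int) -> np.ndarray:
    """Pairwise multipliers min(K1*K2, 1) for abundance adjustment.

    ``w`` must be relative abundances summing to 1.  The diagonal is set
    to 1 (self-distances are zero anyway).  Pairs with a zero weight get
    the k -> infinity limit K2 = 2.
    """
    w = np.asarray(w, dtype=float)
    s = w[:, None] + w[None, :]
    hi = np.maximum(w[:, None], w[None, :])
    lo = np.minimum(w[:, None], w[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        K1 = (2.0 / n) / s
        k = hi / lo
        K2 = 2.0 * k / (k + 1.0)
    K2 = np.where(np.isfinite(K2), K2, 2.0)  # k -> inf limit
    factor = np.minimum(K1 * K2, 1.0)
    np.fill_diagonal(factor, 1.0)
    return factor


def adjust_distances(d: DistanceMatrix, w: np.ndarray) -> DistanceMatrix:
    """Abundance-adjusted distance matrix dist_a = min(K1*K2, 1) * dist.

    Never increases any distance; leaves the matrix unchanged when all
    relative abundances equal 1/n.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (d.n,):
        raise ValueError("weight vector length must match distance matrix")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be relative abundances summing to 1")
    factor = adjustment_factors(w, d.n)
    return DistanceMatrix(
        labels=d.labels, values=factor * d.values, metric_tag="adjusted"
    )


def _drop_zero_abundance(c: Community) -> tuple[np.ndarray, np.ndarray]:
    """Points and weights of the positively-abundant members.

    A species with zero individuals is absent, and the abundance-ratio
    coefficient is undefined at w = 0, so such members are dropped with a
    warning before any abundance-weighted computation.
    """
    pts = c.points
    if c.abundances is None:
        return pts, np.full(c.n, 1.0 / c.n)
    keep = c.abundances > 0
    if not keep.all():
        dropped = [m for m, k in zip(c.members, keep) if not k]
        warnings.warn(
            f"community {c.community_id!r}: dropping zero-abundance "
            f"species {dropped} before abundance-weighted computation",
            stacklevel=3,
        )
    return pts[keep], relative_abundances(c.abundances[keep])


def fee0_for_community(
    c: Community, abundance_weighted: bool = False
) -> tuple[float, MinimumSpanningTree]:
    """FEE0 and the MST it was computed from.

    In abundance-weighted mode the MST is recomputed on the adjusted
    distances and FEE0 is taken over the adjusted branch lengths; with
    equal abundances (or presence-absence data) this is identical to the
    raw computation.
    """
    if abundance_weighted:
        pts, w = _drop_zero_abundance(c)
        labels = tuple(
            m
            for m, a in zip(
                c.members,
                c.abundances if c.abundances is not None else [1] * c.n,
            )
            if a > 0
        )
    else:
        pts, w = c.points, None
        labels = c.members
    if pts.shape[0] < 2:
        raise ValueError(
            f"community {c.community_id!r}: FEE0 requires at least two "
            "species with positive abundance"
        )
    values = squareform(pdist(pts))
    if abundance_weighted:
        values = adjustment_factors(w, pts.shape[0]) * values
    d = DistanceMatrix(
        labels=labels,
        values=values,
        metric_tag="adjusted" if abundance_weighted else "raw",
    )
    mst = compute_mst(d)
    return fee0(mst.branch_lengths), mst
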