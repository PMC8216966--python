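"""Reference distance-based functional diversity indices.

Implementations of the five indices commonly used as comparison points
for MST-based diversity statistics: convex-hull functional richness
(FRic), MST-based functional evenness (FEve, Villeger et al. 2008),
functional divergence (FDiv, Villeger et al. 2008), functional
dispersion (FDis, Laliberte & Legendre 2010), and Rao's quadratic
entropy.

Several of these are undefined for particular inputs (FRic needs more
species than trait dimensions, FEve needs n >= 3, FDiv needs M >= 2).
Those preconditions raise :class:`UndefinedIndexError`, which batch
drivers convert to missing values with recorded reasons rather than
aborting a whole analysis.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .mst_fee import _prim

__all__ = [
    "UndefinedIndexError",
    "fric",
    "feve",
    "fdiv",
    "fdis",
    "rao_q",
]


class UndefinedIndexError(ValueError):
    """An index's preconditions are not met; carries the reason."""


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    return pts


def _weights(points: np.ndarray, w) -> np.ndarray:
    n = points.shape[0]
    if w is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weight vector length must match point count")
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def fric(points: np.ndarray) -> float:
    """Functional richness: volume of the convex hull of the points.

    In one dimension this is the trait range; in two, the hull area.
    Undefined when n <= M or when the points are affinely degenerate
    (e.g., collinear in 2-D), since the hull then has zero M-volume.
    """
    pts = _as_points(points)
    n, M = pts.shape
    if n <= M:
        raise UndefinedIndexError(
            f"FRic undefined: richness {n} must exceed trait dimension {M}"
        )
    if M == 1:
        return float(np.ptp(pts[:, 0]))
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        raise UndefinedIndexError(
            "FRic undefined: degenerate (affinely dependent) configuration"
        ) from None


def feve(points: np.ndarray, w=None) -> float:
    """Functional evenness on the MST (partial weighted evenness).

    Each MST branch b = (i, j) gets weighted evenness
    EW_b = dist(i, j) / (w_i + w_j); the partial weighted evenness
    PEW_b = EW_b / sum(EW) is compared to the perfectly even value
    1/(n-1):

        FEve = (sum_b min(PEW_b, 1/(n-1)) - 1/(n-1)) / (1 - 1/(n-1))

    Equals 1 for equal abundances on an equal-branch MST; needs n >= 3.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 3:
        raise UndefinedIndexError(
            f"FEve undefined: needs at least three species, got {n}"
        )
    w = _weights(pts, w)
    diff = pts[:, None, :] - pts[None, :, :]
    dmat = np.sqrt((diff * diff).sum(-1))
    lengths, ii, jj = _prim(dmat)
    ew = lengths / (w[ii] + w[jj])
    total = ew.sum()
    if total == 0:
        raise UndefinedIndexError(
            "FEve undefined: all species coincide in trait space"
        )
    pew = ew / total
    even = 1.0 / (n - 1)
    return float((np.minimum(pew, even).sum() - even) / (1.0 - even))


def fdiv(points: np.ndarray, w=None) -> float:
    """Functional divergence: abundance-weighted deviation from the
    hull-vertex centre of gravity.

    With G the unweighted centroid of the convex-hull vertices,
    dG_i = ||p_i - G||, and dGbar the unweighted mean of the dG_i:

        FDiv = (sum_i w_i (dG_i - dGbar) + dGbar)
             / (sum_i w_i |dG_i - dGbar| + dGbar)

    Bounded in [0, 1].  Undefined for one-dimensional trait spaces
    (no hull) and for degenerate configurations.
    """
    pts = _as_points(points)
    n, M = pts.shape
    if M < 2:
        raise UndefinedIndexError(
            "FDiv undefined: not available for the one-trait case"
        )
    if n <= M:
        raise UndefinedIndexError(
            f"FDiv undefined: richness {n} must exceed trait dimension {M}"
        )
    w = _weights(pts, w)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        raise UndefinedIndexError(
            "FDiv undefined: degenerate (affinely dependent) configuration"
        ) from None
    G = pts[hull.vertices].mean(axis=0)
    dG = np.linalg.norm(pts - G, axis=1)
    dGbar = dG.mean()
    dev = dG - dGbar
    denom = float(w @ np.abs(dev)) + dGbar
    if denom == 0:
        raise UndefinedIndexError(
            "FDiv undefined: all species coincide in trait space"
        )
    return float((w @ dev + dGbar) / denom)


def fdis(points: np.ndarray, w=None) -> float:
    """Functional dispersion: weighted mean distance to the weighted
    centroid, sum_i w_i ||p_i - c|| with c = sum_i w_i p_i.

    Zero exactly when all positively-weighted points coincide.
    """
    pts = _as_points(points)
    if pts.shape[0] < 2:
        raise UndefinedIndexError("FDis undefined below two species")
    w = _weights(pts, w)
    c = w @ pts
    return float(w @ np.linalg.norm(pts - c, axis=1))


def rao_q(d: np.ndarray, w=None) -> float:
    """Rao's quadratic entropy Q = sum_ij w_i w_j d_ij^2 / 2.

    ``d`` is a symmetric pairwise trait-distance matrix.  The squared
    half-distance convention is the one the widely used FD/ade4 R
    implementations compute (``divc``), which is what published index
    comparisons are based on; with ultrametric dissimilarities it
    reduces to the classical mean pairwise dissimilarity.  Zero exactly
    when every pair with positive weight sits at distance zero.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("Rao's Q needs a square distance matrix")
    n = d.shape[0]
    if n < 2:
        raise UndefinedIndexError("Rao's Q undefined below two species")
    if w is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != (n,):
            raise ValueError("weight vector length must match matrix size")
    return float(w @ (d * d) @ w) / 2.0
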