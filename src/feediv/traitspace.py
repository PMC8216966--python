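"""Species pools and communities in a unit-hypercube trait space.

A species pool of ``N`` species measured for ``M`` continuous traits is
represented as ``N`` points in the ``M``-dimensional unit hypercube after
per-trait min-max normalization.  The pool fixes the normalization bounds
for every community in an analysis, so that all communities share one
frame of reference.  A community is a subset of the pool's species,
optionally with abundances; presence-absence data are equivalent to equal
abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpeciesPool",
    "Community",
    "DistanceMatrix",
    "normalize_traits",
    "relative_abundances",
    "euclidean_distances",
]


def normalize_traits(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize each trait column to [0, 1].

    Each raw value ``x`` maps to ``(x - min) / (max - min)`` using the
    column minimum and maximum.  A constant column (max == min) maps to
    all zeros with a warning: the species coincide in that dimension and
    zero is the honest geometric statement.

    Parameters
    ----------
    raw
        ``N x M`` array of raw trait values, all finite.

    Returns
    -------
    norm, bounds
        ``norm`` is ``N x M`` in [0, 1]; ``bounds`` is ``M x 2`` with the
        (min, max) used per column, needed to place later communities in
        the same frame.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] < 1:
        raise ValueError("need at least one species to normalize traits")
    if not np.isfinite(raw).all():
        bad = np.argwhere(~np.isfinite(raw))
        r, c = bad[0]
        raise ValueError(
            f"non-finite trait value at species row {r}, trait column {c}"
        )
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        cols = np.flatnonzero(constant)
        warnings.warn(
            f"trait column(s) {cols.tolist()} are constant; "
            "all values mapped to 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, span)
    norm = (raw - lo) / safe
    norm[:, constant] = 0.0
    return norm, np.column_stack([lo, hi])


def relative_abundances(A: Sequence[float]) -> np.ndarray:
    """Convert raw abundances to relative abundances w_i = A_i / sum(A)."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = A.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector: no individuals present")
    return A / total


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between a community's species.

    ``metric_tag`` records whether the values are raw trait-space
    distances or abundance-adjusted ones (the latter may be non-metric).
    """

    labels: tuple
    values: np.ndarray
    metric_tag: str = "raw"

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def euclidean_distances(points: np.ndarray, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between points in trait space.

    In an M-dimensional unit hypercube no distance can exceed sqrt(M).
    Duplicate points are allowed (distance zero).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("need at least two points for pairwise distances")
    if not np.isfinite(points).all():
        raise ValueError("points contain non-finite coordinates")
    if labels is None:
        labels = tuple(range(points.shape[0]))
    return DistanceMatrix(
        labels=tuple(labels),
        values=squareform(pdist(points)),
        metric_tag="raw",
    )


@dataclass
class SpeciesPool:
    """A pool of N species located in the M-dimensional unit hypercube.

    The pool defines the normalization bounds and (for empirical-pool
    null models) the sampling frame.  Construct with
    :meth:`from_raw_traits` to normalize raw measurements, or with
    :meth:`from_normalized` for traits already on the 0-1 scale.
    """

    species_ids: tuple
    raw_traits: np.ndarray
    norm_traits: np.ndarray
    bounds: np.ndarray

    def __post_init__(self):
        self.species_ids = tuple(str(s) for s in self.species_ids)
        if len(set(self.species_ids)) != len(self.species_ids):
            dupes = sorted(
                {s for s in self.species_ids if self.species_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate species ids in pool: {dupes}")
        self.raw_traits = np.atleast_2d(np.asarray(self.raw_traits, float))
        self.norm_traits = np.atleast_2d(np.asarray(self.norm_traits, float))
        if self.raw_traits.shape != self.norm_traits.shape:
            raise ValueError("raw and normalized trait shapes differ")
        if len(self.species_ids) != self.norm_traits.shape[0]:
            raise ValueError("species id count must match trait rows")
        if (self.norm_traits < 0).any() or (self.norm_traits > 1).any():
            raise ValueError("normalized traits must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.species_ids)}

    @classmethod
    def from_raw_traits(cls, species_ids, raw: np.ndarray) -> "SpeciesPool":
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        norm, bounds = normalize_traits(raw)
        return cls(tuple(species_ids), raw, norm, bounds)

    @classmethod
    def from_normalized(cls, species_ids, norm: np.ndarray) -> "SpeciesPool":
        """Wrap traits already in [0, 1]; bounds are taken as (0, 1)."""
        norm = np.atleast_2d(np.asarray(norm, dtype=float))
        bounds = np.tile([0.0, 1.0], (norm.shape[1], 1))
        return cls(tuple(species_ids), norm.copy(), norm, bounds)

    @property
    def N(self) -> int:
        return self.norm_traits.shape[0]

    @property
    def M(self) -> int:
        return self.norm_traits.shape[1]

    def indices_of(self, species: Sequence[str]) -> np.ndarray:
        missing = [s for s in species if s not in self._index]
        if missing:
            raise KeyError(
                f"species absent from pool: {missing}; communities may only "
                "contain pool species (bounds are never extended silently)"
            )
        return np.array([self._index[s] for s in species], dtype=int)


@dataclass
class Community:
    """A species subset of a pool, optionally with abundances.

    ``abundances`` absent means presence-absence data, treated as equal
    abundance 1/n throughout.  Index computation requires n >= 2.
    """

    pool: SpeciesPool
    members: tuple
    abundances: Optional[np.ndarray] = None
    community_id: str = "community"

    def __post_init__(self):
        self.members = tuple(str(s) for s in self.members)
        if len(set(self.members)) != len(self.members):
            raise ValueError(
                f"community {self.community_id!r} lists a species twice"
            )
        self._indices = self.pool.indices_of(self.members)
        if self.abundances is not None:
            A = np.asarray(self.abundances, dtype=float)
            if A.shape != (len(self.members),):
                raise ValueError(
                    f"community {self.community_id!r}: abundance vector "
                    "length must match member count"
                )
            if (A < 0).any():
                raise ValueError(
                    f"community {self.community_id!r}: negative abundance"
                )
            if np.count_nonzero(A) < 2:
                raise ValueError(
                    f"community {self.community_id!r}: need at least two "
                    "species with positive abundance"
                )
            self.abundances = A

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def points(self) -> np.ndarray:
        """Normalized trait coordinates of the member species (n x M)."""
        return self.pool.norm_traits[self._indices]

    def relative_abundances(self) -> np.ndarray:
        """w_i per member; equal weights 1/n for presence-absence data."""
        if self.abundances is None:
            return np.full(self.n, 1.0 / self.n)
        return relative_abundances(self.abundances)

    def distance_matrix(self) -> DistanceMatrix:
        return euclidean_distances(self.points, labels=self.members)
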