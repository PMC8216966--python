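"""Null distributions of FEE0 and the richness-independent FEE index.

FEE0 depends intrinsically on species richness n, so raw values are not
comparable across richness levels.  The FEE index removes that
dependence with a null model: generate Q random communities of the same
richness n in the same M-dimensional trait space, compute FEE0 for each,
and report the observed value's position in that empirical distribution,

    FEE = F_Q(X) = #{ x_i <= X } / Q

the right-continuous empirical CDF evaluated at the observed FEE0.  By
the probability-integral transform, communities assembled at random get
FEE values uniform on (0, 1] regardless of n; FEE near 1 means the
community is unusually extended/even relative to random assembly, FEE
near 0 unusually clustered.

Two null samplers are provided: ``uniform`` draws n points i.i.d. from
the uniform unit hypercube (the no-prior-knowledge default), and
``pool`` draws n species without replacement from an observed pool's
normalized trait rows.  Null communities are always equal-abundance;
the same curves serve the abundance-adjusted statistic because adjusted
branch lengths live on the same scale.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .mst_fee import fee0, mst_branch_lengths
from .traitspace import Community, SpeciesPool

__all__ = [
    "NullCDF",
    "CDFLibrary",
    "sample_null_fee0",
    "fee",
    "fee_for_community",
    "save_cdf_library",
    "load_cdf_library",
]

DEFAULT_Q = 10_000

_FORMAT_HEADER = "feediv-cdf-library\t1"


@dataclass(frozen=True)
class NullCDF:
    """Sorted FEE0 draws from the null model for one (n, M) pair."""

    n: int
    M: int
    Q: int
    seed: int
    sampling: str
    samples: np.ndarray

    def __post_init__(self):
        s = self.samples
        if len(s) != self.Q or self.Q < 1:
            raise ValueError("sample count must equal Q >= 1")
        if (np.diff(s) < 0).any():
            raise ValueError("samples must be sorted ascending")
        if (s < 0).any():
            raise ValueError("FEE0 draws must be nonnegative")


def _substream(seed: int, n: int, M: int, sampling: str) -> np.random.Generator:
    # independent, order-free substream per (n, M, sampling)
    key = (n, M, 0 if sampling == "uniform" else 1)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=key)
    )


def sample_null_fee0(
    n: int,
    M: int,
    Q: int = DEFAULT_Q,
    seed: int = 0,
    sampling: str = "uniform",
    pool: Optional[SpeciesPool] = None,
) -> NullCDF:
    """Build the empirical null distribution of FEE0 for richness n.

    Each of the Q null communities is n points either drawn i.i.d. from
    the M-dimensional uniform(0,1) distribution (``sampling="uniform"``)
    or drawn without replacement from ``pool``'s normalized trait rows
    (``sampling="pool"``).  FEE0 is always computed on raw (unadjusted)
    distances.  Reproducible given ``seed``.
    """
    if n < 2:
        raise ValueError("null model needs richness n >= 2")
    if M < 1 or Q < 1:
        raise ValueError("need M >= 1 and Q >= 1")
    if sampling == "pool":
        if pool is None:
            raise ValueError("pool sampling requires a SpeciesPool")
        if pool.M != M:
            raise ValueError(f"pool has M={pool.M}, requested M={M}")
        if pool.N < n:
            raise ValueError(
                f"cannot draw {n} distinct species from a pool of {pool.N}"
            )
    elif sampling != "uniform":
        raise ValueError(f"unknown sampling scheme {sampling!r}")

    rng = _substream(seed, n, M, sampling)
    draws = np.empty(Q)
    if sampling == "uniform":
        pts_all = rng.random((Q, n, M))
        for q in range(Q):
            l = mst_branch_lengths(squareform(pdist(pts_all[q])))
            draws[q] = np.minimum(l, l.mean()).sum()
    else:
        traits = pool.norm_traits
        for q in range(Q):
            idx = rng.choice(pool.N, size=n, replace=False)
            l = mst_branch_lengths(squareform(pdist(traits[idx])))
            draws[q] = np.minimum(l, l.mean()).sum()
    draws.sort()
    return NullCDF(n=n, M=M, Q=Q, seed=seed, sampling=sampling, samples=draws)


def fee(X, cdf: NullCDF):
    """Empirical-CDF value of observed FEE0 against a null curve.

    Returns #{x_i <= X}/Q exactly (ties count as <=, no interpolation).
    Accepts a scalar or an array of observed values.
    """
    pos = np.searchsorted(cdf.samples, X, side="right")
    out = pos / cdf.Q
    return float(out) if np.isscalar(X) else out


@dataclass
class CDFLibrary:
    """Cache of null curves keyed by (n, M, sampling).

    Lookups are exact: there is never a silent fallback to a neighbouring
    richness, because comparing an observed FEE0 against a wrong-n curve
    silently biases FEE.
    """

    Q: int = DEFAULT_Q
    seed: int = 0
    sampling: str = "uniform"
    pool: Optional[SpeciesPool] = None
    curves: dict = field(default_factory=dict)

    def build(self, n_values, M: int) -> "CDFLibrary":
        """Add curves for every richness in ``n_values`` at dimension M."""
        for n in n_values:
            key = (int(n), int(M), self.sampling)
            if key not in self.curves:
                self.curves[key] = sample_null_fee0(
                    int(n), int(M), self.Q, self.seed, self.sampling, self.pool
                )
        return self

    def get(self, n: int, M: int) -> NullCDF:
        key = (int(n), int(M), self.sampling)
        try:
            return self.curves[key]
        except KeyError:
            raise KeyError(
                f"no null curve for n={n}, M={M}, sampling={self.sampling!r}; "
                f"build one with CDFLibrary.build([{n}], {M}) or the "
                "'feediv nullcdf' command"
            ) from None

    def get_or_build(self, n: int, M: int) -> NullCDF:
        key = (int(n), int(M), self.sampling)
        if key not in self.curves:
            self.curves[key] = sample_null_fee0(
                int(n), int(M), self.Q, self.seed, self.sampling, self.pool
            )
        return self.curves[key]


def fee_for_community(
    c: Community, library: CDFLibrary, abundance_weighted: bool = False
) -> float:
    """FEE of a community via its FEE0 and the matching (n, M) null curve."""
    from .mst_fee import fee0_for_community

    X, mst = fee0_for_community(c, abundance_weighted=abundance_weighted)
    n = mst.n_branches + 1  # richness after any zero-abundance drops
    cdf = library.get(n, c.pool.M)
    return fee(X, cdf)


def save_cdf_library(library: CDFLibrary, path) -> None:
    """Write a library to a gzip-compressed tabular text file.

    Samples are serialized as C99 hex floats so the round trip is
    bit-exact.
    """
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(_FORMAT_HEADER + "\n")
        fh.write(f"Q\t{library.Q}\tseed\t{library.seed}"
                 f"\tsampling\t{library.sampling}\n")
        for (n, M, sampling), cdf in sorted(library.curves.items()):
            fh.write(f"#curve\tn\t{n}\tM\t{M}\tQ\t{cdf.Q}"
                     f"\tseed\t{cdf.seed}\tsampling\t{sampling}\n")
            for x in cdf.samples:
                fh.write(float(x).hex() + "\n")


def load_cdf_library(path) -> CDFLibrary:
    """Read a library written by :func:`save_cdf_library`.

    Refuses corrupted or version-mismatched files outright — a partial
    load would poison downstream FEE values.
    """
    with gzip.open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _FORMAT_HEADER:
        raise ValueError(
            f"{path}: not a feediv CDF library (bad or missing header)"
        )
    meta = lines[1].split("\t")
    if len(meta) != 6 or meta[0] != "Q":
        raise ValueError(f"{path}: corrupted library metadata line")
    lib = CDFLibrary(Q=int(meta[1]), seed=int(meta[3]), sampling=meta[5])
    i = 2
    while i < len(lines):
        parts = lines[i].split("\t")
        if parts[0] != "#curve" or len(parts) != 11:
            raise ValueError(f"{path}: corrupted curve header at line {i + 1}")
        n, M, Q = int(parts[2]), int(parts[4]), int(parts[6])
        seed, sampling = int(parts[8]), parts[10]
        block = lines[i + 1 : i + 1 + Q]
        if len(block) != Q:
            raise ValueError(f"{path}: truncated sample block at line {i + 1}")
        samples = np.array([float.fromhex(s) for s in block])
        lib.curves[(n, M, sampling)] = NullCDF(
            n=n, M=M, Q=Q, seed=seed, sampling=sampling, samples=samples
        )
        i += 1 + Q
    return lib
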