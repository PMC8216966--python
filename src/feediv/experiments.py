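"""Computational studies of the FEE index.

Two studies plus a generic scenario runner:

* the null-model correlation study — many equal-abundance communities
  assembled at random across a wide richness gradient, used to measure
  how FEE and five reference indices relate to each other and to
  species richness;
* the assembly-process detection study — paired lottery simulations
  under neutral, niche-filtering and limiting-similarity dynamics,
  evaluated with one-sided paired t tests and index-versus-richness
  regressions;
* a scenario runner that evaluates all indices on hand-specified
  communities from a TSV file, for trend checks on constructed series.

All randomness flows from one master seed; pools, communities, null
curves and simulations each get an independent, order-free substream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import fd_reference as fdr
from .assembly_sim import (
    AssemblyConfig,
    init_assembly,
    run_forward,
    uniform_pool_traits,
)
from .mst_fee import compute_mst, fee0, fee0_for_community
from .null_model import CDFLibrary, fee
from .traitspace import Community, DistanceMatrix, SpeciesPool

__all__ = [
    "CorrelationDesign",
    "ExperimentReport",
    "generate_null_communities",
    "community_indices",
    "run_correlation_experiment",
    "run_assembly_experiment",
    "run_scenarios",
]

INDEX_COLUMNS = ["FEE", "FEE0", "FRic", "FEve", "FDiv", "FDis", "RaoQ"]


@dataclass(frozen=True)
class CorrelationDesign:
    """Design of the null-model correlation study.

    ``replicates`` independent communities per richness level, each
    drawn (equal abundance) from its own fresh pool of ``pool_size``
    species with uniform traits in ``M`` dimensions.
    """

    richness_min: int = 2
    richness_max: int = 100
    replicates: int = 200
    pool_size: int = 300
    M: int = 2
    Q: int = 2000
    seed: int = 0

    @property
    def richness_values(self) -> range:
        return range(self.richness_min, self.richness_max + 1)

    @property
    def total_communities(self) -> int:
        return len(self.richness_values) * self.replicates


@dataclass
class ExperimentReport:
    """Per-community index table plus the study's summary statistics."""

    index_table: pd.DataFrame
    correlations: Optional[pd.DataFrame] = None
    correlation_pvalues: Optional[pd.DataFrame] = None
    paired_tests: Optional[pd.DataFrame] = None
    regressions: Optional[pd.DataFrame] = None
    undefined_counts: Optional[pd.Series] = None
    seed: Optional[int] = None


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=key)
    )


def generate_null_communities(design: CorrelationDesign):
    """Yield (richness, replicate, points) for every community in the design.

    Each community is a fresh random ``richness``-subset of its own
    fresh uniform pool.  Reproducible: the stream depends only on the
    design seed.
    """
    if design.richness_max > design.pool_size:
        raise ValueError("richness cannot exceed pool size")
    rng = _rng_for(design.seed, 1)
    for n in design.richness_values:
        for rep in range(design.replicates):
            pool = rng.random((design.pool_size, design.M))
            members = rng.choice(design.pool_size, size=n, replace=False)
            yield n, rep, pool[members]


def community_indices(
    points: np.ndarray,
    w: Optional[np.ndarray] = None,
    library: Optional[CDFLibrary] = None,
) -> dict:
    """All indices for one community; undefined ones become NaN.

    ``w`` are relative abundances (None means equal).  FEE is computed
    only when a null-curve library is supplied.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    row: dict = {"n": n}
    dmat = squareform(pdist(points))
    mst_l = compute_mst(
        DistanceMatrix(tuple(range(n)), dmat)
    ).branch_lengths
    row["FEE0"] = fee0(mst_l)
    if library is not None:
        row["FEE"] = fee(row["FEE0"], library.get_or_build(n, points.shape[1]))
    for name, call in (
        ("FRic", lambda: fdr.fric(points)),
        ("FEve", lambda: fdr.feve(points, w)),
        ("FDiv", lambda: fdr.fdiv(points, w)),
        ("FDis", lambda: fdr.fdis(points, w)),
        ("RaoQ", lambda: fdr.rao_q(dmat, w)),
    ):
        try:
            row[name] = call()
        except fdr.UndefinedIndexError as err:
            row[name] = np.nan
            row.setdefault("undefined_reasons", {})[name] = str(err)
    return row


def _pairwise_pearson(table: pd.DataFrame, columns):
    """Pearson r and two-sided p per column pair, NaNs deleted pairwise."""
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for a in range(k):
        for b in range(a + 1, k):
            x = table[columns[a]].to_numpy(float)
            y = table[columns[b]].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            res = stats.pearsonr(x[ok], y[ok])
            r.iloc[a, b] = r.iloc[b, a] = res.statistic
            p.iloc[a, b] = p.iloc[b, a] = res.pvalue
    return r, p


def run_correlation_experiment(
    design: CorrelationDesign,
    library: Optional[CDFLibrary] = None,
    richness_window: Optional[tuple[int, int]] = None,
) -> ExperimentReport:
    """Run the null-model correlation study.

    Builds (or reuses) a uniform null-curve library covering the
    richness range, computes FEE and the five reference indices for
    every community, and reports the full Pearson correlation matrix
    of the indices and richness.  ``richness_window`` optionally
    restricts the correlation analysis to a sub-range of richness
    without regenerating communities.
    """
    if library is None:
        library = CDFLibrary(Q=design.Q, seed=design.seed + 1, sampling="uniform")
    library.build(design.richness_values, design.M)

    rows = []
    for n, rep, points in generate_null_communities(design):
        row = community_indices(points, w=None, library=library)
        row.pop("undefined_reasons", None)
        row["replicate"] = rep
        rows.append(row)
    table = pd.DataFrame(rows)

    analysed = table
    if richness_window is not None:
        lo, hi = richness_window
        analysed = table[(table["n"] >= lo) & (table["n"] <= hi)]
    columns = ["n"] + [c for c in INDEX_COLUMNS if c in analysed.columns]
    r, p = _pairwise_pearson(analysed, columns)
    undefined = analysed[columns].isna().sum()
    return ExperimentReport(
        index_table=table,
        correlations=r,
        correlation_pvalues=p,
        undefined_counts=undefined,
        seed=design.seed,
    )


def _paired_t_row(index, mode, label, higher, lower):
    """One-sided paired t that ``higher`` exceeds ``lower`` on average."""
    a = np.asarray(higher, float)
    b = np.asarray(lower, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    diffs = a - b
    if ok.sum() < 2 or np.allclose(diffs, 0.0):
        return {
            "index": index, "mode": mode, "hypothesis": label,
            "n_pairs": int(ok.sum()), "t": 0.0, "p": 0.5, "degenerate": True,
        }
    res = stats.ttest_rel(a, b, alternative="greater")
    return {
        "index": index, "mode": mode, "hypothesis": label,
        "n_pairs": int(ok.sum()), "t": float(res.statistic),
        "p": float(res.pvalue), "degenerate": False,
    }


def _result_to_community(result, pool: SpeciesPool) -> Community:
    members = result.members
    return Community(
        pool=pool,
        members=tuple(str(i) for i in members),
        abundances=result.abundances[members].astype(float),
    )


def run_assembly_experiment(
    replicates: int = 300,
    config: Optional[AssemblyConfig] = None,
    Q: int = 2000,
    seed: int = 0,
    indices: tuple = ("FEE",),
) -> ExperimentReport:
    """Paired comparison of neutral, NF and LS assembly.

    Each replicate builds one pool and one initial community, then runs
    all three processes from that identical starting point (the pairing
    structure).  FEE is evaluated in both presence-absence and
    abundance-weighted modes against a shared uniform null-curve
    library; additional reference indices can be requested via
    ``indices``.  Returns per-run index values, one-sided paired t tests
    for the orderings neutral > NF and LS > neutral, and per-process
    regressions of each index on final richness.
    """
    base = config or AssemblyConfig()
    library = CDFLibrary(Q=Q, seed=seed + 2, sampling="uniform")
    rows = []
    for rep in range(replicates):
        rng_init = _rng_for(seed, 2, rep)
        pool_traits = uniform_pool_traits(base.pool_size, base.M, rng_init)
        init_abund = init_assembly(base, rng_init)
        pool = SpeciesPool.from_normalized(
            [str(i) for i in range(base.pool_size)], pool_traits
        )
        for proc_i, process in enumerate(("neutral", "nf", "ls")):
            cfg = replace(base, process=process)
            result = run_forward(
                pool_traits,
                cfg,
                rng=_rng_for(seed, 3, rep, proc_i),
                initial_abundances=init_abund,
            )
            comm = _result_to_community(result, pool)
            row = {
                "replicate": rep,
                "process": process,
                "richness": result.final_richness,
            }
            x_pa, _ = fee0_for_community(comm, abundance_weighted=False)
            x_ab, mst_ab = fee0_for_community(comm, abundance_weighted=True)
            cdf = library.get_or_build(comm.n, base.M)
            row["FEE_pa"] = fee(x_pa, cdf)
            row["FEE_ab"] = fee(x_ab, library.get_or_build(
                mst_ab.n_branches + 1, base.M))
            if len(indices) > 1 or indices != ("FEE",):
                extra = community_indices(comm.points, w=None)
                extra_ab = community_indices(
                    comm.points, w=comm.relative_abundances()
                )
                for name in indices:
                    if name == "FEE":
                        continue
                    row[f"{name}_pa"] = extra.get(name, np.nan)
                    row[f"{name}_ab"] = extra_ab.get(name, np.nan)
            rows.append(row)
    table = pd.DataFrame(rows)

    wide = table.pivot(index="replicate", columns="process")
    t_rows, reg_rows = [], []
    value_cols = [c for c in table.columns
                  if c.endswith("_pa") or c.endswith("_ab")]
    for col in value_cols:
        index_name, mode = col.rsplit("_", 1)
        t_rows.append(_paired_t_row(
            index_name, mode, "neutral > NF",
            wide[(col, "neutral")], wide[(col, "nf")]))
        t_rows.append(_paired_t_row(
            index_name, mode, "LS > neutral",
            wide[(col, "ls")], wide[(col, "neutral")]))
        for process in ("neutral", "nf", "ls"):
            sub = table[table["process"] == process]
            x = sub["richness"].to_numpy(float)
            y = sub[col].to_numpy(float)
            ok = np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                slope, pval, r = np.nan, np.nan, np.nan
            else:
                res = stats.linregress(x[ok], y[ok])
                slope, pval, r = res.slope, res.pvalue, res.rvalue
            reg_rows.append({
                "index": index_name, "mode": mode, "process": process,
                "slope": slope, "p": pval, "r": r, "n": int(ok.sum()),
            })
    return ExperimentReport(
        index_table=table,
        paired_tests=pd.DataFrame(t_rows),
        regressions=pd.DataFrame(reg_rows),
        seed=seed,
    )


def run_scenarios(
    scenarios: pd.DataFrame,
    library: Optional[CDFLibrary] = None,
    Q: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate all indices on hand-specified scenario communities.

    ``scenarios`` has columns ``scenario_id, species_id,
    trait_1..trait_M, abundance`` with trait coordinates already on the
    0-1 scale.  Rows are processed in file order, one output row per
    scenario, so monotone-trend checks across a series read top to
    bottom.
    """
    if scenarios.empty:
        return pd.DataFrame(
            columns=["scenario_id", "n"] + INDEX_COLUMNS
        )
    trait_cols = [c for c in scenarios.columns if c.startswith("trait_")]
    if not trait_cols:
        raise ValueError("scenario table has no trait_* columns")
    M = len(trait_cols)
    if library is None:
        library = CDFLibrary(Q=Q, seed=seed, sampling="uniform")
    out = []
    for sid in scenarios["scenario_id"].unique():
        sub = scenarios[scenarios["scenario_id"] == sid]
        points = sub[trait_cols].to_numpy(float)
        if (points < 0).any() or (points > 1).any():
            raise ValueError(
                f"scenario {sid!r}: trait coordinates must lie in [0, 1]"
            )
        if "abundance" in sub.columns:
            A = sub["abundance"].to_numpy(float)
            w = A / A.sum()
        else:
            w = None
        row = community_indices(points, w=w, library=library)
        row.pop("undefined_reasons", None)
        # abundance-weighted FEE0/FEE replace the equal-weight values
        # when abundances are present
        if w is not None and not np.allclose(w, w[0]):
            pool = SpeciesPool.from_normalized(
                [str(i) for i in range(points.shape[0])], points
            )
            comm = Community(
                pool, tuple(pool.species_ids), abundances=A
            )
            x_ab, mst_ab = fee0_for_community(comm, abundance_weighted=True)
            row["FEE0"] = x_ab
            row["FEE"] = fee(
                x_ab, library.get_or_build(mst_ab.n_branches + 1, M)
            )
        row["scenario_id"] = sid
        out.append(row)
    cols = ["scenario_id", "n"] + [
        c for c in INDEX_COLUMNS if any(c in r for r in out)
    ]
    return pd.DataFrame(out)[cols]
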