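"""Strict readers and writers for the package's tabular formats.

All files are UTF-8, tab-delimited, with a header row:

* traits.tsv — ``species_id, trait_1 .. trait_M``; one row per species.
* communities.tsv — long format ``community_id, species_id[, abundance]``;
  a missing abundance column means presence-absence data.
* scenarios.tsv — ``scenario_id, species_id, trait_1 .. trait_M,
  abundance`` with trait coordinates already on the 0-1 scale.
* MST edge lists — ``species_i, species_j, length``.

Validation errors name the offending row so malformed input can be
located; numbers are serialized with 12 significant digits, enough for
bit-stable regression comparisons of doubles.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .mst_fee import MinimumSpanningTree
from .traitspace import Community, SpeciesPool

__all__ = [
    "read_traits",
    "write_traits",
    "read_communities",
    "write_communities",
    "read_scenarios",
    "write_mst_edges",
    "write_index_table",
]

FLOAT_FORMAT = "%.12g"


def read_traits(path, normalized: bool = False) -> SpeciesPool:
    """Read a traits TSV into a species pool.

    ``normalized=True`` declares the values already on the 0-1 scale
    (bounds recorded as (0, 1)); otherwise min-max normalization over the
    pool is applied.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "species_id" or df.shape[1] < 2:
        raise ValueError(
            f"{path}: expected header 'species_id<TAB>trait_1...'; "
            f"got columns {list(df.columns)}"
        )
    dupes = df["species_id"][df["species_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"{path}: duplicate species id(s) {sorted(set(dupes))}"
        )
    trait_cols = list(df.columns[1:])
    values = df[trait_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(~np.isfinite(values))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric trait value at data row {r + 1}, "
            f"column {trait_cols[c]!r}"
        )
    ids = df["species_id"].tolist()
    if normalized:
        return SpeciesPool.from_normalized(ids, values)
    return SpeciesPool.from_raw_traits(ids, values)


def write_traits(pool: SpeciesPool, path, normalized: bool = False) -> None:
    traits = pool.norm_traits if normalized else pool.raw_traits
    df = pd.DataFrame(
        traits, columns=[f"trait_{j + 1}" for j in range(pool.M)]
    )
    df.insert(0, "species_id", pool.species_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_communities(path, pool: SpeciesPool) -> list[Community]:
    """Read a long-format community TSV against an existing pool.

    Unknown species, duplicate memberships and negative abundances are
    rejected with the offending community and row named.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["community_id", "species_id"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{path}: expected header starting "
            f"'community_id<TAB>species_id'; got {list(df.columns)}"
        )
    has_abund = "abundance" in df.columns
    if has_abund:
        abund = pd.to_numeric(df["abundance"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(abund.to_numpy()))
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric abundance at data row {bad[0] + 1}"
            )
        if (abund < 0).any():
            row = int(np.flatnonzero((abund < 0).to_numpy())[0])
            raise ValueError(
                f"{path}: negative abundance at data row {row + 1}"
            )
        df = df.assign(abundance=abund)
    out = []
    for cid, sub in df.groupby("community_id", sort=False):
        out.append(
            Community(
                pool=pool,
                members=tuple(sub["species_id"]),
                abundances=(
                    sub["abundance"].to_numpy(float) if has_abund else None
                ),
                community_id=str(cid),
            )
        )
    return out


def write_communities(communities, path) -> None:
    rows = []
    for c in communities:
        for i, s in enumerate(c.members):
            row = {"community_id": c.community_id, "species_id": s}
            if c.abundances is not None:
                row["abundance"] = c.abundances[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_scenarios(path) -> pd.DataFrame:
    """Read a scenario TSV; raises with a line number on malformed rows."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    needed = {"scenario_id", "species_id"}
    if not needed.issubset(df.columns):
        raise ValueError(
            f"{path}: scenario file needs columns {sorted(needed)} plus "
            f"trait_1..trait_M; got {list(df.columns)}"
        )
    trait_cols = [c for c in df.columns if c.startswith("trait_")]
    if not trait_cols:
        raise ValueError(f"{path}: no trait_* columns found")
    check_cols = trait_cols + (
        ["abundance"] if "abundance" in df.columns else []
    )
    for col in check_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data "
                f"row {bad[0] + 1} (file line {bad[0] + 2})"
            )
        df[col] = vals
    return df


def write_mst_edges(mst: MinimumSpanningTree, path) -> None:
    """Export an MST as a species_i/species_j/length edge list."""
    pd.DataFrame(
        mst.edges, columns=["species_i", "species_j", "length"]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_index_table(
    table: pd.DataFrame, path, reasons: Optional[pd.DataFrame] = None
) -> None:
    """Write a per-community index CSV; undefined values stay empty.

    When ``reasons`` is given it is written next to the table as
    ``<path>.reasons.csv`` explaining each missing cell.
    """
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if reasons is not None and len(reasons):
        reasons.to_csv(f"{path}.reasons.csv", index=False)
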