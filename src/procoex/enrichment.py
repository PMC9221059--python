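"""Hypergeometric over-representation analysis of subcommunities.

For a query of ``n`` genes drawn from a universe of ``N``, overlapping a
functional set of ``K`` genes in ``k``, the enrichment p-value is the
hypergeometric upper tail

    p = sum_{j >= k} C(K, j) C(N - K, n - j) / C(N, n)

computed through scipy's survival function (stable in log space).  Sets are
filtered to a size window (default 5-2000 members after intersection with
the universe) before testing, and Benjamini-Hochberg adjustment is applied
within each subcommunity's batch of tests — matching how per-query web
enrichment tools behave; a global adjustment is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .communities import Partition
from .errors import InputError
from .diffexp import bh_adjust

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["subcommunity", "set_name", "k", "K", "n", "N", "p", "q"]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One hypergeometric test of a query against one gene set."""

    set_name: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size within universe
    N: int  # universe size
    p: float
    subcommunity: str | None = None
    q: float | None = None


def ora(query: Iterable[str], geneset: Iterable[str], universe: Iterable[str],
        set_name: str = "") -> EnrichmentRecord:
    """Hypergeometric upper-tail test of query/set overlap in a universe.

    Genes outside the universe are dropped (with a warning) before counting.
    """
    universe = set(universe)
    if not universe:
        raise InputError("universe is empty")
    query = set(query)
    geneset = set(geneset)
    stray = (query | geneset) - universe
    if stray:
        logger.warning("dropping %d genes outside the universe", len(stray))
    query &= universe
    geneset &= universe
    N = len(universe)
    K = len(geneset)
    n = len(query)
    k = len(query & geneset)
    # upper tail P(X >= k); sf(k-1) = P(X > k-1)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentRecord(set_name=set_name, k=k, K=K, n=n, N=N, p=p)


def enrich_partition(
    partition: Partition,
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_size: int = 5,
    max_size: int = 2000,
    min_query_mapped: int = 3,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """ORA of every subcommunity against every retained gene set.

    Sets whose intersection with the universe falls outside
    ``[min_size, max_size]`` are excluded before testing; subcommunities
    with fewer than ``min_query_mapped`` genes in the universe are skipped.
    BH adjustment runs within each subcommunity unless ``global_fdr``.
    Rows are sorted by (subcommunity, q, p).
    """
    universe = set(universe)
    if not universe:
        raise InputError("universe is empty")
    retained = {
        name: set(members) & universe
        for name, members in collections.items()
    }
    retained = {
        name: members
        for name, members in retained.items()
        if min_size <= len(members) <= max_size
    }
    rows = []
    for sc, members in sorted(partition.subcommunity_members().items()):
        query = set(members) & universe
        if len(query) < min_query_mapped:
            continue
        for name, geneset in sorted(retained.items()):
            rec = ora(query, geneset, universe, set_name=name)
            rows.append(
                {
                    "subcommunity": sc,
                    "set_name": name,
                    "k": rec.k,
                    "K": rec.K,
                    "n": rec.n,
                    "N": rec.N,
                    "p": rec.p,
                }
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS[:-1])
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        return table
    if global_fdr:
        table["q"] = bh_adjust(table["p"])
    else:
        table["q"] = np.nan
        for sc, idx in table.groupby("subcommunity").groups.items():
            table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"])
    return table.sort_values(["subcommunity", "q", "p"], kind="mergesort").reset_index(
        drop=True
    )


def enrichment_heatmap_table(table: pd.DataFrame, q_cut: float = 1e-5) -> pd.DataFrame:
    """Gene set x subcommunity matrix of -log10(q); non-significant = blank.

    Cells with ``q`` above ``q_cut`` are NaN (rendered blank/white); rows
    and columns with no significant cell are dropped.
    """
    if table.empty:
        return pd.DataFrame()
    sig = table[table["q"] <= q_cut]
    if sig.empty:
        return pd.DataFrame()
    mat = sig.pivot_table(
        index="set_name", columns="subcommunity", values="q", aggfunc="min"
    )
    return -np.log10(mat)


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
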