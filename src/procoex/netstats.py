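"""Topology and annotation statistics of the inferred network.

Covers the descriptive layer of the analysis: the degree histogram and its
log-log power-law fit, per-subcommunity expression assortativity (do edges
join proteins that shift the same way in tumors?), cis/trans classification
of edges by chromosome, and connected-component sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .communities import Partition
from .errors import InputError
from .network import Network

logger = logging.getLogger(__name__)


def degree_distribution(net: Network) -> dict[int, int]:
    """Histogram degree -> node count; zero-count degrees omitted."""
    if net.n_nodes == 0:
        raise InputError("empty network")
    g = net.to_networkx()
    hist: dict[int, int] = {}
    for _, deg in g.degree():
        hist[deg] = hist.get(deg, 0) + 1
    return dict(sorted(hist.items()))


@dataclass(frozen=True)
class DegreeFit:
    """OLS fit of log10(count) on log10(degree)."""

    alpha: float  # slope; negative for a decaying power law
    intercept: float
    corr: float  # signed Pearson r of the fitted points
    n_points: int

    @property
    def abs_corr(self) -> float:
        return abs(self.corr)


def fit_power_law(hist: Mapping[int, int]) -> DegreeFit | None:
    """Log-log least-squares power-law fit of a degree histogram.

    Uses points with degree >= 1 and count > 0.  This is the classical
    log-log regression read off a degree-distribution plot (not a
    maximum-likelihood tail fit), so ``alpha`` is directly comparable to
    slopes reported from such plots.  Returns None (with a warning) when
    fewer than 3 usable points exist.
    """
    pts = [(k, c) for k, c in hist.items() if k >= 1 and c > 0]
    if len(pts) < 3:
        logger.warning("degree histogram has %d usable points (< 3); fit skipped", len(pts))
        return None
    logk = np.log10([k for k, _ in pts])
    logc = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(logk, logc, 1)
    if np.allclose(logc, logc[0]):
        corr = 0.0  # flat histogram: zero slope, correlation undefined -> 0
        slope = 0.0
    else:
        corr = float(pearsonr(logk, logc).statistic)
    return DegreeFit(alpha=float(slope), intercept=float(intercept),
                     corr=corr, n_points=len(pts))


@dataclass(frozen=True)
class AssortativityRecord:
    """Same-sign edge fraction of one subcommunity."""

    subcommunity: str
    n_edges: int
    expass: float


def expression_assortativity(
    net: Network,
    partition: Partition,
    signs: pd.Series,
    min_edges: int = 10,
) -> pd.DataFrame:
    """Expression assortativity (expass) per subcommunity.

    ``expass`` is the fraction of a subcommunity's internal edges whose two
    endpoints carry the same differential-expression sign (+1/-1).  Only
    subcommunities with strictly more than ``min_edges`` internal edges are
    reported.  Every edge endpoint must have a sign.
    """
    signs = pd.Series(signs)
    sub_of = partition.subcommunity
    if sub_of is None:
        raise InputError("partition has no level-2 labels; run subpartition first")
    counts: dict[str, list[int]] = {}
    for a, b in zip(net.edges["protein_a"], net.edges["protein_b"]):
        for node in (a, b):
            if node not in signs.index or pd.isna(signs.loc[node]):
                raise InputError(f"node {node!r} has no expression sign")
        sa, sb = sub_of.get(a), sub_of.get(b)
        if sa is None or sb is None or sa != sb:
            continue
        tot_same = counts.setdefault(str(sa), [0, 0])
        tot_same[0] += 1
        if int(signs.loc[a]) == int(signs.loc[b]):
            tot_same[1] += 1
    rows = [
        {"subcommunity": sc, "n_edges": tot, "expass": same / tot}
        for sc, (tot, same) in sorted(counts.items())
        if tot > min_edges
    ]
    return pd.DataFrame(rows, columns=["subcommunity", "n_edges", "expass"])


@dataclass(frozen=True)
class CisTransSummary:
    """Edge counts by chromosomal relation of the endpoints."""

    n_cis: int
    n_trans: int
    n_unmapped: int

    @property
    def n_edges(self) -> int:
        return self.n_cis + self.n_trans + self.n_unmapped

    @property
    def cis_fraction(self) -> float:
        mapped = self.n_cis + self.n_trans
        return self.n_cis / mapped if mapped else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_cis": self.n_cis,
            "n_trans": self.n_trans,
            "n_unmapped": self.n_unmapped,
            "cis_fraction": self.cis_fraction,
        }


def classify_cis_trans(
    net: Network, chrom_map: Mapping[str, str]
) -> tuple[CisTransSummary, pd.DataFrame]:
    """Classify every edge as cis / trans / unmapped.

    cis: both endpoints on the same chromosome; trans: different
    chromosomes; unmapped: at least one endpoint absent from the map.
    Also returns a per-chromosome breakdown of cis edge counts.
    """
    n_cis = n_trans = n_unmapped = 0
    per_chrom: dict[str, int] = {}
    for a, b in zip(net.edges["protein_a"], net.edges["protein_b"]):
        ca = chrom_map.get(a)
        cb = chrom_map.get(b)
        if ca is None or cb is None:
            n_unmapped += 1
        elif ca == cb:
            n_cis += 1
            per_chrom[ca] = per_chrom.get(ca, 0) + 1
        else:
            n_trans += 1
    breakdown = pd.DataFrame(
        sorted(per_chrom.items()), columns=["chromosome", "n_cis_edges"]
    )
    return CisTransSummary(n_cis, n_trans, n_unmapped), breakdown


def component_sizes(net: Network) -> list[int]:
    """Connected-component sizes, descending; isolated nodes count as 1."""
    g = net.to_networkx()
    return sorted((len(c) for c in nx.connected_components(g)), reverse=True)


def giant_component(net: Network) -> Network:
    """The induced subnetwork of the largest connected component."""
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        raise InputError("empty network")
    giant = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    return net.subgraph(giant)
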