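"""Two-level hierarchical community detection by greedy modularity.

Level 1 partitions the network with greedy agglomerative modularity
maximisation (CNM-style: repeatedly merge the community pair with the
largest modularity gain until no positive gain remains).  Level 2 reruns
the same procedure on each community's induced subgraph, yielding
subcommunities labelled ``SC<c>_<k>``.  Labels are mutually exclusive and
exhaustive at both levels, and every subcommunity is wholly contained in
one community.

Modularity is ``Q = sum_i (e_ii - a_i^2)`` with ``e_ii`` the fraction of
edge weight inside community ``i`` and ``a_i`` the fraction of edge ends in
it.  Detection is weighted by MI by default — on a p-thresholded network
the inside of a module can be nearly complete, and only the weights carry
the finer submodule structure; with equal weights the criterion reduces to
the unweighted one.  Connected components are partitioned independently and
isolated nodes form singleton communities.  Community ids are assigned by
descending size (ties by lexicographically smallest member), which makes
the labelling deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from networkx.algorithms import community as nx_comm

from .errors import InputError
from .network import Network


@dataclass
class Partition:
    """Node labels at one or two levels, with modularity at each."""

    community: pd.Series  # node -> int community id (1-based)
    q_level1: float
    subcommunity: pd.Series | None = None  # node -> "SC<c>_<k>"
    q_level2: float | None = None
    q_by_community: dict[int, float] = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return int(self.community.nunique())

    @property
    def n_subcommunities(self) -> int:
        if self.subcommunity is None:
            raise InputError("partition has no level-2 labels; run subpartition first")
        return int(self.subcommunity.nunique())

    def members(self, community_id: int) -> list[str]:
        return list(self.community.index[self.community == community_id])

    def subcommunity_members(self) -> dict[str, list[str]]:
        if self.subcommunity is None:
            raise InputError("partition has no level-2 labels; run subpartition first")
        return {
            str(sc): list(self.subcommunity.index[self.subcommunity == sc])
            for sc in self.subcommunity.unique()
        }

    def write(self, path) -> None:
        df = pd.DataFrame({"community": self.community})
        if self.subcommunity is not None:
            df["subcommunity"] = self.subcommunity
        df.to_csv(path, sep="\t", index_label="pGene")

    @classmethod
    def read(cls, path) -> "Partition":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            community=df["community"],
            q_level1=float("nan"),
            subcommunity=df["subcommunity"] if "subcommunity" in df.columns else None,
        )


def _weight_arg(weighted: bool) -> str | None:
    return "mi" if weighted else None


def _greedy_merge(g: nx.Graph, weighted: bool) -> list[set[str]]:
    """CNM-style agglomerative modularity maximisation on one graph.

    Every node starts as its own community; the connected pair with the
    largest modularity gain ``dQ = 2 (e_ij - a_i a_j)`` is merged until no
    positive gain remains.  A community is named by its lexicographically
    smallest member and, among equal gains, the smallest (i, j) pair merges
    first, which makes the outcome deterministic.
    """
    import heapq

    w_attr = _weight_arg(weighted)
    two_w = 2.0 * sum(d.get(w_attr, 1.0) if w_attr else 1.0 for _, _, d in g.edges(data=True))
    if two_w == 0:
        return [{n} for n in g.nodes]

    def _w(d) -> float:
        return float(d.get(w_attr, 1.0)) if w_attr else 1.0

    members: dict[str, set[str]] = {n: {n} for n in g.nodes}
    a: dict[str, float] = {n: 0.0 for n in g.nodes}
    e: dict[str, dict[str, float]] = {n: {} for n in g.nodes}
    for u, v, d in g.edges(data=True):
        w = _w(d) / two_w
        a[u] += w
        a[v] += w
        e[u][v] = e[u].get(v, 0.0) + 2.0 * w
        e[v][u] = e[v].get(u, 0.0) + 2.0 * w

    def _dq(i: str, j: str) -> float:
        return e[i][j] - 2.0 * a[i] * a[j]

    heap: list[tuple[float, str, str]] = []
    for i in e:
        for j in e[i]:
            if i < j:
                heapq.heappush(heap, (-_dq(i, j), i, j))

    eps = 1e-12
    while heap:
        neg_dq, i, j = heapq.heappop(heap)
        if i not in members or j not in members or j not in e[i]:
            continue
        if abs(-neg_dq - _dq(i, j)) > 1e-15:  # stale entry
            continue
        if -neg_dq <= eps:
            break
        # merge j into i (i < j by construction)
        members[i] |= members.pop(j)
        a[i] += a[j]
        del a[j]
        del e[i][j]
        del e[j][i]
        for k, w in e.pop(j).items():
            e[k].pop(j)
            e[i][k] = e[i].get(k, 0.0) + w
            e[k][i] = e[i][k]
        for k in e[i]:
            lo, hi = (i, k) if i < k else (k, i)
            heapq.heappush(heap, (-_dq(lo, hi), lo, hi))
    return list(members.values())


def _community_sets(g: nx.Graph, weighted: bool) -> list[set[str]]:
    """Greedy modularity communities of one graph, largest first.

    The greedy merge runs globally: the gain of merging two communities
    with no edge between them is negative, so connected components can
    never coalesce, isolated nodes stay singleton communities, and — unlike
    partitioning each component with its own weight normalisation — the
    degree-null term is computed against the whole network, which is what
    the modularity objective defines.
    """
    found = _greedy_merge(g, weighted)
    return sorted(found, key=lambda c: (-len(c), min(c)))


def detect_communities(net: Network, weighted: bool = True) -> Partition:
    """Level-1 partition of the network; raises on an empty edge set."""
    if net.n_edges == 0:
        raise InputError("cannot detect communities in a network with no edges")
    g = net.to_networkx()
    sets = _community_sets(g, weighted)
    labels = {}
    for cid, members in enumerate(sets, start=1):
        for node in members:
            labels[node] = cid
    community = pd.Series(labels, name="community").reindex(net.nodes).astype(int)
    q = modularity(net, community, weighted=weighted)
    return Partition(community=community, q_level1=q)


def subpartition(net: Network, partition: Partition, weighted: bool = True) -> Partition:
    """Add level-2 labels by re-partitioning each community's subgraph.

    A community that does not split (e.g. a clique) gets the single label
    ``SC<c>_1``; a disconnected community necessarily splits into its
    components.  Subcommunity numbering is by descending size.
    """
    g = net.to_networkx()
    sub_labels: dict[str, str] = {}
    q_by_comm: dict[int, float] = {}
    for cid in sorted(partition.community.unique()):
        members = partition.members(int(cid))
        sub = g.subgraph(members)
        sets = _community_sets(nx.Graph(sub), weighted)
        for k, s in enumerate(sets, start=1):
            for node in s:
                sub_labels[node] = f"SC{cid}_{k}"
        if sub.number_of_edges() > 0 and len(sets) > 1:
            sub_net = Network(
                net.edges[
                    net.edges["protein_a"].isin(members)
                    & net.edges["protein_b"].isin(members)
                ].copy(),
                nodes=sorted(members),
            )
            q_by_comm[int(cid)] = modularity(
                sub_net, pd.Series({n: lab for n, lab in sub_labels.items() if n in set(members)}),
                weighted=weighted,
            )
        else:
            q_by_comm[int(cid)] = 0.0
    subcommunity = pd.Series(sub_labels, name="subcommunity").reindex(net.nodes)
    q2 = modularity(net, subcommunity, weighted=weighted)
    return Partition(
        community=partition.community,
        q_level1=partition.q_level1,
        subcommunity=subcommunity,
        q_level2=q2,
        q_by_community=q_by_comm,
    )


def modularity(net: Network, labels, weighted: bool = True) -> float:
    """Modularity Q of a labelling that covers every network node."""
    labels = pd.Series(labels)
    missing = set(net.nodes) - set(labels.index)
    if missing:
        raise InputError(f"labels missing for nodes: {sorted(missing)[:5]}")
    g = net.to_networkx()
    groups: dict = {}
    for node in net.nodes:
        groups.setdefault(labels.loc[node], set()).add(node)
    return float(
        nx_comm.modularity(g, list(groups.values()), weight=_weight_arg(weighted))
    )
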