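"""Weighted undirected network container and its plain-text formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import FormatError

EDGE_COLUMNS = ["protein_a", "protein_b", "mi", "p"]


def _canonical_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Order endpoints lexicographically (a < b) and drop self/duplicate pairs."""
    edges = edges.copy()
    a = edges["protein_a"].astype(str)
    b = edges["protein_b"].astype(str)
    swap = a > b
    edges.loc[swap, ["protein_a", "protein_b"]] = edges.loc[
        swap, ["protein_b", "protein_a"]
    ].to_numpy()
    edges = edges[edges["protein_a"] != edges["protein_b"]]
    edges = edges.drop_duplicates(subset=["protein_a", "protein_b"], keep="first")
    return edges.reset_index(drop=True)


@dataclass
class Network:
    """Undirected simple graph: MI-weighted protein pairs plus edge p-values.

    ``edges`` has columns ``protein_a, protein_b, mi, p`` with endpoints in
    lexicographic order; ``nodes`` may include isolated proteins (e.g. after
    a top-k cut).  ``provenance`` records how the edge set was produced
    (threshold, k, permutation settings).
    """

    edges: pd.DataFrame
    nodes: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("protein_a", "protein_b", "mi") if c not in self.edges.columns]
        if missing:
            raise FormatError(f"edge table lacks columns {missing}")
        if "p" not in self.edges.columns:
            self.edges = self.edges.assign(p=float("nan"))
        self.edges = _canonical_edges(self.edges[EDGE_COLUMNS])
        endpoint_nodes = sorted(
            set(self.edges["protein_a"]).union(self.edges["protein_b"])
        )
        if self.nodes is None:
            self.nodes = endpoint_nodes
        else:
            self.nodes = [str(n) for n in self.nodes]
            orphan = set(endpoint_nodes) - set(self.nodes)
            if orphan:
                raise FormatError(f"edges reference nodes outside node set: {sorted(orphan)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["protein_a"], self.edges["protein_b"]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            zip(self.edges["protein_a"], self.edges["protein_b"], self.edges["mi"]),
            weight="mi",
        )
        return g

    def subgraph(self, nodes) -> "Network":
        nodes = set(nodes)
        keep = self.edges["protein_a"].isin(nodes) & self.edges["protein_b"].isin(nodes)
        return Network(self.edges[keep].copy(), nodes=sorted(nodes), provenance=dict(self.provenance))

    # -- I/O --------------------------------------------------------------
    def write_edge_list(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))

    def write_sif(self, path) -> None:
        """Cytoscape SIF export: ``a mi b`` per edge."""
        with open(path, "w") as fh:
            for a, b in zip(self.edges["protein_a"], self.edges["protein_b"]):
                fh.write(f"{a}\tmi\t{b}\n")

    @classmethod
    def read_edge_list(cls, path, nodes=None) -> "Network":
        path = Path(path)
        edges = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
        if not {"protein_a", "protein_b"}.issubset(edges.columns):
            raise FormatError(f"{path.name}: expected columns protein_a, protein_b")
        if "mi" not in edges.columns:
            edges["mi"] = 1.0
        edges["protein_a"] = edges["protein_a"].str.upper()
        edges["protein_b"] = edges["protein_b"].str.upper()
        return cls(edges, nodes=nodes)
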