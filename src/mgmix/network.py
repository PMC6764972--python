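"""Collapse fitted parameters into a signed weighted network.

Each nonzero parameter block becomes one undirected edge with a scalar
signed weight: β_st for continuous pairs, the single free entry of ρ for a
continuous–binary pair, the single free entry of φ for a binary–binary pair.
Blocks with more than one free entry (variables with > 2 levels) are
collapsed to their signed maximum-magnitude entry, with the full block's L2
norm kept alongside so no information is lost.  Exact zeros yield no edge.
"""

from __future__ import annotations

import dataclasses
import difflib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .model import MGMParameters

__all__ = [
    "EdgeNetwork",
    "NeighborhoodModel",
    "collapse_edges",
    "first_order_neighborhood",
    "export_network",
    "import_network",
]

# presentation hints for downstream renderers
_LAYER_COLORS = {
    "clinical_chemistry": "blue",
    "demographic": "orange",
    "drug": "cyan",
    "nmr": "red",
    "other": "grey",
}


@dataclasses.dataclass
class EdgeNetwork:
    """Undirected signed network over the model's variables."""

    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["weight"])

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "source": min(u, v),
                "target": max(u, v),
                "weight": d["weight"],
                "norm": d["norm"],
                "block": d["block"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "weight", "norm", "block"])
        return df.sort_values(["source", "target"]).reset_index(drop=True)


@dataclasses.dataclass
class NeighborhoodModel:
    """A center node with its directly connected nodes, ordered by |weight|."""

    center: str
    kind: str
    neighbors: list[tuple[str, float, str]]  # (name, collapsed weight, block)
    intercept: dict  # alpha/beta_diag for continuous, theta vector for categorical

    def neighbor_names(self) -> list[str]:
        return [n for n, _, _ in self.neighbors]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.neighbors, columns=["neighbor", "weight", "block"])


def _signed_max(block: np.ndarray) -> float:
    flat = np.asarray(block, dtype=float).ravel()
    return float(flat[np.argmax(np.abs(flat))])


def collapse_edges(params: MGMParameters) -> EdgeNetwork:
    """Build the signed edge network from fitted parameters."""
    cont, cat = params.var_names()
    layers = params.layers or {}
    G = nx.Graph()
    for s, name in enumerate(cont):
        G.add_node(
            name,
            kind="continuous",
            layer=layers.get(name, "other"),
            color=_LAYER_COLORS.get(layers.get(name, "other"), "grey"),
            shape="circle",
            alpha=float(params.alpha[s]),
            beta_diag=float(params.beta[s, s]),
        )
    for j, name in enumerate(cat):
        sl = params.block_slice(j)
        G.add_node(
            name,
            kind="categorical",
            layer=layers.get(name, "other"),
            color=_LAYER_COLORS.get(layers.get(name, "other"), "grey"),
            shape="rectangle",
            theta=",".join(repr(float(t)) for t in params.theta[sl]),
        )

    def add(u, v, block_vals, block):
        norm = float(np.linalg.norm(np.asarray(block_vals).ravel()))
        if norm == 0.0:
            return
        G.add_edge(u, v, weight=_signed_max(block_vals), norm=norm, block=block)

    p = params.p
    for s in range(p):
        for t in range(s + 1, p):
            add(cont[s], cont[t], params.beta[s, t], "beta")
    for s in range(p):
        for j in range(params.q):
            sl = params.block_slice(j)
            add(cont[s], cat[j], params.rho[s, sl.start + 1 : sl.stop], "rho")
    for r in range(params.q):
        for j in range(r + 1, params.q):
            slr, slj = params.block_slice(r), params.block_slice(j)
            blk = params.phi[slr.start + 1 : slr.stop, slj.start + 1 : slj.stop]
            add(cat[r], cat[j], blk, "phi")
    return EdgeNetwork(G)


def first_order_neighborhood(net: EdgeNetwork, center: str) -> NeighborhoodModel:
    """All nodes directly connected to ``center``, sorted by |weight| descending.

    Ties are broken by node name for determinism.
    """
    G = net.graph
    if center not in G:
        near = difflib.get_close_matches(center, list(G.nodes), n=5)
        raise KeyError(f"unknown node {center!r}; similar names: {near}")
    nbrs = [
        (v, float(d["weight"]), str(d["block"])) for v, d in G.adj[center].items()
    ]
    nbrs.sort(key=lambda t: (-abs(t[1]), t[0]))
    attrs = G.nodes[center]
    if attrs.get("kind", "continuous") == "continuous":
        intercept = {"alpha": attrs.get("alpha", 0.0), "beta_diag": attrs.get("beta_diag", -1.0)}
    else:
        intercept = {"theta": [float(x) for x in str(attrs.get("theta", "0.0")).split(",")]}
    return NeighborhoodModel(center, attrs.get("kind", "continuous"), nbrs, intercept)


def export_network(net: EdgeNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write GraphML (full attributes) or an edge-list TSV.

    The TSV carries edges only (columns source, target, weight, norm, block);
    GraphML round-trips the network exactly, including isolated nodes.
    """
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_tsv":
        net.edges_dataframe().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError("format must be 'graphml' or 'edge_tsv'")


def import_network(path: str | Path, format: str = "graphml") -> EdgeNetwork:
    if format == "graphml":
        G = nx.read_graphml(path)
        G = nx.relabel_nodes(G, {n: str(n) for n in G.nodes})
        return EdgeNetwork(nx.Graph(G))
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        G = nx.Graph()
        for _, r in df.iterrows():
            G.add_edge(
                str(r["source"]),
                str(r["target"]),
                weight=float(r["weight"]),
                norm=float(r["norm"]),
                block=str(r["block"]),
            )
        return EdgeNetwork(G)
    raise ValueError("format must be 'graphml' or 'edge_tsv'")
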