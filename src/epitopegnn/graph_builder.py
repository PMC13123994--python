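"""Typed residue-graph construction and the multi-scale adjacency stack.

A protein is a graph whose nodes are residues and whose edges come in
three flavours:

* sequential edges between residues close along the chain
  (0 < |i−j| < ``d_seq``);
* radius edges between residues whose Cα atoms are closer than ``d_r`` Å
  but at least ``d_long`` apart in sequence;
* k-nearest-neighbour edges in 3D, again restricted to |i−j| ≥ ``d_long``
  and symmetrized.

The multi-scale GCN consumes the union graph through the nested k-hop
adjacencies A₁ ⊆ A₂ ⊆ A₃ (within ≤ k hops, self-loops included).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphParams",
    "ProteinGraph",
    "build_sequential_edges",
    "build_radius_edges",
    "build_knn_edges",
    "assemble_graph",
    "khop_adjacency",
    "normalized_adjacency",
    "graph_to_tsv",
]


@dataclasses.dataclass(frozen=True)
class GraphParams:
    d_seq: int = 3      # sequential edges: 0 < |i-j| < d_seq
    d_r: float = 10.0   # radius edges: Cα distance < d_r Å
    k: int = 10         # KNN edges: k nearest in 3D
    d_long: int = 5     # spatial edges require |i-j| >= d_long

    def __post_init__(self):
        if self.d_seq < 1 or self.k < 1:
            raise ValueError("d_seq and k must be positive")
        if self.d_long <= self.d_seq:
            raise ValueError("d_long must exceed d_seq")


@dataclasses.dataclass
class ProteinGraph:
    n_nodes: int
    edges_seq: set
    edges_radius: set
    edges_knn: set
    union_adj: np.ndarray   # symmetric binary, zero diagonal
    multi_adj: dict         # {1: A1, 2: A2, 3: A3}, self-loops included

    @property
    def edge_types(self) -> dict:
        """Map (i, j) with i<j → set of type tags on that pair."""
        tags: dict = {}
        for name, edges in (("seq", self.edges_seq),
                            ("radius", self.edges_radius),
                            ("knn", self.edges_knn)):
            for e in edges:
                tags.setdefault(e, set()).add(name)
        return tags


def _canon(i: int, j: int) -> tuple:
    return (i, j) if i < j else (j, i)


def build_sequential_edges(n: int, d_seq: int = 3) -> set:
    """Pairs with 0 < |i−j| < d_seq (strict on both sides)."""
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, min(i + d_seq, n))
    }


def build_radius_edges(ca_coords: np.ndarray, d_r: float = 10.0,
                       d_long: int = 5) -> set:
    """Pairs with Cα distance strictly < d_r and |i−j| ≥ d_long."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca_coords must be (N, 3)")
    n = ca.shape[0]
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    ii, jj = np.triu_indices(n, k=d_long)
    keep = dist[ii, jj] < d_r
    return set(zip(ii[keep].tolist(), jj[keep].tolist()))


def build_knn_edges(ca_coords: np.ndarray, k: int = 10,
                    d_long: int = 5) -> set:
    """Undirected union of each residue's k nearest 3D neighbours among
    residues with |i−j| ≥ d_long; distance ties break to the smaller index."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca_coords must be (N, 3)")
    n = ca.shape[0]
    edges: set = set()
    for i in range(n):
        cand = [j for j in range(n) if abs(i - j) >= d_long]
        if not cand:
            continue
        d = np.linalg.norm(ca[cand] - ca[i], axis=1)
        order = sorted(range(len(cand)), key=lambda t: (d[t], cand[t]))
        for t in order[:k]:
            edges.add(_canon(i, cand[t]))
    return edges


def assemble_graph(ca_coords: np.ndarray,
                   params: GraphParams = GraphParams()) -> ProteinGraph:
    """Build the full typed graph and its multi-scale adjacency stack."""
    ca = np.asarray(ca_coords, dtype=float)
    n = ca.shape[0]
    e_seq = build_sequential_edges(n, params.d_seq)
    e_rad = build_radius_edges(ca, params.d_r, params.d_long)
    e_knn = build_knn_edges(ca, params.k, params.d_long)
    union = np.zeros((n, n), dtype=np.int8)
    for i, j in e_seq | e_rad | e_knn:
        union[i, j] = union[j, i] = 1
    multi = {k: khop_adjacency(union, k) for k in (1, 2, 3)}
    return ProteinGraph(
        n_nodes=n,
        edges_seq=e_seq,
        edges_radius=e_rad,
        edges_knn=e_knn,
        union_adj=union,
        multi_adj=multi,
    )


def khop_adjacency(union_adj: np.ndarray, k: int) -> np.ndarray:
    """A_k[i, j] = 1 iff shortest-path distance(i, j) ≤ k, incl. self-loops."""
    n = union_adj.shape[0]
    if n == 0:
        return np.zeros((0, 0), dtype=np.int8)
    dist = shortest_path(csr_matrix(union_adj), method="D", unweighted=True)
    return (dist <= k).astype(np.int8)


def normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization D^{-1/2} A D^{-1/2} (degrees from A)."""
    deg = adj.sum(axis=1).astype(float)
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    return adj * dinv[:, None] * dinv[None, :]


def graph_to_tsv(graph: ProteinGraph, edge_path, header_path,
                 params: GraphParams = GraphParams()) -> None:
    """Export the edge list as TSV (i, j, type) plus a JSON header."""
    with open(edge_path, "w") as fh:
        fh.write("i\tj\ttype\n")
        for (i, j), tags in sorted(graph.edge_types.items()):
            for tag in sorted(tags):
                fh.write(f"{i}\t{j}\t{tag}\n")
    with open(header_path, "w") as fh:
        json.dump(
            {
                "n_nodes": graph.n_nodes,
                "params": dataclasses.asdict(params),
                "n_edges": {
                    "seq": len(graph.edges_seq),
                    "radius": len(graph.edges_radius),
                    "knn": len(graph.edges_knn),
                },
            },
            fh,
            indent=2,
        )
        fh.write("\n")
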