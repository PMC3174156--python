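"""Residue interaction graphs and the local-closeness (LC) centrality.

LC for a node is C = n1 + n2/4 + n3/9 + n4/16 with n_k the number of nodes
at shortest-path distance exactly k; deep, well-packed pockets score high.
The contact rule (any heavy-atom pair < 5.0 Å, or Cα pairs < 8.0 Å when
only a Cα trace is available) is a documented reconstruction and both
cutoffs are configurable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from bindlev.structure_io import CalphaStructure, HeavyStructure

__all__ = [
    "HEAVY_CONTACT_CUTOFF",
    "CALPHA_CONTACT_CUTOFF",
    "build_residue_graph",
    "build_residue_graph_calpha",
    "local_closeness",
    "score_location_lc",
    "write_lc_table",
]

HEAVY_CONTACT_CUTOFF = 5.0
CALPHA_CONTACT_CUTOFF = 8.0


def build_residue_graph(
    structure: HeavyStructure, contact_cutoff: float = HEAVY_CONTACT_CUTOFF
) -> nx.Graph:
    """Simple graph with an edge wherever any heavy-atom pair of two residues
    is within ``contact_cutoff`` Å."""
    graph = nx.Graph()
    graph.add_nodes_from(range(structure.n_residues))
    tree = cKDTree(structure.coords)
    ridx = structure.residue_index
    for a, b in tree.query_pairs(contact_cutoff):
        u, v = int(ridx[a]), int(ridx[b])
        if u != v:
            graph.add_edge(u, v)
    return graph


def build_residue_graph_calpha(
    structure: CalphaStructure, contact_cutoff: float = CALPHA_CONTACT_CUTOFF
) -> nx.Graph:
    """Cα-only fallback contact graph (wider cutoff than the heavy-atom rule)."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(structure)))
    tree = cKDTree(structure.coords)
    for a, b in tree.query_pairs(contact_cutoff):
        graph.add_edge(int(a), int(b))
    return graph


def local_closeness(graph: nx.Graph, max_depth: int = 4) -> np.ndarray:
    """Per-node LC values C = Σ_{k=1..4} n_k / k², indexed by node id.

    Nodes must be integers 0..N−1 (residue handles).  Isolated nodes get 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n = graph.number_of_nodes()
    values = np.zeros(n)
    for node in graph.nodes:
        dist = nx.single_source_shortest_path_length(graph, node, cutoff=max_depth)
        c = 0.0
        for d in dist.values():
            if 1 <= d <= max_depth:
                c += 1.0 / (d * d)
        values[int(node)] = c
    return values


def score_location_lc(
    residues: Iterable[int], lc_values: np.ndarray | Mapping[int, float], top_n: int = 10
) -> float:
    """Mean LC of the ``top_n`` highest-LC residues of a probe location
    (plain mean when the location has fewer residues)."""
    residues = sorted(set(int(r) for r in residues))
    if not residues:
        raise ValueError("cannot score an empty location")
    vals = np.sort([float(lc_values[r]) for r in residues])[::-1]
    return float(np.mean(vals[:top_n]))


def write_lc_table(structure: CalphaStructure, lc_values: np.ndarray) -> str:
    """Two-column (residue id, C) text table."""
    labels = structure.residue_labels()
    rows = ["# residue LC"]
    rows += [f"{labels[i]} {lc_values[i]:.6f}" for i in range(len(structure))]
    return "\n".join(rows) + "\n"
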