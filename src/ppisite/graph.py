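"""The labeled residue graph: nodes are amino acids, edges are Cα contacts.

An edge joins two residues when their Cα atoms are at most ``cutoff`` Å
apart (default 6.0, inclusive — the comparison is a plain ``<=`` with no
epsilon). Edges may cross chain boundaries within the same complex.
Residues without a Cα atom cannot carry edges and are excluded from the
graph (they still count toward chain-length filtering upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .rasa import ResidueAnnotation
from .structures import ResidueId, Structure

logger = logging.getLogger(__name__)

__all__ = ["ResidueNode", "ProteinGraph", "build_graph", "degree_stats"]

DEFAULT_CUTOFF = 6.0


@dataclass
class ResidueNode:
    """A graph node: residue identity, features and Cα position."""

    rid: ResidueId
    annotation: ResidueAnnotation
    ca: tuple[float, float, float]


@dataclass
class ProteinGraph:
    """Residue contact graph of one structure.

    Nodes are integer indices into ``nodes``; ``g`` is the undirected edge
    structure and carries no attributes of its own.
    """

    structure_id: str
    nodes: list[ResidueNode]
    g: nx.Graph
    cutoff: float = DEFAULT_CUTOFF
    _by_rid: dict[ResidueId, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_rid:
            self._by_rid = {n.rid: i for i, n in enumerate(self.nodes)}

    def index_of(self, rid: ResidueId) -> int:
        return self._by_rid[rid]

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([n.ca for n in self.nodes])

    def __len__(self) -> int:
        return len(self.nodes)


def build_graph(
    structure: Structure,
    annotations: Mapping[ResidueId, ResidueAnnotation],
    cutoff: float = DEFAULT_CUTOFF,
    edges_across_chains: bool = True,
) -> ProteinGraph:
    """Build the Cα contact graph of a structure.

    Neighbor pairs are found with a k-d tree (``query_pairs`` is inclusive
    at the query radius, matching the "at most cutoff" rule); the edge set
    equals the all-pairs scan. Residues missing a Cα or an annotation are
    skipped with a warning.
    """
    nodes: list[ResidueNode] = []
    for res in structure.residues():
        ca = res.ca
        if ca is None:
            logger.warning("%s: residue %s has no CA; excluded from graph",
                           structure.structure_id, res.rid)
            continue
        ann = annotations.get(res.rid)
        if ann is None:
            logger.warning("%s: residue %s lacks annotation; excluded",
                           structure.structure_id, res.rid)
            continue
        nodes.append(ResidueNode(rid=res.rid, annotation=ann, ca=ca))

    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    if nodes:
        pts = np.asarray([n.ca for n in nodes])
        pairs = cKDTree(pts).query_pairs(r=cutoff)
        for i, j in pairs:
            if not edges_across_chains and nodes[i].rid[0] != nodes[j].rid[0]:
                continue
            g.add_edge(i, j)
    return ProteinGraph(structure_id=structure.structure_id, nodes=nodes,
                        g=g, cutoff=cutoff)


def degree_stats(graph: ProteinGraph) -> dict[str, float]:
    """Mean/min/max node degree; a sanity statistic, logged at build time."""
    if len(graph) == 0:
        logger.warning("degree_stats on empty graph")
        return {"mean": 0.0, "min": 0.0, "max": 0.0}
    degs = [d for _, d in graph.g.degree()]
    return {"mean": sum(degs) / len(degs), "min": float(min(degs)),
            "max": float(max(degs))}
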