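"""Structural elements: per-residue neighborhood subgraphs.

Two neighborhood families are supported, both centered on one residue:

* ``d_i`` — the center plus every node within *i* graph hops; always a
  connected subgraph.
* ``c_k`` — the center plus its *k* nearest nodes by Euclidean Cα distance,
  taken over the whole graph regardless of adjacency; the induced subgraph
  may be disconnected.

Graph distances between member pairs are measured inside the element's
induced subgraph (the element is the self-contained pattern that gets
hashed). Pairs in different components of a disconnected c_k element get
the sentinel value ``d_max``, which also clamps any longer path.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import ProteinGraph

__all__ = [
    "StructuralElement",
    "extract_d_neighborhood",
    "extract_c_neighborhood",
    "extract_element",
    "element_graph_distance",
]


@dataclass
class StructuralElement:
    """A central node with its neighborhood and induced edges.

    ``members`` always contains ``center``; ``kind`` is "d" or "c" with the
    corresponding radius/count in ``param``.
    """

    center: int
    members: frozenset[int]
    subgraph: nx.Graph
    kind: str
    param: int

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("center must be a member of its own element")
        if self.kind == "d" and len(self.members) > 1:
            assert nx.is_connected(self.subgraph), "d-neighborhood must be connected"


def extract_d_neighborhood(
    graph: ProteinGraph, center: int, i: int
) -> StructuralElement:
    """All nodes within ``i`` hops of ``center`` (BFS ball), with induced edges."""
    if i < 0:
        raise ValueError("hop radius must be >= 0")
    if center not in graph.g:
        raise KeyError(f"node {center} not in graph")
    reach = nx.single_source_shortest_path_length(graph.g, center, cutoff=i)
    members = frozenset(reach)
    return StructuralElement(
        center=center,
        members=members,
        subgraph=graph.g.subgraph(members).copy(),
        kind="d",
        param=i,
    )


def extract_c_neighborhood(
    graph: ProteinGraph, center: int, k: int
) -> StructuralElement:
    """The center plus its ``k`` spatially nearest nodes, with induced edges.

    Nearness is Euclidean Cα distance over *all* graph nodes, not only
    graph neighbors. Exact distance ties at the k-th slot break
    deterministically by node index. If fewer than ``k`` other nodes exist,
    all of them are taken.
    """
    if k < 0:
        raise ValueError("neighbor count must be >= 0")
    if center not in graph.g:
        raise KeyError(f"node {center} not in graph")
    n = len(graph)
    take = min(k, n - 1)
    if take < k:
        import logging
        logging.getLogger(__name__).warning(
            "c_%d requested but only %d other nodes exist", k, n - 1
        )
    coords = graph.coords
    d = np.linalg.norm(coords - coords[center], axis=1)
    # stable sort on (distance, node index); drop the center itself (d=0, first)
    order = np.lexsort((np.arange(n), d))
    others = [int(x) for x in order if int(x) != center][:take]
    members = frozenset([center, *others])
    return StructuralElement(
        center=center,
        members=members,
        subgraph=graph.g.subgraph(members).copy(),
        kind="c",
        param=k,
    )


def extract_element(
    graph: ProteinGraph, center: int, kind: str, param: int
) -> StructuralElement:
    """Dispatch on neighborhood kind: "d" (hop ball) or "c" (k-nearest)."""
    if kind == "d":
        return extract_d_neighborhood(graph, center, param)
    if kind == "c":
        return extract_c_neighborhood(graph, center, param)
    raise ValueError(f"unknown element kind {kind!r}")


def element_graph_distance(
    element: StructuralElement, a: int, b: int, d_max: int = 31
) -> int:
    """Hop distance between two members inside the element's subgraph.

    Different components → ``d_max``; any distance above ``d_max`` is
    clamped to it, keeping the pair encoding total and bounded.
    """
    if a not in element.members or b not in element.members:
        raise KeyError("node outside element")
    if a == b:
        return 0
    try:
        d = nx.shortest_path_length(element.subgraph, a, b)
    except nx.NetworkXNoPath:
        return d_max
    return min(d, d_max)
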