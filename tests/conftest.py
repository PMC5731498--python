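import networkx as nx
import numpy as np
import pytest

from ppisite.graph import ProteinGraph, ResidueNode
from ppisite.rasa import ResidueAnnotation
from ppisite.structures import Atom, Residue, Structure
from ppisite.synthetic import FixtureSpec, make_complex, make_kb_corpus


def single_atom_structure(coords, letters=None, chain_ids=None, radius=1.7,
                          structure_id="TOY"):
    """A Structure whose residues are single Cα spheres at given coords."""
    n = len(coords)
    letters = letters or "A" * n
    chain_ids = chain_ids or ["A"] * n
    chains: dict[str, list[Residue]] = {}
    counters: dict[str, int] = {}
    for (x, y, z), aa, cid in zip(coords, letters, chain_ids):
        counters[cid] = counters.get(cid, 0) + 1
        chains.setdefault(cid, []).append(
            Residue(chain_id=cid, seqnum=counters[cid], icode="", aa=aa,
                    atoms=[Atom("CA", "C", (float(x), float(y), float(z)),
                                radius)])
        )
    return Structure(structure_id=structure_id, chains=chains)


def manual_graph(edges, coords=None, letters=None, bins=None,
                 structure_id="TOY"):
    """A ProteinGraph with an explicit edge list (topology under our control)."""
    n = 1 + max((max(e) for e in edges), default=-1)
    if coords is not None:
        n = max(n, len(coords))
    coords = coords if coords is not None else [(3.0 * i, 0.0, 0.0) for i in range(n)]
    letters = letters or "A" * n
    nodes = [
        ResidueNode(
            rid=("A", i + 1, ""),
            annotation=ResidueAnnotation(
                aa=letters[i], rasa=0.5,
                rasa_bin=None if bins is None else bins[i],
            ),
            ca=tuple(float(c) for c in coords[i]),
        )
        for i in range(n)
    ]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return ProteinGraph(structure_id=structure_id, nodes=nodes, g=g)


def random_geometric_graph(rng, n_max=50, box=20.0, cutoff=6.0):
    """Seeded random node cloud with the inclusive distance-cutoff edge rule."""
    n = int(rng.integers(2, n_max + 1))
    coords = rng.uniform(0, box, size=(n, 3))
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff
    ]
    return manual_graph(edges, coords=[tuple(c) for c in coords])


@pytest.fixture
def two_chain_complex():
    spec = FixtureSpec(structure_id="TST1", chain_lengths=(10, 10),
                       contact_positions=(5, 6), contact_gap=0.3, seed=3)
    return make_complex(spec)


@pytest.fixture(scope="session")
def corpus6():
    return make_kb_corpus(6, seed=11, chain_lengths=(12, 12))


@pytest.fixture(scope="session")
def kb_c2(corpus6):
    from ppisite.fingerprints import FeatureConfig
    from ppisite.kb import build_kb

    return build_kb([s for s, _ in corpus6], FeatureConfig(length=1023),
                    element_kind="c", element_param=2)
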