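"""Per-residue interface prediction against a knowledge base.

For each residue of a query structure: extract its structural element,
fingerprint it, retrieve the tie-inclusive nearest neighbors S from the
knowledge base (prefiltered by the central-feature key, optionally
excluding the query's own structure), split S into interface hits I and
non-interface hits N by the stored labels, and report p = |I|/|S| as the
interface probability. The binary call is interface iff p is strictly
greater than the decision threshold.

The ``reference`` preset fixes the parameters of the published comparison
setup: c12 neighborhoods, 1023-bit fingerprints, amino-acid type as both
the neighborhood and the central feature, a single most-similar element
(n = 1) and decision threshold 0.5175.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import pandas as pd

from .elements import extract_element
from .fingerprints import FeatureConfig, build_fingerprint, central_key
from .graph import ProteinGraph, build_graph
from .kb import KnowledgeBase, annotate_structure, query
from .rasa import ResidueAnnotation
from .structures import ResidueId, Structure, label_interfaces

__all__ = [
    "PredictorParams",
    "ResiduePrediction",
    "reference_params",
    "predict_residue",
    "predict_graph",
    "predict_structure",
    "predictions_frame",
]


@dataclass(frozen=True)
class PredictorParams:
    """Everything the prediction step is parameterised by.

    ``n_similar`` is the nearest-neighbor count before tie inclusion;
    ``threshold`` is the strict lower bound on p = |I|/|S| for an
    interface call.
    """

    element_kind: str = "c"
    element_param: int = 12
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_similar: int = 1
    threshold: float = 0.5175
    exclude_self: bool = True


def reference_params(**overrides) -> PredictorParams:
    """The published comparison setup; any field can be overridden."""
    return replace(PredictorParams(), **overrides)


@dataclass(frozen=True)
class ResiduePrediction:
    """One residue's retrieval outcome and call.

    ``probability`` is |I|/|S|, or None when the retrieval set was empty
    (``defined`` False; the call defaults to non-interface).
    """

    rid: ResidueId
    probability: Optional[float]
    n_interface: int
    n_noninterface: int
    n_retrieved: int
    call: bool
    nearest_distance: Optional[int]

    @property
    def defined(self) -> bool:
        return self.probability is not None


def call_from_probability(p: Optional[float], threshold: float) -> bool:
    return p is not None and p > threshold


def predict_residue(
    graph: ProteinGraph,
    center: int,
    kb: KnowledgeBase,
    params: PredictorParams,
    exclude_structure: Optional[str] = None,
) -> ResiduePrediction:
    """Score one graph node against the knowledge base."""
    node = graph.nodes[center]
    element = extract_element(graph, center, params.element_kind,
                              params.element_param)
    anns = {i: graph.nodes[i].annotation for i in element.members}
    fp = build_fingerprint(element, anns, params.features)
    key = central_key(node.annotation, params.features)
    hits = query(kb, fp, key, n=params.n_similar,
                 exclude_structure=exclude_structure)
    n_s = len(hits)
    n_i = sum(r.interface for r, _ in hits)
    p = n_i / n_s if n_s else None
    return ResiduePrediction(
        rid=node.rid,
        probability=p,
        n_interface=n_i,
        n_noninterface=n_s - n_i,
        n_retrieved=n_s,
        call=call_from_probability(p, params.threshold),
        nearest_distance=hits[0][1] if hits else None,
    )


def predict_graph(
    graph: ProteinGraph,
    kb: KnowledgeBase,
    params: PredictorParams,
) -> list[ResiduePrediction]:
    exclude = graph.structure_id if params.exclude_self else None
    return [
        predict_residue(graph, i, kb, params, exclude_structure=exclude)
        for i in range(len(graph))
    ]


def predict_structure(
    structure: Structure,
    kb: KnowledgeBase,
    params: Optional[PredictorParams] = None,
    annotations: Optional[Mapping[ResidueId, ResidueAnnotation]] = None,
    **rasa_kwargs,
) -> list[ResiduePrediction]:
    """Predict every residue of a structure.

    The element spec and feature config always come from the KB header so
    query and KB agree bit-for-bit; ``params`` only contributes n, the
    threshold and self-exclusion. Deterministic for a fixed KB.
    """
    params = params or PredictorParams()
    params = replace(
        params,
        element_kind=kb.element_kind,
        element_param=kb.element_param,
        features=kb.config,
    )
    if annotations is None:
        annotations = annotate_structure(structure, bin_edges=kb.bin_edges,
                                         **rasa_kwargs)
    graph = build_graph(structure, annotations)
    return predict_graph(graph, kb, params)


def predictions_frame(
    predictions: list[ResiduePrediction],
    structure_id: str,
    annotations: Optional[Mapping[ResidueId, ResidueAnnotation]] = None,
) -> pd.DataFrame:
    """Tabulate predictions (one row per residue) for TSV output."""
    rows = []
    for p in predictions:
        chain, seqnum, icode = p.rid
        ann = annotations.get(p.rid) if annotations else None
        rows.append(
            {
                "structure_id": structure_id,
                "chain": chain,
                "seqnum": seqnum,
                "icode": icode,
                "aa": ann.aa if ann else "",
                "rasa": ann.rasa if ann else float("nan"),
                "probability": p.probability,
                "n_interface": p.n_interface,
                "n_retrieved": p.n_retrieved,
                "call": int(p.call),
                "defined": int(p.defined),
            }
        )
    return pd.DataFrame(rows)
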