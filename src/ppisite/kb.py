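"""The fingerprint knowledge base: build, persist, query.

One record per residue of the corpus: the fingerprint of its structural
neighborhood, the exact-match prefilter key of its central features, its
interface label and its provenance (structure id + residue id). Records are
grouped by central key; a query first restricts itself to the group whose
key equals the query residue's (the K_A prefilter) and then ranks by
Hamming distance with *tie-inclusive* nearest-neighbor semantics: every
record tied with the n-th smallest distance is returned, so the result can
exceed n.

On disk the KB is a little-endian binary file: a magic/version header, a
JSON configuration blob (fingerprint length, bit widths, feature lists,
element spec, RASA bin edges), a structure-id table, then the records
grouped by sorted central key. Two builds from identical input produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .elements import extract_element
from .fingerprints import (
    FeatureConfig,
    Fingerprint,
    bit_difference,
    build_fingerprint,
    central_key,
)
from .graph import ProteinGraph, build_graph, degree_stats
from .rasa import ResidueAnnotation, bin_rasa, compute_rasa, derive_bin_edges
from .structures import ResidueId, Structure, label_interfaces

logger = logging.getLogger(__name__)

__all__ = [
    "KBRecord",
    "KnowledgeBase",
    "KBFormatError",
    "annotate_structure",
    "build_kb",
    "save_kb",
    "load_kb",
    "query",
]

MAGIC = b"PPKB"
VERSION = 1


class KBFormatError(ValueError):
    """The knowledge-base file is corrupt or config-incompatible."""


@dataclass(frozen=True)
class KBRecord:
    fingerprint: Fingerprint
    key: tuple[int, ...]
    interface: bool
    structure_id: str
    rid: ResidueId


@dataclass
class KnowledgeBase:
    config: FeatureConfig
    element_kind: str
    element_param: int
    bin_edges: Optional[tuple[float, ...]]
    records: list[KBRecord] = field(default_factory=list)
    groups: dict[tuple[int, ...], list[int]] = field(default_factory=dict)

    def add(self, record: KBRecord) -> None:
        if record.fingerprint.length != self.config.length:
            raise KBFormatError("record fingerprint length differs from KB config")
        if len(record.key) != len(self.config.central_features):
            raise KBFormatError("record key arity differs from KB config")
        self.groups.setdefault(record.key, []).append(len(self.records))
        self.records.append(record)

    @property
    def n_interface(self) -> int:
        return sum(r.interface for r in self.records)

    def structure_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.structure_id, None)
        return list(seen)


def annotate_structure(
    structure: Structure,
    bin_edges: Optional[Sequence[float]] = None,
    labels: Optional[dict[ResidueId, bool]] = None,
    **rasa_kwargs,
) -> dict[ResidueId, ResidueAnnotation]:
    """Per-residue annotations: type, RASA (+ bin when edges given), label."""
    rasa = compute_rasa(structure, **rasa_kwargs)
    out: dict[ResidueId, ResidueAnnotation] = {}
    for res in structure.residues():
        if res.rid not in rasa:
            continue
        value = rasa[res.rid]
        out[res.rid] = ResidueAnnotation(
            aa=res.aa,
            rasa=value,
            rasa_bin=bin_rasa(value, bin_edges) if bin_edges is not None else None,
            interface=labels.get(res.rid) if labels is not None else None,
        )
    return out


def _needs_bins(config: FeatureConfig) -> bool:
    return "rasa_bin" in (*config.neighborhood_features, *config.central_features)


def build_kb(
    structures: Iterable[Structure],
    config: FeatureConfig,
    element_kind: str = "c",
    element_param: int = 12,
    interface_tolerance: float = 0.5,
    **rasa_kwargs,
) -> KnowledgeBase:
    """Build a knowledge base from filtered multi-chain structures.

    RASA is computed first for the whole corpus; when a RASA-bin feature is
    configured, the 10 equal-frequency bin edges are derived from the pooled
    distribution and frozen into the KB so queries bin identically. One
    record is then emitted per graph node of every structure. Deterministic
    given input order.
    """
    structures = list(structures)
    if not structures:
        raise KBFormatError("cannot build a knowledge base from zero structures")

    rasa_all = [compute_rasa(s, **rasa_kwargs) for s in structures]
    edges: Optional[tuple[float, ...]] = None
    if _needs_bins(config):
        pooled = [v for per in rasa_all for v in per.values()]
        edges = derive_bin_edges(pooled)

    kb = KnowledgeBase(
        config=config,
        element_kind=element_kind,
        element_param=element_param,
        bin_edges=edges,
    )
    for s, rasa in zip(structures, rasa_all):
        labels = label_interfaces(s, tolerance=interface_tolerance)
        anns: dict[ResidueId, ResidueAnnotation] = {}
        for res in s.residues():
            if res.rid not in rasa:
                continue
            v = rasa[res.rid]
            anns[res.rid] = ResidueAnnotation(
                aa=res.aa,
                rasa=v,
                rasa_bin=bin_rasa(v, edges) if edges is not None else None,
                interface=labels[res.rid],
            )
        g = build_graph(s, anns)
        stats = degree_stats(g)
        logger.info("%s: %d nodes, mean degree %.2f",
                    s.structure_id, len(g), stats["mean"])
        node_anns = {i: n.annotation for i, n in enumerate(g.nodes)}
        for i, node in enumerate(g.nodes):
            element = extract_element(g, i, element_kind, element_param)
            fp = build_fingerprint(element, node_anns, config)
            kb.add(
                KBRecord(
                    fingerprint=fp,
                    key=central_key(node.annotation, config),
                    interface=bool(node.annotation.interface),
                    structure_id=s.structure_id,
                    rid=node.rid,
                )
            )
    logger.info("KB built: %d records (%d interface / %d non-interface)",
                len(kb.records), kb.n_interface,
                len(kb.records) - kb.n_interface)
    return kb


# ---------------------------------------------------------------- binary IO

def _header_dict(kb: KnowledgeBase) -> dict:
    return {
        "length": kb.config.length,
        "widths": dict(kb.config.widths),
        "neighborhood_features": list(kb.config.neighborhood_features),
        "central_features": list(kb.config.central_features),
        "element_kind": kb.element_kind,
        "element_param": kb.element_param,
        "bin_edges": list(kb.bin_edges) if kb.bin_edges is not None else None,
    }


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the KB to its versioned little-endian binary format."""
    header = json.dumps(_header_dict(kb), sort_keys=True).encode()
    sids = kb.structure_ids()
    sid_index = {s: i for i, s in enumerate(sids)}
    fp_nbytes = (kb.config.length + 7) // 8

    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<HI", VERSION, len(header)))
        fh.write(header)
        fh.write(struct.pack("<I", len(sids)))
        for s in sids:
            raw = s.encode()
            fh.write(struct.pack("<H", len(raw)) + raw)
        fh.write(struct.pack("<I", len(kb.groups)))
        for key in sorted(kb.groups):
            idxs = kb.groups[key]
            fh.write(struct.pack("<B", len(key)))
            fh.write(struct.pack(f"<{len(key)}H", *key))
            fh.write(struct.pack("<I", len(idxs)))
            for i in idxs:
                r = kb.records[i]
                fh.write(r.fingerprint.to_bytes().ljust(fp_nbytes, b"\x00"))
                fh.write(struct.pack("<BI", int(r.interface),
                                     sid_index[r.structure_id]))
                rid_raw = f"{r.rid[0]}|{r.rid[1]}|{r.rid[2]}".encode()
                fh.write(struct.pack("<H", len(rid_raw)) + rid_raw)


def _read_exact(fh, n: int) -> bytes:
    raw = fh.read(n)
    if len(raw) != n:
        raise KBFormatError("truncated knowledge-base file")
    return raw


def load_kb(path: str | Path) -> KnowledgeBase:
    """Read a KB file back; refuses wrong magic or unknown version."""
    with open(path, "rb") as fh:
        if _read_exact(fh, 4) != MAGIC:
            raise KBFormatError(f"{path}: not a knowledge-base file (bad magic)")
        version, hlen = struct.unpack("<HI", _read_exact(fh, 6))
        if version != VERSION:
            raise KBFormatError(
                f"{path}: format version {version}, this build reads {VERSION}"
            )
        try:
            header = json.loads(_read_exact(fh, hlen))
        except json.JSONDecodeError as exc:
            raise KBFormatError(f"{path}: corrupt header: {exc}") from exc
        config = FeatureConfig(
            neighborhood_features=tuple(header["neighborhood_features"]),
            central_features=tuple(header["central_features"]),
            length=header["length"],
            widths=header["widths"],
        )
        kb = KnowledgeBase(
            config=config,
            element_kind=header["element_kind"],
            element_param=header["element_param"],
            bin_edges=tuple(header["bin_edges"])
            if header["bin_edges"] is not None
            else None,
        )
        (n_sids,) = struct.unpack("<I", _read_exact(fh, 4))
        sids = []
        for _ in range(n_sids):
            (slen,) = struct.unpack("<H", _read_exact(fh, 2))
            sids.append(_read_exact(fh, slen).decode())
        fp_nbytes = (config.length + 7) // 8
        (n_groups,) = struct.unpack("<I", _read_exact(fh, 4))
        for _ in range(n_groups):
            (arity,) = struct.unpack("<B", _read_exact(fh, 1))
            key = struct.unpack(f"<{arity}H", _read_exact(fh, 2 * arity))
            if arity != len(config.central_features):
                raise KBFormatError("key arity inconsistent with header config")
            (count,) = struct.unpack("<I", _read_exact(fh, 4))
            for _ in range(count):
                fp = Fingerprint.from_bytes(_read_exact(fh, fp_nbytes),
                                            config.length)
                label, sid_i = struct.unpack("<BI", _read_exact(fh, 5))
                (rlen,) = struct.unpack("<H", _read_exact(fh, 2))
                chain, seq, icode = _read_exact(fh, rlen).decode().split("|")
                kb.add(
                    KBRecord(
                        fingerprint=fp,
                        key=key,
                        interface=bool(label),
                        structure_id=sids[sid_i],
                        rid=(chain, int(seq), icode),
                    )
                )
        if fh.read(1):
            raise KBFormatError(f"{path}: trailing bytes after records")
    return kb


# ------------------------------------------------------------------- query

def query(
    kb: KnowledgeBase,
    query_fp: Fingerprint,
    key: tuple[int, ...],
    n: int = 1,
    exclude_structure: Optional[str] = None,
) -> list[tuple[KBRecord, int]]:
    """Tie-inclusive nearest neighbors of a query fingerprint.

    Candidates are the records whose central key equals ``key`` (minus any
    from ``exclude_structure``); an unseen key falls back to scanning the
    whole KB with a warning. Returns every candidate whose Hamming distance
    is at most the n-th smallest — ties with the n-th distance are all
    included, so the result can be larger than ``n``. Sorted by
    (distance, structure id, residue id) for determinism; the *set* of
    returned records is independent of storage order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if query_fp.length != kb.config.length:
        raise KBFormatError(
            f"query fingerprint length {query_fp.length} does not match "
            f"knowledge base length {kb.config.length}"
        )
    if len(key) != len(kb.config.central_features):
        raise KBFormatError("central key arity does not match KB config")
    idxs = kb.groups.get(key)
    if idxs is None:
        logger.warning("central key %s unseen in KB; falling back to full scan",
                       key)
        idxs = range(len(kb.records))
    candidates = [
        kb.records[i]
        for i in idxs
        if exclude_structure is None
        or kb.records[i].structure_id != exclude_structure
    ]
    if not candidates:
        return []
    scored = [(r, bit_difference(query_fp, r.fingerprint)) for r in candidates]
    distances = sorted(d for _, d in scored)
    cutoff = distances[min(n, len(distances)) - 1]
    hits = [(r, d) for r, d in scored if d <= cutoff]
    hits.sort(key=lambda rd: (rd[1], rd[0].structure_id, rd[0].rid))
    return hits
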