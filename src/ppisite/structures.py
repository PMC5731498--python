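"""Protein structure model: parsing, chain filtering and interface labeling.

A :class:`Structure` is a minimal, format-agnostic view of a protein complex:
chains of residues of atoms, with coordinates and van der Waals radii. Two
residues in *different* chains are interface partners when the van der Waals
surfaces of any two of their atoms come within a tolerance (default 0.5 Å) of
each other; this surface-gap rule defines the ground-truth labels everything
downstream learns from and is evaluated against.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueId",
    "ParseError",
    "EmptyStructureError",
    "load_vdw_table",
    "parse_structure",
    "filter_for_kb",
    "label_interfaces",
    "label_interfaces_brute_force",
]


class ParseError(ValueError):
    """Input file could not be interpreted as a protein structure."""


class EmptyStructureError(ParseError):
    """The file parsed but contained no protein chains."""


# Residue identity follows author numbering: (chain id, sequence number,
# insertion code). Insertion code is "" when absent.
ResidueId = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, position (Å) and vdW radius (Å)."""

    name: str
    element: str
    coord: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.radius > 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


@dataclass
class Residue:
    """One amino acid: identity, one-letter type and its atoms."""

    chain_id: str
    seqnum: int
    icode: str
    aa: str  # one-letter code, upper case
    atoms: list[Atom]

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seqnum, self.icode)

    @property
    def ca(self) -> Optional[tuple[float, float, float]]:
        """Cα coordinates, or None when the atom is missing."""
        for a in self.atoms:
            if a.name == "CA" and a.element == "C":
                return a.coord
        return None


@dataclass
class Structure:
    """A (possibly multi-chain) protein structure.

    ``chains`` maps chain id to an ordered residue list; insertion order is
    the file order and is preserved through every transformation.
    """

    structure_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            for r in residues:
                if r.chain_id != cid:
                    raise ValueError(
                        f"residue {r.rid} filed under chain {cid!r}"
                    )

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


_VDW_CACHE: dict[str, float] | None = None


def load_vdw_table(path: str | Path | None = None) -> dict[str, float]:
    """Element → vdW radius (Å). Bundled Bondi-style table by default.

    The table carries a ``default`` key used for elements not listed.
    """
    global _VDW_CACHE
    if path is None:
        if _VDW_CACHE is None:
            raw = resources.files("ppisite.data").joinpath("vdw_radii.json").read_text()
            _VDW_CACHE = {
                k.upper(): float(v)
                for k, v in json.loads(raw).items()
                if not k.startswith("_") and k != "default"
            }
            _VDW_CACHE["default"] = float(json.loads(raw)["default"])
        return dict(_VDW_CACHE)
    raw = Path(path).read_text()
    table = {
        k.upper(): float(v)
        for k, v in json.loads(raw).items()
        if not k.startswith("_")
    }
    table.setdefault("default", 1.7)
    return table


def _radius_for(element: str, vdw: dict[str, float]) -> float:
    return vdw.get(element.upper(), vdw["default"])


def parse_structure(
    path: str | Path,
    fmt: str = "auto",
    vdw_table: dict[str, float] | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only protein chains are kept: nucleic-acid polymers, waters and chains
    without any mappable amino acid are dropped. Of alternate locations the
    highest-occupancy one is kept (first on ties); only the first model of a
    multi-model file is read. Nonstandard residues with a tabulated parent
    (MSE → M and similar) are mapped to the parent one-letter code; residues
    without a mappable code are skipped with a warning.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    vdw = vdw_table or load_vdw_table()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            one = info.one_letter_code.upper()
            if not ("A" <= one <= "Z") or one == "X":
                logger.warning(
                    "%s: residue %s %s has no one-letter mapping; skipped",
                    path.name, res.name, res.seqid.num,
                )
                continue
            atoms = _collapse_altlocs(res, vdw)
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seqnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    aa=one,
                    atoms=atoms,
                )
            )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise EmptyStructureError(f"{path.name}: no protein chains")
    return Structure(structure_id=path.stem.upper(), chains=chains)


def _collapse_altlocs(res, vdw: dict[str, float]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, first on ties."""
    best: dict[str, object] = {}
    order: list[str] = []
    for atom in res:
        key = atom.name
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occ > best[key].occ:
            best[key] = atom
    out = []
    for key in order:
        a = best[key]
        el = a.element.name if a.element else ""
        out.append(
            Atom(
                name=a.name,
                element=el.upper() or "C",
                coord=(a.pos.x, a.pos.y, a.pos.z),
                radius=_radius_for(el or "C", vdw),
            )
        )
    return out


def filter_for_kb(
    structure: Structure, min_chain_len: int = 5
) -> Optional[Structure]:
    """Apply the corpus filtering rules used for knowledge-base construction.

    Chains shorter than ``min_chain_len`` residues are removed; if fewer than
    two chains remain the whole structure is rejected and ``None`` is
    returned (query-side prediction does not apply the two-chain rule).
    Idempotent.
    """
    kept = {
        cid: residues
        for cid, residues in structure.chains.items()
        if len(residues) >= min_chain_len
    }
    if len(kept) < 2:
        return None
    return Structure(structure_id=structure.structure_id, chains=kept)


def label_interfaces(
    structure: Structure, tolerance: float = 0.5
) -> dict[ResidueId, bool]:
    """Label each residue interface/non-interface by the surface-gap rule.

    A residue is an interface residue iff some atom of it and some atom of a
    *different* chain have ``dist - r_a - r_b <= tolerance``. Candidate atom
    pairs are found with a k-d tree at radius ``2*r_max + tolerance`` so the
    work stays subquadratic; the result is identical to the all-pairs scan
    (see :func:`label_interfaces_brute_force`).
    """
    ids: list[ResidueId] = [r.rid for r in structure.residues()]
    labels: dict[ResidueId, bool] = {rid: False for rid in ids}
    if len(structure.chains) < 2:
        logger.warning(
            "%s: single chain, all residues labeled non-interface",
            structure.structure_id,
        )
        return labels

    coords, radii, chain_of, res_of = [], [], [], []
    for cid, residues in structure.chains.items():
        for r in residues:
            for a in r.atoms:
                coords.append(a.coord)
                radii.append(a.radius)
                chain_of.append(cid)
                res_of.append(r.rid)
    pts = np.asarray(coords)
    rad = np.asarray(radii)
    tree = cKDTree(pts)
    cutoff = 2.0 * float(rad.max()) + tolerance
    for i, j in tree.query_pairs(r=cutoff):
        if chain_of[i] == chain_of[j]:
            continue
        gap = float(np.linalg.norm(pts[i] - pts[j])) - rad[i] - rad[j]
        if gap <= tolerance:
            labels[res_of[i]] = True
            labels[res_of[j]] = True
    return labels


def label_interfaces_brute_force(
    structure: Structure, tolerance: float = 0.5
) -> dict[ResidueId, bool]:
    """O(n²) reference implementation of :func:`label_interfaces`."""
    labels: dict[ResidueId, bool] = {r.rid: False for r in structure.residues()}
    flat = [
        (cid, r.rid, a)
        for cid, residues in structure.chains.items()
        for r in residues
        for a in r.atoms
    ]
    for x, (cid_a, rid_a, a) in enumerate(flat):
        for cid_b, rid_b, b in flat[x + 1 :]:
            if cid_a == cid_b:
                continue
            d = math.dist(a.coord, b.coord)
            if d - a.radius - b.radius <= tolerance:
                labels[rid_a] = True
                labels[rid_b] = True
    return labels
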