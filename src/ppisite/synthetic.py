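"""Deterministic synthetic multi-chain complexes with known interface truth.

The generator emits schematic but geometrically valid structures: each
chain is a Cα trace along the x axis with the canonical 3.8 Å consecutive
spacing (plus a small seeded z jitter so solvent exposure varies), chains
are stacked in parallel rows separated by ``chain_gap`` Å, and every
residue carries one side-chain carbon sphere. At planted contact positions
the side-chain spheres of facing chains reach toward each other so their
van der Waals surface gap is exactly ``contact_gap``; everywhere else
inter-chain atom pairs keep a surface gap of at least ~1.9 Å. Interface
truth is therefore known analytically: exactly the contact residues when
``contact_gap <= 0.5``, and nothing otherwise — and it must coincide with
what the surface-gap labeler recomputes (the central fixture contract).

Geometry is schematic on purpose: every rule of the prediction method
depends only on distances, radii, sequences and labels, none on real
protein conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structures import Atom, Residue, ResidueId, Structure

__all__ = [
    "FixtureSpec",
    "FixtureGeometryError",
    "make_complex",
    "make_kb_corpus",
    "write_fixture_pdb",
    "AA_ALPHABET",
    "SHARED_MOTIF",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CA_SPACING = 3.8
CARBON_RADIUS = 1.7  # both backbone and side-chain spheres are carbon

# Motif planted at the start of the first chain of every corpus structure
# when shared neighborhoods are requested; six distinct residue types.
SHARED_MOTIF = "WYKFMH"

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class FixtureGeometryError(ValueError):
    """The requested fixture geometry cannot keep its margins."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complex.

    ``contact_positions`` are 0-based residue indices at which every
    adjacent chain pair is bridged; ``contact_gap`` is the resulting
    surface gap in Å (<= 0.5 plants interface residues, larger values
    plant near-contacts that must *not* be labeled).
    """

    structure_id: str = "SYN1"
    chain_lengths: tuple[int, ...] = (10, 10)
    sequences: Optional[tuple[str, ...]] = None
    contact_positions: tuple[int, ...] = (5,)
    contact_gap: float = 0.3
    chain_gap: float = 10.0
    jitter: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chain_lengths) < 1:
            raise FixtureGeometryError("need at least one chain")
        if self.sequences is not None:
            if len(self.sequences) != len(self.chain_lengths):
                raise FixtureGeometryError("one sequence per chain required")
            for seq, ln in zip(self.sequences, self.chain_lengths):
                if len(seq) != ln:
                    raise FixtureGeometryError("sequence length mismatch")
        contact_dist = 2 * CARBON_RADIUS + self.contact_gap
        # side chains protrude 1 Å; 2.4 Å of slack keeps non-contact pairs
        # >= ~1.9 Å away from the labeling tolerance
        if self.chain_gap < max(8.0, contact_dist + 2.4):
            raise FixtureGeometryError(
                f"chain_gap {self.chain_gap} too small: chains would overlap "
                "or erode the non-interface margin"
            )
        for p in self.contact_positions:
            if not 0 <= p < min(self.chain_lengths):
                raise FixtureGeometryError(
                    f"contact position {p} outside every chain"
                )
        if not 0.0 <= self.jitter <= 0.3:
            raise FixtureGeometryError("jitter must be within [0, 0.3] Å")


def _chain_ids(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def _random_sequences(spec: FixtureSpec, rng: np.random.Generator) -> tuple[str, ...]:
    return tuple(
        "".join(rng.choice(list(AA_ALPHABET), size=ln)) for ln in spec.chain_lengths
    )


def make_complex(
    spec: FixtureSpec,
    out_path: str | Path | None = None,
) -> tuple[Structure, dict[ResidueId, bool]]:
    """Build one synthetic complex and its analytic interface truth.

    Same spec (same seed included) → identical structure, and identical
    bytes when written to ``out_path``.
    """
    rng = np.random.default_rng(spec.seed)
    sequences = spec.sequences or _random_sequences(spec, rng)
    chain_ids = _chain_ids(len(spec.chain_lengths))
    n_chains = len(chain_ids)
    contact_dist = 2 * CARBON_RADIUS + spec.contact_gap
    reach = (spec.chain_gap - contact_dist) / 2.0

    chains: dict[str, list[Residue]] = {}
    for m, (cid, seq) in enumerate(zip(chain_ids, sequences)):
        y0 = m * spec.chain_gap
        residues = []
        for i, aa in enumerate(seq):
            x = i * CA_SPACING
            z = float(rng.uniform(-spec.jitter, spec.jitter))
            atoms = [Atom("CA", "C", (x, y0, z), CARBON_RADIUS)]
            is_contact = i in spec.contact_positions
            if is_contact and m + 1 < n_chains:
                # reach toward the chain above; meets its partner at the
                # planted surface gap exactly (z pinned to 0)
                atoms.append(Atom("CB", "C", (x, y0 + reach, 0.0), CARBON_RADIUS))
            if is_contact and m > 0:
                name = "CG" if len(atoms) == 2 else "CB"
                atoms.append(Atom(name, "C", (x, y0 - reach, 0.0), CARBON_RADIUS))
            if len(atoms) == 1:
                side = 1.0 if m + 1 < n_chains else -1.0
                atoms.append(Atom("CB", "C", (x, y0 + side, z), CARBON_RADIUS))
            residues.append(
                Residue(chain_id=cid, seqnum=i + 1, icode="", aa=aa, atoms=atoms)
            )
        chains[cid] = residues
    structure = Structure(structure_id=spec.structure_id, chains=chains)

    interface_planted = spec.contact_gap <= 0.5 and n_chains >= 2
    truth: dict[ResidueId, bool] = {}
    for res in structure.residues():
        idx = res.seqnum - 1
        truth[res.rid] = bool(interface_planted and idx in spec.contact_positions)

    if out_path is not None:
        write_fixture_pdb(structure, out_path)
    return structure, truth


def write_fixture_pdb(structure: Structure, path: str | Path) -> None:
    """Write a fixture structure as a standard PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = THREE_LETTER[res.aa]
            g_res.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            for atom in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element)
                g_atom.pos = gemmi.Position(*atom.coord)
                g_atom.occ = 1.0
                g_atom.b_iso = 0.0
                g_res.add_atom(g_atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _canonical_triple(a: str, b: str, c: str) -> tuple[str, str, str]:
    # a triple read forwards or backwards hashes to the same pair set
    lo, hi = sorted((a, c))
    return (b, lo, hi)


def make_kb_corpus(
    n_complexes: int,
    seed: int = 0,
    chain_lengths: tuple[int, ...] = (12, 12),
    shared_motif: bool = False,
    contact_gap: float = 0.3,
) -> list[tuple[Structure, dict[ResidueId, bool]]]:
    """A seeded corpus of complexes with controlled neighborhood overlap.

    With ``shared_motif`` False, sequences are sampled so that every
    consecutive residue triple is unique across the whole corpus (up to
    reversal, which hashes identically) and chain-terminal letter pairs
    differ — small (c2-scale) neighborhoods then collide neither within nor
    across structures. With ``shared_motif`` True, every structure's first
    chain instead starts with the fixed motif ``SHARED_MOTIF``, planting
    identical local neighborhoods in all structures so cross-structure
    exact fingerprint matches are guaranteed.
    """
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, str, str]] = set()
    alphabet = list(AA_ALPHABET)
    contact = min(chain_lengths) - 3  # away from chain starts and the motif

    def sample_chain(length: int, motif: str = "") -> str:
        seq = list(motif)
        while len(seq) < length:
            i = len(seq)
            for _ in range(200):
                x = str(rng.choice(alphabet))
                if i == 1 and x == seq[0]:
                    continue
                if i == length - 1 and x == seq[-1]:
                    continue
                if i >= 2:
                    trip = _canonical_triple(seq[i - 2], seq[i - 1], x)
                    if trip in seen:
                        continue
                    seen.add(trip)
                seq.append(x)
                break
            else:  # pragma: no cover - 20-letter alphabet never exhausts
                raise RuntimeError("could not sample a fresh residue triple")
        return "".join(seq)

    corpus = []
    for c in range(n_complexes):
        motif = SHARED_MOTIF if shared_motif else ""
        sequences = tuple(
            sample_chain(ln, motif if ci == 0 else "")
            for ci, ln in enumerate(chain_lengths)
        )
        spec = FixtureSpec(
            structure_id=f"SYN{c + 1:03d}",
            chain_lengths=chain_lengths,
            sequences=sequences,
            contact_positions=(contact,),
            contact_gap=contact_gap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        corpus.append(make_complex(spec))
    return corpus
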