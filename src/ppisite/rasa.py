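"""Relative accessible surface area (RASA) and its equal-frequency binning.

RASA is a residue's solvent-accessible surface area divided by the maximal
reference exposure of its residue type; values are unitless fractions,
usually in [0, 1] but allowed to exceed 1 slightly for unusually extended
conformations. SASA is computed per chain *in isolation* by default — the
complex context would drive interface residues toward RASA ≈ 0 and leak the
label the method is trying to predict.

Bin edges for the 10 equal-frequency RASA bins are the empirical deciles of
a knowledge base's pooled RASA distribution; they are persisted with the
knowledge base so queries bin with exactly the same edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .structures import Residue, ResidueId, Structure

__all__ = [
    "ResidueAnnotation",
    "DegenerateDistributionError",
    "load_max_asa_table",
    "compute_sasa",
    "compute_rasa",
    "derive_bin_edges",
    "bin_rasa",
    "N_BINS",
]

N_BINS = 10


class DegenerateDistributionError(ValueError):
    """The RASA sample is too concentrated to define 10 nonempty bins."""


@dataclass
class ResidueAnnotation:
    """Per-residue features entering the graph and the fingerprints."""

    aa: str
    rasa: float
    rasa_bin: Optional[int] = None
    interface: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.rasa < 0:
            raise ValueError("RASA must be non-negative")
        if self.rasa_bin is not None and not 0 <= self.rasa_bin < N_BINS:
            raise ValueError("RASA bin index out of range")


_MAX_ASA_CACHE: dict[str, float] | None = None


def load_max_asa_table(path: str | Path | None = None) -> dict[str, float]:
    """One-letter residue type → theoretical maximal ASA (Å²)."""
    global _MAX_ASA_CACHE
    if path is None:
        if _MAX_ASA_CACHE is None:
            raw = resources.files("ppisite.data").joinpath("max_asa.json").read_text()
            _MAX_ASA_CACHE = {
                k: float(v) for k, v in json.loads(raw).items() if not k.startswith("_")
            }
        return dict(_MAX_ASA_CACHE)
    raw = Path(path).read_text()
    return {k: float(v) for k, v in json.loads(raw).items() if not k.startswith("_")}


def _chain_sasa(
    residues: Sequence[Residue], probe_radius: float, point_number: int
) -> list[float]:
    """Shrake-Rupley SASA (Å²) per residue of one isolated chain."""
    import biotite.structure as struc

    n_atoms = sum(len(r.atoms) for r in residues)
    arr = struc.AtomArray(n_atoms)
    radii = np.empty(n_atoms)
    res_index = np.empty(n_atoms, dtype=int)
    i = 0
    for ri, res in enumerate(residues):
        for atom in res.atoms:
            arr.coord[i] = atom.coord
            arr.chain_id[i] = res.chain_id[:4]
            arr.res_id[i] = res.seqnum
            arr.ins_code[i] = res.icode[:1]
            arr.res_name[i] = "UNK"
            arr.atom_name[i] = atom.name[:6]
            arr.element[i] = atom.element[:2]
            radii[i] = atom.radius
            res_index[i] = ri
            i += 1
    per_atom = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=radii,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    out = np.zeros(len(residues))
    np.add.at(out, res_index, per_atom)
    return out.tolist()


def compute_rasa(
    structure: Structure,
    probe_radius: float = 1.4,
    point_number: int = 300,
    max_asa_table: Mapping[str, float] | None = None,
    rasa_context: str = "chain",
    on_missing_reference: str = "fallback",
    fallback_reference: float = 200.0,
) -> dict[ResidueId, float]:
    """RASA per residue: SASA / reference maximal ASA, clipped to >= 0.

    ``rasa_context`` selects whether SASA sees each chain in isolation
    (default, label-safe) or the whole complex. Residue types missing from
    the reference table are skipped (``on_missing_reference="skip"``) or
    normalised by ``fallback_reference`` (default).
    """
    if rasa_context not in ("chain", "complex"):
        raise ValueError("rasa_context must be 'chain' or 'complex'")
    table = max_asa_table or load_max_asa_table()
    out: dict[ResidueId, float] = {}

    if rasa_context == "chain":
        groups = [list(res) for res in structure.chains.values()]
    else:
        groups = [list(structure.residues())]
    for residues in groups:
        sasas = _chain_sasa(residues, probe_radius, point_number)
        for res, sasa in zip(residues, sasas):
            ref = table.get(res.aa)
            if ref is None:
                if on_missing_reference == "skip":
                    continue
                ref = fallback_reference
            out[res.rid] = max(0.0, sasa / ref)
    return out


def derive_bin_edges(rasa_values: Iterable[float]) -> tuple[float, ...]:
    """The 9 interior decile cut points of a pooled RASA sample.

    Bins are left-closed/right-open except the last, which absorbs
    everything above the ninth edge. Raises
    :class:`DegenerateDistributionError` when the sample cannot support 10
    distinct bins.
    """
    values = np.asarray(sorted(rasa_values), dtype=float)
    if values.size < N_BINS:
        raise DegenerateDistributionError(
            f"need at least {N_BINS} RASA values, got {values.size}"
        )
    if np.unique(values).size < N_BINS:
        raise DegenerateDistributionError(
            "fewer than 10 distinct RASA values; equal-frequency bins undefined"
        )
    qs = np.arange(1, N_BINS) / N_BINS
    edges = np.quantile(values, qs)
    if np.unique(edges).size < len(edges):
        raise DegenerateDistributionError(
            "tied deciles: distribution too concentrated for 10 bins"
        )
    return tuple(float(e) for e in edges)


def bin_rasa(value: float, edges: Sequence[float]) -> int:
    """Bin index 0..9 for a RASA value under left-closed/right-open edges.

    A value exactly on an edge falls in the higher bin; anything above the
    last edge maps to bin 9.
    """
    if value < 0:
        raise ValueError("RASA must be non-negative")
    if list(edges) != sorted(set(edges)):
        raise ValueError("bin edges must be strictly increasing")
    # 'right' side => edge value itself belongs to the higher bin
    return int(np.searchsorted(np.asarray(edges), value, side="right"))
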