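"""Pairwise bit fingerprints of structural elements.

Each structural element is hashed into a fixed-length bit array in the
style of atom-pair chemical fingerprints, transplanted from atoms to
residues: for every unordered pair of distinct member residues, the two
residues' feature codes and their graph distance are packed into one
integer index ``i`` by fixed-width bit concatenation, and bit ``i mod l``
of the fingerprint is set. Fingerprints are compared by Hamming distance
(number of differing bits); smaller means more similar.

Hashing is lossy by design: non-isomorphic elements may collide on a
fingerprint, and no de-duplication is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .elements import StructuralElement, element_graph_distance
from .rasa import ResidueAnnotation

__all__ = [
    "FeatureConfig",
    "Fingerprint",
    "encode_feature",
    "encode_pair",
    "build_fingerprint",
    "bit_difference",
    "FEATURE_NAMES",
    "DEFAULT_WIDTHS",
]

FEATURE_NAMES = ("aa_type", "rasa_bin")

# Bit widths: aa_type codes run 1..25 (alphabet position), rasa_bin 0..9,
# graph distance 0..D_max with D_max = 2^width - 1.
DEFAULT_WIDTHS = {"aa_type": 5, "rasa_bin": 4, "distance": 5}


@dataclass(frozen=True)
class FeatureConfig:
    """Which features label the neighborhood pairs and the central residue.

    ``neighborhood_features`` enter the pair encoding inside fingerprints;
    ``central_features`` form the exact-match prefilter key of the central
    residue. The two lists are independent. ``length`` is the fingerprint
    bit length; 63, 255 and 1023 are the usual presets.
    """

    neighborhood_features: tuple[str, ...] = ("aa_type",)
    central_features: tuple[str, ...] = ("aa_type",)
    length: int = 1023
    widths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_WIDTHS)
    )

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fingerprint length must be >= 1")
        for f in (*self.neighborhood_features, *self.central_features):
            if f not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {f!r}")
        if not self.neighborhood_features:
            raise ValueError("need at least one neighborhood feature")
        if self.widths["aa_type"] < 5 or self.widths["rasa_bin"] < 4:
            raise ValueError("feature bit-width too small for its code range")

    @property
    def d_max(self) -> int:
        return (1 << self.widths["distance"]) - 1


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit array stored as an arbitrary-precision int."""

    bits: int
    length: int

    def __post_init__(self) -> None:
        if self.bits < 0 or self.bits >> self.length:
            raise ValueError("bits outside declared fingerprint length")

    @property
    def popcount(self) -> int:
        return self.bits.bit_count()

    def to_bytes(self) -> bytes:
        return self.bits.to_bytes((self.length + 7) // 8, "little")

    @classmethod
    def from_bytes(cls, raw: bytes, length: int) -> "Fingerprint":
        return cls(bits=int.from_bytes(raw, "little"), length=length)


def encode_feature(annotation: ResidueAnnotation, feature: str) -> int:
    """Small-integer code of one residue feature.

    ``aa_type`` is the 1-based position of the one-letter code in the Latin
    alphabet ('A' → 1 … 'Y' → 25); ``rasa_bin`` is the bin index 0..9.
    """
    if feature == "aa_type":
        aa = annotation.aa
        if len(aa) != 1 or not "A" <= aa <= "Z":
            raise ValueError(f"unencodable amino-acid letter {aa!r}")
        return ord(aa) - ord("A") + 1
    if feature == "rasa_bin":
        if annotation.rasa_bin is None:
            raise ValueError("rasa_bin requested but annotation has no bin")
        return annotation.rasa_bin
    raise ValueError(f"unknown feature {feature!r}")


def _codes(annotation: ResidueAnnotation, features: Sequence[str]) -> tuple[int, ...]:
    return tuple(encode_feature(annotation, f) for f in features)


def encode_pair(
    codes_a: Sequence[int],
    codes_b: Sequence[int],
    d: int,
    config: FeatureConfig,
) -> int:
    """Pack two residues' feature codes and their graph distance into one int.

    Layout (big-endian concatenation of fixed-width fields):
    ``g1_A .. gn_A | d | g1_B .. gn_B``. The pair is canonicalized first —
    the lexicographically smaller code tuple plays the role of A — so the
    index is invariant to argument order.
    """
    a, b = tuple(codes_a), tuple(codes_b)
    if len(a) != len(b) or len(a) != len(config.neighborhood_features):
        raise ValueError("code tuple arity does not match feature config")
    if a > b:
        a, b = b, a
    if not 0 <= d <= config.d_max:
        raise ValueError(f"distance {d} outside 0..{config.d_max}")
    widths = [config.widths[f] for f in config.neighborhood_features]
    out = 0
    for code, w in zip(a, widths):
        if code >> w:
            raise ValueError(f"feature code {code} overflows {w} bits")
        out = (out << w) | code
    out = (out << config.widths["distance"]) | d
    for code, w in zip(b, widths):
        if code >> w:
            raise ValueError(f"feature code {code} overflows {w} bits")
        out = (out << w) | code
    return out


def build_fingerprint(
    element: StructuralElement,
    annotations: Mapping[int, ResidueAnnotation],
    config: FeatureConfig,
) -> Fingerprint:
    """Hash every unordered member pair of an element into one bit array.

    The center is an ordinary member; a single-node element has no pairs
    and yields the all-zero fingerprint. Deterministic: member iteration
    order cannot affect the result because pair indices are canonicalized.
    """
    bits = 0
    members = sorted(element.members)
    code_of = {
        m: _codes(annotations[m], config.neighborhood_features) for m in members
    }
    for x in range(len(members)):
        for y in range(x + 1, len(members)):
            a, b = members[x], members[y]
            d = element_graph_distance(element, a, b, d_max=config.d_max)
            i = encode_pair(code_of[a], code_of[b], d, config)
            bits |= 1 << (i % config.length)
    return Fingerprint(bits=bits, length=config.length)


def central_key(
    annotation: ResidueAnnotation, config: FeatureConfig
) -> tuple[int, ...]:
    """Exact-match prefilter key of the central residue."""
    return _codes(annotation, config.central_features)


def bit_difference(f1: Fingerprint, f2: Fingerprint) -> int:
    """Hamming distance between two equal-length fingerprints."""
    if f1.length != f2.length:
        raise ValueError(
            f"fingerprint length mismatch: {f1.length} vs {f2.length}"
        )
    return (f1.bits ^ f2.bits).bit_count()
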