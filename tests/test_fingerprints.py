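"""Pairwise fingerprint encoding and Hamming comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppisite.elements import extract_c_neighborhood, extract_d_neighborhood
from ppisite.fingerprints import (
    FeatureConfig,
    Fingerprint,
    bit_difference,
    build_fingerprint,
    encode_feature,
    encode_pair,
)
from ppisite.rasa import ResidueAnnotation

from conftest import manual_graph, random_geometric_graph


class TestEncodeFeature:
    @pytest.mark.parametrize("aa, code", [("A", 1), ("C", 3), ("Y", 25)])
    def test_alphabet_position(self, aa, code):
        assert encode_feature(ResidueAnnotation(aa=aa, rasa=0.5), "aa_type") == code

    def test_rasa_bin_passthrough(self):
        ann = ResidueAnnotation(aa="A", rasa=0.5, rasa_bin=7)
        assert encode_feature(ann, "rasa_bin") == 7

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            encode_feature(ResidueAnnotation(aa="?", rasa=0.5), "aa_type")

    def test_missing_bin_rejected(self):
        with pytest.raises(ValueError):
            encode_feature(ResidueAnnotation(aa="A", rasa=0.5), "rasa_bin")


class TestEncodePair:
    CFG = FeatureConfig(neighborhood_features=("aa_type",),
                        widths={"aa_type": 5, "rasa_bin": 4, "distance": 5})

    def test_concatenation_arithmetic(self):
        # widths (5,5,5): i = a*2^10 + d*2^5 + b
        assert encode_pair((1,), (3,), 2, self.CFG) == 1 * 2**10 + 2 * 2**5 + 3

    def test_symmetric_after_canonicalization(self):
        assert encode_pair((3,), (1,), 2, self.CFG) == encode_pair((1,), (3,), 2, self.CFG)

    def test_all_zero_codes(self):
        assert encode_pair((0,), (0,), 0, self.CFG) == 0

    def test_code_overflow_rejected(self):
        with pytest.raises(ValueError):
            encode_pair((40,), (1,), 0, self.CFG)

    def test_distance_overflow_rejected(self):
        with pytest.raises(ValueError):
            encode_pair((1,), (1,), 32, self.CFG)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.integers(1, 25), b=st.integers(1, 25), d=st.integers(0, 31))
    def test_symmetry_property(self, a, b, d):
        assert encode_pair((a,), (b,), d, self.CFG) == encode_pair((b,), (a,), d, self.CFG)


class TestBuildFingerprint:
    def test_single_node_element_is_all_zero(self):
        g = manual_graph([], coords=[(0, 0, 0)])
        e = extract_c_neighborhood(g, 0, 0)
        anns = {0: ResidueAnnotation(aa="A", rasa=0.5)}
        fp = build_fingerprint(e, anns, FeatureConfig(length=1023))
        assert fp.bits == 0 and fp.popcount == 0

    def test_modular_hash_sets_expected_bit(self):
        # rasa_bin feature, widths (4,5,4): pair (0, d=1, 3) -> i = 1*16+3 = 19;
        # with l = 16 that is l + 3, so exactly bit 3 must be set.
        cfg = FeatureConfig(neighborhood_features=("rasa_bin",), length=16)
        g = manual_graph([(0, 1)], coords=[(0, 0, 0), (3, 0, 0)])
        e = extract_d_neighborhood(g, 0, 1)
        anns = {0: ResidueAnnotation(aa="A", rasa=0.1, rasa_bin=0),
                1: ResidueAnnotation(aa="A", rasa=0.9, rasa_bin=3)}
        fp = build_fingerprint(e, anns, cfg)
        assert fp.bits == 1 << 3

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        g = random_geometric_graph(rng)
        anns = {i: ResidueAnnotation(aa="ACDEF"[i % 5], rasa=0.5)
                for i in range(len(g))}
        cfg = FeatureConfig(length=255)
        e = extract_c_neighborhood(g, 0, 6)
        assert build_fingerprint(e, anns, cfg) == build_fingerprint(e, anns, cfg)

    def test_invariant_under_node_relabeling(self):
        """Isomorphic elements with the same feature labels hash identically."""
        rng = np.random.default_rng(4)
        g = random_geometric_graph(rng, n_max=25)
        letters = [str(x) for x in rng.choice(list("ACDEFGHIKL"), size=len(g))]
        cfg = FeatureConfig(length=255)
        perm = rng.permutation(len(g))
        inv = np.empty(len(g), dtype=int)
        inv[perm] = np.arange(len(g))
        relabeled = manual_graph(
            [(int(inv[u]), int(inv[v])) for u, v in g.g.edges],
            coords=[tuple(g.coords[int(i)]) for i in perm],
            letters="".join(letters[int(i)] for i in perm),
        )
        for center in range(min(len(g), 8)):
            e1 = extract_c_neighborhood(g, center, 5)
            e2 = extract_c_neighborhood(relabeled, int(inv[center]), 5)
            anns1 = {i: ResidueAnnotation(aa=letters[i], rasa=0.5)
                     for i in e1.members}
            anns2 = {i: ResidueAnnotation(aa=letters[int(perm[i])], rasa=0.5)
                     for i in e2.members}
            assert build_fingerprint(e1, anns1, cfg) == build_fingerprint(e2, anns2, cfg)

    def test_popcount_bounded_by_pair_count(self):
        rng = np.random.default_rng(12)
        g = random_geometric_graph(rng)
        anns = {i: ResidueAnnotation(aa="W", rasa=0.5) for i in range(len(g))}
        cfg = FeatureConfig(length=63)
        for center in range(min(len(g), 10)):
            e = extract_c_neighborhood(g, center, 6)
            m = len(e.members)
            fp = build_fingerprint(e, anns, cfg)
            assert fp.popcount <= m * (m - 1) // 2


class TestBitDifference:
    def test_identical_is_zero(self):
        f = Fingerprint(bits=0b10110, length=5)
        assert bit_difference(f, f) == 0

    def test_complement_is_length(self):
        l = 16
        f = Fingerprint(bits=0b1010101010101010, length=l)
        g = Fingerprint(bits=f.bits ^ ((1 << l) - 1), length=l)
        assert bit_difference(f, g) == l

    def test_counts_differing_positions(self):
        f = Fingerprint(bits=0b10110, length=5)
        g = Fingerprint(bits=0b00111, length=5)
        assert bit_difference(f, g) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bit_difference(Fingerprint(0, 63), Fingerprint(0, 255))

    @settings(max_examples=300, derandomize=True)
    @given(st.tuples(*[st.integers(0, 2**63 - 1)] * 3))
    def test_metric_axioms(self, bits):
        a, b, c = (Fingerprint(x, 63) for x in bits)
        assert bit_difference(a, b) == bit_difference(b, a)
        assert (bit_difference(a, b) == 0) == (a.bits == b.bits)
        assert bit_difference(a, c) <= bit_difference(a, b) + bit_difference(b, c)


class TestFeatureConfig:
    def test_rejects_too_narrow_widths(self):
        with pytest.raises(ValueError):
            FeatureConfig(widths={"aa_type": 4, "rasa_bin": 4, "distance": 5})

    def test_rejects_unknown_feature(self):
        with pytest.raises(ValueError):
            FeatureConfig(neighborhood_features=("charge",))

    def test_d_max_from_distance_width(self):
        assert FeatureConfig().d_max == 31
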