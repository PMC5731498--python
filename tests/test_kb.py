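"""Knowledge base: build, binary round-trip, tie-inclusive kNN query."""

import numpy as np
import pytest

from ppisite.fingerprints import FeatureConfig, Fingerprint, bit_difference
from ppisite.kb import (
    KBFormatError,
    KBRecord,
    KnowledgeBase,
    build_kb,
    load_kb,
    query,
    save_kb,
)


def _kb_with_distances(distances, length=16, key=(1,), interface=None):
    """A KB whose records sit at the given Hamming distances from fp=0."""
    cfg = FeatureConfig(length=length)
    kb = KnowledgeBase(config=cfg, element_kind="c", element_param=2,
                       bin_edges=None)
    for i, d in enumerate(distances):
        bits = (1 << d) - 1  # d low bits set -> popcount d
        kb.add(KBRecord(
            fingerprint=Fingerprint(bits=bits, length=length),
            key=key,
            interface=bool(interface[i]) if interface else (i % 2 == 0),
            structure_id=f"S{i}",
            rid=("A", i + 1, ""),
        ))
    return kb, Fingerprint(bits=0, length=length)


class TestQuery:
    def test_self_match_at_distance_zero(self):
        kb, q = _kb_with_distances([0, 3, 5])
        hits = query(kb, q, (1,), n=1)
        assert len(hits) == 1 and hits[0][1] == 0

    def test_ties_with_nth_distance_all_included(self):
        kb, q = _kb_with_distances([0, 2, 2, 2, 5])
        hits = query(kb, q, (1,), n=2)
        assert len(hits) == 4
        assert sorted(d for _, d in hits) == [0, 2, 2, 2]

    def test_result_independent_of_insertion_order(self):
        rng = np.random.default_rng(0)
        distances = [0, 2, 2, 2, 5, 7, 7, 1]
        base_hits = None
        for _ in range(5):
            order = rng.permutation(len(distances))
            kb = KnowledgeBase(config=FeatureConfig(length=16),
                               element_kind="c", element_param=2, bin_edges=None)
            for i in order:
                d = distances[i]
                kb.add(KBRecord(Fingerprint((1 << d) - 1, 16), (1,),
                                i % 2 == 0, f"S{i}", ("A", int(i) + 1, "")))
            hits = {(r.structure_id, r.rid, d)
                    for r, d in query(kb, Fingerprint(0, 16), (1,), n=3)}
            if base_hits is None:
                base_hits = hits
            assert hits == base_hits

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(77)
        cfg = FeatureConfig(length=63)
        kb = KnowledgeBase(config=cfg, element_kind="c", element_param=2,
                           bin_edges=None)
        records = []
        for i in range(200):
            fp = Fingerprint(int(rng.integers(0, 2**63)), 63)
            rec = KBRecord(fp, (int(rng.integers(1, 4)),), bool(rng.integers(2)),
                           f"S{i % 7}", ("A", i + 1, ""))
            kb.add(rec)
            records.append(rec)
        for trial in range(20):
            q = Fingerprint(int(rng.integers(0, 2**63)), 63)
            key = (int(rng.integers(1, 4)),)
            n = int(rng.integers(1, 6))
            hits = query(kb, q, key, n=n)
            # oracle: independent full sort over the key group
            cand = [(bit_difference(q, r.fingerprint), r) for r in records
                    if r.key == key]
            cand.sort(key=lambda x: x[0])
            cutoff = cand[min(n, len(cand)) - 1][0]
            expected = {(r.structure_id, r.rid) for d, r in cand if d <= cutoff}
            assert {(r.structure_id, r.rid) for r, _ in hits} == expected

    def test_prefilter_soundness(self):
        kb, q = _kb_with_distances([1, 2, 3], key=(4,))
        kb.add(KBRecord(Fingerprint(0, 16), (9,), True, "SX", ("B", 1, "")))
        hits = query(kb, q, (4,), n=5)
        assert all(r.key == (4,) for r, _ in hits)

    def test_exclusion_removes_structure_records(self):
        kb, q = _kb_with_distances([0, 1, 2])
        hits = query(kb, q, (1,), n=3, exclude_structure="S0")
        assert all(r.structure_id != "S0" for r, _ in hits)
        assert hits[0][1] == 1

    def test_unseen_key_falls_back_to_full_scan(self, caplog):
        kb, q = _kb_with_distances([0, 1])
        with caplog.at_level("WARNING"):
            hits = query(kb, q, (12,), n=1)
        assert len(hits) == 1 and hits[0][1] == 0

    def test_length_mismatch_refused(self):
        kb, _ = _kb_with_distances([0, 1])
        with pytest.raises(KBFormatError):
            query(kb, Fingerprint(0, 1023), (1,), n=1)

    def test_empty_after_exclusion(self):
        kb, q = _kb_with_distances([3])
        assert query(kb, q, (1,), n=1, exclude_structure="S0") == []


class TestBuild:
    def test_one_record_per_graph_node(self, corpus6, kb_c2):
        total = sum(s.n_residues for s, _ in corpus6)
        assert len(kb_c2.records) == total

    def test_empty_input_rejected(self):
        with pytest.raises(KBFormatError):
            build_kb([], FeatureConfig())

    def test_bin_edges_derived_only_when_needed(self, corpus6):
        cfg = FeatureConfig(neighborhood_features=("aa_type", "rasa_bin"))
        kb = build_kb([s for s, _ in corpus6][:3], cfg,
                      element_kind="c", element_param=2)
        assert kb.bin_edges is not None and len(kb.bin_edges) == 9


class TestRoundTrip:
    def test_save_load_lossless(self, kb_c2, tmp_path):
        path = tmp_path / "kb.bin"
        save_kb(kb_c2, path)
        back = load_kb(path)
        assert back.config == kb_c2.config
        assert back.element_kind == kb_c2.element_kind
        assert back.element_param == kb_c2.element_param
        assert back.bin_edges == kb_c2.bin_edges
        assert len(back.records) == len(kb_c2.records)
        orig = {(r.structure_id, r.rid): (r.fingerprint, r.key, r.interface)
                for r in kb_c2.records}
        new = {(r.structure_id, r.rid): (r.fingerprint, r.key, r.interface)
               for r in back.records}
        assert orig == new

    def test_two_identical_builds_byte_stable(self, corpus6, tmp_path):
        cfg = FeatureConfig(length=255)
        paths = []
        for tag in ("a", "b"):
            kb = build_kb([s for s, _ in corpus6], cfg,
                          element_kind="c", element_param=2)
            p = tmp_path / f"{tag}.bin"
            save_kb(kb, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_truncated_file_rejected(self, kb_c2, tmp_path):
        path = tmp_path / "kb.bin"
        save_kb(kb_c2, path)
        raw = path.read_bytes()
        (tmp_path / "trunc.bin").write_bytes(raw[: len(raw) // 2])
        with pytest.raises(KBFormatError):
            load_kb(tmp_path / "trunc.bin")

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.bin"
        path.write_bytes(b"NOPE" + b"\x00" * 50)
        with pytest.raises(KBFormatError):
            load_kb(path)

    def test_mismatched_query_length_refused_after_reload(self, kb_c2, tmp_path):
        path = tmp_path / "kb.bin"
        save_kb(kb_c2, path)
        back = load_kb(path)  # l = 1023
        with pytest.raises(KBFormatError):
            query(back, Fingerprint(0, 63), (1,), n=1)
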