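# Methods notes

## Model and assumptions

`ppisite` is a retrieval-based (instance-based) classifier. It assumes that
the local structural context of a residue — which residue types surround
it, and how they are arranged — carries most of the signal about whether
the residue sits in a protein–protein interface, and that a sufficiently
large corpus of known complexes contains near-duplicates of almost any
query neighborhood. There is no parametric model and no training step;
"learning" is building the knowledge base, and prediction is
nearest-neighbor voting over hashed neighborhood patterns.

The pipeline rests on three definitions:

* **Contact graph.** Nodes are amino acids; an edge joins residues whose
  Cα atoms are at most 6 Å apart. The comparison is an inclusive `<=` with
  no epsilon: 6.0 Å is an edge, 6.000001 Å is not. Edges may cross chain
  boundaries within a complex (`edges_across_chains`, default on), since
  the physics of an interface does not respect chain labels.
* **Interface label.** A residue is interface when the van der Waals
  surface gap `dist(a,b) − r(a) − r(b)` between one of its atoms and any
  atom of a *different* chain is ≤ 0.5 Å. Labels are computed against the
  union of all other chains, not per chain pair. vdW radii come from a
  bundled Bondi-style element table (`data/vdw_radii.json`), overridable;
  labels depend on this table, which is why it is data, not code.
* **RASA.** Residue SASA divided by a bundled theoretical maximal ASA per
  residue type (`data/max_asa.json`, Tien-style Gly-X-Gly values). SASA is
  Shrake–Rupley (biotite backend) with probe radius 1.4 Å and a
  300-point Fibonacci mesh per atom, computed on each chain *in
  isolation* by default (`rasa_context: chain`). Computing it on the
  complex would push interface residues toward RASA ≈ 0 and leak the very
  label being predicted; the complex mode exists as an explicit option.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| contact cutoff | 6.0 Å | Cα distance defining graph edges |
| interface tolerance | 0.5 Å | vdW surface gap defining ground truth |
| element kind / size | c₁₂ | k-nearest neighborhoods give uniform element sizes; d_i sizes fluctuate with local density |
| fingerprint length *l* | 1023 bits | longer = fewer hash collisions at linear cost in comparison time; 63/255/1023 are the usual presets |
| features | aa_type (both sides) | RASA bins are supported but add hash-space volume and correlate strongly with node degree |
| bit widths | aa 5, rasa 4, distance 5 | smallest widths covering the code ranges; D_max = 2⁵−1 = 31 |
| n (neighbors) | 1 | tie-inclusive, so n = 1 can still return many records |
| threshold τ | 0.5175 | strict comparison p > τ; with n = 1 and no ties p ∈ {0,1}, so τ only matters for tie splits |
| min chain length | 5 residues | corpus filter; complexes keeping < 2 chains are rejected for KB use |
| surface rules | RASA ≥ 0.05 or > 0 | evaluation-time masks, dataset-dependent |

## Numerical and design choices

* **Pair canonicalization.** The pair index concatenates g^A ‖ d ‖ g^B,
  which is asymmetric; the lexicographically smaller code tuple always
  plays A. Without this, the same neighborhood could hash differently
  depending on iteration order.
* **All pairs, center included.** Every unordered pair of distinct element
  members is encoded; the center is not treated specially. A single-node
  element (c₀/d₀) has no pairs and yields the all-zero fingerprint.
* **Graph distance inside the element.** Distances for the pair encoding
  are shortest paths in the element's induced subgraph — the element is
  the stored, self-contained pattern. Pairs split across components of a
  disconnected c_k element get the sentinel D_max = 31, which also clamps
  longer paths, keeping the encoding total and bounded.
* **c_k ties.** Exact Euclidean ties at the k-th slot break by node index,
  deterministically. This changes the element, so it is pinned, not left
  to sort stability.
* **Hashing.** Bit position is literally `i mod l` — no secondary hash.
  Collisions (non-isomorphic elements sharing a fingerprint) are tolerated
  by design and no de-duplication or isomorphism filtering is attempted.
* **Tie-inclusive kNN.** Retrieval returns every record whose Hamming
  distance is ≤ the n-th smallest, so |S| ≥ n when records exist; results
  are a set, independent of storage order. An unseen central key falls
  back to scanning the whole KB (with a warning) rather than returning no
  prediction. Search is an exhaustive popcount scan within the key group;
  at any scale where this package is used, that is instant, and any
  accelerated index would be required to match the scan exactly.
* **Probability and call.** p = |I|/|S|; the call is strict, p > τ. An
  empty S (e.g. a single-structure KB queried with self-exclusion) yields
  an undefined probability: the residue is reported flagged, call
  non-interface.
* **MCC.** Computed with exact integer arithmetic under the radical; any
  zero factor in the denominator defines MCC = 0 (the random-prediction
  convention). Confusion counts pool residues across a dataset by default;
  per-protein averaging is a different statistic and is available
  separately, because published comparisons are ambiguous about which is
  used.
* **KB file format.** Little-endian: magic `PPKB`, version, a JSON header
  (fingerprint length, bit widths, feature lists, element spec, RASA bin
  edges), a structure-id table, then records grouped by sorted central
  key. Loading refuses wrong magic, unknown versions and truncated files;
  querying refuses fingerprint-length mismatches. Two builds from the same
  input are byte-identical.
* **Binning.** The 10 RASA bins are equal-frequency: edges are the 9
  empirical deciles of the corpus's pooled RASA distribution, persisted in
  the KB header so queries bin identically. Bins are left-closed /
  right-open, values on an edge go up, values above the last edge map to
  bin 9. Edges are only derived when a RASA feature is actually
  configured. A sample with fewer than 10 distinct values (or tied
  deciles) is rejected as degenerate rather than silently producing empty
  bins.
* **Parsing.** gemmi reads PDB and mmCIF. Only the first model is used;
  nucleic-acid chains, waters and unmappable residues are dropped; of
  alternate locations the highest-occupancy one is kept (first on ties);
  nonstandard residues with a tabulated parent (MSE → M etc.) map to the
  parent letter. Residues without a Cα are excluded from the graph but
  still count toward chain-length filtering.

## The synthetic-data generator

Real corpora require a PDB snapshot; the generator instead emits schematic
complexes whose interface truth is known analytically. Each chain is a Cα
trace along the x axis with the canonical 3.8 Å spacing and a small seeded
z jitter (≤ 0.25 Å, so solvent exposure varies smoothly); chains sit in
parallel rows 10 Å apart; every residue carries one side-chain carbon. At
planted contact positions the side chains of facing chains reach toward
each other so their surface gap is *exactly* the requested `contact_gap`
(0.3 Å by default — interface); all other inter-chain atom pairs keep a
surface gap ≥ ~1.9 Å, comfortably past the 0.5 Å rule. The central fixture
contract — generator truth equals the labeler's output — is asserted in
the tests and in the acceptance script.

Corpus generation controls neighborhood overlap: in the default mode,
sequences are sampled so that every consecutive residue triple is unique
across the corpus up to reversal (which hashes identically) and
chain-terminal letter pairs differ; at c₂ scale this makes every
fingerprint unique within its central-key group, which is what makes the
self-consistency check (predicting KB members with self-hits allowed gives
MCC = 1) a sharp test rather than a probabilistic one. In motif mode,
every structure's first chain starts with one fixed six-residue motif, so
exact cross-structure matches exist by construction even under
self-exclusion.

What the generator does **not** emulate: real backbone geometry and
side-chain packing, realistic residue-type and contact statistics, RASA
distributions of real proteins, chains that wrap back within 6 Å of
themselves (fixture graphs are paths, mean degree < 2, far sparser than
the ~5.4 contacts per residue of real complexes), and hash-collision rates
at realistic KB sizes. Passing tests therefore demonstrate the
correctness of the machinery — labeling, extraction, hashing, retrieval,
scoring — not the predictive accuracy of the method on real structures,
which depends entirely on the knowledge base it is given.

## Problem sizes

The test suite and acceptance script run on corpora of 4–10 two-chain
complexes of 12 residues per chain (≤ 240 knowledge-base records), c₂
elements and 63–1023-bit fingerprints; oracle-equivalence checks use 100
random graphs of up to 50 nodes and 20 labeled complexes. These sizes
exercise every code path (ties, disconnected elements, fallback scans,
empty retrievals) while keeping the whole suite in seconds.

## Known limitations

* Shrake–Rupley SASA on a fixed lab-frame point mesh is exactly invariant
  under translation but only approximately invariant under rotation
  (O(1/√points) wobble); with the default 300-point mesh this is ~1%.
  RASA values are also not comparable across different radii tables,
  probe radii or normalization constants — all four are explicit
  configuration pinned into the KB, since no single published convention
  exists.
* Interface labels are computed against the union of all partner chains;
  per-chain-pair labeling would differ for multi-chain complexes.
* Biological assemblies, symmetry mates and NMR multi-model handling are
  out of scope (first model only); sequence-derived features are out of
  scope by design.
* Post-prediction smoothing (e.g. CRF-style relabeling from neighbors) and
  isomorphism-based filtering of hash collisions are deliberately not
  implemented; both add complexity for marginal or unmeasurable gain in
  this retrieval scheme.
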