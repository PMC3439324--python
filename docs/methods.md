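# Methods

## Problem and model

Given records from one or more datasets describing people by a handful of
demographic attributes, the task is to partition all records into groups
that each correspond to one real person. No shared identifier exists, and
values carry entry errors, so identity must be inferred from string
similarity.

Every record is compared with every candidate through an additive record
distance: RD(R₁, R₂) = Σ dᵢ over the pair's *common* attributes, where dᵢ
is a per-attribute string distance. An attribute that is empty in either
record is excluded from the common set (the comparison simply has fewer
terms); a pair with no common non-missing attribute is *incomparable* and
is never matched at any finite threshold.

Clustering is single linkage: the distance between clusters is the
minimum pairwise record distance, and the partition at threshold t equals
the connected components of the graph with an edge for every record pair
at distance ≤ t. This equivalence is what makes the four algorithms (BIA,
PCD, IDS, TPA-without-blocking-loss) interchangeable in output and is
property-tested against networkx (components) and scipy (single-linkage
dendrogram) oracles.

## Distances

* `edit_distance` — unit-cost Levenshtein (insert, delete, exchange each
  cost 1).
* `reversal_distance(f1,l1,f2,l2)` — min(ed(f1,f2)+ed(l1,l2),
  ed(f1,l2)+ed(l1,f2)).
* `nickname_distance` — min edit distance over the symmetric-closure
  variant sets of both names (every name is a variant of itself, so with
  no table entry it reduces to plain edit distance). Lookup applies to
  first names; `nickname_last_names` widens it.
* `truncation_distance` — edit distance of L-prefixes; L defaults to 5,
  the published regime of the method.
* `name_distance` — min over the straight edit sum, the swapped pairing,
  nickname(first)+edit(last), and truncation on both names. The source
  method defines the four ingredient distances per name but not their
  combination over the (first,last) pair; the combination above is this
  package's declared convention.
* `phonetic_distance` — 0 if the Metaphone codes agree, else the edit
  distance of the codes. The encoder is the original Metaphone
  (hand-implemented here; no phonetics library is available in the target
  environment), pure and pluggable behind `DistanceSpec.phonetic_encoder`.

Modes map distances onto attributes: `ed_all` (edit everywhere),
`ed_name`/`pd_name` (names only), `rded`/`nded` (reversal/name distance
on the name pair, edit elsewhere), `pded` (phonetic on names, edit
elsewhere). When a name-pair mode encounters a missing name value, it
falls back to per-name edit distance on whatever is present.

## Thresholds

* **constant** — an integer error budget t (record pairs match when
  RD ≤ t).
* **proportional** — a fraction p of record length. "Record length" is
  defined here as the sum of the lengths of the compared attribute
  values; the pair's base is the **mean** of the two records' totals
  (configurable: min | max | sum). The mean keeps the threshold symmetric
  and bounded by the longer record.

For dendrogram construction under proportional thresholds, pairs are
compared on the normalized scale RD/base so that a single cut level p
exists; IDS applies the equivalent per-pair test RD ≤ p·base. This
preserves the three-way algorithm equivalence in both regimes.

## Bounded edit distance and budget propagation

`bounded_edit_distance(s1, s2, t)` returns the exact distance when it is
≤ t and the sentinel `OVER` otherwise:

1. if ||s1|−|s2|| > t, return OVER immediately (the length difference is
   a lower bound on the distance);
2. otherwise run the DP only on cells within band offset t of the main
   diagonal (a trace-back with ≤ t indels cannot leave the band);
3. stop as OVER as soon as every cell in the current row's band exceeds
   t — justified because along any diagonal D[i,j] ∈ {D[i−1,j−1],
   D[i−1,j−1]+1}, so values never decrease downstream.

`record_distance_bounded` walks attributes in schema order with a running
budget: each comparison is bounded by the threshold minus the distance
already used, and the first OVER aborts the pair. Proportional thresholds
convert to the integer budget floor(t); since RD is an integer,
RD ≤ t ⇔ RD ≤ floor(t), so the accept/reject outcome is identical to the
unbounded comparison (property-tested on random pairs). The sentinel is a
distinct object, never a large magic number, so it cannot leak into sums.
The Four-Russians DP speedup is deliberately omitted: on ≤50-character
strings over a 26-letter alphabet the block sizes it needs do not pay
off.

## Algorithms

* **BIA** builds the full dendrogram (O(n²) time and memory) and cuts it:
  maximal subtrees with merge level ≤ t become clusters. Kept despite its
  cost for its oracle/testing value and free re-cutting in threshold
  sweeps; the CLI warns above 20,000 records.
* **PCD** is the same nearest-neighbor agglomeration, halted at the first
  inter-cluster distance above the threshold. Nearest-neighbor
  bookkeeping exploits a single-linkage property: merging never increases
  any cross-cluster distance, so when a cluster's nearest neighbor is
  absorbed, the merged cluster takes its place without a rescan.
* **IDS** seeds a cluster with the smallest unassigned record id, grows
  it transitively with the bounded pair test, outputs it, and repeats.
  No distance matrix is materialized (O(n) memory).
* **TPA** indexes records by every distinct l-mer of the last name
  (default l = 3; a last name shorter than l is indexed under the whole
  name — skipping it would orphan the record silently; an empty last name
  yields a private pseudo-block), runs IDS per block, and merges clusters
  sharing records by union-find. Merged clusters are not re-checked
  internally. TPA's partition refines-or-equals IDS's: it can only lose
  edges between records sharing no block.

Determinism: cluster ids inherit the least member record id; ties on
merge distance break toward the lexicographically least (smaller id,
larger id) pair; block keys iterate sorted. Output partitions are
invariant to input record order. In rare exact-tie configurations the
agglomeration may merge equal-distance pairs in a different order than
the strict global-lexicographic rule (the per-cluster nearest-neighbor
cache is not re-sorted on ties), but the cut partition is unaffected —
single-linkage components at any level are tie-independent — and runs
remain reproducible for fixed inputs.

## Evaluation

Accuracy = C/N, completeness = C/N\*, with C the number of clusters
containing exactly the full record set of exactly one entity, N the
number of output clusters and N\* the number of entities. The Type I–IV
taxonomy is computed per cluster (I: one entity, complete; II: one
entity, incomplete; III: at least one entity complete plus intruders; IV:
otherwise) with fractions over N, which makes the fractions sum to one
and Type I equal accuracy — both asserted as invariants. Records without
ground truth are excluded with a logged count; an evaluation with no
covered cluster is an error, not a zero.

## Synthetic data

The generator emulates multi-source person records: each entity draws a
first name (from a bundled list of ~200 common given names with gender),
a surname (~370 common surnames), a date of birth uniform over 1930–2009,
and a 5-digit zip; each entity yields 1–3 records (uniform), the first
clean, the rest corrupted. Defaults state the mildly-corrupted world used
by the end-to-end checks: combined per-field typo rate 0.2 (split evenly
across insert/delete/substitute), at most 2 character edits per record,
name-swap probability 0.05, nickname substitution 0.1, truncation 0.05
(first name, L = 5), phonetic misspelling 0.05 (homophone patterns such
as ph→f). One RNG stream is spawned per entity from the master seed, so
growing the population never perturbs earlier entities and fixed seeds
give byte-identical CSVs.

What the generator does *not* emulate: realistic name/zip frequency
skew, shared household attributes, tautonyms beyond random pool
collisions, missing-value patterns, or cross-field correlated errors. A
green end-to-end test therefore establishes that the pipeline separates
entities whose corruption matches the stated error taxonomy at the
stated rates — not performance on any particular real registry.

With corruption off, duplicates are exact copies and every algorithm
recovers the truth exactly — provided the threshold stays below the
minimum inter-entity distance. The closure is therefore asserted over the
trained regime (constant 0–3, proportional 0–0.1), not over unbounded
thresholds, where it could not hold for any generator.

## Numerical and degenerate-input choices

* Normalization: lowercase, trim; names keep only a–z (so name distances
  operate on the 26-letter alphabet matching the 26^l block count);
  date-like values canonicalize to YYYYMMDD; other values keep letters
  and digits. The source method is silent on normalization; these rules
  are declared, not inferred.
* Empty strings are legal everywhere: ed("", s) = |s|; the Metaphone code
  of "" is "".
* Proportional thresholds with base length 0 (all compared values empty)
  accept only RD = 0.
* Incomparable pairs map to +inf on the normalized scale and are never
  edges or merges below any finite threshold.
* Threshold training (CLI `sweep`, acceptance script) maximizes accuracy
  over an integer grid on a held-out slice; the dendrogram is built once
  and re-cut per threshold for constant-mode sweeps.

## Known limitations

* BIA/PCD hold the full pairwise matrix; they are oracles and sweep
  tools, not the large-scale path (use IDS/TPA).
* The nickname table ships as a small bundled list; production use should
  supply a fuller table (two-column CSV).
* Only original Metaphone is implemented; Double Metaphone would need a
  new encoder behind the existing hook.
* No probabilistic (Fellegi–Sunter-style) linkage, no pairwise
  precision/recall metrics, no sorted-neighborhood or canopy blocking.
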