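# Methods

## Model and assumptions

The package treats record linkage as clustering under a bounded edit
budget: two records refer to the same individual when the total number of
character errors between their shared comparison attributes is at most a
user threshold τ.  This is a deliberately transparent error model — it
captures typing errors (insertions, deletions, substitutions) but not
phonetic equivalence, nicknames, transposed fields or date formats.  The
pipeline assumes:

* attribute values are strings; comparison is case-insensitive (values
  are folded to upper case at load time, originals kept for output);
* datasets may have different schemas, but only pairs in a subset
  relation participate in exact matching, and only attributes present in
  both records are ever distance-compared;
* the blocking attribute is stable enough that two records of one
  individual usually share a k-mer of it.  Blocking is a recall/runtime
  trade-off, not a correctness device: pairs sharing no block are never
  compared.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| τ (`threshold`) | max total edit errors per record pair | required; 2 for the simulated corpora, 1 in the worked example | low-error data works well at 1; heavier corruption needs 2 |
| `k` | k-mer window for blocking | 3 | larger k → more, smaller blocks → faster but lower recall |
| `alphabet` | characters kept for blocking | `letters26` | also `digits10`, `alnum36`; out-of-alphabet characters are stripped before windowing |
| `method` | per-attribute distance | `edit` | `reversal` = min over the two orientations of the first string; `truncation` = free truncation of the longer value, then edit distance |
| `priority` | ordered tie-break attributes | empty | rank i contributes 2^(m−1−i) on an exact majority match, so higher ranks dominate |
| `proportional` | per-pair threshold ratio ρ | off | τ(a,b) = ⌈ρ·min(aggregated lengths)⌉, scaling with the shorter record |

## Numerical and procedural choices

* **Bounded distances.**  Per-attribute distances are computed banded at
  the remaining budget (edlib's Myers bit-vector algorithm), so cost is
  O(τ·len) rather than O(len²), and the summed record distance aborts to
  a distinguished EXCEEDS token as soon as the budget is spent.  EXCEEDS
  behaves as +∞ in the complete-linkage matrix.  Empty values are legal
  and compared by length.
* **Exact phase.**  Sort keys concatenate the folded common attributes
  with a separator (U+001F) outside every alphabet.  The radix sort is an
  MSD byte sort, stable, with exhausted keys ordered before extensions.
  Datasets with identical schemas are sorted jointly once — by
  transitivity this equals running every pair among them, including
  self-pairs, which catch within-dataset duplicates.  For a proper-subset
  schema pair S ⊂ T, an equal-key run merges only if it contains an
  S-side record; two T records agreeing merely on S attributes are not
  duplicates.  Representatives are the widest-schema member of each
  cluster (ties: smallest id), preserving comparison power downstream.
* **Blocking.**  Duplicate k-mers within one value insert once, so block
  sizes count distinct records.  A value shorter than k forms a single
  key padded with `#`; a value empty after normalization goes to one
  overflow block per attribute rather than being dropped.  Multiple
  blocking attributes build independent indexes whose candidate pairs are
  unioned.
* **Agglomeration.**  Within a component, the pair of clusters at minimum
  complete-linkage distance merges while that minimum is ≤ τ, with the
  Lance–Williams maximum update d(i∪j, k) = max(d(i,k), d(j,k)).  Ties
  between equal-distance pairs break on the lexicographically smallest
  (min-member-id, min-member-id) pair, making runs reproducible where the
  mathematics is genuinely ambiguous.  Merge distances are non-decreasing
  and every output cluster has diameter ≤ τ.
* **Priority refinement** is a single deterministic pass over records in
  id order (not a fixed-point iteration, which could cycle): a record
  moves only when the destination preserves the diameter bound and its
  priority score strictly improves over its current cluster scored
  without itself.  A cluster's value of a priority attribute is the
  majority among members holding that attribute, ties to the smallest
  value.  The power-of-two weighting realizes "higher-priority attributes
  dominate" exactly; it is a design choice where only the dominance
  requirement is fixed.
* **Evaluation.**  Category definitions are per cluster and inherited by
  each member record; a cluster admitting several readings takes the best
  one (precedence I > II > III > IV).  "Complete" means containing every
  corpus record of that individual.  Ownership ties in the accuracy
  computation break to the smallest individual id (the correct-label
  count is unaffected by the choice among tied owners).
* **Parallel execution** shards sorting by 3-character prefix ranges,
  blocking by contiguous representative shards, distance work by greedy
  longest-processing-time groups of blocks costed at (block size)², and
  complete linkage by component groups; component discovery stays
  central.  A pair split across block groups may be distance-tested
  twice, which cannot change the edge set.  The executor's only claim is
  bit-identical output to the sequential pipeline for every worker count;
  speedup is hardware-dependent and deliberately not asserted.

## Synthetic data

The generators produce a base population (unique first name, unique last
name, unique 9-digit SSN, random dob) and replicate it:

* **type 1** — `copies` replicas (default 10); each record's last name
  receives one uniform-random edit with probability p (default 0.15);
* **type 2** — a fixed ten-dataset mixture: four clean replicas plus two
  fully-corrupted replicas used three times each;
* **type 3** — three replicas with distinct attribute subsets (default a
  chain, so all schema pairs are comparable), every last name edited
  once, each replica cloned verbatim so the exact phase can halve the
  representative count.

Last names are codewords, not realistic names: five disjoint per-position
alphabets (AEIOU / BCDFG / HJKLM / NPQRS / TVWXZ) cycle along the string,
and a base-5 payload of d digits is repeated five times (length 5d, d = 6
for 10,000 individuals).  Two distinct codewords differ in ≥ 5 positions,
and any alignment offset of 1–4 pairs characters from disjoint alphabets;
hence every position where the identity alignment differs costs at least
one operation in any alignment using fewer than five indels, giving
pairwise Levenshtein ≥ 5 = 2·τ_default + 1.  With at most one edit per
generated record, same-individual records stay within distance 2 and
different-individual records beyond it, so perfect recovery is achievable
at τ = 2 and the pipeline's measured accuracies are attributable to the
algorithm rather than to luck in a name distribution.  SSNs come from an
affine bijection on 9-digit integers; dob is uniform (month 1–12, day
1–28, year 1940–2005).

What this emulates — and what it does not: corruption touches exactly one
attribute with exactly one edit, first names are error-free and unique,
and cross-individual similarity is bounded away from the threshold.  Real
data violate all three (errors in blocking attributes, shared surnames,
near-miss individuals), so passing accuracy bounds here demonstrates
correct mechanics and separation-respecting behaviour, not field
performance.  The documented accuracy figures are therefore treated as
floors achievable under clean separation, and the evaluation module is
the tool to measure real corpora on their own terms.

## Problem sizes used in the checked results

The standard simulated run uses 10,000 individuals × 10 replicas
(100,000 records) at p = 0.15, τ = 2, k = 3, first-name blocking, SSN
truth — completing in a few seconds on one CPU; the parallel-equivalence
check uses a 2,000-record corpus across 1, 2 and 4 workers.  These sizes
were chosen so the whole suite re-runs quickly while keeping every
per-record statistic well inside its binomial noise floor.

## Known limitations

* No phonetic, numeric or date-aware distances; no pairwise
  precision/recall metrics; no database or fixed-width inputs (UTF-8 CSV
  only).
* The priority-scoring weights and the reversal/truncation distance
  semantics are concrete choices among several defensible readings; both
  are documented above and isolated behind the config.
* Exact matching requires schema subset relations; datasets with
  overlapping but incomparable schemas only interact through the
  approximate phases.
* The parallel executor targets a single machine (process pool), not a
  distributed cluster.
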