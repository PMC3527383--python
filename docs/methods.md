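# Methods

## Model and procedure

`pairuniq` treats duplicate identification as a sorting problem. A read
pair is a tuple of two nucleotide strings (the mates). Define, for reads
`a` and `b`:

* `same(a, b)` — `a` and `b` are byte-identical, or the shorter is an
  exact match to the 5' end of the longer. This cross-length equality is
  what lets one library sequenced to different read lengths (or trimmed
  per-read) be deduplicated as a whole: the sequencer reads the same
  molecule from the same end, so a shorter duplicate is a 5' prefix of a
  longer one.
* order — bases are compared position by position under `A < C < G < T`;
  the first difference decides; a full 5' prefix match orders by length,
  shorter first.

Pairs are compared read 1 first, read 2 only if the read-1 sequences are
`same`; two pairs are *duplicate candidates* iff both mates are `same`.
Among candidates, the pair whose mates are **both** at least as long
*dominates*; the dominated pair is removed. If each pair is strictly
longer in one mate, neither dominates and both are kept — length is
evidence of a genuine molecule, and discarding either would throw away
observed bases.

The pipeline is: load everything into memory → stable merge sort under
the pair comparator → one left-to-right scan of the sorted list removing
dominated candidates → write. Quality strings play no role anywhere;
retained reads keep their exact input bytes (header, sequence, quality).

## Comparator details and numerical choices

* **Base order beyond A/C/G/T.** The four-base rule coincides with ASCII
  byte order, so the comparator is plain byte order, which totally orders
  any IUPAC/ambiguity character (`N` falls between `G` and `T`). `N`
  matches only `N`; wildcard matching would merge distinct molecules.
* **Case.** Byte-wise, no case folding — the conservative reading for
  mixed-case input.
* **Empty sequences** are rejected at parse time; the comparator's
  semantics would be undefined for them.
* **Stability and ties.** The sort is stable on input ordinal, so among
  byte-identical copies the earliest input pair survives and the output is
  a deterministic function of the input bytes, platform-independently.
* **Sort algorithm.** A hand-written stable top-down merge sort drives the
  pair comparator. Merge sort has the property that every two adjacent
  output elements were directly compared (or are adjacent in an input
  run), which keeps the output adjacent-wise non-decreasing even where
  the comparator is non-transitive (see *Limitations*). Stores in which
  each mate has a single fixed read length are dispatched to the C-level
  stable sort on the `(read1, read2)` key: with uniform lengths,
  prefix-equivalence degenerates to byte identity and the comparator is
  exactly that key order (a property test asserts the two paths agree).
* **Scan semantics.** The scan holds the *active representatives* of the
  current duplicate run — all pairs seen so far that are mutually
  non-dominated. A new pair that is a candidate of none of them closes the
  run; one dominated by an active pair is dropped; otherwise it joins the
  active set, first displacing any active pairs it dominates. A pair is
  only ever dropped against a pair that is itself retained, and because a
  dominated candidate is a 5' prefix of its dominator in both mates
  (making dominance chains transitive), every removed pair is guaranteed
  duplicate-equivalent to, and dominated by, a pair present in the
  output. With uniform read lengths every run holds exactly one active
  representative and the scan is the plain adjacent comparison. A scan
  that instead keeps only the single most recent representative loses
  this guarantee after a keep-both event: a later dominator can no longer
  see the earlier retained pair, and a re-run then removes more pairs;
  that is why the multi-representative form is used.

## Tunable parameters

Pipeline: the output mode (`fastq-pair`, `fasta-pair`,
`fasta-interleaved`) is the only knob; the algorithm itself has no
parameters.

Generator (`FixtureSpec`): `n_clusters` (original fragments; default 500),
`read_len_1`/`read_len_2` (bp; default 75, a standard short-read length),
`multiplicity_dist` (PCR copies per fragment; default
`{1: 0.5, 2: 0.25, 4: 0.25}`, i.e. ~2 copies per fragment and ~50%
duplicates, a level between typical paired-end and mate-pair libraries),
`truncation_prob` with `max_truncation` (per-copy probability of 3'
shortening by up to `max_truncation` bases, independently per mate, at
least one mate shortened; default off), `substitution_prob` (per-copy
probability of one random base change in one mate, which makes the copy a
non-duplicate under exact matching — a sequencing error or heterozygous
site; default off), and `seed`.

## What the generator emulates — and does not

It emulates exactly the structure the algorithm keys on: duplicate
clusters of controlled multiplicity, 5'-anchored length variation among
copies, and point differences that break duplicate identity. Truncation is
3'-only by design, since 5' trimming would break the 5'-anchored
equivalence on purpose. It does **not** model realistic per-base error
profiles, quality-score distributions (qualities are a constant `I`),
insert-size distributions, adapter read-through, base-composition bias,
or reference-derived reads. Passing tests therefore demonstrate the
combinatorial correctness of the comparator/sort/scan machinery on known
ground truth, not error-robustness on real instrument data — on real
libraries, reads of the same fragment differing by a sequencing error are
*not* identified as duplicates (by design: exact matching maximally
preserves polymorphism, at the cost of sensitivity to errors).

The manifest's expected survivor count comes from the generator's own
brute-force all-pairs oracle (shared code with the deduplicator: none).
With truncation off, all copies have fixed lengths and the oracle reduces
provably to first-occurrence exact-key deduplication, computed in O(n);
variable-length instances use the O(n²) scan and are kept small.

## Problem sizes used in the tests

Oracle-equivalence checks run 20 seeds of ~1,000 equal-length pairs;
dominance-bound checks run 50 seeds of ≤ 200 variable-length pairs against
the all-pairs oracle; ground-truth checks run 1 / 100 / 10,000 clusters;
the scaling check runs 0.1 / 0.5 / 1.0 million pairs in memory and asserts
near-linear growth of the sort-and-scan time (within 3× of the linear
ideal, absorbing timer noise; no absolute throughput is asserted). The
whole suite completes in about a minute on one CPU.

## Known limitations

* **Whole dataset in memory.** Deliberate: both mates of every pair must
  be retrievable at comparison time, and the three-step design assumes
  random access. No streaming/external sort.
* **Adjacent-scan incompleteness on mixed lengths.** Duplicate-equivalence
  is not transitive across lengths (`AC` ~ `ACG` and `AC` ~ `ACT`, but
  `ACG` ≁ `ACT`), so a sorted order can interleave non-candidates between
  two candidates, which an adjacent scan then never compares. Such missed
  merges are exactly characterized: every *removed* pair is dominated by a
  *retained* pair, but a retained pair may still be dominated by another
  retained pair that never became adjacent.
* **Re-running can remove a little more.** For the same reason, and
  because consulting read 2 only under read-1 prefix-equivalence makes the
  pair comparator non-transitive (sorting a retained subset can create new
  adjacencies), a second pass over the output is not guaranteed to be a
  no-op in adversarial regimes — dense prefix entanglement such as 12–14
  bp reads with up to 8 bp of truncation. A second pass only ever removes
  additional duplicates (converging toward the transitive closure); it
  never alters retained bytes. For uniform read lengths the first pass is
  provably complete and idempotent, and across the tested realistic
  mixed-length regimes (≥ 30 bp reads, truncation ≤ ~25% of read length)
  second passes remove nothing.
* **No reverse-complement awareness, no optical-duplicate heuristics, no
  quality-based survivor choice** — out of scope by design; survivor
  choice is by length dominance and input order only.
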