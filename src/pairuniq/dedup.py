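"""De novo PCR-duplicate removal for paired reads.

The method needs no reference genome.  It works in three steps:

1. import all read pairs into memory (:mod:`pairuniq.pairio`);
2. sort the pairs by their nucleotide sequences with a stable merge sort;
3. scan the sorted list once, comparing adjacent pairs, and keep one
   representative of every run of duplicates.

Two reads are *duplicate-equivalent* when they are byte-identical or when
the shorter is an exact match to the 5' end of the longer — the rule that
lets libraries with mixed read lengths (e.g. several runs of one library)
be deduplicated together.  Two read pairs are duplicate candidates when
both mates are duplicate-equivalent.  Among two candidate pairs the one
whose mates are both at least as long is kept; if each pair is longer in
one mate, neither dominates and both are kept.

The base ordering is A < C < G < T.  Because that coincides with ASCII
byte order, the comparator uses plain byte order throughout, which also
gives a total order over ambiguity characters ('N' falls between 'G' and
'T').  'N' matches only 'N': equivalence is exact base identity, never a
wildcard.  Sequences are compared byte-wise without case folding; quality
strings play no role in either the comparison or the choice of survivor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Callable

from .pairio import (
    PairStore,
    ReadPair,
    load_pairs,
    parse_input_list,
    write_output,
)

__all__ = [
    "Ordering",
    "Selection",
    "DedupResult",
    "compare_sequences",
    "duplicate_equivalent",
    "compare_pairs",
    "pair_sort_cmp",
    "sort_pairs",
    "select_representative",
    "remove_duplicates",
    "dedup_pipeline",
]

logger = logging.getLogger("pairuniq")


class Ordering(Enum):
    """Result of a sequence or pair comparison.

    For :func:`compare_sequences`, ``EQUAL`` means byte identity.  For
    :func:`compare_pairs`, ``EQUAL`` means duplicate-equivalence of both
    mates — the duplicate-candidate criterion — not byte identity.
    """

    BEFORE = -1
    EQUAL = 0
    AFTER = 1


class Selection(Enum):
    """Outcome of representative selection between two duplicate pairs."""

    KEEP_P = "keep-p-drop-q"
    KEEP_Q = "keep-q-drop-p"
    KEEP_BOTH = "keep-both"


def compare_sequences(a: str, b: str) -> Ordering:
    """Order two nucleotide sequences.

    Bases at the same position are compared one by one under A < C < G < T
    (extended to full byte order for any other character); the first
    differing base decides.  If one sequence is a 5' prefix of the other,
    the shorter sorts first.  ``EQUAL`` only for byte-identical input.
    """
    if a == b:
        return Ordering.EQUAL
    # Byte order subsumes both the base rule and the shorter-prefix-first
    # length rule.
    return Ordering.BEFORE if a < b else Ordering.AFTER


def duplicate_equivalent(a: str, b: str) -> bool:
    """True iff ``a`` and ``b`` are the same read sequence for dedup purposes.

    That is: byte-identical, or the shorter is an exact match to the 5'
    end of the longer.
    """
    return a.startswith(b) or b.startswith(a)


def compare_pairs(p: ReadPair, q: ReadPair) -> Ordering:
    """Order two read pairs; ``EQUAL`` marks duplicate candidates.

    The first mates are compared first; the second mates are consulted only
    if the first mates are duplicate-equivalent.  ``EQUAL`` is returned iff
    *both* mates are duplicate-equivalent — exactly the duplicate-candidate
    criterion.  (Two candidate pairs of unequal lengths still have a
    well-defined relative sort position; see :func:`pair_sort_cmp`.)
    """
    a1, b1 = p.read1.sequence, q.read1.sequence
    if not duplicate_equivalent(a1, b1):
        return compare_sequences(a1, b1)
    a2, b2 = p.read2.sequence, q.read2.sequence
    if not duplicate_equivalent(a2, b2):
        return compare_sequences(a2, b2)
    return Ordering.EQUAL


def pair_sort_cmp(p: ReadPair, q: ReadPair) -> int:
    """Strict three-way comparator used by the sort.

    Refines :func:`compare_pairs`: duplicate candidates that are not
    byte-identical are ordered by the length rule (shorter read1 first,
    then shorter read2), so every duplicate-equivalence run in the sorted
    list has its shorter members first.  Byte-identical pairs compare as 0
    and keep their input order (the sort is stable).
    """
    a1, b1 = p.read1.sequence, q.read1.sequence
    if a1 != b1 and not (a1.startswith(b1) or b1.startswith(a1)):
        return -1 if a1 < b1 else 1
    a2, b2 = p.read2.sequence, q.read2.sequence
    if a2 != b2 and not (a2.startswith(b2) or b2.startswith(a2)):
        return -1 if a2 < b2 else 1
    # Duplicate candidates: shorter mates first (prefix => byte order agrees
    # with length order).
    if a1 != b1:
        return -1 if a1 < b1 else 1
    if a2 != b2:
        return -1 if a2 < b2 else 1
    return 0


def _merge_sort(items: list, cmp: Callable) -> list:
    """Stable top-down merge sort under a three-way comparator.

    Merge sort guarantees that every two adjacent elements of the output
    were either directly compared or are adjacent within an input run, so
    the output is adjacent-wise non-decreasing even where the comparator
    is not transitive (possible for pairs entangled by prefix equivalence).
    """
    n = len(items)
    if n <= 1:
        return items
    mid = n // 2
    left = _merge_sort(items[:mid], cmp)
    right = _merge_sort(items[mid:], cmp)
    merged = []
    i = j = 0
    while i < len(left) and j < len(right):
        # Take from the left on ties: stability.
        if cmp(right[j], left[i]) < 0:
            merged.append(right[j])
            j += 1
        else:
            merged.append(left[i])
            i += 1
    merged.extend(left[i:])
    merged.extend(right[j:])
    return merged


def sort_pairs(store: PairStore) -> PairStore:
    """Return a new :class:`PairStore` sorted under :func:`pair_sort_cmp`.

    The sort is stable: byte-identical pairs keep their input-ordinal
    order, so the survivor chosen later among exact duplicates is the
    earliest input copy.

    When every read1 has one fixed length and every read2 has one fixed
    length (the common single-run case), prefix equivalence degenerates to
    byte identity and the comparator coincides with plain lexicographic
    order on the (read1, read2) sequence tuple; that case is dispatched to
    the C-level sort.  Mixed-length stores use the merge sort above.
    """
    pairs = list(store)
    if not pairs:
        return PairStore()
    len1 = {len(p.read1.sequence) for p in pairs}
    len2 = {len(p.read2.sequence) for p in pairs}
    if len(len1) == 1 and len(len2) == 1:
        pairs.sort(key=lambda p: (p.read1.sequence, p.read2.sequence))
    else:
        pairs = _merge_sort(pairs, pair_sort_cmp)
    return PairStore(pairs)


def select_representative(p: ReadPair, q: ReadPair) -> Selection:
    """Choose the survivor among two duplicate-candidate pairs.

    The pair whose mates are both at least as long as the other's is kept;
    if each pair is strictly longer in one mate, neither dominates and both
    are kept.  When all four lengths are equal the dominance is mutual and
    the earlier-input pair is kept, so the survivor's header and quality
    are deterministic.

    Raises ``ValueError`` if the two pairs are not duplicate candidates.
    """
    if compare_pairs(p, q) is not Ordering.EQUAL:
        raise ValueError("select_representative called on non-duplicate pairs")
    l1p, l2p = len(p.read1.sequence), len(p.read2.sequence)
    l1q, l2q = len(q.read1.sequence), len(q.read2.sequence)
    p_dominates = l1p >= l1q and l2p >= l2q
    q_dominates = l1q >= l1p and l2q >= l2p
    if p_dominates and q_dominates:
        return Selection.KEEP_P if p.ordinal <= q.ordinal else Selection.KEEP_Q
    if p_dominates:
        return Selection.KEEP_P
    if q_dominates:
        return Selection.KEEP_Q
    return Selection.KEEP_BOTH


@dataclass
class DedupResult:
    """Retained pairs (in sorted order) plus run counters."""

    retained: list[ReadPair]
    n_input: int
    n_retained: int
    n_removed: int

    @property
    def duplicate_percent(self) -> float:
        """Removed pairs as a percentage of input pairs."""
        return 100.0 * self.n_removed / self.n_input if self.n_input else 0.0


def _is_candidate(p: ReadPair, q: ReadPair) -> bool:
    return duplicate_equivalent(p.read1.sequence, q.read1.sequence) and duplicate_equivalent(
        p.read2.sequence, q.read2.sequence
    )


def remove_duplicates(sorted_store: PairStore) -> DedupResult:
    """Identify duplicates by a single scan over adjacent sorted pairs.

    The scan holds the *active representatives* of the current duplicate
    run: the pairs seen so far that are mutually non-dominated.  Each next
    pair is compared against them:

    * not a candidate of any active pair — the run is over; the active
      pairs are emitted and the new pair opens the next run;
    * dominated by an active pair (both its mates at least as long) — the
      new pair is dropped;
    * otherwise the new pair is retained as a further representative,
      first displacing any active pairs it dominates.

    Dropping only against retained pairs keeps the guarantee that every
    removed pair is duplicate-equivalent to, and dominated by, a pair that
    survives to the output: because a dominated candidate is a 5' prefix
    of its dominator in both mates, domination chains stay equivalent.

    With a single read length per mate (the usual case) duplicate
    candidates are byte-identical, every run keeps exactly one
    representative, and the scan is the plain adjacent comparison.
    Retained pairs keep their original bytes untouched.
    """
    pairs = list(sorted_store)
    n_input = len(pairs)
    retained: list[ReadPair] = []
    n_removed = 0
    active: list[ReadPair] = []
    for pair in pairs:
        candidates = [_is_candidate(rep, pair) for rep in active]
        if not any(candidates):
            retained.extend(active)
            active = [pair]
            continue
        len1, len2 = len(pair.read1.sequence), len(pair.read2.sequence)
        dominated = any(
            is_cand
            and len(rep.read1.sequence) >= len1
            and len(rep.read2.sequence) >= len2
            for rep, is_cand in zip(active, candidates)
        )
        if dominated:
            # Earliest-wins on mutual dominance: the sort is stable, so a
            # byte-identical active pair always has the earlier ordinal.
            n_removed += 1
            continue
        survivors = []
        for rep, is_cand in zip(active, candidates):
            if is_cand and len1 >= len(rep.read1.sequence) and len2 >= len(rep.read2.sequence):
                n_removed += 1
            else:
                survivors.append(rep)
        survivors.append(pair)
        active = survivors
    retained.extend(active)
    return DedupResult(
        retained=retained,
        n_input=n_input,
        n_retained=len(retained),
        n_removed=n_removed,
    )


def dedup_pipeline(
    input_list_path,
    out1,
    out2=None,
    mode: str = "fastq-pair",
) -> DedupResult:
    """Full run: load, sort, remove duplicates, write.

    ``input_list_path`` names the plain-text file listing the paired FASTQ
    inputs (adjacent lines are mates).  Counts and the duplicate
    percentage are logged on the ``pairuniq`` logger.
    """
    input_list = parse_input_list(input_list_path)
    store = load_pairs(input_list)
    result = remove_duplicates(sort_pairs(store))
    write_output(result, out1, out2, mode)
    logger.info(
        "pairs in: %d; pairs out: %d; duplicates removed: %d (%.2f%%)",
        result.n_input,
        result.n_retained,
        result.n_removed,
        result.duplicate_percent,
    )
    return result
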