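"""Seeded simulator of paired read libraries with known duplicate structure.

The generator emulates the duplicate structure that PCR amplification
imprints on a sequencing library: a set of *clusters*, each descending
from one original DNA fragment.  Every cluster has a template read pair of
i.i.d. uniform A/C/G/T bases; the cluster then emits ``multiplicity``
copies of that template, where the multiplicity is drawn from a
user-supplied distribution.  Two optional per-copy perturbations are
modelled:

* **3' truncation** — the copy stays identical at the 5' end but is 1..k
  bases shorter (as happens when the same fragment is sequenced to
  different lengths, e.g. across runs).  Truncated copies remain
  duplicate-equivalent to their template under the 5'-prefix rule.
  Truncation is 3'-only by construction: trimming the 5' end would destroy
  duplicate identity under a 5'-anchored equivalence.
* **substitution** — the copy carries one random base substitution in one
  mate, which makes it a *non*-duplicate under the exact-match rule
  (emulating a sequencing error or a heterozygous site).

All emitted pairs are shuffled with the seeded generator, so duplicates
are scattered through the files as in a real library.  Qualities are a
constant 'I'; headers encode the cluster id.  The same seed always yields
byte-identical output.

The manifest carries the ground truth: cluster id and perturbation flags
per emitted pair, and the expected survivor count computed by the
generator's own brute-force oracle (independent of :mod:`pairuniq.dedup`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pairio import PairStore, ReadPair, SeqRead, write_output

__all__ = [
    "FixtureSpec",
    "ManifestRecord",
    "FixtureManifest",
    "generate_pairs",
    "generate_library",
    "read_manifest",
    "oracle_survivor_indices",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic paired library.

    Defaults describe a typical short-insert Illumina library slice: 500
    fragment clusters of 75 bp + 75 bp paired reads with mixed PCR
    multiplicities (half the fragments unamplified, the rest seen 2 or 4
    times, i.e. about 1,000 emitted pairs and a 50% duplicate level), no
    truncation and no substitutions.
    """

    n_clusters: int = 500
    read_len_1: int = 75
    read_len_2: int = 75
    multiplicity_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 4: 0.25}
    )
    truncation_prob: float = 0.0
    max_truncation: int = 10
    substitution_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if min(self.read_len_1, self.read_len_2) < 10:
            raise ValueError("read lengths must be >= 10")
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ValueError("truncation_prob must be in [0, 1]")
        if not 0.0 <= self.substitution_prob <= 1.0:
            raise ValueError("substitution_prob must be in [0, 1]")
        total = sum(self.multiplicity_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"multiplicity probabilities sum to {total}, not 1")
        if any(m < 1 for m in self.multiplicity_dist):
            raise ValueError("multiplicities must be >= 1")
        if any(p < 0 for p in self.multiplicity_dist.values()):
            raise ValueError("multiplicity probabilities must be >= 0")
        if self.truncation_prob > 0 and not (
            1 <= self.max_truncation < min(self.read_len_1, self.read_len_2)
        ):
            raise ValueError(
                f"read length too small for requested truncation depth "
                f"{self.max_truncation}"
            )


@dataclass(slots=True)
class ManifestRecord:
    """Ground truth for one emitted pair, keyed by its output position."""

    pair_id: int
    cluster_id: int
    is_truncated: bool
    is_mutated: bool


@dataclass
class FixtureManifest:
    """Per-pair ground truth plus the oracle's expected survivor count."""

    records: list[ManifestRecord]
    expected_survivor_count: int


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    rows = _BASES[draws]
    return [row.tobytes().decode("ascii") for row in rows]


def _equivalent(a: str, b: str) -> bool:
    # Deliberate re-statement of prefix equivalence, character by character,
    # so the oracle shares no code with the implementation under test.
    if len(a) > len(b):
        a, b = b, a
    for i in range(len(a)):
        if a[i] != b[i]:
            return False
    return True


def oracle_survivor_indices(seq_pairs: Sequence[tuple[str, str]]) -> list[int]:
    """Brute-force all-pairs duplicate oracle; returns surviving indices.

    A pair is dropped when some other pair is duplicate-equivalent in both
    mates and at least as long in both mates (dominance); among mutually
    dominating (identical-length) pairs only the earliest survives.  When
    all pairs share one read1 length and one read2 length this reduces to
    first-occurrence exact-key deduplication, computed directly in O(n);
    otherwise the O(n^2) scan is used (intended for small instances).
    """
    n = len(seq_pairs)
    len1 = {len(s1) for s1, _ in seq_pairs}
    len2 = {len(s2) for _, s2 in seq_pairs}
    if len(len1) <= 1 and len(len2) <= 1:
        seen: set[tuple[str, str]] = set()
        survivors = []
        for i, key in enumerate(seq_pairs):
            if key not in seen:
                seen.add(key)
                survivors.append(i)
        return survivors

    survivors = []
    for i, (a1, a2) in enumerate(seq_pairs):
        dropped = False
        for j, (b1, b2) in enumerate(seq_pairs):
            if i == j:
                continue
            if not (_equivalent(a1, b1) and _equivalent(a2, b2)):
                continue
            j_dominates = len(b1) >= len(a1) and len(b2) >= len(a2)
            if not j_dominates:
                continue
            i_dominates = len(a1) >= len(b1) and len(a2) >= len(b2)
            if not i_dominates or j < i:
                dropped = True
                break
        if not dropped:
            survivors.append(i)
    return survivors


def generate_pairs(spec: FixtureSpec) -> tuple[PairStore, FixtureManifest]:
    """Generate one library in memory.

    Returns the shuffled :class:`PairStore` (ordinals follow the shuffled
    emission order, as they would after loading the written files) and the
    matching manifest.
    """
    rng = np.random.default_rng(spec.seed)
    templates1 = _random_sequences(rng, spec.n_clusters, spec.read_len_1)
    templates2 = _random_sequences(rng, spec.n_clusters, spec.read_len_2)
    mults = list(spec.multiplicity_dist)
    probs = [spec.multiplicity_dist[m] for m in mults]
    multiplicity = rng.choice(mults, size=spec.n_clusters, p=probs)

    entries: list[tuple[str, str, int, bool, bool]] = []
    for cid in range(spec.n_clusters):
        s1, s2 = templates1[cid], templates2[cid]
        for _ in range(int(multiplicity[cid])):
            t1, t2 = s1, s2
            is_truncated = spec.truncation_prob > 0 and rng.random() < spec.truncation_prob
            if is_truncated:
                d1 = int(rng.integers(0, spec.max_truncation + 1))
                d2 = int(rng.integers(0, spec.max_truncation + 1))
                if d1 == 0 and d2 == 0:
                    d1 = int(rng.integers(1, spec.max_truncation + 1))
                if d1:
                    t1 = t1[:-d1]
                if d2:
                    t2 = t2[:-d2]
            is_mutated = spec.substitution_prob > 0 and rng.random() < spec.substitution_prob
            if is_mutated:
                mate = int(rng.integers(0, 2))
                target = t1 if mate == 0 else t2
                pos = int(rng.integers(0, len(target)))
                old = target[pos]
                choices = [b for b in "ACGT" if b != old]
                new = choices[int(rng.integers(0, len(choices)))]
                mutated = target[:pos] + new + target[pos + 1 :]
                if mate == 0:
                    t1 = mutated
                else:
                    t2 = mutated
            entries.append((t1, t2, cid, is_truncated, is_mutated))

    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]

    pairs: list[ReadPair] = []
    records: list[ManifestRecord] = []
    for pair_id, (t1, t2, cid, is_truncated, is_mutated) in enumerate(entries):
        name = f"c{cid}.p{pair_id}"
        pairs.append(
            ReadPair(
                SeqRead(f"{name}/1", t1, "I" * len(t1)),
                SeqRead(f"{name}/2", t2, "I" * len(t2)),
                ordinal=pair_id,
            )
        )
        records.append(ManifestRecord(pair_id, cid, is_truncated, is_mutated))

    survivor_count = len(oracle_survivor_indices([(t1, t2) for t1, t2, *_ in entries]))
    return PairStore(pairs), FixtureManifest(records, survivor_count)


def generate_library(
    spec: FixtureSpec,
    out1,
    out2,
    manifest_out,
) -> FixtureManifest:
    """Generate a library and write paired FASTQ files plus the manifest.

    The manifest is tab-separated with one row per emitted pair
    (``pair_id``, ``cluster_id``, ``is_truncated``, ``is_mutated``) and a
    leading ``#expected_survivor_count`` comment line.
    """
    store, manifest = generate_pairs(spec)
    write_output(store, out1, out2, "fastq-pair")
    with open(manifest_out, "w") as fh:
        fh.write(f"#expected_survivor_count\t{manifest.expected_survivor_count}\n")
        fh.write("pair_id\tcluster_id\tis_truncated\tis_mutated\n")
        for rec in manifest.records:
            fh.write(
                f"{rec.pair_id}\t{rec.cluster_id}\t{int(rec.is_truncated)}\t{int(rec.is_mutated)}\n"
            )
    return manifest


def read_manifest(path) -> FixtureManifest:
    """Load a manifest written by :func:`generate_library`."""
    lines = Path(path).read_text().splitlines()
    expected = None
    records: list[ManifestRecord] = []
    for line in lines:
        if line.startswith("#expected_survivor_count"):
            expected = int(line.split("\t")[1])
        elif line and not line.startswith(("#", "pair_id")):
            pid, cid, trunc, mut = line.split("\t")
            records.append(ManifestRecord(int(pid), int(cid), bool(int(trunc)), bool(int(mut))))
    if expected is None:
        raise ValueError(f"{path}: missing #expected_survivor_count line")
    return FixtureManifest(records, expected)
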