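# pairuniq

Reference-free removal of PCR duplicates from paired-end short-read
libraries.

## The problem

PCR amplification during sequencing-library preparation produces
*duplicates*: multiple sequenced copies of the same original DNA fragment.
Duplicates carry no independent biological information and bias downstream
analyses — most visibly scaffolding (inflated or conflicting contig links)
and structural-variant discovery. Mapping-based removal (flagging read
pairs aligned to identical coordinates) needs a finished reference genome
and is confounded by genomic variation and repeats. `pairuniq` instead
identifies duplicates *de novo*, purely from the read sequences, so it
works for any species and any library, including reads of mixed lengths.
It is aimed at anyone running QC ahead of assembly, scaffolding, or
variant calling on paired FASTQ data.

## The method

Three steps, entirely in memory:

1. **Import** all read pairs from the listed FASTQ files. In the input-list
   file, two adjacent lines name the two mate files of one library; record
   *i* of each file forms read pair *i*.
2. **Sort** the pairs by nucleotide sequence with a stable merge sort.
   Read 1 is compared first; read 2 is consulted only when the read-1
   sequences are the same. Bases are compared position by position under
   `A < C < G < T`; the first differing base decides. Two reads of unequal
   length whose shorter one exactly matches the 5' end of the longer are
   *the same* for this purpose, and order by length (shorter first).
3. **Scan** the sorted list once, comparing adjacent pairs. Two pairs are
   duplicate candidates when both mates are the same under the rule above.
   Of two candidates, the pair whose mates are **both** at least as long
   is kept and the other discarded; if each pair is longer in one mate,
   neither dominates and both are kept. Among byte-identical copies the
   earliest input copy survives, bytes untouched.

Formally, for reads `a`, `b`: `same(a, b) ⇔ a = b ∨ a = b[1..|a|] ∨
b = a[1..|b|]`, and pair `p` dominates pair `q` iff `same` holds for both
mates, `|p₁| ≥ |q₁|` and `|p₂| ≥ |q₂|`.

On a library whose reads all have one length, the result is provably
identical to exact-key deduplication of the concatenated mate sequences —
the single-read "collapser" strategy applied to merged pairs.

## Worked example

Generate a small synthetic library with known duplicate structure (100
fragment clusters, PCR multiplicities 1/2/4) and deduplicate it:

```sh
python - <<'EOF'
from pairuniq.fixtures import FixtureSpec, generate_library
spec = FixtureSpec(n_clusters=100, multiplicity_dist={1: 0.5, 2: 0.25, 4: 0.25}, seed=11)
generate_library(spec, "reads_1.fq", "reads_2.fq", "manifest.tsv")
open("input_list.txt", "w").write("reads_1.fq\nreads_2.fq\n")
EOF
pairuniq -i input_list.txt -t q -o uniq_1.fq -p uniq_2.fq
```

which prints (to standard error):

```
pairs in: 193
pairs out: 100
duplicates removed: 93 (48.19%)
```

The 100 clusters emitted 193 read pairs; the 93 extra PCR copies were
removed and exactly one representative per original fragment survived,
written as two mate-synchronized FASTQ files. Output types: `-t q` two
FASTQ files, `-t f` two FASTA files, `-t p` one interleaved FASTA file
(mates adjacent; omit `-p`). Exit codes: 0 success, 1 runtime/format
error, 2 usage error.

The same run from Python:

```python
from pairuniq import dedup_pipeline
result = dedup_pipeline("input_list.txt", "uniq_1.fq", "uniq_2.fq", "fastq-pair")
print(result.n_input, result.n_retained, result.duplicate_percent)  # 193 100 48.19...
```

## Layout

- `src/pairuniq/pairio.py` — input-list / FASTQ / FASTA reading and writing
- `src/pairuniq/dedup.py` — comparator, merge sort, adjacent-scan removal
- `src/pairuniq/fixtures.py` — seeded synthetic-library generator + oracle
- `src/pairuniq/cli.py` — the `pairuniq` command
- `docs/methods.md` — model, parameters, numerical choices, limitations
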