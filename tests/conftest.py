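"""Shared helpers: tiny pair constructors and on-disk library builders."""

from __future__ import annotations

from pathlib import Path

import pytest

from pairuniq.pairio import ReadPair, SeqRead


def make_pair(seq1: str, seq2: str, ordinal: int = 0, name: str | None = None) -> ReadPair:
    """Build a ReadPair with synthetic headers and all-'I' qualities."""
    name = name or f"p{ordinal}"
    return ReadPair(
        SeqRead(f"{name}/1", seq1, "I" * len(seq1)),
        SeqRead(f"{name}/2", seq2, "I" * len(seq2)),
        ordinal=ordinal,
    )


def write_fastq(path: Path, reads: list[tuple[str, str, str]]) -> Path:
    """Write (header, sequence, quality) triples as 4-line FASTQ records."""
    with open(path, "w") as fh:
        for header, seq, qual in reads:
            fh.write(f"@{header}\n{seq}\n+\n{qual}\n")
    return path


def write_paired_library(
    tmp_path: Path,
    pairs: list[ReadPair],
    prefix: str = "lib",
) -> Path:
    """Write pairs as two mate FASTQ files plus an input-list file.

    Returns the input-list path.
    """
    r1 = write_fastq(
        tmp_path / f"{prefix}_1.fq",
        [(p.read1.header, p.read1.sequence, p.read1.quality) for p in pairs],
    )
    r2 = write_fastq(
        tmp_path / f"{prefix}_2.fq",
        [(p.read2.header, p.read2.sequence, p.read2.quality) for p in pairs],
    )
    input_list = tmp_path / f"{prefix}_list.txt"
    input_list.write_text(f"{r1}\n{r2}\n")
    return input_list


@pytest.fixture
def four_identical_pairs(tmp_path: Path) -> Path:
    """Input list for a library of 4 byte-identical pairs (1 survivor)."""
    pairs = [make_pair("ACGTACGTAC", "TTGGCCAATT", ordinal=i) for i in range(4)]
    return write_paired_library(tmp_path, pairs)
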