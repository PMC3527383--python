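"""Reading and writing of paired short-read files.

Three on-disk formats are handled here:

* the *input-list* file — plain text, one FASTQ path per line, where two
  adjacent lines name the two mate files of one library (both files must
  list their reads in the same order);
* paired FASTQ input — strict 4-line records (``@header`` / sequence /
  ``+`` / quality); gzip-compressed files are accepted and detected by a
  ``.gz`` suffix;
* the three output modes — two synchronized FASTQ files, two synchronized
  FASTA files, or a single interleaved FASTA file in which records ``2i``
  and ``2i + 1`` are the two mates of pair ``i``.

Reads are never modified on the way through: the header, sequence and
quality bytes written out are exactly the bytes read in.  The ``+`` line
content is the one deliberate exception — it is ignored on input and
emitted as a bare ``+``.

Multi-line ("wrapped") FASTQ is rejected: modern short-read FASTQ is
universally 4-line, and wrapping makes record boundaries ambiguous.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

__all__ = [
    "SeqRead",
    "ReadPair",
    "PairStore",
    "InputList",
    "PairFileError",
    "InputListError",
    "FastqParseError",
    "MateMismatchError",
    "OutputModeError",
    "OUTPUT_MODES",
    "parse_input_list",
    "read_fastq",
    "load_pairs",
    "write_output",
]

PathLike = Union[str, Path]

#: The supported output modes, in the order (two FASTQ files, two FASTA
#: files, one interleaved FASTA file).
OUTPUT_MODES = ("fastq-pair", "fasta-pair", "fasta-interleaved")


class PairFileError(Exception):
    """Base class for violations of the paired-file contracts."""


class InputListError(PairFileError):
    """The input-list file is empty or names an odd number of files."""


class FastqParseError(PairFileError):
    """A FASTQ file contains a malformed 4-line record."""


class MateMismatchError(PairFileError):
    """Two mate files of one library have different record counts."""


class OutputModeError(PairFileError):
    """The requested output mode and arguments are inconsistent."""


@dataclass(slots=True)
class SeqRead:
    """One sequencing read: description, sequence, and quality string.

    ``header`` is the ``@``-line content without the leading ``@``;
    ``quality`` has the same length as ``sequence`` whenever non-empty.
    """

    header: str
    sequence: str
    quality: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class ReadPair:
    """Two mate reads plus the 0-based ordinal of the pair in the input."""

    read1: SeqRead
    read2: SeqRead
    ordinal: int


class PairStore:
    """Ordered, ordinal-indexed collection of :class:`ReadPair`.

    Iteration follows insertion order; :meth:`get` retrieves a pair by its
    input ordinal in O(1) regardless of the current ordering (the index is
    rebuilt when a sorted copy of the store is constructed).
    """

    __slots__ = ("_pairs", "_index")

    def __init__(self, pairs: Iterable[ReadPair] = ()):
        self._pairs: list[ReadPair] = list(pairs)
        self._index: dict[int, int] = {}
        for pos, pair in enumerate(self._pairs):
            if pair.ordinal in self._index:
                raise ValueError(f"duplicate pair ordinal {pair.ordinal}")
            self._index[pair.ordinal] = pos

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[ReadPair]:
        return iter(self._pairs)

    def __getitem__(self, position: int) -> ReadPair:
        return self._pairs[position]

    def get(self, ordinal: int) -> ReadPair:
        """Return the pair carrying input ordinal ``ordinal``."""
        return self._pairs[self._index[ordinal]]

    def __contains__(self, ordinal: int) -> bool:
        return ordinal in self._index


@dataclass(slots=True)
class InputList:
    """Ordered list of FASTQ paths; adjacent entries are mate files."""

    file_paths: list[Path]

    @property
    def file_pairs(self) -> list[tuple[Path, Path]]:
        it = iter(self.file_paths)
        return list(zip(it, it))


def parse_input_list(path: PathLike) -> InputList:
    """Parse an input-list file naming the paired FASTQ files to process.

    Blank lines and surrounding whitespace are ignored; the order of the
    remaining lines is preserved, and adjacent lines are taken as mates.

    Raises
    ------
    InputListError
        If the file names no files, or an odd number of them.
    """
    path = Path(path)
    entries = [line.strip() for line in path.read_text().splitlines()]
    entries = [e for e in entries if e]
    if not entries:
        raise InputListError(f"empty input list: {path}")
    if len(entries) % 2:
        raise InputListError(
            f"unpaired file list: {path} names {len(entries)} files; "
            "mate files must appear in adjacent pairs"
        )
    return InputList([Path(e) for e in entries])


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_fastq(path: PathLike) -> Iterator[SeqRead]:
    """Yield reads from a strict 4-line-record FASTQ file.

    Raises :class:`FastqParseError` naming the file and the 0-based record
    index on any malformed record: a missing ``@`` or ``+`` marker, a
    sequence/quality length mismatch, an empty sequence, whitespace inside
    the sequence, or a truncated final record.
    """
    path = Path(path)
    with _open_text(path) as fh:
        record = 0
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            where = f"{path}: record {record}"
            if not head.startswith("@"):
                raise FastqParseError(f"{where}: header does not start with '@'")
            if not seq:
                raise FastqParseError(f"{where}: empty or missing sequence line")
            if any(c.isspace() for c in seq):
                raise FastqParseError(f"{where}: whitespace inside sequence")
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{where}: missing '+' separator line (wrapped FASTQ is not supported)"
                )
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"{where}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield SeqRead(header=head[1:], sequence=seq, quality=qual)
            record += 1


def load_pairs(input_list: InputList) -> PairStore:
    """Import all read pairs named by ``input_list`` into memory.

    Record ``i`` of mate file A and record ``i`` of mate file B form one
    :class:`ReadPair`; pairs from successive file pairs are concatenated in
    list order and assigned ordinals ``0 .. n-1``.

    Raises
    ------
    MateMismatchError
        If the two files of one pair hold different record counts; the
        message names both files and both counts (never silent truncation).
    FastqParseError
        Propagated from :func:`read_fastq` on any malformed record.
    """
    pairs: list[ReadPair] = []
    ordinal = 0
    for path_a, path_b in input_list.file_pairs:
        it_a, it_b = read_fastq(path_a), read_fastq(path_b)
        count_a = count_b = 0
        while True:
            r1 = next(it_a, None)
            r2 = next(it_b, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                count_a += sum(1 for _ in it_a) + (r1 is not None)
                count_b += sum(1 for _ in it_b) + (r2 is not None)
                raise MateMismatchError(
                    f"mate file length mismatch: {path_a} has {count_a} records "
                    f"but {path_b} has {count_b}"
                )
            count_a += 1
            count_b += 1
            pairs.append(ReadPair(r1, r2, ordinal))
            ordinal += 1
    return PairStore(pairs)


def _require_quality(pairs: Iterable[ReadPair]) -> None:
    for pair in pairs:
        for read in (pair.read1, pair.read2):
            if not read.quality:
                raise OutputModeError(
                    f"quality unavailable for FASTQ output (read '{read.header}')"
                )


def write_output(
    result,
    out1: PathLike,
    out2: PathLike | None,
    mode: str,
) -> int:
    """Write retained read pairs in one of the three output modes.

    ``result`` may be a :class:`~pairuniq.dedup.DedupResult` (its
    ``retained`` list is written) or any iterable of :class:`ReadPair`.
    Returns the number of pairs written.  Sequences, headers and qualities
    are emitted byte-identical to the input reads.
    """
    pairs = list(getattr(result, "retained", result))
    if mode not in OUTPUT_MODES:
        raise OutputModeError(f"unknown output mode {mode!r}; expected one of {OUTPUT_MODES}")
    if mode == "fasta-interleaved":
        if out2 is not None:
            raise OutputModeError("fasta-interleaved mode writes a single file; out2 must be absent")
        with open(out1, "w") as fh:
            for pair in pairs:
                fh.write(f">{pair.read1.header}\n{pair.read1.sequence}\n")
                fh.write(f">{pair.read2.header}\n{pair.read2.sequence}\n")
        return len(pairs)

    if out2 is None:
        raise OutputModeError(f"{mode} mode writes two files; out2 is required")
    if mode == "fastq-pair":
        _require_quality(pairs)
        with open(out1, "w") as fh1, open(out2, "w") as fh2:
            for pair in pairs:
                fh1.write(f"@{pair.read1.header}\n{pair.read1.sequence}\n+\n{pair.read1.quality}\n")
                fh2.write(f"@{pair.read2.header}\n{pair.read2.sequence}\n+\n{pair.read2.quality}\n")
    else:  # fasta-pair
        with open(out1, "w") as fh1, open(out2, "w") as fh2:
            for pair in pairs:
                fh1.write(f">{pair.read1.header}\n{pair.read1.sequence}\n")
                fh2.write(f">{pair.read2.header}\n{pair.read2.sequence}\n")
    return len(pairs)
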