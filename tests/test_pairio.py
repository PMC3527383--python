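"""Input-list parsing, paired FASTQ loading, and the three output writers."""

from __future__ import annotations

import gzip

import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from pairuniq.pairio import (
    FastqParseError,
    InputListError,
    MateMismatchError,
    OutputModeError,
    PairStore,
    load_pairs,
    parse_input_list,
    read_fastq,
    write_output,
)

from conftest import make_pair, write_fastq, write_paired_library


class TestParseInputList:
    def test_minimal_pair_of_files(self, tmp_path):
        lst = tmp_path / "list.txt"
        lst.write_text("a_1.fq\na_2.fq\n")
        parsed = parse_input_list(lst)
        assert [p.name for p in parsed.file_paths] == ["a_1.fq", "a_2.fq"]
        assert len(parsed.file_pairs) == 1

    def test_adjacent_lines_pair_up_in_order(self, tmp_path):
        lst = tmp_path / "list.txt"
        lst.write_text("a_1.fq\na_2.fq\nb_1.fq\nb_2.fq\n")
        pairs = parse_input_list(lst).file_pairs
        assert [(a.name, b.name) for a, b in pairs] == [
            ("a_1.fq", "a_2.fq"),
            ("b_1.fq", "b_2.fq"),
        ]

    def test_blank_lines_and_whitespace_ignored(self, tmp_path):
        lst = tmp_path / "list.txt"
        lst.write_text("\n  a_1.fq  \n\na_2.fq\n\n")
        assert len(parse_input_list(lst).file_paths) == 2

    def test_odd_count_rejected(self, tmp_path):
        lst = tmp_path / "list.txt"
        lst.write_text("a_1.fq\n")
        with pytest.raises(InputListError, match="unpaired file list.*1"):
            parse_input_list(lst)

    def test_empty_list_rejected(self, tmp_path):
        lst = tmp_path / "list.txt"
        lst.write_text("\n\n")
        with pytest.raises(InputListError, match="empty input list"):
            parse_input_list(lst)


class TestReadFastq:
    def test_agrees_with_biopython_on_well_formed_file(self, tmp_path):
        reads = [("r1 extra comment", "ACGTN", "IIIII"), ("r2", "GGCCA", "FFFFF")]
        path = write_fastq(tmp_path / "x.fq", reads)
        ours = [(r.header, r.sequence, r.quality) for r in read_fastq(path)]
        with open(path) as fh:
            ref = list(FastqGeneralIterator(fh))
        assert ours == ref == reads

    def test_gzip_input_detected_by_suffix(self, tmp_path):
        path = tmp_path / "x.fq.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("@r1\nACGT\n+\nIIII\n")
        [read] = list(read_fastq(path))
        assert (read.header, read.sequence, read.quality) == ("r1", "ACGT", "IIII")

    @pytest.mark.parametrize(
        "text,message",
        [
            ("r1\nACGT\n+\nIIII\n", "does not start with '@'"),
            ("@r1\nACGT\nIIII\n+\n", "missing '\\+' separator"),
            ("@r1\nACGT\n+\nIII\n", "quality length 3 != sequence length 4"),
            ("@r1\n\n+\n\n", "empty or missing sequence"),
            ("@r1\nAC GT\n+\nIIIII\n", "whitespace inside sequence"),
            ("@r1\nACGT\n+\nIIII\n@r2\nACGT\n", "record 1"),
        ],
        ids=["no-at", "no-plus", "qual-len", "empty-seq", "whitespace", "truncated"],
    )
    def test_malformed_records_rejected_with_location(self, tmp_path, text, message):
        path = tmp_path / "bad.fq"
        path.write_text(text)
        with pytest.raises(FastqParseError, match=message):
            list(read_fastq(path))


class TestLoadPairs:
    def test_records_zip_into_ordinal_numbered_pairs(self, tmp_path):
        pairs = [make_pair("ACGTACGTAC", "TGCATGCATG", ordinal=i) for i in range(3)]
        input_list = parse_input_list(write_paired_library(tmp_path, pairs))
        store = load_pairs(input_list)
        assert len(store) == 3
        assert [p.ordinal for p in store] == [0, 1, 2]
        assert store.get(2).read1.header == "p2/1"

    def test_multiple_file_pairs_concatenate_in_list_order(self, tmp_path):
        lib_a = [make_pair("AAAAAAAAAA", "CCCCCCCCCC", ordinal=i, name=f"a{i}") for i in range(2)]
        lib_b = [make_pair("GGGGGGGGGG", "TTTTTTTTTT", ordinal=i, name=f"b{i}") for i in range(3)]
        list_a = write_paired_library(tmp_path, lib_a, prefix="a")
        list_b = write_paired_library(tmp_path, lib_b, prefix="b")
        merged = tmp_path / "all.txt"
        merged.write_text(list_a.read_text() + list_b.read_text())
        store = load_pairs(parse_input_list(merged))
        assert len(store) == 5
        assert [p.read1.header for p in store] == ["a0/1", "a1/1", "b0/1", "b1/1", "b2/1"]
        assert [p.ordinal for p in store] == list(range(5))

    def test_mate_count_mismatch_names_files_and_counts(self, tmp_path):
        f1 = write_fastq(tmp_path / "a_1.fq", [("r", "ACGT", "IIII")] * 3)
        f2 = write_fastq(tmp_path / "a_2.fq", [("r", "ACGT", "IIII")] * 2)
        lst = tmp_path / "list.txt"
        lst.write_text(f"{f1}\n{f2}\n")
        with pytest.raises(MateMismatchError, match=r"a_1\.fq has 3 .*a_2\.fq has 2"):
            load_pairs(parse_input_list(lst))

    def test_duplicate_ordinals_rejected_by_store(self):
        with pytest.raises(ValueError, match="duplicate pair ordinal"):
            PairStore([make_pair("ACGT", "ACGT", 1), make_pair("TTTT", "TTTT", 1)])


class TestWriteOutput:
    def test_single_pair_fastq_mode_writes_four_lines_per_file(self, tmp_path):
        pair = make_pair("ACGTACGTAC", "TGCATGCATG")
        n = write_output([pair], tmp_path / "o1.fq", tmp_path / "o2.fq", "fastq-pair")
        assert n == 1
        assert (tmp_path / "o1.fq").read_text().count("\n") == 4
        assert (tmp_path / "o2.fq").read_text().count("\n") == 4

    def test_interleaved_fasta_adjacent_records_are_mates(self, tmp_path):
        pairs = [make_pair("AAAAAAAAAA", "CCCCCCCCCC", 0), make_pair("GGGGGGGGGG", "TTTTTTTTTT", 1)]
        out = tmp_path / "o.fa"
        assert write_output(pairs, out, None, "fasta-interleaved") == 2
        headers = [l[1:] for l in out.read_text().splitlines() if l.startswith(">")]
        assert headers == ["p0/1", "p0/2", "p1/1", "p1/2"]

    def test_fasta_pair_mode_writes_synchronized_files(self, tmp_path):
        pairs = [make_pair("ACGTACGTAC", "TGCATGCATG", i, name=f"x{i}") for i in range(3)]
        write_output(pairs, tmp_path / "o1.fa", tmp_path / "o2.fa", "fasta-pair")
        h1 = [l[1:] for l in (tmp_path / "o1.fa").read_text().splitlines() if l.startswith(">")]
        h2 = [l[1:] for l in (tmp_path / "o2.fa").read_text().splitlines() if l.startswith(">")]
        assert h1 == ["x0/1", "x1/1", "x2/1"]
        assert h2 == ["x0/2", "x1/2", "x2/2"]

    def test_roundtrip_preserves_bytes(self, tmp_path):
        pairs = [make_pair("ACGTNACGTA", "TTGGCCAATT", i) for i in range(4)]
        input_list = write_paired_library(tmp_path, pairs)
        store = load_pairs(parse_input_list(input_list))
        write_output(store, tmp_path / "o1.fq", tmp_path / "o2.fq", "fastq-pair")
        lst2 = tmp_path / "roundtrip.txt"
        lst2.write_text(f"{tmp_path / 'o1.fq'}\n{tmp_path / 'o2.fq'}\n")
        store2 = load_pairs(parse_input_list(lst2))
        as_triples = lambda s: [
            (p.read1.header, p.read1.sequence, p.read1.quality,
             p.read2.header, p.read2.sequence, p.read2.quality)
            for p in s
        ]
        assert as_triples(store) == as_triples(store2)

    def test_missing_quality_blocks_fastq_mode(self, tmp_path):
        pair = make_pair("ACGTACGTAC", "TGCATGCATG")
        pair.read2.quality = ""
        with pytest.raises(OutputModeError, match="quality unavailable for FASTQ output"):
            write_output([pair], tmp_path / "o1.fq", tmp_path / "o2.fq", "fastq-pair")

    @pytest.mark.parametrize(
        "mode,out2", [("fasta-interleaved", "o2.fa"), ("fastq-pair", None), ("fasta-pair", None)]
    )
    def test_out2_presence_must_match_mode(self, tmp_path, mode, out2):
        pair = make_pair("ACGTACGTAC", "TGCATGCATG")
        out2_path = tmp_path / out2 if out2 else None
        with pytest.raises(OutputModeError):
            write_output([pair], tmp_path / "o1", out2_path, mode)
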