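"""Barcode extraction, trimming, length filters and pair merging."""

import pytest
from hypothesis import given, strategies as st

from scindel.reads import (Discard, FilterStats, ReadRecord, ReadStructure,
                           TaggedRead, extract_and_trim, filter_stream,
                           merge_pair, read_fastq, write_fastq)
from scindel.seq import revcomp
from scindel.simulate import default_read_structure


def _build_read(structure: ReadStructure, bc1: str, bc2: str,
                payload: str, read_id: str = "r") -> ReadRecord:
    seq = (structure.constant_1 + bc1 + structure.constant_2 + bc2
           + structure.constant_3 + payload)
    return ReadRecord(read_id=read_id, seq=seq)


BC1, BC2 = "ACGTACGTA", "TTGCATGCA"


class TestExtractAndTrim:
    def test_exact_construction_inverted(self, structure):
        payload = "ACGT" * 15  # 60 nt
        read = _build_read(structure, BC1, BC2, payload)
        out = extract_and_trim(read, structure)
        assert isinstance(out, TaggedRead)
        assert out.barcode == BC1 + BC2
        assert len(out.barcode) == 18
        assert out.payload_seq == payload

    def test_payload_of_45_is_short_read(self, structure):
        read = _build_read(structure, BC1, BC2, "A" * 45)
        out = extract_and_trim(read, structure)
        assert out == Discard("short_read")

    def test_payload_of_46_is_retained(self, structure):
        read = _build_read(structure, BC1, BC2, "A" * 46)
        assert isinstance(extract_and_trim(read, structure), TaggedRead)

    def test_truncated_barcode_is_short_barcode(self, structure):
        # read ends inside the second barcode: 17 barcode bases total
        full = _build_read(structure, BC1, BC2, "")
        cut = len(structure.constant_1) + 9 + len(structure.constant_2) + 8
        read = ReadRecord("r", full.seq[:cut])
        assert extract_and_trim(read, structure) == Discard("short_barcode")

    def test_corrupt_constant_is_structure_not_found(self, structure):
        read = _build_read(structure, BC1, BC2, "A" * 60)
        corrupted = "N" + read.seq[1:]
        out = extract_and_trim(ReadRecord("r", corrupted), structure)
        assert out == Discard("structure_not_found")

    def test_one_mismatch_tolerated_when_configured(self, structure):
        read = _build_read(structure, BC1, BC2, "A" * 60)
        corrupted = ReadRecord("r", "N" + read.seq[1:])
        lenient = ReadStructure(structure.constant_1, structure.constant_2,
                                structure.constant_3,
                                max_constant_mismatches=1)
        out = extract_and_trim(corrupted, lenient)
        assert isinstance(out, TaggedRead)
        assert out.barcode == BC1 + BC2

    @given(st.integers(0, 2**32 - 1))
    def test_pure_function_roundtrip_property(self, seed):
        """Extraction inverts construction for any barcode/payload draw."""
        import numpy as np
        rng = np.random.default_rng(seed)
        structure = default_read_structure()
        bases = "ACGT"
        bc1 = "".join(bases[c] for c in rng.integers(0, 4, 9))
        bc2 = "".join(bases[c] for c in rng.integers(0, 4, 9))
        payload = "".join(bases[c] for c in rng.integers(0, 4, 46 + int(rng.integers(0, 100))))
        read = _build_read(structure, bc1, bc2, payload)
        out = extract_and_trim(read, structure)
        assert isinstance(out, TaggedRead)
        assert out.barcode == bc1 + bc2
        assert out.payload_seq == payload


class TestMergePair:
    def test_overlap_reconstructs_template(self, rng):
        template = "".join("ACGT"[c] for c in rng.integers(0, 4, 150))
        r1 = ReadRecord("p", template[:100], "I" * 100)
        r2 = ReadRecord("p", revcomp(template[50:]), "I" * 100)
        merged = merge_pair(r1, r2, min_overlap=20)
        assert merged.seq == template

    def test_non_overlapping_pair_is_concatenated(self):
        r1 = ReadRecord("p", "ACGTACGTACGTACG")
        r2 = ReadRecord("p", "TTTTGGGGCCCCAAA")
        merged = merge_pair(r1, r2, min_overlap=10)
        assert merged.seq == r1.seq + revcomp(r2.seq)

    def test_conflict_resolved_by_quality(self, rng):
        template = "".join("ACGT"[c] for c in rng.integers(0, 4, 120))
        r1 = ReadRecord("p", template[:80], "I" * 80)
        # mate covers [40, 120); corrupt its copy of position 50, low quality
        mate_region = list(template[40:])
        pos_in_mate = 10  # template position 50
        mate_region[pos_in_mate] = "A" if mate_region[pos_in_mate] != "A" else "C"
        r2_seq = revcomp("".join(mate_region))
        r2 = ReadRecord("p", r2_seq, "#" * len(r2_seq))
        merged = merge_pair(r1, r2, min_overlap=20)
        # hand-computed: overlap [40, 80) resolved from r1 (higher quality)
        assert merged.seq[:80] == template[:80]
        assert merged.seq == template[:80] + template[80:]


class TestFilterStream:
    def test_known_mixture_tally(self, structure):
        good = [_build_read(structure, BC1, BC2, "C" * 60, f"g{i}")
                for i in range(7)]
        short = [_build_read(structure, BC1, BC2, "C" * 45, f"s{i}")
                 for i in range(2)]
        trunc = ReadRecord("t0", _build_read(structure, BC1, BC2, "").seq[:40])
        tagged, stats = filter_stream(good + short + [trunc], structure)
        assert stats.n_input == 10
        assert stats.n_retained == 7
        assert stats.discards["short_read"] == 2
        assert stats.discards["short_barcode"] == 1
        assert len(tagged) == 7

    def test_empty_input(self, structure):
        tagged, stats = filter_stream([], structure)
        assert tagged == []
        assert stats.n_input == 0
        assert stats.n_retained == 0
        assert sum(stats.discards.values()) == 0

    @given(st.integers(0, 2**32 - 1))
    def test_conservation_property(self, seed):
        """input = retained + sum of discard reasons, always."""
        import numpy as np
        rng = np.random.default_rng(seed)
        structure = default_read_structure()
        reads = []
        for i in range(30):
            kind = rng.integers(0, 3)
            payload = "G" * int(rng.integers(0, 100))
            read = _build_read(structure, BC1, BC2, payload, f"r{i}")
            if kind == 2:  # random corruption somewhere in the prefix
                p = int(rng.integers(0, structure.prefix_len))
                read = ReadRecord(read.read_id,
                                  read.seq[:p] + "N" + read.seq[p + 1:])
            reads.append(read)
        _, stats = filter_stream(reads, structure)
        assert stats.n_input == stats.n_retained + sum(stats.discards.values())


class TestFastqIO:
    def test_roundtrip(self, tmp_path):
        reads = [ReadRecord("a", "ACGT", "IIII"), ReadRecord("b", "GGCC")]
        path = tmp_path / "x.fastq"
        write_fastq(reads, path)
        back = list(read_fastq(path))
        assert [r.seq for r in back] == ["ACGT", "GGCC"]
        assert back[0].qual == "IIII"

    def test_malformed_fastq_reports_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@ok\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="malformed FASTQ record at index"):
            list(read_fastq(path))
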