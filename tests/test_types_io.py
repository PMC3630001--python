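"""Domain types, coordinate handling, and file round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readscrub.io import (
    parse_psl_line,
    read_protocol,
    read_psl,
    read_reads,
    write_cleaned,
    write_protocol,
    write_psl,
    format_psl_record,
)
from readscrub.types import Interval, ProtocolSpec, PslRecord, Read, reverse_complement

dna = st.text(alphabet="ACGTN", min_size=1, max_size=40)


class TestRead:
    def test_initial_clean_spans_sequence(self):
        r = Read(id="r1", seq="ACGT")
        assert r.clean == Interval(0, 4) and r.status == "active"

    def test_qual_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="r1"):
            Read(id="r1", seq="ACGT", qual=[30, 30, 30])

    def test_set_clean_refuses_to_widen_and_logs_nested_intervals(self):
        r = Read(id="r1", seq="A" * 20)
        r.set_clean("s1", Interval(2, 18))
        r.set_clean("s2", Interval(5, 15))
        with pytest.raises(ValueError):
            r.set_clean("s3", Interval(0, 20))
        for _, before, after in r.trim_log:
            assert before.start <= after.start <= after.end <= before.end

    def test_discard_records_reason(self):
        r = Read(id="r1", seq="ACGT")
        r.discard("no_barcode")
        assert r.status == "discarded" and r.discard_reason == "no_barcode"


@given(dna)
@settings(max_examples=100, deadline=None)
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


class TestReadReads:
    def test_fasta_full_span_interval(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">r1\nACGT\n")
        (read,) = read_reads(str(p))
        assert read.id == "r1" and read.seq == "ACGT" and read.clean == Interval(0, 4)
        assert read.qual is None

    def test_fastq_phred33_decoding(self, tmp_path):
        p = tmp_path / "in.fastq"
        p.write_text("@r1\nAC\n+\nII\n")
        (read,) = read_reads(str(p))
        assert read.qual == [40, 40]

    def test_qual_pairing_and_length_mismatch(self, tmp_path):
        fa = tmp_path / "in.fasta"
        qa = tmp_path / "in.qual"
        fa.write_text(">r1\nACGT\n")
        qa.write_text(">r1\n30 30 30\n")
        with pytest.raises(ValueError, match="r1"):
            list(read_reads(str(fa), str(qa)))

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">r1\nACGT\n>r1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            list(read_reads(str(p)))


class TestWriteCleaned:
    def test_clean_subsequence_extraction(self, tmp_path):
        r = Read(id="r1", seq="AAACGTAAA")
        r.set_clean("x", Interval(3, 6))
        out = tmp_path / "out.fasta"
        write_cleaned([r], str(out))
        assert ">r1" in out.read_text() and "\nCGT\n" in out.read_text()

    def test_discard_reason_in_header(self, tmp_path):
        r = Read(id="r1", seq="ACGT")
        r.discard("no_barcode")
        out, disc = tmp_path / "o.fasta", tmp_path / "d.fasta"
        write_cleaned([r], str(out), discarded_fasta=str(disc))
        assert "no_barcode" in disc.read_text()
        assert out.read_text() == ""

    def test_empty_interval_moves_read_to_discarded(self, tmp_path):
        r = Read(id="r1", seq="ACGT")
        r.set_clean("x", Interval(2, 2))
        out, disc = tmp_path / "o.fasta", tmp_path / "d.fasta"
        counts = write_cleaned([r], str(out), discarded_fasta=str(disc))
        assert counts == {"cleaned": 0, "discarded": 1}
        assert "empty_after_trim" in disc.read_text()

    def test_zero_reads_gives_valid_empty_file(self, tmp_path):
        out = tmp_path / "o.fasta"
        write_cleaned([], str(out))
        assert out.read_text() == ""

    def test_full_span_round_trip_is_identity(self, tmp_path, rng):
        from conftest import random_dna

        seqs = {f"r{i}": random_dna(rng, int(rng.integers(1, 80))) for i in range(10)}
        src = tmp_path / "src.fasta"
        src.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        out = tmp_path / "out.fasta"
        write_cleaned(list(read_reads(str(src))), str(out))
        back = {r.id: r.seq for r in read_reads(str(out))}
        assert back == seqs


class TestProtocol:
    def test_role_encoded_headers(self, tmp_path):
        p = tmp_path / "proto.fasta"
        p.write_text(">MID1|barcode\nACGAGTGCGT\n>P1|amp5\nAAGCAGTGGT\n")
        spec = read_protocol(str(p))
        assert spec.barcodes == {"MID1": "ACGAGTGCGT"}
        assert spec.primers == [("P1", "AAGCAGTGGT", "amp5")]

    def test_unknown_role_rejected(self, tmp_path):
        p = tmp_path / "proto.fasta"
        p.write_text(">X|frobnicate\nACGT\n")
        with pytest.raises(ValueError, match="unknown role"):
            read_protocol(str(p))

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "proto.fasta"
        p.write_text(">X|barcode\n\n>Y|barcode\nACGT\n")
        with pytest.raises(ValueError):
            read_protocol(str(p))

    def test_export_import_round_trip(self, tmp_path, protocol):
        p = tmp_path / "proto.fasta"
        write_protocol(protocol, str(p))
        back = read_protocol(str(p))
        assert back == protocol

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(adapters5=[("a", "ACGT"), ("a", "GGGG")])


class TestPsl:
    LINE = (
        "90\t2\t0\t0\t0\t0\t1\t8\t+\tread1\t92\t0\t92\tchr1\t1000\t100\t200\t2\t"
        "50,42,\t0,50,\t100,158,"
    )

    def test_parse_21_column_row(self):
        rec = parse_psl_line(self.LINE)
        assert rec.q_name == "read1" and rec.t_start == 100 and rec.strand == "+"
        assert rec.block_sizes == (50, 42)

    def test_reject_short_rows(self):
        with pytest.raises(ValueError, match="columns"):
            parse_psl_line("\t".join(self.LINE.split("\t")[:15]))

    def test_round_trip_through_file(self, tmp_path):
        rec = parse_psl_line(self.LINE)
        path = tmp_path / "a.psl"
        write_psl([rec], str(path))
        assert read_psl(str(path)) == [rec]

    def test_invalid_interval_rejected(self):
        rec = self.LINE.split("\t")
        rec[11], rec[12] = "92", "0"  # qstart >= qend
        with pytest.raises(ValueError):
            parse_psl_line("\t".join(rec))
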