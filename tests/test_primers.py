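"""Middle/end acceptance criteria, the error taxonomy, and trimming."""

import pytest

from readscrub.align import FORWARD, REVERSE, AlignmentHit
from readscrub.primers import (
    MatchCriteria,
    ReadErrorType,
    TrimPolicy,
    classify_read,
    locate_hits,
    trim_by_hits,
)
from readscrub.types import Interval, Read, reverse_complement

PRIMER = "AAGCAGTGGTATCAACGCAG"  # 20 bp
FILLER = ("GCTAGCTTGCAGTGCGCTCCAGGCTACCTGGACTGCTTGA" * 12)[:400]


def _read(seq: str) -> Read:
    return Read(id="r", seq=seq)


class TestLocateHits:
    def test_internal_exact_match_is_a_middle_hit(self):
        seq = FILLER[:100] + PRIMER + FILLER[100:380]
        hits = locate_hits(
            _read(seq), [("P", PRIMER, "amp5")],
            MatchCriteria(middle_min_len=16, middle_min_pid=94.0),
        )
        assert len(hits) == 1
        h = hits[0]
        assert h.read_iv == Interval(100, 120) and h.pid == 100.0

    def test_partial_primer_at_read_start_is_an_end_hit(self):
        seq = PRIMER[8:] + FILLER[:120]  # last 12 primer bases begin the read
        hits = locate_hits(
            _read(seq), [("P", PRIMER, "amp5")],
            MatchCriteria(end_max_unaligned_subj=8, end_max_unaligned_read=0),
        )
        assert len(hits) == 1 and hits[0].overhang_subj_left == 8
        assert hits[0].read_iv.start == 0

    def test_end_hit_rejected_when_subject_overhang_exceeds_limit(self):
        seq = PRIMER[8:] + FILLER[:120]
        hits = locate_hits(
            _read(seq), [("P", PRIMER, "amp5")],
            MatchCriteria(end_max_unaligned_subj=5, end_max_unaligned_read=0),
        )
        assert hits == []

    def test_middle_hit_rejected_below_min_length(self):
        seq = FILLER[:100] + PRIMER + FILLER[100:380]
        hits = locate_hits(
            _read(seq), [("P", PRIMER, "amp5")], MatchCriteria(middle_min_len=25)
        )
        assert hits == []

    def test_every_returned_hit_satisfies_its_criterion(self):
        crit = MatchCriteria()
        seq = PRIMER[10:] + FILLER[:200] + PRIMER + FILLER[200:350]
        read = _read(seq)
        for h in locate_hits(read, [("P", PRIMER, "amp5")], crit):
            zone = crit.zone()
            if h.overhang_read_5 <= zone or h.overhang_read_3 <= zone:
                assert h.pid >= crit.end_min_pid
            else:
                assert h.aln_len >= crit.middle_min_len and h.pid >= crit.middle_min_pid

    def test_middle_hits_stable_under_flanking_sequence(self):
        crit = MatchCriteria()
        core = FILLER[:80] + PRIMER + FILLER[80:160]
        h1 = locate_hits(_read(core), [("P", PRIMER, "amp5")], crit)
        extended = FILLER[160:240] + core + FILLER[240:320]
        h2 = locate_hits(_read(extended), [("P", PRIMER, "amp5")], crit)
        assert len(h1) == len(h2) == 1
        assert h2[0].read_iv.start - h1[0].read_iv.start == 80
        assert h1[0].pid == h2[0].pid and h1[0].aln_len == h2[0].aln_len


def _hit(orientation, start, end, name="P", role="amp5"):
    return AlignmentHit(
        subject_name=name, subject_role=role, orientation=orientation,
        read_iv=Interval(start, end), subj_iv=Interval(0, end - start),
        pid=100.0, aln_len=end - start, matches=end - start, score=end - start,
        overhang_read_5=start, overhang_read_3=0,
        overhang_subj_left=0, overhang_subj_right=0,
    )


class TestClassifyRead:
    CRIT = MatchCriteria()

    def test_flush_forward_hit_is_ok(self):
        read = Read(id="r", seq="A" * 400)
        assert classify_read([_hit(FORWARD, 0, 20)], read, self.CRIT) == ReadErrorType.OK

    def test_reverse_then_forward_is_rf(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(REVERSE, 0, 20), _hit(FORWARD, 380, 400)]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.RF

    def test_same_primer_both_orientations_is_fr(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(FORWARD, 0, 20), _hit(REVERSE, 380, 400)]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.fr

    def test_forward_hit_with_leading_gap_is_sf(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(FORWARD, 7, 27), _hit(REVERSE, 380, 400, name="Q", role="amp3")]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.SF

    def test_reverse_hit_with_trailing_gap_is_re(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(FORWARD, 0, 20), _hit(REVERSE, 350, 370, name="Q", role="amp3")]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.RE

    def test_multiple_forward_matches_are_nf(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(FORWARD, 0, 20), _hit(FORWARD, 200, 220), _hit(FORWARD, 300, 320)]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.NF

    def test_multiple_reverse_matches_are_nr(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(REVERSE, 300, 320, name="Q", role="amp3"),
                _hit(REVERSE, 380, 400, name="Q", role="amp3")]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.NR

    def test_rf_takes_precedence_over_nf(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(REVERSE, 0, 20, name="Q", role="amp3"),
                _hit(FORWARD, 100, 120), _hit(FORWARD, 380, 400)]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.RF

    def test_non_primer_hits_are_ignored(self):
        read = Read(id="r", seq="A" * 400)
        hits = [_hit(FORWARD, 50, 70, name="vec", role="vector")]
        assert classify_read(hits, read, self.CRIT) == ReadErrorType.OK


class TestTrimByHits:
    CRIT = MatchCriteria()

    def test_ok_read_trims_between_flush_hits(self):
        read = Read(id="r", seq="G" * 400)
        hits = [_hit(FORWARD, 0, 20), _hit(REVERSE, 380, 400, name="Q", role="amp3")]
        trim_by_hits(read, hits, TrimPolicy(), self.CRIT, kind=ReadErrorType.OK)
        assert read.clean == Interval(20, 380)

    def test_nf_salvage_keeps_longest_hit_free_interval(self):
        read = Read(id="r", seq="G" * 400)
        hits = [_hit(FORWARD, 0, 20), _hit(FORWARD, 200, 220)]
        trim_by_hits(read, hits, TrimPolicy(), self.CRIT, kind=ReadErrorType.NF)
        assert read.clean == Interval(20, 200)

    def test_rf_discarded_by_default_policy(self):
        read = Read(id="r", seq="G" * 400)
        hits = [_hit(REVERSE, 0, 20), _hit(FORWARD, 380, 400)]
        trim_by_hits(read, hits, TrimPolicy(), self.CRIT, kind=ReadErrorType.RF)
        assert read.status == "discarded" and read.discard_reason == "primer_RF"

    def test_primer_only_read_is_discarded(self):
        read = Read(id="r", seq="G" * 40)
        hits = [_hit(FORWARD, 0, 20), _hit(REVERSE, 20, 40, name="Q", role="amp3")]
        trim_by_hits(read, hits, TrimPolicy(), self.CRIT, kind=ReadErrorType.OK)
        assert read.status == "discarded" and read.discard_reason == "primer_only"

    def test_trimming_never_widens_the_interval(self):
        read = Read(id="r", seq="G" * 400)
        read.set_clean("x", Interval(10, 390))
        hits = [_hit(FORWARD, 10, 30)]
        trim_by_hits(read, hits, TrimPolicy(), self.CRIT, kind=ReadErrorType.OK)
        assert 10 <= read.clean.start and read.clean.end <= 390
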