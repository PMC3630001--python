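"""Alignment kernels against brute-force dynamic-programming oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ends_free_nw_score, semiglobal_distance
from readscrub.align import (
    FORWARD,
    REVERSE,
    Seed,
    banded_nw_extend,
    seed_hits,
    semiglobal_prefix_align,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=25)


class TestSemiglobalPrefix:
    @pytest.mark.parametrize(
        "pattern,read,max_errors,errors,read_end,aligned",
        [
            ("ACGT", "ACGTTTTT", 0, 0, 4, True),   # exact prefix
            ("ACGT", "ATGTTTTT", 1, 1, 4, True),   # one substitution
            ("ACGT", "AGTTTTTT", 1, 1, 3, True),   # one deletion, shorter prefix
            ("ACGT", "TTTTACGT", 2, 3, None, False),  # min distance 3 > 2
        ],
    )
    def test_known_alignments(self, pattern, read, max_errors, errors, read_end, aligned):
        res = semiglobal_prefix_align(pattern, read, max_errors)
        assert res.aligned is aligned
        assert res.errors == errors
        if read_end is not None:
            assert res.read_end == read_end

    def test_oracle_confirms_frozen_examples(self):
        assert semiglobal_distance("ACGT", "ATGTTTTT") == (1, 4)
        assert semiglobal_distance("ACGT", "AGTTTTTT") == (1, 3)
        assert semiglobal_distance("ACGT", "TTTTACGT")[0] == 3

    @given(pattern=st.text(alphabet="ACGTN", min_size=1, max_size=12),
           read=st.text(alphabet="ACGTN", min_size=0, max_size=25),
           max_errors=st.integers(min_value=0, max_value=3))
    @settings(max_examples=300, deadline=None)
    def test_matches_full_dp_oracle(self, pattern, read, max_errors):
        want_err, want_end = semiglobal_distance(pattern, read)
        res = semiglobal_prefix_align(pattern, read, max_errors)
        assert res.errors == want_err
        assert res.aligned == (want_err <= max_errors)
        assert res.read_end == want_end  # smallest end achieving the minimum

    def test_n_bases_never_match(self):
        assert semiglobal_prefix_align("NNNN", "NNNN", 0).aligned is False
        assert semiglobal_prefix_align("ACGT", "ANGT", 1).errors == 1


class TestSeedHits:
    def test_unique_exact_word_found_forward(self):
        seeds = seed_hits("ACGTACGT", "TTACGTACGTTT", 8)
        fwd = [s for s in seeds if s.orientation == FORWARD]
        assert len(fwd) == 1 and fwd[0].read_start == 2 and fwd[0].subj_start == 0

    def test_reverse_complement_word_found(self):
        seeds = seed_hits("AAAA", "TTTT", 4)
        assert [s.orientation for s in seeds] == [REVERSE]

    def test_no_shared_word_gives_empty_list(self):
        assert seed_hits("ACGT", "GGGGGGGG", 4) == []

    def test_subject_shorter_than_word_gives_empty_list(self):
        assert seed_hits("ACG", "ACGTACGTACGT", 4) == []

    def test_word_size_below_four_rejected(self):
        with pytest.raises(ValueError):
            seed_hits("ACGT", "ACGT", 3)

    @given(subject=st.text(alphabet="ACGT", min_size=8, max_size=16),
           prefix=st.text(alphabet="ACGT", max_size=20))
    @settings(max_examples=150, deadline=None)
    def test_exact_occurrence_is_always_seeded(self, subject, prefix):
        read = prefix + subject + "GG"
        seeds = seed_hits(subject, read, 8)
        pos = read.find(subject)
        assert any(
            s.orientation == FORWARD and s.read_start <= pos and s.read_end >= pos + len(subject)
            or s.orientation == REVERSE
            for s in seeds
        )
        assert any(s.orientation == FORWARD for s in seeds)


def _full_anchor(subject, read):
    # zero-width anchor at the origin; with a large band this covers everything
    return Seed(0, 0, 0, 0, FORWARD)


class TestBandedExtend:
    def test_identical_sequences_align_perfectly(self):
        s = "ACGTACGTGGCCAATTCCGA"
        hit = banded_nw_extend(s, s, _full_anchor(s, s), band=len(s))
        assert hit.pid == 100.0 and hit.aln_len == 20
        assert (hit.overhang_subj_left, hit.overhang_subj_right) == (0, 0)
        assert (hit.overhang_read_5, hit.overhang_read_3) == (0, 0)

    def test_single_substitution_gives_pid_95(self):
        s = "ACGTACGTGGCCAATTCCGA"
        r = s[:10] + "T" + s[11:]
        assert s[10] != "T"
        hit = banded_nw_extend(s, r, _full_anchor(s, r), band=len(s))
        assert hit.aln_len == 20 and hit.pid == pytest.approx(95.0)
        assert hit.score == ends_free_nw_score(s, r)

    def test_subject_running_past_read_end_becomes_overhang(self):
        s = "ACGTACGTGGCCAATTCCGA"
        r = s[:17]  # last 3 subject bases fall off the read 3' end
        hit = banded_nw_extend(s, r, _full_anchor(s, r), band=len(s))
        assert hit.overhang_subj_right == 3 and hit.overhang_subj_left == 0
        assert hit.pid == 100.0 and hit.aln_len == 17

    def test_band_too_small_to_bridge_insertion_leaves_overhang(self):
        s = "ACGTACGTGGCCAATTCCGA"
        r = s[:10] + "T" * 8 + s[10:]  # 8-base insertion shifts the diagonal
        anchor = Seed(0, 10, 0, 10, FORWARD)
        hit = banded_nw_extend(s, r, anchor, band=3)
        assert hit.overhang_subj_right >= 7  # second half unreachable in-band

    def test_band_below_one_rejected(self):
        with pytest.raises(ValueError):
            banded_nw_extend("ACGT", "ACGT", _full_anchor("ACGT", "ACGT"), band=0)

    @given(subject=st.text(alphabet="ACGT", min_size=4, max_size=20),
           read=st.text(alphabet="ACGT", min_size=4, max_size=20))
    @settings(max_examples=250, deadline=None)
    def test_wide_band_equals_unbanded_score(self, subject, read):
        want = ends_free_nw_score(subject, read)
        hit = banded_nw_extend(subject, read, _full_anchor(subject, read),
                               band=max(len(subject), len(read)))
        if hit is None:
            assert want <= 0
        else:
            assert hit.score == want

    def test_hit_invariant_under_distant_flanking_sequence(self, rng):
        from conftest import random_dna

        subject = random_dna(rng, 20)
        insert_at = 30
        read = random_dna(rng, insert_at) + subject + random_dna(rng, 25)
        seeds = [s for s in seed_hits(subject, read, 11) if s.orientation == FORWARD]
        hit = banded_nw_extend(subject, read, seeds[0], band=5)
        extended = read + random_dna(rng, 40)
        seeds2 = [s for s in seed_hits(subject, extended, 11) if s.orientation == FORWARD]
        hit2 = banded_nw_extend(subject, extended, seeds2[0], band=5)
        assert hit.read_iv == hit2.read_iv
        assert hit.pid == hit2.pid and hit.score == hit2.score
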