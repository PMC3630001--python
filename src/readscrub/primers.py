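"""Adapter/primer location, middle/end acceptance criteria, the erroneous-read
taxonomy, and the trimming consequences.

Acceptance criteria distinguish where a contaminant lands:

* **middle match** — the hit sits away from both ends of the clean
  interval; it must be near-perfect (``aln_len >= middle_min_len`` and
  ``pid >= middle_min_pid``).
* **end match** — the hit starts within ``end_zone`` of the 5' clean
  boundary or ends within ``end_zone`` of the 3' one; it may be partial,
  gated instead by ``pid >= end_min_pid``, at most ``end_max_unaligned_subj``
  subject bases hanging beyond the read end, and at most
  ``end_max_unaligned_read`` read bases left outside the hit toward that
  end.

Amplification-primer hits are then classified into the error taxonomy:

========  =====================================================
OK        at most one forward hit flush at the 5' end and/or one
          reverse hit flush at the 3' end
RF        reverse then forward primer (misoriented insert)
fr        forward and reverse matches of the same primer
SF        forward 5' hit with unaligned read bases before it
RE        reverse 3' hit with unaligned read bases after it
NF / NR   two or more forward / reverse matches (concatenation)
========  =====================================================

Precedence when several apply: RF > fr > NF > NR > SF > RE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .align import FORWARD, REVERSE, AlignmentHit, find_hits
from .types import Interval, Read


class ReadErrorType(str, enum.Enum):
    OK = "OK"
    RF = "RF"
    fr = "fr"
    SF = "SF"
    RE = "RE"
    NF = "NF"
    NR = "NR"


@dataclass(frozen=True)
class MatchCriteria:
    """Middle/end acceptance thresholds for adapter and primer hits.

    ``end_max_unaligned_subj=None`` means ``len(subject) - 8`` per subject
    (at least eight subject bases must align).  ``end_zone=None`` derives
    the zone as ``end_max_unaligned_read + 3``.  ``classify_flush_tol`` is
    the number of boundary bases tolerated before a hit still counts as
    flush with an end for classification purposes.
    """

    middle_min_len: int = 15
    middle_min_pid: float = 94.0
    end_min_pid: float = 90.0
    end_max_unaligned_subj: int | None = None
    end_max_unaligned_read: int = 2
    end_zone: int | None = None
    classify_flush_tol: int = 3

    def __post_init__(self) -> None:
        if self.middle_min_len < 0 or self.end_max_unaligned_read < 0:
            raise ValueError("lengths must be >= 0")
        for p in (self.middle_min_pid, self.end_min_pid):
            if not (0 <= p <= 100):
                raise ValueError("percent identities must be in [0, 100]")

    def zone(self) -> int:
        return self.end_zone if self.end_zone is not None else self.end_max_unaligned_read + 3

    def max_unaligned_subj(self, subject_len: int) -> int:
        if self.end_max_unaligned_subj is not None:
            return self.end_max_unaligned_subj
        return max(0, subject_len - 8)


def _passes(hit: AlignmentHit, subject_len: int, clean_len: int, criteria: MatchCriteria) -> bool:
    zone = criteria.zone()
    at5 = hit.overhang_read_5 <= zone
    at3 = hit.overhang_read_3 <= zone
    if not (at5 or at3):
        return (
            hit.aln_len >= criteria.middle_min_len and hit.pid >= criteria.middle_min_pid
        )
    if hit.pid < criteria.end_min_pid:
        return False
    max_subj = criteria.max_unaligned_subj(subject_len)
    if at5 and (
        hit.overhang_subj_left <= max_subj
        and hit.overhang_read_5 <= criteria.end_max_unaligned_read
    ):
        return True
    if at3 and (
        hit.overhang_subj_right <= max_subj
        and hit.overhang_read_3 <= criteria.end_max_unaligned_read
    ):
        return True
    return False


def locate_hits(
    read: Read,
    subjects: list[tuple[str, str, str]],
    criteria: MatchCriteria,
    word_size: int = 11,
    band: int = 5,
) -> list[AlignmentHit]:
    """All accepted hits of the subjects in the read's clean interval.

    Subjects are (name, sequence, role) triples.  Hits are searched on the
    clean subsequence (both orientations), converted to full-read
    coordinates, filtered by the middle/end criteria, and sorted by read
    position.
    """
    if read.status != "active":
        return []
    clean_seq = read.clean_seq
    accepted: list[AlignmentHit] = []
    for name, seq, role in subjects:
        for hit in find_hits(name, seq, role, clean_seq, word_size=word_size, band=band):
            shifted = hit.shifted(read.clean.start, len(read.seq), read.clean)
            if _passes(shifted, len(seq), read.clean.length, criteria):
                accepted.append(shifted)
    accepted.sort(key=lambda h: (h.read_iv.start, h.read_iv.end))
    return accepted


def classify_read(
    hits: list[AlignmentHit], read: Read, criteria: MatchCriteria
) -> ReadErrorType:
    """Classify a read into the erroneous-read taxonomy from its
    amplification-primer hits."""
    primer_hits = [h for h in hits if h.subject_role in ("amp5", "amp3")]
    tol = criteria.classify_flush_tol
    fwd = [h for h in primer_hits if h.orientation == FORWARD]
    rev = [h for h in primer_hits if h.orientation == REVERSE]
    if primer_hits:
        first = min(primer_hits, key=lambda h: h.read_iv.start)
        last = max(primer_hits, key=lambda h: h.read_iv.end)
        if (
            first.orientation == REVERSE
            and last.orientation == FORWARD
            and first is not last
        ):
            return ReadErrorType.RF
        fwd_names = {h.subject_name for h in fwd}
        rev_names = {h.subject_name for h in rev}
        if fwd_names & rev_names:
            return ReadErrorType.fr
        if len(fwd) >= 2:
            return ReadErrorType.NF
        if len(rev) >= 2:
            return ReadErrorType.NR
        if (
            first.orientation == FORWARD
            and first.read_iv.start - read.clean.start > tol
        ):
            return ReadErrorType.SF
        if (
            last.orientation == REVERSE
            and read.clean.end - last.read_iv.end > tol
        ):
            return ReadErrorType.RE
    return ReadErrorType.OK


DISCARD = "discard"
SALVAGE = "salvage"


@dataclass(frozen=True)
class TrimPolicy:
    """What to do with each erroneous read type.

    Concatenation/misorientation artifacts (RF, fr) are fatal by default;
    the remaining types salvage the longest hit-free sub-interval.
    """

    actions: dict = field(
        default_factory=lambda: {
            ReadErrorType.RF: DISCARD,
            ReadErrorType.fr: DISCARD,
            ReadErrorType.SF: SALVAGE,
            ReadErrorType.RE: SALVAGE,
            ReadErrorType.NF: SALVAGE,
            ReadErrorType.NR: SALVAGE,
        }
    )

    def action(self, kind: ReadErrorType) -> str:
        return self.actions.get(kind, SALVAGE)


def _longest_free_segment(clean: Interval, hits: list[AlignmentHit]) -> Interval:
    """Longest sub-interval of ``clean`` not covered by any hit (ties: leftmost)."""
    edges = sorted(
        (max(h.read_iv.start, clean.start), min(h.read_iv.end, clean.end)) for h in hits
    )
    best = Interval(clean.start, clean.start)
    pos = clean.start
    for s, e in edges:
        if s > pos and (s - pos) > best.length:
            best = Interval(pos, s)
        pos = max(pos, e)
    if clean.end > pos and (clean.end - pos) > best.length:
        best = Interval(pos, clean.end)
    return best


def trim_by_hits(
    read: Read,
    hits: list[AlignmentHit],
    policy: TrimPolicy,
    criteria: MatchCriteria,
    kind: ReadErrorType | None = None,
    stage: str = "primer",
) -> Read:
    """Apply the trimming consequence of a classification.

    OK reads advance past a flush 5' forward hit and retreat before a flush
    3' reverse hit; erroneous reads are discarded or salvaged (longest
    hit-free sub-interval) per the policy.  An empty result discards the
    read with reason ``primer_only``.
    """
    if read.status != "active":
        return read
    if kind is None:
        kind = classify_read(hits, read, criteria)
    read.primer_class = kind.value
    if not hits:
        return read
    tol = criteria.classify_flush_tol
    if kind == ReadErrorType.OK:
        s, e = read.clean
        for h in hits:
            if h.orientation == FORWARD and h.read_iv.start - read.clean.start <= tol:
                s = max(s, h.read_iv.end)
            if h.orientation == REVERSE and read.clean.end - h.read_iv.end <= tol:
                e = min(e, h.read_iv.start)
        if e < s:
            e = s
        if (s, e) != tuple(read.clean):
            read.set_clean(stage, Interval(s, e))
    elif policy.action(kind) == DISCARD:
        read.discard(f"primer_{kind.value}")
        return read
    else:
        seg = _longest_free_segment(read.clean, hits)
        read.set_clean(stage, seg)
    if read.clean.length == 0:
        read.discard("primer_only")
    return read


def trim_terminal_hits(read: Read, hits: list[AlignmentHit], stage: str) -> Read:
    """Trim adapter/vector hits: chains of hits flush with either clean
    boundary are cut off; if middle hits remain, the longest hit-free
    segment is kept."""
    if read.status != "active" or not hits:
        return read
    s, e = read.clean
    changed = True
    remaining = list(hits)
    while changed:
        changed = False
        for h in list(remaining):
            if h.read_iv.start - s <= 3 and h.read_iv.end > s:
                s = max(s, h.read_iv.end)
                remaining.remove(h)
                changed = True
            elif e - h.read_iv.end <= 3 and h.read_iv.start < e:
                e = min(e, h.read_iv.start)
                remaining.remove(h)
                changed = True
    if e < s:
        e = s
    middle = [h for h in remaining if h.read_iv.start < e and h.read_iv.end > s]
    if middle:
        seg = _longest_free_segment(Interval(s, e), middle)
        s, e = seg
    if (s, e) != tuple(read.clean):
        read.set_clean(stage, Interval(s, e))
    if read.clean.length == 0:
        read.discard(f"{stage}_only")
    return read
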