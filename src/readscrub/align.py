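"""Alignment kernels used by every trimming stage.

Three primitives:

* :func:`semiglobal_prefix_align` — bounded-error semi-global alignment of a
  short pattern (a barcode) against the start of a read: the pattern is
  consumed entirely, the read suffix is penalty-free, and mismatches and
  indels all cost 1.
* :func:`seed_hits` — exact shared-word seeding of a contaminant sequence
  (adapter, primer, vector) against a read, in both orientations, with
  co-diagonal seeds merged into candidate regions.
* :func:`banded_nw_extend` — banded Needleman-Wunsch extension of a seed
  region toward the sequence ends, with penalty-free (unaligned) bases at
  the ends, yielding an :class:`AlignmentHit` with percent identity and
  end-overhang geometry.

Reverse-orientation hits are computed by reverse-complementing the subject,
never the read, so read coordinates stay stable.  ``N`` bases match nothing
(they count as mismatches against any base, including ``N``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import Interval, reverse_complement

FORWARD = "forward"
REVERSE = "reverse"

# banded-NW scoring (linear gaps; the barcode DP uses unit edit costs instead)
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2

_NEG = -(10**9)
_N = ord("N")


@dataclass(frozen=True)
class SemiGlobalResult:
    """Outcome of a bounded-error prefix alignment."""

    errors: int
    read_end: int
    aligned: bool


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def semiglobal_prefix_align(pattern: str, read: str, max_errors: int) -> SemiGlobalResult:
    """Align ``pattern`` against a prefix of ``read`` with unit edit costs.

    Minimises mismatches+indels with the pattern fully consumed and the read
    suffix free.  ``read_end`` is the smallest end position on the read
    achieving the minimum (tie-break: shortest prefix).  ``aligned`` is False
    when the minimum exceeds ``max_errors``.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if max_errors < 0:
        raise ValueError("max_errors must be >= 0")
    m = len(pattern)
    if not read:
        return SemiGlobalResult(errors=m, read_end=0, aligned=m <= max_errors)
    r = _encode(read)
    n = r.size
    ar = np.arange(n + 1)
    prev = ar.astype(np.int32)  # row 0: delete j read bases
    pat = _encode(pattern)
    cand = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        p = pat[i - 1]
        sub = ((r != p) | (r == _N) | (p == _N)).astype(np.int32)
        cand[0] = i
        np.minimum(prev[1:] + 1, prev[:-1] + sub, out=cand[1:])
        # insertion (consume read base) closure: cur[j] = min_{k<=j} cand[k] + (j-k)
        prev = np.minimum.accumulate(cand - ar) + ar
        cand = np.empty(n + 1, dtype=np.int32)
    errors = int(prev.min())
    read_end = int(prev.argmin())
    return SemiGlobalResult(errors=errors, read_end=read_end, aligned=errors <= max_errors)


@dataclass(frozen=True)
class Seed:
    """A merged run of co-diagonal exact word matches (a candidate region)."""

    subj_start: int
    subj_end: int
    read_start: int
    read_end: int
    orientation: str

    @property
    def diagonal(self) -> int:
        return self.read_start - self.subj_start


def _exact_word_seeds(subject: str, read: str, word_size: int, orientation: str) -> list[Seed]:
    if len(subject) < word_size or len(read) < word_size:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(read) - word_size + 1):
        index.setdefault(read[j : j + word_size], []).append(j)
    raw: list[tuple[int, int]] = []  # (diagonal, subj_pos)
    for i in range(len(subject) - word_size + 1):
        word = subject[i : i + word_size]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            raw.append((j - i, i))
    if not raw:
        return []
    raw.sort()
    seeds: list[Seed] = []
    d0, s0 = raw[0]
    s_end = s0 + word_size
    for d, s in raw[1:]:
        if d == d0 and s <= s_end:
            s_end = max(s_end, s + word_size)
        else:
            seeds.append(Seed(s0, s_end, s0 + d0, s_end + d0, orientation))
            d0, s0, s_end = d, s, s + word_size
    seeds.append(Seed(s0, s_end, s0 + d0, s_end + d0, orientation))
    return seeds


def merge_seed_regions(seeds: list[Seed], band: int, gap: int) -> list[Seed]:
    """Cluster seeds whose diagonals differ by <= band and that are close on
    the read (gap <= ``gap``) into single candidate regions."""
    out: list[Seed] = []
    for ori in (FORWARD, REVERSE):
        group = sorted(
            (s for s in seeds if s.orientation == ori), key=lambda s: (s.read_start, s.diagonal)
        )
        clusters: list[Seed] = []
        for s in group:
            merged = False
            for k, c in enumerate(clusters):
                if abs(s.diagonal - c.diagonal) <= band and (
                    s.read_start <= c.read_end + gap and c.read_start <= s.read_end + gap
                ):
                    clusters[k] = Seed(
                        min(c.subj_start, s.subj_start),
                        max(c.subj_end, s.subj_end),
                        min(c.read_start, s.read_start),
                        max(c.read_end, s.read_end),
                        ori,
                    )
                    merged = True
                    break
            if not merged:
                clusters.append(s)
        out.extend(clusters)
    return out


def seed_hits(subject: str, read: str, word_size: int = 11) -> list[Seed]:
    """All exact shared words of ``word_size`` between subject (both
    orientations) and read, merged along diagonals into candidate regions."""
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    seeds = _exact_word_seeds(subject, read, word_size, FORWARD)
    seeds += _exact_word_seeds(reverse_complement(subject), read, word_size, REVERSE)
    return merge_seed_regions(seeds, band=word_size, gap=2 * word_size)


@dataclass(frozen=True)
class AlignmentHit:
    """A located contaminant match with identity and end-overhang geometry.

    Coordinates: ``read_iv`` indexes the read string the aligner saw;
    ``subj_iv`` indexes the subject *in the orientation aligned against the
    read* (i.e. the reverse complement's coordinates for reverse hits).
    Overhangs count unaligned bases outside the aligned core: on the read
    toward each read end, and on the subject beyond each side of the core.
    """

    subject_name: str
    subject_role: str
    orientation: str
    read_iv: Interval
    subj_iv: Interval
    pid: float
    aln_len: int
    matches: int
    score: int
    overhang_read_5: int
    overhang_read_3: int
    overhang_subj_left: int
    overhang_subj_right: int

    def shifted(self, offset: int, read_len: int, clean: Interval) -> "AlignmentHit":
        """Re-express a hit found on a clean subsequence in full-read
        coordinates, with read overhangs measured to the clean boundaries."""
        iv = Interval(self.read_iv.start + offset, self.read_iv.end + offset)
        return replace(
            self,
            read_iv=iv,
            overhang_read_5=iv.start - clean.start,
            overhang_read_3=clean.end - iv.end,
        )


def banded_nw_extend(
    subject: str,
    read: str,
    anchor: Seed,
    band: int = 5,
    subject_name: str = "",
    subject_role: str = "",
) -> AlignmentHit | None:
    """Extend a seed region to a full hit with banded Needleman-Wunsch.

    The subject is globally aligned against a read window spanning the
    anchor extended to both subject ends plus ``band``, within a diagonal
    band of half-width ``band`` around the anchor diagonal.  Bases outside
    the band, and terminal gaps, are left unaligned and reported as
    overhangs.  Scoring: match +1, mismatch -1, gap -2; alignment ends are
    penalty-free.  Returns None when no positive-scoring alignment exists.

    If ``anchor.orientation`` is reverse, ``subject`` must already be the
    reverse complement; the hit's ``subj_iv`` stays in that orientation.
    """
    if band < 1:
        raise ValueError("band must be >= 1")
    m = len(subject)
    ws = max(0, anchor.read_start - anchor.subj_start - band)
    we = min(len(read), anchor.read_end + (m - anchor.subj_end) + band)
    window = read[ws:we]
    n = len(window)
    if m == 0 or n == 0:
        return None
    d0 = (anchor.read_start - ws) - anchor.subj_start
    s = _encode(subject)
    w = _encode(window)
    score = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 diag, 2 up, 3 left
    score[0, :] = 0
    score[:, 0] = 0
    for i in range(1, m + 1):
        lo = max(1, i + d0 - band)
        hi = min(n, i + d0 + band)
        if lo > hi:
            continue
        si = s[i - 1]
        for j in range(lo, hi + 1):
            match = si == w[j - 1] and si != _N
            best = score[i - 1, j - 1] + (MATCH_SCORE if match else MISMATCH_SCORE)
            p = 1
            up = score[i - 1, j] + GAP_SCORE
            if up > best:
                best, p = up, 2
            left = score[i, j - 1] + GAP_SCORE
            if left > best:
                best, p = left, 3
            score[i, j] = best
            ptr[i, j] = p
    # ends-free: stop anywhere (remaining suffixes of both sequences unaligned);
    # ties prefer the longest extension so zero-net tails stay aligned
    best_score = int(score.max())
    if best_score <= 0:
        return None
    cand_i, cand_j = np.nonzero(score == best_score)
    pick = int(np.argmax(cand_i + cand_j))
    bi, bj = int(cand_i[pick]), int(cand_j[pick])
    i, j = bi, bj
    matches = 0
    aln_len = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        aln_len += 1
        if p == 1:
            if s[i - 1] == w[j - 1] and s[i - 1] != _N:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    subj_iv = Interval(i, bi)
    read_iv = Interval(ws + j, ws + bj)
    pid = 100.0 * matches / aln_len if aln_len else 0.0
    return AlignmentHit(
        subject_name=subject_name,
        subject_role=subject_role,
        orientation=anchor.orientation,
        read_iv=read_iv,
        subj_iv=subj_iv,
        pid=pid,
        aln_len=aln_len,
        matches=matches,
        score=best_score,
        overhang_read_5=read_iv.start,
        overhang_read_3=len(read) - read_iv.end,
        overhang_subj_left=subj_iv.start,
        overhang_subj_right=m - subj_iv.end,
    )


def find_hits(
    subject_name: str,
    subject: str,
    subject_role: str,
    read: str,
    word_size: int = 11,
    band: int = 5,
) -> list[AlignmentHit]:
    """Seed-and-extend search of one subject (both orientations) in a read.

    Overlapping hits of the same orientation are deduplicated, keeping the
    best score.  Hits are returned sorted by read coordinate.
    """
    hits: list[AlignmentHit] = []
    rc = reverse_complement(subject)
    for seed in seed_hits(subject, read, word_size):
        subj = subject if seed.orientation == FORWARD else rc
        hit = banded_nw_extend(
            subj, read, seed, band=band, subject_name=subject_name, subject_role=subject_role
        )
        if hit is not None:
            hits.append(hit)
    kept: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.read_iv.start)):
        clash = any(
            k.orientation == hit.orientation
            and min(k.read_iv.end, hit.read_iv.end) - max(k.read_iv.start, hit.read_iv.start)
            > 0.5 * min(k.read_iv.length, hit.read_iv.length)
            for k in kept
        )
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h.read_iv.start, h.read_iv.end))
    return kept
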