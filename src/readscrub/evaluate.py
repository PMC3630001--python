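"""Over-/under-trimming evaluation of two cleaners against genome alignments.

Given genome alignments (PSL) of the reads cleaned by two programs, E and
S, with cleaned intervals ``E = [s, t)`` and ``S = [v, w)`` mapping to
genome intervals ``A(E) = [s', t')`` and ``A(S) = [v', w')``:

* reads with multiple genome hits in either PSL are excluded, as are pairs
  whose genome intervals overlap by fewer than ``overlap_min`` bases;
* the best boundary per genome side is ``A(B) = [min(s', v'), max(t', w'))``;
* per read end, a cleaner is **under**-trimmed when its cleaned read is not
  fully aligned on that side (unaligned query bases remain), otherwise
  **over**-trimmed when its aligned genome boundary is not the best of the
  pair, else **correct**.

Strand-reversed hits have their genome sides mapped back to read ends
(5' of a '-'-strand read faces the higher genome coordinate) so the labels
always refer to the read's own 5'/3' ends.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import Interval, PslRecord

CORRECT = "correct"
OVER = "over"
UNDER = "under"


@dataclass(frozen=True)
class TrimComparison:
    read_id: str
    e_iv: Interval
    s_iv: Interval
    a_e: Interval  # genome interval of E's cleaned read
    a_s: Interval
    strand_e: str
    strand_s: str
    class5_e: str
    class5_s: str
    class3_e: str
    class3_s: str
    delta5_e: int
    delta5_s: int
    delta3_e: int
    delta3_s: int


def _single_hits(records: Iterable[PslRecord], label: str) -> dict[str, PslRecord]:
    counts: Counter = Counter()
    hit: dict[str, PslRecord] = {}
    for rec in records:
        counts[rec.q_name] += 1
        hit[rec.q_name] = rec
    return {name: hit[name] for name, c in counts.items() if c == 1}


def _end_classes(
    rec: PslRecord, best_left: int, best_right: int, end_slack: int
) -> tuple[str, str, int, int]:
    """(class5, class3, delta5, delta3) for one cleaner's alignment.

    Deltas are positive genome bases over-trimmed, negative unaligned query
    bases when under-trimmed, 0 when correct.
    """
    gap5 = rec.q_start
    gap3 = rec.q_size - rec.q_end
    # read 5' faces genome left on '+', genome right on '-'
    if rec.strand == "+":
        bound5, best5, sign5 = rec.t_start, best_left, +1
        bound3, best3, sign3 = rec.t_end, best_right, -1
    else:
        bound5, best5, sign5 = rec.t_end, best_right, -1
        bound3, best3, sign3 = rec.t_start, best_left, +1

    def one(gap: int, bound: int, best: int, sign: int) -> tuple[str, int]:
        if gap > end_slack:
            return UNDER, -gap
        excess = sign * (bound - best)
        if excess > 0:
            return OVER, excess
        return CORRECT, 0

    c5, d5 = one(gap5, bound5, best5, sign5)
    c3, d3 = one(gap3, bound3, best3, sign3)
    return c5, c3, d5, d3


def compare_trimming(
    psl_e: Iterable[PslRecord],
    psl_s: Iterable[PslRecord],
    intervals_e: dict[str, Interval],
    intervals_s: dict[str, Interval],
    overlap_min: int = 40,
    end_slack: int = 0,
) -> tuple[list[TrimComparison], pd.DataFrame]:
    """Classify each commonly, uniquely mapped read pair per end per cleaner.

    Returns the per-read comparisons and a summary table with one row per
    (class x end) and one column per cleaner.  Raises when a PSL read id is
    missing from its interval map.
    """
    e_hits = _single_hits(psl_e, "E")
    s_hits = _single_hits(psl_s, "S")
    comparisons: list[TrimComparison] = []
    for name in sorted(set(e_hits) & set(s_hits)):
        e, s = e_hits[name], s_hits[name]
        if name not in intervals_e or name not in intervals_s:
            raise ValueError(f"read {name} present in PSL but missing from intervals")
        if e.t_name != s.t_name or e.strand != s.strand:
            continue
        overlap = min(e.t_end, s.t_end) - max(e.t_start, s.t_start)
        if overlap < overlap_min:
            continue
        best_left = min(e.t_start, s.t_start)
        best_right = max(e.t_end, s.t_end)
        c5e, c3e, d5e, d3e = _end_classes(e, best_left, best_right, end_slack)
        c5s, c3s, d5s, d3s = _end_classes(s, best_left, best_right, end_slack)
        comparisons.append(
            TrimComparison(
                read_id=name,
                e_iv=intervals_e[name],
                s_iv=intervals_s[name],
                a_e=Interval(e.t_start, e.t_end),
                a_s=Interval(s.t_start, s.t_end),
                strand_e=e.strand,
                strand_s=s.strand,
                class5_e=c5e,
                class5_s=c5s,
                class3_e=c3e,
                class3_s=c3s,
                delta5_e=d5e,
                delta5_s=d5s,
                delta3_e=d3e,
                delta3_s=d3s,
            )
        )
    rows = []
    for cls in (UNDER, OVER, CORRECT):
        rows.append(
            {
                "class": cls,
                "E_5p": sum(c.class5_e == cls for c in comparisons),
                "S_5p": sum(c.class5_s == cls for c in comparisons),
                "E_3p": sum(c.class3_e == cls for c in comparisons),
                "S_3p": sum(c.class3_s == cls for c in comparisons),
            }
        )
    summary = pd.DataFrame(rows, columns=["class", "E_5p", "S_5p", "E_3p", "S_3p"])
    return comparisons, summary


def audit_overtrim_kmers(
    comparisons: list[TrimComparison],
    reads: dict[str, str],
    k: int = 6,
    cleaner: str = "e",
) -> pd.DataFrame:
    """Tally the k bases spanning each over-trimmed junction.

    For a 5' over-trim the last ``k`` trimmed bases before the clean start
    are taken from the original read; for a 3' over-trim the first ``k``
    after the clean end.  Windows clipped by the read boundary are flagged.
    Returns columns (kmer, end, count, clipped).
    """
    tallies: Counter = Counter()
    for comp in comparisons:
        iv = comp.e_iv if cleaner == "e" else comp.s_iv
        c5 = comp.class5_e if cleaner == "e" else comp.class5_s
        c3 = comp.class3_e if cleaner == "e" else comp.class3_s
        seq = reads.get(comp.read_id)
        if seq is None:
            continue
        if c5 == OVER:
            window = seq[max(0, iv.start - k) : iv.start]
            tallies[(window, "5p", len(window) < k)] += 1
        if c3 == OVER:
            window = seq[iv.end : iv.end + k]
            tallies[(window, "3p", len(window) < k)] += 1
    rows = [
        {"kmer": kmer, "end": end, "count": c, "clipped": clipped}
        for (kmer, end, clipped), c in sorted(tallies.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows, columns=["kmer", "end", "count", "clipped"])
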