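"""Poly-A tail (3') and poly-T head (5') trimming.

A tail is modelled by three quantities: its length L_p, the fraction of A's
it contains (N_A / L_p), and the distance L_e of its outer edge from the
read end.  The trimmer considers every window whose outer edge lies within L_e of
the 3' end of the clean interval and that starts and ends on an A; the
longest window whose A-fraction is strictly greater than
``min_fraction`` and whose length is at least ``min_len`` is trimmed (the
clean end moves to the window's left edge, which also drops the bases
outside the anchor).  The rule is re-applied until no qualifying window
remains, so trimming is idempotent.  The 5' side is symmetric with T.

Note the fraction criterion deliberately lets a tail window bridge
interior non-A bases, and iteration lets it chain across nearby A's; a
read's A-rich 3' region adjacent to a tail is part of the tail by this
model's definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .types import Interval, Read

STAGE = "polya"


@dataclass(frozen=True)
class PolyAParams:
    min_len: int = 8            # L_p minimum
    min_fraction: float = 0.75  # N_A / L_p must strictly exceed this
    max_end_offset: int = 3     # L_e: outer-edge distance allowance
    both_sides: bool = True     # also trim poly-T heads at the 5' end

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.max_end_offset < 0:
            raise ValueError("max_end_offset must be >= 0")


def find_tail_window(
    seq: str, start: int, end: int, params: PolyAParams, base: str = "A"
) -> Optional[Interval]:
    """Best qualifying tail window in ``seq[start:end]`` at the 3' side.

    Considers every window whose outer edge lies within ``max_end_offset``
    of ``end`` and that starts and ends on ``base`` (the tail expands
    base-runs, it cannot begin or finish on a foreign base); returns the
    longest window with base-fraction > min_fraction and length >=
    min_len, ties resolved toward the window closest to the end.
    """
    best: Optional[Interval] = None
    for wr in range(end, max(start, end - params.max_end_offset) - 1, -1):
        if wr <= start or seq[wr - 1] != base:
            continue
        count = 0
        for wl in range(wr - 1, start - 1, -1):
            if seq[wl] == base:
                count += 1
            else:
                continue  # a tail window starts on the tail base
            length = wr - wl
            if (
                length >= params.min_len
                and count > params.min_fraction * length
                and (best is None or length > best.length)
            ):
                best = Interval(wl, wr)
    return best


def find_head_window(
    seq: str, start: int, end: int, params: PolyAParams, base: str = "T"
) -> Optional[Interval]:
    """Mirror of :func:`find_tail_window` for the 5' side (poly-T head)."""
    best: Optional[Interval] = None
    for wl in range(start, min(end, start + params.max_end_offset + 1)):
        if seq[wl] != base:
            continue
        count = 0
        for wr in range(wl + 1, end + 1):
            if seq[wr - 1] == base:
                count += 1
            else:
                continue  # a head window ends on the head base
            length = wr - wl
            if (
                length >= params.min_len
                and count > params.min_fraction * length
                and (best is None or length > best.length)
            ):
                best = Interval(wl, wr)
    return best


def tail_trim_extent(seq: str, start: int, end: int, params: PolyAParams) -> int:
    """New clean end after 3' poly-A trimming of ``seq[start:end]``.

    The window rule is applied until no qualifying window remains, so the
    result is a fixpoint (trimming is idempotent)."""
    while True:
        win = find_tail_window(seq, start, end, params, base="A")
        if win is None:
            return end
        end = win.start


def head_trim_extent(seq: str, start: int, end: int, params: PolyAParams) -> int:
    """New clean start after 5' poly-T trimming (fixpoint, idempotent)."""
    while True:
        win = find_head_window(seq, start, end, params, base="T")
        if win is None:
            return start
        start = win.end


def trim_polya(read: Read, params: PolyAParams) -> Read:
    """Trim a 3' poly-A tail and (optionally) a 5' poly-T head in place."""
    if read.status != "active":
        return read
    start, end = read.clean
    new_end = tail_trim_extent(read.seq, start, end, params)
    new_start = start
    if params.both_sides:
        new_start = head_trim_extent(read.seq, start, min(new_end, end), params)
        new_start = min(new_start, new_end)
    if (new_start, new_end) != (start, end):
        read.set_clean(STAGE, Interval(new_start, new_end))
    return read
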