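"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (full dynamic-programming
matrices, exhaustive window scans) and stays independent of the package's
optimised implementations.
"""

from __future__ import annotations


def semiglobal_distance(pattern: str, read: str) -> tuple[int, int]:
    """Full-DP semi-global edit distance (pattern consumed, read suffix
    free) and the smallest read end achieving it."""
    m, n = len(pattern), len(read)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        dp[0][j] = j
    for i in range(1, m + 1):
        dp[i][0] = i
        pi = pattern[i - 1]
        for j in range(1, n + 1):
            sub = 0 if (pi == read[j - 1] and pi != "N" and read[j - 1] != "N") else 1
            dp[i][j] = min(dp[i - 1][j] + 1, dp[i][j - 1] + 1, dp[i - 1][j - 1] + sub)
    last = dp[m]
    best = min(last)
    return best, last.index(best)


def ends_free_nw_score(
    subject: str, read: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Unbanded ends-free alignment score: free leading/trailing unaligned
    bases on both sequences (score 0 means no positive alignment)."""
    m, n = len(subject), len(read)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        si = subject[i - 1]
        for j in range(1, n + 1):
            eq = si == read[j - 1] and si != "N"
            dp[i][j] = max(
                dp[i - 1][j - 1] + (match if eq else mismatch),
                dp[i - 1][j] + gap,
                dp[i][j - 1] + gap,
            )
            if dp[i][j] > best:
                best = dp[i][j]
    return best


def _one_tail_pass(seq: str, start: int, end: int, min_len: int, frac: float, offset: int):
    """One exhaustive pass of the 3' tail-window rule; None if no window.

    All windows with outer edge within ``offset`` of the end, starting and
    ending on A; longest qualifying wins, ties toward the end."""
    acount = [0] * (len(seq) + 1)  # prefix counts so the scan stays O(n) per edge
    for i, b in enumerate(seq):
        acount[i + 1] = acount[i] + (b == "A")
    best = None
    for wr in range(max(start + 1, end - offset), end + 1):
        if seq[wr - 1] != "A":
            continue
        for wl in range(start, wr):
            if seq[wl] != "A":
                continue
            length = wr - wl
            if length >= min_len and (acount[wr] - acount[wl]) > frac * length:
                if best is None or length > (best[1] - best[0]) or (
                    length == (best[1] - best[0]) and wr > best[1]
                ):
                    best = (wl, wr)
    return best


def _one_head_pass(seq: str, start: int, end: int, min_len: int, frac: float, offset: int):
    tcount = [0] * (len(seq) + 1)
    for i, b in enumerate(seq):
        tcount[i + 1] = tcount[i] + (b == "T")
    best = None
    for wl in range(start, min(end, start + offset + 1)):
        if seq[wl] != "T":
            continue
        for wr in range(wl + 1, end + 1):
            if seq[wr - 1] != "T":
                continue
            length = wr - wl
            if length >= min_len and (tcount[wr] - tcount[wl]) > frac * length:
                if best is None or length > (best[1] - best[0]) or (
                    length == (best[1] - best[0]) and wl < best[0]
                ):
                    best = (wl, wr)
    return best


def polya_interval_oracle(
    seq: str, min_len: int = 8, frac: float = 0.75, offset: int = 3, both_sides: bool = True
) -> tuple[int, int]:
    """Exhaustive-window tail/head trimming applied to fixpoint; returns
    the surviving (start, end) of the full sequence."""
    start, end = 0, len(seq)
    while True:
        win = _one_tail_pass(seq, start, end, min_len, frac, offset)
        if win is None:
            break
        end = win[0]
    if both_sides:
        while True:
            win = _one_head_pass(seq, start, end, min_len, frac, offset)
            if win is None:
                break
            start = win[1]
    if start > end:
        start = end
    return start, end
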