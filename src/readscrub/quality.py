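"""Low-quality end trimming from per-base Phred scores.

Rule: from each end of the clean interval the boundary advances inward one
base at a time while either the boundary base's own score or the mean of
the inward window of ``window`` bases (clipped to the interval) is below
``min_mean_q``.  If the surviving interval is shorter than ``min_len`` the
read is discarded.  Reads without quality scores pass through unchanged
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .types import Interval, Read

STAGE = "quality"


@dataclass(frozen=True)
class QualityParams:
    window: int = 10
    min_mean_q: float = 20.0
    min_len: int = 40

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")
        if self.min_len < 0:
            raise ValueError("min_len must be >= 0")


def _mean(values: list[int]) -> float:
    return sum(values) / len(values)


def trim_quality(read: Read, params: QualityParams) -> Read:
    if read.status != "active":
        return read
    if read.qual is None:
        warnings.warn(f"read {read.id}: no quality scores, quality trimming skipped")
        return read
    q = read.qual
    s, e = read.clean
    while s < e:
        win = q[s : min(e, s + params.window)]
        if q[s] < params.min_mean_q or _mean(win) < params.min_mean_q:
            s += 1
        else:
            break
    while e > s:
        win = q[max(s, e - params.window) : e]
        if q[e - 1] < params.min_mean_q or _mean(win) < params.min_mean_q:
            e -= 1
        else:
            break
    if (s, e) != tuple(read.clean):
        read.set_clean(STAGE, Interval(s, e))
    if read.clean.length < params.min_len:
        read.discard("low_quality")
    return read
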