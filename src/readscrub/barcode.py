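"""5' barcode (MID) identification, demultiplexing and trimming.

Barcodes are searched semi-globally at the 5' end of the current clean
interval: the barcode must be consumed entirely, the rest of the read is
free, and mismatches and indels each cost one error.  A read whose best
barcode exceeds the error budget is discarded; when two distinct barcodes
tie at the minimal error count the read is discarded as ambiguous so the
QC report can count it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import semiglobal_prefix_align
from .types import Interval, Read

STAGE = "barcode"


@dataclass(frozen=True)
class BarcodeParams:
    max_errors: int = 2
    require_barcode: bool = True
    max_offset: int = 0  # allowed shift of the barcode start from the 5' end

    def __post_init__(self) -> None:
        if self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")
        if self.max_offset < 0:
            raise ValueError("max_offset must be >= 0")


def trim_barcode(read: Read, barcodes: dict[str, str], params: BarcodeParams) -> Read:
    """Assign the best-matching barcode and advance the clean start past it.

    Ties between distinct barcodes discard the read (``ambiguous_barcode``);
    no barcode within ``max_errors`` discards it (``no_barcode``) when
    ``require_barcode`` is set.
    """
    if read.status != "active" or not barcodes:
        return read
    best_err: int | None = None
    best: list[tuple[str, int]] = []  # (name, absolute read_end)
    longest = max(len(b) for b in barcodes.values())
    for offset in range(params.max_offset + 1):
        start = read.clean.start + offset
        if start >= read.clean.end:
            break
        # a prefix alignment within the budget never consumes more than
        # len(barcode) + max_errors read bases
        window = read.seq[start : min(read.clean.end, start + longest + params.max_errors)]
        for name, bc in barcodes.items():
            res = semiglobal_prefix_align(bc, window, params.max_errors)
            if not res.aligned:
                continue
            if best_err is None or res.errors < best_err:
                best_err = res.errors
                best = [(name, start + res.read_end)]
            elif res.errors == best_err:
                best.append((name, start + res.read_end))
    if best_err is None:
        if params.require_barcode:
            read.discard("no_barcode")
        return read
    names = {name for name, _ in best}
    if len(names) > 1:
        read.discard("ambiguous_barcode")
        return read
    name = next(iter(names))
    read_end = min(end for n, end in best if n == name)
    read.sample = name
    read.set_clean(STAGE, Interval(read_end, read.clean.end))
    return read
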