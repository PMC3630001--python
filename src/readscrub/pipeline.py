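"""The cleaning pipeline: stage ordering, bookkeeping, QC collection.

Default stage order: barcode -> adapter -> primer -> polya -> vector ->
quality.  Poly-A runs after primer trimming because tails sit immediately
before the 3' amplification primer (and poly-T heads after the 5' one).
All trimming is virtual; the report tracks counts after every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .barcode import BarcodeParams, trim_barcode
from .polya import PolyAParams, trim_polya
from .primers import (
    MatchCriteria,
    ReadErrorType,
    TrimPolicy,
    classify_read,
    locate_hits,
    trim_by_hits,
    trim_terminal_hits,
)
from .quality import QualityParams, trim_quality
from .report import CleaningReport, collect_step, top_kmers
from .types import ACTIVE, ProtocolSpec, Read

DEFAULT_STAGES = ("barcode", "adapter", "primer", "polya", "vector", "quality")


@dataclass
class PipelineParams:
    barcode: BarcodeParams = field(default_factory=BarcodeParams)
    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    polya: PolyAParams = field(default_factory=PolyAParams)
    quality: QualityParams = field(default_factory=QualityParams)
    policy: TrimPolicy = field(default_factory=TrimPolicy)
    stages: tuple = DEFAULT_STAGES
    word_size: int = 9
    band: int = 5
    kmer_k: int = 6
    kmer_top_n: int = 30


def run_pipeline(
    reads: list[Read], protocol: ProtocolSpec, params: PipelineParams | None = None
) -> tuple[list[Read], CleaningReport]:
    """Run all configured stages over ``reads`` in place; return the reads
    and a fully-populated :class:`CleaningReport`."""
    if params is None:
        params = PipelineParams()
    report = CleaningReport()
    report.add_step(collect_step(reads, "raw"))

    for stage in params.stages:
        if stage == "barcode":
            if protocol.barcodes:
                for read in reads:
                    trim_barcode(read, protocol.barcodes, params.barcode)
            else:
                continue
        elif stage == "adapter":
            if not protocol.adapters:
                continue
            for read in reads:
                if read.status != ACTIVE:
                    continue
                hits = locate_hits(
                    read,
                    protocol.adapters,
                    params.criteria,
                    word_size=params.word_size,
                    band=params.band,
                )
                trim_terminal_hits(read, hits, "adapter")
        elif stage == "primer":
            if not protocol.primers:
                continue
            for read in reads:
                if read.status != ACTIVE:
                    continue
                hits = locate_hits(
                    read,
                    protocol.primer_subjects,
                    params.criteria,
                    word_size=params.word_size,
                    band=params.band,
                )
                kind = classify_read(hits, read, params.criteria)
                report.combo_table[kind.value] += 1
                if kind == ReadErrorType.OK:
                    combo = _ok_combination(hits)
                    report.combo_table[f"OK:{combo}"] += 1
                for h in hits:
                    report.primer_match_hist[(h.subject_name, h.orientation)] += 1
                    report.pos_hist[h.read_iv.start - read.clean.start] += 1
                trim_by_hits(read, hits, params.policy, params.criteria, kind=kind)
        elif stage == "polya":
            for read in reads:
                if read.status != ACTIVE:
                    continue
                before = read.clean
                trim_polya(read, params.polya)
                if read.clean.end < before.end:
                    report.polya_hist[before.end - read.clean.end] += 1
                if read.clean.start > before.start:
                    report.polyt_hist[read.clean.start - before.start] += 1
        elif stage == "vector":
            if not protocol.vectors:
                continue
            for read in reads:
                if read.status != ACTIVE:
                    continue
                hits = locate_hits(
                    read,
                    protocol.vector_subjects,
                    params.criteria,
                    word_size=params.word_size,
                    band=params.band,
                )
                trim_terminal_hits(read, hits, "vector")
        elif stage == "quality":
            for read in reads:
                trim_quality(read, params.quality)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        report.add_step(collect_step(reads, stage))

    for read in reads:
        if read.status != ACTIVE:
            report.discard_reasons[read.discard_reason] += 1
    report.kmer_top = top_kmers(reads, k=params.kmer_k, top_n=params.kmer_top_n)
    return reads, report


def _ok_combination(hits) -> str:
    from .align import FORWARD, REVERSE

    has_f = any(h.orientation == FORWARD for h in hits if h.subject_role in ("amp5", "amp3"))
    has_r = any(h.orientation == REVERSE for h in hits if h.subject_role in ("amp5", "amp3"))
    if has_f and has_r:
        return "F+R"
    if has_f:
        return "F"
    if has_r:
        return "R"
    return "none"
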