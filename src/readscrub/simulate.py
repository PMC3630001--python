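"""Synthetic protocol-contaminated reads with per-read ground truth.

Each read is assembled as::

    [barcode][adapter5][ layout dictated by the planted type ][adapter3]

where the middle layout plants amplification primers according to the
error taxonomy (OK, RF, fr, SF, RE, NF, NR), an optional poly-A tail or
poly-T head, and an insert drawn uniformly over ACGT.  Substitution and
indel errors are then applied at configurable per-base rates, and
454-like quality scores (high plateau, sloping 3' degradation) are drawn
for the final sequence.

Ground truth
------------
The true clean interval is the insert, with the tail-side boundary defined
by the poly-A model itself applied to the noise-free constructed clean
region: genome-templated A's sitting next to a poly-A tail are
unidentifiable in principle, so the tail model's window rule *is* the
boundary definition (see docs/methods.md).  Truth coordinates are mapped
through the error process so they always index the final read.

Inserts and junk segments are rejection-sampled so they share no
seed-length word with any protocol sequence (either orientation); the
planted layout is then the unique explanation of each read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .polya import PolyAParams, head_trim_extent, tail_trim_extent
from .primers import ReadErrorType
from .types import ProtocolSpec, Read, reverse_complement

# Roche 454 MID tags 1-8 (pairwise edit distance >= 5)
DEFAULT_BARCODES = {
    "MID1": "ACGAGTGCGT",
    "MID2": "ACGCTCGACA",
    "MID3": "AGACGCACTC",
    "MID4": "AGCACTGTAG",
    "MID5": "ATCAGACACG",
    "MID6": "ATATCGCGAG",
    "MID7": "CGTGTCTCTA",
    "MID8": "CTCGCGTGTC",
}


def default_protocol() -> ProtocolSpec:
    """A realistic two-primer 454 cDNA protocol used as demo/test fixture."""
    return ProtocolSpec(
        barcodes=dict(DEFAULT_BARCODES),
        adapters5=[("adapA", "GCCTCCCTCGCGCCATCAG")],
        adapters3=[("adapB", "CTGAGACTGCCAAGGCACACAGG")],
        primers=[
            ("ampF", "AAGCAGTGGTATCAACGCAGAGT", "amp5"),
            ("ampR", "GTAATACGACTCACTATAGGGC", "amp3"),
        ],
    )


DEFAULT_MIX = {
    "OK": 0.70,
    "RF": 0.05,
    "fr": 0.05,
    "SF": 0.05,
    "RE": 0.05,
    "NF": 0.05,
    "NR": 0.05,
}


@dataclass
class SimConfig:
    protocol: ProtocolSpec = field(default_factory=default_protocol)
    n_reads: int = 1000
    insert_len: tuple[int, int] = (80, 250)
    artifact_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    polya_len: tuple[int, int] = (8, 20)
    polya_prob: float = 0.75     # P(tail) for layouts that carry one
    polyt_prob: float = 0.10     # P(poly-T head instead), OK layouts only
    junk_len: tuple[int, int] = (8, 20)
    sub_rate: float = 0.01
    indel_rate: float = 0.005
    seed: int = 0
    word_size: int = 9           # screening word for insert/junk rejection
    polya_params: PolyAParams = field(default_factory=PolyAParams)
    qual_plateau: float = 37.0
    qual_sd: float = 2.0
    qual_floor: int = 25
    qual_end_mean: float = 28.0

    def __post_init__(self) -> None:
        total = sum(self.artifact_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"artifact_mix probabilities sum to {total}, expected 1")
        if self.insert_len[0] < 1:
            raise ValueError("insert_len minimum must be >= 1")
        for rate in (self.sub_rate, self.indel_rate):
            if not (0 <= rate < 1):
                raise ValueError("error rates must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    clean_start: int
    clean_end: int
    sample: str
    planted_type: str
    polya_len: int
    polyt_len: int


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _forbidden_words(protocol: ProtocolSpec, k: int) -> set[str]:
    words: set[str] = set()
    seqs = list(protocol.barcodes.values())
    seqs += [s for _, s in protocol.adapters5 + protocol.adapters3 + protocol.vectors]
    seqs += [s for _, s, _ in protocol.primers]
    for s in seqs:
        for variant in (s, reverse_complement(s)):
            for i in range(len(variant) - k + 1):
                words.add(variant[i : i + k])
    return words


def _screened_dna(rng: np.random.Generator, length: int, forbidden: set[str], k: int) -> str:
    for _ in range(100):
        seq = _random_dna(rng, length)
        if length < k or not any(seq[i : i + k] in forbidden for i in range(length - k + 1)):
            return seq
    raise RuntimeError("could not sample a protocol-free segment")


def _mutate(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply substitutions/indels; return mutated sequence and a map from
    original boundary positions (0..len) to mutated positions."""
    out: list[str] = []
    coord = np.empty(len(seq) + 1, dtype=np.int64)
    bases = "ACGT"
    for i, base in enumerate(seq):
        coord[i] = len(out)
        u = rng.random()
        if u < sub_rate:
            out.append(bases[(bases.index(base) + rng.integers(1, 4)) % 4])
        elif u < sub_rate + indel_rate / 2:
            pass  # deletion
        elif u < sub_rate + indel_rate:
            out.append(base)
            out.append(bases[rng.integers(0, 4)])
        else:
            out.append(base)
    coord[len(seq)] = len(out)
    return "".join(out), coord


def _simulate_quality(rng: np.random.Generator, length: int, cfg: SimConfig) -> list[int]:
    pos = np.arange(length)
    mean = np.full(length, cfg.qual_plateau)
    knee = int(0.7 * length)
    if length > knee:
        frac = (pos[knee:] - knee) / max(1, length - knee)
        mean[knee:] = cfg.qual_plateau - (cfg.qual_plateau - cfg.qual_end_mean) * frac
    q = rng.normal(mean, cfg.qual_sd)
    return list(np.clip(np.rint(q), cfg.qual_floor, 40).astype(int))


def _middle_layout(
    kind: str,
    insert: str,
    tail: str,
    head: str,
    junk: str,
    amp5: str,
    amp3_rc: str,
    amp5_rc: str,
) -> tuple[list[str], int]:
    """Segment list between the adapters and the index of the insert+tail
    (or head+insert) segment that carries the true clean region."""
    core = head + insert + tail
    if kind == "OK":
        return [amp5, core, amp3_rc], 1
    if kind == "RF":
        return [amp3_rc, insert, amp5], 1
    if kind == "fr":
        return [amp5, insert, amp5_rc], 1
    if kind == "SF":
        return [junk, amp5, core, amp3_rc], 2
    if kind == "RE":
        return [amp5, core, amp3_rc, junk], 1
    if kind == "NF":
        return [amp5, junk, amp5, core, amp3_rc], 3
    if kind == "NR":
        return [amp5, core, amp3_rc, junk, amp3_rc], 1
    raise ValueError(f"unknown artifact type {kind!r}")


def simulate(config: SimConfig) -> tuple[list[Read], list[TruthRecord]]:
    """Generate reads and ground-truth records in memory (deterministic in
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    protocol = config.protocol
    if not protocol.primers:
        raise ValueError("protocol must define amplification primers")
    amp5 = next(s for _, s, r in protocol.primers if r == "amp5")
    amp3 = next(s for _, s, r in protocol.primers if r == "amp3")
    amp3_rc = reverse_complement(amp3)
    amp5_rc = reverse_complement(amp5)
    adapter5 = protocol.adapters5[0][1] if protocol.adapters5 else ""
    adapter3 = protocol.adapters3[0][1] if protocol.adapters3 else ""
    forbidden = _forbidden_words(protocol, config.word_size)
    kinds = list(config.artifact_mix)
    probs = np.array([config.artifact_mix[k] for k in kinds])
    barcode_names = sorted(protocol.barcodes)

    reads: list[Read] = []
    truths: list[TruthRecord] = []
    for idx in range(config.n_reads):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        sample = barcode_names[rng.integers(0, len(barcode_names))]
        barcode = protocol.barcodes[sample]
        insert = _screened_dna(
            rng, int(rng.integers(config.insert_len[0], config.insert_len[1] + 1)),
            forbidden, config.word_size,
        )
        junk = _screened_dna(
            rng, int(rng.integers(config.junk_len[0], config.junk_len[1] + 1)),
            forbidden, config.word_size,
        )
        tail = head = ""
        if kind not in ("RF", "fr"):
            u = rng.random()
            if u < config.polya_prob:
                tail = "A" * int(rng.integers(config.polya_len[0], config.polya_len[1] + 1))
            elif kind == "OK" and u < config.polya_prob + config.polyt_prob:
                head = "T" * int(rng.integers(config.polya_len[0], config.polya_len[1] + 1))
        middle, core_idx = _middle_layout(
            kind, insert, tail, head, junk, amp5, amp3_rc, amp5_rc
        )
        segments = [barcode, adapter5, *middle, adapter3]
        core_seg = 2 + core_idx
        seq = "".join(segments)
        offsets = np.cumsum([0] + [len(s) for s in segments])
        core_start = int(offsets[core_seg])
        core_end = int(offsets[core_seg + 1])
        # the tail model defines the clean boundary on each side
        true_end = tail_trim_extent(seq, core_start, core_end, config.polya_params)
        true_start = head_trim_extent(seq, core_start, true_end, config.polya_params)
        mutated, coord = _mutate(seq, config.sub_rate, config.indel_rate, rng)
        rid = f"sim{idx:06d}"
        qual = _simulate_quality(rng, len(mutated), config)
        reads.append(Read(id=rid, seq=mutated, qual=qual))
        truths.append(
            TruthRecord(
                read_id=rid,
                clean_start=int(coord[true_start]),
                clean_end=int(coord[true_end]),
                sample=sample,
                planted_type=kind,
                polya_len=len(tail),
                polyt_len=len(head),
            )
        )
    return reads, truths


def write_truth_tsv(truths: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclean_start\tclean_end\tsample\tplanted_type\tpolya_len\tpolyt_len\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.clean_start}\t{t.clean_end}\t{t.sample}\t"
                f"{t.planted_type}\t{t.polya_len}\t{t.polyt_len}\n"
            )


def simulate_reads(config: SimConfig, out_prefix: str) -> dict[str, str]:
    """Generate reads and write ``<prefix>.fasta``, ``<prefix>.qual`` and
    ``<prefix>.truth.tsv`` (plus the protocol as ``<prefix>.protocol.fasta``)."""
    from .io import write_protocol

    reads, truths = simulate(config)
    paths = {
        "fasta": f"{out_prefix}.fasta",
        "qual": f"{out_prefix}.qual",
        "truth": f"{out_prefix}.truth.tsv",
        "protocol": f"{out_prefix}.protocol.fasta",
    }
    with open(paths["fasta"], "w") as ffa, open(paths["qual"], "w") as fq:
        for read in reads:
            ffa.write(f">{read.id}\n{read.seq}\n")
            fq.write(f">{read.id}\n" + " ".join(str(q) for q in read.qual) + "\n")
    write_truth_tsv(truths, paths["truth"])
    write_protocol(config.protocol, paths["protocol"])
    return paths


def read_truth_tsv(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            p = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(p[0], int(p[1]), int(p[2]), p[3], p[4], int(p[5]), int(p[6]))
            )
    return out
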