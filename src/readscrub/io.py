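"""Readers and writers: FASTA (+454-style QUAL), FASTQ, protocol FASTA, PSL.

Sequence formats go through Biopython's SeqIO; the protocol dialect and the
PSL table are handled here.  Protocol FASTA headers encode the role of each
sequence as ``name|role`` with role one of barcode, adapter5, adapter3,
amp5, amp3, vector.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ACTIVE,
    ALL_ROLES,
    Interval,
    ProtocolSpec,
    PslRecord,
    Read,
    ROLE_ADAPTER3,
    ROLE_ADAPTER5,
    ROLE_AMP3,
    ROLE_AMP5,
    ROLE_BARCODE,
    ROLE_VECTOR,
    validate_dna,
)


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_reads(path_seq: str, path_qual: Optional[str] = None) -> Iterator[Read]:
    """Stream reads from FASTA (optionally paired with a QUAL file) or FASTQ.

    Each read starts active with a full-span clean interval.  FASTQ scores
    are decoded as Phred+33.  Raises on duplicate ids and on a QUAL record
    whose score count mismatches its sequence length.
    """
    fmt = _sniff_format(path_seq)
    quals: Optional[dict[str, list[int]]] = None
    if path_qual is not None:
        if fmt == "fastq":
            raise ValueError("a separate QUAL file only pairs with FASTA input")
        quals = {}
        for rec in SeqIO.parse(path_qual, "qual"):
            if rec.id in quals:
                raise ValueError(f"duplicate id in QUAL file: {rec.id}")
            quals[rec.id] = list(rec.letter_annotations["phred_quality"])
    seen: set[str] = set()
    for rec in SeqIO.parse(path_seq, fmt):
        if rec.id in seen:
            raise ValueError(f"duplicate read id: {rec.id}")
        seen.add(rec.id)
        seq = validate_dna(str(rec.seq), f"read {rec.id}")
        qual: Optional[list[int]] = None
        if fmt == "fastq":
            qual = list(rec.letter_annotations["phred_quality"])
        elif quals is not None:
            if rec.id not in quals:
                raise ValueError(f"read {rec.id} has no record in the QUAL file")
            qual = quals[rec.id]
            if len(qual) != len(seq):
                raise ValueError(
                    f"read {rec.id}: {len(qual)} quality scores for {len(seq)} bases"
                )
        yield Read(id=rec.id, seq=seq, qual=qual)


def write_cleaned(
    reads: Iterable[Read],
    out_fasta: str,
    out_qual: Optional[str] = None,
    discarded_fasta: Optional[str] = None,
) -> dict[str, int]:
    """Write cleaned subsequences of active reads; collect discarded reads.

    Active reads emit ``seq[clean.start:clean.end]`` with the clean
    coordinates and sample in the description.  An active read whose clean
    interval is empty is moved to the discarded output with reason
    ``empty_after_trim``.  Discarded reads keep their full original sequence
    and carry the reason in the header.  Returns counts written per file.
    """
    n_clean = n_disc = 0
    qfh = open(out_qual, "w") if out_qual else None
    dfh = open(discarded_fasta, "w") if discarded_fasta else None
    try:
        with open(out_fasta, "w") as fh:
            for read in reads:
                if read.status == ACTIVE and read.clean.length == 0:
                    read.discard("empty_after_trim")
                if read.status == ACTIVE:
                    desc = f"clean={read.clean.start}-{read.clean.end}"
                    if read.sample:
                        desc += f" sample={read.sample}"
                    rec = SeqRecord(Seq(read.clean_seq), id=read.id, description=desc)
                    SeqIO.write(rec, fh, "fasta")
                    n_clean += 1
                    if qfh is not None and read.qual is not None:
                        qrec = SeqRecord(Seq(read.clean_seq), id=read.id, description=desc)
                        qrec.letter_annotations["phred_quality"] = read.clean_qual
                        SeqIO.write(qrec, qfh, "qual")
                elif dfh is not None:
                    rec = SeqRecord(
                        Seq(read.seq), id=read.id, description=f"reason={read.discard_reason}"
                    )
                    SeqIO.write(rec, dfh, "fasta")
                    n_disc += 1
    finally:
        if qfh is not None:
            qfh.close()
        if dfh is not None:
            dfh.close()
    return {"cleaned": n_clean, "discarded": n_disc}


def read_protocol(path: str) -> ProtocolSpec:
    """Load a protocol FASTA whose headers are ``name|role``."""
    barcodes: dict[str, str] = {}
    adapters5: list[tuple[str, str]] = []
    adapters3: list[tuple[str, str]] = []
    primers: list[tuple[str, str, str]] = []
    vectors: list[tuple[str, str]] = []
    for rec in SeqIO.parse(path, "fasta"):
        header = rec.id
        if "|" not in header:
            raise ValueError(f"protocol header {header!r} lacks a '|role' suffix")
        name, role = header.rsplit("|", 1)
        if role not in ALL_ROLES:
            raise ValueError(f"unknown role {role!r} in protocol header {header!r}")
        seq = validate_dna(str(rec.seq), f"protocol {header}")
        if role == ROLE_BARCODE:
            if name in barcodes:
                raise ValueError(f"duplicate barcode name {name}")
            barcodes[name] = seq
        elif role == ROLE_ADAPTER5:
            adapters5.append((name, seq))
        elif role == ROLE_ADAPTER3:
            adapters3.append((name, seq))
        elif role in (ROLE_AMP5, ROLE_AMP3):
            primers.append((name, seq, role))
        elif role == ROLE_VECTOR:
            vectors.append((name, seq))
    return ProtocolSpec(
        barcodes=barcodes,
        adapters5=adapters5,
        adapters3=adapters3,
        primers=primers,
        vectors=vectors,
    )


def write_protocol(protocol: ProtocolSpec, path: str) -> None:
    """Export a protocol back to role-encoded FASTA (inverse of read_protocol)."""
    with open(path, "w") as fh:
        for name, seq in protocol.barcodes.items():
            fh.write(f">{name}|{ROLE_BARCODE}\n{seq}\n")
        for name, seq in protocol.adapters5:
            fh.write(f">{name}|{ROLE_ADAPTER5}\n{seq}\n")
        for name, seq in protocol.adapters3:
            fh.write(f">{name}|{ROLE_ADAPTER3}\n{seq}\n")
        for name, seq, role in protocol.primers:
            fh.write(f">{name}|{role}\n{seq}\n")
        for name, seq in protocol.vectors:
            fh.write(f">{name}|{ROLE_VECTOR}\n{seq}\n")


_PSL_NCOLS = 21


def parse_psl_line(line: str) -> PslRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < _PSL_NCOLS:
        raise ValueError(f"PSL row has {len(parts)} columns, expected {_PSL_NCOLS}")

    def ints(csv: str) -> tuple[int, ...]:
        return tuple(int(x) for x in csv.rstrip(",").split(",") if x)

    return PslRecord(
        matches=int(parts[0]),
        mismatches=int(parts[1]),
        rep_matches=int(parts[2]),
        n_count=int(parts[3]),
        q_num_insert=int(parts[4]),
        q_base_insert=int(parts[5]),
        t_num_insert=int(parts[6]),
        t_base_insert=int(parts[7]),
        strand=parts[8],
        q_name=parts[9],
        q_size=int(parts[10]),
        q_start=int(parts[11]),
        q_end=int(parts[12]),
        t_name=parts[13],
        t_size=int(parts[14]),
        t_start=int(parts[15]),
        t_end=int(parts[16]),
        block_count=int(parts[17]),
        block_sizes=ints(parts[18]),
        q_starts=ints(parts[19]),
        t_starts=ints(parts[20]),
    )


def read_psl(path: str) -> list[PslRecord]:
    """Parse a 21-column PSL file; header lines (psLayout preamble) are skipped."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            first = line.split("\t", 1)[0]
            # tolerate the optional psLayout header block
            if not first or not first.lstrip("-").isdigit():
                if line.startswith(("psLayout", "match", "-", " ")):
                    continue
                raise ValueError(f"malformed PSL line: {line[:60]!r}")
            records.append(parse_psl_line(line))
    return records


def format_psl_record(rec: PslRecord) -> str:
    def csv(values: tuple[int, ...]) -> str:
        return ",".join(str(v) for v in values) + ","

    fields = [
        rec.matches, rec.mismatches, rec.rep_matches, rec.n_count,
        rec.q_num_insert, rec.q_base_insert, rec.t_num_insert, rec.t_base_insert,
        rec.strand, rec.q_name, rec.q_size, rec.q_start, rec.q_end,
        rec.t_name, rec.t_size, rec.t_start, rec.t_end,
        rec.block_count, csv(rec.block_sizes), csv(rec.q_starts), csv(rec.t_starts),
    ]
    return "\t".join(str(f) for f in fields)


def write_psl(records: Iterable[PslRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_psl_record(rec) + "\n")


def write_intervals_tsv(reads: Iterable[Read], path: str) -> None:
    """Write per-read clean intervals (id, start, end, status, reason) as TSV."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tstatus\tdiscard_reason\tsample\tclass\n")
        for r in reads:
            fh.write(
                f"{r.id}\t{r.clean.start}\t{r.clean.end}\t{r.status}\t"
                f"{r.discard_reason or ''}\t{r.sample or ''}\t{r.primer_class or ''}\n"
            )


def read_intervals_tsv(path: str) -> dict[str, Interval]:
    """Read a clean-interval TSV back into an id -> Interval map (active reads)."""
    out: dict[str, Interval] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if "status" in idx and parts[idx["status"]] != ACTIVE:
                continue
            out[parts[idx["read_id"]]] = Interval(
                int(parts[idx["start"]]), int(parts[idx["end"]])
            )
    return out


def write_trim_log_tsv(reads: Iterable[Read], path: str) -> None:
    """Per-read, per-stage interval changes (stage, before, after) as TSV."""
    with open(path, "w") as fh:
        fh.write("read_id\tstage\tbefore_start\tbefore_end\tafter_start\tafter_end\n")
        for r in reads:
            for stage, before, after in r.trim_log:
                fh.write(
                    f"{r.id}\t{stage}\t{before.start}\t{before.end}\t"
                    f"{after.start}\t{after.end}\n"
                )
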