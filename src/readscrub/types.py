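"""Core domain types shared by every cleaning stage.

Coordinate convention: all intervals are 0-based, half-open ``[start, end)``
into the *original* read sequence.  Trimming is virtual — stages narrow the
read's clean interval and append to its trim log; bases are only physically
removed when the read is written out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)!r}")
    return seq


class Interval(NamedTuple):
    """Half-open interval [start, end)."""

    start: int
    end: int

    def __len__(self) -> int:  # length of the spanned region, not the tuple
        return max(0, self.end - self.start)

    @property
    def length(self) -> int:
        return max(0, self.end - self.start)

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


# status values
ACTIVE = "active"
DISCARDED = "discarded"


@dataclass
class Read:
    """A sequencing read with its current clean interval and trim history.

    ``clean`` always refers to coordinates of the original ``seq``; stages
    shrink it monotonically.  A discarded read keeps its full sequence and a
    non-null ``discard_reason``.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    clean: Interval = None  # type: ignore[assignment]
    sample: Optional[str] = None
    status: str = ACTIVE
    discard_reason: Optional[str] = None
    trim_log: list[tuple[str, Interval, Interval]] = field(default_factory=list)
    primer_class: Optional[str] = None  # error-taxonomy label set by the primer stage

    def __post_init__(self) -> None:
        if self.clean is None:
            self.clean = Interval(0, len(self.seq))
        else:
            self.clean = Interval(*self.clean)
        if not (0 <= self.clean.start <= self.clean.end <= len(self.seq)):
            raise ValueError(f"read {self.id}: clean interval {self.clean} outside sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    @property
    def clean_seq(self) -> str:
        return self.seq[self.clean.start : self.clean.end]

    @property
    def clean_qual(self) -> Optional[list[int]]:
        if self.qual is None:
            return None
        return self.qual[self.clean.start : self.clean.end]

    def set_clean(self, stage: str, new: Interval) -> None:
        """Narrow the clean interval, recording the change in the trim log."""
        new = Interval(*new)
        if new.length <= 0:
            new = Interval(new.start, new.start)
        if not (self.clean.start <= new.start and new.end <= self.clean.end):
            raise ValueError(
                f"read {self.id}: stage {stage} tried to widen {self.clean} -> {new}"
            )
        self.trim_log.append((stage, self.clean, new))
        self.clean = new

    def discard(self, reason: str) -> None:
        self.status = DISCARDED
        self.discard_reason = reason


# protocol sequence roles
ROLE_BARCODE = "barcode"
ROLE_ADAPTER5 = "adapter5"
ROLE_ADAPTER3 = "adapter3"
ROLE_AMP5 = "amp5"
ROLE_AMP3 = "amp3"
ROLE_VECTOR = "vector"
ALL_ROLES = (ROLE_BARCODE, ROLE_ADAPTER5, ROLE_ADAPTER3, ROLE_AMP5, ROLE_AMP3, ROLE_VECTOR)


@dataclass
class ProtocolSpec:
    """Named contaminant sequences of a sequencing protocol, by role.

    ``primers`` holds (name, sequence, role) with role amp5 (5' amplification
    primer, expected forward near the 5' end) or amp3 (3' primer, expected as
    a reverse-complement match near the 3' end).
    """

    barcodes: dict[str, str] = field(default_factory=dict)
    adapters5: list[tuple[str, str]] = field(default_factory=list)
    adapters3: list[tuple[str, str]] = field(default_factory=list)
    primers: list[tuple[str, str, str]] = field(default_factory=list)
    vectors: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.barcodes.items():
            self.barcodes[name] = validate_dna(seq, f"barcode {name}")
        for attr in ("adapters5", "adapters3", "vectors"):
            pairs = getattr(self, attr)
            names = [n for n, _ in pairs]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate names in {attr}")
            setattr(self, attr, [(n, validate_dna(s, f"{attr} {n}")) for n, s in pairs])
        pnames = [n for n, _, _ in self.primers]
        if len(pnames) != len(set(pnames)):
            raise ValueError("duplicate primer names")
        fixed = []
        for name, seq, role in self.primers:
            if role not in (ROLE_AMP5, ROLE_AMP3):
                raise ValueError(f"primer {name}: role must be amp5 or amp3, got {role!r}")
            fixed.append((name, validate_dna(seq, f"primer {name}"), role))
        self.primers = fixed

    @property
    def adapters(self) -> list[tuple[str, str, str]]:
        """All adapters as (name, seq, role) triples."""
        return [(n, s, ROLE_ADAPTER5) for n, s in self.adapters5] + [
            (n, s, ROLE_ADAPTER3) for n, s in self.adapters3
        ]

    @property
    def primer_subjects(self) -> list[tuple[str, str, str]]:
        return list(self.primers)

    @property
    def vector_subjects(self) -> list[tuple[str, str, str]]:
        return [(n, s, ROLE_VECTOR) for n, s in self.vectors]


@dataclass(frozen=True)
class PslRecord:
    """One row of a UCSC 21-column PSL alignment (0-based half-open)."""

    matches: int
    mismatches: int
    rep_matches: int
    n_count: int
    q_num_insert: int
    q_base_insert: int
    t_num_insert: int
    t_base_insert: int
    strand: str
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    block_count: int
    block_sizes: tuple[int, ...]
    q_starts: tuple[int, ...]
    t_starts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValueError(
                f"PSL {self.q_name}: query interval [{self.q_start},{self.q_end}) "
                f"invalid for size {self.q_size}"
            )
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ValueError(
                f"PSL {self.q_name}: target interval [{self.t_start},{self.t_end}) "
                f"invalid for size {self.t_size}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"PSL {self.q_name}: bad strand {self.strand!r}")
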