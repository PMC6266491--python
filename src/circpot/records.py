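"""Core record types: genomic intervals and transcript records.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. Minus-strand intervals refer to the reverse complement of
the plus-strand genomic slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGTN")
# IUPAC nucleotide codes; ambiguity codes outside {A,C,G,T,N} collapse to N.
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a sequence over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, context: str = "sequence") -> str:
    """Uppercase, map U->T, collapse non-ACGTN IUPAC codes to N.

    Raises ``ValueError`` naming *context* if a character outside the IUPAC
    nucleotide alphabet is present.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise ValueError(
            f"{context}: characters outside the IUPAC nucleotide alphabet: "
            f"{sorted(bad)}"
        )
    if set(seq) <= VALID_BASES:
        return seq
    return "".join(c if c in VALID_BASES else "N" for c in seq)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a named chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValueError("interval coordinates must be integers")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic single-base overlap test."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptRecord:
    """One input sequence with optional genomic interval and class label."""

    id: str
    sequence: str
    interval: Optional[GenomicInterval] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.sequence is not None and self.interval is not None:
            if len(self.sequence) != len(self.interval):
                raise ValueError(
                    f"record {self.id}: sequence length {len(self.sequence)} "
                    f"!= interval length {len(self.interval)}"
                )

    def __len__(self) -> int:
        return len(self.sequence) if self.sequence else len(self.interval)

    def query_interval(self) -> GenomicInterval:
        """Interval used for annotation queries.

        Records read from FASTA carry no genomic position; annotation tracks
        may then be keyed by transcript id, so the fallback interval spans
        the whole sequence on a contig named after the record.
        """
        if self.interval is not None:
            return self.interval
        return GenomicInterval(self.id, 0, len(self.sequence), "+")


def check_unique_ids(records: list) -> None:
    seen: set = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id}")
        seen.add(rec.id)
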