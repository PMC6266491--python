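"""Reading and writing transcript sets: FASTA, BED6, genome extraction,
and the dataset-construction filters (minimum length, overlap exclusion).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, List, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .records import (
    GenomicInterval,
    TranscriptRecord,
    check_unique_ids,
    normalize_sequence,
    reverse_complement,
)

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> List[TranscriptRecord]:
    """Read a (possibly gzipped) multi-FASTA file into transcript records.

    Sequences are uppercased with U mapped to T; ambiguity codes outside
    {A,C,G,T,N} collapse to N. Record ids are the first whitespace-delimited
    token of each header. Duplicate ids, empty files and non-IUPAC
    characters raise ``ValueError``.
    """
    records: List[TranscriptRecord] = []
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(entry.seq), context=f"record {entry.id!r}")
            if not seq:
                raise ValueError(f"record {entry.id!r}: empty sequence")
            records.append(TranscriptRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: PathLike,
                width: int = 60) -> None:
    """Write transcript records as multi-FASTA (gzipped if path ends .gz)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        for rec in records
    ]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_bed(path: PathLike) -> List[TranscriptRecord]:
    """Read a BED6 file into records carrying intervals but no sequence.

    Columns: chrom, start, end, name, score, strand (tab-separated,
    0-based half-open). A missing strand column defaults to "+". Malformed
    coordinates or empty intervals raise ``ValueError`` with line numbers.
    """
    records: List[TranscriptRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path} line {lineno}: empty or inverted interval "
                    f"{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"line{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            records.append(
                TranscriptRecord(
                    id=name,
                    sequence=None,
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
    if not records:
        raise ValueError(f"no BED records found in {path}")
    return records


def bed_to_sequences(records: Sequence[TranscriptRecord],
                     genome: PathLike) -> List[TranscriptRecord]:
    """Extract strand-aware sequences from a genome FASTA for BED records.

    Plus-strand records get ``genome[chrom][start:end]``; minus-strand
    records get its reverse complement, so ``len(sequence) == end - start``
    always holds. Unknown chromosomes or out-of-bounds intervals raise
    ``ValueError``.
    """
    fasta = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    out: List[TranscriptRecord] = []
    for rec in records:
        iv = rec.interval
        if iv is None:
            raise ValueError(f"record {rec.id}: no interval to extract")
        if iv.chrom not in fasta:
            raise ValueError(f"record {rec.id}: chromosome {iv.chrom!r} "
                             "not in genome")
        chrom_len = len(fasta[iv.chrom])
        if iv.end > chrom_len:
            raise ValueError(
                f"record {rec.id}: interval {iv.chrom}:{iv.start}-{iv.end} "
                f"exceeds chromosome length {chrom_len}"
            )
        seq = normalize_sequence(fasta[iv.chrom][iv.start:iv.end],
                                 context=f"record {rec.id!r}")
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out.append(TranscriptRecord(id=rec.id, sequence=seq, interval=iv,
                                    label=rec.label))
    return out


def filter_transcripts(records: Sequence[TranscriptRecord],
                       min_len: int = 200,
                       exclusion: Optional[Sequence[GenomicInterval]] = None,
                       ) -> List[TranscriptRecord]:
    """Dataset-construction filter: drop short and exclusion-overlapping records.

    Records shorter than ``min_len`` are removed (length exactly ``min_len``
    is kept). If ``exclusion`` intervals are given, any record whose interval
    shares at least one base with any exclusion interval on the same
    chromosome (strand-agnostic) is removed. Order is preserved; the filter
    is idempotent.
    """
    exclusion = list(exclusion or [])
    kept: List[TranscriptRecord] = []
    for rec in records:
        if len(rec) < min_len:
            continue
        if exclusion:
            if rec.interval is None:
                raise ValueError(
                    f"record {rec.id}: exclusion filtering requires intervals"
                )
            if any(rec.interval.overlaps(ex) for ex in exclusion):
                continue
        kept.append(rec)
    return kept
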