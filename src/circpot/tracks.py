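"""Annotation track stores: per-base scores (bedGraph), interval features
(BED) and variant positions (VCF or two-column text), all queryable by
genomic interval.

Uncovered bases in a score track are reported as NaN so that downstream
statistics can skip them explicitly (zero is a meaningful conservation
value and must not be imputed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pysam
from intervaltree import IntervalTree

from .records import GenomicInterval

PathLike = Union[str, Path]


def _open_text(path: PathLike):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


class BedGraphTrack:
    """Per-base score track backed by bedGraph intervals."""

    def __init__(self) -> None:
        self._trees: Dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, value)

    def query(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base values over the interval; NaN where uncovered."""
        out = np.full(len(interval), np.nan)
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return out
        for hit in tree.overlap(interval.start, interval.end):
            lo = max(hit.begin, interval.start) - interval.start
            hi = min(hit.end, interval.end) - interval.start
            out[lo:hi] = hit.data
        return out

    @classmethod
    def from_file(cls, path: PathLike) -> "BedGraphTrack":
        track = cls()
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ValueError(
                        f"{path} line {lineno}: expected 4 bedGraph columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                    value = float(fields[3])
                except ValueError as exc:
                    raise ValueError(
                        f"{path} line {lineno}: malformed bedGraph line") from exc
                if start >= end:
                    raise ValueError(
                        f"{path} line {lineno}: empty interval {start}-{end}")
                track.add(fields[0], start, end, value)
        return track


@dataclass(frozen=True)
class IntervalFeature:
    chrom: str
    start: int
    end: int
    name: str = "."


class IntervalTrack:
    """Named interval annotations (e.g. repeats) queryable by overlap."""

    def __init__(self) -> None:
        self._trees: Dict[str, IntervalTree] = {}

    def add(self, feature: IntervalFeature) -> None:
        self._trees.setdefault(feature.chrom, IntervalTree()).addi(
            feature.start, feature.end, feature)

    def query(self, interval: GenomicInterval) -> List[IntervalFeature]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end)]
        return sorted(hits, key=lambda f: (f.start, f.end, f.name))

    def filtered(self, name_prefix: str) -> "IntervalTrack":
        """New track keeping features whose name starts with the prefix
        (case-insensitive); used to isolate e.g. ALU repeats."""
        prefix = name_prefix.upper()
        out = IntervalTrack()
        for tree in self._trees.values():
            for hit in tree:
                if hit.data.name.upper().startswith(prefix):
                    out.add(hit.data)
        return out

    @classmethod
    def from_file(cls, path: PathLike) -> "IntervalTrack":
        track = cls()
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path} line {lineno}: expected >= 3 BED columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path} line {lineno}: non-integer coordinates") from exc
                if start >= end:
                    raise ValueError(
                        f"{path} line {lineno}: empty interval {start}-{end}")
                name = fields[3] if len(fields) > 3 else "."
                track.add(IntervalFeature(fields[0], start, end, name))
        return track


class VariantTrack:
    """Variant position set; positions are 0-based single bases."""

    def __init__(self) -> None:
        self._positions: Dict[str, List[int]] = {}
        self._arrays: Dict[str, np.ndarray] = {}

    def add(self, chrom: str, pos: int) -> None:
        self._positions.setdefault(chrom, []).append(pos)
        self._arrays.pop(chrom, None)

    def _sorted(self, chrom: str) -> np.ndarray:
        if chrom not in self._arrays:
            uniq = np.unique(np.asarray(self._positions.get(chrom, []), dtype=int))
            self._arrays[chrom] = uniq
        return self._arrays[chrom]

    def query(self, interval: GenomicInterval) -> np.ndarray:
        """Unique variant positions falling in [start, end)."""
        pos = self._sorted(interval.chrom)
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        return pos[lo:hi]

    @classmethod
    def from_vcf(cls, path: PathLike) -> "VariantTrack":
        track = cls()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                # VCF POS is 1-based; store 0-based.
                track.add(rec.chrom, rec.pos - 1)
        return track

    @classmethod
    def from_positions_file(cls, path: PathLike) -> "VariantTrack":
        """Two-column (chrom, 0-based position) text file."""
        track = cls()
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(
                        f"{path} line {lineno}: expected chrom and position")
                try:
                    track.add(fields[0], int(fields[1]))
                except ValueError as exc:
                    raise ValueError(
                        f"{path} line {lineno}: non-integer position") from exc
        return track


def read_track(path: PathLike, kind: str):
    """Load an annotation track of the given kind.

    kind: "bedgraph" -> BedGraphTrack (per-base values, NaN where uncovered);
    "bed" -> IntervalTrack (overlapping features); "vcf" -> VariantTrack.
    """
    if kind == "bedgraph":
        return BedGraphTrack.from_file(path)
    if kind == "bed":
        return IntervalTrack.from_file(path)
    if kind == "vcf":
        return VariantTrack.from_vcf(path)
    raise ValueError(f"unknown track kind {kind!r}; "
                     "expected bedgraph, bed or vcf")


@dataclass
class AnnotationBundle:
    """The annotation inputs of the external feature group.

    conservation: per-base score track (phyloP-like); repeats: interval
    annotations whose name column carries the repeat class (ALU matched by
    case-insensitive prefix); variants: variant position set.
    """

    conservation: Optional[BedGraphTrack] = None
    repeats: Optional[IntervalTrack] = None
    variants: Optional[VariantTrack] = None

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"annotation bundle missing required track(s): {missing}")
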