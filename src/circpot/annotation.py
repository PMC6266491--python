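"""Conservation and "other" feature computations.

Two conservation features (mean and population SD of a per-base score) and
five others: ALU overlap fraction, tandem-repeat coverage, longest-ORF
length, ORF propensity and SNP density. ORF and tandem-repeat features come
from the sequence itself; the rest need annotation tracks and a genomic
interval.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np

from .records import GenomicInterval
from .tracks import IntervalFeature, VariantTrack

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))


def conservation_stats(scores: Sequence[float]) -> Tuple[float, float]:
    """Mean and population standard deviation of per-base scores.

    NaN entries mark uncovered bases and are skipped. All-missing input
    raises ``ValueError``.
    """
    arr = np.asarray(scores, dtype=float)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise ValueError("conservation_stats: no non-missing values")
    return float(valid.mean()), float(valid.std(ddof=0))


def longest_orf(sequence: str) -> Tuple[int, float]:
    """Longest complete open reading frame over the three forward frames.

    An ORF is ATG..(TAA|TAG|TGA) in-frame; the returned length counts both
    the start and the stop codon. Returns (0, 0.0) when no complete ORF
    exists. The second value is the ORF length divided by sequence length
    (ORF propensity).
    """
    n = len(sequence)
    if n < 3:
        raise ValueError("longest_orf requires length >= 3")
    best = 0
    for frame in range(3):
        open_start = None
        for i in range(frame, n - 2, 3):
            codon = sequence[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - open_start)
                open_start = None
        # ORFs without an in-frame stop are incomplete and do not count
    return best, best / n


def tandem_repeat_fraction(sequence: str, max_period: int = 12,
                           min_copies: int = 2, min_span: int = 6) -> float:
    """Fraction of sequence covered by exact tandem repeat arrays.

    A tandem array is a maximal run of period-p repetition (p <= max_period)
    spanning at least ``min_copies`` full copies and ``min_span`` bases.
    Overlapping arrays of different periods count once via the coverage
    union.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("tandem_repeat_fraction: empty sequence")
    covered = np.zeros(n, dtype=bool)
    for p in range(1, min(max_period, n - 1) + 1):
        i = 0
        while i < n - p:
            if sequence[i] == sequence[i + p]:
                j = i
                while j < n - p and sequence[j] == sequence[j + p]:
                    j += 1
                # positions i..j-1 matched; periodic block spans i..j+p-1
                span = (j - i) + p
                if span >= min_span and span // p >= min_copies:
                    covered[i:j + p] = True
                i = j + 1
            else:
                i += 1
    return float(covered.sum()) / n


def interval_overlap_fraction(interval: GenomicInterval,
                              features: Iterable[IntervalFeature]) -> float:
    """Fraction of the interval's bases covered by the union of features."""
    mask = np.zeros(len(interval), dtype=bool)
    for feat in features:
        if feat.chrom != interval.chrom:
            continue
        lo = max(feat.start, interval.start) - interval.start
        hi = min(feat.end, interval.end) - interval.start
        if hi > lo:
            mask[lo:hi] = True
    return float(mask.sum()) / len(interval)


def snp_density(interval: GenomicInterval, variants: VariantTrack) -> float:
    """Unique variant positions within the interval per base."""
    return len(variants.query(interval)) / len(interval)
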