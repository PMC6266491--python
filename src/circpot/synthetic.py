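"""Synthetic labeled sequence datasets with controllable class signal.

The generator emulates the structure of a circRNA-vs-background training
set without any external downloads: two classes of random sequences with
tunable GC composition, planted splice-like motifs (GTAG by default) at
class-specific rates, genomic placement on a toy genome so BED mode is
testable, and fixture annotation tracks (conservation with a class mean
shift, ALU-like repeat intervals at class-dependent density, uniform
variant positions).

The defaults are the package's reference study conditions: 500 sequences
per class, lengths 200-1000 nt (mirroring the >= 200 nt dataset filter),
GTAG planted at 2.0 vs 0.5 expected occurrences per 100 nt, GC 0.55 vs
0.45, a +0.5 conservation mean shift for positives, ALU carrier
probability 0.4 for positives (half that for negatives) and one variant
per 100 nt in both classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import write_fasta
from .records import GenomicInterval, TranscriptRecord, reverse_complement
from .tracks import (
    AnnotationBundle,
    BedGraphTrack,
    IntervalFeature,
    IntervalTrack,
    VariantTrack,
)

BASES = np.array(list("ACGT"))
_SPACER = 25          # bases between records on the toy genome
_CONS_BLOCK = 5       # conservation track resolution (nt per bedGraph step)
_ALU_LEN = 300        # ALU-like repeat length (typical Alu element size)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study conditions; seed fixed => identical output."""

    n_pos: int = 500
    n_neg: int = 500
    length_range_pos: Tuple[int, int] = (200, 1000)
    length_range_neg: Tuple[int, int] = (200, 1000)
    motif: str = "GTAG"
    motif_rate_pos: float = 2.0   # expected planted motifs per 100 nt
    motif_rate_neg: float = 0.5
    gc_pos: float = 0.55
    gc_neg: float = 0.45
    alu_prob: float = 0.4         # positive-class ALU carrier probability
    variant_rate: float = 0.01    # variants per base, both classes
    conservation_shift: float = 0.5  # positive-class conservation mean shift
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("motif_rate_pos", "motif_rate_neg", "alu_prob",
                     "variant_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gc_pos", "gc_neg"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("length_range_pos", "length_range_neg"):
            lo, hi = getattr(self, name)
            if not (4 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 4 <= lo <= hi")
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be a non-empty A/C/G/T string")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        obj = json.loads(text)
        for key in ("length_range_pos", "length_range_neg"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)


@dataclass
class SyntheticDataset:
    """Generated records plus their toy genome and annotation tracks."""

    records: List[TranscriptRecord]
    annotations: AnnotationBundle
    genome: Dict[str, str]
    config: SyntheticConfig

    # raw track rows kept so file output matches the in-memory bundle
    conservation_rows: List[Tuple[str, int, int, float]] = field(default_factory=list)
    repeat_rows: List[Tuple[str, int, int, str]] = field(default_factory=list)
    variant_rows: List[Tuple[str, int]] = field(default_factory=list)

    def write(self, outdir) -> Dict[str, Path]:
        """Write FASTA/BED/bedGraph/VCF fixtures plus the config as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fname for name, fname in [
            ("genome", "genome.fa"), ("fasta", "transcripts.fa"),
            ("bed", "transcripts.bed"), ("pos", "pos.fa"), ("neg", "neg.fa"),
            ("conservation", "conservation.bedgraph"),
            ("repeats", "repeats.bed"), ("variants", "variants.vcf"),
            ("config", "config.json")]}
        write_fasta([TranscriptRecord(id=c, sequence=s)
                     for c, s in self.genome.items()], paths["genome"])
        write_fasta(self.records, paths["fasta"])
        write_fasta([r for r in self.records if r.label == 1], paths["pos"])
        write_fasta([r for r in self.records if r.label == 0], paths["neg"])
        with open(paths["bed"], "w") as fh:
            for rec in self.records:
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.id}\t0"
                         f"\t{iv.strand}\n")
        with open(paths["conservation"], "w") as fh:
            for chrom, start, end, value in self.conservation_rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")
        with open(paths["repeats"], "w") as fh:
            for chrom, start, end, name in self.repeat_rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")
        with open(paths["variants"], "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, seq in self.genome.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos in sorted(self.variant_rows):
                ref = self.genome[chrom][pos]
                alt = "A" if ref != "A" else "G"
                fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")
        paths["config"].write_text(self.config.to_json())
        return paths


def _random_sequence(rng: np.random.Generator, length: int, gc: float,
                     motif: str, motif_rate: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(BASES, size=length, p=p)
    m = len(motif)
    if length >= m and motif_rate > 0:
        k = rng.poisson(motif_rate * length / 100.0)
        for pos in rng.integers(0, length - m + 1, size=k):
            seq[pos:pos + m] = list(motif)
    return "".join(seq)


def _class_params(config: SyntheticConfig, label: int) -> dict:
    if label == 1:
        return dict(length_range=config.length_range_pos, gc=config.gc_pos,
                    motif_rate=config.motif_rate_pos,
                    alu_prob=config.alu_prob,
                    cons_mean=config.conservation_shift)
    return dict(length_range=config.length_range_neg, gc=config.gc_neg,
                motif_rate=config.motif_rate_neg,
                alu_prob=config.alu_prob / 2.0, cons_mean=0.0)


def generate_classification_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a labeled two-class dataset with annotation tracks.

    Sequences are drawn i.i.d. per base from a class GC-biased composition
    with Poisson-planted motif insertions. Every record is placed on a toy
    genome chromosome (random strand; minus-strand records store the
    reverse complement on the genome) so BED-mode extraction round-trips.
    The conservation track is blockwise N(mu_class, 1) at 5 nt resolution;
    ALU-like intervals appear at class-dependent density alongside
    class-neutral non-ALU repeats; variant positions are uniform.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    records: List[TranscriptRecord] = []
    genome_parts: List[str] = []
    cons_rows: List[Tuple[str, int, int, float]] = []
    repeat_rows: List[Tuple[str, int, int, str]] = []
    variant_rows: List[Tuple[str, int]] = []
    offset = 0

    labels = [1] * config.n_pos + [0] * config.n_neg
    counters = {1: 0, 0: 0}
    for label in labels:
        par = _class_params(config, label)
        counters[label] += 1
        rid = f"{'pos' if label else 'neg'}_{counters[label]:04d}"
        lo, hi = par["length_range"]
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length, par["gc"], config.motif,
                               par["motif_rate"])
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = offset, offset + length
        genome_parts.append(seq if strand == "+" else reverse_complement(seq))
        interval = GenomicInterval(chrom, start, end, strand)
        records.append(TranscriptRecord(id=rid, sequence=seq,
                                        interval=interval, label=label))

        # conservation: blockwise values with the class mean shift
        for b in range(start, end, _CONS_BLOCK):
            value = float(rng.normal(par["cons_mean"], 1.0))
            cons_rows.append((chrom, b, min(b + _CONS_BLOCK, end), value))
        # repeats: ALU-like at class density, non-ALU noise in both classes
        if rng.random() < par["alu_prob"]:
            for _ in range(int(rng.integers(1, 3))):
                alu_len = min(_ALU_LEN, length)
                a = int(rng.integers(start, end - alu_len + 1))
                repeat_rows.append((chrom, a, a + alu_len, "ALU"))
        if rng.random() < 0.3:
            l1_len = min(150, length)
            a = int(rng.integers(start, end - l1_len + 1))
            repeat_rows.append((chrom, a, a + l1_len, "L1"))
        # variants: uniform unique positions
        n_var = rng.binomial(length, config.variant_rate)
        if n_var:
            for pos in rng.choice(length, size=n_var, replace=False):
                variant_rows.append((chrom, start + int(pos)))

        spacer = "".join(rng.choice(BASES, size=_SPACER))
        genome_parts.append(spacer)
        offset = end + _SPACER

    genome = {chrom: "".join(genome_parts)}

    conservation = BedGraphTrack()
    for c, s, e, v in cons_rows:
        conservation.add(c, s, e, v)
    repeats = IntervalTrack()
    for c, s, e, name in repeat_rows:
        repeats.add(IntervalFeature(c, s, e, name))
    variants = VariantTrack()
    for c, p in variant_rows:
        variants.add(c, p)

    bundle = AnnotationBundle(conservation=conservation, repeats=repeats,
                              variants=variants)
    return SyntheticDataset(records=records, annotations=bundle,
                            genome=genome, config=config,
                            conservation_rows=cons_rows,
                            repeat_rows=repeat_rows,
                            variant_rows=variant_rows)


def generate_null_dataset(config: SyntheticConfig) -> List[TranscriptRecord]:
    """Labeled records where both classes share the negative-class
    distribution, so the labels carry no signal (AUC ~ 0.5 checks)."""
    null_config = SyntheticConfig(
        n_pos=config.n_pos, n_neg=config.n_neg,
        length_range_pos=config.length_range_neg,
        length_range_neg=config.length_range_neg,
        motif=config.motif,
        motif_rate_pos=config.motif_rate_neg,
        motif_rate_neg=config.motif_rate_neg,
        gc_pos=config.gc_neg, gc_neg=config.gc_neg,
        alu_prob=config.alu_prob, variant_rate=config.variant_rate,
        conservation_shift=0.0, seed=config.seed)
    # all sequence-level parameters are equal across classes, so the labels
    # carry no signal for any sequence-derived feature
    return generate_classification_dataset(null_config).records
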