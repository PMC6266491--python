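"""The feature encoding: 70 basic sequence features, plus assembly of the
full 178-feature vector (basic + Top-K graph + 2 conservation + 5 other)
and its min-max normalization.

Basic features, in canonical schema order: sequence length; AG, GT, GTAG
and AGGT frequencies (the donor/acceptor dinucleotides and their
backsplice-order concatenations); GC content; and the 64 trinucleotide
frequencies in lexicographic order. All frequencies use overlapping-window
counts divided by the number of windows, so they are scale-free in sequence
length. Windows containing N are excluded from both numerator and
denominator of the trinucleotide frequencies.

Three feature profiles are supported: ``gc_len`` (GC content and length
only), ``sequence_only`` (basic + graph; the profile available for plain
FASTA input with no genomic context) and ``all`` (adds the conservation and
annotation features, which require tracks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from .annotation import (
    conservation_stats,
    interval_overlap_fraction,
    longest_orf,
    snp_density,
    tandem_repeat_fraction,
)
from .graph import GraphFeatureIndex, encode_graph_matrix
from .records import TranscriptRecord
from .tracks import AnnotationBundle

PROFILES = ("gc_len", "sequence_only", "all")

TRINUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=3)]
MOTIFS = ("GT", "AG", "GTAG", "AGGT")

BASIC_NAMES = (
    ["length", "freq_AG", "freq_GT", "freq_GTAG", "freq_AGGT", "gc_content"]
    + [f"freq_{t}" for t in TRINUCLEOTIDES]
)
CONSERVATION_NAMES = ["cons_mean", "cons_sd"]
OTHER_NAMES = ["alu", "tandem", "orf_length", "orf_prop", "snp_density"]


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T); N bases are ignored entirely."""
    if not sequence:
        raise ValueError("gc_content: empty sequence")
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        raise ValueError("gc_content: sequence contains no unambiguous bases")
    return gc / (gc + at)


def trinucleotide_frequencies(sequence: str) -> np.ndarray:
    """Overlapping trinucleotide frequencies over the 64 A/C/G/T triplets.

    Windows containing N are skipped in both numerator and denominator, so
    an N-free sequence's frequencies sum to exactly 1. A sequence whose
    every window contains N yields all zeros.
    """
    n = len(sequence)
    if n < 3:
        raise ValueError("trinucleotide_frequencies requires length >= 3")
    counts: Dict[str, int] = {}
    valid = 0
    for i in range(n - 2):
        tri = sequence[i:i + 3]
        if "N" in tri:
            continue
        valid += 1
        counts[tri] = counts.get(tri, 0) + 1
    out = np.zeros(64)
    if valid:
        for k, tri in enumerate(TRINUCLEOTIDES):
            out[k] = counts.get(tri, 0) / valid
    return out


def motif_frequencies(sequence: str) -> np.ndarray:
    """Frequencies of the GT, AG, GTAG and AGGT motifs (in that order).

    Each motif's overlapping occurrence count is divided by the number of
    windows of its own length, ``len(sequence) - len(motif) + 1``.
    """
    n = len(sequence)
    if n < 4:
        raise ValueError("motif_frequencies requires length >= 4")
    out = np.empty(4)
    for k, motif in enumerate(MOTIFS):
        m = len(motif)
        count = sum(1 for i in range(n - m + 1) if sequence[i:i + m] == motif)
        out[k] = count / (n - m + 1)
    return out


def basic_features(sequence: str) -> np.ndarray:
    """The 70 basic features in canonical schema order."""
    gt, ag, gtag, aggt = motif_frequencies(sequence)
    head = [float(len(sequence)), ag, gt, gtag, aggt, gc_content(sequence)]
    return np.concatenate([head, trinucleotide_frequencies(sequence)])


@dataclass
class FeatureSchema:
    """Canonical feature order, group tags and learned normalization bounds."""

    names: List[str]
    groups: List[str]
    profile: str
    norm_min: Optional[np.ndarray] = None
    norm_max: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if len(self.groups) != len(self.names):
            raise ValueError("groups and names must align")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.norm_min is not None and self.norm_max is not None:
            if np.any(np.asarray(self.norm_min) > np.asarray(self.norm_max)):
                raise ValueError("norm_min must be <= norm_max elementwise")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def fitted(self) -> bool:
        return self.norm_min is not None and self.norm_max is not None

    def group_sizes(self) -> Dict[str, int]:
        sizes: Dict[str, int] = {}
        for g in self.groups:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def to_json(self) -> str:
        return json.dumps({
            "names": self.names,
            "groups": self.groups,
            "profile": self.profile,
            "norm_min": None if self.norm_min is None else list(map(float, self.norm_min)),
            "norm_max": None if self.norm_max is None else list(map(float, self.norm_max)),
        })

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        obj = json.loads(text)
        return cls(
            names=obj["names"], groups=obj["groups"], profile=obj["profile"],
            norm_min=None if obj["norm_min"] is None else np.asarray(obj["norm_min"]),
            norm_max=None if obj["norm_max"] is None else np.asarray(obj["norm_max"]),
        )


def build_schema(profile: str = "sequence_only",
                 graph_k: int = 101) -> FeatureSchema:
    """Construct the canonical schema for a profile.

    The full profile with the default Top-101 graph features has exactly
    178 names (70 basic, 101 graph, 2 conservation, 5 other).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected {PROFILES}")
    if profile == "gc_len":
        return FeatureSchema(names=["gc_content", "length"],
                             groups=["basic", "basic"], profile=profile)
    names = list(BASIC_NAMES)
    groups = ["basic"] * len(BASIC_NAMES)
    names += [f"graph_{k}" for k in range(graph_k)]
    groups += ["graph"] * graph_k
    if profile == "all":
        names += CONSERVATION_NAMES
        groups += ["conservation"] * len(CONSERVATION_NAMES)
        names += OTHER_NAMES
        groups += ["other"] * len(OTHER_NAMES)
    return FeatureSchema(names=names, groups=groups, profile=profile)


@dataclass
class FeatureVector:
    """An ordered feature vector tied to its schema."""

    values: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError(
                f"vector length {self.values.shape} does not match schema "
                f"length {len(self.schema)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def fit_normalizer(matrix: np.ndarray, schema: FeatureSchema) -> FeatureSchema:
    """Learn per-feature min/max bounds from a training matrix.

    Returns a new schema carrying the bounds. Constant features get
    ``min == max`` and normalize to 0.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_normalizer requires an n x p matrix with n >= 2")
    if X.shape[1] != len(schema):
        raise ValueError("matrix width does not match schema length")
    if not np.all(np.isfinite(X)):
        raise ValueError("fit_normalizer: non-finite entries")
    scaler = MinMaxScaler(clip=True).fit(X)
    return FeatureSchema(names=schema.names, groups=schema.groups,
                         profile=schema.profile,
                         norm_min=scaler.data_min_.copy(),
                         norm_max=scaler.data_max_.copy())


def apply_normalizer(values: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    """Min-max normalize to [0, 1] with clipping for out-of-range values."""
    if not schema.fitted:
        raise ValueError("schema has no fitted normalization bounds")
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != len(schema):
        raise ValueError(
            f"vector length {v.shape[-1]} does not match schema length "
            f"{len(schema)}")
    span = schema.norm_max - schema.norm_min
    safe = np.where(span > 0, span, 1.0)
    out = (v - schema.norm_min) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


class FeatureNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style min-max normalizer over a feature schema."""

    def __init__(self, schema: Optional[FeatureSchema] = None):
        self.schema = schema

    def fit(self, X, y=None):
        base = self.schema
        if base is None:
            X = np.asarray(X, dtype=float)
            base = FeatureSchema(
                names=[f"f{i}" for i in range(X.shape[1])],
                groups=["basic"] * X.shape[1], profile="sequence_only")
        self.schema_ = fit_normalizer(X, base)
        return self

    def transform(self, X):
        check_is_fitted(self, "schema_")
        return apply_normalizer(np.asarray(X, dtype=float), self.schema_)


def _annotation_values(record: TranscriptRecord,
                       annotations: AnnotationBundle) -> np.ndarray:
    """cons_mean, cons_sd + the five 'other' features for one record."""
    annotations.require("conservation", "repeats", "variants")
    qiv = record.query_interval()
    cons = annotations.conservation.query(qiv)
    mean, sd = conservation_stats(cons)
    alu_feats = [f for f in annotations.repeats.query(qiv)
                 if f.name.upper().startswith("ALU")]
    alu = interval_overlap_fraction(qiv, alu_feats)
    tandem = tandem_repeat_fraction(record.sequence)
    orf_len, orf_prop = longest_orf(record.sequence)
    snp = snp_density(qiv, annotations.variants)
    return np.array([mean, sd, alu, tandem, float(orf_len), orf_prop, snp])


def assemble_features(record: TranscriptRecord,
                      annotations: Optional[AnnotationBundle] = None,
                      graph_index: Optional[GraphFeatureIndex] = None,
                      profile: str = "sequence_only") -> FeatureVector:
    """Assemble one record's raw (unnormalized) feature vector.

    Profile ``gc_len`` needs nothing extra; ``sequence_only`` needs a fitted
    graph feature index; ``all`` additionally needs annotation tracks.
    """
    matrix, schema = assemble_feature_matrix(
        [record], annotations=annotations, graph_index=graph_index,
        profile=profile)
    return FeatureVector(values=matrix[0], schema=schema)


def assemble_feature_matrix(records: Sequence[TranscriptRecord],
                            annotations: Optional[AnnotationBundle] = None,
                            graph_index: Optional[GraphFeatureIndex] = None,
                            profile: str = "sequence_only",
                            graph_counts=None):
    """Assemble an n x p raw feature matrix plus its schema.

    ``graph_counts`` may carry a precomputed n x hash_dim hashed count
    matrix for the records (in order) to avoid re-encoding.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected {PROFILES}")
    if profile == "gc_len":
        schema = build_schema(profile)
        rows = [[gc_content(r.sequence), float(len(r.sequence))]
                for r in records]
        return np.asarray(rows, dtype=float), schema
    if graph_index is None:
        raise ValueError(
            f"profile {profile!r} requires the graph feature group "
            "(no graph_index supplied)")
    if profile == "all" and annotations is None:
        raise ValueError(
            "profile 'all' requires the conservation and other feature "
            "groups (no annotations supplied)")
    schema = build_schema(profile, graph_k=len(graph_index))
    basic = np.asarray([basic_features(r.sequence) for r in records])
    if graph_counts is None:
        graph_counts = encode_graph_matrix(
            [r.sequence for r in records], graph_index.params)
    graph = graph_index.project(graph_counts)
    blocks = [basic, graph]
    if profile == "all":
        blocks.append(np.asarray([_annotation_values(r, annotations)
                                  for r in records]))
    matrix = (np.hstack(blocks) if records
              else np.empty((0, len(schema))))
    return matrix, schema


class SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from transcript records to raw feature matrices.

    Parameters mirror :func:`assemble_feature_matrix`; compose with
    :class:`FeatureNormalizer` in a sklearn ``Pipeline`` for the full
    normalized encoding.
    """

    def __init__(self, profile: str = "sequence_only",
                 graph_index: Optional[GraphFeatureIndex] = None,
                 annotations: Optional[AnnotationBundle] = None):
        self.profile = profile
        self.graph_index = graph_index
        self.annotations = annotations

    def fit(self, X=None, y=None):
        self.schema_ = build_schema(
            self.profile,
            graph_k=len(self.graph_index) if self.graph_index is not None else 101)
        return self

    def transform(self, records: Sequence[TranscriptRecord]) -> np.ndarray:
        matrix, schema = assemble_feature_matrix(
            records, annotations=self.annotations,
            graph_index=self.graph_index, profile=self.profile)
        self.schema_ = schema
        return matrix

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "schema_"):
            self.fit()
        return np.asarray(self.schema_.names, dtype=object)
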