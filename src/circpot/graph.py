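"""Hashed neighborhood-pair graph features on nucleotide path graphs.

Each sequence is viewed as a labeled path graph (one node per base, edges
between neighbours). Features are pairs of rooted neighborhood subgraphs:
for every unordered pair of roots at backbone distance d <= D and every
radius r <= R, a canonical key describing the two radius-r neighborhoods is
hashed into a fixed-dimension count vector (the hashed-kernel trick;
collisions are accepted). On a path graph a radius-r neighborhood is just
the sequence window around the root, canonicalized over reflection, so a
sequence and its reverse encode identically.

Feature selection follows the training recipe: fit a random forest on the
hashed features of a labeled subset and keep the Top-K by impurity
importance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import json
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class GraphParams:
    """Encoder parameters: neighborhood radius R, max root distance D,
    hashed dimension and hash seed."""

    radius: int = 2
    distance: int = 4
    hash_dim: int = 32768
    hash_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.hash_dim < 64:
            raise ValueError("hash_dim must be >= 64")


def _hash_key(key: str, hash_seed: int, hash_dim: int) -> int:
    # crc32 with a seed-mixed initial value: fast, deterministic, seedable.
    init = (hash_seed * 2654435761 + 0x9E3779B9) & 0xFFFFFFFF
    return zlib.crc32(key.encode("ascii"), init) % hash_dim


def _neighborhood(sequence: str, root: int, r: int) -> str:
    """Canonical label of the radius-r neighborhood rooted at ``root``.

    The rooted sub-path has a left arm and a right arm (truncated at the
    sequence ends); reflection is the only non-trivial automorphism, so the
    canonical form orders the two arms lexicographically.
    """
    left = sequence[max(0, root - r):root][::-1]  # read outward from root
    right = sequence[root + 1:root + 1 + r]
    if left <= right:
        return f"{sequence[root]}<{left}|{right}"
    return f"{sequence[root]}<{right}|{left}"


def iter_feature_keys(sequence: str, params: GraphParams):
    """Yield the canonical (radius, distance, pair) string keys of a sequence.

    Root pairs are unordered; d = 0 pairs a root with itself.
    """
    n = len(sequence)
    R, D = params.radius, params.distance
    # neighborhoods[r][i]
    nbh = [[_neighborhood(sequence, i, r) for i in range(n)]
           for r in range(R + 1)]
    for i in range(n):
        for d in range(0, min(D, n - 1 - i) + 1):
            j = i + d
            for r in range(R + 1):
                a, b = nbh[r][i], nbh[r][j]
                if a > b:
                    a, b = b, a
                yield f"{r}|{d}|{a}|{b}"


def encode_graph_features(sequence: str,
                          params: GraphParams = GraphParams()) -> sp.csr_matrix:
    """Encode one sequence as a 1 x hash_dim sparse count vector."""
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    counts: Dict[int, int] = {}
    for key in iter_feature_keys(sequence, params):
        h = _hash_key(key, params.hash_seed, params.hash_dim)
        counts[h] = counts.get(h, 0) + 1
    if counts:
        cols = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        data = np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
    else:
        cols = np.empty(0, dtype=np.int64)
        data = np.empty(0, dtype=np.float64)
    rows = np.zeros_like(cols)
    return sp.csr_matrix((data, (rows, cols)), shape=(1, params.hash_dim))


def encode_graph_matrix(sequences: Sequence[str],
                        params: GraphParams = GraphParams()) -> sp.csr_matrix:
    """Stack per-sequence hashed count vectors into an n x hash_dim matrix."""
    if len(sequences) == 0:
        return sp.csr_matrix((0, params.hash_dim))
    return sp.vstack([encode_graph_features(s, params) for s in sequences],
                     format="csr")


@dataclass
class GraphFeatureIndex:
    """Hashed feature ids retained after importance ranking (Top-K)."""

    selected_ids: List[int]
    importance: List[float]
    params: GraphParams

    def __post_init__(self) -> None:
        if len(self.selected_ids) != len(set(self.selected_ids)):
            raise ValueError("selected ids must be unique")
        if any(i >= self.params.hash_dim or i < 0 for i in self.selected_ids):
            raise ValueError("selected ids must lie in [0, hash_dim)")
        if any(a < b for a, b in zip(self.importance, self.importance[1:])):
            raise ValueError("importance must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.selected_ids)

    def project(self, X: sp.spmatrix) -> np.ndarray:
        """Dense n x K matrix of the selected hashed-feature counts."""
        return np.asarray(X.tocsr()[:, self.selected_ids].todense())

    def to_json(self) -> str:
        return json.dumps({
            "selected_ids": self.selected_ids,
            "importance": self.importance,
            "params": asdict(self.params),
        })

    @classmethod
    def from_json(cls, text: str) -> "GraphFeatureIndex":
        obj = json.loads(text)
        return cls(selected_ids=list(obj["selected_ids"]),
                   importance=list(obj["importance"]),
                   params=GraphParams(**obj["params"]))


class GraphFeatureSelector(BaseEstimator):
    """Rank hashed graph features with a random forest and keep the Top-K.

    Parameters
    ----------
    radius, distance, hash_dim, hash_seed : encoder parameters.
    top_k : int, default 101
        Number of features retained (50 and 200 behave similarly in
        cross-validation and are supported).
    n_estimators : int, default 100
        Trees in the ranking forest.
    random_state : int or None
        Seed for the ranking forest; fixing it makes selection reproducible
        bit-for-bit.
    """

    def __init__(self, radius: int = 2, distance: int = 4,
                 hash_dim: int = 32768, hash_seed: int = 0,
                 top_k: int = 101, n_estimators: int = 100,
                 random_state=None):
        self.radius = radius
        self.distance = distance
        self.hash_dim = hash_dim
        self.hash_seed = hash_seed
        self.top_k = top_k
        self.n_estimators = n_estimators
        self.random_state = random_state

    @property
    def params_(self) -> GraphParams:
        return GraphParams(self.radius, self.distance, self.hash_dim,
                           self.hash_seed)

    def fit(self, sequences: Sequence[str], y):
        """Encode the sequences, fit the ranking forest and select Top-K.

        ``y`` are binary labels. Ties in importance break toward the lower
        hashed id.
        """
        return self.fit_encoded(
            encode_graph_matrix(list(sequences), self.params_), y)

    def fit_encoded(self, X: sp.spmatrix, y):
        """Fit from an already-hashed count matrix (avoids re-encoding)."""
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature ranking requires both classes")
        params = self.params_
        if X.shape[1] != params.hash_dim:
            raise ValueError("hashed matrix width does not match hash_dim")
        nonzero = np.asarray((X != 0).sum(axis=0)).ravel() > 0
        n_nonzero = int(nonzero.sum())
        if self.top_k > n_nonzero:
            raise ValueError(
                f"top_k={self.top_k} exceeds the {n_nonzero} nonzero "
                "hashed features in the ranking set")
        forest = RandomForestClassifier(n_estimators=self.n_estimators,
                                        random_state=self.random_state,
                                        n_jobs=1)
        forest.fit(X, y)
        imp = forest.feature_importances_
        order = np.lexsort((np.arange(len(imp)), -imp))[:self.top_k]
        self.index_ = GraphFeatureIndex(
            selected_ids=[int(i) for i in order],
            importance=[float(imp[i]) for i in order],
            params=params,
        )
        self.importances_ = imp
        return self

    def transform(self, sequences: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "index_")
        X = encode_graph_matrix(list(sequences), self.params_)
        return self.index_.project(X)


def rank_and_select_graph_features(pos: Sequence[str], neg: Sequence[str],
                                   params: GraphParams = GraphParams(),
                                   top_k: int = 101,
                                   seed=None) -> GraphFeatureIndex:
    """Functional wrapper: rank features on pos vs neg sequences, keep Top-K."""
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    selector = GraphFeatureSelector(
        radius=params.radius, distance=params.distance,
        hash_dim=params.hash_dim, hash_seed=params.hash_seed,
        top_k=top_k, random_state=seed)
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    selector.fit(list(pos) + list(neg), y)
    return selector.index_
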