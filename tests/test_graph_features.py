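from itertools import product

import numpy as np
import pytest

from circpot import (
    GraphFeatureIndex,
    GraphParams,
    encode_graph_features,
    encode_graph_matrix,
    rank_and_select_graph_features,
)
from circpot.graph import _hash_key, iter_feature_keys

from conftest import random_sequences
import oracles


def counts_from_keys(keys, params):
    out = {}
    for key in keys:
        h = _hash_key(key, params.hash_seed, params.hash_dim)
        out[h] = out.get(h, 0) + 1
    return out


class TestEncoder:
    def test_deterministic(self):
        params = GraphParams()
        seq = random_sequences(seed=0, n=1, min_len=300, max_len=300)[0]
        a = encode_graph_features(seq, params)
        b = encode_graph_features(seq, params)
        assert (a != b).nnz == 0

    def test_two_node_path_hand_enumeration(self):
        params = GraphParams(radius=0, distance=1, hash_dim=64)
        vec = encode_graph_features("AC", params)
        # exactly the pairs (A,A,d=0), (C,C,d=0), (A,C,d=1)
        expected = {"0|0|A<||A<|", "0|0|C<||C<|", "0|1|A<||C<|"}
        got_keys = set(iter_feature_keys("AC", params))
        assert got_keys == expected
        assert vec.nnz == 3
        assert vec.sum() == 3

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            GraphParams(radius=-1)
        with pytest.raises(ValueError):
            GraphParams(distance=0)
        with pytest.raises(ValueError):
            GraphParams(hash_dim=8)

    @pytest.mark.parametrize("radius,distance", [(0, 1), (1, 2), (2, 3)])
    def test_short_sequences_match_enumeration_oracle(self, radius, distance):
        params = GraphParams(radius=radius, distance=distance, hash_dim=512)
        for n in range(1, 5):
            for tup in product("ACGT", repeat=n):
                seq = "".join(tup)
                vec = encode_graph_features(seq, params)
                want = counts_from_keys(
                    oracles.oracle_graph_keys(seq, radius, distance), params)
                got = {int(i): int(v) for i, v in
                       zip(vec.indices, vec.data)}
                assert got == want

    def test_reverse_sequence_invariance(self):
        params = GraphParams(radius=2, distance=4, hash_dim=2048)
        for seq in random_sequences(seed=2, n=10, min_len=30, max_len=80):
            fwd = encode_graph_features(seq, params)
            rev = encode_graph_features(seq[::-1], params)
            assert (fwd != rev).nnz == 0

    def test_interior_subsequence_keys_are_contained(self):
        # away from the ends, a subsequence's neighborhood-pair keys recur
        # in any supersequence containing it
        params = GraphParams(radius=2, distance=3, hash_dim=4096)
        rng = np.random.default_rng(3)
        sub = "".join(rng.choice(list("ACGT"), size=40))
        super_seq = ("".join(rng.choice(list("ACGT"), size=25)) + sub
                     + "".join(rng.choice(list("ACGT"), size=25)))
        R = params.radius

        from circpot.graph import _neighborhood

        def interior_keys(seq, lo, hi):
            keys = {}
            n = len(seq)
            for i in range(n):
                for d in range(0, min(params.distance, n - 1 - i) + 1):
                    j = i + d
                    if i < lo + R or j >= hi - R:
                        continue
                    for r in range(R + 1):
                        a, b = sorted([_neighborhood(seq, i, r),
                                       _neighborhood(seq, j, r)])
                        key = f"{r}|{d}|{a}|{b}"
                        keys[key] = keys.get(key, 0) + 1
            return keys

        sub_keys = interior_keys(sub, 0, len(sub))
        super_keys = interior_keys(super_seq, 0, len(super_seq))
        for key, count in sub_keys.items():
            assert super_keys.get(key, 0) >= count


class TestSelection:
    def test_default_returns_requested_k(self):
        pos = random_sequences(seed=4, n=40, min_len=80, max_len=150)
        neg = random_sequences(seed=5, n=40, min_len=80, max_len=150)
        params = GraphParams(radius=1, distance=2, hash_dim=512)
        index = rank_and_select_graph_features(pos, neg, params=params,
                                               top_k=101, seed=0)
        assert len(index) == 101
        assert len(set(index.selected_ids)) == 101
        assert all(a >= b for a, b in
                   zip(index.importance, index.importance[1:]))

    def test_planted_motif_feature_ranks_high(self):
        rng = np.random.default_rng(6)
        motif = "GTAGGTAG"
        neg = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(60)]
        pos = []
        for _ in range(60):
            s = list(rng.choice(list("ACGT"), size=60))
            at = int(rng.integers(0, 60 - len(motif)))
            s[at:at + len(motif)] = list(motif)
            pos.append("".join(s))
        params = GraphParams(radius=1, distance=3, hash_dim=2048)
        index = rank_and_select_graph_features(pos, neg, params=params,
                                               top_k=50, seed=0)
        # ids touching the motif's interior neighborhood pairs
        motif_ids = set(counts_from_keys(
            oracles.oracle_graph_keys(motif, 1, 3), params))
        assert motif_ids & set(index.selected_ids[:10])

    def test_reproducible_under_seed(self):
        pos = random_sequences(seed=7, n=25, min_len=50, max_len=90)
        neg = random_sequences(seed=8, n=25, min_len=50, max_len=90)
        params = GraphParams(radius=1, distance=2, hash_dim=512)
        a = rank_and_select_graph_features(pos, neg, params, top_k=30, seed=9)
        b = rank_and_select_graph_features(pos, neg, params, top_k=30, seed=9)
        assert a.selected_ids == b.selected_ids
        assert a.importance == b.importance

    def test_top_k_exceeding_nonzero_errors(self):
        params = GraphParams(radius=0, distance=1, hash_dim=64)
        with pytest.raises(ValueError, match="top_k"):
            rank_and_select_graph_features(["AC"], ["GT"], params,
                                           top_k=64, seed=0)

    def test_null_labels_give_flat_importance(self):
        # identical distributions: selected features should not dominate
        seqs = random_sequences(seed=10, n=80, min_len=60, max_len=100)
        params = GraphParams(radius=1, distance=2, hash_dim=512)
        index = rank_and_select_graph_features(seqs[:40], seqs[40:], params,
                                               top_k=50, seed=1)
        # with no signal, importance is spread thin: top features carry a
        # small share of total importance mass
        assert sum(index.importance) < 0.5

    def test_index_json_roundtrip(self):
        params = GraphParams(radius=1, distance=2, hash_dim=512)
        index = GraphFeatureIndex([5, 3, 9], [0.5, 0.3, 0.1], params)
        back = GraphFeatureIndex.from_json(index.to_json())
        assert back.selected_ids == index.selected_ids
        assert back.params == params
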