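"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible — per-base dictionaries,
exhaustive scans, pairwise counting — and shares no code with the package
beyond the hash function for graph keys (the enumeration being checked is
independent; the hash is shared infrastructure).
"""

from itertools import product

import numpy as np

TRIS = ["".join(p) for p in product("ACGT", repeat=3)]
STOPS = {"TAA", "TAG", "TGA"}


def oracle_gc(seq):
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    return (counts["G"] + counts["C"]) / denom


def oracle_trinucleotide(seq):
    tally = dict.fromkeys(TRIS, 0)
    valid = 0
    for i in range(len(seq) - 2):
        w = seq[i], seq[i + 1], seq[i + 2]
        if "N" in w:
            continue
        valid += 1
        tally["".join(w)] += 1
    if valid == 0:
        return np.zeros(64)
    return np.array([tally[t] / valid for t in TRIS])


def oracle_motifs(seq):
    out = []
    for motif in ("GT", "AG", "GTAG", "AGGT"):
        m = len(motif)
        hits = 0
        for i in range(len(seq)):
            if seq[i:i + m] == motif:
                hits += 1
        out.append(hits / (len(seq) - m + 1))
    return np.array(out)


def oracle_longest_orf(seq):
    """Max over all (ATG position, first in-frame stop) pairs."""
    n = len(seq)
    best = 0
    for i in range(n - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= n:
            if seq[j:j + 3] in STOPS:
                best = max(best, j + 3 - i)
                break
            j += 3
    return best, best / n


def oracle_tandem_fraction(seq, max_period=12, min_copies=2, min_span=6):
    """Exhaustive offset/period enumeration with per-base coverage."""
    n = len(seq)
    covered = set()
    for p in range(1, max_period + 1):
        for i in range(n):
            j = i
            while j + p < n and seq[j + p] == seq[j]:
                j += 1
            span = (j - i) + p if j > i else 0
            if j > i and span >= min_span and span // p >= min_copies:
                covered.update(range(i, j + p))
    return len(covered) / n


def oracle_conservation(scores):
    vals = [s for s in scores if not np.isnan(s)]
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    return mean, var ** 0.5


def oracle_overlap_fraction(start, end, features):
    """Per-base membership against (start, end) feature tuples."""
    hit = 0
    for b in range(start, end):
        if any(fs <= b < fe for fs, fe in features):
            hit += 1
    return hit / (end - start)


def oracle_snp_density(start, end, positions):
    inside = {p for p in positions if start <= p < end}
    return len(inside) / (end - start)


def oracle_fractile(score, val_scores):
    below = sum(1 for v in val_scores if v < score)
    equal = sum(1 for v in val_scores if v == score)
    return (below + 0.5 * equal) / len(val_scores)


def oracle_auc(pos, neg):
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_graph_keys(seq, radius, distance):
    """Independent neighborhood-pair enumeration on the path graph.

    Neighborhoods are found by explicit breadth-first search over the
    adjacency list; canonical keys use the same string format as the
    encoder so hashed ids can be compared.
    """
    n = len(seq)
    adj = {i: [j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)}

    def bfs_arms(root, r):
        # distances by BFS, then split reachable nodes into the two arms
        dist = {root: 0}
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist and dist[u] < r:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        left = [seq[v] for v in sorted((v for v in dist if v < root), reverse=True)]
        right = [seq[v] for v in sorted(v for v in dist if v > root)]
        return "".join(left), "".join(right)

    def canon(root, r):
        left, right = bfs_arms(root, r)
        a, b = sorted([left, right])
        return f"{seq[root]}<{a}|{b}"

    keys = []
    for i in range(n):
        for j in range(i, min(i + distance, n - 1) + 1):
            for r in range(radius + 1):
                a, b = sorted([canon(i, r), canon(j, r)])
                keys.append(f"{r}|{j - i}|{a}|{b}")
    return keys
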