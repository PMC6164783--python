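"""Independent brute-force oracles used by the tests.

These deliberately share no code with the implementation: alignments are
scored by exhaustive enumeration of alignment paths, and linkage heights by
a direct agglomerative loop.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _all_global_alignments(a: str, b: str):
    """Yield alignment op strings over {'M','A','B'} (A: gap in b)."""
    def rec(i, j, ops):
        if i == len(a) and j == len(b):
            yield ops
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, ops + "M")
        if i < len(a):
            yield from rec(i + 1, j, ops + "A")
        if j < len(b):
            yield from rec(i, j + 1, ops + "B")
    yield from rec(0, 0, "")


def _score_ops(a: str, b: str, ops: str, gap_open: int,
               gap_extend: int) -> float:
    """Affine gap cost: a gap of length k costs gap_open + k*gap_extend."""
    score, i, j = 0.0, 0, 0
    prev = None
    for op in ops:
        if op == "M":
            score += _B62[a[i], b[j]]
            i, j = i + 1, j + 1
        else:
            if op != prev:
                score -= gap_open
            score -= gap_extend
            if op == "A":
                i += 1
            else:
                j += 1
        prev = op
    return score


def global_score_bruteforce(a: str, b: str, gap_open: int = 11,
                            gap_extend: int = 1) -> float:
    return max(_score_ops(a, b, ops, gap_open, gap_extend)
               for ops in _all_global_alignments(a, b))


def local_score_bruteforce(a: str, b: str, gap_open: int = 11,
                           gap_extend: int = 1) -> float:
    """Best over all substring pairs, including the empty alignment (0)."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, global_score_bruteforce(
                a[i1:i2], b[j1:j2], gap_open, gap_extend))
    return best


def random_additive_tree(n_taxa: int, rng):
    """Random binary tree -> (ids, distance matrix, set of bipartitions)."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # grow by random leaf attachment; store as children lists
    nodes = {i: None for i in range(n_taxa)}  # leaf ids
    clusters = [[i] for i in range(n_taxa)]
    dist = np.zeros((n_taxa, n_taxa))
    # build distances by joining random pairs with random positive lengths
    active = list(range(n_taxa))
    heights = {}
    joins = []
    while len(active) > 1:
        i = active.pop(int(rng.integers(len(active))))
        j = active.pop(int(rng.integers(len(active))))
        li = float(rng.uniform(0.5, 3.0))
        lj = float(rng.uniform(0.5, 3.0))
        joins.append((i, j, li, lj))
        active.append(len(clusters))
        clusters.append(clusters[i] + clusters[j])
    # path lengths: accumulate depth of each leaf below each internal node
    depth = {i: {i: 0.0} for i in range(n_taxa)}
    splits = set()
    for k, (i, j, li, lj) in enumerate(joins, start=n_taxa):
        d_i = {leaf: d + li for leaf, d in depth[i].items()}
        d_j = {leaf: d + lj for leaf, d in depth[j].items()}
        for a, da in d_i.items():
            for b, db in d_j.items():
                dist[a, b] = dist[b, a] = da + db
        depth[k] = {**d_i, **d_j}
        side = frozenset(ids[x] for x in depth[i])
        if 1 < len(side) < n_taxa - 1:
            anchor = min(ids)
            splits.add(side if anchor not in side
                       else frozenset(ids) - side)
        side = frozenset(ids[x] for x in depth[j])
        if 1 < len(side) < n_taxa - 1:
            anchor = min(ids)
            splits.add(side if anchor not in side
                       else frozenset(ids) - side)
    return ids, dist, splits


def average_linkage_heights(matrix: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering (euclidean rows)."""
    n = matrix.shape[0]
    d = np.sqrt(((matrix[:, None, :] - matrix[None, :, :]) ** 2).sum(-1))
    clusters = {i: [i] for i in range(n)}
    heights = []
    nxt = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = (np.inf, None)
        for x, a in enumerate(keys):
            for b in keys[x + 1:]:
                h = np.mean([d[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if h < best[0] - 1e-12:
                    best = (h, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return heights
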