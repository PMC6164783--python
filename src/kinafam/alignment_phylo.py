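"""Progressive multiple alignment, distances, neighbor joining, bootstrap.

The multiple alignment follows the classic progressive recipe: a UPGMA guide
tree over pairwise global-alignment distances, then profile-profile
Needleman-Wunsch merges with average-of-pairs column scores and affine gaps.
Distances between aligned sequences are p-distances with pairwise deletion;
trees come from Saitou-Nei neighbor joining, and bootstrap supports are
Felsenstein column resampling mapped onto the reference tree's bipartitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .kinase_scan import AA, AA_INDEX, ScanConfig, _aligner, _check_alphabet
from .phylotree import Node

GAP_CODE = 20  # row index for '-' in profile count matrices


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: dict[str, str]

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def __post_init__(self):
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in width")

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def to_matrix(self) -> np.ndarray:
        """ids x width integer matrix; gaps coded as GAP_CODE."""
        code = {a: i for i, a in enumerate(AA)}
        code["-"] = GAP_CODE
        code["X"] = GAP_CODE  # treated as missing
        return np.array([[code[c] for c in self.rows[i]] for i in self.ids])


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("not a valid distance matrix")


# ------------------------------------------------------- pairwise global

def needleman_wunsch(a: str, b: str, config: ScanConfig | None = None):
    """Optimal global alignment (score, gapped_a, gapped_b), affine gaps."""
    config = config or ScanConfig()
    if not a or not b:
        raise ValueError("empty sequence")
    _check_alphabet(a, config)
    _check_alphabet(b, config)
    aligner = _aligner(config, "global")
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return int(aln.score), ga, gb


# ---------------------------------------------------------- progressive

def _profile(rows: list[str]) -> np.ndarray:
    """width x 21 residue-count profile (last row counts gaps)."""
    width = len(rows[0])
    prof = np.zeros((width, 21))
    for r in rows:
        for j, c in enumerate(r):
            prof[j, AA_INDEX.get(c, GAP_CODE) if c != "-" else GAP_CODE] += 1
    return prof


def _profile_align(rows_a: list[str], rows_b: list[str],
                   config: ScanConfig) -> tuple[list[str], list[str]]:
    """Profile-profile NW with average column scores and affine gaps."""
    sub = substitution_matrices.load(config.substitution_matrix)
    S20 = np.array([[sub[x, y] for y in AA] for x in AA])
    pa, pb = _profile(rows_a), _profile(rows_b)
    fa = pa[:, :20] / np.maximum(pa[:, :20].sum(1, keepdims=True), 1)
    fb = pb[:, :20] / np.maximum(pb[:, :20].sum(1, keepdims=True), 1)
    score = fa @ S20 @ fb.T  # column-pair average substitution score
    la, lb = score.shape
    go, ge = -(config.gap_open + config.gap_extend), -config.gap_extend
    NEG = -1e12
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (consume a)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for j in range(1, lb + 1):
        Y[0, j] = go + (j - 1) * ge
    js = np.arange(lb + 1)
    for i in range(1, la + 1):
        si = score[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        best_prev = np.maximum(np.maximum(Mi1, Xi1), Yi1)
        Mi[1:] = best_prev[:-1] + si
        # vertical gap (consume a): depends on the previous row only
        np.maximum(np.maximum(Mi1 + go, Xi1 + ge), Yi1 + go, out=Xi)
        # horizontal gap (consume b): Yi[j] = max(Mi[j-1]+go, Xi[j-1]+go,
        # Yi[j-1]+ge); the Y->Y chain collapses to a prefix max
        base = np.maximum(Mi, Xi) - ge * js
        prefix = np.maximum.accumulate(base)
        Yi[1:] = go + ge * (js[1:] - 1) + prefix[:-1]
    # traceback
    i, j = la, lb
    ops = []
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            ops.append("M")
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            cand = [M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go]
            ops.append("X")
            i -= 1
            state = int(np.argmax(cand))
        elif state == 2 and j > 0:
            cand = [M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go]
            ops.append("Y")
            j -= 1
            state = int(np.argmax(cand))
        else:  # boundary
            if i > 0:
                ops.append("X"); i -= 1; state = 1
            else:
                ops.append("Y"); j -= 1; state = 2
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "Y"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def _upgma_order(ids: list[str], dist: np.ndarray):
    """UPGMA join order: list of (cluster_a, cluster_b) member-index lists."""
    clusters = [[i] for i in range(len(ids))]
    d = dist.astype(float).copy()
    active = list(range(len(ids)))
    joins = []
    while len(active) > 1:
        best = (np.inf, None)
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                if d[a, b] < best[0]:
                    best = (d[a, b], (a, b))
        a, b = best[1]
        joins.append((clusters[a], clusters[b]))
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        newrow = (na * d[a, :] + nb * d[b, :]) / (na + nb)
        d = np.vstack([d, newrow])
        d = np.hstack([d, np.append(newrow, 0.0)[:, None]])
        clusters.append(merged)
        active.remove(a)
        active.remove(b)
        active.append(len(clusters) - 1)
    return joins


def progressive_msa(seqs: dict[str, str],
                    config: ScanConfig | None = None) -> MultipleAlignment:
    """Progressive alignment: UPGMA guide tree + profile-profile merges."""
    config = config or ScanConfig()
    ids = list(seqs)
    if len(ids) == 1:
        return MultipleAlignment(ids=ids, rows=dict(seqs))
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ga, gb = needleman_wunsch(seqs[ids[i]], seqs[ids[j]], config)
            comp = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
            mism = sum(1 for x, y in comp if x != y)
            dist[i, j] = dist[j, i] = mism / len(comp) if comp else 1.0
    aligned: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[ids[i]]]) for i in range(n)}
    cluster_of = {i: i for i in range(n)}
    next_key = n
    for members_a, members_b in _upgma_order(ids, dist):
        ka, kb = cluster_of[members_a[0]], cluster_of[members_b[0]]
        idx_a, rows_a = aligned.pop(ka)
        idx_b, rows_b = aligned.pop(kb)
        out_a, out_b = _profile_align(rows_a, rows_b, config)
        merged = (idx_a + idx_b, out_a + out_b)
        aligned[next_key] = merged
        for m in merged[0]:
            cluster_of[m] = next_key
        next_key += 1
    idx, rows = next(iter(aligned.values()))
    row_map = dict(zip(idx, rows))
    out_rows = {ids[i]: row_map[i] for i in range(n)}
    return MultipleAlignment(ids=ids, rows=out_rows)


# ------------------------------------------------------------ distances

def p_distance(msa: MultipleAlignment,
               mat: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise-deletion p-distance over alignment columns."""
    m = msa.to_matrix() if mat is None else mat
    n = len(msa.ids)
    valid = m != GAP_CODE
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        comp = both.sum(axis=1)
        mism = ((m[i] != m) & both).sum(axis=1)
        if np.any(comp[np.arange(n) != i] == 0):
            bad = [msa.ids[j] for j in range(n)
                   if j != i and comp[j] == 0]
            raise ValueError(
                f"no comparable columns between {msa.ids[i]} and {bad}")
        with np.errstate(invalid="ignore"):
            d[i] = np.where(comp > 0, mism / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # symmetric by construction; guard rounding
    return DistanceMatrix(ids=list(msa.ids), matrix=d)


# --------------------------------------------------------------- NJ tree

def neighbor_joining(D: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining; unrooted tree (trifurcating root).

    Ties in the Q criterion break toward the lexicographically smallest id
    pair; negative branch lengths are clamped to zero.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [Node(name=i) for i in D.ids]
    d = D.matrix.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        Q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = [(min(nodes[active[i]].name or "", nodes[active[j]].name or ""),
                 max(nodes[active[i]].name or "", nodes[active[j]].name or ""),
                 i, j)
                for i in range(r) for j in range(i + 1, r)
                if Q[i, j] <= qmin + 1e-12]
        _, _, i, j = min(cand)
        a, b = active[i], active[j]
        da = 0.5 * sub[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        db = sub[i, j] - da
        u = Node(name=None, children=[nodes[a], nodes[b]])
        nodes[a].length = max(0.0, da)
        nodes[b].length = max(0.0, db)
        # distances from the new node
        new_d = 0.5 * (d[a, :] + d[b, :] - d[a, b])
        d = np.vstack([d, new_d])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(u)
        u.name = min(x for x in (nodes[a].name, nodes[b].name) if x) \
            if (nodes[a].name or nodes[b].name) else None
        active.remove(a)
        active.remove(b)
        active.append(len(nodes) - 1)
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    nodes[i].length = max(0.0, (dij + dik - djk) / 2)
    nodes[j].length = max(0.0, (dij + djk - dik) / 2)
    nodes[k].length = max(0.0, (dik + djk - dij) / 2)
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    _clear_internal_names(root)
    return root


def _clear_internal_names(node: Node) -> None:
    if not node.is_leaf:
        node.name = None
        for c in node.children:
            _clear_internal_names(c)


def tree_path_lengths(tree: Node) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additive metric)."""
    leaves = tree.leaves()
    ids = [l.name for l in leaves]
    parents = {id(tree): None}
    for node in tree.iter_nodes():
        for c in node.children:
            parents[id(c)] = node

    def path(n):
        out = []
        while n is not None:
            out.append(n)
            n = parents[id(n)]
        return out

    n = len(leaves)
    mat = np.zeros((n, n))
    paths = [path(l) for l in leaves]
    for i in range(n):
        anc_i = {id(x): k for k, x in enumerate(paths[i])}
        for j in range(i + 1, n):
            dist = 0.0
            for x in paths[j]:
                if id(x) in anc_i:
                    lca = x
                    break
                dist += x.length or 0.0
            for x in paths[i][:anc_i[id(lca)]]:
                dist += x.length or 0.0
            mat[i, j] = mat[j, i] = dist
    return DistanceMatrix(ids=ids, matrix=mat)


# -------------------------------------------------------------- bootstrap

def bootstrap_support(msa: MultipleAlignment, n_reps: int = 1000,
                      seed: int = 0) -> Node:
    """NJ tree with Felsenstein bootstrap supports on internal edges."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mat = msa.to_matrix()
    ref = neighbor_joining(p_distance(msa, mat=mat))
    ref_splits = ref.bipartitions()
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    width = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep_mat = mat[:, cols]
        try:
            rep_tree = neighbor_joining(p_distance(msa, mat=rep_mat))
        except ValueError:
            continue  # a pair lost all comparable columns in this resample
        for s in rep_tree.bipartitions():
            if s in counts:
                counts[s] += 1
    for node in ref.iter_nodes():
        if node is ref or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        all_leaves = frozenset(ref.leaf_names())
        anchor = min(all_leaves)
        key = side if anchor not in side else all_leaves - side
        if key in counts:
            node.support = 100.0 * counts[key] / n_reps
    return ref
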