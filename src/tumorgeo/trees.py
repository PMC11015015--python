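"""Sector phylogenies and tree-derived spatial blocks.

Trees over tumor sectors are built two ways: maximum parsimony on the
binary mutation matrix (Fitch small-parsimony scoring, exhaustive search
for small trees, neighbor-joining start + nearest-neighbor-interchange
hill climbing otherwise) and neighbor joining on any distance matrix.

Spatial blocks are found by cutting the tree into k connected pieces (all
ways of removing k-1 edges), scoring every induced leaf partition with a
distance-based Calinski-Harabasz (CH) index in which dispersion is the
mean sum of pairwise distances,

    SS_within  = sum_k sum_{i<j in k} d(i,j) / n_k
    SS_between = sum_{i<j} d(i,j) / N - SS_within
    CH         = SS_between * (N - K) / (SS_within * (K - 1)),

and picking the cluster count k (default 2-5) that maximizes the best CH.
Note this is deliberately not the classical variance-based CH index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .model import MutationMatrix, SectorMap

__all__ = [
    "ParsimonyResult",
    "SpatialBlockPartition",
    "build_parsimony_tree",
    "build_nj_tree",
    "tree_distance",
    "cut_tree_partitions",
    "ch_index",
    "find_spatial_blocks",
    "block_contiguity",
]


# ---------------------------------------------------------------------------
# Fitch parsimony on an adjacency representation of an unrooted binary tree.
# Leaves are 0..n-1; character states are encoded as bitmasks per site
# (1 = absent, 2 = present, 3 = ambiguous/either).


def _leaf_masks(m: MutationMatrix) -> np.ndarray:
    return (m.presence.astype(np.uint8) + 1)


def _postorder(adj: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs, children before parents, starting below root."""
    out, stack = [], [(root, -1)]
    while stack:
        node, parent = stack.pop()
        out.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    out.reverse()
    return out


def _fitch_masks(adj, leaf_masks, order):
    """Down-pass state masks for every node; root is order[-1][0]."""
    n_chars = leaf_masks.shape[1]
    masks: dict[int, np.ndarray] = {}
    changes = np.zeros(n_chars, dtype=np.int64)
    n_leaves = leaf_masks.shape[0]
    for node, parent in order:
        if node < n_leaves:
            masks[node] = leaf_masks[node]
            continue
        children = [nb for nb in adj[node] if nb != parent]
        acc = masks[children[0]]
        for ch in children[1:]:
            inter = acc & masks[ch]
            empty = inter == 0
            acc = np.where(empty, acc | masks[ch], inter)
            changes += empty
        masks[node] = acc
    return masks, changes


def _fitch_score(adj, leaf_masks) -> int:
    """Parsimony length of the tree (rooted anywhere; here at leaf 0)."""
    order = _postorder(adj, 0)
    masks, changes = _fitch_masks(adj, leaf_masks, order)
    # the root leaf itself still has to be reconciled with its subtree
    child = adj[0][0]
    changes = changes + ((masks[0] & masks[child]) == 0)
    return int(changes.sum())


def _fitch_edge_lengths(adj, leaf_masks) -> dict[frozenset[int], int]:
    """Per-edge change counts of one most-parsimonious reconstruction.

    The traceback assigns each node a single state top-down (keep the
    parent's state when compatible with the node's down-pass set, else the
    lexicographically smallest member); the per-edge change indicators sum
    to the Fitch score.
    """
    order = _postorder(adj, 0)
    masks, _ = _fitch_masks(adj, leaf_masks, order)
    lengths: dict[frozenset[int], int] = {}
    state = {0: masks[0]}
    for node, parent in reversed(order):  # preorder
        if parent == -1:
            continue
        ps = state[parent]
        down = masks[node]
        keep = (ps & down) != 0
        low = down & (-down).astype(down.dtype)  # lowest set bit
        state[node] = np.where(keep, ps, low)
        lengths[frozenset((node, parent))] = int((~keep).sum())
    return lengths


def _nni_neighbors(adj):
    """Yield (u, v, x, y): swap subtree x (neighbor of u) with y (of v)."""
    for u in sorted(adj):
        for v in sorted(adj[u]):
            if u >= v or len(adj[u]) < 3 or len(adj[v]) < 3:
                continue  # internal edges only, each once
            a, b = [nb for nb in adj[u] if nb != v]
            c, d = [nb for nb in adj[v] if nb != u]
            yield u, v, a, c
            yield u, v, a, d


def _apply_nni(adj, u, v, x, y):
    adj[u][adj[u].index(x)] = y
    adj[v][adj[v].index(y)] = x
    adj[x][adj[x].index(u)] = v
    adj[y][adj[y].index(v)] = u


def _treenode_to_adj(tree: TreeNode, names) -> dict[int, list[int]]:
    """skbio tree -> adjacency with leaves 0..n-1; multifurcations resolved
    arbitrarily (depth-first) except a basal trifurcation, which is the
    standard unrooted representation."""
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    adj: dict[int, list[int]] = {}
    counter = itertools.count(n)

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def visit(tn) -> int:
        if tn.is_tip():
            return index[tn.name]
        kids = [visit(ch) for ch in tn.children]
        me = next(counter)
        adj.setdefault(me, [])
        while len(kids) > (3 if tn.is_root() and tn.parent is None else 2):
            extra = next(counter)
            a, b = kids.pop(), kids.pop()
            add_edge(extra, a)
            add_edge(extra, b)
            kids.append(extra)
        for k in kids:
            add_edge(me, k)
        return me

    root_id = visit(tree)
    # a rooted binary top (degree 2) is suppressed into the unrooted edge
    if len(adj[root_id]) == 2:
        a, b = adj.pop(root_id)
        adj[a][adj[a].index(root_id)] = b
        adj[b][adj[b].index(root_id)] = a
    return adj


def _enumerate_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1 by stepwise addition."""
    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}

    def edges_of(adj):
        return [(a, b) for a in adj for b in adj[a] if a < b]

    def recurse(adj, next_leaf, next_internal):
        if next_leaf == n:
            yield adj
            return
        for a, b in edges_of(adj):
            new = {k: list(v) for k, v in adj.items()}
            mid = next_internal
            new[a][new[a].index(b)] = mid
            new[b][new[b].index(a)] = mid
            new[mid] = [a, b, next_leaf]
            new[next_leaf] = [mid]
            yield from recurse(new, next_leaf + 1, next_internal + 1)

    if n == 3:
        yield {k: list(v) for k, v in base.items()}
        return
    yield from recurse(base, 3, n + 1)


@dataclass(frozen=True)
class ParsimonyResult:
    """Maximum-parsimony tree with Fitch change counts as branch lengths."""

    tree: TreeNode = field(repr=False)
    score: int
    method: str
    star: bool = False  # all sectors identical: topology is arbitrary


def _nni_hill_climb(adj, leaf_masks):
    """Steepest-descent NNI until no interchange improves the score."""
    score = _fitch_score(adj, leaf_masks)
    improved = True
    while improved:
        improved = False
        best_move, best_score = None, score
        for u, v, x, y in _nni_neighbors(adj):
            _apply_nni(adj, u, v, x, y)
            s = _fitch_score(adj, leaf_masks)
            _apply_nni(adj, u, v, y, x)
            if s < best_score:
                best_move, best_score = (u, v, x, y), s
        if best_move is not None:
            _apply_nni(adj, *best_move)
            score = best_score
            improved = True
    return adj, score


def _random_topology(n: int, rng: np.random.Generator) -> dict[int, list[int]]:
    """Random unrooted binary topology by stepwise addition."""
    adj = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    next_internal = n + 1
    for leaf in range(3, n):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        mid = next_internal
        next_internal += 1
        adj[a][adj[a].index(b)] = mid
        adj[b][adj[b].index(a)] = mid
        adj[mid] = [a, b, leaf]
        adj[leaf] = [mid]
    return adj


def build_parsimony_tree(
    m: MutationMatrix,
    outgroup: str | None = None,
    method: str = "auto",
    n_restarts: int = 16,
    rng_seed: int = 0,
) -> ParsimonyResult:
    """Maximum-parsimony sector tree from binary mutation presence.

    ``method``: ``exhaustive`` enumerates every unrooted binary topology
    (feasible up to ~9 leaves); ``nni`` hill-climbs with steepest-descent
    nearest-neighbor interchanges from the neighbor-joining tree on
    Hamming distances plus ``n_restarts`` seeded random starting
    topologies (restarts escape the local optima single-start NNI is
    prone to); ``auto`` picks exhaustive for <= 8 leaves.  Deterministic
    given the input order and ``rng_seed``.  Branch lengths are per-edge
    change counts from one most-parsimonious reconstruction.  ``outgroup``
    (typically the normal, mutation-free sample, included as a row) roots
    the returned tree.
    """
    names = list(m.sectors)
    n = len(names)
    if n < 3:
        raise ValueError("parsimony tree needs at least 3 sectors")
    leaf_masks = _leaf_masks(m)

    if all((m.presence[0] == m.presence[i]).all() for i in range(n)):
        root = TreeNode()
        for name in names:
            tip = TreeNode(name=name)
            tip.length = 0.0
            root.append(tip)
        return ParsimonyResult(tree=root, score=0, method="star", star=True)

    if method == "auto":
        method = "exhaustive" if n <= 8 else "nni"
    if method == "exhaustive":
        best_adj, best_score = None, None
        for adj in _enumerate_topologies(n):
            score = _fitch_score(adj, leaf_masks)
            if best_score is None or score < best_score:
                best_adj, best_score = adj, score
        adj, score = best_adj, best_score
    elif method == "nni":
        from .distances import genetic_distance

        rng = np.random.default_rng(rng_seed)
        starts = [_treenode_to_adj(nj(genetic_distance(m, "hamming")), names)]
        starts += [_random_topology(n, rng) for _ in range(n_restarts)]
        adj, score = None, None
        for start in starts:
            cand, cand_score = _nni_hill_climb(start, leaf_masks)
            if score is None or cand_score < score:
                adj, score = cand, cand_score
    else:
        raise ValueError(f"unknown parsimony search method {method!r}")

    edge_lengths = _fitch_edge_lengths(adj, leaf_masks)
    tree = _build_tree_with_lengths(adj, names, edge_lengths)
    if outgroup is not None:
        if outgroup not in names:
            raise ValueError(f"outgroup {outgroup!r} is not a sector")
        tree = tree.root_by_outgroup([outgroup])
    return ParsimonyResult(tree=tree, score=int(score), method=method)


def _build_tree_with_lengths(adj, names, edge_lengths) -> TreeNode:
    root = adj[0][0]  # internal node next to leaf 0 -> basal trifurcation

    def build(node, parent):
        tn = TreeNode(name=names[node]) if node < len(names) else TreeNode()
        if parent >= 0:
            tn.length = float(edge_lengths[frozenset((node, parent))])
        for nb in adj[node]:
            if nb != parent:
                tn.append(build(nb, node))
        return tn

    return build(root, -1)


def build_nj_tree(d: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; negative branch lengths are set to zero."""
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    return nj(d, neg_as_zero=True)


def tree_distance(t: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix."""
    t = t.copy()
    for node in t.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return t.tip_tip_distances()


# ---------------------------------------------------------------------------
# Tree cutting and CH scoring


def _edge_leaf_sets(t: TreeNode, names):
    """Per-edge (non-root node) descendant-leaf bitmasks, plus full mask."""
    index = {name: i for i, name in enumerate(names)}
    masks = []
    node_mask = {}
    for node in t.postorder(include_self=True):
        if node.is_tip():
            node_mask[id(node)] = 1 << index[node.name]
        else:
            node_mask[id(node)] = 0
            for ch in node.children:
                node_mask[id(node)] |= node_mask[id(ch)]
        if not node.is_root():
            masks.append(node_mask[id(node)])
    full = (1 << len(names)) - 1
    return masks, full


def _cut_partitions_bitmask(t: TreeNode, k: int, names):
    """All leaf partitions induced by removing k-1 edges; deduplicated.

    Components containing no leaf are skipped.  Partitions are returned as
    frozensets of leaf bitmasks.
    """
    masks, full = _edge_leaf_sets(t, names)
    n_edges = len(masks)
    seen = set()
    out = []
    if k == 1:
        return [frozenset((full,))]
    for combo in itertools.combinations(range(n_edges), k - 1):
        comps = []
        ok = True
        sets = [masks[i] for i in combo]
        for i, mi in enumerate(sets):
            comp = mi
            for j, mj in enumerate(sets):
                if i != j and (mj & mi) == mj and mj != mi:
                    comp &= ~mj
            if comp == 0:
                ok = False
                break
            comps.append(comp)
        if not ok:
            continue
        rest = full
        for mi in sets:
            rest &= ~mi
        if rest == 0:
            continue
        comps.append(rest)
        key = frozenset(comps)
        if len(key) == len(comps) and key not in seen:
            seen.add(key)
            out.append(key)
    return out


def cut_tree_partitions(t: TreeNode, k: int) -> list[list[frozenset[str]]]:
    """Every partition of the leaves into k clusters obtainable by removing
    k-1 tree edges (components with no leaf are not allowed)."""
    names = sorted(tip.name for tip in t.tips())
    if not (2 <= k <= len(names)):
        raise ValueError(f"k={k} outside 2..{len(names)}")
    result = []
    for part in _cut_partitions_bitmask(t, k, names):
        clusters = [
            frozenset(names[i] for i in range(len(names)) if mask >> i & 1)
            for mask in part
        ]
        clusters.sort(key=lambda c: sorted(c))
        result.append(clusters)
    result.sort(key=lambda clusters: [sorted(c) for c in clusters])
    return result


def ch_index(d: DistanceMatrix, clusters) -> float:
    """Distance-based CH score of a partition (see module docstring).

    ``clusters`` is an iterable of sector-label collections covering all of
    ``d``'s ids.  Returns ``inf`` when the within-cluster dispersion is 0
    (identical points within every cluster).
    """
    clusters = [list(c) for c in clusters]
    K = len(clusters)
    if K < 2:
        raise ValueError("CH index needs at least 2 clusters")
    labels = [s for c in clusters for s in c]
    if sorted(labels) != sorted(d.ids):
        raise ValueError("clusters must partition the distance matrix ids")
    data = d.data
    pos = {s: i for i, s in enumerate(d.ids)}
    N = len(d.ids)
    ss_total = data[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for c in clusters:
        idx = [pos[s] for s in c]
        sub = data[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return float("inf")
    return float(ss_between * (N - K) / (ss_within * (K - 1)))


def _batch_ch(data: np.ndarray, partitions, n: int) -> np.ndarray:
    """CH scores for many bitmask partitions over the same distance matrix."""
    N = n
    ss_total = data[np.triu_indices(N, k=1)].sum() / N
    bit = (1 << np.arange(N, dtype=np.int64))
    scores = np.empty(len(partitions))
    row_sums_cache: dict[int, float] = {}

    def within(mask: int) -> float:
        val = row_sums_cache.get(mask)
        if val is None:
            idx = np.flatnonzero(mask & bit)
            sub = data[np.ix_(idx, idx)]
            val = sub.sum() / 2.0, len(idx)
            row_sums_cache[mask] = val
        return val

    for p, part in enumerate(partitions):
        K = len(part)
        ss_w = 0.0
        for mask in part:
            s, nk = within(mask)
            ss_w += s / nk
        ss_b = ss_total - ss_w
        scores[p] = np.inf if ss_w == 0 else ss_b * (N - K) / (ss_w * (K - 1))
    return scores


@dataclass(frozen=True)
class SpatialBlockPartition:
    """Best tree-cut partition per cluster count and the chosen k.

    ``labels`` maps each sector to a block id (1-based, ordered by each
    block's alphabetically first sector); ``ch_by_k`` holds the best CH
    score for every candidate k; ``chosen_k`` maximizes it (ties to the
    smaller k).
    """

    labels: dict[str, int]
    k: int
    ch_by_k: dict[int, float]
    chosen_k: int
    source: str = "dna"
    partitions_by_k: dict[int, tuple[frozenset[str], ...]] = field(
        default_factory=dict, repr=False
    )

    def block_sets(self) -> list[frozenset[str]]:
        out: dict[int, set[str]] = {}
        for s, b in self.labels.items():
            out.setdefault(b, set()).add(s)
        return [frozenset(out[b]) for b in sorted(out)]


def find_spatial_blocks(
    t: TreeNode,
    k_range=range(2, 6),
    d: DistanceMatrix | None = None,
    source: str = "dna",
) -> SpatialBlockPartition:
    """Cut the sector tree into blocks, choosing k by the CH index.

    For each k in ``k_range`` every edge-removal partition is scored with
    the distance-based CH index on ``d`` (default: the tree's own patristic
    distances) and the best kept; the reported partition is the one whose k
    maximizes CH.  Ties break to smaller k, then to the lexicographically
    smallest partition, so results do not depend on input order.
    """
    if d is None:
        d = tree_distance(t)
    names = sorted(tip.name for tip in t.tips())
    if sorted(d.ids) != names:
        raise ValueError("distance matrix ids do not match the tree's leaves")
    d = d.filter(names)
    data = d.data
    n = len(names)
    ch_by_k: dict[int, float] = {}
    best_part: dict[int, frozenset[int]] = {}
    for k in k_range:
        if not (2 <= k <= n):
            continue
        partitions = _cut_partitions_bitmask(t, k, names)
        parts_sorted = sorted(
            (tuple(sorted(p)) for p in partitions)
        )  # lexicographic determinism
        scores = _batch_ch(data, parts_sorted, n)
        best = int(np.argmax(scores))  # first (lexicographically smallest) max
        ch_by_k[k] = float(scores[best])
        best_part[k] = parts_sorted[best]
    if not ch_by_k:
        raise ValueError("k_range contains no feasible cluster count")
    chosen_k = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
    chosen = best_part[chosen_k]
    clusters = [
        sorted(names[i] for i in range(n) if mask >> i & 1) for mask in chosen
    ]
    clusters.sort(key=lambda c: c[0])
    labels = {s: b + 1 for b, c in enumerate(clusters) for s in c}
    partitions_by_k = {
        k: tuple(
            frozenset(names[i] for i in range(n) if mask >> i & 1)
            for mask in part
        )
        for k, part in best_part.items()
    }
    return SpatialBlockPartition(
        labels=labels,
        k=chosen_k,
        ch_by_k=ch_by_k,
        chosen_k=chosen_k,
        source=source,
        partitions_by_k=partitions_by_k,
    )


def block_contiguity(p: SpatialBlockPartition, sm: SectorMap) -> float:
    """Fraction of sectors whose nearest spatial neighbor shares their block."""
    missing = [s for s in sm.sectors if s not in p.labels]
    if missing:
        raise ValueError(f"sectors without block labels: {missing[:5]}")
    xy = sm.coords
    n = len(sm.sectors)
    if n < 2:
        raise ValueError("contiguity needs at least 2 sectors")
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = d2.argmin(axis=1)
    same = [
        p.labels[sm.sectors[i]] == p.labels[sm.sectors[j]]
        for i, j in enumerate(nearest)
    ]
    return float(np.mean(same))
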