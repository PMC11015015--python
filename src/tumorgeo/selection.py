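"""Neutrality and progression statistics.

Under neutral growth (every lineage equally fit) a tumor's sector tree
should look like a draw from the Yule process — repeated equal-rate
splitting of lineages.  Selection makes some lineages over-represented
and the tree imbalanced.  Imbalance is measured by the Sackin index
S = sum over leaves of the leaf's depth (number of edges to the root);
the test compares the observed S against Monte-Carlo samples of S for
Yule trees with the same leaf count, one-sided toward imbalance.

Also here: the exact binomial test of clonal asymmetry (are derived
blocks larger than ancestral ones?) and the genome instability index
(fraction of the genome with |log2(CN/2)| > 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import TreeNode

from .model import CNProfile

__all__ = [
    "SackinResult",
    "AsymmetrySummary",
    "sackin_index",
    "yule_tree",
    "yule_sackin_null",
    "sackin_yule_test",
    "clonal_asymmetry",
    "gii",
]


def yule_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Draw one rooted binary tree topology from the Yule process.

    Starting from a two-leaf root, a uniformly chosen leaf is repeatedly
    split until ``n_leaves`` leaves exist; leaves are named t1..tn.
    """
    if n_leaves < 2:
        raise ValueError("Yule trees need at least 2 leaves")
    root = TreeNode()
    leaves = []
    for i in (0, 1):
        tip = TreeNode(name=f"t{i + 1}", length=1.0)
        root.append(tip)
        leaves.append(tip)
    for k in range(2, n_leaves):
        pick = leaves[rng.integers(len(leaves))]
        left = TreeNode(name=pick.name, length=1.0)
        right = TreeNode(name=f"t{k + 1}", length=1.0)
        pick.name = None
        pick.append(left)
        pick.append(right)
        leaves[leaves.index(pick)] = left
        leaves.append(right)
    return root


def sackin_index(t: TreeNode, exclude: str | None = None) -> int:
    """Sum of leaf depths (in edges) of a rooted tree.

    ``exclude`` drops one leaf (typically the normal/outgroup sample)
    before counting; multifurcations are allowed.
    """
    t = _drop_leaf(t, exclude) if exclude is not None else t
    return int(sum(_leaf_depths(t)))


def _leaf_depths(t: TreeNode) -> list[int]:
    depths = []
    stack = [(t, 0)]
    while stack:
        node, depth = stack.pop()
        if node.is_tip():
            depths.append(depth)
        for ch in node.children:
            stack.append((ch, depth + 1))
    return depths


def _drop_leaf(t: TreeNode, name: str) -> TreeNode:
    names = [tip.name for tip in t.tips()]
    if name not in names:
        raise ValueError(f"leaf {name!r} not in tree")
    keep = [n for n in names if n != name]
    return t.shear(keep)


def yule_sackin_null(
    n_leaves: int, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo samples of the Sackin index under the Yule process.

    A Yule tree on n leaves is grown by repeatedly splitting a uniformly
    chosen leaf.  Only leaf depths matter for S, so the simulation tracks
    the depth multiset: splitting a leaf of depth d replaces it by two
    leaves of depth d+1 (S increases by d + 2).  Vectorized across the
    ``n_sim`` replicates.
    """
    if n_leaves < 2:
        raise ValueError("Yule trees need at least 2 leaves")
    depths = np.zeros((n_sim, n_leaves), dtype=np.int64)
    rows = np.arange(n_sim)
    # start from the first split: two leaves at depth 1
    depths[:, :2] = 1
    for k in range(2, n_leaves):
        pick = rng.integers(0, k, size=n_sim)
        d = depths[rows, pick]
        depths[rows, pick] = d + 1
        depths[rows, k] = d + 1
    return depths.sum(axis=1)


@dataclass(frozen=True)
class SackinResult:
    """Observed Sackin index and its one-sided Yule-null p-value."""

    s: int
    n_leaves: int
    null_samples: int
    p_value: float
    rng_seed: int
    resolved_multifurcations: bool = False


def sackin_yule_test(
    t: TreeNode,
    n_sim: int = 9999,
    rng_seed: int = 0,
    exclude: str | None = None,
) -> SackinResult:
    """Test tree imbalance against the equal-fitness (Yule) null.

    ``p = (1 + #{S_null >= S_obs}) / (n_sim + 1)``, one-sided toward
    imbalance: small p means the tree is more imbalanced than equal-rate
    branching explains.  The Yule null conditions only on the leaf count.
    Multifurcations are resolved uniformly at random (seeded) before
    computing S, and the result is flagged.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    t = _drop_leaf(t, exclude) if exclude is not None else t
    n = t.count(tips=True)
    if n < 3:
        raise ValueError("Sackin test needs at least 3 leaves")
    rng = np.random.default_rng(rng_seed)
    t, resolved = _resolve_multifurcations(t, rng)
    s_obs = sackin_index(t)
    null = yule_sackin_null(n, n_sim, rng)
    p = (1.0 + np.count_nonzero(null >= s_obs)) / (n_sim + 1.0)
    return SackinResult(
        s=s_obs, n_leaves=n, null_samples=n_sim, p_value=float(p),
        rng_seed=rng_seed, resolved_multifurcations=resolved,
    )


def _resolve_multifurcations(t: TreeNode, rng: np.random.Generator):
    t = t.copy()
    resolved = False
    for node in list(t.traverse(include_self=True)):
        while len(node.children) > 2:
            resolved = True
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            merged = TreeNode(length=0.0)
            node.remove(a)
            node.remove(b)
            merged.append(a)
            merged.append(b)
            node.append(merged)
    return t, resolved


@dataclass(frozen=True)
class AsymmetrySummary:
    """Sector counts of ancestral vs derived groups with a binomial test.

    Under neutral growth a late-arising (derived) clone should be the
    minor one; a derived fraction far above 0.5 is clonal asymmetry.
    ``p_value`` is the exact two-sided binomial test against 0.5.
    """

    n_ancestral: int
    n_derived: int
    derived_fraction: float
    p_value: float


def clonal_asymmetry(
    block_labels: dict[str, int],
    group_of_block: dict[int, str],
) -> AsymmetrySummary:
    """Summarize the sector split between ancestral and derived blocks.

    ``group_of_block`` maps every block id to ``"ancestral"`` or
    ``"derived"``; both groups must be present.
    """
    counts = {"ancestral": 0, "derived": 0}
    for sector, block in block_labels.items():
        group = group_of_block.get(block)
        if group not in counts:
            raise ValueError(
                f"block {block} of sector {sector!r} has no valid group"
            )
        counts[group] += 1
    n_anc, n_der = counts["ancestral"], counts["derived"]
    if n_anc == 0 or n_der == 0:
        raise ValueError("both ancestral and derived groups must be non-empty")
    total = n_anc + n_der
    p = stats.binomtest(n_der, total, 0.5, alternative="two-sided").pvalue
    return AsymmetrySummary(
        n_ancestral=n_anc,
        n_derived=n_der,
        derived_fraction=n_der / total,
        p_value=float(p),
    )


def gii(cn: CNProfile, threshold: float = 0.2) -> float:
    """Genome instability index: fraction of the genome with
    |log2(CN/2)| > ``threshold``.  CN = 0 counts as aberrant (the log
    ratio diverges); bases not covered by any segment count as normal.
    """
    aberrant = 0
    for _, start, end, c in cn.segments:
        if c == 0 or abs(np.log2(c / 2.0)) > threshold:
            aberrant += end - start
    return aberrant / cn.genome_length
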