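"""Parsimony and NJ trees, tree cutting, and the distance-based CH index."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from tumorgeo import (
    MutationMatrix,
    SectorMap,
    block_contiguity,
    build_nj_tree,
    build_parsimony_tree,
    ch_index,
    cut_tree_partitions,
    find_spatial_blocks,
    tree_distance,
)
from tumorgeo.trees import SpatialBlockPartition, _enumerate_topologies, _fitch_score, _leaf_masks


def brute_force_parsimony(m: MutationMatrix) -> int:
    """Minimum Fitch score over every unrooted binary topology."""
    masks = _leaf_masks(m)
    return min(_fitch_score(adj, masks) for adj in _enumerate_topologies(len(m.sectors)))


def random_tree(names, rng, min_len=0.1, max_len=2.0) -> TreeNode:
    """Random rooted binary tree with uniform branch lengths."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(min_len, max_len)))
             for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(min_len, max_len)))
        parent.append(a)
        parent.append(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


class TestParsimony:
    def test_known_four_taxon_split(self, paired_mutations):
        res = build_parsimony_tree(paired_mutations, method="exhaustive")
        # m1 and m2 each need one change; the four private variants one each
        assert res.score == 6
        splits = {frozenset(t.name for t in ch.tips()) or frozenset([ch.name])
                  for ch in res.tree.traverse() if not ch.is_root()}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_duplicated_character_adds_its_score(self, paired_mutations):
        doubled = MutationMatrix(
            paired_mutations.sectors,
            paired_mutations.variants + ("m1b",),
            np.column_stack([paired_mutations.presence,
                             paired_mutations.presence[:, 0]]),
        )
        base = build_parsimony_tree(paired_mutations, method="exhaustive").score
        assert build_parsimony_tree(doubled, method="exhaustive").score == base + 1

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_nni_matches_exhaustive_minimum(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(8):
            presence = rng.integers(0, 2, size=(n_leaves, 20))
            presence[0, 0] = 1  # ensure at least one present variant
            m = MutationMatrix(tuple(f"S{i}" for i in range(n_leaves)),
                               tuple(f"v{i}" for i in range(20)), presence)
            if all((presence[0] == presence[i]).all() for i in range(n_leaves)):
                continue
            nni = build_parsimony_tree(m, method="nni")
            assert nni.score == brute_force_parsimony(m)

    def test_branch_lengths_sum_to_score(self, paired_mutations):
        res = build_parsimony_tree(paired_mutations, method="exhaustive")
        total = sum(n.length for n in res.tree.traverse() if not n.is_root())
        assert total == res.score

    def test_identical_sectors_give_flagged_star(self):
        m = MutationMatrix(("A", "B", "C"), ("m1",), np.ones((3, 1), dtype=int))
        res = build_parsimony_tree(m)
        assert res.star
        assert res.score == 0
        assert {t.name for t in res.tree.tips()} == {"A", "B", "C"}

    def test_outgroup_roots_tree(self, paired_mutations):
        withnormal = MutationMatrix(
            paired_mutations.sectors + ("N",),
            paired_mutations.variants,
            np.vstack([paired_mutations.presence,
                       np.zeros(len(paired_mutations.variants), dtype=int)]),
        )
        res = build_parsimony_tree(withnormal, outgroup="N")
        root_children_tips = [{t.name for t in ch.tips()} or {ch.name}
                              for ch in res.tree.children]
        assert {"N"} in root_children_tips


class TestNJ:
    def test_additive_matrix_recovered(self):
        rng = np.random.default_rng(1)
        names = [f"S{i}" for i in range(8)]
        t = random_tree(names, rng)
        dm = t.tip_tip_distances()
        nj_tree = build_nj_tree(dm)
        back = tree_distance(nj_tree).filter(dm.ids)
        np.testing.assert_allclose(back.data, dm.data, atol=1e-9)

    def test_three_taxon_closed_form(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4 -> a=1, b=1, c=3
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                            ids=["A", "B", "C"])
        t = build_nj_tree(dm)
        back = tree_distance(t).filter(["A", "B", "C"])
        np.testing.assert_allclose(back.data, dm.data, atol=1e-12)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        names = [f"S{i}" for i in range(6)]
        t = random_tree(names, rng)
        dm = t.tip_tip_distances()
        perm = list(rng.permutation(names))
        d1 = tree_distance(build_nj_tree(dm)).filter(names)
        d2 = tree_distance(build_nj_tree(dm.filter(perm))).filter(names)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-9)

    def test_too_few_labels(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["A", "B"])
        with pytest.raises(ValueError):
            build_nj_tree(dm)


class TestTreeDistance:
    def test_two_leaf_path(self):
        t = TreeNode.read(["(A:1,B:2);"])
        assert tree_distance(t)["A", "B"] == pytest.approx(3.0)

    def test_star_tree(self):
        t = TreeNode.read(["(A:1.5,B:1.5,C:1.5,D:1.5);"])
        d = tree_distance(t)
        off = d.data[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 3.0)

    def test_missing_lengths_treated_as_zero(self):
        t = TreeNode.read(["((A:1,B:1),C:1);"])
        assert tree_distance(t)["A", "C"] == pytest.approx(2.0)


def brute_force_cuts(t: TreeNode, k: int):
    """Oracle: try every (k-1)-subset of edges, partition by connectivity."""
    edges = [n for n in t.traverse(include_self=False)]
    names = sorted(tip.name for tip in t.tips())
    found = set()
    for cut in itertools.combinations(edges, k - 1):
        cut_set = set(id(n) for n in cut)
        # build adjacency without the cut edges
        comp = {}

        def walk(node, label):
            comp[id(node)] = label
            for ch in node.children:
                if id(ch) not in cut_set:
                    walk(ch, label)

        labels = 0
        walk(t, labels)
        for n in cut:
            labels += 1
            walk(n, labels)
        groups = {}
        for tip in t.tips():
            groups.setdefault(comp[id(tip)], set()).add(tip.name)
        if len(groups) == k and all(groups.values()):
            found.add(frozenset(frozenset(g) for g in groups.values()))
    return found


class TestCuts:
    def test_four_leaf_internal_cut_present(self, paired_mutations):
        t = build_parsimony_tree(paired_mutations, method="exhaustive").tree
        parts = cut_tree_partitions(t, 2)
        as_sets = {frozenset(frozenset(c) for c in p) for p in parts}
        assert frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}) in as_sets

    def test_k_equals_n_gives_singletons(self):
        t = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
        parts = cut_tree_partitions(t, 4)
        assert len(parts) == 1
        assert all(len(c) == 1 for c in parts[0])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_brute_force_on_caterpillar(self, k):
        t = TreeNode.read(["((((A:1,B:1):1,C:1):1,D:1):1,E:1);"])
        parts = cut_tree_partitions(t, k)
        as_sets = {frozenset(frozenset(c) for c in p) for p in parts}
        assert as_sets == brute_force_cuts(t, k)

    def test_invalid_k_rejected(self):
        t = TreeNode.read(["((A:1,B:1):1,C:1);"])
        with pytest.raises(ValueError):
            cut_tree_partitions(t, 9)


def brute_force_ch(d: DistanceMatrix, clusters) -> float:
    """Straight transcription of the dispersion formulas, double loops."""
    ids = list(d.ids)
    n = len(ids)
    K = len(clusters)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[ids[i], ids[j]] / n
    ss_within = 0.0
    for c in clusters:
        c = list(c)
        for a in range(len(c)):
            for b in range(a + 1, len(c)):
                ss_within += d[c[a], c[b]] / len(c)
    ss_between = ss_total - ss_within
    if ss_within == 0:
        return float("inf")
    return ss_between * (n - K) / (ss_within * (K - 1))


class TestCHIndex:
    def test_worked_example(self):
        # two tight pairs distance 1 apart, 10 across: SS_w=1, SS_b=9.5
        data = np.array(
            [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 1], [10, 10, 1, 0]],
            dtype=float,
        )
        d = DistanceMatrix(data, ids=["A", "B", "C", "D"])
        assert ch_index(d, [{"A", "B"}, {"C", "D"}]) == pytest.approx(19.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            ids = [f"S{i}" for i in range(n)]
            raw = rng.uniform(0.1, 5, size=(n, n))
            data = (raw + raw.T) / 2
            np.fill_diagonal(data, 0)
            d = DistanceMatrix(data, ids=ids)
            k = int(rng.integers(2, min(n, 4) + 1))
            labels = rng.integers(0, k, size=n)
            while len(set(labels)) < k:
                labels = rng.integers(0, k, size=n)
            clusters = [{ids[i] for i in range(n) if labels[i] == c}
                        for c in range(k)]
            assert ch_index(d, clusters) == pytest.approx(
                brute_force_ch(d, clusters), abs=1e-10)

    def test_identical_points_within_clusters_is_infinite(self):
        data = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], float)
        d = DistanceMatrix(data, ids=["A", "B", "C", "D"])
        assert ch_index(d, [{"A", "B"}, {"C", "D"}]) == np.inf

    def test_bad_partition_rejected(self):
        d = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["A", "B"])
        with pytest.raises(ValueError, match="partition"):
            ch_index(d, [{"A"}, {"A", "B"}])


class TestSpatialBlocks:
    def test_k_range_of_one_value(self, paired_mutations):
        t = build_parsimony_tree(paired_mutations, method="exhaustive").tree
        part = find_spatial_blocks(t, k_range=[2])
        assert part.chosen_k == 2
        assert set(part.ch_by_k) == {2}

    def test_invariant_to_sector_order(self, paired_mutations):
        t = build_parsimony_tree(paired_mutations, method="exhaustive").tree
        part1 = find_spatial_blocks(t)
        rev = MutationMatrix(paired_mutations.sectors[::-1],
                             paired_mutations.variants,
                             paired_mutations.presence[::-1])
        part2 = find_spatial_blocks(
            build_parsimony_tree(rev, method="exhaustive").tree)
        assert part1.labels == part2.labels
        assert part1.chosen_k == part2.chosen_k

    def test_labels_cover_all_sectors(self, paired_mutations):
        t = build_parsimony_tree(paired_mutations, method="exhaustive").tree
        part = find_spatial_blocks(t)
        assert sorted(part.labels) == sorted(paired_mutations.sectors)
        blocks = part.block_sets()
        assert all(blocks)


class TestContiguity:
    def _partition(self, labels):
        k = len(set(labels.values()))
        return SpatialBlockPartition(labels=labels, k=k, ch_by_k={k: 1.0},
                                     chosen_k=k)

    def test_half_plane_blocks_fully_contiguous(self):
        # two 2x3 patches separated by a gap wider than the within-patch
        # spacing: every nearest neighbor stays within the patch
        coords = [(x, y) for x in (0.0, 1.0, 2.0) for y in (0.0, 1.0)]
        coords += [(x, y) for x in (5.0, 6.0, 7.0) for y in (0.0, 1.0)]
        sm = SectorMap("p", tuple(f"S{i}" for i in range(12)),
                       np.array(coords))
        labels = {f"S{i}": (1 if i < 6 else 2) for i in range(12)}
        assert block_contiguity(self._partition(labels), sm) == 1.0

    def test_single_block_is_one(self, square_map):
        labels = {s: 1 for s in square_map.sectors}
        assert block_contiguity(self._partition(labels), square_map) == 1.0

    def test_alternating_blocks_are_zero(self):
        xs = np.arange(6.0)
        coords = np.column_stack([xs, np.zeros(6)])
        sm = SectorMap("p", tuple(f"S{i}" for i in range(6)), coords)
        labels = {f"S{i}": i % 2 for i in range(6)}
        assert block_contiguity(self._partition(labels), sm) == 0.0
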