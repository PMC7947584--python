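import math

import numpy as np
import pytest

from terlkit.io import Msa, SequenceRecord
from terlkit.iteralign import (
    AlignmentState,
    IterAlignConfig,
    TreeNode,
    align_cluster,
    greedy_identity_cluster,
    iterate_align,
    mask_gappy_columns,
    merge_by_guide_tree,
    profile_similarity,
    reinsert_masked,
    similarity_to_distance,
    upgma,
)
from terlkit.synthetic import simulate_related_families


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        recs = [SequenceRecord("a", "MKVLWAG"), SequenceRecord("b", "MKVLWAG")]
        cs = greedy_identity_cluster(recs, 0.5)
        assert len(set(cs.assignments.values())) == 1

    def test_unrelated_sequences_two_clusters(self):
        recs = [SequenceRecord("a", "MMMMMMMMMM"), SequenceRecord("b", "WWWWWWWWWW")]
        cs = greedy_identity_cluster(recs, 0.5)
        assert len(set(cs.assignments.values())) == 2

    def test_planted_families_recovered(self):
        recs, truth = simulate_related_families(2, 5, 200, 0.05, 0.6, seed=31)
        cs = greedy_identity_cluster(recs, 0.5)
        clusters = {}
        for sid, cid in cs.assignments.items():
            clusters.setdefault(cid, set()).add(truth.family_of[sid])
        assert len(clusters) == 2
        assert all(len(v) == 1 for v in clusters.values())

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            greedy_identity_cluster([SequenceRecord("a", "MK")], 0.0)


class TestAlignCluster:
    def test_single_sequence_trivial(self):
        msa = align_cluster([SequenceRecord("a", "MKV")])
        assert msa.records == (("a", "MKV"),)

    def test_identical_pair_gap_free(self):
        msa = align_cluster(
            [SequenceRecord("a", "MKVLW"), SequenceRecord("b", "MKVLW")]
        )
        assert msa.n_cols == 5
        assert "-" not in msa.row("a") + msa.row("b")

    def test_indel_pair_matches_optimal(self):
        msa = align_cluster([SequenceRecord("a", "MKVI"), SequenceRecord("b", "MKI")])
        assert msa.n_cols == 4
        assert msa.row("b").count("-") == 1
        assert msa.row("a") == "MKVI"

    def test_degapping_recovers_inputs(self):
        recs, _ = simulate_related_families(1, 8, 150, 0.2, 0.0, seed=5)
        msa = align_cluster(recs)
        assert {r.id: r.residues for r in msa.degap()} == {
            r.id: r.residues for r in recs
        }


class TestProfileSimilarity:
    def test_self_similarity_is_one(self):
        recs, _ = simulate_related_families(1, 4, 60, 0.2, 0.0, seed=9)
        msa = align_cluster(recs)
        assert profile_similarity(msa, msa) == pytest.approx(1.0)

    def test_symmetric(self):
        ra, _ = simulate_related_families(1, 3, 50, 0.2, 0.0, seed=1)
        rb, _ = simulate_related_families(1, 3, 50, 0.2, 0.0, seed=2)
        a, b = align_cluster(ra), align_cluster(rb)
        assert profile_similarity(a, b) == pytest.approx(profile_similarity(b, a))

    def test_disjoint_residue_profiles_clamped_to_zero(self, blosum62):
        # poly-W vs poly-P cross-scores are uniformly negative
        a = Msa((("a1", "WWWWWWWW"), ("a2", "WWWWWWWW")))
        b = Msa((("b1", "PPPPPPPP"), ("b2", "PPPPPPPP")))
        assert blosum62.score("W", "P") < 0
        assert profile_similarity(a, b) == 0.0


class TestSimilarityToDistance:
    def test_perfect_similarity_zero_distance(self):
        assert similarity_to_distance(1.0) == 0.0

    def test_strictly_decreasing(self):
        assert similarity_to_distance(0.2) > similarity_to_distance(0.8)

    def test_floor(self):
        assert similarity_to_distance(0.0) == pytest.approx(-math.log(1e-6))
        assert similarity_to_distance(1e-7) == pytest.approx(-math.log(1e-6))


def brute_upgma_heights(D, labels):
    """Independent UPGMA re-implementation tracking leaf-set -> height."""
    dist = {
        frozenset([a, b]): D[i][j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    sizes = {frozenset([l]): 1 for l in labels}
    active = [frozenset([l]) for l in labels]
    heights = {}
    # simple O(n^3) agglomeration over leaf sets
    pair_d = {}
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            pair_d[(a, b)] = dist[frozenset(set(a) | set(b))]
    while len(active) > 1:
        (a, b), d = min(pair_d.items(), key=lambda kv: (kv[1], sorted(kv[0][0] | kv[0][1])))
        new = a | b
        heights[new] = d / 2
        active = [c for c in active if c not in (a, b)]
        new_pair_d = {}
        for (x, y), v in pair_d.items():
            if x in (a, b) or y in (a, b):
                continue
            new_pair_d[(x, y)] = v
        for c in active:
            da = pair_d.get((a, c), pair_d.get((c, a)))
            db = pair_d.get((b, c), pair_d.get((c, b)))
            new_pair_d[(c, new)] = (da * sizes[a] + db * sizes[b]) / (
                sizes[a] + sizes[b]
            )
        sizes[new] = sizes[a] + sizes[b]
        active.append(new)
        pair_d = new_pair_d
    return heights


def _node_heights(tree):
    out = {}

    def _walk(n):
        if n.is_leaf:
            return
        out[frozenset(n.leaves())] = n.height
        for c in n.children:
            _walk(c)

    _walk(tree)
    return out


class TestUpgma:
    def test_two_leaves(self):
        tree = upgma(np.array([[0.0, 3.0], [3.0, 0.0]]), ["A", "B"])
        assert tree.height == pytest.approx(1.5)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        D = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        tree = upgma(D, ["A", "B", "C"])
        heights = _node_heights(tree)
        assert heights[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert heights[frozenset({"A", "B", "C"})] == pytest.approx(4.0)

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(2)
        n = 5
        M = rng.uniform(1, 10, (n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"L{i}" for i in range(n)]
        t1 = _node_heights(upgma(D, labels))
        perm = rng.permutation(n)
        Dp = D[np.ix_(perm, perm)]
        t2 = _node_heights(upgma(Dp, [labels[i] for i in perm]))
        assert set(t1) == set(t2)
        for k in t1:
            assert t1[k] == pytest.approx(t2[k])

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            M = rng.uniform(1, 10, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            labels = [f"L{i}" for i in range(n)]
            mine = _node_heights(upgma(D, labels))
            oracle = brute_upgma_heights(D.tolist(), labels)
            assert set(mine) == set(oracle)
            for k in mine:
                assert mine[k] == pytest.approx(oracle[k], abs=1e-9)

    def test_nan_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma(D, ["A", "B"])


class TestMasking:
    def test_gap_free_msa_untouched(self):
        msa = Msa((("a", "MKVLW"), ("b", "MKVLW")))
        masked, record = mask_gappy_columns(msa)
        assert masked.records == msa.records
        assert reinsert_masked(masked, record).records == msa.records

    def test_two_thirds_gap_column_not_masked(self):
        # 2 gaps of 3 rows = 66.7% <= 67%: strictly-greater rule keeps it
        msa = Msa((("a", "MAK"), ("b", "M-K"), ("c", "M-K")))
        masked, _ = mask_gappy_columns(msa, max_gap=0.67)
        assert masked.n_cols == 3

    def test_mask_and_reinsert_round_trip(self):
        msa = Msa(
            (
                ("a", "MK-VLW-A"),
                ("b", "MKQVLWQA"),
                ("c", "MK-VLW-A"),
                ("d", "MK-VLW-A"),
            )
        )
        masked, record = mask_gappy_columns(msa, max_gap=0.5)
        assert masked.n_cols == 6
        restored = reinsert_masked(masked, record)
        assert {r.id: r.residues for r in restored.degap()} == {
            r.id: r.residues for r in msa.degap()
        }

    def test_inconsistent_mask_rejected(self):
        msa = Msa((("a", "MK"),))
        _, record = mask_gappy_columns(msa)
        from terlkit.iteralign import MaskRecord

        bad = MaskRecord({"nope": ((0, "W"),)})
        with pytest.raises(ValueError, match="unknown"):
            reinsert_masked(msa, bad)


class TestMergeByGuideTree:
    def _three_blocks(self):
        blocks = [
            Msa((("a1", "MKVLW"),)),
            Msa((("b1", "MKVLW"),)),
            Msa((("c1", "MKVLW"),)),
        ]
        return AlignmentState(0, blocks)

    def _tree(self, h_low, h_high):
        return TreeNode(
            h_high,
            children=(
                TreeNode(
                    h_low,
                    children=(TreeNode(0.0, label="a1"), TreeNode(0.0, label="b1")),
                ),
                TreeNode(0.0, label="c1"),
            ),
        )

    def test_threshold_above_root_single_block(self):
        out = merge_by_guide_tree(self._three_blocks(), self._tree(1.0, 4.0), 5.0)
        assert len(out.blocks) == 1

    def test_threshold_below_everything_no_merge(self):
        out = merge_by_guide_tree(self._three_blocks(), self._tree(1.0, 4.0), 0.5)
        assert len(out.blocks) == 3

    def test_partial_merge_at_paper_threshold(self):
        out = merge_by_guide_tree(self._three_blocks(), self._tree(1.0, 4.0), 2.3)
        assert sorted(len(b.ids) for b in out.blocks) == [1, 2]

    def test_unknown_leaf_rejected(self):
        tree = TreeNode(1.0, children=(TreeNode(0, label="a1"), TreeNode(0, label="zz")))
        with pytest.raises(ValueError, match="zz"):
            merge_by_guide_tree(self._three_blocks(), tree, 5.0)


class TestIterateAlign:
    def test_near_identical_sequences_one_iteration(self):
        recs, _ = simulate_related_families(1, 5, 120, 0.05, 0.0, seed=21)
        res = iterate_align(recs, IterAlignConfig(max_iterations=5))
        assert res.converged
        assert res.alignment.n_rows == 5

    def test_planted_families_merge_with_conservation(self):
        recs, _ = simulate_related_families(3, 6, 150, 0.1, 0.45, seed=77)
        res = iterate_align(recs, IterAlignConfig(max_iterations=20))
        assert res.converged
        assert res.alignment.n_rows == len(recs)
        assert {r.id: r.residues for r in res.alignment.degap()} == {
            r.id: r.residues for r in recs
        }
        # block counts never increase
        assert all(
            b <= a for a, b in zip(res.block_counts, res.block_counts[1:])
        )

    def test_zero_depth_threshold_blocks_all_merges(self):
        recs = [
            SequenceRecord("a", "MMMMWWWWKKKK"),
            SequenceRecord("b", "PPPPGGGGEEEE"),
        ]
        res = iterate_align(
            recs, IterAlignConfig(depth_threshold=0.0, max_iterations=3)
        )
        assert not res.converged
        assert res.alignment.n_rows == 1
        assert len(res.unaligned_ids) == 1

    def test_relaxed_parameters_never_shrink_final_block(self):
        recs, _ = simulate_related_families(3, 4, 120, 0.15, 0.5, seed=55)
        strict = iterate_align(
            recs, IterAlignConfig(cluster_threshold=0.5, depth_threshold=2.3, max_iterations=5)
        )
        relaxed = iterate_align(
            recs, IterAlignConfig(cluster_threshold=0.01, depth_threshold=6.0, max_iterations=5)
        )
        assert relaxed.alignment.n_rows >= strict.alignment.n_rows
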