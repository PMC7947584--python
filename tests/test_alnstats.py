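import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from terlkit.alnstats import (
    column_homogeneity,
    column_score,
    column_stats,
    column_to_reference_position,
    consensus_residue,
    henikoff_weights,
    random_expectation_score,
    trim_alignment,
)
from terlkit.io import AMINO_ACIDS, Msa
from terlkit.synthetic import simulate_msa

from conftest import brute_henikoff, brute_homogeneity, random_msa


class TestHenikoffWeights:
    def test_identical_rows_share_weight_equally(self):
        msa = Msa(tuple((f"s{i}", "MKVLW") for i in range(1, 6)))
        w = henikoff_weights(msa)
        assert np.allclose(w.weights, 0.2)

    def test_single_row(self):
        w = henikoff_weights(Msa((("only", "MKV"),)))
        assert np.allclose(w.weights, [1.0])

    def test_hand_computed_three_row_example(self, small_msa):
        # rows AA, AC, CC: col1 gives A-rows 1/4 each and the C-row 1/2,
        # col2 mirrors it; raw sums (.75, .5, .75) normalize to below
        w = henikoff_weights(small_msa)
        assert np.allclose(w.weights, [0.375, 0.25, 0.375], atol=1e-9)

    def test_matches_brute_force_on_random_msas(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            msa = random_msa(rng, int(rng.integers(2, 7)), int(rng.integers(2, 9)))
            assert np.allclose(
                henikoff_weights(msa).weights, brute_henikoff(msa), atol=1e-9
            )

    def test_all_gap_row_rejected(self):
        msa = Msa((("ok", "MK"), ("bad", "--")))
        with pytest.raises(ValueError, match="bad"):
            henikoff_weights(msa)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        msa = random_msa(rng, int(rng.integers(1, 9)), int(rng.integers(1, 12)))
        assert abs(henikoff_weights(msa).weights.sum() - 1.0) < 1e-9


class TestColumnScores:
    def test_single_row_scores_diagonal(self, blosum62):
        msa = Msa((("s1", "A"),))
        w = henikoff_weights(msa)
        assert column_score(msa, w, 0, "A", blosum62) == blosum62.score("A", "A")

    def test_two_equal_weight_rows_average(self, blosum62):
        msa = Msa((("s1", "A"), ("s2", "C")))
        w = henikoff_weights(msa)
        expected = (blosum62.score("A", "G") + blosum62.score("C", "G")) / 2
        assert column_score(msa, w, 0, "G", blosum62) == pytest.approx(expected)

    def test_consensus_by_brute_force_over_20_candidates(self, blosum62):
        msa = Msa((("s1", "I"), ("s2", "L"), ("s3", "V")))
        w = henikoff_weights(msa)
        scores = {
            x: column_score(msa, w, 0, x, blosum62) for x in AMINO_ACIDS
        }
        best = max(scores.values())
        expected = min(x for x in scores if scores[x] == best)
        assert consensus_residue(msa, w, 0, blosum62) == expected

    def test_conserved_column_consensus(self, blosum62):
        for res in ("A", "W"):
            msa = Msa((("s1", res), ("s2", res)))
            w = henikoff_weights(msa)
            assert consensus_residue(msa, w, 0, blosum62) == res

    def test_random_expectation_is_background_weighted_sum(self, blosum62):
        msa = Msa((("s1", "A"), ("s2", "A")))
        w = henikoff_weights(msa)
        expected = sum(
            blosum62.background[i] * blosum62.score("A", AMINO_ACIDS[i])
            for i in range(20)
        )
        assert random_expectation_score(msa, w, 0, blosum62) == pytest.approx(expected)

    def test_random_expectation_never_exceeds_consensus_score(self, blosum62):
        rng = np.random.default_rng(7)
        for _ in range(20):
            msa = random_msa(rng, 4, 3, gap_p=0.1)
            w = henikoff_weights(msa)
            for j in range(msa.n_cols):
                c = consensus_residue(msa, w, j, blosum62)
                qc = column_score(msa, w, j, c, blosum62)
                qr = random_expectation_score(msa, w, j, blosum62)
                assert qr <= qc + 1e-12


class TestHomogeneity:
    def test_perfectly_conserved_column_is_one(self, blosum62):
        for res in AMINO_ACIDS:
            msa = Msa(tuple((f"s{i}", res) for i in range(1, 5)))
            w = henikoff_weights(msa)
            assert column_homogeneity(msa, w, 0, blosum62) == pytest.approx(1.0)

    def test_bounded_and_matches_compositional_oracle(self, blosum62):
        rng = np.random.default_rng(11)
        for _ in range(50):
            msa = random_msa(rng, int(rng.integers(2, 7)), int(rng.integers(1, 9)))
            w = henikoff_weights(msa)
            for j in range(msa.n_cols):
                if all(seq[j] == "-" for _, seq in msa.records):
                    continue
                h = column_homogeneity(msa, w, j, blosum62)
                assert 0.0 <= h <= 1.0
                assert h == pytest.approx(brute_homogeneity(msa, j, blosum62), abs=1e-9)

    def test_mean_homogeneity_increases_with_planted_conservation(self, blosum62):
        means = []
        for p in (0.3, 0.6, 0.9):
            msa, _ = simulate_msa(30, 200, conservation_p=p, gap_p=0.0, seed=123)
            stats = column_stats(msa, blosum62)
            means.append(np.mean([s.homogeneity for s in stats]))
        assert means[0] < means[1] < means[2]


class TestTrim:
    def test_clean_alignment_unchanged(self, blosum62):
        msa = Msa(tuple((f"s{i}", "MKVLW") for i in range(1, 4)))
        trimmed, kept = trim_alignment(msa, 0.5, 0.1, blosum62)
        assert trimmed.records == msa.records
        assert kept == [0, 1, 2, 3, 4]

    def test_gappy_column_removed(self, blosum62):
        # 10 rows; column 1 has 6 gaps (60% > 50%)
        rows = tuple(
            (f"s{i}", ("M-K" if i <= 6 else "MAK")) for i in range(1, 11)
        )
        trimmed, kept = trim_alignment(Msa(rows), 0.5, 0.1, blosum62)
        assert kept == [0, 2]

    def test_boundary_gap_fraction_kept(self, blosum62):
        # exactly 50% gaps passes the <= threshold
        rows = tuple(
            (f"s{i}", ("M-K" if i <= 5 else "MAK")) for i in range(1, 11)
        )
        _, kept = trim_alignment(Msa(rows), 0.5, 0.1, blosum62)
        assert 1 in kept

    def test_low_homogeneity_column_removed(self, blosum62):
        # find a gap-free random column with brute-force H < 0.1
        rng = np.random.default_rng(3)
        while True:
            msa = random_msa(rng, 6, 1, gap_p=0.0)
            wide = Msa(tuple((rid, seq + "W") for (rid, seq) in msa.records))
            if brute_homogeneity(wide, 0, blosum62) < 0.1:
                break
        _, kept = trim_alignment(wide, 0.5, 0.1, blosum62)
        assert kept == [1]

    def test_idempotent(self, blosum62):
        rng = np.random.default_rng(5)
        msa = random_msa(rng, 8, 30, gap_p=0.3)
        once, _ = trim_alignment(msa, 0.5, 0.1, blosum62)
        twice, kept = trim_alignment(once, 0.5, 0.1, blosum62)
        assert twice.records == once.records
        assert kept == list(range(once.n_cols))

    def test_all_columns_removed_raises(self, blosum62):
        # every column is two-thirds gaps, so the gap rule removes them all
        msa = Msa((("a", "A--"), ("b", "-C-"), ("c", "--D")))
        with pytest.raises(ValueError, match="every column"):
            trim_alignment(msa, 0.5, 0.1, blosum62)

    def test_joint_mode_requires_both_violations(self, blosum62):
        # column 1: 60% gaps but homogeneous -> kept under joint, removed by default
        rows = tuple(
            (f"s{i}", ("M-K" if i <= 6 else "MWK")) for i in range(1, 11)
        )
        _, kept_or = trim_alignment(Msa(rows), 0.5, 0.1, blosum62)
        _, kept_joint = trim_alignment(Msa(rows), 0.5, 0.1, blosum62, joint=True)
        assert 1 not in kept_or
        assert 1 in kept_joint


class TestReferenceMapping:
    def test_gap_free_reference(self):
        msa = Msa((("ref", "MKVLWA"),))
        assert column_to_reference_position(msa, "ref", 5) == 6

    def test_gap_column_maps_to_none(self):
        msa = Msa((("ref", "M-KV"), ("x", "MAKV")))
        assert column_to_reference_position(msa, "ref", 1) is None

    def test_counts_non_gaps(self):
        msa = Msa((("ref", "M-KV"), ("x", "MAKV")))
        assert column_to_reference_position(msa, "ref", 3) == 3

    def test_unknown_reference(self):
        msa = Msa((("ref", "MK"),))
        with pytest.raises(KeyError):
            column_to_reference_position(msa, "nope", 0)
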