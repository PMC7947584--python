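import numpy as np
import pytest

from terlkit.filters import (
    consensus_similarity_filter,
    detect_walker_a,
    domain_coverage_filter,
    pssm_coverage_filter,
    select_representatives,
)
from terlkit.io import AMINO_ACIDS, Msa, ProfileHit, SequenceRecord
from terlkit.synthetic import simulate_terl_family


def _hit(sid="s1", slen=500, pid="P", plen=500, kind="full",
         pspan=(1, 500), sspan=(1, 500), e=1e-30):
    return ProfileHit(sid, slen, pid, plen, kind, pspan, sspan, e)


class TestDomainCoverage:
    def test_full_profile_hit_keeps(self):
        d = domain_coverage_filter(500, [_hit(pspan=(50, 450))])  # 80% of profile
        assert d.kept and d.rule == "full_profile_75"

    def test_no_hits_removed_with_detail(self):
        d = domain_coverage_filter(500, [])
        assert not d.kept and d.detail == "no hits"

    def test_single_n_terminal_match_not_enough(self):
        # 90% of an N-terminal profile, half the sequence left C-ward,
        # but no C-side match at all
        h = _hit(pid="PN", plen=250, kind="n_terminal", pspan=(1, 225), sspan=(1, 250))
        d = domain_coverage_filter(500, [h])
        assert not d.kept
        assert "C" in d.detail

    def test_two_domain_matches_keep(self):
        hn = _hit(pid="PN", plen=300, kind="n_terminal", pspan=(1, 300), sspan=(1, 300))
        hc = _hit(pid="PC", plen=200, kind="c_terminal", pspan=(1, 181), sspan=(320, 500))
        d = domain_coverage_filter(500, [hn, hc])
        assert d.kept and d.rule == "two_profile_domains"

    def test_margin_requirement_enforced(self):
        # C-terminal match leaving only 10% of the sequence N-ward: the
        # missing ATPase domain has no room, so no C-side credit
        hc = _hit(pid="PC", plen=200, kind="c_terminal", pspan=(1, 200), sspan=(50, 500))
        hn = _hit(pid="PN", plen=300, kind="n_terminal", pspan=(1, 300), sspan=(1, 300))
        d = domain_coverage_filter(500, [hn, hc])
        assert not d.kept

    def test_partial_full_profile_hits_pair_up(self):
        # two partial hits to one full profile, one on each end
        ha = _hit(pspan=(1, 200), sspan=(1, 200))
        hb = _hit(pspan=(301, 500), sspan=(301, 500))
        d = domain_coverage_filter(500, [ha, hb])
        assert d.kept and d.rule == "two_profile_domains"

    def test_monotone_in_profile_coverage(self):
        # extending a hit's profile span never flips kept -> removed
        base_span = (100, 300)
        kept_seen = False
        for hi in range(300, 501, 25):
            h = _hit(pspan=(base_span[0], hi), sspan=(100, 400))
            d = domain_coverage_filter(500, [h])
            if kept_seen:
                assert d.kept
            kept_seen = kept_seen or d.kept
        assert kept_seen  # the widest hit covers >= 75% of the full profile

    def test_planted_truncations_removed_exactly(self):
        records, hits, truth = simulate_terl_family(30, 10, 400, 0.1, seed=17)
        by = {}
        for h in hits:
            by.setdefault(h.sequence_id, []).append(h)
        removed = {
            r.id
            for r in records
            if not domain_coverage_filter(len(r), by[r.id]).kept
        }
        assert removed == set(truth.truncated_ids)


class TestConsensusSimilarity:
    def test_consensus_identical_row_kept(self, blosum62):
        msa = Msa((("a", "MKVLW"), ("b", "MKVLW"), ("c", "MKVLW")))
        decisions = consensus_similarity_filter(msa, blosum62)
        assert all(d.kept for d in decisions)
        assert "ratio 1.000" in decisions[0].detail

    def test_all_gap_row_removed(self, blosum62):
        rows = tuple((f"s{i}", "MKVLWMKVLW") for i in range(1, 6)) + (("empty", "-" * 10),)
        decisions = consensus_similarity_filter(Msa(rows), blosum62)
        by_id = {d.sequence_id: d for d in decisions}
        assert not by_id["empty"].kept
        assert all(by_id[f"s{i}"].kept for i in range(1, 6))

    def test_boundary_ratio(self, blosum62):
        # consensus column is all-W (S(W,W)=11); a probe row keeping k of
        # 20 W-columns and gaps elsewhere has score/perfect = k/20
        n_cols = 20
        rows = tuple((f"s{i}", "W" * n_cols) for i in range(1, 6))
        for k, expect_kept in ((1, False), (2, True)):  # 0.05 vs 0.10
            probe = "W" * k + "-" * (n_cols - k)
            decisions = consensus_similarity_filter(
                Msa(rows + (("probe", probe),)), blosum62
            )
            d = {x.sequence_id: x for x in decisions}["probe"]
            assert d.kept is expect_kept, d.detail

    def test_never_removes_consensus_row_on_random_msas(self, blosum62):
        from conftest import random_msa
        from terlkit.alnstats import column_stats

        rng = np.random.default_rng(23)
        for _ in range(10):
            msa = random_msa(rng, 5, 12, gap_p=0.2)
            stats = column_stats(msa, blosum62)
            cons = "".join(st.consensus or "-" for st in stats)
            if cons.replace("-", "") == "":
                continue
            augmented = Msa(msa.records + (("consrow", cons),))
            decisions = consensus_similarity_filter(augmented, blosum62)
            # the appended row is not guaranteed to be *the* consensus of the
            # augmented MSA, but it can only score higher than before, so it
            # must always be kept
            assert {d.sequence_id: d for d in decisions}["consrow"].kept


class TestPssmCoverage:
    def test_gap_free_alignment_full_coverage(self):
        msa = Msa((("a", "MKVLW"), ("b", "MKVLW")))
        decisions, extracted = pssm_coverage_filter(msa)
        assert all(d.kept for d in decisions)
        assert extracted["a"].residues == "MKVLW"

    def test_sparse_row_removed(self):
        n_cols = 20
        rows = tuple((f"s{i}", "W" * n_cols) for i in range(1, 6))
        probe = "W" * 12 + "-" * 8  # 60% coverage
        decisions, _ = pssm_coverage_filter(Msa(rows + (("probe", probe),)))
        assert not {d.sequence_id: d for d in decisions}["probe"].kept

    def test_boundary_75_percent_kept_and_extracted(self):
        n_cols = 20
        rows = tuple((f"s{i}", "W" * n_cols) for i in range(1, 6))
        probe = "W" * 15 + "-" * 5  # exactly 75%
        decisions, extracted = pssm_coverage_filter(Msa(rows + (("probe", probe),)))
        assert {d.sequence_id: d for d in decisions}["probe"].kept
        assert extracted["probe"].residues == "W" * 15


class TestWalkerA:
    def test_canonical_motif(self):
        assert detect_walker_a("MAAGPSGSGKSTLL") == 4

    def test_absent(self):
        assert detect_walker_a("A" * 50) is None

    def test_planted_offset_recovered(self):
        records, _, truth = simulate_terl_family(5, 0, 400, 0.0, seed=3)
        for r in records:
            assert detect_walker_a(r) == truth.motif_offset


class TestRepresentatives:
    def _rec(self, sid, n):
        return SequenceRecord(sid, "A" * n)

    def test_singleton(self):
        r = self._rec("x", 10)
        assert select_representatives({"c": [r]}) == {"c": r}

    def test_odd_median(self):
        members = [self._rec("a", 100), self._rec("b", 200), self._rec("c", 300)]
        assert select_representatives({"c": members})["c"].id == "b"

    def test_even_takes_lower_middle(self):
        members = [self._rec(s, n) for s, n in
                   (("a", 100), ("b", 200), ("c", 300), ("d", 400))]
        assert select_representatives({"c": members})["c"].id == "b"

    def test_length_ties_break_by_id(self):
        members = [self._rec(s, 100) for s in ("z", "m", "a")]
        assert select_representatives({"c": members})["c"].id == "m"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_representatives({"c": []})
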