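import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirmeta.rra import (aggregate, beta_score, corrected_p,
                         normalized_ranks, order_stat_pvalues,
                         permutation_p, prioritize_list)
from mirmeta.synthetic import SignalSpec, simulate_ranked_studies

from conftest import make_list


class TestPrioritize:
    def test_pvalues_sort_ascending(self):
        lst = make_list(mirnas=("a", "b", "c"), pvals=(0.03, 0.001, 0.02))
        assert prioritize_list(lst).mirna_ids == ("b", "c", "a")

    def test_fold_changes_sort_by_abs_log2(self):
        # |log2 0.1| = 3.32 > |log2 4| = 2 > |log2 2| = 1
        lst = make_list(mirnas=("a", "b", "c"), fcs=(4.0, 0.1, 2.0))
        assert prioritize_list(lst).mirna_ids == ("b", "a", "c")

    def test_no_evidence_keeps_input_order(self):
        lst = make_list(mirnas=("z", "y", "x"))
        assert prioritize_list(lst).mirna_ids == ("z", "y", "x")

    def test_mixed_evidence_rejected(self):
        lst = make_list(mirnas=("a", "b"))
        entries = (lst.entries[0],
                   type(lst.entries[0])("b", p_value=0.1))
        lst = type(lst)(lst.study_id, lst.direction, entries,
                        lst.platform_size)
        with pytest.raises(ValueError, match="mixed evidence"):
            prioritize_list(lst)

    def test_ties_break_by_input_order(self):
        lst = make_list(mirnas=("a", "b", "c"), pvals=(0.01, 0.01, 0.001))
        assert prioritize_list(lst).mirna_ids == ("c", "a", "b")


class TestNormalizedRanks:
    def test_rank_over_platform_size(self):
        ranks = normalized_ranks([make_list(mirnas=("a", "b"), platform=100)])
        assert ranks["a"][0] == pytest.approx(0.01)
        assert ranks["b"][0] == pytest.approx(0.02)

    def test_vector_length_equals_presence_count(self):
        lists = [make_list(f"s{i}", "up",
                           ("hub", f"u{i}") if i < 5 else (f"u{i}", f"v{i}"))
                 for i in range(11)]
        ranks = normalized_ranks(lists)
        assert len(ranks["hub"]) == 5
        assert "absent" not in ranks

    def test_mixed_directions_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            normalized_ranks([make_list(direction="up"),
                              make_list("s2", direction="down")])


class TestBetaScore:
    def test_single_rank_is_uniform(self):
        for r in (0.01, 0.5, 1.0):
            assert beta_score([r]) == pytest.approx(r)

    def test_two_ranks_binomial_tail(self):
        # p1 = 1-(1-0.1)^2 = 0.19, p2 = 0.2^2 = 0.04
        p = order_stat_pvalues([0.1, 0.2])
        assert p == pytest.approx([0.19, 0.04])
        assert beta_score([0.1, 0.2]) == pytest.approx(0.04)

    def test_three_equal_ranks(self):
        p = order_stat_pvalues([0.5, 0.5, 0.5])
        assert p == pytest.approx([0.875, 0.5, 0.125])
        assert beta_score([0.5, 0.5, 0.5]) == pytest.approx(0.125)

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ValueError):
            beta_score([0.0, 0.5])
        with pytest.raises(ValueError):
            beta_score([1.5])

    def test_monte_carlo_oracle_small_n(self):
        """Order-statistic tails agree with brute-force uniform sampling."""
        rng = np.random.default_rng(123)
        M = 20_000
        for n in (1, 2, 3, 4):
            for _ in range(5):
                r = np.sort(rng.uniform(size=n))
                p = order_stat_pvalues(r)
                draws = np.sort(rng.uniform(size=(M, n)), axis=1)
                for j in range(n):
                    est = (draws[:, j] <= r[j]).mean()
                    se = max(np.sqrt(p[j] * (1 - p[j]) / M), 1e-8)
                    assert abs(est - p[j]) <= 4 * se

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=8),
           st.integers(0, 7), st.floats(0.1, 0.99))
    def test_improving_a_rank_never_increases_rho(self, ranks, i, frac):
        i = i % len(ranks)
        better = list(ranks)
        better[i] = ranks[i] * frac
        assert beta_score(better) <= beta_score(ranks) + 1e-12

    def test_scale_free_in_platform_size(self):
        # rho depends only on normalized ranks, not the platform they
        # came from: same k/N after doubling both k and N
        a = normalized_ranks([make_list(mirnas=("x",), platform=100)])
        b = normalized_ranks([make_list(
            "s2", mirnas=tuple(f"f{i}" for i in range(1)) + ("x",),
            platform=200)])
        # x at rank 1/100 vs rank 2/200
        assert beta_score(a["x"]) == pytest.approx(beta_score(b["x"]))


class TestCorrectedP:
    @pytest.mark.parametrize("rho, n, expected", [
        (0.04, 2, 0.08),
        (0.5, 11, 1.0),
        (0.3, 1, 0.3),
    ])
    def test_bonferroni_over_lists(self, rho, n, expected):
        assert corrected_p(rho, n) == pytest.approx(expected)


class TestPermutation:
    def _complete_lists(self, seed, n_mirnas=80, n_lists=6):
        uni = [f"m{i:03d}" for i in range(n_mirnas)]
        return simulate_ranked_studies(
            n_lists, uni, [n_mirnas] * n_lists, [n_mirnas] * n_lists,
            [], seed=seed)

    def test_worst_scoring_mirna_has_permutation_p_near_one(self):
        lists = self._complete_lists(seed=1)
        ranks = normalized_ranks(lists)
        rho = {m: beta_score(r) for m, r in ranks.items()}
        worst = max(rho, key=rho.get)
        p = permutation_p(lists, rho, B=500, seed=2)
        assert p[worst] > 0.8

    def test_seed_required(self):
        lists = self._complete_lists(seed=1)
        with pytest.raises(ValueError, match="seed"):
            permutation_p(lists, {}, B=500)

    def test_orders_agree_with_corrected_p(self):
        # corrected and permutation p's should rank the miRNAs the same
        # way wherever the Bonferroni product is not capped at 1 (capping
        # creates mechanical ties with no ordering information)
        uni = [f"m{i:03d}" for i in range(300)]
        sigs = [SignalSpec(f"m00{i}", "up", 0.9, 0.02) for i in range(5)]
        lists = simulate_ranked_studies(11, uni, [300] * 11, [300] * 11,
                                        sigs, seed=3)
        recs = aggregate(lists, B=1000, seed=4)
        cp = np.array([r.corrected_p for r in recs])
        pp = np.array([r.permutation_p for r in recs])
        mask = cp < 1.0
        assert mask.sum() > 50
        assert stats.spearmanr(cp[mask], pp[mask]).statistic > 0.9


class TestAggregate:
    def test_planted_top_mirna_scores_best(self):
        uni = [f"m{i:03d}" for i in range(100)]
        sig = [SignalSpec("m000", "up", 1.0, 0.001)]
        lists = simulate_ranked_studies(6, uni, [100] * 6, [10] * 6,
                                        sig, seed=5)
        recs = aggregate(lists)
        assert recs[0].mirna_id == "m000"
        assert recs[0].corrected_p == min(r.corrected_p for r in recs)

    def test_directions_are_independent(self):
        up = [make_list(f"s{i}", "up", ("a", "b", "c")) for i in range(3)]
        down1 = [make_list(f"s{i}", "down", ("x", "y")) for i in range(2)]
        down2 = [make_list(f"s{i}", "down", ("y", "x")) for i in range(2)]
        up_recs_1 = [r for r in aggregate(up + down1) if r.direction == "up"]
        up_recs_2 = [r for r in aggregate(up + down2) if r.direction == "up"]
        assert up_recs_1 == up_recs_2

    def test_fewer_than_two_lists_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            aggregate([make_list()])

    def test_strict_mode_penalizes_absences(self):
        lists = [make_list(f"s{i}", "up",
                           ("hub", "x") if i == 0 else ("x", f"y{i}"))
                 for i in range(4)]
        rec = {r.mirna_id: r for r in aggregate(lists)}
        strict = {r.mirna_id: r for r in aggregate(lists, strict=True)}
        assert strict["hub"].corrected_p >= rec["hub"].corrected_p
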