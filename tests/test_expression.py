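import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirmeta.expression import (bh_fdr, direction_call, kruskal_wallis,
                                log2_transform, median_fold_change,
                                nb_differential, rank_sum_test,
                                validate_candidates)
from mirmeta.io import ExpressionMatrix
from mirmeta.synthetic import (ExpressionSimSpec, feature_ids,
                               simulate_expression)


def _matrix(values, unit="RPM", n_tumor=None):
    values = np.asarray(values, dtype=float)
    n_tumor = n_tumor if n_tumor is not None else values.shape[1] // 2
    samples = [f"s{i}" for i in range(values.shape[1])]
    groups = pd.Series(["tumor"] * n_tumor
                       + ["normal"] * (values.shape[1] - n_tumor),
                       index=samples)
    data = pd.DataFrame(values, columns=samples,
                        index=[f"f{i}" for i in range(values.shape[0])])
    return ExpressionMatrix(data, unit, groups)


class TestLog2Transform:
    def test_values(self):
        m = _matrix([[0.0, 3.0]])
        t = log2_transform(m, pseudocount=1.0)
        assert t.data.iloc[0].tolist() == [0.0, 2.0]
        assert t.unit == "log2RPM"

    def test_double_transform_guarded(self):
        t = log2_transform(_matrix([[1.0, 1.0]]))
        with pytest.raises(ValueError, match="log2"):
            log2_transform(t)

    def test_inverse_recovers_input(self):
        m = _matrix(np.random.default_rng(1).uniform(0, 50, (4, 6)))
        t = log2_transform(m)
        back = 2.0 ** t.data - 1.0
        assert np.allclose(back, m.data, atol=1e-9)


class TestMedianFoldChange:
    def test_simple_ratio(self):
        assert median_fold_change([8, 8, 8], [2, 2, 2]) == pytest.approx(4.0)

    def test_identical_groups(self):
        assert median_fold_change([5, 7], [5, 7]) == pytest.approx(1.0)

    def test_all_zero_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero"):
            assert median_fold_change([0, 0], [0, 0]) == 1.0

    def test_scaling_equivariance(self):
        t, n = [3.0, 5.0, 9.0], [2.0, 4.0, 8.0]
        base = median_fold_change(t, n)
        scaled = median_fold_change([7.0 * x for x in t], n)
        assert scaled == pytest.approx(7.0 * base)

    def test_recovers_planted_log2fc(self):
        """Planted log2 FC ~ 2.56 recovered by the median estimator."""
        errs = []
        for seed in range(20):
            _, rpm = simulate_expression(ExpressionSimSpec(
                200, 60, 30, {"g0001": 2.56}, seed=1000 + seed))
            fc = median_fold_change(rpm.group_values("g0001", "tumor"),
                                    rpm.group_values("g0001", "normal"))
            errs.append(math.log2(fc) - 2.56)
        assert abs(np.median(errs)) < 0.5


class TestRankSum:
    def test_exact_two_sided(self):
        # 2 extreme assignments of C(4,2)=6 equally likely ones
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_pooled_values(self):
        _, p = rank_sum_test([5, 5], [5, 5, 5])
        assert p == 1.0

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(0.5, size=10)
            _, p_exact = rank_sum_test(x, y)  # n=20 tie-free -> exact
            from scipy.stats import mannwhitneyu
            p_approx = mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert abs(p_exact - p_approx) < 0.02

    def test_monotone_transform_invariance(self):
        x, y = [1.0, 3.0, 9.0], [2.0, 5.0, 30.0]
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(np.log(x), np.log(y))
        assert p1 == pytest.approx(p2)


class TestKruskal:
    def test_identical_groups(self):
        H, p = kruskal_wallis([1, 1, 1, 1, 1, 1], list("aabbcc"))
        assert (H, p) == (0.0, 1.0)

    def test_hand_computed_h(self):
        # rank sums 3, 7, 11 over groups {1,2},{3,4},{5,6}:
        # H = 12/(6*7) * (9 + 49 + 121)/2 - 3*7 = 32/7
        H, p = kruskal_wallis([1, 2, 3, 4, 5, 6], list("aabbcc"))
        assert H == pytest.approx(32 / 7)

    def test_shift_invariance(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        H1, _ = kruskal_wallis(vals, list("abcabc"))
        H2, _ = kruskal_wallis([v + 100 for v in vals], list("abcabc"))
        assert H1 == pytest.approx(H2)

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="rank_sum"):
            kruskal_wallis([1, 2, 3, 4], list("aabb"))


class TestBhFdr:
    def test_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=30))
    def test_min_fdr_at_least_min_p(self, ps):
        fdr = bh_fdr(ps)
        assert fdr.min() >= min(ps) - 1e-15
        assert (fdr <= 1.0 + 1e-15).all()


class TestValidateCandidates:
    @pytest.mark.parametrize("fc, fdr, expected, should_pass", [
        (5.89, 3.50e-26, "up", True),     # strong up candidate
        (0.52, 1.33e-12, "down", False),  # 0.52 > 0.5: fails symmetric cut
        (0.41, 1.43e-16, "down", True),
        (0.90, 3.29e-01, "down", False),
        (3.50, 1.10e-26, "up", True),
    ])
    def test_joint_cutoff_rule(self, fc, fdr, expected, should_pass):
        call = direction_call(fc, fdr, fdr_cut=0.05, fc_cut=2.0)
        assert (call == expected) is should_pass

    def test_end_to_end_on_planted_matrix(self):
        planted = {"g0001": 2.56, "g0002": -1.29, "g0003": 0.0}
        _, rpm = simulate_expression(ExpressionSimSpec(
            300, 100, 50, planted, seed=3))
        res = validate_candidates(rpm, {"g0001": "up", "g0002": "down",
                                        "g0003": "up"})
        assert {"g0001", "g0002"} <= res.passed
        assert "g0003" not in res.passed
        assert res.records["g0001"].direction == "up"

    def test_absent_candidate_is_a_miss_not_an_error(self):
        _, rpm = simulate_expression(ExpressionSimSpec(10, 5, 5, seed=4))
        res = validate_candidates(rpm, {"nope": "up", "g0001": "up"})
        assert res.misses == ["nope"]

    def test_disabled_cutoffs_pass_everything(self):
        _, rpm = simulate_expression(ExpressionSimSpec(20, 5, 5, seed=5))
        cands = {f: "up" for f in feature_ids(20)[:5]}
        res = validate_candidates(rpm, cands, fdr_cut=1.0, fc_cut=1.0)
        passed_or_down = {m for m, r in res.records.items()
                          if r.direction in ("up", "down")}
        assert passed_or_down == set(cands)


class TestNbDifferential:
    def test_null_calibration_single_run(self):
        raw, _ = simulate_expression(ExpressionSimSpec(1000, 30, 30, seed=6))
        recs, up, down = nb_differential(raw)
        assert (len(up) + len(down)) / len(recs) <= 0.01

    def test_planted_genes_detected(self):
        ids = feature_ids(1000)
        planted = {ids[i]: (2.0 if i % 2 else -2.0) for i in range(50)}
        raw, _ = simulate_expression(ExpressionSimSpec(
            1000, 30, 30, planted, seed=7))
        recs, up, down = nb_differential(raw)
        called = up | down
        tp = len(called & set(planted))
        assert tp / len(planted) >= 0.8
        assert (len(called) - tp) / max(1, len(called)) <= 0.15
        assert up <= {g for g, l in planted.items() if l > 0} | (called - set(planted))

    def test_library_size_invariance(self):
        raw, _ = simulate_expression(ExpressionSimSpec(200, 10, 10, seed=8))
        recs1, _, _ = nb_differential(raw)
        doubled = raw.data.copy()
        doubled.iloc[:, 0] *= 2
        m2 = ExpressionMatrix(doubled, "raw_count", raw.groups)
        recs2, _, _ = nb_differential(m2)
        lfc1 = np.array([r.log2_fc for r in recs1])
        lfc2 = np.array([r.log2_fc for r in recs2])
        assert np.allclose(lfc1, lfc2, atol=1e-6)

    def test_all_zero_gene_excluded_with_warning(self):
        raw, _ = simulate_expression(ExpressionSimSpec(50, 5, 5, seed=9))
        data = raw.data.copy()
        data.iloc[0] = 0.0
        m = ExpressionMatrix(data, "raw_count", raw.groups)
        with pytest.warns(UserWarning, match="all-zero"):
            recs, _, _ = nb_differential(m)
        assert len(recs) == 49

    def test_requires_counts(self):
        _, rpm = simulate_expression(ExpressionSimSpec(10, 5, 5, seed=10))
        with pytest.raises(ValueError, match="raw counts"):
            nb_differential(rpm)
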