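import numpy as np
import pandas as pd
import pytest

from mirmeta.targets import (TargetOverlapResult, consensus_predicted,
                             correlation_filter, correlation_matrix,
                             integrate_targets, overlap_selection,
                             shared_targets)
from mirmeta.synthetic import simulate_targets


class TestConsensus:
    def test_membership_counting(self):
        pred = {"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g3"}}
        assert consensus_predicted(pred) == {"g2", "g3"}

    def test_identical_sources(self):
        pred = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        assert consensus_predicted(pred) == {"g1", "g2"}

    def test_disjoint_sources_empty(self):
        assert consensus_predicted({"A": {"g1"}, "B": {"g2"}}) == set()

    def test_min_sources_antitone(self):
        pred = {"A": {"g1", "g2"}, "B": {"g2"}, "C": {"g2", "g3"}}
        sets = [consensus_predicted(pred, k) for k in (1, 2, 3)]
        assert sets[0] >= sets[1] >= sets[2]

    def test_min_sources_bound(self):
        with pytest.raises(ValueError, match="min_sources"):
            consensus_predicted({"A": {"g1"}}, min_sources=2)


class TestOverlap:
    def test_empty_input_gives_empty(self):
        assert overlap_selection(set(), {"g"}, {"g"}) == set()

    def test_idempotent_on_equal_sets(self):
        s = {"g1", "g2"}
        assert overlap_selection(s, s, s) == s

    def test_planted_triple_membership(self):
        true = {f"t{i}" for i in range(40)}
        noise = {f"n{i}" for i in range(20)}
        assert overlap_selection(true | noise, true | {"v"},
                                 true | {"d"}) == true


class TestCorrelationFilter:
    def _planted(self, rho=-0.4, n=400, n_genes=10, seed=17):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        z = rng.standard_normal(n)
        mir = pd.Series(z, index=samples, name="mir")
        rows = {}
        for g in range(n_genes):
            noise = rng.standard_normal(n)
            rows[f"g{g}"] = rho * z + np.sqrt(1 - rho ** 2) * noise
        return mir, pd.DataFrame(rows, index=samples).T

    def test_planted_anticorrelation_retained_with_sign(self):
        mir, genes = self._planted()
        retained, recs = correlation_filter(mir, genes)
        assert len(retained) >= 8
        assert all(r.r_s < 0 for r in recs if r.var_b in retained)

    def test_null_type_i_rate(self):
        mir, genes = self._planted(rho=0.0, n_genes=200, seed=18)
        retained, _ = correlation_filter(mir, genes, alpha=0.05)
        assert len(retained) / 200 < 0.12

    def test_alpha_one_retains_everything(self):
        mir, genes = self._planted(n_genes=5)
        retained, _ = correlation_filter(mir, genes, alpha=1.0)
        assert retained == set(genes.index)

    def test_expected_sign_mode(self):
        mir, genes = self._planted(rho=0.5, n_genes=5, seed=19)
        retained, _ = correlation_filter(mir, genes,
                                         expected_sign="negative")
        assert retained == set()

    def test_constant_gene_dropped(self):
        mir, genes = self._planted(n_genes=3)
        genes.iloc[0] = 7.0
        with pytest.warns(UserWarning, match="zero expression variance"):
            retained, recs = correlation_filter(mir, genes)
        assert genes.index[0] not in {r.var_b for r in recs}


class TestCorrelationMatrix:
    def test_identical_rows_cluster_adjacent(self):
        rng = np.random.default_rng(20)
        samples = [f"s{i}" for i in range(30)]
        base = rng.standard_normal(30)
        genes = pd.DataFrame(
            {"gA": base, "gZ": base,
             "gM": rng.standard_normal(30),
             "gQ": rng.standard_normal(30)},
            index=samples).T
        mirs = pd.DataFrame(rng.standard_normal((2, 30)),
                            index=["m1", "m2"], columns=samples)
        res = correlation_matrix(mirs, genes)
        ia, iz = res.row_order.index("gA"), res.row_order.index("gZ")
        assert abs(ia - iz) == 1

    def test_planted_block_structure_recovered(self):
        rng = np.random.default_rng(21)
        n = 120
        samples = [f"s{i}" for i in range(n)]
        up_driver = rng.standard_normal(n)
        down_driver = -up_driver
        rows = {}
        for i in range(6):
            rows[f"up{i}"] = up_driver + 0.5 * rng.standard_normal(n)
        for i in range(6):
            rows[f"dn{i}"] = down_driver + 0.5 * rng.standard_normal(n)
        genes = pd.DataFrame(rows, index=samples).T
        mirs = pd.DataFrame({"mU": up_driver, "mD": down_driver},
                            index=samples).T
        res = correlation_matrix(mirs, genes)
        order = res.row_order
        first_half = set(order[:6])
        assert first_half in ({f"up{i}" for i in range(6)},
                              {f"dn{i}" for i in range(6)})
        assert (res.values.loc["up0", "mU"] > 0
                and res.values.loc["up0", "mD"] < 0)

    def test_null_cells_scale_as_root_n(self):
        rng = np.random.default_rng(22)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        genes = pd.DataFrame(rng.standard_normal((10, n)),
                             index=[f"g{i}" for i in range(10)],
                             columns=samples)
        mirs = pd.DataFrame(rng.standard_normal((3, n)),
                            index=list("abc"), columns=samples)
        res = correlation_matrix(mirs, genes)
        assert np.abs(res.values.to_numpy()).mean() < 2 / np.sqrt(n)

    def test_orders_are_permutations(self):
        rng = np.random.default_rng(23)
        samples = [f"s{i}" for i in range(20)]
        genes = pd.DataFrame(rng.standard_normal((4, 20)),
                             index=list("wxyz"), columns=samples)
        mirs = pd.DataFrame(rng.standard_normal((2, 20)),
                            index=["m1", "m2"], columns=samples)
        res = correlation_matrix(mirs, genes)
        assert sorted(res.row_order) == list("wxyz")
        assert sorted(res.col_order) == ["m1", "m2"]


class TestSharedTargets:
    def _result(self, mirna, retained):
        retained = set(retained)
        return TargetOverlapResult(mirna, retained, retained, retained, [])

    def test_intersection_semantics(self):
        res = [self._result("a", {"g1", "g2"}),
               self._result("b", {"g2", "g3"}),
               self._result("c", {"g2"})]
        assert shared_targets(res) == {"g2"}
        assert shared_targets(list(reversed(res))) == {"g2"}

    def test_disjoint_sets_empty(self):
        assert shared_targets([self._result("a", {"g1"}),
                               self._result("b", {"g2"})]) == set()

    def test_subset_chain_enforced(self):
        with pytest.raises(ValueError, match="subset"):
            TargetOverlapResult("m", {"g1"}, {"g1", "g2"}, set(), [])

    def test_planted_shared_gene_recovered_end_to_end(self):
        sim = simulate_targets(
            ["miR-1", "miR-2", "miR-3"],
            anti_correlated_genes={"miR-1": {"GA"}, "miR-2": {"GB"},
                                   "miR-3": {"GC"}},
            shared_gene="GSHARED", seed=24)
        results, shared = integrate_targets(
            sim.collection, sim.truth["de_genes"],
            sim.mirna.data, sim.mrna.data)
        assert shared == {"GSHARED"}
        for res in results:
            assert res.retained_genes <= res.overlap_genes \
                <= res.consensus_predicted
            anti = sim.truth["planted_anti"].get(res.mirna_id, set())
            assert anti <= res.retained_genes

    def test_identical_sources_consensus(self):
        sim = simulate_targets(["miR-1"], source_overlap=1.0, seed=25)
        per_source = sim.collection.predicted_for("miR-1")
        cons = consensus_predicted(per_source)
        for genes in per_source.values():
            assert cons == genes
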