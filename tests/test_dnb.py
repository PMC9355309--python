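import numpy as np
import pandas as pd
import pytest

from tipdnb.dnb import (
    cluster_by_correlation,
    composite_index,
    evaluate_group,
    pcc_matrix,
    run_dnb,
    select_high_sd_genes,
    tipping_point,
)
from tipdnb.deg import normalize_log_cpm
from tipdnb.io_core import DesignError
from tipdnb.synthetic import DnbSpec, SimulationConfig, simulate_timecourse

from conftest import make_matrix
from oracles import brute_force_ci


class TestSelectHighSdGenes:
    def test_fold_rule(self):
        rng = np.random.default_rng(0)
        # gene 0: SD ~4 in group, ~1 in reference; gene 1: equal SDs
        ref = np.column_stack([rng.normal(8, 1, (2, 10))])
        grp = np.vstack([rng.normal(8, 4, (1, 10)), rng.normal(8, 1, (1, 10))])
        vals = np.hstack([ref, grp])
        m = make_matrix(vals, ["a"] * 10 + ["b"] * 10, ["a", "b"])
        sel = select_high_sd_genes(m, "b", "a", sd_fold=2.0)
        assert sel["gene_id"].tolist() == ["g0"]

    def test_identical_sds_select_nothing(self):
        rng = np.random.default_rng(1)
        half = rng.normal(8, 1, (20, 5))
        vals = np.hstack([half, half])  # identical replicate values per group
        m = make_matrix(vals, ["a"] * 5 + ["b"] * 5, ["a", "b"])
        sel = select_high_sd_genes(m, "b", "a", sd_fold=2.0)
        assert len(sel) == 0

    def test_zero_reference_sd_flagged(self):
        vals = np.array([[5.0, 5.0, 5.0, 1.0, 9.0, 5.0]])
        m = make_matrix(vals, ["a"] * 3 + ["b"] * 3, ["a", "b"])
        sel = select_high_sd_genes(m, "b", "a")
        assert sel["gene_id"].tolist() == ["g0"]
        assert bool(sel["flagged"].iloc[0])

    def test_requires_replicates(self):
        m = make_matrix(np.ones((2, 3)), ["a", "a", "b"], ["a", "b"])
        with pytest.raises(DesignError):
            select_high_sd_genes(m, "b", "a")

    def test_ftest_mode_finds_inflated_variance(self):
        rng = np.random.default_rng(4)
        vals = np.hstack([rng.normal(8, 1, (50, 10)), rng.normal(8, 1, (50, 10))])
        vals[:5, 10:] = rng.normal(8, 5, (5, 10))  # genes 0-4 strongly inflated in b
        m = make_matrix(vals, ["a"] * 10 + ["b"] * 10, ["a", "b"])
        sel = select_high_sd_genes(m, "b", "a", method="ftest", ftest_alpha=0.05)
        assert set(sel["gene_id"]) == {f"g{i}" for i in range(5)}

    def test_absolute_sd_mode_ignores_reference(self):
        rng = np.random.default_rng(5)
        vals = np.hstack([rng.normal(8, 2, (40, 10)), rng.normal(8, 1, (40, 10))])
        vals[:3, 10:] = rng.normal(8, 6, (3, 10))  # outliers within group b itself
        m = make_matrix(vals, ["a"] * 10 + ["b"] * 10, ["a", "b"])
        sel = select_high_sd_genes(m, "b", "a", sd_fold=3.0, use_reference=False)
        assert set(sel["gene_id"]) == {"g0", "g1", "g2"}

    def test_module_recall_with_planted_inflation(self):
        """A module with fourfold variance inflation is recovered at a 1.5
        SD-fold cut with 30 replicates."""
        cfg = SimulationConfig(
            n_genes=300, replicates=30,
            dnb=DnbSpec("IR22", module_size=20, variance_inflation=4.0,
                        intra_corr=0.6, inter_corr=0.0),
            seed=21,
        )
        matrix, truth = simulate_timecourse(cfg)
        log = normalize_log_cpm(matrix)
        sel = select_high_sd_genes(log, "IR22", "sham", sd_fold=1.5)
        recall = len(set(sel["gene_id"]) & set(truth.dnb_module)) / len(truth.dnb_module)
        assert recall >= 0.9


class TestPccMatrix:
    def test_unit_diagonal_and_symmetry(self, timecourse_matrix):
        genes = timecourse_matrix.gene_ids[:5]
        c = pcc_matrix(timecourse_matrix, "IR22", genes)
        np.testing.assert_allclose(np.diag(c.to_numpy()), 1.0)
        np.testing.assert_allclose(c.to_numpy(), c.to_numpy().T, atol=1e-15)

    def test_perfect_anticorrelation(self):
        vals = np.array([[1.0, 2, 3, 0, 0, 0], [3.0, 2, 1, 0, 0, 0]])
        m = make_matrix(vals, ["b"] * 3 + ["a"] * 3, ["a", "b"])
        c = pcc_matrix(m, "b", ["g0", "g1"])
        assert c.loc["g0", "g1"] == pytest.approx(-1.0)

    def test_hand_evaluated_pearson(self):
        # (1,2,3) vs (1,2,4): r = 1/√(28/27) = √(27/28)
        vals = np.array([[1.0, 2, 3, 0, 0, 0], [1.0, 2, 4, 0, 0, 0]])
        m = make_matrix(vals, ["b"] * 3 + ["a"] * 3, ["a", "b"])
        c = pcc_matrix(m, "b", ["g0", "g1"])
        assert c.loc["g0", "g1"] == pytest.approx(np.sqrt(27 / 28), abs=1e-12)

    def test_zero_variance_gene_gets_zero(self, caplog):
        vals = np.array([[1.0, 2, 3, 0, 0, 0], [5.0, 5, 5, 0, 0, 0]])
        m = make_matrix(vals, ["b"] * 3 + ["a"] * 3, ["a", "b"])
        with caplog.at_level("WARNING"):
            c = pcc_matrix(m, "b", ["g0", "g1"])
        assert c.loc["g0", "g1"] == 0.0
        assert c.loc["g1", "g1"] == 1.0


class TestClusterByCorrelation:
    @staticmethod
    def _block_pcc(sizes, within, between):
        n = sum(sizes)
        c = np.full((n, n), between, dtype=float)
        start = 0
        for s in sizes:
            c[start: start + s, start: start + s] = within
            start += s
        np.fill_diagonal(c, 1.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(c, index=genes, columns=genes)

    def test_forced_block_found(self):
        pcc = self._block_pcc([5, 8], within=0.95, between=0.05)
        big, _ = cluster_by_correlation(pcc, threshold=0.9, min_cluster_size=5)
        assert sorted(len(c) for c in big) == [5, 8]

    def test_weak_correlations_no_cluster(self):
        pcc = self._block_pcc([10], within=0.5, between=0.5)
        big, small = cluster_by_correlation(pcc, threshold=0.9, min_cluster_size=5)
        assert big == []
        assert len(small) == 10  # all singletons

    def test_two_blocks_match_connected_components(self):
        """On well-separated blocks the tree cut agrees with the connected
        components of the |PCC| ≥ 0.9 graph."""
        pcc = self._block_pcc([6, 7], within=0.95, between=0.1)
        big, _ = cluster_by_correlation(pcc, threshold=0.9, min_cluster_size=5)
        adj = np.abs(pcc.to_numpy()) >= 0.9
        np.fill_diagonal(adj, False)
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components(adj, directed=False)
        comps = {}
        for g, lab in zip(pcc.index, labels):
            comps.setdefault(lab, []).append(g)
        big_comps = sorted(
            [sorted(v) for v in comps.values() if len(v) >= 5], key=lambda c: (-len(c), c[0])
        )
        assert big == big_comps

    def test_threshold_range_checked(self):
        pcc = self._block_pcc([5], within=0.95, between=0.0)
        with pytest.raises(ValueError):
            cluster_by_correlation(pcc, threshold=1.2)

    def test_component_mode_agrees_on_separated_blocks(self):
        pcc = self._block_pcc([6, 7], within=0.95, between=0.1)
        avg, _ = cluster_by_correlation(pcc, 0.9, 5, method="average")
        comp, _ = cluster_by_correlation(pcc, 0.9, 5, method="components")
        assert avg == comp


class TestCompositeIndex:
    def test_ratio_identity_pcc1_equals_pcc0(self):
        assert composite_index(7.3, 0.5, 0.5) == pytest.approx(7.3, abs=1e-15)

    def test_random_triples_match_direct_evaluation(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            sd = float(rng.uniform(0, 20))
            p1 = float(rng.uniform(0, 1))
            p0 = float(rng.uniform(1e-3, 1))
            assert composite_index(sd, p1, p0) == pytest.approx(sd * p1 / p0, abs=1e-15)

    def test_degenerate_cluster_rejected(self):
        with pytest.raises(ValueError, match="pcc0"):
            composite_index(1.0, 0.5, 1e-9)

    def test_monotonicity(self):
        assert composite_index(2.0, 0.8, 0.4) > composite_index(1.0, 0.8, 0.4)
        assert composite_index(1.0, 0.8, 0.2) > composite_index(1.0, 0.8, 0.4)


class TestEvaluateGroup:
    @staticmethod
    def _random_instance(seed, n_genes=50, n_groups=5, reps=3):
        rng = np.random.default_rng(seed)
        groups = [f"grp{j}" for j in range(n_groups)]
        # heterogeneous per-gene, per-group SDs so selection is non-trivial
        sds = rng.uniform(0.3, 3.0, size=(n_genes, n_groups))
        vals = np.hstack(
            [rng.normal(8, sds[:, [j]], size=(n_genes, reps)) for j in range(n_groups)]
        )
        per_sample = [g for g in groups for _ in range(reps)]
        return make_matrix(vals, per_sample, groups), groups

    def test_pipeline_ci_matches_brute_force_oracle(self):
        """Every reported cluster CI equals a from-scratch recomputation
        (direct SDs and all-pairs Pearson from the raw replicate values)."""
        checked = 0
        for seed in range(50):
            m, groups = self._random_instance(seed)
            for group in groups[1:]:
                res = evaluate_group(m, group, sd_fold=1.2, pcc_threshold=0.6,
                                     min_cluster_size=3)
                if not res.clusters:
                    continue
                cols = m.columns_of(group)
                idx = m.gene_index()
                selected = res.selected["gene_id"].tolist()
                values_by_gene = {g: m.values[idx[g], cols].tolist() for g in selected}
                for stat in res.clusters:
                    if stat.ci is None:
                        continue
                    ci, mean_sd, pcc1, pcc0 = brute_force_ci(
                        values_by_gene, stat.genes, selected
                    )
                    assert stat.ci == pytest.approx(ci, abs=1e-12)
                    assert stat.mean_sd == pytest.approx(mean_sd, abs=1e-12)
                    assert stat.pcc1 == pytest.approx(pcc1, abs=1e-12)
                    assert stat.pcc0 == pytest.approx(pcc0, abs=1e-12)
                    checked += 1
        assert checked >= 20  # the oracle actually exercised

    def test_reference_against_itself_selects_nothing(self, timecourse_matrix):
        res = evaluate_group(timecourse_matrix, "sham", "sham", sd_fold=2.0)
        assert res.selected_gene_number == 0
        assert res.best_cluster is None

    def test_no_candidate_cluster_is_flagged_not_raised(self, timecourse_matrix):
        res = evaluate_group(timecourse_matrix, "IR22", sd_fold=50.0)
        assert res.best_cluster is None
        assert res.ci is None

    def test_ci_invariant_under_gene_and_replicate_permutation(self):
        m, groups = self._random_instance(99)
        res1 = evaluate_group(m, groups[1], sd_fold=1.2, pcc_threshold=0.6, min_cluster_size=3)
        rng = np.random.default_rng(0)
        gperm = rng.permutation(m.n_genes)
        # permute genes, and swap replicate columns within the evaluated group
        cols = np.arange(m.n_samples)
        gc = m.columns_of(groups[1])
        cols[gc] = gc[::-1]
        m2 = make_matrix(
            m.values[np.ix_(gperm, cols)],
            [m.design.sample_to_group[m.sample_ids[c]] for c in cols],
            m.design.group_order,
            gene_ids=[m.gene_ids[i] for i in gperm],
        )
        res2 = evaluate_group(m2, groups[1], sd_fold=1.2, pcc_threshold=0.6, min_cluster_size=3)
        if res1.best_cluster is None:
            assert res2.best_cluster is None
        else:
            assert res2.ci == pytest.approx(res1.ci, abs=1e-9)
            assert sorted(res2.best_cluster.genes) == sorted(res1.best_cluster.genes)

    def test_genome_wide_pcc0_universe(self):
        """With pcc0_universe='all', PCC0 runs against every other gene in
        the matrix; for a decoupled planted module that drops PCC0 and
        raises CI relative to the selected-only universe."""
        cfg = SimulationConfig(
            n_genes=300, replicates=10,
            dnb=DnbSpec("IR22", module_size=15, variance_inflation=4.0,
                        intra_corr=0.9, inter_corr=0.1),
            seed=8,
        )
        matrix, _ = simulate_timecourse(cfg)
        # raw log2 scale: the planted correlation structure without the
        # library-size coupling CPM introduces
        log = make_matrix(
            np.log2(matrix.values + 0.5),
            [matrix.design.sample_to_group[s] for s in matrix.sample_ids],
            matrix.design.group_order,
            gene_ids=matrix.gene_ids,
        )
        sel = evaluate_group(log, "IR22", pcc0_universe="selected")
        full = evaluate_group(log, "IR22", pcc0_universe="all")
        assert sel.best_cluster is not None and full.best_cluster is not None
        # n = 10 sample correlations fold to |PCC| ≈ 0.3 even at a true
        # background correlation of 0.1; the genome-wide universe must still
        # sit well below the selected-only universe (other high-SD genes)
        assert full.best_cluster.pcc0 < 0.35
        assert full.best_cluster.pcc0 < sel.best_cluster.pcc0
        assert full.best_cluster.ci > sel.best_cluster.ci

    def test_synthetic_tipping_group_module_recovered(self):
        cfg = SimulationConfig(
            n_genes=500, replicates=10,
            dnb=DnbSpec("IR22", module_size=20, variance_inflation=4.0,
                        intra_corr=0.9, inter_corr=0.1),
            seed=17,
        )
        matrix, truth = simulate_timecourse(cfg)
        log = normalize_log_cpm(matrix)
        res = evaluate_group(log, "IR22")
        assert res.best_cluster is not None
        got = set(res.best_cluster.genes)
        planted = set(truth.dnb_module)
        jaccard = len(got & planted) / len(got | planted)
        assert jaccard >= 0.6


class TestTippingPoint:
    def test_reported_ci_profile_argmax(self):
        """The group with the largest CI wins; checked on the canonical
        five-group CI profile where the middle group peaks."""
        from tipdnb.dnb import DnbClusterStats, DnbGroupResult

        cis = {"IR16": 18.15, "IR18": 19.43, "IR22": 23.32, "IR26": 19.10, "IR30": 19.35}
        results = []
        for g, ci in cis.items():
            stat = DnbClusterStats(g, ["a", "b"], ci, 1.0, 1.0, ci)
            results.append(
                DnbGroupResult(group=g, selected=pd.DataFrame({"gene_id": ["a", "b"]}),
                               clusters=[stat], best_cluster=stat)
            )
        winner, table = tipping_point(results)
        assert winner == "IR22"
        assert list(table["group"]) == list(cis)

    def test_single_defined_ci_wins_with_warning(self, caplog):
        from tipdnb.dnb import DnbClusterStats, DnbGroupResult

        stat = DnbClusterStats("b", ["x", "y"], 1.0, 0.9, 0.3, 3.0)
        results = [
            DnbGroupResult(group="b", selected=pd.DataFrame({"gene_id": ["x", "y"]}),
                           clusters=[stat], best_cluster=stat),
            DnbGroupResult(group="c", selected=pd.DataFrame({"gene_id": []})),
        ]
        with caplog.at_level("WARNING"):
            winner, _ = tipping_point(results)
        assert winner == "b"
        assert any("low-confidence" in r.message for r in caplog.records)

    def test_all_undefined_reports_no_transition(self, caplog):
        from tipdnb.dnb import DnbGroupResult

        results = [DnbGroupResult(group="b", selected=pd.DataFrame({"gene_id": []}))]
        with caplog.at_level("WARNING"):
            winner, table = tipping_point(results)
        assert winner is None
        assert table["CI"].isna().all()

    def test_run_dnb_recovers_planted_group(self):
        cfg = SimulationConfig(
            n_genes=500, replicates=10,
            dnb=DnbSpec("IR22", module_size=20, variance_inflation=4.0,
                        intra_corr=0.9, inter_corr=0.1),
            seed=33,
        )
        matrix, truth = simulate_timecourse(cfg)
        winner, table, _ = run_dnb(normalize_log_cpm(matrix))
        assert winner == truth.tipping_group
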