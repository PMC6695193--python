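import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from methdriver import (
    ClinicalTable,
    OmicsMatrix,
    associate_clusters,
    consensus_cluster,
    fisher_exact,
    gene_set_enrichment,
    intra_inter_consensus,
    pac_score,
    tumor_marker_enrichment,
)
from methdriver.data_io import DataError


def _hypergeom_two_sided(table):
    """Oracle: sum of hypergeometric probabilities <= the observed
    table's, enumerated over the full support with fixed margins."""
    a, b, c, d = np.asarray(table).ravel()
    n_total = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n_total), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n_total, r1, c1)
    p_obs = hypergeom.pmf(a, n_total, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestPacScore:
    def test_crisp_consensus_scores_zero(self):
        C = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=float)
        assert pac_score(C) == 0.0

    def test_fully_ambiguous_scores_one(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        assert pac_score(C) == 1.0

    def test_half_ambiguous_counts_directly(self):
        C = np.zeros((4, 4))
        np.fill_diagonal(C, 1.0)
        C[0, 1] = C[0, 2] = C[1, 2] = 0.5  # 3 of 6 upper-triangle entries
        C = np.maximum(C, C.T)
        assert pac_score(C) == 0.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        C = rng.random((8, 8))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        perm = rng.permutation(8)
        assert pac_score(C) == pytest.approx(pac_score(C[np.ix_(perm, perm)]))


class TestIntraInterConsensus:
    def test_perfect_block_matrix(self):
        C = np.zeros((6, 6))
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        intra, inter = intra_inter_consensus(C, [1, 1, 1, 2, 2, 2])
        assert intra == 100.0 and inter == 0.0

    def test_constant_consensus(self):
        C = np.full((6, 6), 0.3)
        np.fill_diagonal(C, 1.0)
        intra, inter = intra_inter_consensus(C, [1, 1, 1, 2, 2, 2])
        assert intra == pytest.approx(30.0) and inter == pytest.approx(30.0)

    def test_hand_enumerated_five_samples(self):
        rng = np.random.default_rng(1)
        C = rng.random((5, 5))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        labels = np.array([1, 1, 1, 2, 2])
        intra_pairs = [(0, 1), (0, 2), (1, 2), (3, 4)]
        inter_pairs = [(0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4)]
        want_intra = np.mean([C[i, j] for i, j in intra_pairs]) * 100
        want_inter = np.mean([C[i, j] for i, j in inter_pairs]) * 100
        intra, inter = intra_inter_consensus(C, labels)
        assert intra == pytest.approx(want_intra)
        assert inter == pytest.approx(want_inter)

    def test_single_cluster_errors(self):
        with pytest.raises(DataError):
            intra_inter_consensus(np.eye(4), [1, 1, 1, 1])


class TestConsensusCluster:
    def test_single_full_subsample_equals_one_kmeans_run(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (6, 3)), rng.normal(5, 0.3, (6, 3))])
        res = consensus_cluster(X, k_range=[2], n_boot=1, subsample_frac=1.0, seed=0)
        C = res.per_k[2].consensus.to_numpy()
        assert set(np.unique(C)) <= {0.0, 1.0}

    def test_two_groups_separate_cleanly(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (15, 10)), rng.normal(10, 1, (15, 10))])
        res = consensus_cluster(X, k_range=[2], n_boot=50, seed=1)
        r = res.per_k[2]
        truth = np.array([0] * 15 + [1] * 15)
        same_truth = truth[:, None] == truth[None, :]
        C = r.consensus.to_numpy()
        iu = np.triu_indices(30, k=1)
        assert np.nanmin(C[iu][same_truth[iu]]) > 0.95
        assert np.nanmax(C[iu][~same_truth[iu]]) < 0.05
        assert r.pac < 0.05 and r.intra > 95 and r.inter < 25

    def test_consensus_matrix_structure(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (12, 5))
        res = consensus_cluster(X, k_range=[2, 3], n_boot=20, seed=2)
        for r in res.per_k.values():
            C = r.consensus.to_numpy()
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            np.testing.assert_array_equal(np.diag(C), 1.0)
            finite = C[np.isfinite(C)]
            assert finite.min() >= 0 and finite.max() <= 1
            assert sorted(r.labels.unique()) == list(range(1, r.k + 1))

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            consensus_cluster(np.zeros((5, 3)), k_range=[2])

    def test_heatmap_export_writes_png(self, tmp_path):
        from methdriver.evaluation import plot_consensus_heatmap

        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (8, 4)), rng.normal(6, 1, (8, 4))])
        res = consensus_cluster(X, k_range=[2], n_boot=10, seed=3)
        out = tmp_path / "consensus.png"
        plot_consensus_heatmap(res.per_k[2], out)
        assert out.stat().st_size > 0


class TestAssociateClusters:
    def _clinical(self, df, types):
        return ClinicalTable(table=df, column_types=types)

    def test_perfectly_associated_categorical(self):
        idx = [f"S{i}" for i in range(60)]
        labels = pd.Series([1] * 30 + [2] * 30, index=idx)
        clin = self._clinical(
            pd.DataFrame({"subtype": ["A"] * 30 + ["B"] * 30}, index=idx),
            {"subtype": "categorical"},
        )
        out = associate_clusters(labels, clin).set_index("feature")
        assert out.loc["subtype", "p_value"] < 1e-10
        assert out.loc["subtype", "test"] == "chi2"

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        idx = [f"S{i}" for i in range(60)]
        pvals = []
        for _ in range(200):
            labels = pd.Series(rng.integers(1, 3, 60), index=idx)
            clin = self._clinical(
                pd.DataFrame({"grade": rng.integers(1, 5, 60)}, index=idx),
                {"grade": "ordinal"},
            )
            out = associate_clusters(labels, clin)
            pvals.append(out["p_value"].iloc[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_kruskal_matches_closed_form_for_tie_free_ranks(self):
        # 6 samples, 2 clusters, values = distinct ranks 1..6
        idx = [f"S{i}" for i in range(6)]
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=idx)
        clin = self._clinical(
            pd.DataFrame({"grade": [1, 2, 3, 4, 5, 6]}, index=idx),
            {"grade": "ordinal"},
        )
        out = associate_clusters(labels, clin)
        n = 6
        h = 12 / (n * (n + 1)) * (3 * 2**2 + 3 * 5**2) - 3 * (n + 1)
        assert out["statistic"].iloc[0] == pytest.approx(h)

    def test_single_level_feature_untestable(self):
        idx = [f"S{i}" for i in range(10)]
        labels = pd.Series([1] * 5 + [2] * 5, index=idx)
        clin = self._clinical(
            pd.DataFrame({"stage": [2] * 10}, index=idx), {"stage": "ordinal"}
        )
        out = associate_clusters(labels, clin)
        assert out["note"].iloc[0] == "single_level_untestable"
        assert np.isnan(out["p_value"].iloc[0])


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        _, p = fisher_exact([[2, 2], [2, 2]])
        assert p == 1.0

    def test_zero_margin_p_one(self):
        _, p = fisher_exact([[0, 0], [5, 7]])
        assert p == 1.0

    @pytest.mark.parametrize(
        "table",
        [
            [[0, 10], [10, 0]],
            [[5, 1], [2, 8]],
            [[3, 7], [9, 2]],
            [[1, 0], [0, 1]],
            [[12, 3], [4, 11]],
        ],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        _, p = fisher_exact(table)
        assert p == pytest.approx(_hypergeom_two_sided(table), rel=1e-9)

    def test_odds_ratio_definition(self):
        odds, _ = fisher_exact([[6, 2], [3, 4]])
        assert odds == pytest.approx((6 * 4) / (2 * 3))

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestTumorMarkerEnrichment:
    def _expr(self, X):
        X = np.asarray(X, dtype=float)
        return OmicsMatrix(
            pd.DataFrame(
                X,
                index=[f"S{i}" for i in range(X.shape[0])],
                columns=[f"G{j}" for j in range(X.shape[1])],
            )
        )

    def test_empty_driver_list(self):
        rng = np.random.default_rng(6)
        expr = self._expr(rng.normal(0, 1, (30, 10)))
        stage = pd.Series(rng.integers(1, 5, 30), index=expr.values.index)
        enr = tumor_marker_enrichment(expr, stage, set(), set(expr.gene_ids))
        assert enr.overlap == [] and enr.p_value == 1.0

    def test_fisher_on_constructed_overlap(self):
        # markers and drivers planted so the 2x2 table is fully known
        rng = np.random.default_rng(7)
        n, n_genes = 80, 60
        stage = rng.integers(1, 5, n).astype(float)
        X = rng.normal(0, 0.05, (n, n_genes))  # low variance background
        marker_genes = [f"G{j}" for j in range(12)]
        for j in range(12):  # strong stage coupling and high variance
            X[:, j] = stage * 2 + rng.normal(0, 0.5, n)
        expr = self._expr(X)
        drivers = {f"G{j}" for j in range(6, 18)}  # 6 markers among 12 drivers
        enr = tumor_marker_enrichment(
            expr, pd.Series(stage, index=expr.values.index),
            drivers, set(expr.gene_ids),
        )
        assert set(marker_genes) <= set(enr.markers)
        assert {f"G{j}" for j in range(6, 12)} <= set(enr.overlap)
        # the reported p must equal the exact hypergeometric oracle on the
        # 2x2 table implied by the reported marker/driver sets
        markers = set(enr.markers)
        a = len(markers & drivers)
        b = len(drivers - markers)
        c = len(markers - drivers)
        d = 60 - a - b - c
        assert enr.p_value == pytest.approx(
            _hypergeom_two_sided([[a, b], [c, d]]), rel=1e-9
        )

    def test_direction_rule_excludes_inconsistent_gene(self):
        rng = np.random.default_rng(8)
        n = 60
        stage = rng.integers(1, 5, n).astype(float)
        X = rng.normal(0, 0.05, (n, 5))
        X[:, 0] = stage * 2 + rng.normal(0, 0.5, n)  # positively correlated
        X[:, 1] = -stage * 2 + rng.normal(0, 0.5, n)  # negatively correlated
        expr = self._expr(X)
        stage_s = pd.Series(stage, index=expr.values.index)
        bg = set(expr.gene_ids)
        no_dir = tumor_marker_enrichment(expr, stage_s, {"G0"}, bg)
        assert "G0" in no_dir.markers and "G1" in no_dir.markers
        hyper_dir = tumor_marker_enrichment(
            expr, stage_s, {"G0"}, bg, directions={"G0": "hyper", "G1": "hyper"}
        )
        # hyper-methylated candidates must lose expression with progression
        assert "G0" not in hyper_dir.markers and "G1" in hyper_dir.markers

    def test_drivers_outside_background_rejected(self):
        rng = np.random.default_rng(9)
        expr = self._expr(rng.normal(0, 1, (20, 4)))
        stage = pd.Series(rng.integers(1, 5, 20), index=expr.values.index)
        with pytest.raises(ValueError):
            tumor_marker_enrichment(expr, stage, {"NOT_A_GENE"}, set(expr.gene_ids))


class TestGeneSetEnrichment:
    def test_exact_term_match_is_top_hit(self):
        background = {f"G{i}" for i in range(50)}
        terms = {
            "hit": {f"G{i}" for i in range(10)},
            "other": {f"G{i}" for i in range(25, 40)},
        }
        out = gene_set_enrichment({f"G{i}" for i in range(10)}, terms, background)
        assert out.iloc[0]["term"] == "hit"
        assert out.iloc[0]["p_value"] < out.iloc[1]["p_value"]

    def test_overlap_counts_match_set_intersection(self):
        rng = np.random.default_rng(10)
        background = {f"G{i}" for i in range(100)}
        terms = {
            f"t{k}": set(rng.choice(sorted(background), 15, replace=False))
            for k in range(5)
        }
        query = set(rng.choice(sorted(background), 20, replace=False))
        out = gene_set_enrichment(query, terms, background).set_index("term")
        for name, tset in terms.items():
            assert out.loc[name, "n_overlap"] == len(query & tset)

    def test_term_without_background_overlap_skipped(self):
        out = gene_set_enrichment(
            {"G1"}, {"ghost": {"X1", "X2"}}, {"G1", "G2", "G3"}
        )
        assert len(out) == 0

    def test_null_queries_control_fdr(self):
        rng = np.random.default_rng(11)
        background = [f"G{i}" for i in range(200)]
        terms = {
            f"t{k}": set(rng.choice(background, 20, replace=False))
            for k in range(20)
        }
        false_calls = 0
        n_sim = 200
        for _ in range(n_sim):
            query = set(rng.choice(background, 15, replace=False))
            out = gene_set_enrichment(query, terms, set(background))
            false_calls += int((out["q_value"] <= 0.1).sum() > 0)
        assert false_calls / n_sim <= 0.15
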