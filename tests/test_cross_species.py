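"""Ortholog filtering, PCA, Ward clustering, validation statistics, OGGs."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from olfatlas.cross_species import (
    assign_oggs,
    cluster_high_abundance_test,
    filter_orthologs,
    pca_correlation,
    pearson_gamma,
    select_cluster_count,
    silhouette,
    ward_cluster,
    wb_ratio,
)
from olfatlas.ligand_enrichment import binom_two_tail
from conftest import (
    brute_pearson_gamma,
    brute_silhouette,
    brute_wb_ratio,
    random_dissimilarity_instance,
)


class TestFilterOrthologs:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["group_id", "s1", "s2", "aa_identity_to_human"])

    def test_boundary_aa_identity(self):
        table = self._table([("g1", "a1", "b1", 39.9), ("g2", "a2", "b2", 40.0)])
        flags = {
            "s1": pd.Series(True, index=["a1", "a2"]),
            "s2": pd.Series(True, index=["b1", "b2"]),
        }
        kept = filter_orthologs(table, flags, ["s1", "s2"])
        assert kept["group_id"].tolist() == ["g2"]

    def test_missing_member_dropped(self):
        table = self._table([("g1", "a1", None, 80.0)])
        flags = {"s1": pd.Series(True, index=["a1"]), "s2": pd.Series(dtype=bool)}
        assert filter_orthologs(table, flags, ["s1", "s2"]).empty

    def test_unexpressed_everywhere_dropped(self):
        table = self._table([("g1", "a1", "b1", 80.0)])
        flags = {
            "s1": pd.Series(False, index=["a1"]),
            "s2": pd.Series(False, index=["b1"]),
        }
        assert filter_orthologs(table, flags, ["s1", "s2"]).empty

    def test_species_without_expression_data_errors(self):
        table = self._table([("g1", "a1", "b1", 80.0)])
        with pytest.raises(KeyError, match="s2"):
            filter_orthologs(table, {"s1": pd.Series(True, index=["a1"])}, ["s1", "s2"])


class TestPcaCorrelation:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"u": x, "v": 3 * x + 1})
        res = pca_correlation(df)
        np.testing.assert_allclose(res.variance_explained, [100.0, 0.0], atol=1e-9)

    def test_orthogonal_contrasts_split_evenly(self):
        # two exactly uncorrelated variables -> eigenvalues of the 2x2 identity
        df = pd.DataFrame({"u": [1.0, 1.0, -1.0, -1.0], "v": [1.0, -1.0, 1.0, -1.0]})
        res = pca_correlation(df)
        np.testing.assert_allclose(res.variance_explained, [50.0, 50.0], atol=1e-9)

    def test_variance_sums_and_orthonormal_loadings(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        res = pca_correlation(df)
        assert res.variance_explained.sum() == pytest.approx(100.0)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-9)

    def test_reconstruction(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(25, 4)))
        res = pca_correlation(df)
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(Z @ res.loadings.to_numpy(), res.scores.to_numpy(), atol=1e-9)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_correlation(df)


class TestWardCluster:
    def test_separation_1d(self):
        X = np.array([[0.0], [0.1], [10.0]])
        labels = ward_cluster(X, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (15, 3)), rng.normal(8, 0.3, (15, 3))])
        labels = ward_cluster(X, 2)
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(5, 0.3, (8, 2))])
        labels = ward_cluster(X, 2)
        perm = rng.permutation(len(X))
        labels_p = ward_cluster(X[perm], 2)
        # same partition after inverting the permutation
        a = labels[perm]
        agree = (labels_p == a).all() or ((labels_p != a).all() and len(set(labels_p)) == 2)
        assert agree

    def test_k_exceeds_n_errors(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((3, 2)), 4)


class TestValidationStatistics:
    def test_silhouette_hand_example(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        D = np.abs(pts[:, None] - pts[None, :])
        labels = [1, 1, 2, 2]
        # hand per-point values: (b-a)/max(a,b) with a=0.1, b in {10.05, 9.95}
        assert silhouette(D, labels) == pytest.approx(0.98999975, abs=1e-6)

    def test_all_identical_points_zero(self):
        D = np.zeros((4, 4))
        assert silhouette(D, [1, 1, 2, 2]) == 0.0

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([0.0, 0.2, 9.0])
        D = np.abs(pts[:, None] - pts[None, :])
        # singleton {9.0}: s=0 by convention; other two get positive s
        assert silhouette(D, [1, 1, 2]) > 0

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 3)), [1, 1, 1])

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(100):
            X = rng.normal(size=(20, 3))
            D = squareform(pdist(X))
            labels = rng.integers(1, 3, size=20)
            if len(np.unique(labels)) < 2:
                continue
            vals.append(silhouette(D, labels))
        assert abs(np.mean(vals)) < 0.2

    def test_pearson_gamma_separated_blobs(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        D = np.abs(pts[:, None] - pts[None, :])
        assert pearson_gamma(D, [1, 1, 2, 2]) == pytest.approx(1.0, abs=0.01)

    def test_pearson_gamma_permutation_null(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        D = squareform(pdist(X))
        vals = []
        for _ in range(200):
            labels = rng.permutation([1] * 6 + [2] * 6)
            vals.append(pearson_gamma(D, labels))
        assert abs(np.mean(vals)) < 0.05

    def test_wb_hand_example(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        D = np.abs(pts[:, None] - pts[None, :])
        # within pairs: 0.1, 0.1 -> mean 0.1; between: 10, 10.1, 9.9, 10 -> mean 10
        assert wb_ratio(D, [1, 1, 2, 2]) == pytest.approx(0.1 / 10.0, abs=1e-12)

    def test_wb_scale_invariance(self):
        D, labels = random_dissimilarity_instance(np.random.default_rng(6))
        assert wb_ratio(3.7 * D, labels) == pytest.approx(wb_ratio(D, labels))

    def test_wb_random_labels_near_one(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(100):
            X = rng.normal(size=(16, 3))
            D = squareform(pdist(X))
            labels = rng.permutation([1] * 8 + [2] * 8)
            vals.append(wb_ratio(D, labels))
        assert abs(np.mean(vals) - 1.0) < 0.1

    @pytest.mark.parametrize("stat,oracle", [
        (silhouette, brute_silhouette),
        (pearson_gamma, brute_pearson_gamma),
        (wb_ratio, brute_wb_ratio),
    ])
    def test_matches_brute_force_oracle(self, stat, oracle):
        rng = np.random.default_rng(8)
        for _ in range(200):
            D, labels = random_dissimilarity_instance(rng)
            assert stat(D, labels) == pytest.approx(oracle(D, labels), abs=1e-10)

    def test_silhouette_matches_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        for _ in range(20):
            X = rng.normal(size=(15, 3))
            D = squareform(pdist(X))
            labels = rng.integers(0, 3, size=15)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(D, labels) == pytest.approx(
                silhouette_score(D, labels, metric="precomputed"), abs=1e-9
            )


class TestSelectClusterCount:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_planted_blobs(self, k_true):
        rng = np.random.default_rng(10 + k_true)
        centers = rng.normal(scale=12, size=(k_true, 5))
        X = np.vstack([c + rng.normal(scale=1, size=(20, 5)) for c in centers])
        k_star, diags = select_cluster_count(X)
        assert k_star == k_true
        assert [d.k for d in diags] == list(range(2, 9))

    def test_diagnostics_ranges(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        _, diags = select_cluster_count(X, range(2, 5))
        for d in diags:
            assert -1 <= d.asw <= 1
            assert -1 <= d.pearson_gamma <= 1
            assert d.wb_ratio > 0
            assert len(np.unique(d.labels)) == d.k

    def test_too_few_objects(self):
        with pytest.raises(ValueError):
            select_cluster_count(np.zeros((5, 2)), range(2, 9))


class TestAssignOggs:
    def test_planted_groups_recovered(self, cfg, catalogs, orthology, species_data):
        table, truth = orthology
        abundances = {sp: species_data[sp]["abundance"] for sp in cfg.species}
        ogg, z = assign_oggs(table, catalogs, abundances, list(cfg.species))
        assert len(ogg) == 73
        assert set(ogg["group_id"]) == set(truth["group_id"])

    def test_class_prefixes(self, cfg, catalogs, orthology, species_data):
        table, truth = orthology
        abundances = {sp: species_data[sp]["abundance"] for sp in cfg.species}
        ogg, _ = assign_oggs(table, catalogs, abundances, list(cfg.species))
        n1 = ogg["ogg_id"].str.startswith("OGG1-").sum()
        n2 = ogg["ogg_id"].str.startswith("OGG2-").sum()
        assert (n1, n2) == (18, 55)
        # prefix consistent with member class
        assert (ogg.loc[ogg["or_class"] == "I", "ogg_id"].str.startswith("OGG1-")).all()

    def test_rows_standardized(self, cfg, catalogs, orthology, species_data):
        table, _ = orthology
        abundances = {sp: species_data[sp]["abundance"] for sp in cfg.species}
        _, z = assign_oggs(table, catalogs, abundances, list(cfg.species))
        vals = z.to_numpy()
        varying = vals.std(axis=1) > 0
        np.testing.assert_allclose(vals[varying].mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(vals[varying].std(axis=1), 1, atol=1e-9)

    def test_pseudogene_member_excluded(self, cfg, catalogs, species_data):
        # build a 2-group table: one all-intact, one with a pseudogene member
        abundances = {sp: species_data[sp]["abundance"] for sp in cfg.species}
        row_ok, row_bad = {"group_id": "gA"}, {"group_id": "gB"}
        for sp in cfg.species:
            cat = catalogs[sp]
            intact = cat.index[(cat["status"] == "intact") & (cat["or_class"] == "II")]
            row_ok[sp] = intact[0]
            row_bad[sp] = intact[1]
        sp1 = cfg.species[1]
        row_bad[sp1] = catalogs[sp1].index[catalogs[sp1]["status"] == "pseudogene"][0]
        table = pd.DataFrame([row_ok, row_bad])
        ogg, _ = assign_oggs(table, catalogs, abundances, list(cfg.species))
        assert ogg["group_id"].tolist() == ["gA"]


class TestClusterHighAbundance:
    def test_binomial_against_enumeration(self):
        ogg = pd.DataFrame({"s1": [f"g{i}" for i in range(12)]})
        labels = np.ones(12, dtype=int)
        top = {"s1": {f"g{i}" for i in range(6)}}
        res = cluster_high_abundance_test(ogg, labels, top, ["s1"])
        assert len(res) == 1
        assert res.loc[0, "k"] == 6 and res.loc[0, "n"] == 12
        assert res.loc[0, "p_two_tail"] == pytest.approx(binom_two_tail(6, 12, 0.1))

    def test_zero_hits_small_cluster(self):
        ogg = pd.DataFrame({"s1": ["g0", "g1", "g2"]})
        res = cluster_high_abundance_test(ogg, [1, 1, 1], {"s1": set()}, ["s1"])
        assert res.loc[0, "p_two_tail"] == 1.0

    def test_planted_enrichment_power(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            k = rng.binomial(12, 0.5)
            p = binom_two_tail(k, 12, 0.1)
            rejections += p < 0.05
        assert rejections / n_rep >= 0.9
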