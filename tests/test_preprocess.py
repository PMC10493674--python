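import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from braincomm import preprocess, simulate
from braincomm.preprocess import (
    OTHER_CELLS,
    annotate_clusters,
    embed_cluster,
    filter_cells,
    normalize_log,
    select_hvg,
)
from conftest import make_adata


class TestFilterCells:
    def test_strict_20_percent_threshold(self):
        # mito fractions 0, .10, .20, .21, .50 on a 100-count budget -> 3 survive
        counts = np.array([[100, 0], [90, 10], [80, 20], [79, 21], [50, 50]], dtype=float)
        adata = make_adata(counts, mt_flags=[False, True])
        out = filter_cells(adata)
        assert out.n_obs == 3
        assert list(out.obs_names) == ["c0", "c1", "c2"]

    def test_no_mito_flags_keeps_everything(self):
        adata = make_adata(np.ones((4, 3)), mt_flags=[False] * 3)
        assert filter_cells(adata).n_obs == 4

    def test_zero_count_cell_removed(self):
        adata = make_adata(np.array([[1.0, 1.0], [0.0, 0.0]]), mt_flags=[False, False])
        out = filter_cells(adata)
        assert list(out.obs_names) == ["c0"]

    def test_idempotent(self, two_sample_adata):
        once = filter_cells(two_sample_adata)
        twice = filter_cells(once)
        assert np.array_equal(once.X, twice.X)

    def test_rejects_normalized_input(self, annotated_adata):
        with pytest.raises(ValueError, match="normalized"):
            filter_cells(annotated_adata)


class TestNormalizeLog:
    def test_equal_split_forced(self):
        adata = make_adata(np.array([[1.0, 1.0]]))
        out = normalize_log(adata)
        assert np.allclose(out.X, np.log1p(5000.0))

    def test_all_zero_gene_stays_zero(self):
        adata = make_adata(np.array([[2.0, 0.0], [3.0, 0.0]]))
        assert np.all(normalize_log(adata).X[:, 1] == 0)

    def test_back_transform_totals(self, two_sample_adata):
        out = normalize_log(filter_cells(two_sample_adata))
        totals = np.expm1(out.X).sum(axis=1)
        assert np.allclose(totals, 10_000.0, atol=1e-6)

    def test_library_size_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(5, 20)).astype(float) + 1
        scaled = counts.copy()
        scaled[2] *= 7  # one cell sequenced 7x deeper
        a = normalize_log(make_adata(counts))
        b = normalize_log(make_adata(scaled))
        assert np.allclose(a.X[2], b.X[2])

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_log(make_adata(np.array([[1.0, -1.0]])))


class TestSelectHVG:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(1)
        counts = np.column_stack([rng.poisson(2, 50), np.full(50, 3.0)]).astype(float)
        adata = make_adata(counts)
        assert select_hvg(adata, n=1) == ["g0"]

    def test_n_exceeding_gene_count_warns_and_returns_all(self):
        adata = make_adata(np.ones((3, 4)))
        with pytest.warns(UserWarning):
            genes = select_hvg(adata, n=10)
        assert sorted(genes) == ["g0", "g1", "g2", "g3"]

    def test_planted_high_dispersion_genes_rank_top(self):
        # 20 overdispersed genes among 2000 near-Poisson genes: all in top 50
        rng = np.random.default_rng(2)
        n_cells = 300
        flat = rng.poisson(2.0, size=(n_cells, 2000)).astype(float)
        p = 0.3 / (0.3 + 2.0)
        noisy = rng.negative_binomial(0.3, p, size=(n_cells, 20)).astype(float)
        adata = make_adata(np.column_stack([flat, noisy]))
        planted = {f"g{i}" for i in range(2000, 2020)}
        top50 = set(select_hvg(adata, n=50))
        assert planted <= top50


class TestEmbedCluster:
    def test_two_separated_populations(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.3, size=(40, 10))
        b = rng.normal(5, 0.3, size=(40, 10))
        adata = make_adata(np.abs(np.vstack([a, b])))
        adata.uns["normalized"] = True
        labels = embed_cluster(adata, n_pcs=5, k_neighbors=10, seed=0)
        truth = [0] * 40 + [1] * 40
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_cells_form_one_cluster(self):
        adata = make_adata(np.ones((30, 10)))
        adata.uns["normalized"] = True
        labels = embed_cluster(adata, n_pcs=3, k_neighbors=15, seed=0)
        assert len(set(labels)) == 1

    def test_too_many_pcs_rejected(self):
        adata = make_adata(np.ones((10, 5)))
        with pytest.raises(ValueError, match="n_pcs"):
            embed_cluster(adata, n_pcs=5)

    def test_cell_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = np.abs(np.vstack([rng.normal(0, 0.3, (30, 8)), rng.normal(4, 0.3, (30, 8))]))
        perm = rng.permutation(60)
        a = make_adata(X)
        b = make_adata(X[perm])
        for m in (a, b):
            m.uns["normalized"] = True
        la = embed_cluster(a, n_pcs=4, k_neighbors=10, seed=0)
        lb = embed_cluster(b, n_pcs=4, k_neighbors=10, seed=0)
        assert adjusted_rand_score(la[perm], lb) == 1.0


class TestAnnotateClusters:
    def _annotated(self, counts, clusters, markers):
        adata = make_adata(counts)
        adata.uns["normalized"] = True
        adata.obs["cluster"] = list(clusters)
        return adata, annotate_clusters(adata, markers)

    def test_gfap_cluster_is_astrocytes(self):
        # cluster 0 over-expresses g0 (GFAP) only
        rng = np.random.default_rng(5)
        counts = np.abs(rng.normal(1.0, 0.1, size=(40, 4)))
        counts[:20, 0] += 3.0
        adata = make_adata(counts)
        adata.uns["normalized"] = True
        adata.obs["cluster"] = [0] * 20 + [1] * 20
        adata.var_names = ["GFAP", "X1", "X2", "X3"]
        assignment = annotate_clusters(adata, {"astrocytes": ["GFAP"], "microglia": ["CX3CR1"]})
        assert assignment[0] == "astrocytes"

    def test_no_marker_signal_gives_other_cells(self):
        rng = np.random.default_rng(6)
        counts = np.abs(rng.normal(1.0, 0.05, size=(30, 5)))
        _, assignment = self._annotated(
            counts, [0] * 15 + [1] * 15, {"astrocytes": ["GFAP"]})
        assert set(assignment.values()) == {OTHER_CELLS}

    def test_six_planted_types_all_recovered(self, two_sample_adata):
        adata = preprocess.normalize_log(preprocess.filter_cells(two_sample_adata))
        hvgs = select_hvg(adata, n=100)
        embed_cluster(adata, hvgs=hvgs, seed=0)
        annotate_clusters(adata, simulate.DEFAULT_MARKERS)
        by_cluster = adata.obs.groupby("cluster", observed=True)
        for _, grp in by_cluster:
            majority = grp["true_cell_type"].mode()[0]
            assert (grp["cell_type"] == majority).all()
        assert set(adata.obs["cell_type"]) >= set(simulate.BRAIN_CELL_TYPES)

    def test_missing_cluster_labels_rejected(self, annotated_adata):
        sub = annotated_adata[:10].copy()
        sub.obs = sub.obs.drop(columns=[c for c in ("cluster",) if c in sub.obs])
        with pytest.raises(ValueError, match="cluster"):
            annotate_clusters(sub, simulate.DEFAULT_MARKERS)
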