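"""Normalization arithmetic, HVG ranking, PCA conventions, SNN graph,
community detection, embedding and panel annotation."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ommatidia.cluster import (annotate_clusters, build_snn_graph,
                               compute_pca, detect_communities, embed_2d,
                               normalize_log_cp10k, select_hvgs)
from ommatidia.iocore import CountMatrix


class TestNormalize:
    def test_direct_arithmetic(self):
        y = normalize_log_cp10k(np.array([[1, 0, 9]]))
        assert y[0] == pytest.approx([6.90875, 0.0, 9.10509], abs=1e-4)

    def test_depth_invariance(self):
        a = normalize_log_cp10k(np.array([[1, 2, 3]]))
        b = normalize_log_cp10k(np.array([[2, 4, 6]]))
        assert np.allclose(a, b)

    def test_within_cell_monotonicity(self):
        y = normalize_log_cp10k(np.array([[5, 3, 9, 0]]))
        x = np.array([5, 3, 9, 0])
        assert np.all(np.argsort(y[0]) == np.argsort(x, kind="stable"))

    def test_all_zero_cell_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            y = normalize_log_cp10k(np.array([[0, 0], [1, 1]]))
        assert np.all(y[0] == 0)


class TestSelectHvgs:
    def test_constant_gene_never_selected(self, rng):
        X = rng.poisson(3.0, size=(100, 10)).astype(float)
        X[:, 4] = 7.0
        hvgs = select_hvgs(X, 9)
        assert 4 not in hvgs

    def test_requesting_all_genes_returns_informative_set(self, rng):
        X = rng.poisson(3.0, size=(50, 8)).astype(float)
        with pytest.warns(UserWarning, match="informative"):
            hvgs = select_hvgs(np.hstack([X, np.ones((50, 1))]), 9)
        assert set(hvgs) == set(range(8))

    def test_planted_markers_rank_highly(self, default_dataset):
        """>=95% of fold-8 planted markers land in the top n_hvg."""
        truth = default_dataset["truth"].genes
        hvgs = select_hvgs(default_dataset["matrix"], 1000)
        planted = truth.index[truth["marker_of"].isin(
            ["R1-6", "cone", "pigment1", "pigment23", "noneye", "R7/8"])]
        assert np.isin(planted, hvgs).mean() >= 0.95


class TestComputePca:
    def test_single_axis_of_variance(self, rng):
        t = rng.normal(size=50)
        X = np.outer(t, [1.0, 2.0, -1.0])
        scores, _, evr = compute_pca(X, n_dims=2, scale="none")
        assert evr[0] == pytest.approx(1.0)

    def test_reconstruction_improves_with_dims(self, rng):
        X = rng.normal(size=(60, 20))
        errs = []
        for d in (2, 5, 10):
            scores, loadings, _ = compute_pca(X, n_dims=d, scale="none")
            recon = scores @ loadings
            errs.append(np.linalg.norm(X - X.mean(0) - recon))
        assert errs[0] > errs[1] > errs[2]

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(40, 6))
        s1, l1, _ = compute_pca(X, n_dims=3, scale="zscore", seed=0)
        s2, l2, _ = compute_pca(X, n_dims=3, scale="zscore", seed=0)
        assert np.allclose(s1, s2) and np.allclose(l1, l2)
        for j in range(3):
            assert l1[j, np.argmax(np.abs(l1[j]))] > 0

    def test_excess_dims_reduced_with_warning(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.warns(UserWarning, match="reduced"):
            scores, _, _ = compute_pca(X, n_dims=50, scale="none")
        assert scores.shape == (10, 4)

    def test_same_type_cells_cluster_in_pc_space(self, default_run,
                                                 default_dataset):
        scores = default_run["result"].pca
        types = default_run["truth_kept"]["type"].to_numpy()
        rng = np.random.default_rng(0)
        idx = rng.choice(len(scores), 2000, replace=False)
        S, T = scores[idx], types[idx]
        d = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=-1)
        same = T[:, None] == T[None, :]
        iu = np.triu_indices(len(S), 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()


class TestSnnGraph:
    def test_collinear_points_share_middle_neighbor(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        g = build_snn_graph(pts, k=1, prune=0.0)
        edges = {tuple(e) for e in g.edges}
        assert (0, 1) in edges and (1, 2) in edges

    def test_identical_mutually_nearest_cells_weight_one(self):
        pts = np.array([[0.0], [0.0], [10.0], [10.0]])
        g = build_snn_graph(pts, k=1, prune=0.0)
        w = {tuple(e): wt for e, wt in zip(map(tuple, g.edges), g.weights)}
        assert w[(0, 1)] == pytest.approx(1.0)
        assert w[(2, 3)] == pytest.approx(1.0)

    def test_weights_in_unit_interval_and_undirected(self, rng):
        pts = rng.normal(size=(60, 3))
        g = build_snn_graph(pts, k=5)
        assert np.all(g.weights > 0) and np.all(g.weights <= 1)
        # stored as i<j pairs: no duplicate orientations
        pairs = [tuple(e) for e in g.edges]
        assert len(pairs) == len(set(pairs))
        assert all(a < b for a, b in pairs)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k"):
            build_snn_graph(np.zeros((3, 2)), k=3)


class TestDetectCommunities:
    def test_two_cliques_two_communities(self):
        from ommatidia.cluster import SNNGraph
        import itertools as it
        edges = [*it.combinations(range(8), 2),
                 *it.combinations(range(8, 16), 2)]
        g = SNNGraph(16, np.array(edges), np.ones(len(edges)))
        labels = detect_communities(g, resolution=0.8, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:8])) == 1

    def test_blobs_never_merged_across_gap(self, rng):
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2)) + 50
        g = build_snn_graph(np.vstack([a, b]), k=5)
        labels = detect_communities(g, resolution=0.8, seed=0)
        # the disconnected blobs share no community label
        assert not (set(labels[:30]) & set(labels[30:]))

    def test_deterministic_under_seed(self, rng):
        pts = rng.normal(size=(80, 4))
        g = build_snn_graph(pts, k=8)
        l1 = detect_communities(g, 0.8, seed=3)
        l2 = detect_communities(g, 0.8, seed=3)
        assert np.array_equal(l1, l2)

    def test_at_least_as_many_communities_as_types(self, default_run):
        labels = default_run["result"].labels
        n_types = default_run["truth_kept"]["type"].nunique()
        assert len(np.unique(labels)) >= n_types


class TestEmbed2d:
    def test_seeded_and_tiny_input(self):
        pts = np.random.default_rng(0).normal(size=(3, 4))
        e1 = embed_2d(pts, seed=1)
        e2 = embed_2d(pts, seed=1)
        assert e1.shape == (3, 2)
        assert np.allclose(e1, e2)

    def test_trustworthiness_on_synthetic_blobs(self, rng):
        from sklearn.manifold import trustworthiness
        centers = rng.normal(scale=12, size=(5, 10))
        X = np.vstack([c + rng.normal(size=(80, 10)) for c in centers])
        emb = embed_2d(X, seed=0)
        assert trustworthiness(X, emb, n_neighbors=15) >= 0.85


class TestAnnotateClusters:
    def test_rh5_dominant_cluster_is_pale_r8(self):
        symbols = ["Rh5", "Rh6", "sens", "ninaE", "Rh3", "Rh4", "pros",
                   "ct", "Crys", "w", "Pdh", "santa-maria", "wrapper", "hth"]
        expr = np.zeros((90, len(symbols)))
        labels = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        expr[:30, 0] = 5.0     # cluster a: Rh5 + sens
        expr[:30, 2] = 1.0
        expr[30:60, 3] = 6.0   # cluster b: ninaE
        expr[60:, 7] = 4.0     # cluster c: ct + Crys
        expr[60:, 8] = 4.0
        ann = annotate_clusters(expr, labels, symbols)
        assert ann.loc["a", "type"] == "R8"
        assert ann.loc["a", "subtype"] == "pale"
        assert ann.loc["b", "type"] == "R1-6"
        assert ann.loc["c", "type"] == "cone"

    def test_missing_panel_gene_warns_but_annotates(self):
        symbols = ["Rh5", "Rh6", "ninaE"]   # sens and others absent
        expr = np.zeros((20, 3))
        expr[:10, 0] = 4.0
        expr[10:, 2] = 5.0
        labels = ["a"] * 10 + ["b"] * 10
        with pytest.warns(UserWarning, match="absent"):
            ann = annotate_clusters(expr, labels, symbols)
        assert ann.loc["a", "type"] == "R8"

    def test_clusters_match_majority_truth_type(self, default_run):
        """>=95% of clusters annotated to the majority true type."""
        res = default_run["result"]
        truth = default_run["truth_kept"]["type"].to_numpy()
        hits = 0
        clusters = np.unique(res.labels)
        for k in clusters:
            maj = pd.Series(truth[res.labels == k]).mode()[0]
            hits += res.annotation.loc[k, "type"] == maj
        assert hits / len(clusters) >= 0.95

    def test_end_to_end_type_recovery(self, default_run):
        """ARI between true types and annotated clusters >= 0.90."""
        from ommatidia.ablation import cluster_ari
        truth = default_run["truth_kept"]["type"].to_numpy()
        assigned = np.asarray(default_run["result"].cell_types, dtype=object)
        assert cluster_ari(truth, assigned) >= 0.90

    def test_embedding_isolation(self, default_dataset):
        """Computing the 2-D embedding changes no table output."""
        from ommatidia import cluster as cl
        from ommatidia.iocore import PipelineConfig
        sub = default_dataset["matrix"].subset_cells(np.arange(400))
        cfg = PipelineConfig(seed=0, n_hvg=500, neighbors_k=10)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            r1 = cl.run_clustering(sub, cfg, with_embedding=False, seed=1)
            r2 = cl.run_clustering(sub, cfg, with_embedding=True, seed=1)
        assert np.array_equal(r1.labels, r2.labels)
        pd.testing.assert_frame_equal(r1.annotation, r2.annotation)
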