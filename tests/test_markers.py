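"""Marker calling: exact and asymptotic rank tests, fold-change arithmetic,
specificity classes, shared-pair markers and over-representation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ommatidia.markers import (classify_specificity, find_shared_pair_markers,
                               hypergeom_enrichment, intersect_markers,
                               log2_fold_change, rank_markers_wilcoxon,
                               rank_test, wilcoxon_exact_p)


def brute_force_exact_p(x, y):
    """Independent oracle: enumerate assignments, count as-extreme U values."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mean_u = n1 * len(y) / 2.0
    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
    obs = abs(u_of(range(n1)) - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(combo) - mean_u) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankTest:
    def test_complete_separation_three_vs_three(self):
        p = wilcoxon_exact_p(np.array([5.0, 6, 7]), np.array([0.0, 0, 1]))
        assert p == pytest.approx(0.1)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        for n1, n2 in [(3, 3), (4, 5), (6, 4), (8, 8)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            ours = wilcoxon_exact_p(x, y)
            ref = stats.mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12), (n1, n2)

    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10_000))
    def test_exact_matches_enumeration_with_ties(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=n1).astype(float)
        y = rng.integers(0, 3, size=n2).astype(float)
        assert wilcoxon_exact_p(x, y) == pytest.approx(
            brute_force_exact_p(x, y), abs=1e-12)

    def test_null_calibration_of_asymptotic_test(self):
        """Type-I error <= 0.06 at alpha 0.05 over 10,000 null genes."""
        rng = np.random.default_rng(0)
        A = rng.normal(size=(60, 10_000))
        B = rng.normal(size=(80, 10_000))
        p = stats.mannwhitneyu(A, B, axis=0, method="asymptotic").pvalue
        assert (p < 0.05).mean() <= 0.06

    def test_dispatch_small_vs_large(self):
        x, y = np.arange(3.0), np.arange(3.0) + 10
        assert rank_test(x, y) == wilcoxon_exact_p(x, y)


class TestFoldChange:
    def test_mean_cp10k_arithmetic(self):
        assert log2_fold_change(np.array([300.0]), np.array([30.0]))[0] == \
            pytest.approx(np.log2(301 / 31))

    def test_symmetry(self):
        a, b = np.array([12.0]), np.array([90.0])
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))


class TestRankMarkersWilcoxon:
    def _toy(self):
        rng = np.random.default_rng(0)
        n = 60
        expr = rng.random((n, 4)) * 0.05
        labels = np.array(["A"] * 20 + ["B"] * 40)
        expr[:20, 0] = 3.0 + rng.random(20)      # A-specific
        expr[:, 1] = 2.0 + rng.random(n)         # ubiquitous
        return expr, labels

    def test_positive_marker_called_with_small_p(self):
        expr, labels = self._toy()
        t = rank_markers_wilcoxon(expr, labels, min_pct=0.25)
        row = t[(t["gene"] == "g0") & (t["cluster"] == "A")]
        assert len(row) == 1
        assert row["p_adj"].iloc[0] < 1e-6
        assert row["log2fc"].iloc[0] > 0.25

    def test_only_pos_excludes_depleted_genes(self):
        expr, labels = self._toy()
        t = rank_markers_wilcoxon(expr, labels, min_pct=0.25, only_pos=True)
        assert ((t["gene"] == "g0") & (t["cluster"] == "B")).sum() == 0

    def test_small_cluster_skipped_with_warning(self):
        expr = np.random.default_rng(0).random((12, 3))
        labels = np.array(["A"] * 2 + ["B"] * 10)
        with pytest.warns(UserWarning, match="skipped"):
            t = rank_markers_wilcoxon(expr, labels, min_pct=0.0,
                                      logfc_threshold=0.0)
        assert "A" not in set(t["cluster"])

    def test_bonferroni_relation(self):
        expr, labels = self._toy()
        t = rank_markers_wilcoxon(expr, labels, min_pct=0.0,
                                  logfc_threshold=0.0)
        for k, sub in t.groupby("cluster"):
            m = len(sub)
            assert np.allclose(sub["p_adj"],
                               np.minimum(sub["p"] * m, 1.0))

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError, match="two clusters"):
            rank_markers_wilcoxon(np.ones((5, 2)), ["A"] * 5)


class TestIntersectMarkers:
    def _table(self, genes, cluster="R8", p=0.01):
        return pd.DataFrame({"gene": genes, "cluster": cluster,
                             "p": [p] * len(genes)})

    def test_identical_tables_intersect_to_identity(self):
        t = self._table(["a", "b", "c"])
        out = intersect_markers([t, t.copy(), t.copy()])
        assert set(out["gene"]) == {"a", "b", "c"}

    def test_disjoint_tables_intersect_to_empty(self):
        out = intersect_markers([self._table(["a"]), self._table(["b"])])
        assert out.empty

    def test_missing_cluster_warns_empty(self):
        t1 = self._table(["a"], cluster="R8")
        t2 = self._table(["a"], cluster="R7")
        with pytest.warns(UserWarning, match="absent"):
            out = intersect_markers([t1, t2])
        assert out.empty

    def test_ordered_by_worst_p(self):
        t1 = pd.DataFrame({"gene": ["a", "b"], "cluster": "R8",
                           "p": [0.5, 0.001]})
        t2 = pd.DataFrame({"gene": ["a", "b"], "cluster": "R8",
                           "p": [0.001, 0.002]})
        out = intersect_markers([t1, t2])
        assert list(out["gene"]) == ["b", "a"]
        assert list(out["worst_p"]) == [0.002, 0.5]

    def test_planted_markers_survive_triplicate_intersection(self):
        """>=90% of planted exclusive markers common to three seeds."""
        import warnings
        import ommatidia as om
        from ommatidia.cluster import normalize_log_cp10k
        tables = []
        truth_markers = None
        for seed in (21, 22, 23):
            sim = om.SimConfig(n_cells=1500, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m, ann, truth = om.generate_retina_dataset(sim)
                expr = normalize_log_cp10k(m)
                t = rank_markers_wilcoxon(expr, ann["type"].to_numpy(),
                                          counts=m.densify(),
                                          gene_symbols=m.gene_symbols)
            tables.append(t)
            truth_markers = truth.genes
        out = intersect_markers(tables)
        planted = truth_markers[truth_markers["marker_of"].isin(
            ["R1-6", "cone", "pigment1", "pigment23"])]
        hits = sum(((out["gene"] == r["symbol"])
                    & (out["cluster"] == r["marker_of"])).any()
                   for _, r in planted.iterrows())
        assert hits / len(planted) >= 0.90


class TestClassifySpecificity:
    def _expr(self, fractions, n_per=100):
        """One gene detected at exactly the given fraction per cluster."""
        blocks, labels = [], []
        for ci, f in enumerate(fractions):
            col = np.zeros(n_per)
            col[:round(f * n_per)] = 1.0
            blocks.append(col)
            labels += [f"c{ci}"] * n_per
        expr = np.concatenate(blocks)[:, None]
        return expr, np.array(labels)

    def _classify(self, fractions, home="c0", tau=0.1, exclude=()):
        expr, labels = self._expr(fractions)
        cand = pd.DataFrame({"gene": ["g0"], "cluster": [home]})
        return classify_specificity(expr, labels, cand, tau=tau,
                                    exclude_clusters=exclude)

    def test_home_only_is_class_1(self):
        out = self._classify([0.8, 0.02, 0.02, 0.02])
        assert out["specificity_class"].iloc[0] == "1"

    def test_home_plus_one_is_class_2(self):
        out = self._classify([0.8, 0.5, 0.02, 0.02])
        assert out["specificity_class"].iloc[0] == "2"

    def test_home_plus_two_is_class_3(self):
        out = self._classify([0.8, 0.5, 0.5, 0.02])
        assert out["specificity_class"].iloc[0] == "3"

    def test_everywhere_is_ubiquitous(self):
        out = self._classify([0.8, 0.5, 0.5, 0.5])
        assert out["specificity_class"].iloc[0] == "ubiquitous"

    def test_not_expressed_flagged(self):
        out = self._classify([0.02, 0.5, 0.02, 0.02])
        assert out["specificity_class"].iloc[0] == "not_expressed"

    def test_excluded_cluster_ignored(self):
        out = self._classify([0.8, 0.5, 0.02, 0.02], exclude=("c1",))
        assert out["specificity_class"].iloc[0] == "1"

    def test_excluded_home_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            self._classify([0.8, 0.02, 0.02, 0.02], exclude=("c0",))

    @pytest.mark.parametrize("tau,expected",
                             [(0.05, "3"), (0.10, "2"), (0.25, "1")])
    def test_tau_sweep_tightens_class(self, tau, expected):
        # detection (0.8, 0.15, 0.07, 0.02): raising tau strips clusters
        # from the "expressed" set one by one
        out = self._classify([0.8, 0.15, 0.07, 0.02], tau=tau)
        assert out["specificity_class"].iloc[0] == expected

    def test_invariant_to_cell_order(self):
        expr, labels = self._expr([0.8, 0.5, 0.02, 0.02])
        cand = pd.DataFrame({"gene": ["g0"], "cluster": ["c0"]})
        a = classify_specificity(expr, labels, cand)
        perm = np.random.default_rng(1).permutation(len(labels))
        b = classify_specificity(expr[perm], labels[perm], cand)
        assert a["specificity_class"].iloc[0] == b["specificity_class"].iloc[0]


class TestSharedPairMarkers:
    def test_planted_shared_markers_found(self, default_markers):
        shared = default_markers["shared_R7_R8"]
        planted = [f"mk-R7.8-{j + 1:02d}" for j in range(20)]
        assert set(planted) <= set(shared)

    def test_class1_gene_not_returned(self, default_markers,
                                      default_run):
        # an R8-exclusive opsin is not an R7/8-shared marker
        assert "Rh5" not in default_markers["shared_R7_R8"]

    def test_missing_pair_member_rejected(self):
        expr = np.ones((10, 2))
        with pytest.raises(ValueError, match="R8"):
            find_shared_pair_markers(expr, ["R7"] * 10, ("R7", "R8"))

    def test_tau_zero_warns_superset(self):
        expr = np.ones((10, 1))
        labels = ["R7"] * 5 + ["R8"] * 5
        with pytest.warns(UserWarning, match="tau"):
            out = find_shared_pair_markers(expr, labels, ("R7", "R8"), tau=0.0)
        assert out == ["g0"]


class TestHypergeomEnrichment:
    UNIVERSE = [f"u{i}" for i in range(100)]

    def test_frozen_overlap_example(self):
        gene_set = {"s": self.UNIVERSE[:10]}
        marker_list = self.UNIVERSE[5:15]     # overlap 5
        out = hypergeom_enrichment(marker_list, gene_set, self.UNIVERSE)
        p = out["p"].iloc[0]
        assert p == pytest.approx(0.000671627748, rel=1e-6)
        assert 1e-4 < p < 1e-3

    def test_zero_overlap_gives_p_one(self):
        out = hypergeom_enrichment(self.UNIVERSE[50:60],
                                   {"s": self.UNIVERSE[:10]}, self.UNIVERSE)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_set_equal_to_list_maximally_enriched(self):
        lst = self.UNIVERSE[:10]
        out = hypergeom_enrichment(
            lst, {"self": lst, "other": self.UNIVERSE[40:80]}, self.UNIVERSE)
        row = out[out["set"] == "self"].iloc[0]
        assert row["fold_enrichment"] == pytest.approx(len(self.UNIVERSE) / 10)
        assert row["p"] == out["p"].min()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment(["a"], {"s": ["a"]}, [])

    def test_bh_qvalues_monotone_in_p(self):
        sets = {f"s{i}": self.UNIVERSE[i * 5:i * 5 + 10] for i in range(8)}
        out = hypergeom_enrichment(self.UNIVERSE[:12], sets, self.UNIVERSE)
        assert (out.sort_values("p")["q"].diff().dropna() >= -1e-12).all()
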