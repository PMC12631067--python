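"""QC filtering, normalization, and the cluster-uniqueness rule."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst
from statsmodels.stats.multitest import multipletests

from orthatlas import QCThresholds, filter_cells_genes, normalize_log, unique_cluster_genes
from orthatlas.preprocess import regress_out_depth

from conftest import make_adata


def brute_force_filter(counts, min_cells, min_genes):
    """Independent two-step oracle: gene pass on input, then cell pass."""
    counts = np.asarray(counts)
    keep_g = (counts > 0).sum(axis=0) >= min_cells
    sub = counts[:, keep_g]
    keep_c = (sub > 0).sum(axis=1) >= min_genes
    return keep_c, keep_g


class TestFilter:
    def test_gene_below_min_cells_removed(self):
        counts = np.zeros((5, 2), dtype=int)
        counts[:2, 0] = 1  # gene 0 in 2 cells only
        counts[:, 1] = 1
        ad = make_adata(counts)
        out = filter_cells_genes(ad, QCThresholds(min_cells_per_gene=3, min_genes_per_cell=0))
        assert list(out.var_names) == [ad.var_names[1]]
        assert out.uns["qc_report"]["genes_removed"] == 1

    def test_zero_thresholds_identity(self):
        rng = np.random.default_rng(0)
        ad = make_adata(rng.integers(0, 3, size=(10, 8)))
        out = filter_cells_genes(ad, QCThresholds(0, 0))
        assert out.shape == ad.shape
        assert (out.X != ad.X).nnz == 0

    def test_matches_brute_force_two_step(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 2, size=(20, 30))
        t = QCThresholds(min_cells_per_gene=3, min_genes_per_cell=5)
        keep_c, keep_g = brute_force_filter(counts, 3, 5)
        out = filter_cells_genes(make_adata(counts), t)
        assert out.shape == (keep_c.sum(), keep_g.sum())
        np.testing.assert_array_equal(np.asarray(out.X.todense()), counts[np.ix_(keep_c, keep_g)])

    def test_everything_removed_is_an_error(self):
        ad = make_adata(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="min_cells_per_gene"):
            filter_cells_genes(ad, QCThresholds(min_cells_per_gene=10, min_genes_per_cell=0))
        with pytest.raises(ValueError, match="min_genes_per_cell"):
            filter_cells_genes(ad, QCThresholds(min_cells_per_gene=0, min_genes_per_cell=10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_single_pass_idempotent_or_disclosed(self, seed):
        """A second pass changes nothing, or the report discloses non-fixpoint."""
        rng = np.random.default_rng(seed)
        counts = (rng.random((12, 15)) < 0.3).astype(int)
        t = QCThresholds(min_cells_per_gene=2, min_genes_per_cell=2)
        try:
            once = filter_cells_genes(make_adata(counts), t)
        except ValueError:
            return
        if once.uns["qc_report"]["is_fixpoint"]:
            twice = filter_cells_genes(once, t)
            assert twice.shape == once.shape

    def test_fixpoint_mode_is_stable(self):
        rng = np.random.default_rng(5)
        counts = (rng.random((15, 20)) < 0.25).astype(int)
        t = QCThresholds(min_cells_per_gene=2, min_genes_per_cell=2)
        out = filter_cells_genes(make_adata(counts), t, fixpoint=True)
        again = filter_cells_genes(out, t)
        assert again.shape == out.shape
        assert out.uns["qc_report"]["is_fixpoint"]


class TestNormalize:
    def test_closed_form_cell(self):
        ad = make_adata([[2, 0, 8], [1, 1, 8]])
        out = normalize_log(ad, target_sum=10.0)
        row0 = np.asarray(out.X.todense())[0]
        np.testing.assert_allclose(row0, [np.log(3), 0.0, np.log(9)], rtol=1e-12)

    def test_equal_cells_get_equal_vectors(self):
        ad = make_adata([[3, 1, 0]] * 4)
        out = normalize_log(ad, target_sum=100.0)
        X = np.asarray(out.X.todense())
        assert np.ptp(X, axis=0).max() == 0.0

    def test_expm1_sums_conserved(self):
        rng = np.random.default_rng(1)
        ad = make_adata(rng.integers(0, 6, size=(8, 12)) + (rng.random((8, 12)) < 0.1))
        out = normalize_log(ad, target_sum=1e4)
        sums = np.expm1(np.asarray(out.X.todense())).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-9)

    def test_zero_pattern_preserved(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=(10, 10))
        counts[:, 0] += 1  # guard against zero-total cells
        out = normalize_log(make_adata(counts))
        np.testing.assert_array_equal(
            np.asarray(out.X.todense()) > 0, counts > 0
        )

    def test_zero_total_cell_rejected(self):
        ad = make_adata([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="zero total"):
            normalize_log(ad)

    def test_layer_tag_enforced(self):
        ad = make_adata([[1.0, 2.0]], layer="normalized")
        with pytest.raises(ValueError, match="raw"):
            normalize_log(ad)


def test_regress_out_depth_removes_depth_trend():
    rng = np.random.default_rng(3)
    counts = rng.poisson(np.outer(rng.uniform(1, 5, 30), rng.uniform(0.5, 2, 10)))
    counts[:, 0] += 1
    norm = normalize_log(make_adata(counts))
    resid = regress_out_depth(norm)
    depth = np.asarray(norm.layers["counts"].sum(axis=1)).ravel()
    X = np.asarray(resid.X)
    corr = [st.pearsonr(depth, X[:, j])[0] for j in range(X.shape[1]) if X[:, j].std() > 0]
    assert max(abs(c) for c in corr) < 1e-8


class TestUniqueClusterGenes:
    def _toy(self):
        # 3 clusters x 10 cells, 20 genes with planted detection patterns
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 4, size=(30, 20))  # everything detected
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        counts[:, 0] = 0
        counts[:10, 0] = 5  # unique to a: 100% in a, 0% elsewhere
        counts[:, 1] = 0
        counts[10:20, 1] = 3  # unique to b
        counts[:, 2] = 0
        counts[:10, 2] = [4] * 6 + [0] * 4  # 60% in a, 0 elsewhere
        counts[:, 3] = 0
        counts[:10, 3] = 5
        counts[10:12, 3] = 5  # 20% in b -> fails frac_out
        return make_adata(counts, cell_types=labels), np.asarray(labels)

    def test_planted_pattern_matches_brute_force(self):
        ad, labels = self._toy()
        norm = normalize_log(ad)
        got = unique_cluster_genes(norm, "cell_type")

        # independent rule evaluation: detection fractions + scipy Wilcoxon + BH
        X = np.asarray(norm.X.todense())
        expected = {}
        for k in ("a", "b", "c"):
            mask = labels == k
            p = np.array([
                st.mannwhitneyu(X[mask, j], X[~mask, j], alternative="two-sided",
                                method="asymptotic", use_continuity=True).pvalue
                for j in range(X.shape[1])
            ])
            adj = multipletests(p, method="fdr_bh")[1]
            det_in = (X[mask] > 0).mean(axis=0)
            keep = []
            for j in range(X.shape[1]):
                outs = [(X[labels == c, j] > 0).mean() for c in "abc" if c != k]
                if det_in[j] > 0.5 and max(outs) <= 0.1 and adj[j] <= 0.05:
                    keep.append(norm.var_names[j])
            expected[k] = keep
        assert {k: sorted(v) for k, v in got.items()} == {
            k: sorted(v) for k, v in expected.items()
        }
        assert norm.var_names[0] in got["a"]
        assert norm.var_names[1] in got["b"]

    def test_ubiquitous_gene_unique_nowhere(self):
        ad, _ = self._toy()
        got = unique_cluster_genes(normalize_log(ad), "cell_type")
        g_everywhere = ad.var_names[5]
        assert all(g_everywhere not in v for v in got.values())

    def test_outputs_disjoint_across_clusters(self):
        ad, _ = self._toy()
        got = unique_cluster_genes(normalize_log(ad), "cell_type")
        all_genes = [g for v in got.values() for g in v]
        assert len(all_genes) == len(set(all_genes))

    def test_single_cluster_rejected(self):
        ad = make_adata(np.ones((4, 3)), cell_types=["x"] * 4, layer="normalized")
        with pytest.raises(ValueError, match="2 clusters"):
            unique_cluster_genes(ad, "cell_type")
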