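"""Elastic-net identity models: fitting, signatures, scoring, overlap."""

import numpy as np
import pandas as pd
import pytest

from orthatlas import (
    balanced_sample,
    extract_signature,
    fit_signature,
    score_cells,
    signature_overlap,
)
from orthatlas.ortholog import OrthologMap
from orthatlas.signatures import SignatureModel

from conftest import make_adata


class TestBalancedSample:
    def test_small_type_kept_whole(self):
        labels = ["a"] * 400 + ["b"] * 10
        idx = balanced_sample(labels, n_per_type=1000, seed=0)
        assert len(idx) == 410

    def test_large_type_capped_and_subset(self):
        labels = np.array(["a"] * 5000 + ["b"] * 100)
        idx = balanced_sample(labels, n_per_type=1000, seed=1)
        assert (labels[idx] == "a").sum() == 1000
        assert (labels[idx] == "b").sum() == 100
        assert len(set(idx)) == len(idx)

    def test_same_seed_identical(self):
        labels = ["a"] * 2000 + ["b"] * 1500
        i1 = balanced_sample(labels, 1000, seed=9)
        i2 = balanced_sample(labels, 1000, seed=9)
        np.testing.assert_array_equal(i1, i2)


def hadamard_training_set(n_genes=3):
    """8-cell design whose standardized columns are orthonormal in the 1/n sense."""
    H = np.array(
        [
            [1, 1, 1],
            [1, 1, -1],
            [1, -1, 1],
            [1, -1, -1],
            [-1, 1, 1],
            [-1, 1, -1],
            [-1, -1, 1],
            [-1, -1, -1],
        ],
        dtype=float,
    )[:, :n_genes]
    y = (H[:, 0] > 0).astype(int)
    labels = ["target" if v else "rest" for v in y]
    ad = make_adata(H, cell_types=labels, layer="normalized")
    return ad, H, y


def soft_threshold(z, lam, alpha):
    return np.sign(z) * max(abs(z) - lam * alpha, 0.0) / (1.0 + lam * (1.0 - alpha))


class TestFitSignature:
    @pytest.mark.parametrize("lam,alpha", [(0.1, 0.5), (0.3, 0.5), (0.2, 0.9)])
    def test_orthonormal_design_matches_soft_threshold(self, lam, alpha):
        ad, H, y = hadamard_training_set()
        model = fit_signature(ad, "target", l1_ratio=alpha, penalty=lam)
        yc = y - y.mean()
        expected = [soft_threshold(H[:, j] @ yc / len(y), lam, alpha) for j in range(3)]
        np.testing.assert_allclose(model.weights, expected, atol=1e-6)

    def test_separating_gene_gets_positive_weight_noise_zero(self):
        rng = np.random.default_rng(6)
        n = 60
        labels = ["target"] * 20 + ["rest"] * 40
        X = rng.normal(0, 1, size=(n, 10))
        X[:20, 0] += 4.0  # one clean separator
        X -= X.min() - 0.1  # keep values positive so every gene is "expressed"
        ad = make_adata(X, cell_types=labels, layer="normalized")
        model = fit_signature(ad, "target", penalty=0.2)
        w = dict(zip(model.genes, model.weights))
        assert w[ad.var_names[0]] > 0
        assert sum(v != 0 for g, v in w.items() if g != ad.var_names[0]) == 0

    def test_infinite_penalty_gives_null_model(self):
        ad, _, y = hadamard_training_set()
        model = fit_signature(ad, "target", penalty=1e9)
        np.testing.assert_allclose(model.weights, 0.0)
        assert model.intercept == pytest.approx(y.mean())

    def test_single_class_rejected(self):
        ad, _, _ = hadamard_training_set()
        with pytest.raises(ValueError, match="single class"):
            fit_signature(ad, "not-present")

    def test_same_seed_reproducible(self, merged_small):
        merged, _, _ = merged_small
        sub = merged[merged.obs["species"] == "human"].copy()
        sub.uns = dict(merged.uns)
        m1 = fit_signature(sub, "sertoli", penalty="cv", seed=3)
        m2 = fit_signature(sub, "sertoli", penalty="cv", seed=3)
        assert m1.penalty == m2.penalty
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)

    def test_sparsity_monotone_in_penalty(self, merged_small):
        merged, _, _ = merged_small
        sub = merged[merged.obs["species"] == "human"].copy()
        sub.uns = dict(merged.uns)
        sizes = []
        for lam in (0.005, 0.02, 0.08, 0.3):
            m = fit_signature(sub, "sertoli", penalty=lam)
            sizes.append(len(extract_signature(m)))
        assert sizes == sorted(sizes, reverse=True)

    def test_scale_invariance_with_refit_standardization(self):
        rng = np.random.default_rng(8)
        X = rng.gamma(2, 1, size=(40, 6))
        labels = ["target"] * 15 + ["rest"] * 25
        ad1 = make_adata(X, cell_types=labels, layer="normalized")
        ad2 = make_adata(X * 10.0, cell_types=labels, layer="normalized")
        m1 = fit_signature(ad1, "target", penalty=0.05)
        m2 = fit_signature(ad2, "target", penalty=0.05)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-8)

    def test_model_round_trips_through_dict(self):
        ad, _, _ = hadamard_training_set()
        m = fit_signature(ad, "target", penalty=0.1)
        back = SignatureModel.from_dict(m.to_dict())
        np.testing.assert_allclose(back.weights, m.weights)
        assert back.genes == m.genes


class TestExtractSignature:
    def _model(self, weights):
        return SignatureModel(
            species="human", cell_type="t",
            genes=[f"g{i}" for i in range(len(weights))],
            weights=np.asarray(weights, dtype=float), intercept=0.0,
            mean=np.zeros(len(weights)), sd=np.ones(len(weights)),
            l1_ratio=0.5, penalty=0.1,
        )

    def test_only_strictly_positive_weights(self):
        assert extract_signature(self._model([0.5, 0.0, -0.3])) == ["g0"]

    def test_all_nonpositive_gives_empty(self):
        assert extract_signature(self._model([0.0, -1.0])) == []

    def test_sorted_by_descending_weight(self):
        sig = extract_signature(self._model([0.1, 0.9, 0.5]))
        assert sig == ["g1", "g2", "g0"]


class TestScoreCells:
    def test_all_zero_cell_closed_form(self):
        model = SignatureModel(
            species="human", cell_type="t", genes=["hum:G0001", "hum:G0002"],
            weights=np.array([2.0, -1.0]), intercept=0.7,
            mean=np.array([1.0, 3.0]), sd=np.array([2.0, 0.5]),
            l1_ratio=0.5, penalty=0.1,
        )
        ad = make_adata([[0.0, 0.0]], layer="normalized")
        got = score_cells(model, ad)["score"].iloc[0]
        expected = 0.7 + 2.0 * (0 - 1.0) / 2.0 + (-1.0) * (0 - 3.0) / 0.5
        assert got == pytest.approx(expected)

    def test_in_sample_separation(self, merged_small):
        merged, _, _ = merged_small
        sub = merged[merged.obs["species"] == "human"].copy()
        sub.uns = dict(merged.uns)
        model = fit_signature(sub, "sertoli", penalty=0.02)
        scores = score_cells(model, sub)
        by_type = scores.groupby("cell_type", observed=True)["score"].mean()
        assert by_type.idxmax() == "sertoli"

    def test_cross_species_transfer_ranks_homolog_first(self, merged_small):
        merged, _, truth = merged_small
        sub = merged[merged.obs["species"] == "human"].copy()
        sub.uns = dict(merged.uns)
        model = fit_signature(sub, "sertoli", penalty=0.02)
        scores = score_cells(model, merged)
        mouse = scores[scores["species"] == "mouse"]
        by_type = mouse.groupby("cell_type", observed=True)["score"].mean()
        assert by_type.idxmax() == truth.homology["sertoli"]

    def test_too_many_missing_genes_rejected(self):
        model = SignatureModel(
            species="human", cell_type="t",
            genes=["hum:G0001", "nope1", "nope2"],
            weights=np.ones(3), intercept=0.0,
            mean=np.zeros(3), sd=np.ones(3), l1_ratio=0.5, penalty=0.1,
        )
        ad = make_adata([[1.0, 2.0]], layer="normalized")
        with pytest.raises(ValueError, match="missing"):
            score_cells(model, ad)


class TestSignatureOverlap:
    def _map(self, n):
        rows = [(f"hsa:S{i}", f"mmu:S{i}", "one2one") for i in range(n)]
        return OrthologMap(
            pd.DataFrame(rows, columns=["gene_a", "gene_b", "homology_class"])
        )

    def test_sertoli_composition(self):
        omap = self._map(11)
        sig_h = [f"hsa:S{i}" for i in range(11)] + [f"hsa:X{i}" for i in range(81)]
        sig_m = [f"mmu:S{i}" for i in range(11)] + [f"mmu:Y{i}" for i in range(76)]
        ov = signature_overlap(sig_h, sig_m, omap)
        assert ov.species_a_total == 92
        assert ov.species_b_total == 87
        assert ov.shared == 11

    def test_slc_composition(self):
        omap = self._map(7)
        sig_h = [f"hsa:S{i}" for i in range(7)] + [f"hsa:X{i}" for i in range(52)]
        sig_m = [f"mmu:S{i}" for i in range(7)] + [f"mmu:Y{i}" for i in range(74)]
        ov = signature_overlap(sig_h, sig_m, omap)
        assert (ov.species_a_total, ov.species_b_total) == (59, 81)

    def test_disjoint_signatures_share_nothing(self):
        omap = self._map(3)
        ov = signature_overlap(["hsa:X1"], ["mmu:Y1"], omap)
        assert ov.shared == 0 and ov.species_a_total == 1
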