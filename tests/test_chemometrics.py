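"""Descriptor PCA, similarity conventions and variable clustering."""

import numpy as np
import pandas as pd
import pytest

from bbbqsar.chemometrics import (
    DegenerateColumnError,
    cluster_variables,
    run_pca,
    similarity_matrix,
    standardize,
    variable_similarity,
)
from bbbqsar.dataset import descriptor_panel


@pytest.fixture(scope="module")
def panel(fixture_frame):
    return descriptor_panel(fixture_frame)


class TestStandardize:
    def test_simple_column(self):
        z = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["a"], [-1, 0, 1])

    def test_constant_column_named_in_error(self):
        frame = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(DegenerateColumnError, match="flat"):
            standardize(frame)

    def test_fixture_columns_zero_mean_unit_sd(self, panel):
        z = standardize(panel)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)


class TestPca:
    def test_eigenvalues_sum_to_descriptor_count(self, panel):
        pca = run_pca(panel)
        assert pca.eigenvalues.sum() == pytest.approx(panel.shape[1], abs=1e-10)
        assert (np.diff(pca.eigenvalues) <= 1e-12).all()

    def test_loadings_orthonormal(self, panel):
        L = run_pca(panel).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_correlation_matrix_reconstruction(self, panel):
        pca = run_pca(panel)
        L = pca.loadings.to_numpy()
        rebuilt = L @ np.diag(pca.eigenvalues) @ L.T
        corr = np.corrcoef(standardize(panel).to_numpy(), rowvar=False)
        assert np.allclose(rebuilt, corr, atol=1e-10)

    def test_scores_uncorrelated_across_components(self, panel):
        scores = run_pca(panel).scores.to_numpy()
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10

    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 20)
        pca = run_pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert np.allclose(np.abs(pca.loadings["PC1"]), 1 / np.sqrt(2), atol=1e-10)
        assert pca.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_matches_characteristic_polynomial_oracle(self):
        # brute-force eigenvalues of a 3x3 correlation matrix via poly roots
        corr = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, -0.3], [0.2, -0.3, 1.0]])
        chol = np.linalg.cholesky(corr)
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5000, 3)) @ chol.T
        pca = run_pca(pd.DataFrame(data, columns=list("abc")))
        sample_corr = np.corrcoef(data, rowvar=False)
        roots = np.sort(np.roots(np.poly(sample_corr)))[::-1]
        assert np.allclose(pca.eigenvalues, roots.real, atol=1e-8)

    def test_fewer_rows_than_columns_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            run_pca(pd.DataFrame(np.random.default_rng(0).random((3, 5))))

    def test_fixture_loading_values(self, panel):
        """PC1/PC2 loadings of the size and polarity descriptors (2-dp,
        magnitudes compared where the global component sign may flip)."""
        L = run_pca(panel).loadings
        assert L.loc["mw", "PC1"] == pytest.approx(0.49, abs=0.005)
        assert L.loc["alpha", "PC1"] == pytest.approx(0.42, abs=0.005)
        assert L.loc["tpsa", "PC1"] == pytest.approx(0.41, abs=0.005)
        assert L.loc["hb_total", "PC1"] == pytest.approx(0.40, abs=0.005)
        assert abs(L.loc["mw", "PC2"]) == pytest.approx(0.40, abs=0.005)
        assert abs(L.loc["alpha", "PC2"]) == pytest.approx(0.51, abs=0.005)
        assert abs(L.loc["tpsa", "PC2"]) == pytest.approx(0.52, abs=0.005)
        assert abs(L.loc["hb_total", "PC2"]) == pytest.approx(0.56, abs=0.005)


class TestSimilarity:
    def test_identical_vectors_give_100(self):
        x = np.arange(10.0)
        assert variable_similarity(x, x) == pytest.approx(100.0)

    def test_uncorrelated_gives_50_under_correlation_distance(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal
        assert variable_similarity(x, y, "correlation-distance") == pytest.approx(50.0)
        assert variable_similarity(x, y, "absolute-correlation") == pytest.approx(0.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        base = variable_similarity(x, y)
        assert variable_similarity(3 * x - 7, y) == pytest.approx(base, abs=1e-10)
        assert variable_similarity(x, 0.01 * y + 100) == pytest.approx(base, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateColumnError):
            variable_similarity(np.ones(5), np.arange(5.0))

    def test_fixture_size_pair_matches_calibrated_value(self, panel):
        sim = variable_similarity(panel["mw"], panel["alpha"])
        assert round(sim, 2) == 92.57

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            variable_similarity(np.arange(4.0), np.arange(4.0), "cosine")


class TestClustering:
    def test_three_cluster_cut_recovers_descriptor_blocks(self, panel):
        clustering = cluster_variables(similarity_matrix(panel))
        cut = clustering.cut(3)
        assert frozenset({"mw", "alpha"}) in cut
        assert frozenset({"tpsa", "hb_total"}) in cut
        assert frozenset({"nrb"}) in cut

    def test_merge_similarities_non_increasing(self, panel):
        clustering = cluster_variables(similarity_matrix(panel))
        sims = [s for _, _, s in clustering.merge_sequence]
        assert all(a >= b - 1e-9 for a, b in zip(sims, sims[1:]))

    def test_nrb_merge_levels_match_published_dendrogram(self, panel):
        """Single linkage: NRB joins the size cluster near 74.05% and the
        final merge with the polarity cluster lands at 68.98%."""
        clustering = cluster_variables(similarity_matrix(panel), "single")
        nrb_size = clustering.cluster_similarity(["nrb"], ["mw", "alpha"])
        nrb_pol = clustering.cluster_similarity(["nrb"], ["tpsa", "hb_total"])
        assert nrb_size == pytest.approx(74.05, abs=0.015)
        assert nrb_pol == pytest.approx(68.98, abs=0.005)
        # and those are actual merge heights of the dendrogram
        heights = [round(s, 2) for _, _, s in clustering.merge_sequence]
        assert round(nrb_size, 2) in heights
        assert round(nrb_pol, 2) in heights

    def test_two_variables_single_merge_at_pairwise_similarity(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"a": rng.standard_normal(30)})
        frame["b"] = frame["a"] * 0.5 + rng.standard_normal(30)
        sim = similarity_matrix(frame)
        clustering = cluster_variables(sim)
        assert len(clustering.merge_sequence) == 1
        _, _, level = clustering.merge_sequence[0]
        assert level == pytest.approx(sim.loc["a", "b"], abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame([[100.0, 30.0], [60.0, 100.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_variables(bad)
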