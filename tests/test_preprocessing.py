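import numpy as np
import pytest

from contraclust import (
    CountMatrix,
    PreprocessConfig,
    ValidationError,
    filter_genes,
    log_transform,
    normalize_library_size,
    preprocess,
    scale_genes,
    select_hvg,
)
from contraclust.preprocessing import dispersion_rank


def _cm(counts, labels=None):
    counts = np.asarray(counts, dtype=float)
    n, d = counts.shape
    return CountMatrix(
        counts, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(d)], labels
    )


class TestFilterGenes:
    def test_gene_in_single_cell_discarded(self):
        cm = _cm([[0, 1, 3], [5, 2, 0], [0, 3, 2]])
        out = filter_genes(cm, 2)
        # first gene expressed in one cell only -> dropped
        assert list(out.gene_ids) == ["g1", "g2"]

    def test_gene_in_two_cells_kept(self):
        cm = _cm([[0, 1], [1, 1], [2, 1]])
        out = filter_genes(cm, 2)
        assert list(out.gene_ids) == ["g0", "g1"]

    def test_dense_matrix_unchanged(self):
        cm = _cm(np.arange(1, 13).reshape(3, 4))
        out = filter_genes(cm, 2)
        np.testing.assert_array_equal(out.counts, cm.counts)

    def test_error_when_everything_removed(self):
        cm = _cm([[1, 0], [0, 1]])
        with pytest.raises(ValidationError):
            filter_genes(cm, 3)


class TestNormalizeLibrarySize:
    def test_hand_worked_example(self):
        # totals 4 and 8, median 6
        out = normalize_library_size(_cm([[1, 3, 0], [2, 2, 4]]))
        np.testing.assert_allclose(out, [[1.5, 4.5, 0.0], [1.5, 1.5, 3.0]])

    def test_identity_when_totals_equal(self):
        cm = _cm([[1, 3], [2, 2], [0, 4]])
        np.testing.assert_allclose(normalize_library_size(cm), cm.counts)

    def test_row_sums_equal_median(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.integers(1, 50, size=(11, 7)))
        out = normalize_library_size(cm)
        median = np.median(cm.counts.sum(axis=1))
        np.testing.assert_allclose(out.sum(axis=1), median, rtol=1e-9)

    def test_zero_total_cell_named_in_error(self):
        cm = _cm([[0, 0], [1, 2]])
        with pytest.raises(ValidationError, match="c0"):
            normalize_library_size(cm)


class TestLogTransform:
    def test_zeros_and_closed_form(self):
        out = log_transform(np.array([[0.0, np.e - 1.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0]])

    def test_order_preserving(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 100, size=(6, 5))
        out = log_transform(m)
        orig_order = np.argsort(m, axis=None)
        np.testing.assert_array_equal(np.argsort(out, axis=None), orig_order)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_transform(np.array([[-0.1]]))


class TestSelectHVG:
    def test_higher_dispersion_ranks_first(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 1, size=(200, 1))
        wide = 10 + 2.0 * (base - 10)  # same mean, 4x the variance
        m = np.hstack([base, wide])
        _, ranked = select_hvg(m, np.array(["narrow", "wide"], dtype=object), 2)
        assert list(ranked) == ["wide", "narrow"]

    def test_n_top_equal_d_is_permutation(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 5, size=(30, 8))
        ids = np.array([f"g{j}" for j in range(8)], dtype=object)
        _, ranked = select_hvg(m, ids, 8)
        assert sorted(ranked) == sorted(ids)

    def test_planted_variable_genes_recovered(self):
        """Genes with group-structured means rank inside the top selection."""
        rng = np.random.default_rng(4)
        n, d, planted = 120, 2000, 10
        m = rng.poisson(5.0, size=(n, d)).astype(float)
        groups = np.repeat([0, 1], n // 2)
        for j in range(planted):
            m[groups == 1, j] += 30.0
        m = np.log1p(m)
        _, ranked = select_hvg(m, np.arange(d).astype(object), 50)
        recovered = sum(1 for g in ranked if int(g) < planted)
        assert recovered >= 8

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 10, size=(40, 25))
        ids = np.array([f"g{j}" for j in range(25)], dtype=object)
        perm = rng.permutation(25)
        _, r1 = select_hvg(m, ids, 10)
        _, r2 = select_hvg(m[:, perm], ids[perm], 10)
        assert list(r1) == list(r2)

    def test_n_top_too_large_rejected(self):
        with pytest.raises(ValidationError):
            select_hvg(np.ones((3, 2)), np.array(["a", "b"], dtype=object), 5)

    def test_broadly_agrees_with_scanpy_dispersion_selection(self):
        """Cross-check against scanpy's binned-dispersion gene selection.

        The rankings differ in binning details (equal-frequency mean bins on
        the log matrix here, percentile bins with a median-based z-score in
        scanpy's cell_ranger flavour), so broad agreement, not identity, is
        the contract.
        """
        scanpy = pytest.importorskip("scanpy")
        import anndata

        rng = np.random.default_rng(6)
        counts = rng.negative_binomial(2, 0.3, size=(150, 400)).astype(float)
        logged = np.log1p(counts)
        adata = anndata.AnnData(X=logged)
        scanpy.pp.highly_variable_genes(adata, n_top_genes=50, flavor="cell_ranger")
        sc_top = set(np.flatnonzero(adata.var["highly_variable"].to_numpy()))
        ours = set(int(i) for i in dispersion_rank(logged)[:50])
        assert len(ours & sc_top) >= 35


class TestScaleGenes:
    def test_column_standardised(self):
        out, mean, std = scale_genes(np.array([[1.0], [2.0], [3.0]]))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1.0) < 1e-12

    def test_constant_column_becomes_zero(self):
        out, _, _ = scale_genes(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_array_equal(out, [[0.0], [0.0], [0.0]])

    def test_means_vanish_on_random_input(self):
        rng = np.random.default_rng(7)
        out, _, _ = scale_genes(rng.uniform(0, 9, size=(21, 13)))
        assert np.abs(out.mean(axis=0)).max() < 1e-10


class TestFullRecipe:
    def test_default_width_is_500(self, easy_dataset):
        pm = preprocess(easy_dataset.counts)
        assert pm.values.shape == (1000, 500)
        assert np.abs(pm.values.mean(axis=0)).max() < 1e-6
        stds = pm.values.std(axis=0)
        assert np.all((np.abs(stds - 1) < 1e-4) | (stds == 0))

    def test_step_toggles(self):
        rng = np.random.default_rng(8)
        cm = _cm(rng.integers(0, 9, size=(20, 30)))
        cfg = PreprocessConfig(n_top_genes="all", scale=False, log=False)
        pm = preprocess(cm, cfg)
        # only filtering + normalisation + reordering: row sums at the median
        median = np.median(cm.counts.sum(axis=1))
        np.testing.assert_allclose(pm.values.sum(axis=1), median, rtol=1e-9)
        assert pm.per_gene_mean is None

    def test_deterministic(self, tiny_dataset):
        a = preprocess(tiny_dataset.counts)
        b = preprocess(tiny_dataset.counts)
        assert np.array_equal(a.values, b.values)
        assert list(a.selected_genes) == list(b.selected_genes)
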