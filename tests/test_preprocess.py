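import numpy as np
import pandas as pd
import pytest

from csfprognostics.matrix import AbundanceMatrix
from csfprognostics.preprocess import (TamporConfig,
                                       bootstrap_regress_covariates,
                                       filter_completeness, filter_quantified,
                                       knn_impute, median_polish,
                                       scale_sample_loading, tampor,
                                       zeros_to_missing)

from conftest import make_matrix


def meta_for(m, batches):
    return pd.DataFrame({"sample_id": m.sample_ids, "batch_id": batches})


class TestScaleSampleLoading:
    def test_equal_loading_unchanged(self):
        m = make_matrix([[1, 2], [3, 2]], scale="raw")
        out = scale_sample_loading(m)
        assert np.allclose(out.values, m.values)

    def test_hand_computed_scaling_with_missing(self):
        m = make_matrix([[1, 4], [1, 0]], mask=[[False, False], [False, True]],
                        scale="raw")
        out = scale_sample_loading(m)
        assert np.allclose(out.values[:, 0], [2, 2])
        assert np.allclose(out.values[0, 1], 4)
        assert out.mask[1, 1]

    def test_column_sums_equalized(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(1, 10, (5, 4)), scale="raw")
        out = scale_sample_loading(m)
        sums = out.values.sum(axis=0)
        assert np.allclose(sums, m.values.sum(axis=0).max())

    def test_all_missing_sample_is_an_error(self):
        m = make_matrix([[0.0, 1.0]], mask=[[True, False]], scale="raw")
        with pytest.raises(ValueError, match="s0"):
            scale_sample_loading(m)


class TestZerosToMissing:
    def test_zero_cell_masked_and_conserved(self):
        m = make_matrix([[0.0, 5.0]], scale="raw")
        out = zeros_to_missing(m)
        assert out.mask[0, 0] and not out.mask[0, 1]
        assert out.mask.sum() == m.mask.sum() + (m.values == 0).sum()

    def test_no_zeros_is_a_no_op(self):
        m = make_matrix([[1.0, 5.0]], scale="raw")
        assert not zeros_to_missing(m).mask.any()


class TestQuantificationFilters:
    def test_half_observed_retained_inclusive(self):
        m = make_matrix(np.ones((1, 100)),
                        mask=[[True] * 50 + [False] * 50], scale="raw")
        assert filter_quantified(m).n_proteins == 1

    def test_below_half_dropped(self):
        m = make_matrix(np.ones((1, 100)),
                        mask=[[True] * 51 + [False] * 49], scale="raw")
        assert filter_quantified(m).n_proteins == 0

    @pytest.mark.parametrize("n_obs,kept", [(96, 1), (95, 0), (100, 1)])
    def test_completeness_boundary_is_strict(self, n_obs, kept):
        mask = [[False] * n_obs + [True] * (100 - n_obs)]
        m = make_matrix(np.ones((1, 100)), mask=mask)
        assert filter_completeness(m, 0.95).n_proteins == kept


class TestTampor:
    def test_constant_matrix_maps_to_zero(self):
        m = make_matrix(np.full((3, 6), 7.0), scale="raw")
        out = tampor(m, meta_for(m, ["a"] * 3 + ["b"] * 3))
        assert np.allclose(out.values, 0, atol=1e-8)
        assert out.scale == "log2"

    def test_per_batch_scalar_cancels_in_ratio_step(self):
        # batch2 = batch1 x 2 exactly; normalized values must coincide
        m = make_matrix([[10, 12, 20, 24], [5, 4, 10, 8]], scale="raw")
        out = tampor(m, meta_for(m, ["b1", "b1", "b2", "b2"]))
        assert np.allclose(out.values[:, :2], out.values[:, 2:], atol=1e-8)

    def test_exact_invariance_to_batch_scaling(self, small_cohort, small_config):
        meta, m, _ = small_cohort
        m = zeros_to_missing(m)
        base = tampor(m, meta)
        factor = np.where(
            meta.set_index("sample_id").loc[m.sample_ids, "batch_id"] == "b01",
            8.0, 1.0)
        scaled = AbundanceMatrix(m.values * factor[None, :], m.mask,
                                 m.protein_ids, m.sample_ids, "raw")
        out = tampor(scaled, meta)
        diff = np.abs(base.observed() - out.observed())
        assert np.nanmax(diff) < 1e-8

    def test_single_sample_rescaling_removed_by_polish(self, small_cohort):
        # An 8x (3 log2 units) rescaling of one sample is removed almost
        # entirely. Removal is not exact: the scaled sample shifts its own
        # batch's denominator median where it is the pivotal order statistic,
        # and the polish residual itself is not unique. What must hold is
        # that the residual effect is a tiny fraction of the injected offset.
        meta, m, _ = small_cohort
        m = zeros_to_missing(m)
        base = tampor(m, meta)
        factor = np.ones(m.n_samples)
        factor[5] = 8.0
        scaled = AbundanceMatrix(m.values * factor[None, :], m.mask,
                                 m.protein_ids, m.sample_ids, "raw")
        out = tampor(scaled, meta)
        diff = np.abs(base.observed() - out.observed())
        assert np.nanmax(diff) < 0.1  # vs the injected 3.0 log2 offset
        assert np.nanmedian(diff) < 0.01

    def test_polish_is_idempotent(self, small_cohort):
        meta, m, _ = small_cohort
        out = tampor(zeros_to_missing(m), meta)
        again, _, delta = median_polish(out.observed(), tol=1e-8)
        assert np.nanmax(np.abs(again - out.observed())) < 1e-6

    def test_row_and_column_medians_near_zero(self, small_cohort):
        meta, m, _ = small_cohort
        out = tampor(zeros_to_missing(m), meta)
        obs = out.observed()
        assert np.nanmax(np.abs(np.nanmedian(obs, axis=0))) < 1e-8
        assert np.nanmax(np.abs(np.nanmedian(obs, axis=1))) < 1e-8


class TestBootstrapRegression:
    def test_exact_linear_dependence_reduces_to_zero(self):
        x = np.arange(10.0)
        m = make_matrix(np.tile(2 * x, (3, 1)))
        out = bootstrap_regress_covariates(m, pd.DataFrame({"x": x}),
                                           n_boot=50, seed=0)
        assert np.allclose(out.values - out.values[:, :1], 0, atol=1e-10)

    def test_orthogonal_covariate_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        vals = np.tile(rng.normal(size=(4, 1)), (1, 12))  # constant rows
        m = make_matrix(vals)
        x = np.tile([0.0, 1.0], 6)
        out = bootstrap_regress_covariates(m, pd.DataFrame({"x": x}),
                                           n_boot=30, seed=0)
        assert np.allclose(out.values, vals, atol=1e-10)

    def test_constant_shift_of_covariate_absorbed_by_intercept(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        vals = 1.5 * x[None, :] + rng.normal(0, 0.01, (3, 20))
        m = make_matrix(vals)
        out1 = bootstrap_regress_covariates(m, pd.DataFrame({"x": x}),
                                            n_boot=40, seed=5)
        out2 = bootstrap_regress_covariates(m, pd.DataFrame({"x": x + 100}),
                                            n_boot=40, seed=5)
        centered1 = out1.values - out1.values.mean(axis=1, keepdims=True)
        centered2 = out2.values - out2.values.mean(axis=1, keepdims=True)
        assert np.allclose(centered1, centered2, atol=1e-8)

    def test_missing_cells_stay_missing(self):
        m = make_matrix(np.ones((2, 8)), mask=np.eye(2, 8, dtype=bool))
        out = bootstrap_regress_covariates(
            m, pd.DataFrame({"x": np.arange(8.0)}), n_boot=10, seed=0)
        assert np.array_equal(out.mask, m.mask)


class TestKnnImpute:
    def test_constant_row_imputes_the_constant(self):
        m = make_matrix(np.full((2, 6), 5.0), mask=[[False] * 6,
                                                    [True] + [False] * 5])
        out = knn_impute(m, k=2)
        assert np.isclose(out.values[1, 0], 5.0)
        assert not out.mask.any()

    def test_hand_computed_two_neighbour_mean(self):
        # samples s0..s2 over 3 proteins; s2 missing protein p2
        vals = np.array([[1.0, 1.1, 1.05],
                         [2.0, 2.2, 2.10],
                         [3.0, 3.1, 0.0]])
        mask = np.zeros((3, 3), bool)
        mask[2, 2] = True
        m = make_matrix(vals, mask=mask)
        out = knn_impute(m, k=2)
        # both donors observed at p2; nearest two samples are s0 and s1
        assert np.isclose(out.values[2, 2], np.mean([3.0, 3.1]))

    def test_observed_cells_unchanged(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 10))
        mask = rng.random((5, 10)) < 0.2
        mask[:, 0] = False
        m = make_matrix(np.where(mask, 0, vals), mask=mask)
        out = knn_impute(m, k=3)
        assert np.allclose(out.values[~mask], vals[~mask])

    def test_empty_sample_is_an_error(self):
        m = make_matrix([[0.0], [0.0]], mask=[[True], [True]])
        with pytest.raises(ValueError):
            knn_impute(m, k=1)
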