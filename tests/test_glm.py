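import numpy as np
import pandas as pd
import pytest
from scipy import stats

from limbicvbm import (VoxelwiseGLM, build_design_matrix, fdr_correct,
                       median_split, permutation_cluster_fwe,
                       uncorrected_tmap)
from conftest import make_stack


def ols_t_oracle(Y, X, c):
    """Long-hand normal-equations t statistic, independent of the package."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    s2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(s2 * (c @ XtX_inv @ c))
    return (c @ beta) / se


def _table(groups, ages=None, sexes=None):
    n = len(groups)
    return pd.DataFrame({
        "group": groups,
        "age": ages if ages is not None else np.linspace(50, 70, n),
        "sex": sexes if sexes is not None else ["F", "M"] * (n // 2) +
               ["F"] * (n % 2),
    })


class TestDesignMatrix:
    def test_minimal_design(self):
        d = build_design_matrix(_table(["control", "control", "pd", "pd"]),
                                covariates=())
        assert d.X.shape == (4, 2) and d.rank == 2
        np.testing.assert_array_equal(d.X[:, 1], [0, 0, 1, 1])
        np.testing.assert_array_equal(d.contrast, [0, 1])

    def test_single_sex_is_rank_deficient(self):
        with pytest.raises(ValueError, match="sex"):
            build_design_matrix(_table(["control", "pd"] * 3,
                                       sexes=["M"] * 6))

    def test_missing_covariate_values(self):
        t = _table(["control", "pd"] * 3)
        t.loc[2, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design_matrix(t)


class TestVoxelwiseGLM:
    def test_matches_ols_oracle(self, rng):
        vals = rng.random((6, 10))
        stack = make_stack(vals, shape=(10, 1, 1))
        design = build_design_matrix(stack.subjects)
        res = VoxelwiseGLM(stack, design).fit()
        oracle = ols_t_oracle(vals, design.X, design.contrast)
        np.testing.assert_allclose(res.t, oracle, atol=1e-8)

    def test_identical_groups_give_t_zero(self):
        row = np.linspace(0.4, 0.6, 5)
        vals = np.tile(row, (8, 1)) + np.arange(8)[:, None] * 0.01
        # same subject-level pattern in both groups after sorting rows
        vals = np.vstack([vals[:4], vals[:4]])
        stack = make_stack(vals, shape=(5, 1, 1),
                           ages=np.r_[np.arange(4), np.arange(4)],
                           groups=["control"] * 4 + ["pd"] * 4)
        design = build_design_matrix(stack.subjects, covariates=())
        res = VoxelwiseGLM(stack, design).fit()
        np.testing.assert_allclose(res.t, 0.0, atol=1e-10)

    def test_shift_invariance(self, rng):
        vals = rng.random((8, 6))
        stack = make_stack(vals, shape=(6, 1, 1))
        stack2 = make_stack(vals + 5.0, shape=(6, 1, 1))
        d = build_design_matrix(stack.subjects)
        t1 = VoxelwiseGLM(stack, d).fit().t
        t2 = VoxelwiseGLM(stack2, d).fit().t
        np.testing.assert_allclose(t1, t2, atol=1e-10)

    def test_age_centring_leaves_contrast_t_unchanged(self, rng):
        vals = rng.random((10, 4))
        stack = make_stack(vals, shape=(4, 1, 1))
        d1 = build_design_matrix(stack.subjects)
        t2_table = stack.subjects.copy()
        t2_table["age"] = t2_table["age"] - t2_table["age"].mean()
        d2 = build_design_matrix(t2_table)
        np.testing.assert_allclose(VoxelwiseGLM(stack, d1).fit().t,
                                   VoxelwiseGLM(stack, d2).fit().t,
                                   atol=1e-10)


class TestPermutationFWE:
    def _stack(self, rng, n=8, v=12):
        vals = rng.random((n, v))
        vals[n // 2:, 4:7] -= 0.4  # planted deficit in the pd half
        return make_stack(vals, shape=(v, 1, 1))

    def test_vacuous_threshold_gives_empty_clusters(self, rng):
        stack = self._stack(rng)
        d = build_design_matrix(stack.subjects, covariates=())
        res = permutation_cluster_fwe(stack, d, cluster_forming_t=1e6,
                                      n_perm=100, seed=1)
        assert len(res.cluster_table) == 0

    def test_corrected_p_lower_bound(self, rng):
        stack = self._stack(rng)
        d = build_design_matrix(stack.subjects, covariates=())
        res = permutation_cluster_fwe(stack, d, cluster_forming_t=1.5,
                                      n_perm=200, seed=2)
        assert res.exhaustive  # C(8,4)=70 < 200 -> exact enumeration
        assert (res.cluster_table["p_corr"] >= 1.0 / res.n_perm).all()
        assert (res.cluster_table["p_corr"] <= 1.0).all()

    def test_invariant_to_subject_order_and_constant_shift(self, rng):
        stack = self._stack(rng)
        d = build_design_matrix(stack.subjects, covariates=())
        res = permutation_cluster_fwe(stack, d, cluster_forming_t=1.5,
                                      n_perm=200, seed=3)
        perm = rng.permutation(stack.n_subjects)
        shuffled = make_stack(stack.values[perm] + 2.0, shape=(12, 1, 1),
                              groups=list(stack.subjects["group"].iloc[perm]),
                              ages=stack.subjects["age"].iloc[perm].to_numpy())
        d2 = build_design_matrix(shuffled.subjects, covariates=())
        res2 = permutation_cluster_fwe(shuffled, d2, cluster_forming_t=1.5,
                                       n_perm=200, seed=99)
        # exhaustive enumeration: seeds are irrelevant, p is exact
        np.testing.assert_allclose(
            np.sort(res.cluster_table["p_corr"].to_numpy()),
            np.sort(res2.cluster_table["p_corr"].to_numpy()), atol=1e-12)

    def test_small_n_perm_warns(self, rng):
        stack = self._stack(rng)
        d = build_design_matrix(stack.subjects, covariates=())
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_cluster_fwe(stack, d, n_perm=50, seed=1)


class TestUncorrected:
    def test_identical_groups_nothing_survives(self):
        vals = np.tile(np.linspace(0.3, 0.7, 6), (10, 1))
        vals += np.random.default_rng(0).normal(0, 0.01, vals.shape)
        half = vals[:5]
        vals = np.vstack([half, half])
        stack = make_stack(vals, shape=(6, 1, 1),
                           groups=["control"] * 5 + ["pd"] * 5,
                           ages=np.r_[np.arange(5), np.arange(5)])
        d = build_design_matrix(stack.subjects, covariates=())
        _, table = uncorrected_tmap(stack, d)
        assert len(table) == 0

    def test_pooled_variance_t_oracle(self, rng):
        a = rng.random(5)
        b = rng.random(5) + 0.3
        vals = np.r_[a, b][:, None]
        stack = make_stack(vals, shape=(1, 1, 1),
                           groups=["control"] * 5 + ["pd"] * 5)
        d = build_design_matrix(stack.subjects, covariates=())
        tmap, _ = uncorrected_tmap(stack, d)
        # textbook pooled-variance two-sample t (b vs a)
        sp2 = ((a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8)
        t_hand = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert tmap.data[0, 0, 0] == pytest.approx(t_hand, abs=1e-10)

    def test_default_thresholds(self):
        import inspect
        sig = inspect.signature(uncorrected_tmap)
        assert sig.parameters["t_threshold"].default == 2.8
        assert sig.parameters["p_threshold"].default == 0.005


class TestFdrAndSplit:
    def test_all_ones_nothing_significant(self):
        reject, _ = fdr_correct(np.ones(10))
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, adj = fdr_correct(np.array([0.01]), q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.01)

    def test_step_up_by_hand(self):
        # sorted p vs q*k/m: 0.001<=0.0125, 0.01<=0.025, 0.02<=0.0375,
        # 0.9>0.05 -> first three rejected
        reject, _ = fdr_correct(np.array([0.001, 0.01, 0.02, 0.9]), q=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])

    def test_nan_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            reject, adj = fdr_correct(np.array([0.001, np.nan]), q=0.05)
        assert reject[0] and not reject[1] and np.isnan(adj[1])

    def test_median_split_two_point(self):
        t = pd.DataFrame({"updrs3": [10.0, 30.0]})
        mild, moderate = median_split(t)
        assert (len(mild), len(moderate)) == (1, 1)

    def test_threshold_value_goes_to_upper_group(self):
        mild, moderate = median_split(pd.DataFrame({"updrs3": [21.0]}))
        assert len(mild) == 0 and len(moderate) == 1

    def test_median_threshold_balances_sizes(self, rng):
        scores = rng.permutation(np.linspace(0, 60, 101))
        t = pd.DataFrame({"updrs3": scores})
        mild, moderate = median_split(t, threshold=float(np.median(scores)))
        assert abs(len(mild) - len(moderate)) <= 1

    def test_missing_scores_excluded(self):
        t = pd.DataFrame({"updrs3": [10.0, np.nan, 30.0]})
        mild, moderate = median_split(t)
        assert len(mild) + len(moderate) == 2
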