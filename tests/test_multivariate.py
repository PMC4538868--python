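"""PCA, clustering and OPLS-DA against independent oracles and identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ionopls.multivariate import (
    compute_pcorr,
    compute_vip,
    cross_validate_q2,
    cv_anova,
    fit_opls_da,
    fit_pca,
    hierarchical_cluster,
    variable_stats,
)
from ionopls.preprocess import autoscale

from conftest import pls1_nipals


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


def _labels(n1, n2):
    idx = [f"s{i}" for i in range(n1 + n2)]
    return pd.Series(["ctrl"] * n1 + ["trt"] * n2, index=idx)


class TestPca:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(5, 4)))
        model = fit_pca(X, 3)
        centered = X - X.mean()
        evals = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        np.testing.assert_allclose(
            model.scores.var(axis=0, ddof=1), evals[:3], rtol=1e-10
        )
        np.testing.assert_allclose(
            model.r2x, evals[:3] / evals.sum(), rtol=1e-10
        )
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(3), atol=1e-10
        )

    def test_rank_one_matrix_fully_explained_by_first_component(self):
        u = np.arange(1.0, 7.0)
        v = np.array([2.0, -1.0, 3.0])
        model = fit_pca(_frame(np.outer(u, v)), 1)
        assert model.r2x[0] == pytest.approx(1.0)

    def test_rotation_leaves_spectrum_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        a = fit_pca(_frame(X), 4)
        b = fit_pca(_frame(X @ Q), 4)
        np.testing.assert_allclose(a.r2x, b.r2x, atol=1e-10)

    def test_components_beyond_rank_rejected(self):
        X = _frame(np.outer(np.arange(4.0), [1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 3)


class TestHierarchicalCluster:
    def test_two_separated_groups_split_at_the_top(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(12, 1, (6, 4))])
        Z, order = hierarchical_cluster(_frame(X))
        groups = [int(s[1:]) < 5 for s in order]
        assert sum(a != b for a, b in zip(groups, groups[1:])) == 1

    def test_duplicate_samples_merge_at_height_zero(self):
        X = _frame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        Z, _ = hierarchical_cluster(X)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_single_sample_trivial_tree(self):
        Z, order = hierarchical_cluster(_frame([[1.0, 2.0]]))
        assert len(Z) == 0 and order == ["s0"]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            hierarchical_cluster(_frame([[1.0, np.nan], [2.0, 3.0]]))


class TestOplsDa:
    def test_no_orthogonal_components_matches_pls1_nipals(self):
        """With n_orth=0 the predictive component is PLS1's first component."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = _frame(rng.normal(size=(12, 30)))
            labels = _labels(6, 6)
            model = fit_opls_da(autoscale(X), labels, n_orth=0)
            Xc = autoscale(X).values.to_numpy()
            y = np.where(labels == "trt", 1.0, -1.0)
            w, t, q = pls1_nipals(Xc - Xc.mean(0), y - y.mean())
            sign = np.sign(w @ model.w.to_numpy())
            np.testing.assert_allclose(model.w, sign * w, atol=1e-8)
            np.testing.assert_allclose(model.t, sign * t, atol=1e-8)

    def test_predictions_match_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(10, 6)))
        labels = _labels(5, 5)
        model = fit_opls_da(autoscale(X), labels, n_orth=0)
        y = np.where(labels == "trt", 1.0, -1.0)
        sk = PLSRegression(n_components=1, scale=False).fit(autoscale(X).values, y)
        np.testing.assert_allclose(
            model.predict(autoscale(X).values).to_numpy(),
            sk.predict(autoscale(X).values).ravel(),
            atol=1e-8,
        )

    def test_pure_class_difference_gives_r2y_one(self):
        X = np.zeros((8, 5))
        X[4:] += np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        model = fit_opls_da(_frame(X), _labels(4, 4), n_orth=0)
        assert model.r2y == pytest.approx(1.0)

    def test_orthogonal_filtering_rescues_separation(self):
        """Large y-orthogonal structured variation mixes the PLS score but
        not the OPLS 1+1 predictive score."""
        rng = np.random.default_rng(4)
        n = 14
        y = np.array([-1.0] * 7 + [1.0] * 7)
        g = rng.normal(size=n) * 6
        g -= g @ y / (y @ y) * y  # exactly y-orthogonal confounder
        a = rng.normal(size=25)
        b = a + rng.normal(size=25) * 0.6  # overlapping loading directions
        X = np.outer(y, a) + np.outer(g, b) + rng.normal(size=(n, 25)) * 0.1
        labels = _labels(7, 7)

        def sep(t):
            return abs(stats.ttest_ind(t[:7], t[7:]).statistic)

        t_pls = fit_opls_da(_frame(X), labels, n_orth=0).t.to_numpy()
        t_opls = fit_opls_da(_frame(X), labels, n_orth=1).t.to_numpy()
        assert sep(t_opls) > 2 * sep(t_pls)
        assert sep(t_opls) > 5

    def test_deflation_leaves_no_orthogonal_projection(self):
        rng = np.random.default_rng(5)
        X = _frame(rng.normal(size=(12, 20)))
        model = fit_opls_da(autoscale(X), _labels(6, 6), n_orth=3)
        for a in model.T_o.columns:
            assert abs(model.t @ model.T_o[a]) < 1e-8
        assert np.linalg.norm(model.w) == pytest.approx(1.0)

    def test_r2y_non_decreasing_in_orthogonal_components(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(size=(12, 15)))
        labels = _labels(6, 6)
        r2 = [fit_opls_da(autoscale(X), labels, n_orth=k).r2y for k in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_sign_convention_points_to_positive_class(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        X[5:, 0] += 4.0
        labels = _labels(5, 5)
        model = fit_opls_da(autoscale(_frame(X)), labels, n_orth=0, positive_class="trt")
        assert model.t[labels == "trt"].mean() > model.t[labels == "ctrl"].mean()
        assert compute_pcorr(model, autoscale(_frame(X)))[0] > 0

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(8)
        X = _frame(rng.normal(size=(6, 4)))
        one_class = pd.Series(["a"] * 6, index=X.index)
        with pytest.raises(ValueError, match="two classes"):
            fit_opls_da(X, one_class)
        labels = _labels(3, 3)
        with pytest.raises(ValueError, match="n_orth"):
            fit_opls_da(X, labels, n_orth=-1)
        with pytest.raises(ValueError, match="rank"):
            fit_opls_da(X, labels, n_orth=10)


class TestCrossValidation:
    def test_strong_effect_gives_high_q2_and_significance(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 100))
            X[5:, :50] += 6.0
            labels = _labels(5, 5)
            cv = cross_validate_q2(autoscale(_frame(X)), labels, n_orth=1)
            assert cv.q2 > 0.9
            _, p = cv_anova(cv, 2)
            assert p < 0.05

    def test_permuted_labels_average_near_zero(self):
        rng = np.random.default_rng(9)
        X = autoscale(_frame(rng.normal(size=(12, 25))))
        vals = []
        base = np.array(["ctrl"] * 6 + ["trt"] * 6)
        for _ in range(100):
            labels = pd.Series(rng.permutation(base), index=X.values.index)
            vals.append(cross_validate_q2(X, labels, n_orth=0).q2)
        assert max(vals) <= 1.0
        assert np.mean(vals) < 0.1

    def test_fold_count_exceeding_samples_rejected(self):
        rng = np.random.default_rng(10)
        X = autoscale(_frame(rng.normal(size=(6, 4))))
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate_q2(X, _labels(3, 3), n_folds=9)

    def test_cv_anova_limits_and_df_checks(self):
        from ionopls.multivariate import CvResult

        cv = CvResult(q2=0.0, press=10.0, ss=10.0, n=12,
                      predictions=pd.Series(dtype=float), folds=pd.Series(dtype=int))
        F, p = cv_anova(cv, 2)
        assert F <= 0 and p == 1.0
        with pytest.raises(ValueError, match="degrees of freedom"):
            cv_anova(CvResult(0.0, 1.0, 2.0, 3, pd.Series(dtype=float),
                              pd.Series(dtype=int)), 2)


class TestVariableStats:
    def test_vip_mean_square_is_one_and_copies_get_unit_vip(self):
        rng = np.random.default_rng(11)
        X = _frame(rng.normal(size=(10, 12)))
        model = fit_opls_da(autoscale(X), _labels(5, 5), n_orth=1)
        vip = compute_vip(model)
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-8)
        col = rng.normal(size=10)
        copies = _frame(np.tile(col[:, None], (1, 5)))
        m2 = fit_opls_da(autoscale(copies), _labels(5, 5), n_orth=0)
        np.testing.assert_allclose(compute_vip(m2), 1.0, atol=1e-10)

    def test_informative_variable_tops_vip_ranking(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 20))
            X[6:, 0] += 3.5
            model = fit_opls_da(autoscale(_frame(X)), _labels(6, 6), n_orth=0)
            wins += int(compute_vip(model).idxmax() == 0)
        assert wins >= 95

    def test_pcorr_exact_for_score_aligned_columns(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 4))
        labels = _labels(5, 5)
        X[5:, 0] += 5.0
        model = fit_opls_da(autoscale(_frame(X)), labels, n_orth=0)
        t = model.t.to_numpy()
        aug = _frame(np.column_stack([t, -t, X]))
        pc = compute_pcorr(model, aug)
        assert pc[0] == pytest.approx(1.0)
        assert pc[1] == pytest.approx(-1.0)

    def test_pcorr_matches_direct_correlation_oracle(self):
        rng = np.random.default_rng(13)
        X = _frame(rng.normal(size=(10, 6)))
        model = fit_opls_da(autoscale(X), _labels(5, 5), n_orth=1)
        pc = compute_pcorr(model, autoscale(X))
        for j in range(6):
            direct = np.corrcoef(autoscale(X).values[j], model.t)[0, 1]
            assert pc[j] == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_column_gives_missing_pcorr(self):
        rng = np.random.default_rng(14)
        X = np.column_stack([rng.normal(size=(10, 3)), np.zeros(10)])
        labels = _labels(5, 5)
        model = fit_opls_da(_frame(X) - _frame(X).mean(), labels, n_orth=0)
        pc = compute_pcorr(model, _frame(X))
        assert np.isnan(pc[3]) and pc[:3].notna().all()

    def test_label_flip_leaves_magnitudes_invariant(self):
        rng = np.random.default_rng(15)
        X = autoscale(_frame(rng.normal(size=(10, 8))))
        labels = _labels(5, 5)
        a = variable_stats(fit_opls_da(X, labels, positive_class="trt"), X)
        b = variable_stats(fit_opls_da(X, labels, positive_class="ctrl"), X)
        np.testing.assert_allclose(a["vip"], b["vip"], atol=1e-10)
        np.testing.assert_allclose(a["pcorr"], -b["pcorr"], atol=1e-10)
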