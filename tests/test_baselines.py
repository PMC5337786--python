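import numpy as np
import pytest

from hybridbci.baselines import (CSPModel, csp_features, csp_fit, lda_fit,
                                 lda_score, prob_fuse, swlda_fit, swlda_score)
from hybridbci.core import DataError


class TestCSP:
    def test_two_channel_toy_closed_form(self):
        model = csp_fit([np.diag([4.0, 1.0])], [np.diag([1.0, 4.0])])
        assert np.allclose(model.eigenvalues, [0.8, 0.2])
        w = model.filters[0]
        assert abs(w[0]) > abs(w[1])  # first filter selects channel 1

    def test_equal_class_covariances_give_half_eigenvalues(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((4, 4))
        S = M @ M.T
        model = csp_fit([S], [S])
        assert np.allclose(model.eigenvalues, 0.5)

    def test_filters_normalize_composite_covariance(self):
        rng = np.random.default_rng(1)
        A, B = rng.standard_normal((2, 5, 5))
        Sp, Sm = A @ A.T, B @ B.T
        model = csp_fit([Sp], [Sm])
        for w in model.filters:
            assert np.isclose(w @ (Sp + Sm) @ w, 1.0, atol=1e-8)

    def test_swapped_classes_reverse_eigenvalue_order(self):
        rng = np.random.default_rng(2)
        A, B = rng.standard_normal((2, 4, 4))
        Sp, Sm = A @ A.T, B @ B.T
        fwd = csp_fit([Sp], [Sm]).eigenvalues
        rev = csp_fit([Sm], [Sp]).eigenvalues
        assert np.allclose(np.sort(fwd), np.sort(1.0 - rev), atol=1e-8)

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            csp_fit([], [np.eye(3)])


class TestCSPFeatures:
    def _toy_segments(self, n=30, seed=3):
        # class +1 strong on channel 0, class -1 strong on channel 1
        rng = np.random.default_rng(seed)
        pos = [np.diag([3.0, 1.0]) @ rng.standard_normal((2, 200))
               for _ in range(n)]
        neg = [np.diag([1.0, 3.0]) @ rng.standard_normal((2, 200))
               for _ in range(n)]
        return pos, neg

    def test_class_discriminative_sign_pattern(self):
        pos, neg = self._toy_segments()
        covs = lambda xs: [np.cov(x) for x in xs]
        model = csp_fit(covs(pos), covs(neg), n_pairs=1)
        fp = np.mean([csp_features(s, model, m=1) for s in pos], axis=0)
        fn = np.mean([csp_features(s, model, m=1) for s in neg], axis=0)
        assert fp[0] > fn[0]       # first filter favors class +1 variance
        assert fp[1] < fn[1]

    def test_scale_invariance(self):
        pos, neg = self._toy_segments(seed=4)
        model = csp_fit([np.cov(x) for x in pos], [np.cov(x) for x in neg],
                        n_pairs=1)
        f1 = csp_features(pos[0], model, m=1)
        f2 = csp_features(17.0 * pos[0], model, m=1)
        assert np.allclose(f1, f2, atol=1e-12)

    def test_equal_variance_filters_give_uniform_features(self):
        model = CSPModel(filters=np.eye(2), eigenvalues=np.array([0.5, 0.5]),
                         n_pairs=1)
        rng = np.random.default_rng(5)
        seg = np.tile(rng.standard_normal(300), (2, 1))
        f = csp_features(seg, model, m=1)
        assert np.allclose(f, np.log(0.5), atol=1e-12)


class TestLDA:
    def test_separated_clouds_fit_perfectly(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(5, 1, (30, 3)), rng.normal(-5, 1, (30, 3))])
        y = np.array([1] * 30 + [-1] * 30)
        model = lda_fit(X, y)
        preds = [1 if lda_score(model, x) >= 0 else -1 for x in X]
        assert np.array_equal(preds, y)

    def test_identical_means_give_negligible_weights(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (200, 4))
        y = np.array([1, -1] * 100)
        model = lda_fit(X, y)
        assert np.linalg.norm(model.weights) < 0.5  # no signal to latch onto

    def test_class_mean_midpoint_scores_zero(self):
        rng = np.random.default_rng(8)
        Xp = rng.normal(2, 1, (40, 3))
        Xn = rng.normal(-1, 1, (40, 3))
        model = lda_fit(np.vstack([Xp, Xn]), [1] * 40 + [-1] * 40)
        mid = 0.5 * (Xp.mean(axis=0) + Xn.mean(axis=0))
        assert abs(lda_score(model, mid)) < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            lda_fit(np.zeros((10, 2)), np.ones(10))


class TestSWLDA:
    def test_informative_feature_selected_first(self):
        rng = np.random.default_rng(9)
        n = 60
        y = np.array([1, -1] * (n // 2), dtype=float)
        X = rng.standard_normal((n, 30))
        X[:, 17] = y + 0.05 * rng.standard_normal(n)
        model = swlda_fit(X, y)
        assert model.selected[0] == 17

    def test_zero_entry_threshold_gives_intercept_only(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 20))
        y = np.array([1, -1] * 20, dtype=float)
        model = swlda_fit(X, y, p_enter=0.0)
        assert model.intercept_only
        assert len(model.selected) == 0
        assert swlda_score(model, X[0]) == model.intercept

    def test_cap_on_selected_features(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 555))
        y = np.array([1, -1] * 50, dtype=float)
        model = swlda_fit(X, y, p_enter=0.9, p_remove=0.95, max_features=60)
        assert len(model.selected) <= 60

    def test_selection_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((50, 40))
        y = np.array([1, -1] * 25, dtype=float)
        X[:, 3] += y
        m1 = swlda_fit(X, y)
        perm = rng.permutation(50)
        m2 = swlda_fit(X[perm], y[perm])
        assert set(m1.selected) == set(m2.selected)


class TestProbFusion:
    def test_positive_average(self):
        assert prob_fuse(2.0, -1.0) == 1

    def test_zero_average_is_minus_one(self):
        # strict "larger than 0" rule, unlike the DS classifier's ">= 0"
        assert prob_fuse(1.0, -1.0) == -1
        assert prob_fuse(0.0, 0.0) == -1

    def test_idempotent_on_matching_scores(self):
        assert prob_fuse(0.7, 0.7) == 1
        assert prob_fuse(-0.7, -0.7) == -1

    def test_uninformative_partner_degenerates_to_strict_sign(self):
        assert prob_fuse(0.0, 2.0) == 1
        assert prob_fuse(0.0, -2.0) == -1
        assert prob_fuse(0.0, 0.0) == -1
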