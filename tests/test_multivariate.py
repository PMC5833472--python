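"""PLS-DA / OPLS-DA models, cross-validation and permutation testing."""

import numpy as np
import pytest

from plasmet.core import ValidationError
from plasmet.multivariate import (
    cross_validate,
    fit_oplsda,
    fit_plsda,
    permutation_validate,
    project_samples,
)


def two_cluster_data(n_per=20, p=5, sep=10.0, seed=0, noise_features=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p + noise_features))
    X[n_per:, :p] += sep
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestPLSDA:
    def test_first_weight_closed_form(self):
        """NIPALS component-1 weight is proportional to X_scaled^T y_centered
        for a two-class problem (single effective indicator direction)."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 8))
        y = np.array(["a"] * 15 + ["b"] * 15)
        m = fit_plsda(X, y, n_components=1)
        Z = (X - m.x_mean_) / m.x_std_
        yc = (y == "b").astype(float)
        yc -= yc.mean()
        w_oracle = Z.T @ yc
        w_oracle /= np.linalg.norm(w_oracle)
        # align sign before comparing
        w = m.x_weights_[:, 0]
        if np.dot(w, w_oracle) < 0:
            w_oracle = -w_oracle
        np.testing.assert_allclose(w, w_oracle, atol=1e-10)

    def test_matches_sklearn_pls_scores(self):
        """Independent cross-check: scores agree with sklearn's NIPALS
        PLSRegression on a centered/scaled two-class problem."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_cluster_data(n_per=12, p=6, sep=1.0, seed=3, noise_features=4)
        m = fit_plsda(X, y, n_components=2)
        yv = (y == "b").astype(float)
        sk = PLSRegression(n_components=2, scale=True).fit(X, yv)
        for k in range(2):
            a = m.x_scores_[:, k]
            b = sk.x_scores_[:, k]
            if np.dot(a, b) < 0:
                b = -b
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-8)

    def test_perfect_separation_scores_disjoint(self):
        X, y = two_cluster_data(sep=10.0)
        m = fit_plsda(X, y, n_components=1)
        s_a = m.x_scores_[y == "a", 0]
        s_b = m.x_scores_[y == "b", 0]
        assert max(s_a.max(), s_b.max()) == pytest.approx(
            max(np.concatenate([s_a, s_b]))
        )
        assert s_a.max() < s_b.min() or s_b.max() < s_a.min()

    def test_exact_linear_fit_r2y_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        # y indicator exactly linear in X: threshold a noiseless score
        score = X @ np.array([1.0, -2.0, 0.5, 0, 0, 0])
        y = np.where(score > np.median(score), "hi", "lo")
        # make the indicator literally linear: regress on the sign pattern
        Xlin = np.column_stack([score > np.median(score), rng.normal(size=(40, 3))])
        m = fit_plsda(Xlin.astype(float), y, n_components=4)
        assert m.r2y_cum_[-1] == pytest.approx(1.0, abs=1e-8)

    def test_r2y_monotone_bounded(self):
        X, y = two_cluster_data(sep=1.0, noise_features=10)
        m = fit_plsda(X, y, n_components=4)
        r2 = m.r2y_cum_
        assert np.all(np.diff(r2) >= -1e-12)
        assert r2[-1] <= 1 + 1e-12

    def test_score_orthogonality(self):
        X, y = two_cluster_data(sep=1.0, seed=4, noise_features=10)
        m = fit_plsda(X, y, n_components=3)
        T = m.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_constant_column_rejected_by_name(self):
        import pandas as pd

        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)),
                         columns=["m1", "m2", "flat"])
        X["flat"] = 1.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValidationError, match="flat"):
            fit_plsda(X, y, 1)

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValidationError, match="b"):
            fit_plsda(X, y, 1)


class TestOPLSDA:
    def test_zero_orthogonal_equals_one_component_plsda(self):
        X, y = two_cluster_data(sep=1.0, seed=5, noise_features=8)
        o = fit_oplsda(X, y, n_orthogonal=0)
        p = fit_plsda(X, y, n_components=1)
        np.testing.assert_allclose(
            o.x_scores_[:, 0], p.x_scores_[:, 0], rtol=1e-8, atol=1e-8
        )

    def test_score_orthogonality(self):
        X, y = two_cluster_data(sep=1.0, seed=6, noise_features=8)
        o = fit_oplsda(X, y, n_orthogonal=2)
        t = o.x_scores_[:, 0]
        for k in range(o.n_orthogonal_):
            to = o.ortho_scores_[:, k]
            assert abs(t @ to) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(to)

    def test_confound_removal_not_worse_than_plsda(self):
        """Planted y-orthogonal structured variation: OPLS predictive scores
        separate classes at least as well as PLS-DA component 1."""
        rng = np.random.default_rng(7)
        n = 40
        y = np.array(["a"] * 20 + ["b"] * 20)
        signal = (y == "b").astype(float) - 0.5
        confound = rng.normal(size=n)  # independent of y by construction
        confound -= confound.mean()
        X = np.outer(signal, rng.normal(size=15)) * 0.8
        X += np.outer(confound, rng.normal(size=15)) * 3.0
        X += rng.normal(size=(n, 15)) * 0.3

        def smd(scores):
            a, b = scores[y == "a"], scores[y == "b"]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        o = fit_oplsda(X, y, n_orthogonal=1)
        p = fit_plsda(X, y, n_components=1)
        assert smd(o.x_scores_[:, 0]) >= smd(p.x_scores_[:, 0]) - 1e-9

    def test_requires_two_classes(self):
        X = np.random.default_rng(0).normal(size=(9, 4))
        y = np.array(["a", "b", "c"] * 3)
        with pytest.raises(ValidationError, match="2 classes"):
            fit_oplsda(X, y, 1)


class TestProjection:
    def test_self_projection_reproduces_training_scores(self):
        X, y = two_cluster_data(sep=2.0, seed=8)
        for m in (fit_plsda(X, y, 2), fit_oplsda(X, y, 1)):
            np.testing.assert_allclose(
                project_samples(m, X), m.x_scores_ if m.kind == "plsda"
                else np.column_stack([m.x_scores_, m.ortho_scores_]),
                atol=1e-10,
            )

    def test_training_mean_projects_to_origin(self):
        X, y = two_cluster_data(sep=2.0, seed=9)
        m = fit_plsda(X, y, 2)
        scores = project_samples(m, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_pooled_qc_projects_near_source_groups(self):
        """A QC pooled from groups A and B lands nearer the A/B centroid
        midpoint than to group C's centroid."""
        rng = np.random.default_rng(10)
        p = 12
        mu = {g: rng.normal(scale=3.0, size=p) for g in "ABC"}
        X = np.vstack([mu[g] + rng.normal(scale=0.5, size=(15, p)) for g in "ABC"])
        y = np.repeat(list("ABC"), 15)
        m = fit_plsda(X, y, 2)
        qc = ((mu["A"] + mu["B"]) / 2 + rng.normal(scale=0.1, size=(6, p)))
        qc_scores = project_samples(m, qc).mean(axis=0)
        cent = {g: m.x_scores_[y == g].mean(axis=0) for g in "ABC"}
        d_ab = np.linalg.norm(qc_scores - (cent["A"] + cent["B"]) / 2)
        d_c = np.linalg.norm(qc_scores - cent["C"])
        assert d_ab < d_c

    def test_feature_mismatch_rejected(self):
        X, y = two_cluster_data()
        m = fit_plsda(X, y, 1)
        with pytest.raises(ValidationError, match="feature"):
            project_samples(m, X[:, :-1])


class TestCrossValidation:
    def test_partition_each_sample_predicted_once(self):
        X, y = two_cluster_data(n_per=14, sep=1.0)
        q = cross_validate(X, y, "plsda", 2, folds=7, seed=1)
        assert int(q.classification_table.to_numpy().sum()) == len(y)
        assert q.classification_table.loc["a"].sum() == 14
        assert q.classification_table.loc["b"].sum() == 14

    def test_separable_classes_cc_100(self):
        X, y = two_cluster_data(n_per=21, sep=10.0)
        q = cross_validate(X, y, "plsda", 2, folds=7, seed=0)
        assert q.cc_percent == 100.0

    def test_cc_invariant_to_label_renaming(self):
        X, y = two_cluster_data(n_per=14, sep=1.5)
        q1 = cross_validate(X, y, "plsda", 2, folds=7, seed=3)
        renamed = np.where(y == "a", "zzz", "qqq")
        q2 = cross_validate(X, renamed, "plsda", 2, folds=7, seed=3)
        assert q1.cc_percent == q2.cc_percent

    def test_reproducible_with_seed(self):
        X, y = two_cluster_data(n_per=14, sep=0.5, noise_features=5)
        q1 = cross_validate(X, y, "plsda", 2, folds=7, seed=42)
        q2 = cross_validate(X, y, "plsda", 2, folds=7, seed=42)
        assert q1.q2_cum == q2.q2_cum
        assert q1.cc_percent == q2.cc_percent

    def test_too_few_samples_errors(self):
        X, y = two_cluster_data(n_per=3)
        with pytest.raises(ValidationError):
            cross_validate(X, y, "plsda", 1, folds=7, seed=0)
        # folds reduced with a warning when classes are small but viable
        with pytest.warns(UserWarning, match="reducing folds"):
            q = cross_validate(np.vstack([X, X]), np.concatenate([y, y]),
                              "plsda", 1, folds=7, seed=0)
        assert q.folds == 6

    def test_q2_le_r2y_on_random_data(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 15))
            beta = rng.normal(size=15)
            y = np.where(X @ beta + rng.normal(size=30) > 0, "a", "b")
            if min((y == "a").sum(), (y == "b").sum()) < 5:
                continue
            q = cross_validate(X, y, "plsda", 2, folds=5, seed=seed)
            hits += q.q2 <= q.r2y + 1e-9
        assert hits >= 0.95 * 20 - 1  # sanity band, not a theorem


class TestPermutation:
    def test_add_one_bound_and_strong_separation(self):
        X, y = two_cluster_data(n_per=14, sep=10.0)
        p_r2y, p_q2 = permutation_validate(X, y, "plsda", 2,
                                           n_permutations=99, folds=7, seed=0)
        assert p_q2 >= 1 / 100
        assert p_q2 == pytest.approx(0.01)

    def test_minimum_permutations_enforced(self):
        X, y = two_cluster_data()
        with pytest.raises(ValidationError):
            permutation_validate(X, y, "plsda", 1, n_permutations=5, seed=0)
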