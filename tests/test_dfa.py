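import numpy as np
import pytest

from caretraj import dfa


def gaussian_groups(rng, means, n_per, cov=None):
    p = len(means[0])
    cov = np.eye(p) if cov is None else cov
    X = np.vstack([rng.multivariate_normal(m, cov, size=n)
                   for m, n in zip(means, n_per)])
    y = np.repeat(np.arange(len(means)), n_per)
    return X, y


class TestFit:
    def test_two_separated_1d_groups(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_groups(rng, [[-3.0], [3.0]], [50, 50])
        m = dfa.fit(X, y)
        assert m.s == 1
        assert m.centroids[0, 0] == pytest.approx(-m.centroids[1, 0],
                                                  abs=1e-9)

    def test_identical_groups_zero_eigenvalues(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 3))
        X = np.vstack([base, base])
        y = np.repeat([0, 1], 40)
        m = dfa.fit(X, y)
        assert np.allclose(m.eigenvalues, 0.0, atol=1e-9)

    def test_six_predictors_five_groups_give_four_functions(self):
        rng = np.random.default_rng(2)
        means = rng.normal(size=(5, 6))
        X, y = gaussian_groups(rng, means, [30] * 5)
        m = dfa.fit(X, y)
        assert m.s == 4

    def test_canonical_scores_unit_pooled_within_variance(self):
        rng = np.random.default_rng(3)
        means = rng.normal(scale=2.0, size=(4, 5))
        X, y = gaussian_groups(rng, means, [40, 50, 60, 30])
        m = dfa.fit(X, y)
        scores = m.scores(X)
        n, g = len(X), 4
        for i in range(m.s):
            within = sum(
                ((scores[y == k, i] - scores[y == k, i].mean()) ** 2).sum()
                for k in range(g)) / (n - g)
            assert within == pytest.approx(1.0, abs=1e-9)
        # zero pooled within-group correlation across functions
        W = np.zeros((m.s, m.s))
        for k in range(g):
            d = scores[y == k] - scores[y == k].mean(axis=0)
            W += d.T @ d
        off = W - np.diag(np.diag(W))
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_singular_within_matrix_signaled(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=60)
        X = np.column_stack([a, 2 * a])       # collinear predictors
        y = np.repeat([0, 1], 30)
        with pytest.raises(np.linalg.LinAlgError):
            dfa.fit(X, y)

    def test_matches_sklearn_lda_oracle(self):
        """Classification and eigenvalue structure agree with an
        independent implementation (sklearn eigen-solver LDA)."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        rng = np.random.default_rng(5)
        means = rng.normal(scale=1.5, size=(3, 4))
        X, y = gaussian_groups(rng, means, [40, 60, 50])
        m = dfa.fit(X, y, priors="proportional")
        ours = dfa.classify(m, X)
        ref = sklearn_lda(solver="svd").fit(X, y)
        assert (ours == ref.predict(X)).mean() > 0.98


class TestWilks:
    @pytest.mark.parametrize("p,g", [(p, g) for p in range(1, 9)
                                     for g in range(2, 7)])
    def test_df_closed_form_grid(self, p, g):
        rng = np.random.default_rng(p * 10 + g)
        means = rng.normal(scale=1.5, size=(g, p))
        X, y = gaussian_groups(rng, means, [p + g + 5] * g)
        m = dfa.fit(X, y)
        seq = dfa.wilks_sequence(m)
        for row in seq:
            mm = row["functions_removed"]
            assert row["df"] == (p - mm) * (g - 1 - mm)

    def test_no_discrimination_gives_lambda_one(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(50, 3))
        X = np.vstack([base, base])
        y = np.repeat([0, 1], 50)
        m = dfa.fit(X, y)
        row = dfa.wilks_sequence(m)[0]
        assert row["wilks_lambda"] == pytest.approx(1.0, abs=1e-9)
        assert row["chi2"] == pytest.approx(0.0, abs=1e-6)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(7)
        means = rng.normal(scale=2.0, size=(4, 5))
        X, y = gaussian_groups(rng, means, [40] * 4)
        m = dfa.fit(X, y)
        assert m.percent_variance().sum() == pytest.approx(100.0)


class TestClassification:
    def test_case_at_centroid_assigned_its_group(self):
        rng = np.random.default_rng(8)
        means = [[-2.0, 0.0], [2.0, 0.0], [0.0, 3.0]]
        X, y = gaussian_groups(rng, means, [40, 40, 40])
        m = dfa.fit(X, y, priors=np.full(3, 1 / 3))
        pred = dfa.classify(m, m.class_means)
        assert list(pred) == [0, 1, 2]

    def test_degenerate_predictors_classify_to_largest_prior(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 2))            # no group signal
        y = np.repeat(np.arange(5), 20)
        priors = np.array([0.532, 0.201, 0.079, 0.130, 0.058])
        m = dfa.fit(X, y, priors=priors)
        # overwhelm any sampling noise in the means
        m.class_means[:] = m.class_means.mean(axis=0)
        pred = dfa.classify(m, X)
        assert (pred == 0).all()

    def test_brute_force_discriminant_score_oracle(self):
        """Classification equals exhaustive evaluation of the Gaussian
        discriminant score formula computed from scratch."""
        rng = np.random.default_rng(10)
        means = rng.normal(scale=1.2, size=(3, 3))
        X, y = gaussian_groups(rng, means, [25, 30, 20])
        m = dfa.fit(X, y)
        Swinv = np.linalg.inv(m.pooled_within_cov)
        expected = []
        for x in X:
            scores = [
                -0.5 * (x - mu) @ Swinv @ (x - mu) + np.log(pr)
                for mu, pr in zip(m.class_means, m.priors)]
            expected.append(int(np.argmax(scores)))
        assert list(dfa.classify(m, X)) == expected

    def test_loo_accuracy_band_on_registry_like_covariates(self):
        """With class-conditional intake covariates whose means differ by
        fractions of a within-class SD and a dominant lowest-severity
        class, leave-one-out accuracy lands in a band around one half --
        overlapping T-score distributions keep discrimination modest."""
        from caretraj import simulate
        cfg = simulate.default_config(n_children=900, seed=17)
        sim = simulate.sample_cohort(cfg)
        cov = sim.covariates
        X = np.column_stack([
            (cov["sex"] == "M").astype(float),
            cov["age_at_index"].to_numpy(float),
            cov[list(simulate.SCALES)].to_numpy(float)])
        acc = dfa.loo_cv(X, sim.true_labels.to_numpy())
        assert 40.0 < acc < 65.0

    def test_loo_close_to_resubstitution_on_separated_clouds(self):
        rng = np.random.default_rng(11)
        means = [[-2.5, 0.0], [2.5, 0.0]]
        X, y = gaussian_groups(rng, means, [100, 100])
        rep = dfa.report(X, y)
        assert abs(rep.loo_accuracy - rep.resubstitution_accuracy) <= 2.0
        assert rep.classification_table.sum() == 200
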