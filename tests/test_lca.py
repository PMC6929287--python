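import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caretraj import lca
from caretraj.lca import (LCAModel, bootstrap_gof, choose_from_improvements,
                          em_fit, entropy, fit_indices, grouped_fit,
                          loglik_brute_force, modal_assignment,
                          sample_from_model, select_num_classes)


def two_block_data(n=60, j=6):
    X = np.zeros((n, j))
    X[: n // 2] = 1.0
    return X


class TestEmFit:
    def test_one_class_closed_form(self):
        rng = np.random.default_rng(0)
        X = (rng.random((40, 5)) < 0.3).astype(float)
        fit = em_fit(X, K=1, n_starts=1, seed=0)
        m = X.mean(axis=0)
        assert np.allclose(fit.model.theta[0], np.clip(m, 1e-6, 1 - 1e-6),
                           atol=1e-6)
        nj = X.sum(axis=0)
        n = len(X)
        expected = float((nj * np.log(m) + (n - nj) * np.log(1 - m)).sum())
        assert fit.loglik == pytest.approx(expected, rel=1e-6)

    def test_separated_blocks_recovered(self):
        fit = em_fit(two_block_data(), K=2, n_starts=4, seed=1)
        assert np.allclose(np.sort(fit.model.pi), [0.5, 0.5], atol=1e-6)
        th = fit.model.theta
        assert (np.allclose(th[0], 1 - 1e-6) and np.allclose(th[1], 1e-6)) \
            or (np.allclose(th[1], 1 - 1e-6) and np.allclose(th[0], 1e-6))
        assert np.allclose(np.abs(fit.posteriors - 0.5).max(axis=1), 0.5,
                           atol=1e-9)

    def test_loglik_monotone_every_iteration(self):
        rng = np.random.default_rng(3)
        X = (rng.random((80, 10)) < rng.random(10)).astype(float)
        fit = em_fit(X, K=3, n_starts=3, seed=3)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_posterior_rows_and_weights_normalized(self):
        rng = np.random.default_rng(4)
        X = (rng.random((50, 8)) < 0.4).astype(float)
        fit = em_fit(X, K=3, n_starts=2, seed=4)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert fit.model.pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.model.pi) <= 1e-12)  # canonical order

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_loglik_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        j = int(rng.integers(2, 7))
        K = int(rng.integers(1, 4))
        X = (rng.random((n, j)) < rng.random(j)).astype(float)
        fit = em_fit(X, K, n_starts=2, max_em_iter=60, seed=seed)
        assert fit.loglik == pytest.approx(
            loglik_brute_force(X, fit.model.pi, fit.model.theta), rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            em_fit(np.array([[0.0, 0.5]]), K=1)
        with pytest.raises(ValueError):
            em_fit(np.zeros((3, 2)), K=5)


class TestFitIndicesAndEntropy:
    def test_index_arithmetic(self):
        aic, bic, caic = fit_indices(-100.0, 10, 100)
        assert aic == pytest.approx(220.0)
        assert bic == pytest.approx(200 + 10 * np.log(100))
        assert caic == pytest.approx(bic + 10)

    def test_entropy_boundaries(self):
        one_hot = np.eye(4)[np.array([0, 1, 2, 3, 0])]
        assert entropy(one_hot) == pytest.approx(1.0)
        uniform = np.full((6, 3), 1 / 3)
        assert entropy(uniform) == pytest.approx(0.0, abs=1e-12)
        assert entropy(np.ones((5, 1))) == 1.0

    def test_entropy_hand_computed_value(self):
        val = entropy(np.array([[0.8, 0.2]]))
        h = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert val == pytest.approx(1 - h / np.log(2), abs=1e-9)
        assert val == pytest.approx(0.2781, abs=2e-4)

    def test_entropy_increases_with_separation(self):
        rng = np.random.default_rng(7)
        vals = []
        for sep in (0.1, 0.3, 0.45):
            theta = np.vstack([np.full(10, 0.5 - sep),
                               np.full(10, 0.5 + sep)])
            model = LCAModel(pi=np.array([0.5, 0.5]), theta=theta)
            X = sample_from_model(model, 400, rng)
            vals.append(em_fit(X, 2, n_starts=3, seed=1).entropy)
        assert vals[0] < vals[1] < vals[2]


class TestSelection:
    def test_rule_on_precomputed_improvements(self):
        ks = [2, 3, 4, 5, 6]
        assert choose_from_improvements(
            ks, [0.05, 0.03, 0.024, 0.015]) == 5
        assert choose_from_improvements(ks, [0.01, 0.05, 0.05, 0.05]) == 2
        assert choose_from_improvements(
            ks, [0.05, 0.05, 0.05, 0.05],
            converged=[True, True, False, True, True]) == 3

    def test_select_recovers_three_well_separated_classes(self):
        rng = np.random.default_rng(11)
        theta = np.array([[0.9] * 4 + [0.1] * 8,
                          [0.1] * 4 + [0.9] * 4 + [0.1] * 4,
                          [0.1] * 8 + [0.9] * 4])
        model = LCAModel(pi=np.array([0.4, 0.35, 0.25]), theta=theta)
        X = sample_from_model(model, 600, rng)
        trace = select_num_classes(X, range(2, 6), seed=2, n_starts=4)
        assert trace.chosen_k == 3

    def test_modal_assignment_and_ties(self):
        post = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        assert list(modal_assignment(post)) == [0, 0, 1]


class TestGrouped:
    def test_single_group_matches_plain_fit(self):
        X = two_block_data()
        plain = em_fit(X, 2, n_starts=3, seed=5)
        grp = grouped_fit(X, np.zeros(len(X), int), 2, n_starts=3, seed=5)
        assert grp.loglik == pytest.approx(plain.loglik, rel=1e-8)
        assert grp.n_params == plain.n_params

    def test_no_group_effect_means_grouped_bic_not_better(self):
        rng = np.random.default_rng(21)
        theta = np.vstack([np.full(8, 0.8), np.full(8, 0.2)])
        model = LCAModel(pi=np.array([0.6, 0.4]), theta=theta)
        wins = 0
        for rep in range(5):
            X = sample_from_model(model, 500, rng)
            groups = rng.integers(0, 3, size=500)
            plain = em_fit(X, 2, n_starts=3, seed=rep)
            grp = grouped_fit(X, groups, 2, n_starts=3, seed=rep)
            wins += grp.bic >= plain.bic
        assert wins >= 4

    def test_strong_group_effect_detected(self):
        rng = np.random.default_rng(22)
        theta = np.vstack([np.full(8, 0.85), np.full(8, 0.15)])
        n_half = 300
        z1 = rng.choice(2, n_half, p=[0.9, 0.1])
        z2 = rng.choice(2, n_half, p=[0.1, 0.9])
        z = np.concatenate([z1, z2])
        X = (rng.random((2 * n_half, 8)) < theta[z]).astype(float)
        groups = np.repeat([0, 1], n_half)
        plain = em_fit(X, 2, n_starts=3, seed=1)
        grp = grouped_fit(X, groups, 2, n_starts=3, seed=1)
        assert grp.bic < plain.bic

    def test_group_smaller_than_k_rejected(self):
        X = two_block_data(20, 4)
        groups = np.array([0] * 19 + [1])
        with pytest.raises(ValueError):
            grouped_fit(X, groups, 2)


class TestBootstrapGof:
    def test_nonpositive_nboot_rejected(self):
        X = two_block_data()
        fit = em_fit(X, 2, n_starts=2, seed=0)
        with pytest.raises(ValueError):
            bootstrap_gof(fit, X, n_boot=0)

    def test_underfit_model_rejected(self):
        rng = np.random.default_rng(13)
        theta = np.vstack([np.full(8, 0.9), np.full(8, 0.1)])
        model = LCAModel(pi=np.array([0.5, 0.5]), theta=theta)
        X = sample_from_model(model, 300, rng)
        fit1 = em_fit(X, 1, n_starts=1, seed=0)
        p = bootstrap_gof(fit1, X, n_boot=30, seed=0)
        assert p <= 0.05

    def test_true_model_not_rejected_usually(self):
        rng = np.random.default_rng(14)
        theta = np.vstack([np.full(6, 0.8), np.full(6, 0.2)])
        model = LCAModel(pi=np.array([0.5, 0.5]), theta=theta)
        X = sample_from_model(model, 250, rng)
        fit2 = em_fit(X, 2, n_starts=3, seed=3)
        p = bootstrap_gof(fit2, X, n_boot=40, seed=3)
        assert p > 0.05
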