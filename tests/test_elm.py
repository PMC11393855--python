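import numpy as np
import pytest

from snoreforge.elm import (ELMClassifier, WELMClassifier, KernelWELMClassifier,
                            class_weights, kernel_matrix, composited_kernel,
                            resolve_view_split, _ridge_solve)

from conftest import blobs


@pytest.fixture(scope="module")
def separable():
    return blobs([30, 30], [(0.0, 0.0), (4.0, 4.0)], seed=0)


class TestRidgeAlgebra:
    def test_both_solution_branches_agree(self, rng):
        for _ in range(20):
            n, d = 20, 30
            H = rng.normal(size=(n, d))
            T = rng.normal(size=(n, 3))
            dual = H @ _ridge_solve(H, T, 0.1, force_branch="dual")
            primal = H @ _ridge_solve(H, T, 0.1, force_branch="primal")
            np.testing.assert_allclose(dual, primal, atol=1e-8)

    def test_ridge_shrinks_output_weights(self, separable):
        X, y = separable
        norms = []
        for lam in (1e-3, 1e-1, 1e1, 1e3, 1e6):
            m = ELMClassifier(n_hidden=40, ridge=lam, random_state=0).fit(X, y)
            norms.append(np.linalg.norm(m.output_weights_))
        assert all(a > b for a, b in zip(norms, norms[1:]))


class TestElm:
    def test_zero_hidden_params_give_half_activations(self):
        m = ELMClassifier(n_hidden=3, hidden=(np.zeros((3, 2)), np.zeros(3)))
        m.input_weights_, m.biases_ = m.hidden
        H = m.hidden_activations(np.random.default_rng(0).normal(size=(5, 2)))
        np.testing.assert_allclose(H, 0.5)

    def test_identity_activation_with_unit_weights_reproduces_input(self, rng):
        X = rng.normal(size=(4, 3))
        m = ELMClassifier(n_hidden=3, activation="identity",
                          hidden=(np.eye(3), np.zeros(3)))
        m.input_weights_, m.biases_ = m.hidden
        np.testing.assert_allclose(m.hidden_activations(X), X)

    def test_separable_blobs_fit_perfectly(self, separable):
        X, y = separable
        m = ELMClassifier(n_hidden=40, ridge=0.01, random_state=1).fit(X, y)
        assert (m.predict(X) == y).all()

    def test_fixed_seed_reproducible(self, separable):
        X, y = separable
        m1 = ELMClassifier(n_hidden=20, random_state=5).fit(X, y)
        m2 = ELMClassifier(n_hidden=20, random_state=5).fit(X, y)
        np.testing.assert_array_equal(m1.output_weights_, m2.output_weights_)

    def test_decision_matrix_shape_and_feature_check(self, separable):
        X, y = separable
        m = ELMClassifier(n_hidden=20, random_state=0).fit(X, y)
        assert m.decision_function(X).shape == (60, 2)
        with pytest.raises(ValueError):
            m.predict(X[:, :1])

    def test_label_permutation_invariance(self, separable):
        X, y = separable
        names_a = np.array(["x", "y"])[y]
        names_b = np.array(["y", "x"])[y]  # swapped encoding
        pa = ELMClassifier(n_hidden=40, random_state=2).fit(X, names_a).predict(X)
        pb = ELMClassifier(n_hidden=40, random_state=2).fit(X, names_b).predict(X)
        swap = {"x": "y", "y": "x"}
        assert all(a == swap[b] for a, b in zip(pa, pb))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ELMClassifier().fit(np.zeros((5, 2)), np.zeros(5))


class TestClassWeights:
    def test_unbalanced_example(self):
        np.testing.assert_allclose(class_weights(np.array(["A", "A", "B"])),
                                   [0.5, 0.5, 1.0])

    def test_balanced_classes_uniform(self):
        w = class_weights(np.array([0, 1, 0, 1]))
        np.testing.assert_allclose(w, 0.5)

    def test_per_class_mass_is_one(self, rng):
        y = rng.choice(["a", "b", "c"], size=50)
        w = class_weights(y)
        for c in "abc":
            assert w[y == c].sum() == pytest.approx(1.0)


class TestWelm:
    def test_uniform_weights_reduce_to_elm(self, separable):
        X, y = separable
        elm = ELMClassifier(n_hidden=30, ridge=0.1, random_state=3).fit(X, y)
        welm = ELMClassifier(n_hidden=30, ridge=0.1, random_state=3).fit(
            X, y, sample_weight=np.ones(y.size))
        np.testing.assert_allclose(elm.decision_function(X),
                                   welm.decision_function(X), atol=1e-10)

    def test_minority_recall_at_least_elm_on_imbalance(self):
        wins = 0
        for s in range(5):
            X, y = blobs([95, 5], [(0.0, 0.0), (2.0, 2.0)], scale=1.0, seed=100 + s)
            e = ELMClassifier(n_hidden=50, ridge=0.1, random_state=s).fit(X, y)
            w = WELMClassifier(n_hidden=50, ridge=0.1, random_state=s).fit(X, y)
            rec = lambda m: (m.predict(X)[y == 1] == 1).mean()
            wins += rec(w) >= rec(e)
        assert wins >= 4

    def test_uniform_weight_scaling_absorbed_by_ridge(self, separable):
        X, y = separable
        a = ELMClassifier(n_hidden=25, ridge=0.1, random_state=1).fit(
            X, y, sample_weight=np.ones(y.size))
        b = ELMClassifier(n_hidden=25, ridge=0.2, random_state=1).fit(
            X, y, sample_weight=2.0 * np.ones(y.size))
        np.testing.assert_allclose(a.output_weights_, b.output_weights_, atol=1e-10)

    def test_nonpositive_weights_rejected(self, separable):
        X, y = separable
        with pytest.raises(ValueError):
            WELMClassifier().fit(X, y, sample_weight=np.zeros(y.size))


class TestKernels:
    def test_rbf_diagonal_is_one(self, rng):
        X = rng.normal(size=(10, 4))
        K = kernel_matrix(X, X, "rbf", gamma=0.3)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_polynomial_degree_one_at_origin(self):
        assert kernel_matrix(np.zeros((1, 2)), np.zeros((1, 2)), "poly", degree=1)[0, 0] == 1.0

    def test_rbf_gram_is_symmetric_psd(self, rng):
        X = rng.normal(size=(10, 5))
        K = kernel_matrix(X, X, "rbf", gamma=0.7)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_composited_endpoints_and_midpoint(self, rng):
        X = rng.normal(size=(6, 4))
        v1, v2 = np.array([0, 1]), np.array([2, 3])
        Ks = kernel_matrix(X[:, v1], X[:, v1], "rbf", gamma=1.0)
        Kw = kernel_matrix(X[:, v2], X[:, v2], "poly", degree=2)
        np.testing.assert_allclose(composited_kernel(X, X, v1, v2, mu=1.0), Ks)
        np.testing.assert_allclose(composited_kernel(X, X, v1, v2, mu=0.0), Kw)
        np.testing.assert_allclose(composited_kernel(X, X, v1, v2, mu=0.5),
                                   0.5 * Ks + 0.5 * Kw)

    def test_empty_view_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError):
            composited_kernel(X, X, np.array([], dtype=int), np.array([0]))

    def test_view_split_by_name_prefix(self):
        names = ["time.a", "cep.b", "dwt.c", "freq.d"]
        v1, v2 = resolve_view_split(names)
        assert list(v1) == [0, 2]
        assert list(v2) == [1, 3]


class TestKernelWelm:
    def test_linear_kernel_matches_explicit_welm(self, separable):
        """Representer equivalence: k(x,y) = h(x).h(y) reproduces the
        explicit-feature weighted ELM decision values."""
        X, y = separable
        welm = WELMClassifier(n_hidden=30, ridge=0.1, random_state=4).fit(X, y)

        class LinearK(KernelWELMClassifier):
            def _gram(self, Xa, Xb):
                return welm.hidden_activations(Xa) @ welm.hidden_activations(Xb).T

        lk = LinearK(ridge=0.1, weighted=True).fit(X, y)
        np.testing.assert_allclose(welm.decision_function(X),
                                   lk.decision_function(X), atol=1e-6)

    def test_symmetric_solve_matches_printed_asymmetric_form(self, rng):
        """(lam I + U Omega)^-1 U T equals the U^(1/2)-symmetrized solve."""
        X = rng.normal(size=(12, 3))
        y = rng.choice([0, 1, 2], size=12)
        while np.unique(y).size < 3:
            y = rng.choice([0, 1, 2], size=12)
        w = rng.uniform(0.2, 2.0, size=12)
        model = KernelWELMClassifier(kernel="rbf", gamma=0.5, ridge=0.3).fit(
            X, y, sample_weight=w)
        omega = kernel_matrix(X, X, "rbf", gamma=0.5)
        T = -np.ones((12, 3))
        T[np.arange(12), np.searchsorted(np.unique(y), y)] = 1.0
        printed = np.linalg.solve(0.3 * np.eye(12) + np.diag(w) @ omega,
                                  np.diag(w) @ T)
        np.testing.assert_allclose(model.output_weights_, printed, atol=1e-8)

    def test_training_set_predicted_perfectly_on_separable_data(self, separable):
        X, y = separable
        m = KernelWELMClassifier(kernel="rbf", gamma=0.5, ridge=0.01).fit(X, y)
        assert (m.predict(X) == y).all()

    def test_unweighted_mode_matches_unit_weights(self, separable):
        X, y = separable
        a = KernelWELMClassifier(kernel="rbf", gamma=0.5, ridge=0.1, weighted=False).fit(X, y)
        b = KernelWELMClassifier(kernel="rbf", gamma=0.5, ridge=0.1).fit(
            X, y, sample_weight=np.ones(y.size))
        np.testing.assert_allclose(a.decision_function(X), b.decision_function(X),
                                   atol=1e-10)
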