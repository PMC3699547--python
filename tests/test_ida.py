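"""Intrinsic discriminant analysis: scatter construction, the intrinsic
decomposition, the perturbed generalized eigensolver and its invariances."""

import numpy as np
import pytest
import scipy.linalg

from connida import (
    IntrinsicModel,
    LabeledSampleMatrix,
    class_statistics,
    fit_ida,
    intrinsic_decompose,
    intrinsicconnectomes,
    max_embedding_dimension,
    transform,
)
from connida.connectivity import EdgeIndexMap
from connida.ida import eigen_residual, trace_ratio_objective


def random_problem(p=10, sizes=(8, 12, 10), seed=0):
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for k, n in enumerate(sizes):
        center = rng.standard_normal(p) * 2
        cols.append(center[:, None] + rng.standard_normal((p, n)))
        labels += [f"c{k}"] * n
    return LabeledSampleMatrix.from_arrays(np.concatenate(cols, axis=1), labels)


class TestClassStatistics:
    def test_single_class_degeneracy(self):
        rng = np.random.default_rng(1)
        data = LabeledSampleMatrix.from_arrays(rng.standard_normal((4, 6)), ["a"] * 6)
        m, means, H_cc, H_ind = class_statistics(data)
        np.testing.assert_allclose(means["a"], m)
        np.testing.assert_allclose(H_cc, 0, atol=1e-12)

    def test_two_point_hand_computation(self):
        X = np.array([[0.0, 2.0], [0.0, 0.0]])
        data = LabeledSampleMatrix.from_arrays(X, ["a", "b"])
        m, means, H_cc, H_ind = class_statistics(data)
        np.testing.assert_allclose(m, [1.0, 0.0])
        np.testing.assert_allclose(H_cc[:, 0], [-1.0, 0.0])  # sqrt(1)*(m_a - m)
        np.testing.assert_allclose(H_cc[:, 1], [1.0, 0.0])
        np.testing.assert_allclose(H_ind, 0, atol=1e-12)

    def test_scatter_matrices_match_double_loop_oracle(self):
        data = random_problem(p=10, sizes=(12, 9, 9), seed=2)
        m, means, H_cc, H_ind = class_statistics(data)
        # explicit between-class and within-class scatters
        S_b = np.zeros((10, 10))
        S_w = np.zeros((10, 10))
        start = 0
        for c in data.class_order:
            n_i = data.class_sizes[c]
            dm = means[c] - m
            S_b += n_i * np.outer(dm, dm)
            for j in range(start, start + n_i):
                dv = data.X[:, j] - means[c]
                S_w += np.outer(dv, dv)
            start += n_i
        np.testing.assert_allclose(H_cc @ H_cc.T, S_b, atol=1e-10)
        np.testing.assert_allclose(H_ind @ H_ind.T, S_w, atol=1e-10)
        # weighted class deviations sum to zero
        counts = np.array([data.class_sizes[c] for c in data.class_order])
        dev = np.stack([means[c] - m for c in data.class_order], axis=1)
        np.testing.assert_allclose(dev @ counts, 0, atol=1e-10)

    def test_singleton_class_warns(self):
        X = np.random.default_rng(0).standard_normal((3, 4))
        data = LabeledSampleMatrix.from_arrays(X, ["a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="single sample"):
            class_statistics(data)


class TestIntrinsicDecomposition:
    def test_components_sum_to_sample(self):
        data = random_problem(seed=3)
        for col, label in [(0, data.y[0]), (15, data.y[15])]:
            x = data.X[:, col]
            dec = intrinsic_decompose(x, data, label)
            np.testing.assert_allclose(dec.reconstruction, x, rtol=1e-12, atol=1e-12)

    def test_sample_at_class_mean_has_zero_individual(self):
        data = random_problem(seed=4)
        m, means, _, _ = class_statistics(data)
        dec = intrinsic_decompose(means["c1"], data, "c1")
        np.testing.assert_allclose(dec.individual, 0, atol=1e-12)
        np.testing.assert_allclose(dec.common, m)
        np.testing.assert_allclose(dec.class_common, means["c1"] - m)

    def test_single_class_has_zero_class_common(self):
        rng = np.random.default_rng(5)
        data = LabeledSampleMatrix.from_arrays(rng.standard_normal((6, 9)), ["a"] * 9)
        dec = intrinsic_decompose(data.X[:, 2], data, "a")
        np.testing.assert_allclose(dec.class_common, 0, atol=1e-12)

    def test_unknown_class_rejected(self):
        data = random_problem(seed=6)
        with pytest.raises(ValueError, match="unknown class"):
            intrinsic_decompose(data.X[:, 0], data, "nope")


class TestFitIda:
    def test_toy_recovers_discriminative_axis(self):
        # classes separated along axis 0, within-class noise along axis 1
        rng = np.random.default_rng(7)
        n = 30
        X = np.zeros((2, 2 * n))
        X[0, :n] = -2 + 0.01 * rng.standard_normal(n)
        X[0, n:] = 2 + 0.01 * rng.standard_normal(n)
        X[1] = rng.standard_normal(2 * n)
        data = LabeledSampleMatrix.from_arrays(X, ["a"] * n + ["b"] * n)
        model = fit_ida(data, d=1)
        assert abs(model.W[0, 0]) > 0.99

        # brute-force check: the fitted axis maximizes the trace-ratio
        # objective over a 1-degree angular grid
        _, _, H_cc, H_ind = class_statistics(data)
        angles = np.deg2rad(np.arange(180))
        objs = [
            trace_ratio_objective(
                np.array([[np.cos(a)], [np.sin(a)]]), H_cc, H_ind, model.epsilon
            )
            for a in angles
        ]
        best_angle = angles[int(np.argmax(objs))]
        w_grid = np.array([np.cos(best_angle), np.sin(best_angle)])
        assert abs(w_grid @ model.W[:, 0]) > 0.999

    def test_zero_individual_scatter_closed_form(self):
        # every sample equals its class mean -> S_ind = 0 and the
        # generalized eigenvalues are the S_cc eigenvalues divided by eps
        means = np.array([[0.0, 4.0, 1.0], [0.0, 0.0, 3.0]])
        X = np.repeat(means, 5, axis=1)
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        data = LabeledSampleMatrix.from_arrays(X, labels)
        eps = 0.5
        model = fit_ida(data, d=2, epsilon=eps)
        _, _, H_cc, _ = class_statistics(data)
        expected = np.sort(np.linalg.eigvalsh(H_cc @ H_cc.T))[::-1][:2] / eps
        np.testing.assert_allclose(model.eigenvalues, expected, rtol=1e-8)

    def test_objective_beats_random_projections(self):
        data = random_problem(p=50, sizes=(12, 10, 8), seed=8)
        model = fit_ida(data, d=2)
        _, _, H_cc, H_ind = class_statistics(data)
        fitted = trace_ratio_objective(model.W, H_cc, H_ind, model.epsilon)
        rng = np.random.default_rng(9)
        for _ in range(1000):
            Q, _ = np.linalg.qr(rng.standard_normal((50, 2)))
            assert fitted >= trace_ratio_objective(Q, H_cc, H_ind, model.epsilon)

    def test_eigen_residual_small(self):
        data = random_problem(p=200, sizes=(10, 12, 8), seed=10)
        model = fit_ida(data, d=5)
        assert eigen_residual(model, data) < 1e-8

    def test_span_solver_matches_dense_oracle(self):
        # on a problem small enough to form the scatters densely, the
        # span-based eigenpairs match scipy's dense generalized solver
        data = random_problem(p=60, sizes=(10, 12, 8), seed=11)
        eps = 1e-3
        model = fit_ida(data, d=2, epsilon=eps)
        _, _, H_cc, H_ind = class_statistics(data)
        S_cc = H_cc @ H_cc.T
        S_ind = H_ind @ H_ind.T + eps * np.eye(60)
        eigval, eigvec = scipy.linalg.eigh(S_cc, S_ind)
        order = np.argsort(eigval)[::-1][:2]
        np.testing.assert_allclose(model.eigenvalues, eigval[order], rtol=1e-6)
        for k in range(2):
            v = eigvec[:, order[k]]
            v = v / np.linalg.norm(v)
            assert abs(v @ model.W[:, k]) > 1 - 1e-6  # equal up to sign

    def test_large_epsilon_converges_to_class_common_eigvectors(self):
        data = random_problem(p=40, sizes=(10, 10, 10), seed=12)
        _, _, H_cc, H_ind = class_statistics(data)
        eps = 1e6 * float(np.trace(H_ind @ H_ind.T))
        model = fit_ida(data, d=2, epsilon=eps)
        lead = np.linalg.eigh(H_cc @ H_cc.T)[1][:, ::-1][:, :2]
        for k in range(2):
            assert abs(lead[:, k] @ model.W[:, k]) > 0.999

    def test_constant_shift_invariance(self):
        data = random_problem(seed=13)
        model = fit_ida(data, d=2, epsilon=1e-3)
        shifted = LabeledSampleMatrix.from_arrays(data.X + 5.0, data.y)
        model2 = fit_ida(shifted, d=2, epsilon=1e-3)
        np.testing.assert_allclose(model.W, model2.W, atol=1e-8)

    def test_within_class_permutation_invariance(self):
        # 3 classes so both retained eigenvalues are nonzero and distinct
        # (the lambda = 0 eigenspace is only determined up to rotation)
        data = random_problem(sizes=(6, 7, 6), seed=14)
        X2 = data.X.copy()
        X2[:, [0, 3]] = X2[:, [3, 0]]  # swap two class-0 samples
        model = fit_ida(data, d=2, epsilon=1e-3)
        model2 = fit_ida(LabeledSampleMatrix.from_arrays(X2, data.y), d=2, epsilon=1e-3)
        np.testing.assert_allclose(model.W, model2.W, atol=1e-8)

    def test_dimension_and_epsilon_bounds(self):
        data = random_problem(sizes=(4, 4), seed=15)
        assert max_embedding_dimension(data.n_samples) == 7
        with pytest.raises(ValueError, match="N-1"):
            fit_ida(data, d=8)
        with pytest.raises(ValueError, match="positive"):
            fit_ida(data, d=2, epsilon=0.0)


class TestTransformAndConnectomes:
    def test_transform_matches_loop_product(self):
        data = random_problem(seed=16)
        model = fit_ida(data, d=3)
        rng = np.random.default_rng(17)
        X = rng.standard_normal((data.n_features, 4))
        Z = transform(model, X)
        for i in range(3):
            for j in range(4):
                assert Z[i, j] == pytest.approx(model.W[:, i] @ X[:, j], abs=1e-12)

    def test_transform_linearity_and_zero(self):
        data = random_problem(seed=18)
        model = fit_ida(data, d=2)
        rng = np.random.default_rng(19)
        X = rng.standard_normal((data.n_features, 3))
        Y = rng.standard_normal((data.n_features, 3))
        np.testing.assert_allclose(
            transform(model, 2 * X + 3 * Y),
            2 * transform(model, X) + 3 * transform(model, Y),
            atol=1e-10,
        )
        np.testing.assert_allclose(transform(model, np.zeros_like(X)), 0, atol=1e-15)

    def test_dimension_mismatch_rejected(self):
        data = random_problem(seed=20)
        model = fit_ida(data, d=2)
        with pytest.raises(ValueError, match="features"):
            transform(model, np.zeros((data.n_features + 1, 2)))

    def test_intrinsicconnectome_loadings(self):
        p = 15  # edges of a 6-region map
        em = EdgeIndexMap(6)
        assert len(em) == p
        rng = np.random.default_rng(21)
        X = rng.standard_normal((p, 12))
        data = LabeledSampleMatrix.from_arrays(X, ["a"] * 6 + ["b"] * 6)
        model = fit_ida(data, d=3)
        tabs = intrinsicconnectomes(model, em)
        assert len(tabs) == 3
        for k, tab in enumerate(tabs):
            expected = model.W[:, k] / np.linalg.norm(model.W[:, k])
            np.testing.assert_allclose(tab["loading"].to_numpy(), expected, atol=1e-12)
            assert np.linalg.norm(tab["loading"]) == pytest.approx(1.0)

    def test_nine_component_export(self):
        em = EdgeIndexMap(8)  # 28 edges
        rng = np.random.default_rng(22)
        X = rng.standard_normal((28, 15))
        data = LabeledSampleMatrix.from_arrays(X, ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        model = fit_ida(data, d=9)
        tabs = intrinsicconnectomes(model, em)
        assert len(tabs) == 9
        assert set(tabs[0].columns) >= {"edge_id", "region_i", "region_j", "loading"}


def test_model_serialization_round_trip(tmp_path):
    data = random_problem(seed=23)
    model = fit_ida(data, d=3)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = IntrinsicModel.load(path)
    np.testing.assert_array_equal(loaded.W, model.W)
    np.testing.assert_array_equal(loaded.eigenvalues, model.eigenvalues)
    np.testing.assert_array_equal(loaded.global_mean, model.global_mean)
    assert loaded.epsilon == model.epsilon
    assert set(loaded.class_means) == set(model.class_means)
    for c in model.class_means:
        np.testing.assert_array_equal(loaded.class_means[c], model.class_means[c])
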