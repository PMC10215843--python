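"""Chebyshev filtering, network forward passes, training and metrics."""

import dataclasses

import numpy as np
import pytest

from pesuscept import (
    ChebNetClassifier,
    PathwayMLPClassifier,
    chebyshev_filter,
    coarsen,
    evaluate,
    gcnn_forward,
    mlp_forward,
    normalized_laplacian,
    scale_laplacian,
    train,
)
from pesuscept._nn import cheb_basis

from conftest import random_graph


def scaled(g):
    return scale_laplacian(normalized_laplacian(g)).matrix


class TestChebyshevFilter:
    def test_theta0_is_identity(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 9, 0.4)
        x = rng.normal(size=9)
        theta = np.zeros(6)
        theta[0] = 1.0
        assert np.allclose(chebyshev_filter(x, scaled(g), theta), x)

    def test_theta1_applies_laplacian(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, 7, 0.5)
        Ls = scaled(g)
        x = rng.normal(size=7)
        theta = np.zeros(4)
        theta[1] = 1.0
        assert np.allclose(chebyshev_filter(x, Ls, theta), Ls @ x)

    def test_spectral_oracle(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 8, 0.4)
        Ls = scaled(g)
        K = 5
        theta = rng.normal(size=K)
        x = rng.normal(size=8)
        y = chebyshev_filter(x, Ls, theta)
        vals, U = np.linalg.eigh(Ls)
        T = np.ones((K, 8))
        T[1] = vals
        for k in range(2, K):
            T[k] = 2 * vals * T[k - 1] - T[k - 2]
        oracle = U @ (np.diag(theta @ T) @ (U.T @ x))
        assert np.max(np.abs(y - oracle)) <= 1e-8

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, 10, 0.4)
        Ls = scaled(g)
        x = rng.normal(size=10)
        theta = rng.normal(size=6)
        perm = rng.permutation(10)
        P = np.eye(10)[perm]
        lhs = chebyshev_filter(P @ x, P @ Ls @ P.T, theta)
        rhs = P @ chebyshev_filter(x, Ls, theta)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            chebyshev_filter(np.zeros(5), np.eye(4), np.ones(3))

    def test_multichannel_theta(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, 6, 0.5)
        Ls = scaled(g)
        X = rng.normal(size=(3, 6, 2))
        theta = rng.normal(size=(4, 2, 5))
        out = chebyshev_filter(X, Ls, theta)
        assert out.shape == (3, 6, 5)
        basis = cheb_basis(Ls, 4)
        oracle = sum(
            np.einsum("nm,bmf,fg->bng", basis[k], X, theta[k]) for k in range(4)
        )
        assert np.allclose(out, oracle, atol=1e-10)


def zero_gcnn_params(h, K=20, F=32, fc=(512, 128), n_classes=2):
    sizes = h.level_sizes()
    params = {
        "theta0": np.zeros((K, 1, F)),
        "bconv0": np.zeros(F),
        "theta1": np.zeros((K, F, F)),
        "bconv1": np.zeros(F),
    }
    dims = [sizes[2] * F, *fc, n_classes]
    for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
        params[f"W{i}"] = np.zeros((a, b))
        params[f"b{i}"] = np.zeros(b)
    return params


class TestForwardPasses:
    def test_mlp_zero_params_uniform(self):
        w = [np.zeros((111, 42)), np.zeros((42, 21)), np.zeros((21, 10)), np.zeros((10, 2))]
        b = [np.zeros(42), np.zeros(21), np.zeros(10), np.zeros(2)]
        probs = mlp_forward(np.random.default_rng(0).normal(size=(5, 111)), w, b)
        assert np.allclose(probs, 0.5)

    def test_mlp_parameter_count(self, strong_dataset):
        clf = PathwayMLPClassifier(max_epochs=1)
        clf.fit(strong_dataset.values.T, strong_dataset.groups)
        # 111*42+42 + 42*21+21 + 21*10+10 + 10*2+2
        assert clf.n_parameters_ == 5849

    def test_mlp_input_width_enforced(self):
        w = [np.zeros((111, 42)), np.zeros((42, 2))]
        b = [np.zeros(42), np.zeros(2)]
        with pytest.raises(ValueError, match="features"):
            mlp_forward(np.zeros((2, 7)), w, b)

    def test_gcnn_zero_params_uniform(self, pathway_graph):
        h = coarsen(pathway_graph, 2, seed=0)
        laps = h.scaled_laplacians()
        bases = [cheb_basis(laps[0].matrix, 20), cheb_basis(laps[1].matrix, 20)]
        X = np.random.default_rng(1).normal(size=(4, 111))
        probs = gcnn_forward(X, h, bases, zero_gcnn_params(h))
        assert np.allclose(probs, 0.5)

    def test_gcnn_probabilities_sum_to_one(self, pathway_graph, strong_dataset):
        idx = np.r_[0:30, 66:96]  # both classes represented
        clf = ChebNetClassifier(graph=pathway_graph, max_epochs=2, random_state=0)
        clf.fit(strong_dataset.values.T[idx], strong_dataset.groups[idx])
        probs = clf.predict_proba(strong_dataset.values.T[:10])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_gcnn_shape_bookkeeping(self, pathway_graph, strong_dataset):
        idx = np.r_[0:30, 66:96]
        clf = ChebNetClassifier(graph=pathway_graph, max_epochs=1, random_state=0)
        clf.fit(strong_dataset.values.T[idx], strong_dataset.groups[idx])
        n0, n1, n2 = clf.hierarchy_.level_sizes()
        assert n0 == 4 * n2 and n1 == 2 * n2
        # dense head consumes coarsest nodes x filters
        assert clf.params_["W0"].shape == (n2 * clf.n_filters, 512)

    def test_gcnn_node_relabeling_invariance(self, strong_dataset):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 16, 0.3)
        h = coarsen(g, 2, seed=1)
        X = rng.normal(size=(6, 16))
        laps = h.scaled_laplacians()
        bases = [cheb_basis(laps[0].matrix, 4), cheb_basis(laps[1].matrix, 4)]
        params = zero_gcnn_params(h, K=4, F=3, fc=(7,))
        rng2 = np.random.default_rng(7)
        for k in params:
            params[k] = rng2.normal(size=params[k].shape)
        base = gcnn_forward(X, h, bases, params)
        # relabel nodes: new index of old node i is perm[i]
        perm = rng.permutation(16)
        slot_maps = [m.copy() for m in h.slot_maps]
        real = slot_maps[0] >= 0
        slot_maps[0][real] = perm[slot_maps[0][real]]
        h2 = dataclasses.replace(h, perm0=slot_maps[0], slot_maps=slot_maps)
        X2 = np.empty_like(X)
        X2[:, perm] = X
        relabeled = gcnn_forward(X2, h2, bases, params)
        assert np.allclose(base, relabeled, atol=1e-10)


class TestTraining:
    def test_mlp_deterministic(self, strong_dataset):
        X, y = strong_dataset.values.T, strong_dataset.groups
        a = PathwayMLPClassifier(max_epochs=10, random_state=3).fit(X, y)
        b = PathwayMLPClassifier(max_epochs=10, random_state=3).fit(X, y)
        assert a.loss_curve_ == b.loss_curve_
        assert all(np.array_equal(a.params_[k], b.params_[k]) for k in a.params_)

    def test_gcnn_deterministic_small(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 14, 0.3)
        X = rng.normal(size=(24, 14))
        y = np.array(["a", "b"] * 12)
        kw = dict(graph=g, poly_order=4, n_filters=4, fc_units=(8,),
                  max_epochs=5, random_state=1)
        a = ChebNetClassifier(**kw).fit(X, y)
        b = ChebNetClassifier(**kw).fit(X, y)
        assert a.loss_curve_ == b.loss_curve_

    def test_loss_decreases_and_separable_data_learned(self):
        rng = np.random.default_rng(1)
        n = 80
        X = rng.normal(size=(n, 10))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += 3 * (2 * y - 1)  # wide margin
        clf = PathwayMLPClassifier(hidden_units=(8,), max_epochs=250, random_state=0)
        clf.fit(X, y)
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            PathwayMLPClassifier().fit(X, np.zeros(10))

    def test_train_wrapper_records_split(self, strong_dataset):
        X, y = strong_dataset.values.T, strong_dataset.groups
        clf = PathwayMLPClassifier(max_epochs=15, random_state=0)
        res = train(clf, X, y, sample_ids=strong_dataset.sample_ids, seed=2)
        assert len(res.train_ids) + len(res.test_ids) == len(y)
        assert set(res.train_ids).isdisjoint(res.test_ids)
        assert res.loss_curve[-1] < res.loss_curve[0]

    def test_mlp_forward_matches_sklearn_given_same_weights(self):
        # independent oracle for the forward pass: sklearn's MLP with the
        # same parameters must emit the same softmax probabilities
        sk = pytest.importorskip("sklearn.neural_network")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = rng.integers(0, 3, size=30)  # 3 classes forces a softmax head
        ref = sk.MLPClassifier(hidden_layer_sizes=(5, 4), activation="relu",
                               max_iter=5, random_state=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref.fit(X, y)
        mine = mlp_forward(X, ref.coefs_, ref.intercepts_)
        assert np.allclose(mine, ref.predict_proba(X), atol=1e-10)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([0, 1, 1, 0], [0, 1, 1, 0])
        assert m.accuracy == 1.0 and m.f1_weighted == 1.0

    def test_majority_baseline_closed_form(self):
        y_true = np.array(["control"] * 314 + ["case"] * 66)
        y_pred = np.array(["control"] * 380)
        m = evaluate(y_true, y_pred, labels=["case", "control"])
        assert m.accuracy == pytest.approx(314 / 380)
        p0 = 314 / 380
        assert m.f1_weighted == pytest.approx(p0 * (2 * p0 / (p0 + 1)))
        assert m.per_class["case"]["f1"] == 0.0

    def test_against_hand_rolled_confusion(self):
        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 3, size=100)
        y_pred = rng.integers(0, 3, size=100)
        m = evaluate(y_true, y_pred, labels=[0, 1, 2])
        # second implementation, straight from definitions
        f1s, supports = [], []
        for c in range(3):
            tp = np.sum((y_true == c) & (y_pred == c))
            fp = np.sum((y_true != c) & (y_pred == c))
            fn = np.sum((y_true == c) & (y_pred != c))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            supports.append(np.sum(y_true == c))
            assert m.confusion[c, c] == tp
        acc = np.mean(y_true == y_pred)
        assert m.accuracy == pytest.approx(acc)
        assert m.f1_weighted == pytest.approx(np.average(f1s, weights=supports))

    def test_label_vocabulary_mismatch(self):
        with pytest.raises(ValueError, match="vocabulary"):
            evaluate([0, 1], [0, 2], labels=[0, 1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([0, 1], [0])
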