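"""The seven classifiers: contracts, determinism, oracles."""

import itertools
import math

import numpy as np
import pytest

from dopplergait.apathy_scale import APATHY, NON_APATHY
from dopplergait.models import (
    ENSEMBLE_MEMBERS,
    MODEL_NAMES,
    EnsembleVote,
    FeedForwardNet,
    MajorityVoteEnsemble,
    ModelSpec,
    fit_model,
    make_model,
    nn_parameter_count,
)


def two_clusters(n_per_class=20, gap=4.0, d=8, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n_per_class, d)), rng.normal(gap, 0.3, (n_per_class, d))])
    labels = np.array([APATHY] * n_per_class + [NON_APATHY] * n_per_class, dtype=object)
    return np.abs(X), labels  # non-negative, like count features


class _ConstantVoter:
    """Stub member always voting one label."""

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.label, dtype=object)


class TestParameterCount:
    def test_default_stack(self):
        # (8*16+16)+(16*32+32)+(32*64+64)+(64*1+1)
        assert nn_parameter_count() == 2865

    def test_single_layer(self):
        assert nn_parameter_count(8, (), 1) == 9

    def test_invalid_architecture(self):
        with pytest.raises(ValueError):
            nn_parameter_count(0, (), 1)

    def test_fitted_network_matches_count(self):
        X, labels = two_clusters()
        net = FeedForwardNet(epochs=1, seed=0).fit(X, labels)
        assert net.n_parameters == nn_parameter_count(8, net.hidden_layers, 1)


class TestSevenModels:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_fit_predict_contract(self, name):
        X, labels = two_clusters(seed=4)
        model = fit_model(ModelSpec(name, rng_seed=0), X, labels)
        preds = model.predict(X)
        assert set(preds) <= {APATHY, NON_APATHY}
        assert len(preds) == len(labels)

    def test_svm_separable_clusters_perfect_on_train(self):
        X, labels = two_clusters()
        model = make_model("svm").fit(X, labels)
        assert (model.predict(X) == labels).all()

    def test_knn_k1_reproduces_training_labels(self):
        X, labels = two_clusters(gap=1.0, seed=2)
        model = make_model("knn", k=1).fit(X, labels)
        assert (model.predict(X) == labels).all()

    def test_naive_bayes_point_deep_inside_class(self):
        X, labels = two_clusters(gap=6.0, seed=3)
        model = make_model("naive_bayes").fit(X, labels)
        assert model.predict(X[:1])[0] == APATHY
        assert model.predict(X[-1:])[0] == NON_APATHY

    @pytest.mark.parametrize("name", ["random_forest", "nn"])
    def test_stochastic_models_are_seed_deterministic(self, name):
        X, labels = two_clusters(gap=0.8, seed=5)
        a = make_model(name, seed=11).fit(X, labels).predict(X)
        b = make_model(name, seed=11).fit(X, labels).predict(X)
        assert (a == b).all()

    def test_single_class_training_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="both classes"):
            make_model("svm").fit(X, np.array([APATHY] * 5, dtype=object))

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_model("knn").fit(np.ones((5, 3)), np.array([APATHY] * 4, dtype=object))

    def test_unfitted_predict_rejected(self):
        for name in ("svm", "nn", "ensemble"):
            with pytest.raises(RuntimeError):
                make_model(name).predict(np.ones((1, 8)))

    def test_unknown_model_name(self):
        with pytest.raises(ValueError):
            make_model("perceptron")
        with pytest.raises(ValueError):
            ModelSpec("perceptron")


class TestFeedForwardNet:
    def test_training_is_bit_reproducible(self):
        X, labels = two_clusters(gap=1.0, seed=6)
        p1 = FeedForwardNet(seed=7).fit(X, labels).predict_proba(X)
        p2 = FeedForwardNet(seed=7).fit(X, labels).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_decision_rule_is_strictly_greater_than_half(self, monkeypatch):
        X, labels = two_clusters()
        net = FeedForwardNet(epochs=1).fit(X, labels)
        monkeypatch.setattr(net, "predict_proba", lambda X: np.array([0.51, 0.5, 0.49]))
        assert net.predict(np.ones((3, 8))).tolist() == [APATHY, NON_APATHY, NON_APATHY]

    def test_input_relu_is_identity_on_valid_features(self):
        """Count features are non-negative, so the weight-free ReLU input
        layer changes nothing; negative (invalid) inputs are clipped to the
        same forward pass as their rectified version."""
        X, labels = two_clusters(seed=8)
        net = FeedForwardNet(epochs=2, seed=1).fit(X, labels)
        assert np.array_equal(np.maximum(X, 0.0), X)
        X_neg = X.copy()
        X_neg[0, 0] = -5.0
        assert np.array_equal(net.predict_proba(X_neg), net.predict_proba(np.maximum(X_neg, 0.0)))

    def test_learns_separable_data(self):
        X, labels = two_clusters(gap=3.0, seed=9)
        net = FeedForwardNet(seed=2).fit(X, labels)
        assert (net.predict(X) == labels).mean() > 0.95

    def test_input_width_follows_features(self):
        X, labels = two_clusters(d=10, seed=10)
        net = FeedForwardNet(seed=0).fit(X, labels)
        assert net.n_parameters == nn_parameter_count(10, net.hidden_layers, 1)
        with pytest.raises(ValueError, match="features"):
            net.predict_proba(np.ones((1, 8)))

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            FeedForwardNet(hidden_layers=())
        with pytest.raises(ValueError):
            FeedForwardNet(epochs=0)
        with pytest.raises(ValueError):
            FeedForwardNet(decision_threshold=1.0)


class TestMajorityVoteEnsemble:
    def test_vote_rule_over_all_member_combinations(self):
        """Exhaustive check of apVote >= noapVote over all 2^4 vote patterns."""
        for pattern in itertools.product([APATHY, NON_APATHY], repeat=4):
            ensemble = MajorityVoteEnsemble([_ConstantVoter(lab) for lab in pattern], prefitted=True)
            ap = sum(lab == APATHY for lab in pattern)
            expected = APATHY if ap >= 4 - ap else NON_APATHY
            vote = ensemble.votes(np.ones((1, 8)))[0]
            assert (vote.ap_vote, vote.noap_vote) == (ap, 4 - ap)
            assert ensemble.predict(np.ones((1, 8)))[0] == expected

    def test_tie_breaks_to_apathy(self):
        assert EnsembleVote(2, 2).label == APATHY
        assert EnsembleVote(0, 4).label == NON_APATHY

    def test_default_members(self):
        ensemble = make_model("ensemble", seed=0)
        assert len(ensemble.members) == len(ENSEMBLE_MEMBERS) == 4

    def test_nb_nn_variant(self):
        X, labels = two_clusters(seed=11)
        ensemble = make_model("ensemble", seed=0, members=["naive_bayes", "nn"])
        ensemble.fit(X, labels)
        assert len(ensemble.members) == 2
        assert set(ensemble.predict(X)) <= {APATHY, NON_APATHY}

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            MajorityVoteEnsemble([])


def entropy(p, n):
    """Expected information I(p, n) of a two-class node, in bits."""
    total = p + n
    out = 0.0
    for c in (p, n):
        if c:
            out -= (c / total) * math.log2(c / total)
    return out


def best_gain_feature(X, y):
    """Brute-force: feature whose best binary threshold split maximizes
    gain(A) = I(p, n) - E(A)."""
    p, n = int(y.sum()), int((1 - y).sum())
    root = entropy(p, n)
    best = (-1.0, None)
    for f in range(X.shape[1]):
        for cut in np.unique(X[:, f]):
            left = X[:, f] <= cut
            if not left.any() or left.all():
                continue
            e = 0.0
            for side in (left, ~left):
                e += side.mean() * entropy(int(y[side].sum()), int((1 - y[side]).sum()))
            gain = root - e
            if gain > best[0] + 1e-12:
                best = (gain, f)
    return best[1]


def test_decision_tree_root_split_maximizes_information_gain():
    """The tree's first split agrees with a brute-force gain computation on
    a 10-sample toy table."""
    X = np.array(
        [
            [0.1, 5.0, 2.0],
            [0.2, 4.0, 9.0],
            [0.3, 6.0, 1.0],
            [0.4, 5.5, 8.0],
            [0.45, 4.5, 2.5],
            [0.9, 5.2, 8.5],
            [1.0, 4.8, 1.5],
            [1.1, 6.2, 9.5],
            [1.2, 5.1, 2.2],
            [1.3, 4.9, 8.8],
        ]
    )
    y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    labels = np.where(y == 1, APATHY, NON_APATHY).astype(object)
    model = make_model("decision_tree").fit(X, labels)
    assert model.estimator.tree_.feature[0] == best_gain_feature(X, y)
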