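"""Losses, class weights, flatten contract, SVM/LightGBM behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacsoz.clf import (
    LIGHTGBM_GRID,
    cb_focal_loss,
    cb_weight,
    class_weights,
    default_grid,
    effective_number,
    flatten_comodulogram,
    focal_loss,
    make_model,
    train_gbm,
    train_svm,
    unflatten_comodulogram,
)
from pacsoz.tsncv import auc


class TestFlatten:
    def test_round_trip(self, rng):
        m = rng.standard_normal((16, 16))
        np.testing.assert_array_equal(unflatten_comodulogram(flatten_comodulogram(m)), m)

    def test_single_entry_stays_single(self):
        m = np.zeros((16, 16))
        m[2, 5] = 1.0
        v = flatten_comodulogram(m)
        assert v.shape == (256,)
        assert np.count_nonzero(v) == 1

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            flatten_comodulogram(np.zeros((16, 15)))


class TestClassWeights:
    def test_worked_example(self):
        cw = class_weights((16, 64))
        assert cw.omega == pytest.approx((2.5, 0.625))
        assert cw.penalties(2.0) == pytest.approx((5.0, 1.25))

    def test_balanced_case(self):
        assert class_weights((50, 50)).omega == pytest.approx((1.0, 1.0))

    @given(st.lists(st.integers(1, 10000), min_size=2, max_size=5))
    @settings(deadline=None, max_examples=50)
    def test_balance_identity(self, counts):
        """n_i * omega_i is equal across classes and sums to N_samples."""
        cw = class_weights(counts)
        products = [n * w for n, w in zip(counts, cw.omega)]
        assert all(p == pytest.approx(products[0]) for p in products)
        assert sum(products) == pytest.approx(sum(counts))

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights((0, 5))


class TestFocalLoss:
    def test_gamma_zero_is_balanced_cross_entropy(self, rng):
        """gamma=0, alpha=0.5 gives exactly 0.5 * binary cross-entropy."""
        p = rng.uniform(0.01, 0.99, 200)
        y = rng.integers(0, 2, 200)
        fl = focal_loss(p, y, alpha=0.5, gamma=0.0, reduce="none")
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        np.testing.assert_allclose(fl, 0.5 * bce, atol=1e-12)

    def test_vanishes_as_pt_tends_to_1(self):
        assert focal_loss([0.9999999], [1], alpha=0.75, gamma=2.0) < 1e-12

    def test_worked_value(self):
        """FL(p=0.9, y=1, alpha=0.75, gamma=2) = 0.75 * 0.1^2 * (-ln 0.9)."""
        expected = 0.75 * 0.01 * -np.log(0.9)
        assert focal_loss([0.9], [1], alpha=0.75, gamma=2.0) == pytest.approx(
            expected, abs=1e-9
        )

    def test_monotone_decreasing_in_pt(self):
        p = np.linspace(0.05, 0.95, 50)
        losses = focal_loss(p, np.ones(50, int), alpha=0.75, gamma=2.0, reduce="none")
        assert (np.diff(losses) < 0).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            focal_loss([1.5], [1], alpha=0.75, gamma=2.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            focal_loss([0.5], [1], alpha=0.0, gamma=1.0)
        with pytest.raises(ValueError):
            focal_loss([0.5], [1], alpha=0.5, gamma=-1.0)


class TestCbFocalLoss:
    def test_n_equal_1_is_unweighted(self):
        fl = cb_focal_loss([0.8], [1], n_class_of_y=1, beta=0.9, gamma=2.0)
        unweighted = (1 - 0.8) ** 2 * -np.log(0.8)
        assert fl == pytest.approx(unweighted, abs=1e-12)

    def test_beta_zero_weight_is_1(self):
        assert effective_number(0.0, 1000) == 1.0

    def test_worked_effective_number(self):
        """beta=0.9, n=10: E_n ~ 6.5132, weight ~ 0.15353."""
        en = effective_number(0.9, 10)
        assert en == pytest.approx(6.5132156, abs=1e-6)
        assert cb_weight(0.9, 10) == pytest.approx(0.15353400, abs=1e-6)

    def test_weight_decreasing_in_n(self):
        ns = np.arange(1, 200)
        w = cb_weight(0.99, ns)
        assert (np.diff(w) < 0).all()

    def test_beta_one_rejected(self):
        with pytest.raises(ValueError):
            cb_focal_loss([0.5], [1], n_class_of_y=5, beta=1.0, gamma=2.0)

    def test_loss_non_negative(self, rng):
        p = rng.uniform(0.0, 1.0, 100)
        y = rng.integers(0, 2, 100)
        out = cb_focal_loss(p, y, n_class_of_y=7, beta=0.999, gamma=0.5, reduce="none")
        assert (out >= 0.0).all()


def _separable_toy(rng, n_pos=10, n_neg=10, gap=4.0, d=256):
    X = rng.standard_normal((n_pos + n_neg, d))
    X[:n_pos, 0] += gap
    y = np.zeros(n_pos + n_neg, int)
    y[:n_pos] = 1
    return X, y


class TestSvm:
    def test_separable_training_accuracy(self, rng):
        X, y = _separable_toy(rng)
        m = make_model("svm_linear", {"C": 1.0}).fit(X, y)
        assert ((m.predict_score(X) > 0).astype(int) == y).all()

    def test_class_weighting_rescues_minority(self, rng):
        """19:1 imbalance with a separable minority: weighted recall = 1."""
        X, y = _separable_toy(rng, n_pos=5, n_neg=95, gap=3.0, d=10)
        m = make_model("svm_linear", {"C": 1.0}).fit(X, y)
        pred = (m.predict_score(X) > 0).astype(int)
        assert pred[y == 1].mean() == 1.0

    def test_permuted_labels_chance_auc(self, rng):
        X = rng.standard_normal((200, 20))
        y = rng.integers(0, 2, 200)
        m = make_model("svm_rbf", {"C": 1.0}).fit(X[:100], y[:100])
        a = auc(m.predict_score(X[100:]), y[100:])
        assert 0.3 < a < 0.7

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="single class"):
            make_model("svm_rbf").fit(X, np.ones(10, int))

    def test_proba_monotone_in_decision_score(self, rng):
        """Platt-mapped probabilities preserve the decision-function ranking."""
        X, y = _separable_toy(rng, n_pos=4, n_neg=36)
        m = make_model("svm_rbf", {"C": 1.0}).fit(X, y)
        scores = m.predict_score(X)
        probs = m.predict_proba(X)
        order = np.argsort(scores)
        assert (np.diff(probs[order]) >= 0).all()
        assert probs[y == 1].min() > probs[y == 0].max()

    def test_train_svm_convenience(self, rng):
        X, y = _separable_toy(rng, n_pos=20, n_neg=20, d=8)
        order = rng.permutation(40)
        m = train_svm(X[order], y[order], kernel="rbf",
                      C_grid=(1.0, 10.0), gamma_grid=("scale",))
        assert auc(m.predict_score(X), y) == 1.0
        assert ((m.predict_proba(X) > 0) & (m.predict_proba(X) < 1)).all()


class TestGbm:
    def test_paper_grid_has_448_configurations(self):
        assert len(default_grid("lightgbm")) == 448
        assert {len(v) for v in LIGHTGBM_GRID.values()} == {7, 4}

    def test_separable_training_auc(self, rng):
        X, y = _separable_toy(rng, n_pos=30, n_neg=30, d=16)
        m = make_model("lightgbm", {"num_leaves": 35, "max_depth": 4,
                                    "learning_rate": 0.1, "min_data_in_leaf": 20})
        m.fit(X, y)
        assert auc(m.predict_score(X), y) == 1.0

    def test_permuted_labels_chance_auc(self, rng):
        X = rng.standard_normal((300, 10))
        y = rng.integers(0, 2, 300)
        m = make_model("lightgbm", {"min_data_in_leaf": 20}).fit(X[:200], y[:200])
        a = auc(m.predict_score(X[200:]), y[200:])
        assert 0.3 < a < 0.7

    def test_train_gbm_convenience(self, rng):
        X, y = _separable_toy(rng, n_pos=40, n_neg=40, d=8)
        order = rng.permutation(80)
        small = {"num_leaves": (35,), "max_depth": (4,),
                 "learning_rate": (0.1, 0.15), "min_data_in_leaf": (20,)}
        m = train_gbm(X[order], y[order], grid=small)
        assert auc(m.predict_score(X), y) == 1.0


class TestModelFactory:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_model("random_forest")

    @pytest.mark.parametrize("kind,size", [
        ("svm_linear", 4), ("svm_rbf", 20), ("cnn_focal", 20), ("cnn_cb_focal", 20),
    ])
    def test_default_grid_sizes(self, kind, size):
        grid = default_grid(kind)
        assert len(grid) == size
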