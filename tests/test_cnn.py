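"""CNN primitives, loss, gradients and the estimator contract."""

import numpy as np
import pytest
from sklearn.metrics import log_loss

import sonodeform as sd
from sonodeform.cnn import ShallowCNNClassifier, bce_loss, weighted_summation

EDGE_FILTER = [[1, 1, 1], [0, 0, 0], [-1, -1, -1]]


@pytest.mark.parametrize(
    "patch, expected",
    [
        ([[0, 0, 0], [0, 0, 0], [10, 10, 10]], -30.0),
        ([[10, 10, 10], [10, 10, 10], [10, 10, 10]], 0.0),
        (np.zeros((3, 3)), 0.0),
    ],
)
def test_weighted_summation_horizontal_edge(patch, expected):
    """A horizontal-edge filter contrasts the top row against the bottom."""
    assert weighted_summation(patch, EDGE_FILTER) == expected


def test_weighted_summation_shape_mismatch():
    with pytest.raises(ValueError):
        weighted_summation(np.zeros((2, 2)), np.zeros((3, 3)))


def test_bce_closed_form_values():
    assert bce_loss([1.0], [1.0]) == pytest.approx(0.0, abs=1e-6)
    assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2), abs=1e-12)
    assert bce_loss([0.0], [0.5]) == pytest.approx(np.log(2), abs=1e-12)


def test_bce_matches_per_sample_brute_force(rng):
    y = rng.integers(0, 2, 200).astype(float)
    p = rng.uniform(1e-6, 1 - 1e-6, 200)
    brute = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                      for yi, pi in zip(y, p)])
    assert bce_loss(y, p) == pytest.approx(brute, abs=1e-12)
    assert bce_loss(y, p) == pytest.approx(log_loss(y, p), rel=1e-9)


def test_bce_length_mismatch():
    with pytest.raises(ValueError):
        bce_loss([0, 1], [0.5])


def _tiny_clf():
    return ShallowCNNClassifier(
        conv_filters=(2, 3, 2), fc_width=4, dropout_rate=0.0, epochs=0, seed=1
    )


def test_backprop_matches_numerical_gradient(rng):
    """Analytic gradients agree with central finite differences (float64).

    The check uses directional derivatives over the full parameter vector:
    an isolated rectifier kink straddled by the finite difference would make
    single-coordinate checks fail spuriously, but contributes negligibly to
    a random direction through ~10^3 parameters.
    """
    clf = _tiny_clf()
    X = rng.random((4, 8, 8, 3))
    y = np.array([0, 1, 1, 0], dtype=np.float64)
    init_rng = np.random.default_rng(1)
    # jitter every parameter so no rectifier preactivation sits exactly on
    # its kink (zero-initialised biases put dead samples right on it, where
    # any subgradient is valid and finite differences disagree by design)
    params = {
        k: v.astype(np.float64) + 0.05 * init_rng.standard_normal(v.shape)
        for k, v in clf._init_params((8, 8), init_rng).items()
    }
    prob, cache = clf._forward(X, params)
    grads = clf._backward(prob, y, params, cache)
    check_rng = np.random.default_rng(2)
    eps = 1e-6
    for trial in range(5):
        direction = {
            k: check_rng.standard_normal(p.shape) for k, p in params.items()
        }
        norm = np.sqrt(sum((d**2).sum() for d in direction.values()))
        shifted = {k: params[k] + eps * direction[k] / norm for k in params}
        lp = bce_loss(y, clf._forward(X, shifted)[0])
        shifted = {k: params[k] - eps * direction[k] / norm for k in params}
        lm = bce_loss(y, clf._forward(X, shifted)[0])
        num = (lp - lm) / (2 * eps)
        ana = sum(
            (grads[k] * direction[k] / norm).sum() for k in params
        )
        assert ana == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_identical_seed_identical_init():
    a = _tiny_clf()._init_params((8, 8), np.random.default_rng(7))
    b = _tiny_clf()._init_params((8, 8), np.random.default_rng(7))
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_parameter_count_closed_form():
    """Total parameters equal the hand-computed sum over layers."""
    clf = ShallowCNNClassifier(conv_filters=(32, 64, 128), fc_width=128,
                               epochs=0, seed=0)
    X = np.zeros((2, 64, 64, 3), dtype=np.uint8)
    clf.fit(X, np.array([0, 1]))
    conv1 = 3 * 3 * 3 * 32 + 32
    conv2 = 3 * 3 * 32 * 64 + 64
    conv3 = 3 * 3 * 64 * 128 + 128
    fc1 = (8 * 8 * 128) * 128 + 128  # 64 px pooled thrice -> 8
    fc2 = 128 * 1 + 1
    assert clf.n_parameters() == conv1 + conv2 + conv3 + fc1 + fc2 == 1_142_081


def test_output_in_unit_interval_and_batch_invariant(rng):
    clf = ShallowCNNClassifier(conv_filters=(2, 2, 2), fc_width=4, epochs=1,
                               batch_size=4, seed=3)
    X = rng.integers(0, 256, (12, 16, 16, 3), dtype=np.uint8)
    y = rng.integers(0, 2, 12)
    clf.fit(X, y)
    p = clf.predict_proba(X)[:, 1]
    assert ((p >= 0) & (p <= 1)).all()
    # inference has no batch or dropout stochasticity
    p_single = np.array([clf.predict_proba(X[i:i + 1])[0, 1] for i in range(12)])
    np.testing.assert_allclose(p, p_single, rtol=1e-5, atol=1e-7)


def test_zero_epochs_leaves_model_at_init(rng):
    clf = ShallowCNNClassifier(conv_filters=(2, 2, 2), fc_width=4, epochs=0, seed=5)
    X = rng.integers(0, 256, (4, 16, 16, 3), dtype=np.uint8)
    clf.fit(X, [0, 1, 0, 1])
    init = clf._init_params((16, 16), np.random.default_rng(5))
    for k in init:
        np.testing.assert_array_equal(clf.params_[k], init[k])


@pytest.mark.parametrize("optimizer", ["sgd", "rmsprop", "adagrad", "adadelta", "adam"])
def test_separable_toy_problem_learned(optimizer):
    """All-bright vs all-dark images: every optimizer reaches train acc 1."""
    X = np.zeros((40, 16, 16, 3), dtype=np.uint8)
    X[:20] = 220
    X[20:] = 30
    y = np.r_[np.ones(20), np.zeros(20)]
    lr = {"sgd": 0.025, "rmsprop": 0.0025, "adagrad": 0.025,
          "adadelta": 1.0, "adam": 0.0025}[optimizer]
    clf = ShallowCNNClassifier(
        conv_filters=(4, 8, 8), fc_width=16, optimizer=optimizer,
        learning_rate=lr, epochs=20, batch_size=8, seed=0,
    )
    clf.fit(X, y)
    assert clf.history_["train_acc"][-1] == 1.0
    assert clf.score(X, y) == 1.0


def test_training_deterministic_for_seed(rng):
    X = rng.integers(0, 256, (16, 16, 16, 3), dtype=np.uint8)
    y = rng.integers(0, 2, 16)
    kwargs = dict(conv_filters=(2, 2, 2), fc_width=4, epochs=2, batch_size=4, seed=9)
    a = ShallowCNNClassifier(**kwargs).fit(X, y)
    b = ShallowCNNClassifier(**kwargs).fit(X, y)
    for k in a.params_:
        np.testing.assert_array_equal(a.params_[k], b.params_[k])
    assert a.history_ == b.history_


@pytest.mark.parametrize("score, expected", [(0.9, 1), (0.5, 0), (0.3, 0)])
def test_classify_threshold_half_maps_to_negative(score, expected):
    """Score strictly greater than 0.5 -> invasive; exactly 0.5 -> class 0."""

    class _Stub:
        def __init__(self, s):
            self.s = s

        def predict_proba(self, X):
            return np.array([[1 - self.s, self.s]] * len(X))

    pred, returned = sd.classify(_Stub(score), np.zeros((8, 8, 3)))
    assert pred == expected
    assert returned == score


def test_adadelta_learning_rate_coerced():
    with pytest.warns(UserWarning, match="Adadelta"):
        cfg = sd.TrainConfig(optimizer="adadelta", learning_rate=0.1)
    assert cfg.learning_rate == 1.0


def test_invalid_inputs_rejected(rng):
    clf = _tiny_clf()
    with pytest.raises(ValueError):
        clf.fit(np.zeros((0, 8, 8, 3)), [])
    with pytest.raises(ValueError):
        clf.fit(rng.random((4, 8, 8, 3)), [0, 1, 2, 1])
    with pytest.raises(ValueError):
        ShallowCNNClassifier(conv_filters=(2, 2, 2), epochs=1).fit(
            rng.random((2, 4, 4, 3)), [0, 1]
        )  # too small for three pooling halvings
    with pytest.raises(ValueError):
        ShallowCNNClassifier(optimizer="nadam", epochs=1).fit(
            rng.random((2, 16, 16, 3)), [0, 1]
        )


def test_checkpoint_roundtrip(tmp_path, rng):
    """Saved weights + sidecar JSON restore an identical predictor."""
    X = rng.integers(0, 256, (10, 16, 16, 3), dtype=np.uint8)
    y = rng.integers(0, 2, 10)
    clf = ShallowCNNClassifier(conv_filters=(2, 2, 2), fc_width=4, epochs=2,
                               batch_size=4, seed=21)
    clf.fit(X, y)
    clf.save(tmp_path / "model.npz")
    loaded = ShallowCNNClassifier.load(tmp_path / "model.npz")
    assert loaded.get_params() == clf.get_params()
    np.testing.assert_array_equal(loaded.predict_proba(X), clf.predict_proba(X))


def test_sklearn_contract():
    """get_params/set_params round-trip and clone-ability."""
    from sklearn.base import clone

    clf = ShallowCNNClassifier(fc_width=8, epochs=2)
    params = clf.get_params()
    assert params["fc_width"] == 8
    cloned = clone(clf)
    assert cloned.get_params() == params
    cloned.set_params(epochs=5)
    assert cloned.epochs == 5 and clf.epochs == 2
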