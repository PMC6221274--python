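import numpy as np
import pytest

from d2nnlm import NeuralLMClassifier, gradient_check, grid_search, load_model, save_model
from d2nnlm.evaluation import percent_error
from d2nnlm.network import _forward_cached, _loss_and_grads


def _tiny_net(weights, biases, x):
    _, P = _forward_cached([np.atleast_2d(w) for w in weights],
                           [np.atleast_1d(b) for b in biases],
                           np.atleast_2d(x))
    return P[0]


def test_forward_zero_params_is_uniform():
    W = [np.zeros((3, 4)), np.zeros((4, 2))]
    b = [np.zeros(4), np.zeros(2)]
    _, P = _forward_cached(W, b, np.ones((5, 3)))
    assert np.allclose(P, 0.5)


def test_forward_hand_calculation():
    # 1 input, 1 hidden unit, M=1, b=0, V=(1,-1), k=0
    w = [np.array([[1.0]]), np.array([[1.0, -1.0]])]
    b = [np.array([0.0]), np.array([0.0, 0.0])]
    p0 = _tiny_net(w, b, [0.0])
    assert np.allclose(p0, [0.5, 0.5], atol=1e-12)
    p1 = _tiny_net(w, b, [1.0])
    d = np.tanh(1.0)  # 0.76159...
    expected = np.exp([d, -d]) / np.exp([d, -d]).sum()
    assert np.allclose(p1, expected, atol=1e-12)
    assert abs(p1[0] - 0.8211) < 1e-3


def test_softmax_normalization_and_tanh_bounds():
    rng = np.random.default_rng(0)
    W = [rng.normal(size=(6, 9)), rng.normal(size=(9, 9)) * 0.5,
         rng.normal(size=(9, 3))]
    b = [rng.normal(size=9), rng.normal(size=9), rng.normal(size=3)]
    acts, P = _forward_cached(W, b, rng.normal(size=(40, 6)))
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(P > 0) and np.all(P < 1)
    for a in acts:
        assert np.all(np.abs(a) < 1.0)


def test_loss_closed_forms():
    # data term only: uniform binary prediction -> ln 2 per example
    W = [np.zeros((2, 1)), np.zeros((1, 2))]
    b = [np.zeros(1), np.zeros(2)]
    T = np.array([[1.0, 0.0], [0.0, 1.0]])
    loss, _, _ = _loss_and_grads(W, b, np.zeros((2, 2)), T, 0.0, 0.0)
    assert np.isclose(loss, np.log(2.0))
    # regularization arithmetic: sum of squared weights 4, l2=0.1 adds 0.4
    W2 = [np.array([[2.0]]), np.zeros((1, 2))]
    b2 = [np.zeros(1), np.zeros(2)]
    base, _, _ = _loss_and_grads(W2, b2, np.zeros((1, 1)), np.array([[1.0, 0.0]]),
                                 0.0, 0.0)
    reg, _, _ = _loss_and_grads(W2, b2, np.zeros((1, 1)), np.array([[1.0, 0.0]]),
                                0.0, 0.1)
    assert np.isclose(reg - base, 0.4)
    # l1 arithmetic on the same weight
    l1, _, _ = _loss_and_grads(W2, b2, np.zeros((1, 1)), np.array([[1.0, 0.0]]),
                               0.5, 0.0)
    assert np.isclose(l1 - base, 1.0)


def test_near_perfect_prediction_near_zero_loss():
    W = [np.array([[50.0, -50.0]])]
    b = [np.zeros(2)]
    loss, _, _ = _loss_and_grads(W, b, np.array([[1.0]]), np.array([[1.0, 0.0]]),
                                 0.0, 0.0)
    assert loss < 1e-10


def test_gradient_check_random_architectures():
    rng = np.random.default_rng(42)
    for trial in range(8):
        layers = int(rng.integers(1, 6))
        units = int(rng.integers(1, 33))
        d = int(rng.integers(1, 5))
        X = rng.normal(size=(4, d))
        y = np.array(["a", "b", "a", "b"])
        clf = NeuralLMClassifier(hidden_layers=layers, hidden_units=units,
                                 l1=1e-3, l2=1e-3, random_state=trial)
        ok, dev = gradient_check(clf, X, y, tol=1e-4)
        assert ok, f"layers={layers} units={units}: max deviation {dev}"


def test_gradient_check_detects_corruption():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(4, 3))
    y = np.array(["a", "b", "a", "b"])
    clf = NeuralLMClassifier(hidden_layers=2, hidden_units=4, batch_size=2,
                             random_state=0)
    clf.fit(X[:2], y[:2])
    clf.weights_[0][0, 0] += 0.0  # fitted params: check passes
    ok, _ = gradient_check(clf, X, y, tol=1e-4)
    assert ok
    # corrupt the loss/grad agreement by perturbing a stored weight between
    # the analytic and numeric passes via a wrapper
    from d2nnlm import network as nw
    orig = nw._loss_and_grads

    def corrupted(weights, biases, X_, T, l1, l2):
        loss, gW, gb = orig(weights, biases, X_, T, l1, l2)
        gW[0] = gW[0] + 0.1
        return loss, gW, gb

    nw._loss_and_grads = corrupted
    try:
        ok, dev = gradient_check(clf, X, y, tol=1e-4)
    finally:
        nw._loss_and_grads = orig
    assert not ok and dev > 0.01


def test_training_determinism(separable_2d):
    X, y = separable_2d
    a = NeuralLMClassifier(hidden_units=4, epochs=50, random_state=3).fit(X, y)
    b = NeuralLMClassifier(hidden_units=4, epochs=50, random_state=3).fit(X, y)
    for wa, wb in zip(a.weights_, b.weights_):
        assert np.array_equal(wa, wb)
    c = NeuralLMClassifier(hidden_units=4, epochs=50, random_state=4).fit(X, y)
    assert not all(np.array_equal(wa, wc)
                   for wa, wc in zip(a.weights_, c.weights_))


def test_separable_data_reaches_zero_error(separable_2d):
    # oracle: a linear classifier achieves 0 on this data, so the network must
    X, y = separable_2d
    from sklearn.linear_model import LogisticRegression
    assert LogisticRegression().fit(X, y).score(X, y) == 1.0
    clf = NeuralLMClassifier(hidden_layers=1, hidden_units=4, epochs=500,
                             batch_size=9, random_state=0).fit(X, y)
    assert percent_error(clf.predict(X), y) == 0.0


def test_shuffled_labels_chance_level():
    # permutation null: held-out error is chance (50%) within a wide band
    rng = np.random.default_rng(5)
    errs = []
    for rep in range(20):
        X = rng.normal(size=(40, 3))
        y = np.array(["a", "b"] * 20)
        rng.shuffle(y)
        clf = NeuralLMClassifier(hidden_layers=2, hidden_units=4, epochs=120,
                                 batch_size=8, random_state=rep)
        clf.fit(X[:30], y[:30])
        errs.append(percent_error(clf.predict(X[30:]), y[30:]))
    assert 30.0 <= np.mean(errs) <= 70.0


def test_l2_shrinks_weights_monotonically(separable_2d):
    X, y = separable_2d
    norms = []
    for l2 in (0.0, 0.05, 0.5):
        clf = NeuralLMClassifier(hidden_layers=1, hidden_units=4, epochs=200,
                                 l1=0.0, l2=l2, random_state=0).fit(X, y)
        norms.append(sum(float(np.abs(W).sum()) for W in clf.weights_))
    assert norms[0] > norms[1] > norms[2]


def test_history_recorded(separable_2d):
    X, y = separable_2d
    clf = NeuralLMClassifier(hidden_units=3, epochs=30, random_state=0)
    clf.fit(X, y, validation_data=(X, y))
    assert len(clf.history_) == 30
    assert "validation_percent_error" in clf.history_.columns
    assert clf.history_.train_loss.iloc[-1] < clf.history_.train_loss.iloc[0]


def test_fit_input_validation(separable_2d):
    X, y = separable_2d
    with pytest.raises(ValueError):
        NeuralLMClassifier(batch_size=1000).fit(X, y)
    with pytest.raises(ValueError):
        NeuralLMClassifier().fit(X, y[:-1])
    with pytest.raises(ValueError):
        NeuralLMClassifier().fit(X, np.array(["a"] * len(X)))


def _grid_data(seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-2, 0.5, (16, 2)), rng.normal(2, 0.5, (16, 2))])
    y = np.array(["a"] * 16 + ["b"] * 16)
    idx = rng.permutation(32)
    X, y = X[idx], y[idx]
    return (X[:16], y[:16]), (X[16:24], y[16:24]), (X[24:], y[24:])


def test_grid_search_single_cell():
    train, val, test = _grid_data()
    est = NeuralLMClassifier(epochs=100, batch_size=4, random_state=0)
    best, params, table = grid_search(est, train, val, test, [3], [4], "b")
    assert params == {"hidden_units": 3, "batch_size": 4}
    assert len(table) == 1


def test_grid_search_selects_best_and_breaks_ties():
    train, val, test = _grid_data()
    est = NeuralLMClassifier(epochs=100, random_state=0)
    best, params, table = grid_search(est, train, val, test, [2, 4], [4, 8], "b")
    assert len(table) == 4
    # exhaustive-evaluation oracle over the returned table
    t = table.sort_values(["validation_percent_error", "validation_perplexity",
                           "hidden_units", "batch_size"], kind="mergesort")
    assert params["hidden_units"] == t.iloc[0]["hidden_units"]
    assert params["batch_size"] == t.iloc[0]["batch_size"]
    # on separable data the winning cell attains the table's minimum error
    assert t.iloc[0]["validation_percent_error"] == table.validation_percent_error.min()


def test_save_load_round_trip(tmp_path, separable_2d):
    X, y = separable_2d
    clf = NeuralLMClassifier(hidden_units=3, epochs=40, random_state=1).fit(X, y)
    p = tmp_path / "model.zip"
    save_model(clf, p)
    back = load_model(p)
    assert np.allclose(back.predict_proba(X), clf.predict_proba(X))
    assert list(back.classes_) == list(clf.classes_)
    # identical fits save byte-identical archives
    p2 = tmp_path / "model2.zip"
    clf2 = NeuralLMClassifier(hidden_units=3, epochs=40, random_state=1).fit(X, y)
    save_model(clf2, p2)
    assert p.read_bytes() == p2.read_bytes()
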