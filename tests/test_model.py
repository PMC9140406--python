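import numpy as np
import pytest
from sklearn.base import clone

from dlplink import (
    BipartiteNetwork,
    LocalStructureGCN,
    ModelParams,
    TrainConfig,
    encode_structure,
    extract_local_structure,
    gcn_layer,
    mse_loss,
    predict_link,
    score_structures,
    train,
)
from dlplink.model import _backward, _forward, structure_matrices


def identity_params(dim: int, n_layers: int = 1) -> ModelParams:
    return ModelParams(
        input_projection=np.eye(dim),
        layer_weights=[np.eye(dim) for _ in range(n_layers)],
        readout_weight=np.zeros(dim),
    )


def test_gcn_layer_zero_states_stay_zero():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    H = np.zeros((2, 3))
    assert np.array_equal(gcn_layer(H, A, np.eye(3)), H)


def test_gcn_layer_isolated_node_keeps_nonnegative_state():
    A = np.zeros((2, 2))
    H = np.array([[1.0, 0.5, 0.0], [2.0, 0.0, 3.0]])
    assert np.array_equal(gcn_layer(H, A, np.eye(3)), H)


def test_gcn_layer_two_node_hand_computation():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    a = np.array([1.0, 2.0])
    b = np.array([0.5, 0.0])
    out = gcn_layer(np.vstack([a, b]), A, np.eye(2))
    assert np.allclose(out, np.vstack([a + b, b + a]))


def test_gcn_layer_dimension_mismatch():
    with pytest.raises(ValueError, match="incompatible"):
        gcn_layer(np.zeros((2, 3)), np.zeros((2, 2)), np.eye(4))


def test_encode_structure_is_mean_of_final_states(toy):
    params = identity_params(4)
    H_ls = encode_structure(toy.structure, params=params)
    # independent dense-matrix oracle: relu(X + A X) averaged over rows
    A, X = structure_matrices(toy.structure)
    expected = np.maximum(X + A @ X, 0.0).mean(axis=0)
    assert np.allclose(H_ls, expected)
    assert H_ls.shape == (4,)


def test_encode_structure_invariant_to_node_relabeling(toy):
    """Relabeling node indices permutes rows only; the mean readout and the
    resulting score are unchanged."""
    from dlplink import LocalStructure

    cfg = TrainConfig(hidden_dim=8, num_layers=2, seed=3)
    params = ModelParams.initialize(4, cfg)
    swapped = LocalStructure(
        target_u=1, target_v=1, k=1, label=0,
        nodes=(("u", 0), ("u", 1), ("v", 0), ("v", 1)),
        edges=frozenset({(1, 0), (0, 0), (0, 1)}),
    )
    a = encode_structure(toy.structure, params=params)
    b = encode_structure(swapped, params=params)
    assert np.allclose(a, b)


def test_predict_link_zero_weights_score_half():
    params = ModelParams.zeros(4, hidden_dim=32)
    rng = np.random.default_rng(0)
    for H in (np.zeros(32), np.ones(32) * 5, rng.normal(size=32)):
        assert predict_link(H, params) == 0.5


def test_predict_link_sigmoid_value_and_monotonicity():
    params = ModelParams.zeros(4, hidden_dim=1)
    params.readout_weight = np.array([1.0])
    assert predict_link(np.array([0.8473]), params) == pytest.approx(0.7000, abs=5e-4)
    scores = [predict_link(np.array([x]), params) for x in (-2.0, -0.5, 0.0, 0.5, 2.0)]
    assert scores == sorted(scores)
    assert scores[2] == 0.5
    with pytest.raises(ValueError, match="finite"):
        predict_link(np.array([np.nan]), params)


def test_mse_loss_examples_and_oracle():
    assert mse_loss([0.2, 0.9], [0.2, 0.9]) == 0.0
    assert mse_loss([0.5], [1.0]) == 0.25
    rng = np.random.default_rng(1)
    p, y = rng.random(50), rng.integers(0, 2, 50).astype(float)
    loop = sum((pi - yi) ** 2 for pi, yi in zip(p, y)) / 50
    assert mse_loss(p, y) == pytest.approx(loop)
    with pytest.raises(ValueError, match="mismatch"):
        mse_loss([0.1], [0.0, 1.0])
    with pytest.raises(ValueError, match="at least one"):
        mse_loss([], [])


def test_backward_matches_finite_differences(toy):
    """The hand-derived gradients agree with central finite differences."""
    cfg = TrainConfig(hidden_dim=5, num_layers=2, seed=9)
    A, X = structure_matrices(toy.structure)
    params = ModelParams.initialize(X.shape[1], cfg)
    y = 1.0
    r, cache = _forward(A, X, params, keep=True)
    g_proj, g_layers, g_read = _backward(A, X, params, cache, 2 * (r - y))
    eps = 1e-6

    def numeric(arr):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = arr[idx]
            arr[idx] = old + eps
            up = (_forward(A, X, params) - y) ** 2
            arr[idx] = old - eps
            dn = (_forward(A, X, params) - y) ** 2
            arr[idx] = old
            g[idx] = (up - dn) / (2 * eps)
        return g

    assert np.allclose(numeric(params.input_projection), g_proj, atol=1e-7)
    for W, gW in zip(params.layer_weights, g_layers):
        assert np.allclose(numeric(W), gW, atol=1e-7)
    assert np.allclose(numeric(params.readout_weight), g_read, atol=1e-7)


def _separable_dataset():
    """Structures with vs without a connecting path; trivially separable."""
    rich_net = BipartiteNetwork(2, 2, [(0, 0), (1, 0), (1, 1)])
    rich = extract_local_structure(rich_net, 0, 1, 1)
    bare_net = BipartiteNetwork(2, 2, [(0, 0), (1, 1)])
    bare = extract_local_structure(bare_net, 0, 1, 1)
    return [(rich, 1), (bare, 0)] * 5


def test_train_is_deterministic_per_seed():
    data = _separable_dataset()
    cfg = TrainConfig(epochs=10, seed=4)
    p1, p2 = train(data, cfg), train(data, cfg)
    assert p1.loss_history == p2.loss_history
    for a, b in zip(p1.arrays(), p2.arrays()):
        assert np.array_equal(a, b)
    p3 = train(data, TrainConfig(epochs=10, seed=5))
    assert p1.loss_history != p3.loss_history


def test_training_loss_decreases_across_seeds():
    data = _separable_dataset()
    down = 0
    for seed in range(10):
        params = train(data, TrainConfig(seed=seed))
        if params.loss_history[-1] < params.loss_history[0]:
            down += 1
    assert down >= 9


def test_capacity_on_separable_planted_signal():
    data = _separable_dataset()
    params = train(data, TrainConfig(epochs=400, seed=0))
    structures = [ls for ls, _ in data]
    labels = [y for _, y in data]
    scores = score_structures(structures, params)
    assert mse_loss(scores, labels) < 0.05


def test_train_validates_inputs():
    with pytest.raises(ValueError, match="empty"):
        train([], TrainConfig())
    data = _separable_dataset()
    with pytest.raises(ValueError, match="0 or 1"):
        train([(data[0][0], 2)], TrainConfig())


def test_scores_lie_strictly_inside_unit_interval():
    data = _separable_dataset()
    params = train(data, TrainConfig(epochs=5, seed=1))
    scores = score_structures([ls for ls, _ in data], params)
    assert np.all((scores > 0) & (scores < 1))


def test_estimator_sklearn_conventions():
    est = LocalStructureGCN(epochs=3, random_state=1)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.set_params(hidden_dim=8)
    assert est.hidden_dim == 8
    with pytest.raises(ValueError, match="not fitted"):
        est.predict([])


def test_estimator_fit_predict_round_trip():
    data = _separable_dataset()
    X = [ls for ls, _ in data]
    y = [lab for _, lab in data]
    est = LocalStructureGCN(epochs=20, hidden_dim=8, random_state=0).fit(X, y)
    assert hasattr(est, "params_") and est.n_features_in_ == 4
    scores = est.predict(X)
    assert scores.shape == (10,)
    wrong_k = extract_local_structure(BipartiteNetwork(2, 2, [(0, 0)]), 0, 1, 2)
    with pytest.raises(ValueError, match="k=1"):
        est.fit([wrong_k], [0])


def test_checkpoint_round_trip(tmp_path):
    cfg = TrainConfig(epochs=2, hidden_dim=6, seed=2)
    params = train(_separable_dataset(), cfg)
    path = tmp_path / "model.npz"
    params.save(path, cfg)
    loaded, meta = ModelParams.load(path)
    for a, b in zip(params.arrays(), loaded.arrays()):
        assert np.array_equal(a, b)
    assert meta["hidden_dim"] == 6 and meta["seed"] == 2
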