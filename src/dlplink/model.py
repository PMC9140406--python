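"""GCN encoder, mean readout, link scorer and the training loop.

The scorer reads a local structure as follows.  Node features X (one
row per node, dimension k + 3) are linearly projected to a hidden
dimension d.  Each of L graph-convolution layers then updates every node
from its neighbors with an unweighted self-term,

    h_i  <-  ReLU( h_i + sum_{j in N(i)} W_l h_j ),

where the adjacency comes from the local structure (target edge absent)
and one weight matrix W_l (d x d) is shared by all neighbors of a layer.
The structure representation H_ls is the elementwise mean of the final
node states — permutation invariant and of fixed dimension d regardless
of structure size — and the link score is sigmoid(w . H_ls) in (0, 1),
trained against the 0/1 existence label under mean squared error with
minibatch SGD (momentum + weight decay, PyTorch update semantics).

All forward and backward passes are explicit numpy; the graphs involved
are tiny, so dense per-structure matrices are the fastest honest choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .labeling import NodeFeatureMatrix, features_for_structure
from .local_structure import LocalStructure

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (SGD with momentum and weight decay)."""

    lr: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 1e-5
    epochs: int = 80
    batch_size: int = 5
    num_layers: int = 2
    hidden_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.epochs, self.batch_size, self.num_layers, self.hidden_dim) <= 0:
            raise ValueError("lr, epochs, batch_size, num_layers, hidden_dim must be positive")
        if self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("momentum and weight_decay must be non-negative")


@dataclass
class ModelParams:
    """Learnable parameters: input projection, per-layer GCN weights, readout."""

    input_projection: np.ndarray          # (feature_dim, d)
    layer_weights: list[np.ndarray]       # each (d, d)
    readout_weight: np.ndarray            # (d,)
    loss_history: list[float] = field(default_factory=list)

    @property
    def hidden_dim(self) -> int:
        return self.input_projection.shape[1]

    @property
    def feature_dim(self) -> int:
        return self.input_projection.shape[0]

    def arrays(self) -> list[np.ndarray]:
        return [self.input_projection, *self.layer_weights, self.readout_weight]

    @classmethod
    def initialize(cls, feature_dim: int, config: TrainConfig) -> "ModelParams":
        """Glorot-style uniform initialization, reproducible per seed."""
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dim

        def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        return cls(
            input_projection=glorot(feature_dim, d, (feature_dim, d)),
            layer_weights=[glorot(d, d, (d, d)) for _ in range(config.num_layers)],
            readout_weight=glorot(d, 1, (d,)),
        )

    @classmethod
    def zeros(cls, feature_dim: int, hidden_dim: int = 32, num_layers: int = 2) -> "ModelParams":
        """All-zero parameters; every link score is then exactly 0.5."""
        return cls(
            input_projection=np.zeros((feature_dim, hidden_dim)),
            layer_weights=[np.zeros((hidden_dim, hidden_dim)) for _ in range(num_layers)],
            readout_weight=np.zeros(hidden_dim),
        )

    # -- checkpointing -------------------------------------------------
    def save(self, path: str | Path, config: TrainConfig | None = None) -> None:
        """Flat key -> array archive with the config embedded as JSON."""
        meta = json.dumps(vars(config)) if config is not None else "{}"
        np.savez(
            path,
            input_projection=self.input_projection,
            readout_weight=self.readout_weight,
            n_layers=np.array(len(self.layer_weights)),
            config=np.array(meta),
            **{f"layer_{i}": W for i, W in enumerate(self.layer_weights)},
        )

    @classmethod
    def load(cls, path: str | Path) -> tuple["ModelParams", dict]:
        with np.load(path, allow_pickle=False) as z:
            n_layers = int(z["n_layers"])
            params = cls(
                input_projection=z["input_projection"],
                layer_weights=[z[f"layer_{i}"] for i in range(n_layers)],
                readout_weight=z["readout_weight"],
            )
            meta = json.loads(str(z["config"]))
        return params, meta


def _sigmoid(x: float | np.ndarray) -> float | np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))


def structure_matrices(ls: LocalStructure, features: NodeFeatureMatrix | None = None):
    """Dense (adjacency, feature) matrices for one local structure.

    Rows follow ``features.node_order``; the adjacency is symmetric and
    the target edge is already absent by construction of the structure.
    """
    if features is None:
        features = features_for_structure(ls)
    index = {node: i for i, node in enumerate(features.node_order)}
    n = len(features.node_order)
    A = np.zeros((n, n))
    for u, v in ls.edges:
        i, j = index[("u", u)], index[("v", v)]
        A[i, j] = A[j, i] = 1.0
    return A, features.features


def gcn_layer(H: np.ndarray, A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph-convolution pass: ReLU(h_i + sum_{j in N(i)} W h_j).

    Nodes without neighbors keep ReLU of their own state (empty sum).
    """
    if H.shape[1] != W.shape[0] or W.shape[0] != W.shape[1]:
        raise ValueError(
            f"state dim {H.shape[1]} incompatible with weight shape {W.shape}"
        )
    if A.shape[0] != H.shape[0]:
        raise ValueError("adjacency and state row counts differ")
    return np.maximum(H + (A @ H) @ W.T, 0.0)


def _forward(A: np.ndarray, X: np.ndarray, params: ModelParams, keep: bool = False):
    """Forward pass; with ``keep`` returns the per-layer caches for backprop."""
    H = X @ params.input_projection
    states = [H]
    for W in params.layer_weights:
        Z = H + (A @ H) @ W.T
        H = np.maximum(Z, 0.0)
        states.append(H)
    g = H.mean(axis=0)
    s = float(params.readout_weight @ g)
    r = float(_sigmoid(s))
    if keep:
        return r, (states, g)
    return r


def encode_structure(
    ls: LocalStructure,
    features: NodeFeatureMatrix | None = None,
    params: ModelParams | None = None,
) -> np.ndarray:
    """Structure representation H_ls: mean of final node states (dim d)."""
    if params is None:
        raise ValueError("model parameters are required")
    A, X = structure_matrices(ls, features)
    H = X @ params.input_projection
    for W in params.layer_weights:
        H = gcn_layer(H, A, W)
    return H.mean(axis=0)


def predict_link(H_ls: np.ndarray, params: ModelParams) -> float:
    """Link score sigmoid(w . H_ls) in (0, 1)."""
    if not np.all(np.isfinite(H_ls)):
        raise ValueError("structure representation contains non-finite values")
    return float(_sigmoid(float(params.readout_weight @ np.asarray(H_ls))))


def mse_loss(predictions: Sequence[float], labels: Sequence[float]) -> float:
    """Mean squared error over the evaluated pair set."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean((p - y) ** 2))


def _backward(A, X, params: ModelParams, cache, d_r: float):
    """Gradients of d_r * r with respect to every parameter array."""
    states, g = cache
    H_final = states[-1]
    n = H_final.shape[0]
    s = float(params.readout_weight @ g)
    r = float(_sigmoid(s))
    d_s = d_r * r * (1.0 - r)

    grad_readout = d_s * g
    dH = np.full_like(H_final, 0.0)
    dH += (d_s / n) * params.readout_weight[np.newaxis, :]

    grad_layers: list[np.ndarray] = [None] * len(params.layer_weights)
    for l in range(len(params.layer_weights) - 1, -1, -1):
        W = params.layer_weights[l]
        H_in = states[l]
        H_out = states[l + 1]
        dZ = dH * (H_out > 0)
        AH = A @ H_in
        grad_layers[l] = dZ.T @ AH
        dH = dZ + (A.T @ dZ) @ W
    grad_proj = X.T @ dH
    return grad_proj, grad_layers, grad_readout


def train(
    dataset: Sequence[tuple[LocalStructure, int]],
    config: TrainConfig | None = None,
) -> ModelParams:
    """Fit the scorer on (structure, 0/1 label) pairs.

    Runs ``epochs`` passes of shuffled minibatch SGD (momentum,
    weight decay) on the MSE between scores and labels, accumulating
    gradients over the ``batch_size`` structures of a batch.  Fully
    reproducible for a fixed config seed; the per-epoch mean loss is
    recorded on the returned parameters as ``loss_history``.
    """
    if config is None:
        config = TrainConfig()
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    labels = [int(y) for _, y in dataset]
    if any(y not in (0, 1) for y in labels):
        raise ValueError("labels must be 0 or 1")

    prepared = []
    for (ls, y) in dataset:
        A, X = structure_matrices(ls)
        prepared.append((A, X, float(y)))
    feature_dim = prepared[0][1].shape[1]
    if any(X.shape[1] != feature_dim for _, X, _ in prepared):
        raise ValueError("all structures must share one depth parameter k")

    params = ModelParams.initialize(feature_dim, config)
    velocity = [np.zeros_like(a) for a in params.arrays()]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])

    n = len(prepared)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            grads = [np.zeros_like(a) for a in params.arrays()]
            batch_loss = 0.0
            for i in batch:
                A, X, y = prepared[i]
                r, cache = _forward(A, X, params, keep=True)
                batch_loss += (r - y) ** 2
                d_r = 2.0 * (r - y) / len(batch)
                g_proj, g_layers, g_read = _backward(A, X, params, cache, d_r)
                grads[0] += g_proj
                for l, gl in enumerate(g_layers):
                    grads[1 + l] += gl
                grads[-1] += g_read
            epoch_losses.append(batch_loss / len(batch))
            arrays = params.arrays()
            for a, v, g in zip(arrays, velocity, grads):
                g = g + config.weight_decay * a
                v *= config.momentum
                v += g
                a -= config.lr * v
        params.loss_history.append(float(np.mean(epoch_losses)))
    logger.debug("training finished; final epoch loss %.5f", params.loss_history[-1])
    return params


def score_structures(
    structures: Sequence[LocalStructure], params: ModelParams
) -> np.ndarray:
    """Link scores for a batch of structures under fixed parameters."""
    return np.array([
        _forward(*structure_matrices(ls), params) for ls in structures
    ])


class LocalStructureGCN(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator scoring links from local structures.

    ``fit`` takes a sequence of :class:`LocalStructure` (all extracted at
    the same depth ``k``) and 0/1 existence labels; ``predict`` returns
    scores in (0, 1) comparable to the labels under squared error.

    Parameters mirror :class:`TrainConfig`; ``random_state`` seeds
    initialization and batch shuffling.
    """

    def __init__(
        self,
        k: int = 1,
        hidden_dim: int = 32,
        num_layers: int = 2,
        lr: float = 1e-2,
        momentum: float = 0.9,
        weight_decay: float = 1e-5,
        epochs: int = 80,
        batch_size: int = 5,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            num_layers=self.num_layers,
            hidden_dim=self.hidden_dim,
            seed=self.random_state,
        )

    def fit(self, X: Sequence[LocalStructure], y: Sequence[int]) -> "LocalStructureGCN":
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if any(ls.k != self.k for ls in X):
            raise ValueError(f"all structures must be extracted at k={self.k}")
        params = train(list(zip(X, y)), self._config())
        self.params_ = params
        self.loss_history_ = list(params.loss_history)
        self.n_features_in_ = params.feature_dim
        return self

    def predict(self, X: Sequence[LocalStructure]) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted; call fit first")
        return score_structures(list(X), self.params_)
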