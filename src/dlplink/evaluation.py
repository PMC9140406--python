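"""Evaluation metrics and experiment protocols.

The protocol mirrors standard learned link prediction: hold out 20% of
the observed edges as positive test pairs, sample equally many non-edges
as negatives for both training and testing, train the scorer on local
structures extracted from the *training* graph only, and report MAE and
RMSE between scores and 0/1 existence labels.  Test-time structures are
likewise extracted from the training graph — extracting them from the
full graph would leak the held-out edges into the evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .local_structure import DEFAULT_PATH_CAP, LocalStructure, extract_local_structure
from .model import LocalStructureGCN, TrainConfig
from .network_io import (
    BipartiteNetwork,
    Edge,
    _stage_seed,
    split_edges,
    subsample_links,
)

logger = logging.getLogger(__name__)


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error (1/l) * sum |r_ij - r*_ij|."""
    p, t = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return float(np.mean(np.abs(p - t)))


def rmse(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Root mean square error sqrt((1/l) * sum (r_ij - r*_ij)^2)."""
    p, t = np.asarray(pred, dtype=float), np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass
class EvalResult:
    """Metrics over one prediction set, with the per-pair detail kept."""

    mae: float
    rmse: float
    n_samples: int
    per_pair: list[tuple[Edge, int, float]]  # (pair, truth, score)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"u": u, "v": v, "truth": t, "score": s}
            for (u, v), t, s in self.per_pair
        ]
        return pd.DataFrame(rows, columns=["u", "v", "truth", "score"])


def _extract_many(
    net: BipartiteNetwork,
    pairs: Sequence[Edge],
    k: int,
    literal_hops: bool,
    path_cap: int,
) -> list[LocalStructure]:
    return [
        extract_local_structure(net, u, v, k, literal_hops=literal_hops, path_cap=path_cap)
        for u, v in pairs
    ]


def run_experiment(
    net: BipartiteNetwork,
    k: int,
    config: TrainConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    literal_hops: bool = False,
    path_cap: int = DEFAULT_PATH_CAP,
) -> EvalResult:
    """One full split -> extract -> train -> score evaluation.

    All randomness (split, negative sampling, initialization, batch
    shuffling) fans out deterministically from ``seed``.
    """
    if config is None:
        config = TrainConfig()
    split = split_edges(net, test_fraction, seed)
    train_net = split.training_network(net)

    train_pairs = list(split.train_pos) + list(split.train_neg)
    train_labels = [1] * len(split.train_pos) + [0] * len(split.train_neg)
    test_pairs = list(split.test_pos) + list(split.test_neg)
    test_labels = [1] * len(split.test_pos) + [0] * len(split.test_neg)
    if not test_pairs:
        raise ValueError("split produced an empty test set; use a larger network")

    train_structures = _extract_many(train_net, train_pairs, k, literal_hops, path_cap)
    test_structures = _extract_many(train_net, test_pairs, k, literal_hops, path_cap)

    est = LocalStructureGCN(
        k=k,
        hidden_dim=config.hidden_dim,
        num_layers=config.num_layers,
        lr=config.lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
        epochs=config.epochs,
        batch_size=config.batch_size,
        random_state=_stage_seed(seed, "train"),
    )
    est.fit(train_structures, train_labels)
    scores = est.predict(test_structures)

    per_pair = [
        (pair, truth, float(score))
        for pair, truth, score in zip(test_pairs, test_labels, scores)
    ]
    return EvalResult(
        mae=mae(scores, test_labels),
        rmse=rmse(scores, test_labels),
        n_samples=len(per_pair),
        per_pair=per_pair,
    )


def depth_sweep(
    net: BipartiteNetwork,
    ks: Sequence[int],
    config: TrainConfig | None = None,
    seeds: Sequence[int] = (0,),
    **kwargs,
) -> pd.DataFrame:
    """Evaluate each structural depth k over the given seeds.

    Returns one row per (k, seed); aggregate per-k means with
    :func:`aggregate_sweep`.
    """
    rows = []
    for k in ks:
        for seed in seeds:
            res = run_experiment(net, k, config, seed=seed, **kwargs)
            rows.append({"k": k, "seed": seed, "rmse": res.rmse, "mae": res.mae,
                         "n_samples": res.n_samples})
            logger.info("depth sweep k=%d seed=%d rmse=%.4f mae=%.4f",
                        k, seed, res.rmse, res.mae)
    return pd.DataFrame(rows)


def sparsity_sweep(
    net: BipartiteNetwork,
    fractions: Sequence[float],
    config: TrainConfig | None = None,
    seeds: Sequence[int] = (0,),
    k: int = 1,
    **kwargs,
) -> pd.DataFrame:
    """Evaluate under uniform edge thinning at each retain fraction.

    The retained subnetwork is re-split and re-evaluated per seed; rows
    are sorted by fraction.  Fraction 1.0 reproduces the full-network
    evaluation for the same seeds.
    """
    rows = []
    for fraction in sorted(fractions):
        for seed in seeds:
            sub = subsample_links(net, fraction, seed)
            res = run_experiment(sub, k, config, seed=seed, **kwargs)
            rows.append({"fraction": fraction, "seed": seed, "rmse": res.rmse,
                         "mae": res.mae, "n_samples": res.n_samples})
            logger.info("sparsity sweep fraction=%.2f seed=%d rmse=%.4f mae=%.4f",
                        fraction, seed, res.rmse, res.mae)
    return pd.DataFrame(rows)


def aggregate_sweep(df: pd.DataFrame, by: str) -> pd.DataFrame:
    """Per-level means of rmse/mae over seeds for a sweep table."""
    return (
        df.groupby(by, as_index=False)[["rmse", "mae"]]
        .mean()
        .sort_values(by)
        .reset_index(drop=True)
    )
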