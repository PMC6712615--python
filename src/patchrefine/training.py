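"""Loss, learning-rate schedule, and the shared fit loop.

The networks are supervised by the softmax cross-entropy loss

    L = (1/N) sum_i -log( exp(f_{y_i}) / sum_j exp(f_j) )

and optimized with mini-batch SGD (momentum 0.9), batch size 16, under a
staged schedule: a large initial learning rate of 0.05 (workable because of
the batch-normalization layers), then 0.01, then a further factor of 0.1 per
stage.  For a fixed seed the initialization and batch order are fixed; the
reproducibility contract is statistical, not bitwise across BLAS builds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .models import ModelGraph
from .nn import NumpyNet

__all__ = ["LossInputs", "TrainConfig", "softmax_loss", "lr_at", "fit", "dataset_to_arrays"]


@dataclass
class LossInputs:
    """Class scores f (N x K) and integer labels y (N,) for the softmax loss."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.scores.ndim != 2 or self.scores.shape[0] < 1:
            raise ValueError("scores must be a non-empty N x K matrix")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.labels.shape != (self.scores.shape[0],):
            raise ValueError("labels must be one integer per row of scores")
        K = self.scores.shape[1]
        if self.labels.min() < 0 or self.labels.max() >= K:
            raise ValueError("label out of range [0, K)")


def softmax_loss(inputs: LossInputs) -> float:
    """Mean negative log softmax probability of the true class.

    Numerically stable: subtracts the per-row max before exponentiating
    (log-sum-exp), which leaves the loss unchanged because the softmax is
    shift-invariant.
    """
    f = inputs.scores
    shifted = f - f.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1))
    true_score = shifted[np.arange(f.shape[0]), inputs.labels]
    return float(np.mean(lse - true_score))


def lr_at(stage: int, config: "TrainConfig") -> float:
    """Learning rate of schedule stage ``stage`` (0-based).

    Stage 0 -> 0.05, stage 1 -> 0.01, stage s >= 2 -> 0.01 * 0.1**(s-1).
    """
    if stage < 0:
        raise ValueError("stage must be >= 0")
    lrs = config.lr_stages
    if stage < len(lrs):
        return lrs[stage]
    return lrs[-1] * 0.1 ** (stage - len(lrs) + 1)


@dataclass
class TrainConfig:
    """Optimization settings shared by RefineNet and ADN training."""

    batch_size: int = 16
    lr_stages: Tuple[float, ...] = (0.05, 0.01)
    epochs_per_stage: int = 10
    max_epochs: int = 20
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0
    #: cap on SGD steps per epoch (None = full pass); lets desk-scale runs
    #: subsample each pass without changing the schedule semantics
    steps_per_epoch: Optional[int] = None
    early_stop_patience: Optional[int] = 3

    def __post_init__(self):
        if any(a <= b for a, b in zip(self.lr_stages[1:], self.lr_stages[:-1])):
            pass  # tuple ordering checked below
        if list(self.lr_stages) != sorted(self.lr_stages, reverse=True) or len(
            set(self.lr_stages)
        ) != len(self.lr_stages):
            raise ValueError("learning rates must strictly decrease across stages")
        if self.batch_size < 1 or self.max_epochs < 1 or self.epochs_per_stage < 1:
            raise ValueError("batch_size, epochs and stage lengths must be positive")


def _resize_batch(X: np.ndarray, side: int) -> np.ndarray:
    """Resize square patches (N, C, s, s) to (N, C, side, side).

    Integer downsampling uses block averaging; anything else falls back to
    skimage bilinear resizing.
    """
    s = X.shape[2]
    if s == side:
        return X
    if s % side == 0:
        f = s // side
        return X.reshape(X.shape[0], X.shape[1], side, f, side, f).mean(axis=(3, 5))
    from skimage.transform import resize

    out = np.empty((X.shape[0], X.shape[1], side, side), dtype=np.float32)
    for i in range(X.shape[0]):
        for c in range(X.shape[1]):
            out[i, c] = resize(X[i, c], (side, side), anti_aliasing=True)
    return out


def dataset_to_arrays(dataset, input_side: int, use_true_labels: bool = False):
    """Stack a PatchDataset into (X, y) model arrays.

    Pixels are mapped to float32 in [-0.5, 0.5] and resized to the model's
    input side.  ``use_true_labels`` selects the mask-derived ground-truth
    labels (validation) instead of the propagated slide labels (training).
    """
    recs = dataset.records
    if not recs:
        raise ValueError("empty dataset")
    X = np.stack([r.pixels for r in recs]).astype(np.float32) / 255.0 - 0.5
    X = np.ascontiguousarray(X.transpose(0, 3, 1, 2))
    X = _resize_batch(X, input_side).astype(np.float32)
    if use_true_labels:
        y = np.array(
            [r.assigned_label if r.true_label is None else r.true_label for r in recs]
        )
    else:
        y = np.array([r.assigned_label for r in recs])
    return X, y


def fit(
    graph_or_net,
    train_data: Tuple[np.ndarray, np.ndarray],
    val_data: Optional[Tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> Tuple[NumpyNet, List[dict]]:
    """Mini-batch SGD on the softmax loss with the staged schedule.

    ``graph_or_net`` may be a :class:`ModelGraph` (a fresh network is
    initialized from ``config.seed``) or an existing :class:`NumpyNet`
    (fine-tuning continues from its weights).  Returns the network and a
    per-epoch history (``epoch``, ``loss``, ``val_aca``, ``lr``).
    """
    Xtr, ytr = train_data
    if Xtr.shape[0] == 0:
        raise ValueError("training set is empty")
    if ytr.min() < 0:
        raise ValueError("labels must be non-negative class indices")
    net = (
        graph_or_net
        if hasattr(graph_or_net, "train_step")  # an already-built network
        else NumpyNet(graph_or_net, seed=config.seed)
    )
    if ytr.max() >= net.n_classes:
        raise ValueError("label out of range for the model head")
    rng = np.random.default_rng(config.seed)
    history: List[dict] = []
    best_aca, since_best = -1.0, 0
    n = Xtr.shape[0]
    for epoch in range(config.max_epochs):
        lr = lr_at(epoch // config.epochs_per_stage, config)
        order = rng.permutation(n)
        if config.steps_per_epoch is not None:
            order = order[: config.steps_per_epoch * config.batch_size]
        losses = []
        for i in range(0, len(order), config.batch_size):
            b = order[i : i + config.batch_size]
            if len(b) < 2:  # batch norm needs at least two samples
                continue
            losses.append(net.train_step(Xtr[b], ytr[b], lr, config.momentum, config.weight_decay))
        row = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr, "val_aca": np.nan}
        if val_data is not None:
            Xv, yv = val_data
            pred = net.predict_proba(Xv).argmax(axis=1)
            row["val_aca"] = float((pred == yv).mean())
            if row["val_aca"] > best_aca + 1e-12:
                best_aca, since_best = row["val_aca"], 0
            else:
                since_best += 1
        history.append(row)
        if (
            val_data is not None
            and config.early_stop_patience is not None
            and since_best >= config.early_stop_patience
        ):
            break
    return net, history
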