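"""Deep-reverse active learning (DRAL): iterative mislabeled-patch removal.

Classical active learning adds the most informative unlabeled samples to the
training set; DRAL runs the process in reverse — it *removes* training
patches the model itself is least confident about, on the premise that
slide-label propagation planted mislabeled (normal-tissue) patches in the
pool.  One iteration:

1. the confidence model (RefineNet) predicts class probabilities for every
   training patch;
2. patches whose maximum confidence is strictly below the threshold
   (default 0.5) are flagged;
3. augmentation-group consensus: if strictly more than half of a group's
   orientation variants are flagged (more than 4 of 8), the whole group is
   removed, otherwise only the flagged members are;
4. the model is fine-tuned (warm start) on the reduced set;
5. accuracy is measured on a fixed, truly-labeled validation set.

Removal and fine-tuning alternate until the validation accuracy stops
improving (or an iteration cap is hit); the surviving pool can then be
treated as correctly annotated data for training a deeper classifier.

Note on binary tasks: a 2-class softmax maximum is always >= 0.5, so the
default threshold never flags anything when K = 2; the threshold is
configurable and a warning is issued in that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .nn import NumpyNet
from .patchio import PatchDataset
from .training import TrainConfig, dataset_to_arrays, fit

__all__ = [
    "DRALConfig",
    "DRALLog",
    "flag_low_confidence",
    "consensus_removal",
    "predict_dataset",
    "dral_iteration",
    "run_dral",
    "noise_detection_metrics",
]


@dataclass
class DRALConfig:
    """Selection and stopping rules of the removal loop."""

    confidence_threshold: float = 0.5
    max_iterations: int = 4
    stop_patience: int = 1  # iterations without val-ACA improvement
    satisfactory_aca: Optional[float] = None  # absolute early-out, optional
    finetune_epochs: int = 1
    removal_cap: Optional[float] = None  # max fraction removed per iteration
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.stop_patience < 1:
            raise ValueError("stop_patience must be >= 1")


@dataclass
class DRALLog:
    """Per-iteration record of the loop — training-set sizes, removal counts
    and validation ACA — plus the removed-record ids per iteration."""

    rows: List[dict] = field(default_factory=list)
    removed_ids: List[Set[str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["iteration", "size_before", "size_after", "n_flagged", "n_removed", "val_aca"],
        )


def record_uid(record) -> str:
    """Stable identifier of one augmented patch record."""
    return f"{record.group_id}#a{record.aug_index}"


def flag_low_confidence(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """flag_i = (max_j p_ij < threshold), strict inequality.

    Rows must be probability vectors (non-negative, summing to 1 within 1e-6).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("probabilities must be an N x K matrix")
    if p.min() < 0 or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be probability vectors summing to 1")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if p.shape[1] == 2 and threshold <= 0.5:
        warnings.warn(
            "2-class softmax maxima are always >= 0.5; threshold "
            f"{threshold} will never flag anything",
            stacklevel=2,
        )
    return p.max(axis=1) < threshold


def consensus_removal(
    flags: Sequence[bool],
    group_ids: Sequence[str],
    group_size: int,
    require_complete: bool = True,
) -> np.ndarray:
    """Removal mask after augmentation-group consensus.

    Per group: if strictly more than half of the *nominal* group size is
    flagged, every member is removed ("more than four of the eight");
    otherwise only the flagged members are.  Groups must be complete unless
    ``require_complete`` is False — later cleaning iterations operate on
    pools whose groups earlier rounds already thinned, and the threshold
    stays relative to the nominal size.
    """
    flags = np.asarray(flags, dtype=bool)
    gids = np.asarray(group_ids)
    if flags.shape != gids.shape:
        raise ValueError("flags and group_ids must align")
    remove = flags.copy()
    order = np.argsort(gids, kind="stable")
    sorted_gids = gids[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_gids[1:] != sorted_gids[:-1], True])
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        idx = order[a:b]
        if len(idx) > group_size or (require_complete and len(idx) != group_size):
            raise ValueError(
                f"group {sorted_gids[a]!r} has {len(idx)} members, expected {group_size}"
            )
        if flags[idx].sum() > group_size / 2:
            remove[idx] = True
    return remove


def predict_dataset(net: NumpyNet, dataset: PatchDataset, input_side: int) -> np.ndarray:
    """Class probabilities for every record, each orientation variant scored
    by its own forward pass (no test-time averaging)."""
    X, _ = dataset_to_arrays(dataset, input_side)
    return net.predict_proba(X)


def _val_aca(net: NumpyNet, val_arrays) -> float:
    Xv, yv = val_arrays
    return float((net.predict_proba(Xv).argmax(axis=1) == yv).mean())


def dral_iteration(
    net: NumpyNet,
    train: PatchDataset,
    val_arrays: Tuple[np.ndarray, np.ndarray],
    config: DRALConfig,
    train_config: TrainConfig,
    input_side: int,
    finetune_lr: float = 0.01,
) -> Tuple[PatchDataset, float, dict, Set[str]]:
    """One predict / flag / consensus-remove / fine-tune / validate cycle.

    Returns the reduced dataset, the post-fine-tune validation ACA, the log
    row, and the removed record ids.  Aborts rather than emptying the
    training pool.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    probs = predict_dataset(net, train, input_side)
    flags = flag_low_confidence(probs, config.confidence_threshold)
    gids = [r.group_id for r in train.records]
    remove = consensus_removal(flags, gids, train.group_size, require_complete=False)
    if config.removal_cap is not None:
        cap = int(config.removal_cap * len(train))
        if remove.sum() > cap:
            # keep the lowest-confidence removals up to the cap, whole groups first
            conf = probs.max(axis=1)
            order = np.argsort(conf)
            keep_mask = np.zeros_like(remove)
            taken = 0
            for i in order:
                if remove[i] and taken < cap:
                    keep_mask[i] = True
                    taken += 1
            remove = keep_mask
    if remove.all():
        raise RuntimeError(
            "consensus removal would empty the training set; the confidence "
            "model is uninformative (uniform predictions?) — aborting"
        )
    kept = np.flatnonzero(~remove)
    removed_ids = {record_uid(train.records[i]) for i in np.flatnonzero(remove)}
    reduced = train.subset(kept)
    ft_cfg = replace(
        train_config,
        lr_stages=(finetune_lr,),
        max_epochs=config.finetune_epochs,
        epochs_per_stage=max(1, config.finetune_epochs),
        early_stop_patience=None,
    )
    fit(net, dataset_to_arrays(reduced, input_side), None, ft_cfg)
    aca_val = _val_aca(net, val_arrays)
    row = {
        "size_before": len(train),
        "size_after": len(reduced),
        "n_flagged": int(flags.sum()),
        "n_removed": int(remove.sum()),
        "val_aca": aca_val,
    }
    return reduced, aca_val, row, removed_ids


def run_dral(
    train: PatchDataset,
    val: PatchDataset,
    graph_factory: Callable[[], "object"],
    train_config: TrainConfig,
    config: DRALConfig,
    input_side: int,
) -> Tuple[PatchDataset, DRALLog, NumpyNet]:
    """Full DRAL: initial confidence-model training, then alternating
    removal / fine-tuning until validation ACA stops improving.

    ``val`` must carry ground-truth labels (the stand-in for the fixed,
    pathologist-annotated validation set).  Returns the refined pool, the
    log (iteration 0 records the initially trained model), and the model.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val must be non-empty")
    graph = graph_factory()
    val_arrays = dataset_to_arrays(val, input_side, use_true_labels=True)
    net, _ = fit(
        graph, dataset_to_arrays(train, input_side), val_arrays, train_config
    )
    log = DRALLog()
    best = _val_aca(net, val_arrays)
    log.rows.append(
        {
            "iteration": 0,
            "size_before": len(train),
            "size_after": len(train),
            "n_flagged": 0,
            "n_removed": 0,
            "val_aca": best,
        }
    )
    since_best = 0
    current = train
    for k in range(1, config.max_iterations + 1):
        current, aca_val, row, removed = dral_iteration(
            net, current, val_arrays, config, train_config, input_side
        )
        row["iteration"] = k
        log.rows.append(row)
        log.removed_ids.append(removed)
        if aca_val > best + 1e-12:
            best, since_best = aca_val, 0
        else:
            since_best += 1
        if config.satisfactory_aca is not None and aca_val >= config.satisfactory_aca:
            break
        if since_best >= config.stop_patience:
            break
        if row["n_removed"] == 0:
            break
    return current, log, net


def noise_detection_metrics(
    removed_ids: Set[str], truth_ids: Set[str], total: int
) -> Tuple[float, float, float]:
    """Precision / recall / F of the removal decision against the known
    mislabeled set (synthetic ground truth)."""
    tp = len(removed_ids & truth_ids)
    fp = len(removed_ids - truth_ids)
    fn = len(truth_ids - removed_ids)
    from .evaluation import precision_recall_f

    return precision_recall_f(tp, fp, fn)
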