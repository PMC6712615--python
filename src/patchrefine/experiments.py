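"""Reference end-to-end noise-recovery experiment.

Simulates the full workflow on the synthetic corpus: generate slides, crop
and augment patches with slide-label propagation (injecting a known set of
mislabeled normal-tissue patches), run DRAL with a RefineNet confidence
model, then train the small ADN classifier once on the noisy pool and once
on the DRAL-refined pool and compare their validation accuracies against
ground-truth labels.

The default corpus is 4 classes, 8 slides/class of 256x256 pixels, 64x64
patches at 50% overlap (49 per slide, 1568 base patches, 12544 after 8-fold
orientation augmentation), tumor fraction 0.3 and purity threshold 0.1.
Training uses short staged schedules with capped steps per pass — problem
sizes chosen so a full 5-seed battery runs on one desktop CPU core; the
texture classification task is easy enough that these budgets train both
networks well past chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dral import DRALConfig, DRALLog, noise_detection_metrics, record_uid, run_dral
from .models import ADNConfig, build_adn, build_refinenet
from .patchio import PatchDataset, augment_dataset, extract_patches
from .synthetic import CorpusConfig, expected_noise_rate, generate_corpus
from .training import TrainConfig, dataset_to_arrays, fit

__all__ = ["NoiseRecoveryResult", "noise_recovery_experiment", "small_adn_config"]


def small_adn_config(n_classes: int = 4, input_side: int = 32) -> ADNConfig:
    """The reference 28-weighted-layer ADN topology at a 32x32 input —
    small enough to train on a CPU, identical in structure to the full net."""
    return ADNConfig(
        n_classes=n_classes, input_size=(input_side, input_side), strict_reference=True
    )


@dataclass
class NoiseRecoveryResult:
    seed: int
    noise_rate: float  # ground-truth fraction of mislabeled patches
    removal_precision: float
    removal_recall: float
    removal_f: float
    noisy_aca: float  # ADN trained on the uncleaned pool
    refined_aca: float  # ADN trained on the DRAL-refined pool
    dral_log: DRALLog
    n_train_patches: int
    n_removed: int


def _build_pool(corpus_cfg: CorpusConfig, patch: int, overlap: float,
                purity: float, aug_mode: str) -> PatchDataset:
    slides, _ = generate_corpus(corpus_cfg)
    base = []
    for s in slides:
        base.extend(
            extract_patches(s, patch, overlap, true_mask=s.tumor_mask,
                            purity_threshold=purity)
        )
    ds = augment_dataset(base, aug_mode, corpus_cfg.n_classes)
    ds._slides = slides  # kept for noise-rate bookkeeping
    return ds


def noise_recovery_experiment(
    seed: int,
    n_classes: int = 4,
    n_slides_per_class: int = 8,
    n_val_slides_per_class: int = 4,
    slide_side: int = 256,
    patch_size: int = 64,
    overlap: float = 0.5,
    tumor_fraction: float = 0.3,
    purity_threshold: float = 0.1,
    aug_mode: str = "d4_8",
    rn_input_side: int = 64,
    adn_input_side: int = 32,
    rn_steps_per_epoch: Optional[int] = 150,
    adn_steps_per_epoch: Optional[int] = 250,
    max_iterations: int = 2,
) -> NoiseRecoveryResult:
    """Run one seed of the reference experiment; see the module docstring.

    All stage seeds derive from ``seed``; the validation corpus uses an
    offset so its slides never coincide with training slides.
    """
    train_cfg = CorpusConfig(
        n_slides_per_class=n_slides_per_class,
        slide_size=(slide_side, slide_side),
        tumor_fraction=tumor_fraction,
        n_classes=n_classes,
        seed=seed,
    )
    val_cfg = CorpusConfig(
        n_slides_per_class=n_val_slides_per_class,
        slide_size=(slide_side, slide_side),
        tumor_fraction=tumor_fraction,
        n_classes=n_classes,
        seed=seed + 700_001,
    )
    train = _build_pool(train_cfg, patch_size, overlap, purity_threshold, aug_mode)
    val = _build_pool(val_cfg, patch_size, overlap, purity_threshold, "none")

    noise_rate = expected_noise_rate(
        train._slides, patch_size, overlap, purity_threshold
    )
    truth_ids = {
        record_uid(r)
        for r in train.records
        if r.true_label is not None and r.true_label != r.assigned_label
    }

    rn_train_cfg = TrainConfig(
        lr_stages=(0.05, 0.01),
        epochs_per_stage=1,
        max_epochs=2,
        steps_per_epoch=rn_steps_per_epoch,
        seed=seed,
        early_stop_patience=None,
    )
    dral_cfg = DRALConfig(max_iterations=max_iterations, seed=seed)
    refined, log, _ = run_dral(
        train,
        val,
        lambda: build_refinenet(n_classes, (rn_input_side, rn_input_side)),
        rn_train_cfg,
        dral_cfg,
        rn_input_side,
    )
    removed_ids = set().union(*log.removed_ids) if log.removed_ids else set()
    prec, rec, f = noise_detection_metrics(removed_ids, truth_ids, len(train))

    adn_cfg = small_adn_config(n_classes, adn_input_side)
    adn_train_cfg = TrainConfig(
        lr_stages=(0.05, 0.01),
        epochs_per_stage=1,
        max_epochs=2,
        steps_per_epoch=adn_steps_per_epoch,
        seed=seed + 1,
        early_stop_patience=None,
    )
    val_arrays = dataset_to_arrays(val, adn_input_side, use_true_labels=True)
    acas = {}
    for name, pool in (("noisy", train), ("refined", refined)):
        net, _ = fit(
            build_adn(adn_cfg),
            dataset_to_arrays(pool, adn_input_side),
            None,
            adn_train_cfg,
        )
        pred = net.predict_proba(val_arrays[0]).argmax(axis=1)
        acas[name] = float((pred == val_arrays[1]).mean())

    return NoiseRecoveryResult(
        seed=seed,
        noise_rate=noise_rate,
        removal_precision=prec,
        removal_recall=rec,
        removal_f=f,
        noisy_aca=acas["noisy"],
        refined_aca=acas["refined"],
        dral_log=log,
        n_train_patches=len(train),
        n_removed=len(removed_ids),
    )
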