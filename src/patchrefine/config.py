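"""Experiment configuration: one YAML file drives the whole pipeline.

A root seed deterministically derives per-stage seeds, and every run writes
into a fresh versioned directory (``run_001``, ``run_002``, ...) with a
machine-readable manifest of the files it produced, so reruns never silently
overwrite earlier artifacts.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import yaml

from .synthetic import CorpusConfig

__all__ = ["PatchConfig", "DRALSection", "TrainSection", "ExperimentConfig",
           "load_config", "validate_config", "derive_seed", "new_run_dir"]


@dataclass
class PatchConfig:
    size: int = 64
    overlap: float = 0.5
    aug_mode: str = "d4_8"
    purity_threshold: float = 0.1
    roi: bool = False


@dataclass
class TrainSection:
    batch_size: int = 16
    lr_stages: Tuple[float, ...] = (0.05, 0.01)
    epochs_per_stage: int = 1
    max_epochs: int = 2
    steps_per_epoch: Optional[int] = None
    input_side: int = 64


@dataclass
class DRALSection:
    confidence_threshold: float = 0.5
    max_iterations: int = 4
    stop_patience: int = 1
    finetune_epochs: int = 1


@dataclass
class ExperimentConfig:
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    val_corpus: Optional[CorpusConfig] = None
    patch: PatchConfig = field(default_factory=PatchConfig)
    refinenet: TrainSection = field(default_factory=TrainSection)
    adn: TrainSection = field(default_factory=lambda: TrainSection(input_side=32))
    dral: DRALSection = field(default_factory=DRALSection)
    output_dir: str = "runs"
    seed: int = 0


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, hashed from the root seed.

    Uses crc32 of the stage name (not Python's salted ``hash``) so the
    derivation is identical across processes.
    """
    h = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def _build(cls, data: dict):
    if data is None:
        return cls()
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kw = dict(data)
    for tup_key in ("lr_stages", "slide_size"):
        if tup_key in kw and isinstance(kw[tup_key], list):
            kw[tup_key] = tuple(kw[tup_key])
    return cls(**kw)


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = ExperimentConfig(
        corpus=_build(CorpusConfig, data.get("corpus")),
        val_corpus=_build(CorpusConfig, data["val_corpus"]) if data.get("val_corpus") else None,
        patch=_build(PatchConfig, data.get("patch")),
        refinenet=_build(TrainSection, data.get("refinenet")),
        adn=_build(TrainSection, data.get("adn")),
        dral=_build(DRALSection, data.get("dral")),
        output_dir=data.get("output_dir", "runs"),
        seed=int(data.get("seed", 0)),
    )
    return cfg


def validate_config(cfg: ExperimentConfig) -> List[str]:
    """Every violated invariant, as 'field.path: problem' strings."""
    v: List[str] = []
    p = cfg.patch
    if not (0.0 <= p.overlap < 1.0):
        v.append("patch.overlap: must lie in [0, 1)")
    elif round(p.size * (1 - p.overlap)) < 1:
        v.append("patch.overlap: stride rounds to zero")
    if p.size > min(cfg.corpus.slide_size):
        v.append("patch.size: larger than the slide")
    if not (0.0 < p.purity_threshold <= 1.0):
        v.append("patch.purity_threshold: must lie in (0, 1]")
    if p.aug_mode not in ("d4_8", "rot_4", "none"):
        v.append("patch.aug_mode: unknown mode")
    d = cfg.dral
    if d.max_iterations < 1:
        v.append("dral.max_iterations: must be >= 1")
    if not (0.0 < d.confidence_threshold <= 1.0):
        v.append("dral.confidence_threshold: must lie in (0, 1]")
    if d.stop_patience < 1:
        v.append("dral.stop_patience: must be >= 1")
    for name, sect in (("refinenet", cfg.refinenet), ("adn", cfg.adn)):
        if list(sect.lr_stages) != sorted(set(sect.lr_stages), reverse=True):
            v.append(f"{name}.lr_stages: must strictly decrease")
        if sect.batch_size < 2:
            v.append(f"{name}.batch_size: must be >= 2 (batch norm)")
    side = cfg.refinenet.input_side
    if side % 32 != 0 or side < 32:
        v.append("refinenet.input_side: must be a positive multiple of 32")
    if cfg.adn.input_side < 16:
        v.append("adn.input_side: must be >= 16")
    try:
        CorpusConfig(**{k: getattr(cfg.corpus, k) for k in
                        ("n_slides_per_class", "slide_size", "tumor_fraction", "n_classes", "seed")})
    except ValueError as e:
        v.append(f"corpus: {e}")
    return v


def new_run_dir(base: str) -> str:
    """Next free ``run_NNN`` directory under ``base``."""
    os.makedirs(base, exist_ok=True)
    n = 1
    while True:
        cand = os.path.join(base, f"run_{n:03d}")
        if not os.path.exists(cand):
            os.makedirs(cand)
            return cand
        n += 1
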