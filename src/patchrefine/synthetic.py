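"""Synthetic slide corpora with known, controllable patch-label noise.

Real pathology archives attach one diagnostic label to an entire slide, and
that label is propagated to every cropped patch even though lesions cover
only part of a "cancer" slide — so a known fraction of training patches end
up mislabeled.  This module manufactures that situation deliberately:

* every class is a procedural texture (band-limited filtered Gaussian noise
  with a class-specific spatial frequency and RGB palette), learnable by a
  small CNN in minutes on a CPU yet not trivially so;
* a non-normal slide is class-0 (normal) texture with one or more elliptical
  tumor blobs of its own class texture accreted until a target area fraction
  is covered, mimicking compact lesions whose patch purity varies with
  position;
* the tumor mask gives per-patch ground truth: a patch's true label is the
  slide label if its tumor-pixel fraction reaches a purity threshold, else
  class 0 (normal).

All randomness flows through explicit integer seeds; the corpus seed derives
per-slide seeds by fixed hashing, so identical configs give identical pixels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "TextureSpec",
    "SyntheticSlide",
    "CorpusConfig",
    "default_textures",
    "generate_slide",
    "generate_corpus",
    "save_corpus",
    "patch_true_label",
    "expected_noise_rate",
]

#: per-class (base_frequency cycles/pixel, palette RGB) defaults; class 0 is
#: a pale low-frequency "normal tissue" texture, later classes are darker,
#: higher-frequency and differently colored
_DEFAULT_FREQS = (0.02, 0.06, 0.10, 0.15, 0.24, 0.33)
_DEFAULT_PALETTES = (
    (0.93, 0.82, 0.88),
    (0.55, 0.35, 0.65),
    (0.72, 0.52, 0.32),
    (0.32, 0.52, 0.58),
    (0.62, 0.62, 0.30),
    (0.40, 0.40, 0.70),
)
#: fixed per-channel modulation of the noise field, shared by all classes
_CHANNEL_WEIGHTS = (1.0, 0.75, 0.9)


@dataclass(frozen=True)
class TextureSpec:
    """Procedural texture of one tissue class."""

    class_id: int
    base_frequency: float  # cycles/pixel of the band-limited noise
    contrast: float  # amplitude of the noise term, in [0, 1]
    palette: Tuple[float, float, float]  # mean RGB in [0, 1]

    def __post_init__(self):
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")


def default_textures(n_classes: int, contrast: float = 0.16) -> List[TextureSpec]:
    """Distinct (frequency, palette) pairs for up to 6 classes."""
    if n_classes > len(_DEFAULT_FREQS):
        raise ValueError(f"at most {len(_DEFAULT_FREQS)} default classes")
    return [
        TextureSpec(i, _DEFAULT_FREQS[i], contrast, _DEFAULT_PALETTES[i])
        for i in range(n_classes)
    ]


@dataclass
class SyntheticSlide:
    """One generated slide: pixels in [0, 1], its label, and the tumor mask."""

    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    slide_label: int
    tumor_mask: np.ndarray  # H x W bool; all-zero for the normal class
    seed: int
    slide_id: str = ""


@dataclass
class CorpusConfig:
    """Shape of a synthetic corpus.

    ``tumor_fraction`` is the target fraction of slide area covered by tumor
    texture on non-normal slides; lower values induce more mislabeled
    patches after slide-label propagation.
    """

    n_slides_per_class: int = 8
    slide_size: Tuple[int, int] = (256, 256)  # (W, H)
    tumor_fraction: float = 0.3
    n_classes: int = 4
    seed: int = 0
    textures: Optional[List[TextureSpec]] = None

    def __post_init__(self):
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_slides_per_class < 1:
            raise ValueError("need at least one slide per class")
        if min(self.slide_size) < 8:
            raise ValueError("slide too small")

    def texture_specs(self) -> List[TextureSpec]:
        return self.textures or default_textures(self.n_classes)


def _texture(spec: TextureSpec, shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise texture, palette + contrast * noise."""
    sigma = 1.0 / (2.0 * np.pi * spec.base_frequency)
    noise = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise /= sd
    img = np.empty(shape + (3,), dtype=np.float64)
    for c in range(3):
        img[..., c] = spec.palette[c] + spec.contrast * _CHANNEL_WEIGHTS[c] * noise
    return np.clip(img, 0.0, 1.0)


#: cap on a single lesion's area as a fraction of the slide.  Lesions are
#: multifocal: several blobs of at most 4% slide area each, which for the
#: reference conditions (tumor_fraction 0.3, 64x64 patches at 50% overlap on
#: 256x256 slides, purity threshold 0.1) leaves roughly a fifth of the
#: corpus's patches mislabeled after slide-label propagation.
_MAX_BLOB_FRACTION = 0.04


def _accrete_tumor_mask(
    shape: Tuple[int, int], target: float, rng: np.random.Generator
) -> np.ndarray:
    """Union of random ellipses covering ``target`` (+-0.5 area %) of the slide.

    Each new ellipse's area is capped by the remaining deficit (so the union
    never overshoots the target) and by :data:`_MAX_BLOB_FRACTION`; accretion
    stops once within tolerance or the remaining deficit is below a few
    pixels.
    """
    H, W = shape
    A = H * W
    mask = np.zeros(shape, dtype=bool)
    for _ in range(500):
        covered = mask.mean()
        remaining = target - covered
        if remaining <= 0.005 or remaining * A < 30:
            break
        area = min(remaining, _MAX_BLOB_FRACTION) * A * rng.uniform(0.6, 1.0)
        aspect = rng.uniform(0.6, 1.6)
        r_r = np.sqrt(area * aspect / np.pi)
        r_c = area / (np.pi * r_r)
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        rr, cc = _draw_ellipse(
            cy, cx, r_r, r_c, shape=shape, rotation=rng.uniform(0, np.pi)
        )
        mask[rr, cc] = True
    return mask


def generate_slide(label: int, config: CorpusConfig, seed: int) -> SyntheticSlide:
    """Deterministically render one slide for class ``label``.

    Non-normal slides receive elliptical tumor regions of the label's texture
    over a normal (class-0) background; the returned ``tumor_mask`` marks the
    tumor pixels exactly.  Class 0 has an all-zero mask by construction.
    """
    if not (0 <= label < config.n_classes):
        raise ValueError(f"label {label} outside [0, {config.n_classes})")
    specs = config.texture_specs()
    rng = np.random.default_rng(seed)
    W, H = config.slide_size
    pixels = _texture(specs[0], (H, W), rng)
    mask = np.zeros((H, W), dtype=bool)
    if label != 0 and config.tumor_fraction > 0:
        if config.tumor_fraction >= 1.0:
            mask[:] = True
        else:
            mask = _accrete_tumor_mask((H, W), config.tumor_fraction, rng)
        tumor = _texture(specs[label], (H, W), rng)
        pixels = np.where(mask[..., None], tumor, pixels)
    return SyntheticSlide(pixels=pixels, slide_label=label, tumor_mask=mask, seed=seed)


def _slide_seed(corpus_seed: int, index: int) -> int:
    """Fixed hash from the corpus seed to a per-slide integer seed."""
    ss = np.random.SeedSequence([int(corpus_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_corpus(config: CorpusConfig) -> Tuple[List[SyntheticSlide], pd.DataFrame]:
    """All K * n_slides_per_class slides plus a manifest.

    Slides are ordered class-major; the manifest records the (virtual) file
    path, label and per-slide seed, so the corpus is reproducible from
    ``config.seed`` alone.
    """
    slides, rows = [], []
    idx = 0
    for label in range(config.n_classes):
        for _ in range(config.n_slides_per_class):
            seed = _slide_seed(config.seed, idx)
            slide = generate_slide(label, config, seed)
            slide.slide_id = f"slide_{idx:04d}"
            slides.append(slide)
            rows.append(
                {
                    "path": f"{slide.slide_id}.png",
                    "label": label,
                    "seed": seed,
                    "mask_path": f"{slide.slide_id}_mask.png",
                }
            )
            idx += 1
    return slides, pd.DataFrame(rows)


def save_corpus(slides: List[SyntheticSlide], manifest: pd.DataFrame, out_dir: str) -> str:
    """Write slides as 8-bit RGB PNGs, masks as single-channel PNGs, and the
    manifest as CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    for slide, row in zip(slides, manifest.itertuples(index=False)):
        img = (np.clip(slide.pixels, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(img).save(os.path.join(out_dir, row.path))
        Image.fromarray((slide.tumor_mask * 255).astype(np.uint8), mode="L").save(
            os.path.join(out_dir, row.mask_path)
        )
    path = os.path.join(out_dir, "slides.csv")
    manifest.to_csv(path, index=False)
    return path


def patch_true_label(
    slide_label: int, mask_patch: np.ndarray, purity_threshold: float = 0.1
) -> int:
    """Ground-truth label of a patch from the tumor mask.

    The patch keeps the slide label only if its tumor-pixel fraction reaches
    ``purity_threshold``; otherwise it is normal tissue (class 0).
    """
    if not (0.0 < purity_threshold <= 1.0):
        raise ValueError("purity_threshold must lie in (0, 1]")
    if slide_label == 0:
        return 0
    return slide_label if mask_patch.mean() >= purity_threshold else 0


def expected_noise_rate(
    slides: List[SyntheticSlide],
    patch_size: int,
    overlap: float,
    purity_threshold: float = 0.1,
) -> float:
    """Fraction of grid patches whose propagated label is wrong.

    A patch is mislabeled when its slide is non-normal but its tumor purity
    falls below the threshold (its true label is then class 0, not the slide
    label).  Integral-image sums make this exact and fast; the test suite
    cross-checks it against a direct per-patch loop.
    """
    from .patchio import grid_positions  # local import avoids a cycle

    if not (0.0 < purity_threshold <= 1.0):
        raise ValueError("purity_threshold must lie in (0, 1]")
    total = mislabeled = 0
    for slide in slides:
        H, W = slide.tumor_mask.shape
        if patch_size > min(H, W):
            raise ValueError("patch larger than slide")
        positions = grid_positions(W, H, patch_size, overlap)
        total += len(positions)
        if slide.slide_label == 0:
            continue
        # summed-area table of the mask for O(1) per-patch tumor counts
        sat = np.zeros((H + 1, W + 1), dtype=np.int64)
        np.cumsum(np.cumsum(slide.tumor_mask, axis=0), axis=1, out=sat[1:, 1:])
        w = patch_size
        for (x, y) in positions:
            cnt = sat[y + w, x + w] - sat[y, x + w] - sat[y + w, x] + sat[y, x]
            if cnt / (w * w) < purity_threshold:
                mislabeled += 1
    if total == 0:
        raise ValueError("no patches on the grid")
    return mislabeled / total
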