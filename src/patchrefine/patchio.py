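"""Sliding-window patch extraction, slide-label propagation, RoI masking,
orientation augmentation groups, and patch-manifest I/O.

Patches are cropped on a regular grid (stride = round(w * (1 - overlap)),
partial windows at the right/bottom edges discarded) and every patch inherits
its slide's label — the propagation step that creates label noise wherever a
patch contains only normal tissue.  Each source patch is expanded into an
augmentation *group* of orientation variants (the 8 dihedral poses, or the 4
rotations); the reverse-active-learning consensus rule later operates on
these groups.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import SyntheticSlide, patch_true_label

__all__ = [
    "SlideRecord",
    "PatchRecord",
    "PatchDataset",
    "grid_positions",
    "binarize_roi",
    "extract_patches",
    "augment_group",
    "augment_dataset",
    "write_manifest",
    "read_manifest",
    "ManifestError",
]

GROUP_SIZES = {"d4_8": 8, "rot_4": 4, "none": 1}

MANIFEST_COLUMNS = [
    "patch_path",
    "slide_id",
    "assigned_label",
    "true_label",
    "grid_x",
    "grid_y",
    "group_id",
    "aug_index",
]


class ManifestError(ValueError):
    pass


@dataclass
class SlideRecord:
    """One input image with a slide-level label (and, synthetically, a mask)."""

    pixels: np.ndarray  # H x W x 3, float [0,1] or uint8
    label: int
    slide_id: str
    tumor_mask: Optional[np.ndarray] = None

    @classmethod
    def from_synthetic(cls, slide: SyntheticSlide) -> "SlideRecord":
        return cls(
            pixels=slide.pixels,
            label=slide.slide_label,
            slide_id=slide.slide_id,
            tumor_mask=slide.tumor_mask,
        )


@dataclass
class PatchRecord:
    """One cropped patch. ``assigned_label`` is the propagated slide label;
    ``true_label`` (mask-derived, synthetic corpora only) may disagree with
    it — that disagreement is exactly the injected label noise."""

    pixels: np.ndarray  # w x w x 3 uint8
    assigned_label: int
    slide_id: str
    grid_xy: Tuple[int, int]
    group_id: str
    aug_index: int = 0
    true_label: Optional[int] = None


@dataclass
class PatchDataset:
    """The training pool D: patch records organized in augmentation groups."""

    records: List[PatchRecord]
    group_size: int = 1
    n_classes: int = 2

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> dict:
        out: dict = {}
        for i, r in enumerate(self.records):
            out.setdefault(r.group_id, []).append(i)
        return out

    def validate(self) -> None:
        """Check group completeness and intra-group consistency."""
        for gid, idxs in self.groups().items():
            if len(idxs) != self.group_size:
                raise ManifestError(
                    f"group {gid!r} has {len(idxs)} members, expected {self.group_size}"
                )
            members = [self.records[i] for i in idxs]
            if sorted(m.aug_index for m in members) != list(range(self.group_size)):
                raise ManifestError(f"group {gid!r} aug_index values do not cover "
                                    f"[0, {self.group_size})")
            keys = {(m.slide_id, m.grid_xy, m.assigned_label) for m in members}
            if len(keys) != 1:
                raise ManifestError(f"group {gid!r} members disagree on slide/position/label")

    def subset(self, keep: Sequence[int]) -> "PatchDataset":
        keep = sorted(set(int(i) for i in keep))
        return PatchDataset(
            records=[self.records[i] for i in keep],
            group_size=self.group_size,
            n_classes=self.n_classes,
        )


def grid_positions(W: int, H: int, w: int, overlap: float) -> List[Tuple[int, int]]:
    """Top-left corners of the sliding-window grid.

    Stride s = round(w * (1 - overlap)); positions are (i*s, j*s) for every
    window fully inside the image (no edge padding), so the count is
    (floor((W-w)/s)+1) * (floor((H-w)/s)+1).  For the classic 2048x1536
    slide with 512-pixel windows at 50% overlap this yields 35 positions.
    """
    if w > W or w > H:
        raise ValueError(f"patch side {w} exceeds image {W}x{H}")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    s = int(round(w * (1.0 - overlap)))
    if s < 1:
        raise ValueError("stride rounds to zero; decrease overlap")
    xs = range(0, W - w + 1, s)
    ys = range(0, H - w + 1, s)
    return [(x, y) for y in ys for x in xs]


def binarize_roi(image: np.ndarray) -> np.ndarray:
    """Tissue (region-of-interest) mask via Otsu on luminance.

    Tissue is the darker side of the threshold (slides have bright
    backgrounds); a 3x3 majority vote smooths speckle.  Near-constant images
    are resolved by brightness alone: dark means all tissue, bright means all
    background.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        lum = img[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
    else:
        lum = img.astype(np.float64)
    if img.dtype == np.uint8:
        lum /= 255.0
    if lum.max() - lum.min() < 1e-6:
        return np.full(lum.shape, lum.mean() < 0.5, dtype=bool)
    from skimage.filters import threshold_otsu
    from scipy.ndimage import uniform_filter

    mask = lum < threshold_otsu(lum)
    return uniform_filter(mask.astype(np.float32), size=3) > 0.5


def extract_patches(
    slide: SlideRecord,
    w: int,
    overlap: float,
    roi: Optional[np.ndarray] = None,
    true_mask: Optional[np.ndarray] = None,
    purity_threshold: float = 0.1,
) -> List[PatchRecord]:
    """Crop one un-augmented record per kept grid position.

    Every record's ``assigned_label`` is the slide label.  With an ``roi``
    mask, positions whose window is less than 50% foreground are dropped.
    With a ``true_mask`` (synthetic tumor mask), the ground-truth label is
    set by the purity rule.
    """
    if isinstance(slide, SyntheticSlide):
        slide = SlideRecord.from_synthetic(slide)
    px = slide.pixels
    H, W = px.shape[:2]
    if px.dtype != np.uint8:
        px = (np.clip(px, 0, 1) * 255).round().astype(np.uint8)
    if true_mask is None:
        true_mask = slide.tumor_mask
    records = []
    for (x, y) in grid_positions(W, H, w, overlap):
        if roi is not None and roi[y : y + w, x : x + w].mean() < 0.5:
            continue
        true_label = None
        if true_mask is not None:
            true_label = patch_true_label(
                slide.label, true_mask[y : y + w, x : x + w], purity_threshold
            )
        records.append(
            PatchRecord(
                pixels=px[y : y + w, x : x + w],
                assigned_label=slide.label,
                slide_id=slide.slide_id,
                grid_xy=(x, y),
                group_id=f"{slide.slide_id}:{x}:{y}",
                aug_index=0,
                true_label=true_label,
            )
        )
    return records


def augment_group(patch: PatchRecord, mode: str = "d4_8") -> List[PatchRecord]:
    """Expand one patch into its orientation group.

    ``d4_8``: the four rotations (0/90/180/270 degrees) followed by the
    vertical flip of each — the 8 poses of the dihedral group of the square,
    original included as aug_index 0.  ``rot_4``: rotations only.  All
    transforms are exact array re-indexings; no interpolation.
    """
    if mode not in ("d4_8", "rot_4"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    px = patch.pixels
    if px.shape[0] != px.shape[1]:
        raise ValueError("rotation augmentation requires square patches")
    rots = [np.ascontiguousarray(np.rot90(px, r)) for r in range(4)]
    planes = rots if mode == "rot_4" else rots + [
        np.ascontiguousarray(p[::-1]) for p in rots
    ]
    return [
        replace(patch, pixels=p, aug_index=i) for i, p in enumerate(planes)
    ]


def augment_dataset(
    records: List[PatchRecord], mode: str, n_classes: int
) -> PatchDataset:
    """Apply :func:`augment_group` to every base record."""
    size = GROUP_SIZES[mode]
    out: List[PatchRecord] = []
    for r in records:
        out.extend([r] if mode == "none" else augment_group(r, mode))
    ds = PatchDataset(records=out, group_size=size, n_classes=n_classes)
    ds.validate()
    return ds


# -- manifest I/O --------------------------------------------------------


def write_manifest(dataset: PatchDataset, path: str, patches_dir: Optional[str] = None) -> str:
    """Write patch PNGs plus the manifest CSV; returns the CSV path.

    Rows are sorted by (group_id, aug_index) so that write-read-write is
    byte-stable.
    """
    patches_dir = patches_dir or os.path.join(os.path.dirname(path) or ".", "patches")
    os.makedirs(patches_dir, exist_ok=True)
    rows = []
    recs = sorted(dataset.records, key=lambda r: (r.group_id, r.aug_index))
    for r in recs:
        fname = f"{r.group_id.replace(':', '_')}_a{r.aug_index}.png"
        Image.fromarray(r.pixels).save(os.path.join(patches_dir, fname))
        rows.append(
            {
                "patch_path": os.path.join(os.path.basename(patches_dir), fname),
                "slide_id": r.slide_id,
                "assigned_label": r.assigned_label,
                "true_label": -1 if r.true_label is None else r.true_label,
                "grid_x": r.grid_xy[0],
                "grid_y": r.grid_xy[1],
                "group_id": r.group_id,
                "aug_index": r.aug_index,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(path: str, group_size: Optional[int] = None, n_classes: Optional[int] = None) -> PatchDataset:
    """Load a manifest CSV (and its patch PNGs) back into a PatchDataset.

    Missing columns and dangling pixel paths are reported with row numbers.
    """
    df = pd.read_csv(path) if os.path.getsize(path) > 0 else pd.DataFrame(columns=MANIFEST_COLUMNS)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise ManifestError(f"manifest missing columns: {missing}")
    base = os.path.dirname(path) or "."
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        p = os.path.join(base, row.patch_path)
        if not os.path.exists(p):
            raise ManifestError(f"row {i}: patch file not found: {row.patch_path}")
        records.append(
            PatchRecord(
                pixels=np.asarray(Image.open(p)),
                assigned_label=int(row.assigned_label),
                slide_id=str(row.slide_id),
                grid_xy=(int(row.grid_x), int(row.grid_y)),
                group_id=str(row.group_id),
                aug_index=int(row.aug_index),
                true_label=None if int(row.true_label) < 0 else int(row.true_label),
            )
        )
    if group_size is None:
        sizes = {}
        for r in records:
            sizes[r.group_id] = sizes.get(r.group_id, 0) + 1
        group_size = max(sizes.values()) if sizes else 1
    if n_classes is None:
        n_classes = max((r.assigned_label for r in records), default=1) + 1
    ds = PatchDataset(records=records, group_size=group_size, n_classes=n_classes)
    ds.validate()
    return ds
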