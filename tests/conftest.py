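import numpy as np
import pytest

from patchrefine.patchio import PatchDataset, PatchRecord, augment_dataset, extract_patches
from patchrefine.synthetic import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """Four tiny slides per class, 96x96, 2 classes — fast but non-trivial."""
    cfg = CorpusConfig(
        n_slides_per_class=4, slide_size=(96, 96), tumor_fraction=0.4,
        n_classes=2, seed=11,
    )
    slides, manifest = generate_corpus(cfg)
    return cfg, slides, manifest


@pytest.fixture(scope="session")
def tiny_pool(tiny_corpus):
    """Augmented 32x32 patch pool with ground-truth labels from the masks."""
    cfg, slides, _ = tiny_corpus
    base = []
    for s in slides:
        base.extend(
            extract_patches(s, 32, 0.5, true_mask=s.tumor_mask, purity_threshold=0.1)
        )
    return augment_dataset(base, "d4_8", cfg.n_classes)


def make_patch(rng, side=8, label=1, slide="s0", xy=(0, 0)):
    return PatchRecord(
        pixels=rng.integers(0, 255, (side, side, 3), dtype=np.uint8).astype(np.uint8),
        assigned_label=label,
        slide_id=slide,
        grid_xy=xy,
        group_id=f"{slide}:{xy[0]}:{xy[1]}",
    )
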