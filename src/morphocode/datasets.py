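"""Balanced pattern datasets: generation, preprocessing, storage, splits.

Every dataset holds the same number of replicate patterns for each character
of a codebook.  Replicates are simulated independently with seeds derived
deterministically from ``(base_seed, class index, replicate index)``, so any
single item can be regenerated exactly, generation parallelizes trivially,
and train/test splits are made disjoint by construction through a replicate
offset rather than by bookkeeping.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .codebook import Codebook, SeedingLayout, SeedingNoise, bits_to_seeding, char_to_bits
from .growth import DomainGeometry, GrowthParams, PatternImage, crop_center, simulate

__all__ = [
    "LabeledDataset",
    "generate_dataset",
    "make_test_set",
    "preprocess",
    "item_rng",
    "TEST_REP_OFFSET",
]

#: replicate-index offset separating test seeds from training seeds
TEST_REP_OFFSET = 1_000_000


@dataclass
class LabeledDataset:
    """Preprocessed 80x80 images with integer class labels, balanced."""

    images: np.ndarray  # (n, 80, 80) float32 in [0, 1]
    labels: np.ndarray  # (n,) int
    n_classes: int
    reps_per_class: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def subset_reps(self, reps: int) -> "LabeledDataset":
        """First ``reps`` replicates of every class (keeps balance)."""
        if reps > self.reps_per_class:
            raise ValueError("not enough replicates")
        keep = []
        for c in range(self.n_classes):
            idx = np.flatnonzero(self.labels == c)[:reps]
            keep.append(idx)
        keep = np.concatenate(keep)
        return LabeledDataset(
            images=self.images[keep],
            labels=self.labels[keep],
            n_classes=self.n_classes,
            reps_per_class=reps,
            provenance=dict(self.provenance),
        )

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.images.tobytes())
        h.update(self.labels.tobytes())
        return h.hexdigest()[:16]


def preprocess(pattern, out_side: int = 80) -> np.ndarray:
    """Anti-aliased bilinear rescale to ``out_side`` square, scaled to [0, 1]."""
    px = pattern.pixels if isinstance(pattern, PatternImage) else np.asarray(pattern)
    if px.ndim != 2 or px.shape[0] != px.shape[1]:
        raise ValueError("pattern must be a square 2D image")
    img = px.astype(np.float64) / 255.0 if px.dtype == np.uint8 else px.astype(np.float64)
    if img.shape[0] == out_side:
        return img.astype(np.float32)
    out = resize(img, (out_side, out_side), order=1, anti_aliasing=True)
    return out.astype(np.float32)


def item_rng(base_seed: int, class_index: int, rep_index: int) -> np.random.Generator:
    """The deterministic per-item generator."""
    return np.random.default_rng([base_seed, class_index, rep_index])


def _generate(
    codebook: Codebook,
    layout: SeedingLayout,
    params: GrowthParams,
    geometry: DomainGeometry,
    reps_per_class: int,
    base_seed: int,
    rep_offset: int,
    seeding_noise: SeedingNoise | None,
    crop_radius: float | None,
) -> LabeledDataset:
    if reps_per_class < 1:
        raise ValueError("reps_per_class must be >= 1")
    noise = seeding_noise or SeedingNoise()
    images, labels = [], []
    for ci, char in enumerate(codebook.characters):
        bits = char_to_bits(char, codebook)
        for rep in range(reps_per_class):
            rng = item_rng(base_seed, ci, rep_offset + rep)
            try:
                seed_field = bits_to_seeding(bits, layout, noise, rng)
                pat = simulate(seed_field, params, geometry, rng)
                if crop_radius is not None:
                    pat = crop_center(pat, crop_radius)
            except Exception as e:  # propagate with class/replicate context
                raise RuntimeError(
                    f"simulation failed for char {char!r} replicate {rep}"
                ) from e
            images.append(preprocess(pat))
            labels.append(ci)
    return LabeledDataset(
        images=np.stack(images),
        labels=np.asarray(labels),
        n_classes=codebook.n_classes,
        reps_per_class=reps_per_class,
        provenance={
            "codebook": codebook.digest(),
            "growth": params.digest(),
            "geometry": geometry.config(),
            "base_seed": base_seed,
            "rep_offset": rep_offset,
            "reps_per_class": reps_per_class,
            "crop_radius": crop_radius,
        },
    )


def generate_dataset(
    codebook: Codebook,
    layout: SeedingLayout,
    params: GrowthParams,
    geometry: DomainGeometry,
    reps_per_class: int,
    base_seed: int,
    seeding_noise: SeedingNoise | None = None,
    crop_radius: float | None = None,
    rep_offset: int = 0,
) -> LabeledDataset:
    """Simulate ``reps_per_class`` replicates per character (training split)."""
    if not 0 <= rep_offset < TEST_REP_OFFSET:
        raise ValueError("training rep_offset must lie below TEST_REP_OFFSET")
    if rep_offset + reps_per_class > TEST_REP_OFFSET:
        raise ValueError("training replicates would overlap the test seed range")
    return _generate(
        codebook, layout, params, geometry, reps_per_class, base_seed,
        rep_offset, seeding_noise, crop_radius,
    )


def make_test_set(
    codebook: Codebook,
    layout: SeedingLayout,
    params: GrowthParams,
    geometry: DomainGeometry,
    reps_per_class: int = 100,
    base_seed: int = 0,
    seeding_noise: SeedingNoise | None = None,
    crop_radius: float | None = None,
) -> LabeledDataset:
    """Held-out split: same generator, replicate seeds disjoint from training."""
    return _generate(
        codebook, layout, params, geometry, reps_per_class, base_seed,
        TEST_REP_OFFSET, seeding_noise, crop_radius,
    )


# ---------------------------------------------------------------------------
# on-disk layout: one PNG per item + manifest JSON

def save_dataset(ds: LabeledDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
        cls_dir = directory / f"class_{lab:03d}"
        cls_dir.mkdir(exist_ok=True)
        px = np.floor(255.0 * img + 0.5).astype(np.uint8)
        PatternImage(px, {"label": int(lab)}).save(cls_dir / f"{i:06d}.png")
    manifest = {
        "n_classes": ds.n_classes,
        "reps_per_class": ds.reps_per_class,
        "provenance": ds.provenance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(directory) -> LabeledDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    images, labels = [], []
    for cls_dir in sorted(directory.glob("class_*")):
        lab = int(cls_dir.name.split("_")[1])
        for f in sorted(cls_dir.glob("*.png")):
            images.append(preprocess(PatternImage.load(f)))
            labels.append(lab)
    return LabeledDataset(
        images=np.stack(images),
        labels=np.asarray(labels),
        n_classes=manifest["n_classes"],
        reps_per_class=manifest["reps_per_class"],
        provenance=manifest["provenance"],
    )
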