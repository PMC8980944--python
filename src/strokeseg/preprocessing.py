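"""Volume-to-slice preprocessing: normalize, crop, resize, cache, split.

The default protocol for full-scale (233 x 197) axial slices: per-volume
min-max normalization, a fixed crop with diagonal coordinates (10, 40)
to (190, 220) — necessarily read as (x, y), i.e. rows 40–220 of the 233
and columns 10–190 of the 197 (the (row, col) reading would run past
the 197-pixel width), giving a 180 x 180 region — then bilinear
resizing to 192 x 192.  Masks follow
the same geometry but use nearest-neighbor resampling and are
re-binarized, so no fractional labels are ever produced.

For non-standard geometries (e.g. compact synthetic volumes) the crop is
disabled and the resize targets the configured size; crop coordinates
are only applied when the slice actually contains the crop box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic import SubjectVolume

__all__ = ["PreprocessConfig", "SliceSample", "SplitAssignment",
           "crop_slice", "resize_bilinear", "resize_nearest",
           "normalize_volume", "extract_slices", "preprocess_subject",
           "split_subjects", "cache_slices", "load_cached_slices"]

ATLAS_CROP = ((40, 10), (220, 190))  # (row, col) box for 233 x 197 slices


@dataclass(frozen=True)
class PreprocessConfig:
    """crop: ((r0, c0), (r1, c1)) half-open box, or None to skip.
    target: output (height, width); the full-scale default is 192 x 192.
    normalize: "minmax" (per volume) or "none".
    lesion_only: keep only slices whose mask has foreground (off by
    default — all slices train, matching the imbalance the Dice loss
    addresses)."""

    crop: tuple[tuple[int, int], tuple[int, int]] | None = ATLAS_CROP
    target: tuple[int, int] = (192, 192)
    normalize: str = "minmax"
    lesion_only: bool = False

    def __post_init__(self):
        if self.normalize not in ("minmax", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        th, tw = self.target
        if th < 1 or tw < 1:
            raise ValueError("target size must be positive")


@dataclass
class SliceSample:
    """One preprocessed axial slice with its aligned binary mask."""

    subject_id: str
    slice_index: int
    image: np.ndarray  # (H, W) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        groups = (set(self.train_ids), set(self.val_ids), set(self.test_ids))
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be pairwise disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)

    def to_dict(self) -> dict:
        return {"train": list(self.train_ids), "val": list(self.val_ids),
                "test": list(self.test_ids)}


# ---------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------

def crop_slice(slice_2d: np.ndarray, top_left: tuple[int, int],
               bottom_right: tuple[int, int]) -> np.ndarray:
    """Half-open rectangular crop [r0, r1) x [c0, c1) in (row, col)."""
    slice_2d = np.asarray(slice_2d)
    (r0, c0), (r1, c1) = top_left, bottom_right
    H, W = slice_2d.shape
    if not (0 <= r0 < r1 <= H):
        raise ValueError(f"row crop [{r0}, {r1}) out of bounds for height {H}")
    if not (0 <= c0 < c1 <= W):
        raise ValueError(f"column crop [{c0}, {c1}) out of bounds for width {W}")
    return slice_2d[r0:r1, c0:c1]


def resize_bilinear(slice_2d: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize for intensity images (convexity-preserving)."""
    out = _sk_resize(np.asarray(slice_2d, dtype=np.float64), target, order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def resize_nearest(mask_2d: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize for label maps, re-binarized."""
    out = _sk_resize(np.asarray(mask_2d, dtype=np.float64), target, order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def normalize_volume(image: np.ndarray) -> np.ndarray:
    """Per-volume min-max scaling to [0, 1]; constant volumes -> zeros."""
    image = np.asarray(image, dtype=np.float32)
    if not np.isfinite(image).all():
        raise ValueError("volume contains NaN or Inf")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def _crop_applies(cfg: PreprocessConfig, shape: tuple[int, int]) -> bool:
    if cfg.crop is None:
        return False
    (r0, c0), (r1, c1) = cfg.crop
    H, W = shape
    return r1 <= H and c1 <= W


def _process_pair(image_2d, mask_2d, cfg: PreprocessConfig):
    if _crop_applies(cfg, image_2d.shape):
        image_2d = crop_slice(image_2d, *cfg.crop)
        mask_2d = crop_slice(mask_2d, *cfg.crop)
    if image_2d.shape != tuple(cfg.target):
        image_2d = resize_bilinear(image_2d, cfg.target)
        mask_2d = resize_nearest(mask_2d, cfg.target)
    return (np.asarray(image_2d, dtype=np.float32),
            np.asarray(mask_2d, dtype=np.uint8))


def extract_slices(subject: SubjectVolume,
                   cfg: PreprocessConfig | None = None) -> list[SliceSample]:
    """Run every axial slice of a subject through the full pipeline."""
    cfg = cfg or PreprocessConfig()
    image = subject.image
    if cfg.normalize == "minmax":
        image = normalize_volume(image)
    samples = []
    for idx in range(image.shape[0]):
        img, msk = _process_pair(image[idx], subject.mask[idx], cfg)
        if cfg.lesion_only and msk.sum() == 0:
            continue
        samples.append(SliceSample(subject.subject_id, idx, img, msk))
    return samples


def preprocess_subject(subject: SubjectVolume,
                       cfg: PreprocessConfig | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed (image, mask) volumes restacked in slice order."""
    local = cfg or PreprocessConfig()
    if local.lesion_only:  # volumes must keep every slice
        local = PreprocessConfig(crop=local.crop, target=local.target,
                                 normalize=local.normalize, lesion_only=False)
    samples = extract_slices(subject, local)
    image = np.stack([s.image for s in samples])
    mask = np.stack([s.mask for s in samples])
    return image, mask


def split_subjects(ids: Sequence[str], sizes: tuple[int, int, int],
                   seed: int) -> SplitAssignment:
    """Seeded random partition of subject ids into train/val/test."""
    ids = list(ids)
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != len(ids):
        raise ValueError(
            f"split sizes {sizes} sum to {n_train + n_val + n_test}, "
            f"but there are {len(ids)} subjects")
    if min(sizes) < 0:
        raise ValueError("split sizes must be nonnegative")
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    return SplitAssignment(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train:n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val:]),
    )


# ---------------------------------------------------------------------
# slice cache
# ---------------------------------------------------------------------

def cache_slices(samples: Sequence[SliceSample], directory: str | Path) -> Path:
    """Write each slice (image + mask) as .npy plus a JSON manifest.

    Returns the manifest path; the round trip through
    :func:`load_cached_slices` is lossless.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cache directory {directory}: {exc}") from exc
    entries = []
    for s in samples:
        stem = f"{s.subject_id}_slice{s.slice_index:04d}"
        img_file, msk_file = f"{stem}_img.npy", f"{stem}_msk.npy"
        try:
            np.save(directory / img_file, s.image)
            np.save(directory / msk_file, s.mask)
        except OSError as exc:
            raise OSError(f"failed writing slice cache under {directory}: "
                          f"{exc}") from exc
        entries.append({"subject_id": s.subject_id,
                        "slice_index": s.slice_index,
                        "image": img_file, "mask": msk_file})
    manifest_path = directory / "slices.json"
    manifest_path.write_text(json.dumps({"slices": entries}, indent=2))
    return manifest_path


def load_cached_slices(directory: str | Path) -> list[SliceSample]:
    directory = Path(directory)
    manifest = json.loads((directory / "slices.json").read_text())
    samples = []
    for e in manifest["slices"]:
        samples.append(SliceSample(
            subject_id=e["subject_id"], slice_index=e["slice_index"],
            image=np.load(directory / e["image"]),
            mask=np.load(directory / e["mask"])))
    return samples
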