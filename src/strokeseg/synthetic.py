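"""Synthetic cohort generator emulating MNI-normalised T1 stroke data.

Each subject is a 3D volume containing a bright elliptical "brain"
(smoothly textured) on a dark background, with zero or more darker
ellipsoidal blobs standing in for chronic hypointense lesions, plus
additive Gaussian noise.  The geometry mirrors the real data this
pipeline targets: per-subject image+mask pairs, most subjects with a
single lesion of highly variable size, and many axial slices containing
no lesion at all (severe foreground/background imbalance).

Lesion radii parameterise the *in-plane* semi-axes; the through-plane
semi-axis is scaled by the brain's own depth-to-width aspect ratio so
that blobs remain anatomically plausible in thin stacks (thick-slice
anisotropy).  Generation is fully deterministic: one master seed, with
per-subject seeds derived as ``seed + subject_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["SyntheticConfig", "SubjectVolume", "generate_subject",
           "generate_cohort", "write_cohort", "read_subject",
           "atlas_like_config"]

_BRAIN_FRACTION = 0.42  # brain semi-axis as a fraction of each volume axis


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation parameters.

    n_slices, slice_height, slice_width: volume geometry in voxels.
    lesion_count_range: inclusive [low, high] lesions per subject.
    lesion_radius_range: in-plane lesion semi-axis range in voxels.
    brain_intensity: range for the brain's base intensity in [0, 1].
    lesion_intensity_delta: additive lesion contrast; negative, since
        chronic stroke is hypointense on T1 (default -0.3).
    noise_sd: Gaussian noise standard deviation (image clipped to [0,1]).
    seed: master seed for the cohort.
    """

    n_slices: int = 16
    slice_height: int = 96
    slice_width: int = 96
    lesion_count_range: tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[float, float] = (5.0, 10.0)
    brain_intensity: tuple[float, float] = (0.55, 0.75)
    lesion_intensity_delta: float = -0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_slices, self.slice_height, self.slice_width) < 1:
            raise ValueError("volume dimensions must be positive")
        lo, hi = self.lesion_count_range
        if lo < 0 or lo > hi:
            raise ValueError("lesion_count_range must satisfy 0 <= low <= high")
        rlo, rhi = self.lesion_radius_range
        if rlo <= 0 or rlo > rhi:
            raise ValueError("lesion_radius_range must satisfy 0 < low <= high")
        blo, bhi = self.brain_intensity
        if not (0 <= blo <= bhi <= 1):
            raise ValueError("brain_intensity must be an interval inside [0, 1]")
        if self.lesion_intensity_delta >= 0:
            raise ValueError("lesion_intensity_delta must be negative "
                             "(chronic T1 lesions are hypointense)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        # in-plane containment: the largest lesion must fit in the brain
        min_inplane_axis = 2 * _BRAIN_FRACTION * min(self.slice_height,
                                                     self.slice_width)
        if rhi > min_inplane_axis / 2:
            raise ValueError(
                f"lesion radius upper bound {rhi} exceeds half the smallest "
                f"in-plane brain axis ({min_inplane_axis / 2:.1f})")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("lesion_count_range", "lesion_radius_range", "brain_intensity"):
            d[k] = list(d[k])
        return d


def atlas_like_config(**overrides) -> SyntheticConfig:
    """Full-scale geometry (189 slices of 233 x 197) for shape tests."""
    defaults = dict(n_slices=189, slice_height=233, slice_width=197,
                    lesion_radius_range=(5.0, 25.0))
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@dataclass
class SubjectVolume:
    """One subject: a 3D image with an aligned binary lesion mask."""

    subject_id: str
    image: np.ndarray   # (n_slices, H, W) float32 in [0, 1]
    mask: np.ndarray    # (n_slices, H, W) uint8 in {0, 1}

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _brain_geometry(cfg: SyntheticConfig):
    shape = np.array([cfg.n_slices, cfg.slice_height, cfg.slice_width], float)
    center = (shape - 1) / 2.0
    semi = _BRAIN_FRACTION * shape
    return shape, center, semi


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, int(s)) for s in shape)]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return q <= 1.0


def generate_subject(config: SyntheticConfig, subject_seed: int) -> SubjectVolume:
    """Generate one subject volume; bit-identical for identical inputs."""
    rng = np.random.default_rng(subject_seed)
    shape, center, brain_semi = _brain_geometry(config)
    dims = tuple(int(s) for s in shape)

    brain = _ellipsoid_mask(shape, center, brain_semi)
    base = rng.uniform(*config.brain_intensity)
    # low-frequency texture inside the brain
    texture = ndimage.gaussian_filter(
        rng.standard_normal(dims), sigma=max(min(dims) / 6.0, 1.0))
    t_std = texture.std()
    if t_std > 0:
        texture = texture / t_std * 0.03
    image = np.where(brain, base + texture, 0.05).astype(np.float32)

    # lesions: ellipsoids fully inside the brain
    mask = np.zeros(dims, dtype=np.uint8)
    n_lesions = int(rng.integers(config.lesion_count_range[0],
                                 config.lesion_count_range[1] + 1))
    aspect = brain_semi[0] / max(brain_semi[1], brain_semi[2])
    for _ in range(n_lesions):
        r_inplane = rng.uniform(*config.lesion_radius_range)
        semi = np.array([max(r_inplane * aspect, 1.0), r_inplane, r_inplane])
        # place the center so the lesion provably fits inside the brain:
        # |(c-C)/A| + max(a/A) <= 1 guarantees ellipsoid containment
        max_ratio = float(np.max(semi / brain_semi))
        while True:
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.dot(u, u) <= 1.0:
                break
        cand = center + u * brain_semi * max(1.0 - max_ratio, 0.0)
        lesion = _ellipsoid_mask(shape, cand, semi)
        mask |= lesion.astype(np.uint8)

    image = image + config.lesion_intensity_delta * (mask > 0)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, dims)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SubjectVolume(subject_id=f"sub-{subject_seed:05d}",
                         image=image, mask=mask)


def generate_cohort(n_subjects: int, config: SyntheticConfig) -> list[SubjectVolume]:
    """Generate ``n_subjects`` volumes with seeds ``config.seed + index``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cohort = []
    for i in range(n_subjects):
        vol = generate_subject(config, config.seed + i)
        vol.subject_id = f"sub-{i:03d}"
        cohort.append(vol)
    return cohort


# ---------------------------------------------------------------------
# NIfTI cohort I/O (axis 0 = axial slice)
# ---------------------------------------------------------------------

def write_cohort(cohort: list[SubjectVolume], out_dir: str | Path,
                 config: SyntheticConfig | None = None) -> Path:
    """Write one image + one mask NIfTI per subject plus a JSON manifest.

    Returns the manifest path.  Layout mirrors a flat ATLAS-style
    directory: ``<sid>_t1.nii.gz`` and ``<sid>_mask.nii.gz``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    affine = np.eye(4)
    for vol in cohort:
        img_path = out_dir / f"{vol.subject_id}_t1.nii.gz"
        msk_path = out_dir / f"{vol.subject_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(vol.image.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), msk_path)
        entries.append({"subject_id": vol.subject_id,
                        "image": img_path.name, "mask": msk_path.name,
                        "n_slices": int(vol.image.shape[0])})
    manifest = {
        "subjects": entries,
        "total_slices": int(sum(e["n_slices"] for e in entries)),
    }
    if config is not None:
        manifest["config"] = config.to_dict()
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_subject(image_path: str | Path, mask_path: str | Path,
                 subject_id: str | None = None) -> SubjectVolume:
    image_path, mask_path = Path(image_path), Path(mask_path)
    image = np.asarray(nib.load(image_path).get_fdata(), dtype=np.float32)
    mask = np.asarray(nib.load(mask_path).get_fdata())
    mask = (mask > 0.5).astype(np.uint8)
    sid = subject_id or image_path.name.split("_")[0]
    return SubjectVolume(subject_id=sid, image=image, mask=mask)
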