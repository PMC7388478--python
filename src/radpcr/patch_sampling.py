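"""Seed sampling inside lesion masks and normalized in-plane patch windows.

Seeds are drawn uniformly with replacement over a mask's foreground voxels.
Each seed yields a square in-plane window (default 65x65, i.e. 4225 values)
on the seed's slice, min-max normalized to [0, 1] per patch.  Windows that
would cross the volume boundary are rejected and the seed resampled, so the
retained seeds remain uniform over the interior support.  Cohort assembly
enforces a 1:1 positive:negative patch ratio by scaling the per-image quota of
the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .errors import BalanceError, SamplingError
from .imaging_io import LesionMask, VolumeImage

__all__ = [
    "SeedPoint",
    "Patch",
    "SamplingPlan",
    "SubjectImaging",
    "sample_seed_points",
    "extract_patch",
    "normalize_patch",
    "sample_patches_from_image",
    "build_cohort_patches",
    "patches_to_matrix",
]

#: Resampling budget multiplier before giving up on boundary-crossing seeds.
MAX_RESAMPLE_FACTOR = 100


@dataclass(frozen=True)
class SeedPoint:
    """Patch center: a foreground voxel index with provenance."""

    index: tuple[int, int, int]  # (slice, row, column)
    subject_id: str = ""
    label: int = 0


@dataclass
class Patch:
    """Normalized P x P in-plane intensity window around a seed."""

    values: np.ndarray
    seed: SeedPoint
    source_image_id: str = ""

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class SamplingPlan:
    """Cohort-level sampling configuration."""

    n_per_image: int = 1000
    class_ratio: tuple[int, int] = (1, 1)  # positives : negatives
    patch_size: int = 65
    normalization_scope: str = "patch"  # "patch" | "volume"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_image < 1:
            raise ValueError("n_per_image must be >= 1")
        if min(self.class_ratio) < 1:
            raise ValueError("class_ratio components must be >= 1")
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be a positive odd integer")
        if self.normalization_scope not in ("patch", "volume"):
            raise ValueError("normalization_scope must be 'patch' or 'volume'")


@dataclass
class SubjectImaging:
    """One subject's label plus (image_id, volume, mask) triples."""

    subject_id: str
    label: int
    images: list[tuple[str, VolumeImage, LesionMask]] = field(default_factory=list)


class BoundaryRejection(Exception):
    """Signal (not an error) that a window crosses the volume boundary."""


def sample_seed_points(
    mask: LesionMask,
    n: int,
    rng_seed: int,
    subject_id: str = "",
    label: int = 0,
) -> list[SeedPoint]:
    """Draw ``n`` seeds uniformly (with replacement) from mask foreground."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mask.empty:
        raise SamplingError(f"mask for subject {subject_id!r} has no foreground voxels")
    support = mask.foreground_indices()
    rng = np.random.default_rng(rng_seed)
    picks = rng.integers(0, len(support), size=n)
    return [
        SeedPoint(index=tuple(int(v) for v in support[i]), subject_id=subject_id, label=label)
        for i in picks
    ]


def normalize_patch(raw: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant input maps to all zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("patch contains non-finite values")
    lo = raw.min()
    span = raw.max() - lo
    if span == 0:
        return np.zeros_like(raw)
    return (raw - lo) / span


def extract_patch(
    volume: VolumeImage,
    seed: SeedPoint,
    size: int = 65,
    source_image_id: str = "",
    normalize: bool = True,
) -> Patch:
    """Extract the in-plane window of side ``size`` centered at ``seed``.

    Raises
    ------
    ValueError
        If ``size`` is even or the seed lies outside the volume.
    BoundaryRejection
        If the window would cross the volume boundary (caller resamples).
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"patch size must be odd and positive, got {size}")
    sl, row, col = seed.index
    shape = volume.shape
    if not (0 <= sl < shape[0] and 0 <= row < shape[1] and 0 <= col < shape[2]):
        raise ValueError(f"seed {seed.index} outside volume of shape {shape}")
    half = size // 2
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    if r0 < 0 or c0 < 0 or r1 > shape[1] or c1 > shape[2]:
        raise BoundaryRejection(f"window at {seed.index} crosses volume boundary")
    window = np.array(volume.voxels[sl, r0:r1, c0:c1], dtype=np.float64)
    values = normalize_patch(window) if normalize else window
    return Patch(values=values, seed=seed, source_image_id=source_image_id)


def sample_patches_from_image(
    volume: VolumeImage,
    mask: LesionMask,
    n: int,
    rng_seed: int,
    patch_size: int = 65,
    subject_id: str = "",
    label: int = 0,
    image_id: str = "",
    normalization_scope: str = "patch",
) -> list[Patch]:
    """Sample ``n`` valid patches, resampling boundary-crossing seeds.

    At most ``MAX_RESAMPLE_FACTOR * n`` seeds are drawn before raising
    :class:`SamplingError`.
    """
    if mask.empty:
        raise SamplingError(f"mask for subject {subject_id!r} has no foreground voxels")
    source = volume
    if normalization_scope == "volume":
        lo = float(volume.voxels.min())
        span = float(volume.voxels.max()) - lo
        scaled = (
            np.zeros_like(volume.voxels, dtype=np.float64)
            if span == 0
            else (volume.voxels - lo) / span
        )
        source = VolumeImage(scaled, volume.spacing, volume.origin)

    support = mask.foreground_indices()
    rng = np.random.default_rng(rng_seed)
    patches: list[Patch] = []
    attempts = 0
    budget = MAX_RESAMPLE_FACTOR * n
    while len(patches) < n:
        if attempts >= budget:
            raise SamplingError(
                f"image {image_id!r}: exhausted {budget} seed draws collecting "
                f"{n} boundary-safe patches ({len(patches)} found)"
            )
        idx = support[rng.integers(0, len(support))]
        attempts += 1
        seed = SeedPoint(
            index=tuple(int(v) for v in idx), subject_id=subject_id, label=label
        )
        try:
            patches.append(
                extract_patch(
                    source,
                    seed,
                    size=patch_size,
                    source_image_id=image_id,
                    normalize=(normalization_scope == "patch"),
                )
            )
        except BoundaryRejection:
            continue
    return patches


def _per_image_quotas(total: int, n_images: int) -> list[int]:
    base, extra = divmod(total, n_images)
    return [base + (1 if i < extra else 0) for i in range(n_images)]


def build_cohort_patches(
    subjects: Sequence[SubjectImaging],
    plan: SamplingPlan,
) -> list[Patch]:
    """Sample patches across a cohort with balanced class totals.

    The minority class (by image count, weighted by the ratio) keeps the full
    ``n_per_image`` quota; the majority class's per-image quota is scaled down
    so total positive and negative patch counts differ by at most 1 (for the
    default 1:1 ratio).  Deterministic given ``plan.rng_seed``.
    """
    images: dict[int, list[tuple[SubjectImaging, str, VolumeImage, LesionMask]]] = {0: [], 1: []}
    for subj in subjects:
        if subj.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {subj.label!r}")
        for image_id, vol, mask in subj.images:
            images[subj.label].append((subj, image_id, vol, mask))
    n_pos_img, n_neg_img = len(images[1]), len(images[0])
    if n_pos_img == 0 or n_neg_img == 0:
        raise BalanceError(
            f"both classes required: {n_pos_img} positive / {n_neg_img} negative images"
        )

    r_pos, r_neg = plan.class_ratio
    # per-unit budget limited by the scarcer class
    per_unit = min(
        plan.n_per_image * n_pos_img / r_pos, plan.n_per_image * n_neg_img / r_neg
    )
    totals = {1: int(round(per_unit * r_pos)), 0: int(round(per_unit * r_neg))}

    patches: list[Patch] = []
    for label in (1, 0):
        quotas = _per_image_quotas(totals[label], len(images[label]))
        for quota, (subj, image_id, vol, mask) in zip(quotas, images[label]):
            if quota == 0:
                continue
            seed = _image_seed(plan.rng_seed, subj.subject_id, image_id)
            patches.extend(
                sample_patches_from_image(
                    vol,
                    mask,
                    quota,
                    seed,
                    patch_size=plan.patch_size,
                    subject_id=subj.subject_id,
                    label=label,
                    image_id=image_id,
                    normalization_scope=plan.normalization_scope,
                )
            )
    return patches


def _image_seed(master: int, subject_id: str, image_id: str) -> int:
    return derive_seed(master, "patches", subject_id, image_id)


def patches_to_matrix(patches: Iterable[Patch]) -> tuple[np.ndarray, pd.DataFrame]:
    """Flatten patches to (rows = patches, P*P columns) plus a sidecar table."""
    patches = list(patches)
    if not patches:
        raise ValueError("no patches supplied")
    X = np.stack([p.values.ravel() for p in patches])
    meta = pd.DataFrame(
        {
            "subject_id": [p.seed.subject_id for p in patches],
            "image_id": [p.source_image_id for p in patches],
            "slice": [p.seed.index[0] for p in patches],
            "row": [p.seed.index[1] for p in patches],
            "column": [p.seed.index[2] for p in patches],
            "label": [p.seed.label for p in patches],
        }
    )
    return X, meta
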