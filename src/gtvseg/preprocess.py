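"""Preprocessing: ROI cropping, per-case z-score normalization, augmentation.

The pipeline crops each volume to a fixed region of interest chosen to
contain the tumor in every case (pure index cropping, no resampling), then
normalizes each case's voxel values to zero mean and unit standard
deviation:

    pixel_out = (pixel_in - mean) / sigma

with mean and sigma computed over the whole 3D case (population sigma,
divide by N).  Training data are expanded by a fixed grid of in-plane
transforms: shifts of {-2, 0, +2} pixels on each in-plane axis, rotations
of {-5, 0, +5} degrees about the image center, and an optional left–right
flip — 3 x 3 x 3 x 2 = 54 transforms, applied identically to every slice of
the image and its mask so 2D and 3D training see geometrically consistent
data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import Case, Mask, Volume

__all__ = [
    "RoiBox",
    "NormalizationStats",
    "AugmentationGrid",
    "AugmentationTransform",
    "crop_and_resize",
    "normalize_case",
    "enumerate_augmentations",
    "apply_augmentation",
    "extract_slices",
    "restack_slices",
]


@dataclass(frozen=True)
class RoiBox:
    """Half-open, 0-based index intervals per axis: (slice, row, col)."""

    slices: tuple[int, int]
    rows: tuple[int, int]
    cols: tuple[int, int]

    @property
    def extents(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in (self.slices, self.rows, self.cols))

    @classmethod
    def centered(cls, grid_shape: Sequence[int], target: Sequence[int]) -> "RoiBox":
        """The ROI of extents ``target`` centered in ``grid_shape``."""
        ivals = []
        for ext, tgt in zip(grid_shape, target):
            if tgt > ext:
                raise ValueError(f"target extent {tgt} exceeds grid extent {ext}")
            lo = (ext - tgt) // 2
            ivals.append((lo, lo + tgt))
        return cls(*ivals)

    def as_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in (self.slices, self.rows, self.cols))


@dataclass(frozen=True)
class NormalizationStats:
    mean: float
    sigma: float


def crop_and_resize(case: Case, roi: RoiBox, target: Sequence[int] = (64, 64, 64)) -> Case:
    """Crop volume and mask with the identical ROI; no interpolation.

    The resulting extents must equal ``target`` (default 64^3); spacing is
    preserved because cropping removes voxels without resampling.
    """
    shape = case.volume.shape
    for (lo, hi), ext in zip((roi.slices, roi.rows, roi.cols), shape):
        if not (0 <= lo < hi <= ext):
            raise ValueError(f"roi {roi} out of bounds for grid {shape}")
    if roi.extents != tuple(target):
        raise ValueError(f"roi extents {roi.extents} != target grid {tuple(target)}")
    sl = roi.as_slices()
    volume = Volume(case.volume.voxels[sl], case.volume.spacing, case.volume.dtype_tag)
    mask = None
    if case.mask is not None:
        mask = Mask(case.mask.voxels[sl], case.mask.spacing)
    return replace(case, volume=volume, mask=mask)


def normalize_case(volume: Volume) -> tuple[Volume, NormalizationStats]:
    """Z-score the whole 3D case; raises on constant input (sigma = 0)."""
    v = volume.voxels.astype(np.float64)
    mean = float(v.mean())
    sigma = float(v.std())  # population convention (divide by N)
    if sigma == 0.0:
        raise ValueError("constant volume: standard deviation is zero, cannot normalize")
    out = ((v - mean) / sigma).astype(np.float32)
    return (
        Volume(voxels=out, spacing=volume.spacing, dtype_tag="float32"),
        NormalizationStats(mean=mean, sigma=sigma),
    )


# ------------------------------------------------------------ augmentation


@dataclass(frozen=True)
class AugmentationTransform:
    """One in-plane transform: rotate about center, shift, then flip."""

    shift_rows: int = 0
    shift_cols: int = 0
    rotation_deg: float = 0.0
    flip_lr: bool = False

    @property
    def is_identity(self) -> bool:
        return (
            self.shift_rows == 0
            and self.shift_cols == 0
            and self.rotation_deg == 0.0
            and not self.flip_lr
        )


@dataclass(frozen=True)
class AugmentationGrid:
    """Cartesian grid of in-plane transforms; the default has 54 members."""

    shifts: tuple[int, ...] = (0, -2, 2)
    rotations_deg: tuple[float, ...] = (0.0, -5.0, 5.0)
    flips: tuple[bool, ...] = (False, True)

    def size(self) -> int:
        return len(self.shifts) ** 2 * len(self.rotations_deg) * len(self.flips)


IDENTITY_GRID = AugmentationGrid(shifts=(0,), rotations_deg=(0.0,), flips=(False,))


def enumerate_augmentations(grid: AugmentationGrid = AugmentationGrid()) -> list[AugmentationTransform]:
    """All transforms of the grid, in deterministic order, identity first
    when the grid contains it (each factor lists its neutral element first)."""
    out = [
        AugmentationTransform(shift_rows=sr, shift_cols=sc, rotation_deg=rot, flip_lr=fl)
        for sr, sc, rot, fl in itertools.product(
            grid.shifts, grid.shifts, grid.rotations_deg, grid.flips
        )
    ]
    return out


def _shift2d_planes(vol: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    """Integer in-plane shift of every slice, padding with ``fill``."""
    out = np.full_like(vol, fill)
    r0, r1 = max(dr, 0), vol.shape[1] + min(dr, 0)
    c0, c1 = max(dc, 0), vol.shape[2] + min(dc, 0)
    out[:, r0:r1, c0:c1] = vol[:, r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def apply_augmentation(case: Case, transform: AugmentationTransform) -> Case:
    """Apply one in-plane transform to every slice of both image and mask.

    Rotation uses linear interpolation for the image and nearest neighbor
    for the mask (re-binarized afterwards); translation fills with 0 for
    the mask and with the image minimum for the image, so no artificial
    bright border is created.  The identity transform is exact.
    """
    if not isinstance(transform, AugmentationTransform):
        raise TypeError(f"unknown transform descriptor: {transform!r}")
    img = case.volume.voxels.astype(np.float32)
    msk = case.mask.voxels if case.mask is not None else None
    fill = float(img.min())

    if transform.rotation_deg != 0.0:
        img = ndimage.rotate(
            img, transform.rotation_deg, axes=(1, 2), reshape=False,
            order=1, mode="constant", cval=fill,
        )
        if msk is not None:
            msk = ndimage.rotate(
                msk, transform.rotation_deg, axes=(1, 2), reshape=False,
                order=0, mode="constant", cval=0,
            )
    if transform.shift_rows or transform.shift_cols:
        img = _shift2d_planes(img, transform.shift_rows, transform.shift_cols, fill)
        if msk is not None:
            msk = _shift2d_planes(msk, transform.shift_rows, transform.shift_cols, 0)
    if transform.flip_lr:
        img = img[:, :, ::-1].copy()
        if msk is not None:
            msk = msk[:, :, ::-1].copy()

    volume = Volume(img, case.volume.spacing, "float32")
    mask = Mask((np.asarray(msk) >= 0.5).astype(np.uint8), case.mask.spacing) if msk is not None else None
    return replace(case, volume=volume, mask=mask)


# -------------------------------------------------------------- 2D slices


def extract_slices(case: Case) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Split a case into its ordered (image, mask) slice pairs."""
    img = case.volume.voxels
    msk = case.mask.voxels if case.mask is not None else None
    return [
        (img[k], msk[k] if msk is not None else None) for k in range(img.shape[0])
    ]


def restack_slices(
    pairs: Iterable[tuple[np.ndarray, np.ndarray | None]],
    spacing: tuple[float, float, float],
) -> tuple[Volume, Mask | None]:
    """Inverse of :func:`extract_slices`: restack pairs into a volume (+mask)."""
    imgs, msks = zip(*pairs)
    vol = Volume(np.stack(imgs), spacing, "float32")
    if any(m is None for m in msks):
        return vol, None
    return vol, Mask(np.stack(msks), spacing)
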