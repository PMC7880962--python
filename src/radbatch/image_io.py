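"""Volumes, masks, gray-level discretization, and isotropic resampling.

A :class:`VoxelGrid` stores a 3D scalar image in Hounsfield units together
with its voxel spacing (mm) and physical origin.  Arrays are indexed
``values[ix, iy, iz]`` and the voxel-center convention is

    physical(i) = origin + i * spacing      (per axis)

so index 0 sits exactly at the origin.  File I/O goes through SimpleITK and
supports NRRD (primary) and NIfTI, chosen by file extension.

Preprocessing follows the standard radiomics recipe: resample image and mask
to isotropic voxels (cubic B-spline for the image, nearest neighbor for the
mask), then discretize ROI intensities to fixed-width bins (default 50 HU)
anchored at the bin edge below the ROI minimum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ExtractionError, FormatError

__all__ = [
    "VoxelGrid",
    "ROIMask",
    "DiscretizedROI",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_grid",
    "resample_isotropic",
    "discretize",
]

_EXTENSIONS = (".nrrd", ".nhdr", ".nii", ".nii.gz")


@dataclass
class VoxelGrid:
    """3D scalar image with anisotropic spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU.
    spacing : tuple of float
        Voxel spacing ``(dx, dy, dz)`` in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if min(self.values.shape) < 1:
            raise ValueError("every axis must have at least one voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ROIMask:
    """Binary region-of-interest mask sharing a VoxelGrid's frame."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("ROIMask requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class DiscretizedROI:
    """Gray-level discretization of a ROI.

    ``levels`` holds integer gray levels 1..Ng inside the ROI and 0 outside;
    ``Ng`` is the highest occupied level.
    """

    levels: np.ndarray
    bin_width: float
    Ng: int

    @property
    def roi_levels(self) -> np.ndarray:
        """1D array of the in-ROI levels."""
        return self.levels[self.levels > 0]


def _check_extension(path: str) -> None:
    if not str(path).lower().endswith(_EXTENSIONS):
        raise FormatError(
            f"unsupported volume format for {path!r}; expected one of {_EXTENSIONS}"
        )


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))  # (z, y, x)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    values = sitk.GetArrayFromImage(img).T  # back to (x, y, z)
    return values, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path: str) -> VoxelGrid:
    """Read an NRRD or NIfTI volume into a :class:`VoxelGrid`."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    _check_extension(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps parse failures in RuntimeError
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    values, spacing, origin = _from_sitk(img)
    return VoxelGrid(values.astype(np.float64), spacing, origin)


def write_volume(grid: VoxelGrid, path: str) -> None:
    """Write a volume as NRRD or NIfTI (by extension)."""
    _check_extension(path)
    sitk.WriteImage(_to_sitk(grid.values, grid.spacing, grid.origin), str(path))


def read_mask(path: str) -> ROIMask:
    """Read a binary mask (any nonzero voxel is foreground)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask not found: {path}")
    _check_extension(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read mask {path!r}: {exc}") from exc
    values, spacing, origin = _from_sitk(img)
    return ROIMask(values > 0, spacing, origin)


def write_mask(mask: ROIMask, path: str) -> None:
    """Write a mask as unsigned 8-bit NRRD/NIfTI."""
    _check_extension(path)
    sitk.WriteImage(
        _to_sitk(mask.values.astype(np.uint8), mask.spacing, mask.origin), str(path)
    )


def _output_size(shape, spacing, target) -> tuple[int, ...]:
    # cover the full input physical extent: ceil(n * s / t) voxels per axis
    return tuple(
        max(1, int(np.ceil(n * s / t - 1e-9)))
        for n, s, t in zip(shape, spacing, target)
    )


def resample_grid(
    grid: VoxelGrid,
    new_spacing: tuple[float, float, float],
    order: int = 3,
) -> VoxelGrid:
    """Resample onto a grid with ``new_spacing``, anchored at the same origin.

    ``order`` is the spline order (0 nearest, 1 linear, 3 cubic B-spline with
    prefiltering, which interpolates the samples exactly).  Output size is
    ``ceil(extent / new_spacing)`` per axis; coordinates outside the input are
    clamped to the border value.
    """
    if any(t <= 0 for t in new_spacing):
        raise ValueError(f"target spacing must be positive, got {new_spacing}")
    out_shape = _output_size(grid.shape, grid.spacing, new_spacing)
    coords = np.meshgrid(
        *[
            np.arange(n) * t / s
            for n, t, s in zip(out_shape, new_spacing, grid.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        grid.values, coords, order=order, mode="nearest", prefilter=order > 1
    )
    return VoxelGrid(out, tuple(new_spacing), grid.origin)


def resample_isotropic(
    grid: VoxelGrid, mask: ROIMask, target: float = 1.0
) -> tuple[VoxelGrid, ROIMask]:
    """Resample image and mask to isotropic ``target`` mm voxels.

    Image: cubic B-spline.  Mask: nearest neighbor, re-thresholded at 0.5 so
    the output is strictly binary.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    if grid.shape != mask.shape or grid.spacing != mask.spacing:
        raise ValueError("grid and mask must share shape and spacing")
    iso = (float(target),) * 3
    out_grid = resample_grid(grid, iso, order=3)
    mask_grid = VoxelGrid(mask.values.astype(np.float64), mask.spacing, mask.origin)
    out_mask_vals = resample_grid(mask_grid, iso, order=0).values > 0.5
    return out_grid, ROIMask(out_mask_vals, iso, mask.origin)


def discretize(grid: VoxelGrid, mask: ROIMask, bin_width: float = 50.0) -> DiscretizedROI:
    """Discretize ROI intensities to fixed-width bins.

    The level of a voxel with value v is

        level(v) = floor(v / w) - floor(min_ROI / w) + 1

    i.e. bins of width ``w`` anchored on the absolute HU grid, shifted so the
    bin containing the ROI minimum becomes level 1.  Adding an exact multiple
    of ``w`` to every voxel therefore leaves the levels unchanged.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if grid.shape != mask.shape:
        raise ValueError("grid and mask must share shape")
    roi = mask.values
    if not roi.any():
        raise ExtractionError("empty ROI: nothing to discretize")
    vals = grid.values
    lo = np.floor(vals[roi].min() / bin_width)
    levels = np.zeros(grid.shape, dtype=np.int64)
    levels[roi] = np.floor(vals[roi] / bin_width).astype(np.int64) - int(lo) + 1
    return DiscretizedROI(levels=levels, bin_width=float(bin_width), Ng=int(levels.max()))
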