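"""Volume data model and grid arithmetic.

Everything downstream (lesion delineation, tract overlap, the voxel-wise GLM)
operates on scalar or boolean fields living on one shared regular grid that
stands in for MNI space.  The grid is axis-aligned RAS: world x grows to the
right, y to anterior, z to superior, and the world coordinate of voxel index
``(i, j, k)`` is ``origin_mm + index * spacing_mm``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "MaskVolume",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "assert_same_grid",
    "volume_cc",
    "gaussian_smooth",
    "hemisphere_mask",
    "FWHM_TO_SIGMA",
]

#: Conversion factor between a Gaussian kernel's full width at half maximum
#: and its standard deviation: sigma = FWHM / (2 * sqrt(2 * ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Header round-trip noise tolerated when comparing grids.
_SPACING_ATOL_MM = 1e-6
_ORIGIN_ATOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when volumes expected to share a grid do not."""


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """Regular 3-D sampling grid with mm spacing and an RAS world origin."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("VolumeGrid is strictly 3-D")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) for every voxel."""
        x = self.axis_coordinates(0)[:, None, None]
        y = self.axis_coordinates(1)[None, :, None]
        z = self.axis_coordinates(2)[None, None, :]
        return x, y, z

    def approx_equal(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=_SPACING_ATOL_MM)
            and np.allclose(self.origin_mm, other.origin_mm, atol=_ORIGIN_ATOL_MM)
        )


@dataclasses.dataclass
class ScalarVolume:
    """A finite real-valued field on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} incongruent with grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("ScalarVolume values must all be finite")
        self.values = values

    def copy_with(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.grid, np.array(values))


@dataclasses.dataclass
class MaskVolume:
    """A boolean field on a :class:`VolumeGrid` (lesions, thresholded tracts)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {values.shape} incongruent with grid shape {self.grid.shape}"
            )
        self.values = values.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))


Volume = Union[ScalarVolume, MaskVolume]


def _grid_from_nifti(img: nib.Nifti1Image, path: Path) -> VolumeGrid:
    aff = img.affine
    rot = aff[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    # Inputs are assumed already axis-aligned RAS; anything else needs
    # reorientation upstream, which is out of scope here.
    if not np.allclose(rot, np.diag(spacing), atol=1e-4):
        raise ValueError(
            f"{path}: affine is not axis-aligned RAS; reorient the image before loading"
        )
    return VolumeGrid(
        shape=tuple(img.shape[:3]),
        spacing_mm=tuple(float(s) for s in spacing),
        origin_mm=tuple(float(o) for o in aff[:3, 3]),
    )


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a single 3-D NIfTI-1 volume as a :class:`ScalarVolume`.

    Raises a descriptive error for missing files, multi-volume (4-D) files and
    non-finite voxel data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file does not exist: {path}")
    img = nib.load(path)
    if img.ndim > 3 and any(d > 1 for d in img.shape[3:]):
        raise ValueError(f"{path}: expected a single 3-D volume, got shape {img.shape}")
    data = np.asarray(img.dataobj, dtype=np.float64).reshape(img.shape[:3])
    if not np.all(np.isfinite(data)):
        n_bad = int(np.count_nonzero(~np.isfinite(data)))
        raise ValueError(f"{path}: contains {n_bad} non-finite voxel(s)")
    return ScalarVolume(_grid_from_nifti(img, path), data)


def read_mask(path: str | Path) -> MaskVolume:
    """Read a NIfTI volume and binarize it (non-zero -> True)."""
    vol = read_volume(path)
    return MaskVolume(vol.grid, vol.values != 0)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; masks are stored as uint8 0/1, scalars as float32."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if isinstance(vol, MaskVolume):
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing_mm)
    nib.save(img, path)


def assert_same_grid(vols: Iterable[Volume | VolumeGrid]) -> VolumeGrid:
    """Check that all volumes share one grid; return it.

    Shapes must match exactly; spacing to 1e-6 mm and origin to 1e-3 mm
    (float-header round-trip noise). The first mismatching volume is named.
    """
    grids = [v if isinstance(v, VolumeGrid) else v.grid for v in vols]
    if not grids:
        raise ValueError("assert_same_grid: empty collection")
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise GridMismatchError(f"volume {i}: shape {g.shape} != {ref.shape}")
        if not np.allclose(g.spacing_mm, ref.spacing_mm, atol=_SPACING_ATOL_MM):
            raise GridMismatchError(
                f"volume {i}: spacing {g.spacing_mm} != {ref.spacing_mm}"
            )
        if not np.allclose(g.origin_mm, ref.origin_mm, atol=_ORIGIN_ATOL_MM):
            raise GridMismatchError(f"volume {i}: origin {g.origin_mm} != {ref.origin_mm}")
    return ref


def volume_cc(mask: MaskVolume) -> float:
    """Mask volume in cubic centimetres: true-voxel count x voxel volume / 1000."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def gaussian_smooth(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Per-axis Gaussian smoothing with the kernel width given as FWHM in mm.

    Boundaries are handled by reflection, which keeps the operation
    deterministic and near-mass-conserving away from edges.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be > 0, got {fwhm_mm}")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.grid.spacing_mm]
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="reflect")
    return ScalarVolume(vol.grid, smoothed)


def hemisphere_mask(grid: VolumeGrid, side: str) -> MaskVolume:
    """Mask of one hemisphere by world x sign (RAS: x > 0 is right).

    Voxels whose centre lies within half a voxel of the x = 0 midline belong
    to neither hemisphere, so left and right masks are disjoint on any grid.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    x = grid.axis_coordinates(0)
    half = grid.spacing_mm[0] / 2.0
    if side == "left":
        in_side = x <= -half
    else:
        in_side = x >= half
    values = np.zeros(grid.shape, dtype=bool)
    values[in_side, :, :] = True
    return MaskVolume(grid, values)
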