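"""Geometry-aware PET volume and mask handling.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` with 0-based voxel indices.
* A voxel's world coordinate (mm) is ``origin + index * spacing``.
* Masks always live on the PET grid; a :class:`BinaryMask` carries a
  reference to the grid it was defined on so that mismatches are caught
  early instead of silently mis-aligning lesions.
* Voxel values are body-weight standardized uptake values (SUV_bw),
  dimensionless and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "PetVolume",
    "BinaryMask",
    "AcquisitionMeta",
    "GeometryError",
    "FormatError",
    "InvalidMetadataError",
    "suv_from_activity",
    "voxel_volume_ml",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_mask_nn",
]


class GeometryError(ValueError):
    """Grids or physical extents are inconsistent."""


class FormatError(ValueError):
    """A file could not be interpreted as the expected image type."""


class InvalidMetadataError(ValueError):
    """Acquisition metadata violates its physical constraints."""


@dataclass(frozen=True)
class PetVolume:
    """A 3D scalar grid in SUV_bw with voxel spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise FormatError(f"PET volume must be 3D, got {values.ndim}D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("SUV values must be finite and non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinate (mm) of 0-based voxel indices; vectorised over rows."""
        index = np.asarray(index, dtype=np.float64)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (float) voxel index for world coordinates in mm."""
        world = np.asarray(world, dtype=np.float64)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "PetVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent covered by voxel centers: (lower, upper) corners in mm."""
        lower = np.asarray(self.origin, dtype=np.float64)
        upper = lower + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lower, upper


@dataclass(frozen=True)
class BinaryMask:
    """Boolean voxel mask tied to the geometry of a reference PET grid."""

    values: np.ndarray
    grid: PetVolume

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != bool:
            values = values.astype(bool)
        if values.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {values.shape} does not match grid {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class AcquisitionMeta:
    """Dose/weight metadata entering the SUV_bw normalisation.

    ``uptake_time`` (minutes post-injection) is carried for reporting only.
    """

    body_weight_kg: float
    injected_activity_bq: float
    uptake_time_min: float = 60.0

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0 or self.injected_activity_bq <= 0:
            raise InvalidMetadataError(
                "body weight and injected activity must be strictly positive"
            )


def suv_from_activity(concentration_bq_ml: float, meta: AcquisitionMeta) -> float:
    """Convert an activity concentration (Bq/mL) to SUV_bw.

    SUV_bw = concentration x body weight (g) / injected activity (Bq),
    taking tissue density as 1 g/mL so that the result is dimensionless.
    """
    if concentration_bq_ml < 0:
        raise ValueError("activity concentration must be non-negative")
    return concentration_bq_ml * (meta.body_weight_kg * 1000.0) / meta.injected_activity_bq


def voxel_volume_ml(volume: PetVolume) -> float:
    """Volume of one voxel in mL (dx*dy*dz mm^3 / 1000)."""
    dx, dy, dz = volume.spacing
    return dx * dy * dz / 1000.0


def _affine(volume: PetVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = volume.spacing
    aff[:3, 3] = volume.origin
    return aff


def write_volume(volume: PetVolume, path) -> None:
    """Write a PET volume as NIfTI-1 with a diagonal affine."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume))
    nib.save(img, str(path))


def read_volume(path) -> PetVolume:
    """Read a 3D NIfTI image as a :class:`PetVolume`.

    Spacing is taken from the header zooms, the origin from the affine
    translation. Orientation rotations are not interpreted: volumes are
    expected to be written on axis-aligned grids (as this package writes
    them).
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FormatError(f"no such image file: {path}") from None
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing in header")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return PetVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def write_labelmap_nifti(values: np.ndarray, grid: PetVolume, path) -> None:
    """Write an integer label image (uint16) on a PET grid."""
    img = nib.Nifti1Image(np.asarray(values).astype(np.uint16), _affine(grid))
    nib.save(img, str(path))


def read_mask(path, grid: PetVolume) -> BinaryMask:
    """Read a binary mask and bind it to ``grid`` (shapes must agree)."""
    vol = read_volume(path)
    if vol.shape != grid.shape:
        raise GeometryError(
            f"{path}: mask shape {vol.shape} does not match reference grid {grid.shape}"
        )
    return BinaryMask(vol.values > 0.5, grid)


def read_labelmap_nifti(path, grid: PetVolume) -> np.ndarray:
    vol = read_volume(path)
    if vol.shape != grid.shape:
        raise GeometryError(
            f"{path}: label map shape {vol.shape} does not match grid {grid.shape}"
        )
    return np.rint(vol.values).astype(np.int32)


def resample_mask_nn(mask: BinaryMask, target: PetVolume) -> BinaryMask:
    """Resample a mask onto ``target`` by nearest neighbour in world coordinates.

    Grids are axis-aligned, so the lookup is separable per axis. Target
    voxels whose nearest source voxel falls outside the source grid are
    False. Identical grids return a bitwise-identical mask.
    """
    src = mask.grid
    if src.same_grid(target):
        return BinaryMask(mask.values.copy(), target)

    src_lo, src_hi = src.extent_mm()
    tgt_lo, tgt_hi = target.extent_mm()
    if np.any(tgt_hi < src_lo) or np.any(tgt_lo > src_hi):
        raise GeometryError("source and target grids have disjoint physical extents")

    index_maps = []
    for axis in range(3):
        world = target.origin[axis] + np.arange(target.shape[axis]) * target.spacing[axis]
        idx = np.rint((world - src.origin[axis]) / src.spacing[axis]).astype(np.int64)
        valid = (idx >= 0) & (idx < src.shape[axis])
        index_maps.append((np.clip(idx, 0, src.shape[axis] - 1), valid))

    (ix, vx), (iy, vy), (iz, vz) = index_maps
    out = mask.values[np.ix_(ix, iy, iz)]
    out &= vx[:, None, None] & vy[None, :, None] & vz[None, None, :]
    return BinaryMask(out, target)
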