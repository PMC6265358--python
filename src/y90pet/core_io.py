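"""Voxel-grid data model, mask algebra and image/mask file I/O.

The package works on a single regular 3-D grid per case: voxel index
``(i, j, k)`` maps to the physical *center* ``origin + (i*dx, j*dy, k*dz)``
in millimetres.  All distances (surface distances, ray lengths) are computed
between voxel centers in mm under this convention.

Images are stored on disk as NIfTI-1 (``.nii``/``.nii.gz``); NRRD files are
accepted on read.  Masks are written as ``uint8`` {0, 1} volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np


class FormatError(ValueError):
    """Raised when an on-disk image does not match the expected layout."""


class GeometryError(ValueError):
    """Raised when two objects do not share a voxel grid, or geometry is invalid."""


class EmptyInputError(ValueError):
    """Raised when an operation requires a non-empty mask or sample."""


@dataclass(frozen=True)
class VoxelImage:
    """A 3-D scalar field on a regular anisotropic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar payload (activity concentration in Bq/mL, dose in Gy, ...).
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm; strictly positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    unit : str
        Unit label carried through the pipeline (``"Bq/mL"``, ``"Gy"``, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise FormatError(f"values must be 3-D, got ndim={values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be three positive floats, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (= mL)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VoxelImage":
        """Return a copy on the same grid with new voxel values."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       unit=self.unit if unit is None else unit)

    def same_grid(self, other: "VoxelImage | Mask", tol: float = 1e-6) -> bool:
        g = other.grid if isinstance(other, Mask) else other
        return (self.shape == g.shape
                and np.allclose(self.spacing, g.spacing, atol=tol)
                and np.allclose(self.origin, g.origin, atol=tol))

    def voxel_centers_mm(self, index_array: np.ndarray) -> np.ndarray:
        """Physical centers (mm) for an ``(n, 3)`` array of voxel indices."""
        idx = np.atleast_2d(np.asarray(index_array, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class Mask:
    """A binary volume of interest on a reference grid."""

    values: np.ndarray
    grid: VoxelImage

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(bool)
        if values.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {values.shape} does not match grid shape {self.grid.shape}")
        object.__setattr__(self, "values", values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def indices(self) -> np.ndarray:
        """(n, 3) integer indices of the true voxels."""
        return np.argwhere(self.values)

    def centroid_mm(self) -> np.ndarray:
        """Center of mass of the true voxels, in mm."""
        if self.n_voxels == 0:
            raise EmptyInputError("centroid of an empty mask is undefined")
        return self.grid.voxel_centers_mm(self.indices()).mean(axis=0)


def volume_cm3(mask: Mask) -> float:
    """Mask volume in cm³: voxel count times the voxel volume."""
    return mask.n_voxels * mask.grid.voxel_volume_cm3


def boundary_voxels(mask: Mask) -> Mask:
    """Surface voxels of a mask: true voxels with a 6-connected outside neighbor.

    The grid border counts as outside, so a mask filling the whole grid has
    its faces as boundary.
    """
    if mask.n_voxels == 0:
        raise EmptyInputError("boundary of an empty mask is undefined")
    m = mask.values
    interior = np.ones_like(m)
    for axis in range(3):
        lo = np.roll(m, 1, axis=axis)
        hi = np.roll(m, -1, axis=axis)
        # rolled-in border values are "outside"
        sl_lo = [slice(None)] * 3
        sl_lo[axis] = 0
        lo[tuple(sl_lo)] = False
        sl_hi = [slice(None)] * 3
        sl_hi[axis] = -1
        hi[tuple(sl_hi)] = False
        interior &= lo & hi
    return Mask(values=m & ~interior, grid=mask.grid)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_image(img: VoxelImage, path: str | Path) -> None:
    """Write a VoxelImage (or rasterized mask values) as NIfTI-1."""
    path = Path(path)
    affine = _affine_from_geometry(img.spacing, img.origin)
    nifti = nib.Nifti1Image(np.asarray(img.values, dtype=np.float64), affine)
    nifti.header.set_zooms(img.spacing)
    if img.unit:
        nifti.header["descrip"] = img.unit.encode()[:79]
    nib.save(nifti, str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    """Write a mask as a uint8 {0, 1} NIfTI volume."""
    path = Path(path)
    affine = _affine_from_geometry(mask.grid.spacing, mask.grid.origin)
    nifti = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    nifti.header.set_zooms(mask.grid.spacing)
    nib.save(nifti, str(path))


def _read_nrrd(path: Path) -> VoxelImage:
    import SimpleITK as sitk

    itk_img = sitk.ReadImage(str(path))
    if itk_img.GetDimension() != 3:
        raise FormatError(f"expected 3-D payload, got {itk_img.GetDimension()}-D in {path}")
    # SimpleITK returns (z, y, x); transpose to (x, y, z)
    values = sitk.GetArrayFromImage(itk_img).transpose(2, 1, 0)
    return VoxelImage(values=values,
                      spacing=tuple(itk_img.GetSpacing()),
                      origin=tuple(itk_img.GetOrigin()))


def read_image(path: str | Path) -> VoxelImage:
    """Read a NIfTI (.nii/.nii.gz) or NRRD image as a VoxelImage.

    Raises
    ------
    FormatError
        If the payload is not a 3-D scalar volume or spacing is missing.
    """
    path = Path(path)
    if path.suffix == ".nrrd":
        return _read_nrrd(path)
    nifti = nib.load(str(path))
    values = np.asanyarray(nifti.dataobj)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    if values.ndim != 3:
        raise FormatError(f"expected 3-D payload, got ndim={values.ndim} in {path}")
    zooms = nifti.header.get_zooms()[:3]
    if any(z <= 0 or not np.isfinite(z) for z in zooms):
        raise FormatError(f"missing or invalid spacing {zooms} in {path}")
    origin = tuple(np.asarray(nifti.affine[:3, 3], dtype=float))
    unit = ""
    descrip = nifti.header["descrip"].tobytes().rstrip(b"\x00")
    if descrip:
        unit = descrip.decode(errors="ignore")
    return VoxelImage(values=values, spacing=tuple(float(z) for z in zooms),
                      origin=origin, unit=unit)


def read_mask(path: str | Path, grid: VoxelImage | None = None) -> Mask:
    """Read a binary mask; optionally attach it to an existing grid."""
    img = read_image(path)
    if grid is not None:
        if not img.same_grid(grid):
            raise GeometryError(f"mask geometry in {path} does not match the reference grid")
        return Mask(values=img.values > 0.5, grid=grid)
    return Mask(values=img.values > 0.5, grid=img.with_values(np.zeros(img.shape)))
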