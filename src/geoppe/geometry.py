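"""Image geometry: the voxel-index <-> physical-coordinate mapping.

Tomographic images carry, in their headers, the metadata needed to place
every voxel in the scanner's physical coordinate frame: the *origin* (the
physical position, in mm, of the center of voxel ``(0, 0, 0)``), the
per-axis voxel *spacing* (mm), and a 3x3 orthonormal *direction* matrix of
axis direction cosines.  The physical center of voxel ``(i, j, k)`` is

    p = origin + direction @ (spacing * (i, j, k))

This module implements that mapping, keeps it consistent under cropping and
grid resampling, and converts to/from NIfTI affines.  All coordinates are
millimetres.  The frame convention (RAS vs LPS) is whatever the header
provides; downstream radial embeddings depend only on distance from the
frame origin and are therefore orientation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GeometryError",
    "ContractError",
    "ImageGeometry",
    "Volume",
    "voxel_to_physical",
    "physical_to_voxel",
    "physical_grid",
    "crop_geometry",
    "resample_geometry",
    "geometry_from_affine",
    "affine_from_geometry",
    "load_volume",
    "save_volume",
]

#: maximum tolerated deviation of direction^T direction from the identity
_ORTHO_TOL = 1e-6
#: maximum tolerated shear when decomposing an external affine
_SHEAR_TOL = 1e-3


class GeometryError(ValueError):
    """Invalid geometry metadata or out-of-range voxel access."""


class ContractError(ValueError):
    """Mismatched shapes/geometries between objects that must agree."""


def _as_float3(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise GeometryError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    return arr


@dataclass(frozen=True)
class ImageGeometry:
    """Placement of a 3D voxel grid in the physical (mm) frame.

    Parameters
    ----------
    origin : (3,) float
        Physical coordinate of the *center* of voxel (0, 0, 0), mm
        (the DICOM ImagePositionPatient convention).
    spacing : (3,) float
        Voxel edge lengths per axis, mm; strictly positive.
    direction : (3, 3) float
        Orthonormal matrix whose columns are the physical directions of the
        three voxel axes.  Identity by default.
    size : (3,) int
        Voxel counts (H, W, D); each >= 1.
    """

    origin: np.ndarray
    spacing: np.ndarray
    size: tuple[int, int, int]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        origin = _as_float3(self.origin, "origin")
        spacing = _as_float3(self.spacing, "spacing")
        direction = np.asarray(self.direction, dtype=float)
        size = tuple(int(s) for s in np.asarray(self.size).reshape(-1))
        if len(size) != 3:
            raise GeometryError(f"size must be a 3-vector, got {self.size!r}")
        if np.any(spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {spacing}")
        if any(s < 1 for s in size):
            raise GeometryError(f"size components must be >= 1, got {size}")
        if direction.shape != (3, 3):
            raise GeometryError(f"direction must be 3x3, got {direction.shape}")
        if np.linalg.norm(direction.T @ direction - np.eye(3)) >= _ORTHO_TOL:
            raise GeometryError(
                "direction matrix is not orthonormal "
                f"(||D^T D - I|| = {np.linalg.norm(direction.T @ direction - np.eye(3)):.3g})"
            )
        for arr in (origin, spacing, direction):
            arr.setflags(write=False)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "size", size)

    @property
    def fov(self) -> np.ndarray:
        """Physical extent (mm) covered per axis: size * spacing."""
        return self.spacing * np.asarray(self.size, dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGeometry):
            return NotImplemented
        return (
            self.size == other.size
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.direction, other.direction)
        )

    def isclose(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class Volume:
    """A channels-first intensity array bound to its geometry.

    ``data`` has shape (C, H, W, D); the spatial shape must equal
    ``geometry.size``.  Single-channel data may be passed as (H, W, D) and
    is promoted to (1, H, W, D).
    """

    data: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim == 3:
            data = data[np.newaxis]
        if data.ndim != 4:
            raise ContractError(f"Volume data must be (C,H,W,D), got shape {data.shape}")
        if data.shape[1:] != tuple(self.geometry.size):
            raise ContractError(
                f"Volume spatial shape {data.shape[1:]} does not match "
                f"geometry size {tuple(self.geometry.size)}"
            )
        self.data = data

    @property
    def channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


# ---------------------------------------------------------------------------
# index <-> physical mappings
# ---------------------------------------------------------------------------

def voxel_to_physical(geom: ImageGeometry, index) -> np.ndarray:
    """Physical coordinate (mm) of the center of the voxel at ``index``.

    Voxel (0, 0, 0) maps exactly to ``geom.origin``.
    """
    idx = np.asarray(index, dtype=float).reshape(3)
    for axis in range(3):
        if not (0 <= idx[axis] < geom.size[axis]):
            raise GeometryError(
                f"index {idx[axis]:g} out of bounds on axis {axis} "
                f"(size {geom.size[axis]})"
            )
    return geom.origin + geom.direction @ (geom.spacing * idx)


def physical_to_voxel(geom: ImageGeometry, point) -> np.ndarray:
    """Continuous voxel index of a physical point (inverse of the affine)."""
    p = _as_float3(point, "point")
    return (geom.direction.T @ (p - geom.origin)) / geom.spacing


def physical_grid(geom: ImageGeometry) -> np.ndarray:
    """Physical center coordinates of every voxel, shape (3, H, W, D).

    ``physical_grid(g)[:, i, j, k] == voxel_to_physical(g, (i, j, k))``.
    """
    h, w, d = geom.size
    idx = np.stack(
        np.meshgrid(np.arange(h), np.arange(w), np.arange(d), indexing="ij"),
        axis=0,
    ).astype(float)  # (3, H, W, D)
    scaled = idx * geom.spacing[:, None, None, None]
    rotated = np.einsum("ab,bhwd->ahwd", geom.direction, scaled)
    return rotated + geom.origin[:, None, None, None]


def crop_geometry(geom: ImageGeometry, start, roi) -> ImageGeometry:
    """Geometry of the ``roi``-sized sub-grid starting at voxel ``start``.

    Spacing and direction are unchanged; the new origin is the physical
    center of the start voxel, so the cropped grid's voxel centers coincide
    with the originals.
    """
    start = np.asarray(start, dtype=int).reshape(3)
    roi = np.asarray(roi, dtype=int).reshape(3)
    for axis in range(3):
        if start[axis] < 0 or start[axis] + roi[axis] > geom.size[axis]:
            raise GeometryError(
                f"crop [{start[axis]}, {start[axis] + roi[axis]}) exceeds bounds "
                f"on axis {axis} (size {geom.size[axis]})"
            )
    new_origin = voxel_to_physical(geom, start)
    return ImageGeometry(
        origin=new_origin,
        spacing=geom.spacing,
        direction=geom.direction,
        size=tuple(int(r) for r in roi),
    )


def resample_geometry(geom: ImageGeometry, new_size) -> ImageGeometry:
    """Geometry of the same physical field of view sampled at ``new_size``.

    The FOV edges are preserved: new spacing is ``spacing * size / new_size``
    and the origin shifts by half the spacing change along each axis so the
    outer faces of the first/last voxels coincide with the original FOV.
    """
    new_size = np.asarray(new_size, dtype=int).reshape(3)
    if np.any(new_size < 1):
        raise GeometryError(f"new_size components must be >= 1, got {new_size}")
    old_size = np.asarray(geom.size, dtype=float)
    new_spacing = geom.spacing * old_size / new_size
    shift = (new_spacing - geom.spacing) / 2.0
    new_origin = geom.origin + geom.direction @ shift
    return ImageGeometry(
        origin=new_origin,
        spacing=new_spacing,
        direction=geom.direction,
        size=tuple(int(s) for s in new_size),
    )


# ---------------------------------------------------------------------------
# NIfTI interface
# ---------------------------------------------------------------------------

def affine_from_geometry(geom: ImageGeometry) -> np.ndarray:
    """4x4 homogeneous affine mapping voxel index to physical mm."""
    affine = np.eye(4)
    affine[:3, :3] = geom.direction * geom.spacing[np.newaxis, :]
    affine[:3, 3] = geom.origin
    return affine


def geometry_from_affine(affine: np.ndarray, size) -> ImageGeometry:
    """Decompose a 4x4 affine into origin / spacing / direction.

    Raises
    ------
    GeometryError
        If the affine has shear (non-orthogonal voxel axes) beyond 1e-3.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("affine has a zero-length voxel axis")
    direction = linear / spacing[np.newaxis, :]
    gram = direction.T @ direction
    shear = np.max(np.abs(gram - np.diag(np.diag(gram))))
    if shear > _SHEAR_TOL:
        raise GeometryError(
            f"affine voxel axes are not orthogonal (shear {shear:.2e} > {_SHEAR_TOL}); "
            "oblique/sheared grids are not supported"
        )
    return ImageGeometry(
        origin=affine[:3, 3],
        spacing=spacing,
        direction=direction,
        size=tuple(int(s) for s in np.asarray(size).reshape(-1)),
    )


def load_volume(path) -> Volume:
    """Read a NIfTI file as a Volume; a 4th array axis is taken as channels."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[np.newaxis]
    elif data.ndim == 4:
        data = np.moveaxis(data, -1, 0)  # NIfTI stores channels last
    else:
        raise ContractError(f"expected a 3D or 4D NIfTI, got {data.ndim}D: {path}")
    geom = geometry_from_affine(img.affine, data.shape[1:])
    return Volume(data=data.astype(np.float64), geometry=geom)


def save_volume(vol: Volume, path, dtype=np.float32) -> None:
    """Write a Volume as NIfTI with the affine rebuilt from its geometry."""
    data = vol.data
    if data.shape[0] == 1:
        arr = np.asarray(data[0], dtype=dtype)
    else:
        arr = np.moveaxis(np.asarray(data, dtype=dtype), 0, -1)
    img = nib.Nifti1Image(arr, affine_from_geometry(vol.geometry))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
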