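"""Volumetric image grids with affine (voxel -> world mm) geometry.

Thin container over a numpy array plus a NIfTI-style 4x4 affine, with
reslicing to isotropic resolution and rigid-body resampling.  File I/O goes
through nibabel.
"""

from __future__ import annotations

import dataclasses
import os

import nibabel as nib
import numpy as np

from .bspline import SplineInterpolator
from .errors import GeometryError
from .kinematics import RigidTransform


@dataclasses.dataclass
class VolumeGrid:
    """A 3-D (or 4-D) image with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each spatial axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.data.shape

    def world(self, indices: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of voxel indices to world mm."""
        idx = np.asarray(indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel(self, points: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of world-mm points to (fractional) voxel indices."""
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(points, dtype=float)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def is_binary(self) -> bool:
        vals = np.unique(self.data)
        return vals.size <= 2 and np.all(np.isin(vals, (0, 1)))

    def astype_mask(self) -> np.ndarray:
        return np.asarray(self.data) > 0.5


def load_volume(path: str | os.PathLike) -> VolumeGrid:
    img = nib.load(os.fspath(path))
    return VolumeGrid(np.asarray(img.get_fdata()), img.affine)


def save_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), os.fspath(path))


def _output_grid(vol: VolumeGrid, spacing: float):
    """Axis-aligned output lattice covering the input field of view."""
    shape = np.asarray(vol.data.shape[:3])
    corners = np.array(
        [[i, j, k] for i in (0, shape[0] - 1)
         for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
        dtype=float,
    )
    world = vol.world(corners)
    lo = world.min(axis=0)
    hi = world.max(axis=0)
    out_shape = np.floor((hi - lo) / spacing + 0.5).astype(int) + 1
    out_affine = np.eye(4)
    out_affine[:3, :3] *= spacing
    out_affine[:3, 3] = lo
    return out_shape, out_affine


def reslice_isotropic(
    vol: VolumeGrid,
    spacing: float = 1.0,
    spline_order: int = 7,
    is_mask: bool | None = None,
    threshold: float = 0.5,
) -> VolumeGrid:
    """Reslice a 3-D volume to an isotropic grid at the given spacing (mm).

    The output lattice is axis-aligned in world space and covers the input
    field of view; the world coordinate frame (hence the world origin) is
    unchanged.  Masks (detected automatically, or forced with ``is_mask``)
    are interpolated as floats and re-binarized at ``threshold``.
    """
    if vol.data.ndim != 3:
        raise GeometryError("reslice_isotropic expects a 3-D volume")
    mask_mode = vol.is_binary() if is_mask is None else is_mask
    out_shape, out_affine = _output_grid(vol, spacing)
    # output voxel -> input voxel mapping
    q = np.linalg.inv(vol.affine) @ out_affine
    grid = np.indices(out_shape, dtype=float).reshape(3, -1)
    coords = q[:3, :3] @ grid + q[:3, 3:4]
    interp = SplineInterpolator(
        vol.data.astype(float), degree=spline_order, cval=0.0
    )
    vals = interp(coords).reshape(tuple(out_shape))
    if mask_mode:
        vals = vals >= threshold
    return VolumeGrid(vals, out_affine)


def resample_rigid(
    vol: VolumeGrid,
    motion: RigidTransform,
    spline_order: int = 7,
    interpolator: SplineInterpolator | None = None,
) -> VolumeGrid:
    """Resample a 3-D volume as if the imaged object moved by ``motion``.

    The motion is a world-space rigid transform M: output intensity at world
    point x is the input intensity at M^-1 x (pull-back sampling; this is why
    replaying recorded motion applies the *inverted* transforms).  Out-of-field
    voxels are filled with 0.
    """
    if vol.data.ndim != 3:
        raise GeometryError("resample_rigid expects a 3-D volume")
    a_inv = np.linalg.inv(vol.affine)
    q = a_inv @ motion.inverse().matrix @ vol.affine
    grid = np.indices(vol.data.shape, dtype=float).reshape(3, -1)
    coords = q[:3, :3] @ grid + q[:3, 3:4]
    if interpolator is None:
        interpolator = SplineInterpolator(
            vol.data.astype(float), degree=spline_order, cval=0.0
        )
    vals = interpolator(coords).reshape(vol.data.shape)
    return VolumeGrid(vals, vol.affine.copy())
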