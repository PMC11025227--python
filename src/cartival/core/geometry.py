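"""Transform application, label resampling and surface extraction."""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure

from .types import LabelVolume, LandmarkSet, RigidTransform, SurfaceMesh

__all__ = ["apply_transform", "resample_volume", "mask_to_mesh", "EmptyMaskError"]


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty label mask."""


def apply_transform(T: RigidTransform, x):
    """Apply a rigid transform to a mesh, a landmark set or an (N, 3) cloud.

    Pairwise distances are preserved exactly (up to floating point); the
    returned object has the same type as the input.
    """
    if isinstance(x, SurfaceMesh):
        return SurfaceMesh(T.apply(x.vertices), x.faces, x.frame_id)
    if isinstance(x, LandmarkSet):
        return x.transformed(T)
    pts = np.asarray(x, dtype=float)
    if pts.ndim == 1 and pts.shape == (3,):
        return T.apply(pts)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise TypeError("apply_transform expects a SurfaceMesh, LandmarkSet or (N, 3) array")
    return T.apply(pts)


def resample_volume(v: LabelVolume, T: RigidTransform,
                    target_grid: LabelVolume) -> LabelVolume:
    """Nearest-neighbour resampling of ``v`` through ``T`` onto a target grid.

    ``T`` maps the frame of ``v`` onto the frame of ``target_grid``; each
    target voxel center is pulled back through ``T`` inverse and takes the
    label of the nearest source voxel (labels are categorical, so no
    interpolation).  Target voxels falling outside the source grid become
    background.  If nothing overlaps, an all-background volume is returned
    and a warning is emitted.
    """
    shape = target_grid.shape
    ii, jj, kk = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             np.arange(shape[2]), indexing="ij", sparse=False)
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    world = target_grid.origin_mm + target_grid.spacing_mm * idx
    src_pts = T.inverse().apply(world)
    src_idx = np.rint(v.world_to_index(src_pts)).astype(np.int64)
    inside = np.all((src_idx >= 0) & (src_idx < np.array(v.shape)), axis=1)
    out = np.zeros(idx.shape[0], dtype=v.voxels.dtype)
    if inside.any():
        s = src_idx[inside]
        out[inside] = v.voxels[s[:, 0], s[:, 1], s[:, 2]]
    else:
        warnings.warn("resample_volume: source volume does not overlap the target grid; "
                      "result is all background", stacklevel=2)
    return LabelVolume(out.reshape(shape), target_grid.spacing_mm,
                       target_grid.origin_mm, target_grid.frame_id)


def mask_to_mesh(v: LabelVolume, label: int = 1) -> SurfaceMesh:
    """Extract the 0.5 iso-surface of the binary indicator of ``label``.

    The mask is padded by one background voxel on every side so the surface
    of a solid mask is closed (watertight).  Vertices are returned in world
    millimetre coordinates.
    """
    mask = v.voxels == label
    if not mask.any():
        raise EmptyMaskError(f"label {label} not present in volume (frame {v.frame_id!r})")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # index space -> world: remove pad offset, scale, shift by origin;
    # flip winding so face normals point outward (positive enclosed volume)
    verts = (verts - 1.0) * v.spacing_mm + v.origin_mm
    return SurfaceMesh(verts, faces[:, ::-1], v.frame_id)
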