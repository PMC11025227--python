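"""File I/O for the domain types.

Formats: NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``) for
label volumes (via SimpleITK), STL/PLY for surface meshes (via trimesh), PNG
plus a JSON sidecar (pixel scale, provenance) for binary silhouettes, CSV with
columns ``label,x,y,z`` for landmark sets, and a JSON 4x4 homogeneous matrix
for rigid transforms.  All round-trips are lossless for integer grids and
within 1e-6 mm for float coordinates (PLY is written in ASCII for that reason;
STL stores float32 and is read back at float32 precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import SimpleITK as sitk
import trimesh

from .types import BinarySilhouette, LabelVolume, LandmarkSet, RigidTransform, SurfaceMesh

__all__ = [
    "read_label_volume", "write_label_volume",
    "read_mesh", "write_mesh",
    "read_silhouette", "write_silhouette",
    "read_landmarks", "write_landmarks",
    "read_transform", "write_transform",
]

_ISO_TOL = 1e-6


# -- label volumes --------------------------------------------------------

def read_label_volume(path, frame_id: str = "unknown") -> LabelVolume:
    img = sitk.ReadImage(str(path))
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if np.ptp(spacing) > _ISO_TOL * spacing.max():
        raise ValueError(
            f"{path}: anisotropic spacing {tuple(spacing)} not supported; "
            "volumes must be isotropic")
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if np.abs(direction - np.eye(3)).max() > 1e-6:
        raise ValueError(f"{path}: oblique/non-identity direction matrix not supported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.all(arr == np.round(arr)):
            arr = arr.astype(np.int32)
        else:
            raise ValueError(f"{path}: voxel values are not integer labels")
    return LabelVolume(np.ascontiguousarray(arr.transpose(2, 1, 0)),
                       float(spacing[0]), np.asarray(img.GetOrigin(), dtype=float),
                       frame_id)


def write_label_volume(v: LabelVolume, path) -> None:
    arr = np.ascontiguousarray(np.asarray(v.voxels).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((v.spacing_mm,) * 3)
    img.SetOrigin(tuple(float(x) for x in v.origin_mm))
    sitk.WriteImage(img, str(path))


# -- surface meshes -------------------------------------------------------

def read_mesh(path, frame_id: str = "unknown") -> SurfaceMesh:
    tm = trimesh.load(str(path), force="mesh", process=False)
    if tm.vertices.size == 0:
        raise ValueError(f"{path}: mesh has no vertices")
    return SurfaceMesh.from_trimesh(tm, frame_id)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        # ASCII PLY keeps full float precision for round-trips
        data = tm.export(file_type="ply", encoding="ascii")
        path.write_bytes(data.encode() if isinstance(data, str) else data)
    else:
        tm.export(str(path))


# -- silhouettes ----------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_silhouette(path) -> BinarySilhouette:
    path = Path(path)
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"{side}: missing sidecar with the mm_per_px scale for {path.name}")
    meta = json.loads(side.read_text())
    for key in ("mm_per_px",):
        if key not in meta:
            raise ValueError(f"{side}: sidecar is missing required field {key!r}")
    # PNG rows are image rows (y); stored transposed so pixels[i, j] is (x, y)
    return BinarySilhouette(img.T > 127, float(meta["mm_per_px"]),
                            meta.get("provenance", "photo"))


def write_silhouette(s: BinarySilhouette, path) -> None:
    path = Path(path)
    iio.imwrite(path, (np.asarray(s.pixels).T.astype(np.uint8)) * 255)
    _sidecar_path(path).write_text(json.dumps(
        {"mm_per_px": s.mm_per_px, "provenance": s.provenance}, indent=2) + "\n")


# -- landmarks ------------------------------------------------------------

def read_landmarks(path, frame_id: str = "unknown") -> LandmarkSet:
    df = pd.read_csv(path)
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: landmark CSV is missing columns {sorted(missing)}")
    if len(df) != 6:
        raise ValueError(f"{path}: expected exactly 6 landmarks, found {len(df)}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSet(pts, tuple(df["label"].astype(str)), frame_id)


def write_landmarks(lm: LandmarkSet, path) -> None:
    df = pd.DataFrame({"label": list(lm.labels),
                       "x": lm.points[:, 0], "y": lm.points[:, 1], "z": lm.points[:, 2]})
    df.to_csv(path, index=False, float_format="%.9f")


# -- transforms -----------------------------------------------------------

def read_transform(path) -> RigidTransform:
    data = json.loads(Path(path).read_text())
    if "matrix" not in data:
        raise ValueError(f"{path}: transform JSON is missing field 'matrix'")
    return RigidTransform.from_matrix(np.asarray(data["matrix"], dtype=float))


def write_transform(T: RigidTransform, path) -> None:
    Path(path).write_text(json.dumps({"matrix": T.matrix.tolist()}, indent=2) + "\n")
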