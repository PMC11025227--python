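"""Shared geometric domain types.

World coordinates are in millimetres throughout.  A :class:`LabelVolume` maps
voxel index ``(i, j, k)`` to the world position ``origin_mm + spacing_mm * (i, j, k)``,
i.e. indices address voxel *centers*, axis order (x, y, z).  All grids are
isotropic; anisotropic volumes are rejected at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelVolume",
    "SurfaceMesh",
    "BinarySilhouette",
    "RigidTransform",
    "LandmarkSet",
    "LANDMARK_LABELS",
]

#: Canonical ordered landmark names: anterior rim, two per medial condylar
#: patch, posterior rim, two per lateral patch.  Correspondence between two
#: landmark sets is by position in this order.
LANDMARK_LABELS = (
    "anterior-tibia",
    "medial-plateau-1",
    "medial-plateau-2",
    "posterior-tibia",
    "lateral-plateau-1",
    "lateral-plateau-2",
)

_ORTHO_TOL = 1e-9


def _as_readonly(a: np.ndarray, dtype=None) -> np.ndarray:
    out = np.array(a, dtype=dtype, copy=True)
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` (mm).

    ``rotation`` must be orthonormal with determinant +1 (within 1e-9).
    Composition uses ``@``: ``(A @ B)(x) == A(B(x))``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = _as_readonly(self.rotation, dtype=float)
        t = _as_readonly(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if t.shape != (3,):
            raise ValueError(f"translation must be a 3-vector, got {t.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("rigid transform contains non-finite entries")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"homogeneous matrix must be 4x4, got {m.shape}")
        if np.abs(m[3] - np.array([0.0, 0.0, 0.0, 1.0])).max() > 1e-9:
            raise ValueError("bottom row of a rigid homogeneous matrix must be [0,0,0,1]")
        return RigidTransform(m[:3, :3], m[:3, 3])

    @staticmethod
    def from_axis_angle(axis: np.ndarray, angle_deg: float,
                        translation: np.ndarray | None = None) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        axis = axis / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return RigidTransform(R, t)

    # -- algebra ----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a 3-vector or an (N, 3) point array."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)(x) == self(other(x))``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees.

        Uses atan2 of the skew/trace parts, which stays accurate for tiny
        angles where arccos of the trace loses ~half the significant digits.
        """
        R = self.rotation
        skew = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        s = np.linalg.norm(skew)
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.degrees(np.arctan2(s, c)))

    def geodesic_to(self, other: "RigidTransform") -> float:
        """Rotation geodesic distance to ``other`` in degrees."""
        return RigidTransform(self.rotation.T @ other.rotation, np.zeros(3)).rotation_angle_deg()

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))


@dataclass(frozen=True)
class LabelVolume:
    """3D integer label grid on an isotropic voxel lattice.

    ``voxels[i, j, k]`` sits at world position ``origin_mm + spacing_mm*(i, j, k)``.
    Label 0 is background; label 1 is cartilage by convention.
    """

    voxels: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame_id: str = "unknown"

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={v.ndim}")
        if not np.issubdtype(v.dtype, np.integer):
            if np.issubdtype(v.dtype, np.floating) and np.all(v == np.round(v)):
                v = v.astype(np.int32)
            else:
                raise ValueError("voxel values must be integers")
        if v.size and v.min() < 0:
            raise ValueError("voxel labels must be non-negative")
        if not (float(self.spacing_mm) > 0):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        o = _as_readonly(self.origin_mm, dtype=float)
        if o.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")
        v = _as_readonly(v)
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing_mm", float(self.spacing_mm))
        object.__setattr__(self, "origin_mm", o)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def label_count(self, label: int = 1) -> int:
        return int(np.count_nonzero(self.voxels == label))

    def label_volume_mm3(self, label: int = 1) -> float:
        return self.label_count(label) * self.spacing_mm ** 3

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + self.spacing_mm * np.asarray(idx, dtype=float)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates of world points."""
        return (np.asarray(pts, dtype=float) - self.origin_mm) / self.spacing_mm

    def with_voxels(self, voxels: np.ndarray, frame_id: str | None = None) -> "LabelVolume":
        return LabelVolume(voxels, self.spacing_mm, self.origin_mm,
                           self.frame_id if frame_id is None else frame_id)


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface; vertices in world millimetres."""

    vertices: np.ndarray
    faces: np.ndarray
    frame_id: str = "unknown"

    def __post_init__(self):
        v = _as_readonly(self.vertices, dtype=float)
        f = _as_readonly(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (M, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=np.array(self.vertices),
                               faces=np.array(self.faces), process=False)

    @staticmethod
    def from_trimesh(tm, frame_id: str = "unknown") -> "SurfaceMesh":
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), frame_id)

    def face_normals(self) -> np.ndarray:
        """Unnormalised face normals (cross products; length = 2*area)."""
        tri = self.vertices[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])


@dataclass(frozen=True)
class BinarySilhouette:
    """2D boolean image with a physical pixel scale.

    ``pixels[i, j]`` covers world position ``(i * mm_per_px, j * mm_per_px)``
    up to an arbitrary in-plane offset; comparisons align on centroids, so the
    absolute offset is not stored.
    """

    pixels: np.ndarray
    mm_per_px: float
    provenance: str = "rendered"

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={p.ndim}")
        p = _as_readonly(p.astype(bool))
        if not (float(self.mm_per_px) > 0):
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")
        if self.provenance not in ("rendered", "photo"):
            raise ValueError(f"provenance must be 'rendered' or 'photo', got {self.provenance!r}")
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "mm_per_px", float(self.mm_per_px))

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.pixels))

    @property
    def area_mm2(self) -> float:
        return self.foreground_count * self.mm_per_px ** 2


@dataclass(frozen=True)
class LandmarkSet:
    """Exactly six ordered anatomical landmarks (mm).

    Order follows :data:`LANDMARK_LABELS`; correspondence between two sets is
    by index.  Points must be non-collinear (rank of the centered point matrix
    at least 2), otherwise rigid alignment is underdetermined.
    """

    points: np.ndarray
    labels: tuple[str, ...] = LANDMARK_LABELS
    frame_id: str = "unknown"

    def __post_init__(self):
        p = _as_readonly(self.points, dtype=float)
        if p.shape != (6, 3):
            raise ValueError(f"a landmark set has exactly 6 points, got shape {p.shape}")
        labels = tuple(self.labels)
        if len(labels) != 6:
            raise ValueError("exactly 6 landmark labels required")
        if not np.all(np.isfinite(p)):
            raise ValueError("landmark coordinates must be finite")
        centered = p - p.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError("landmarks are collinear; rigid alignment is underdetermined")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "labels", labels)

    def transformed(self, T: RigidTransform, frame_id: str | None = None) -> "LandmarkSet":
        return LandmarkSet(T.apply(self.points), self.labels,
                           self.frame_id if frame_id is None else frame_id)
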