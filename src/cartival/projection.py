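"""Simulated photography: pose rectification, silhouette rendering, photo
binarization and 2D silhouette alignment.

The physical comparison this emulates photographs a resected tibial-plateau
specimen from directly above (camera 140 mm over the bench, 1.3x zoom) on
1 x 1 mm calibrated grid paper, and renders the 3D segmentation model "with
the same parameters".  Because both images are converted to absolute
millimetres via the grid calibration, absolute magnification cancels; the
default renderer is therefore orthographic, with a pinhole mode retained to
quantify the (sub-percent) parallax error of that choice for flat specimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .core.types import BinarySilhouette, RigidTransform, SurfaceMesh
from .metrics import dsc_2d

__all__ = ["CameraSpec", "pca_rectify", "render_silhouette",
           "binarize_photo", "align_silhouettes", "AlignedPair"]


@dataclass(frozen=True)
class CameraSpec:
    """Camera geometry of the specimen photograph.

    ``mm_per_px`` is the calibrated scale of the output image (grid squares of
    ``grid_pitch_mm`` span exactly ``grid_pitch_mm / mm_per_px`` pixels).  In
    pinhole mode the camera sits at ``(0, 0, distance_mm)`` looking straight
    down, with the grid plane z = 0 mapping at ``mm_per_px``; ``magnification``
    is the optical zoom, which cancels under grid calibration and is kept for
    provenance only.  ``canvas_extent_mm`` optionally fixes the canvas size
    (width, height); by default the canvas is sized to the projected mesh.
    """

    distance_mm: float = 140.0
    magnification: float = 1.3
    mm_per_px: float = 0.1
    grid_pitch_mm: float = 1.0
    mode: str = "orthographic"
    canvas_extent_mm: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mode not in ("orthographic", "pinhole"):
            raise ValueError(f"mode must be 'orthographic' or 'pinhole', got {self.mode!r}")
        if self.mm_per_px <= 0 or self.distance_mm <= 0 or self.grid_pitch_mm <= 0:
            raise ValueError("distance_mm, mm_per_px and grid_pitch_mm must be positive")

    @property
    def grid_pitch_px(self) -> float:
        return self.grid_pitch_mm / self.mm_per_px


# -- PCA pose rectification ----------------------------------------------

def pca_rectify(mesh: SurfaceMesh) -> tuple[SurfaceMesh, RigidTransform]:
    """Rotate a mesh so its principal axes align with x >= y >= z variance.

    The centroid moves to the origin; the largest-variance axis becomes x and
    the smallest (the thickness direction of a plateau) becomes z, signed so
    that the articular (curved) surface faces +z.  Axis signs are fixed
    deterministically: the z sign by the vertex-z skewness (a flat resection
    face below a domed cartilage face skews positive), falling back to a
    face-normal majority vote and then to a largest-component rule for
    symmetric meshes; the x sign by the same skewness rule in x.  Returns the
    rectified mesh and the transform that maps input to output.
    """
    V = np.asarray(mesh.vertices)
    if len(V) < 4:
        raise ValueError("pca_rectify needs at least 4 vertices")
    c = V.mean(axis=0)
    Vc = V - c
    cov = Vc.T @ Vc / len(Vc)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    if evals[0] <= 1e-12 * max(evals[-1], 1e-30):
        raise ValueError("degenerate covariance: vertices are (near-)coplanar")
    axes = evecs[:, ::-1].T                 # rows: x (largest var), y, z (smallest)

    z_axis = _orient_axis(axes[2], Vc, mesh)
    x_axis = _orient_axis_by_skew(axes[0], Vc)
    y_axis = np.cross(z_axis, x_axis)       # right-handed, proper rotation
    R = np.vstack([x_axis, y_axis, z_axis])
    T = RigidTransform(R, -R @ c)
    return SurfaceMesh(Vc @ R.T, mesh.faces, mesh.frame_id), T


def _orient_axis_by_skew(axis: np.ndarray, Vc: np.ndarray) -> np.ndarray:
    m3 = float(np.mean((Vc @ axis) ** 3))
    scale = float(np.mean((Vc @ axis) ** 2)) ** 1.5
    if scale > 0 and abs(m3) > 1e-9 * scale:
        return axis if m3 > 0 else -axis
    # symmetric along this axis: make the largest-magnitude component positive
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


def _orient_axis(axis: np.ndarray, Vc: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """z-sign: skewness first (stable for closed slabs), then normal vote."""
    proj = Vc @ axis
    m3 = float(np.mean(proj ** 3))
    scale = float(np.mean(proj ** 2)) ** 1.5
    if scale > 0 and abs(m3) > 1e-3 * scale:
        return axis if m3 > 0 else -axis
    if mesh.n_faces:
        normals = mesh.face_normals()
        vote = int(np.sum(np.sign(normals @ axis)))
        if abs(vote) > 0.02 * mesh.n_faces:
            return axis if vote > 0 else -axis
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


# -- silhouette rendering -------------------------------------------------

class CanvasOverflowError(ValueError):
    """Mesh projects outside the configured canvas."""

    def __init__(self, required_mm: tuple[float, float], configured_mm: tuple[float, float]):
        self.required_mm = required_mm
        self.configured_mm = configured_mm
        super().__init__(
            f"projected mesh needs a canvas of {required_mm[0]:.1f} x "
            f"{required_mm[1]:.1f} mm but {configured_mm[0]:.1f} x "
            f"{configured_mm[1]:.1f} mm was configured")


def render_silhouette(mesh: SurfaceMesh, cam: CameraSpec | None = None) -> BinarySilhouette:
    """Top-down binary silhouette of a (rectified, z-up) mesh.

    A pixel is foreground iff the vertical ray through its center intersects
    the projected mesh: every triangle is projected (orthographically, or
    through the pinhole at ``(0, 0, distance_mm)``) and rasterised with an
    exact pixel-center point-in-triangle test.  For a closed surface the union
    of projected triangles is exactly the silhouette of the solid.
    """
    cam = cam or CameraSpec()
    mpp = cam.mm_per_px
    if mesh.n_faces == 0:
        return BinarySilhouette(np.zeros((16, 16), dtype=bool), mpp, "rendered")
    V = np.asarray(mesh.vertices)
    if cam.mode == "pinhole":
        zmax = V[:, 2].max()
        if zmax >= cam.distance_mm:
            raise ValueError(f"mesh reaches z={zmax:.1f} mm, at or above the "
                             f"camera ({cam.distance_mm} mm)")
        scale = cam.distance_mm / (cam.distance_mm - V[:, 2])
        P = V[:, :2] * scale[:, None]
    else:
        P = V[:, :2]

    lo = P.min(axis=0)
    hi = P.max(axis=0)
    extent = hi - lo
    if cam.canvas_extent_mm is not None:
        cw, ch = cam.canvas_extent_mm
        if extent[0] > cw or extent[1] > ch:
            raise CanvasOverflowError((float(extent[0]), float(extent[1])), (cw, ch))
        pad = (np.array([cw, ch]) - extent) / 2
        lo = lo - pad
        hi = hi + pad
    # pixel i center at lo + (i + 0.5) * mpp
    shape = (int(np.ceil((hi[0] - lo[0]) / mpp)) + 2,
             int(np.ceil((hi[1] - lo[1]) / mpp)) + 2)
    tri_px = (P[mesh.faces] - lo) / mpp - 0.5   # pixel-center coordinates
    pixels = _rasterize_triangles(tri_px, shape)
    return BinarySilhouette(pixels, mpp, "rendered")


def _rasterize_triangles(tri: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Union of filled 2D triangles, pixel-center inclusion test.

    ``tri`` is (M, 3, 2) in pixel units where pixel (i, j) has center (i, j).
    Triangles are bucketed by bounding-box size so that the typical case —
    millions of voxel-scale marching-cubes triangles — is fully vectorised.
    """
    img = np.zeros(shape, dtype=bool)
    if len(tri) == 0:
        return img
    lo = np.ceil(tri.min(axis=1)).astype(np.int64)
    hi = np.floor(tri.max(axis=1)).astype(np.int64)
    np.clip(lo, 0, np.array(shape) - 1, out=lo)
    np.clip(hi, -1, np.array(shape) - 1, out=hi)
    w = hi - lo + 1
    ok = (w[:, 0] > 0) & (w[:, 1] > 0)
    size = np.maximum(w[:, 0], w[:, 1])

    done = ~ok
    for bucket in (2, 4, 8, 16, 32):
        sel = ~done & (size <= bucket)
        if sel.any():
            _raster_bucket(tri[sel], lo[sel], bucket, img)
            done |= sel
    for m in np.nonzero(~done)[0]:      # rare large triangles: one by one
        _raster_bucket(tri[m:m + 1], lo[m:m + 1], int(size[m]), img)
    return img


def _raster_bucket(tri: np.ndarray, lo: np.ndarray, span: int, img: np.ndarray) -> None:
    n = len(tri)
    off = np.stack(np.meshgrid(np.arange(span), np.arange(span), indexing="ij"),
                   axis=-1).reshape(-1, 2)                      # (span^2, 2)
    pts = lo[:, None, :] + off[None, :, :]                      # (n, span^2, 2)
    p = pts.astype(float)
    a, b, c = tri[:, 0][:, None, :], tri[:, 1][:, None, :], tri[:, 2][:, None, :]

    def edge(p0, p1):
        return ((p1[..., 0] - p0[..., 0]) * (p[..., 1] - p0[..., 1])
                - (p1[..., 1] - p0[..., 1]) * (p[..., 0] - p0[..., 0]))

    e0, e1, e2 = edge(a, b), edge(b, c), edge(c, a)
    inside = ((e0 >= 0) & (e1 >= 0) & (e2 >= 0)) | ((e0 <= 0) & (e1 <= 0) & (e2 <= 0))
    inbounds = ((pts[..., 0] >= 0) & (pts[..., 0] < img.shape[0])
                & (pts[..., 1] >= 0) & (pts[..., 1] < img.shape[1]))
    hit = inside & inbounds
    if hit.any():
        img[pts[..., 0][hit], pts[..., 1][hit]] = True


# -- photograph binarization ----------------------------------------------

def binarize_photo(image: np.ndarray, threshold="otsu", mm_per_px: float = 0.1,
                   polarity: str = "bright") -> BinarySilhouette:
    """Threshold a grayscale photograph into a calibrated binary silhouette.

    ``threshold`` is a grey level or ``"otsu"``; ``polarity`` selects whether
    the object is brighter or darker than the background.  The largest
    connected component is retained, but interior holes are deliberately
    preserved: full-thickness cartilage defects are part of the morphology
    being validated and must survive binarization.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("binarize_photo expects a non-empty 2D grayscale array")
    if threshold == "otsu":
        threshold = float(filters.threshold_otsu(img))
    mask = img > threshold if polarity == "bright" else img < threshold
    if not mask.any():
        raise ValueError("empty foreground after thresholding: check threshold/polarity")
    labels = measure.label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    return BinarySilhouette(mask, mm_per_px, provenance="photo")


# -- silhouette alignment -------------------------------------------------

@dataclass(frozen=True)
class AlignedPair:
    """Co-registered silhouettes plus a record of the alignment decisions."""

    a: BinarySilhouette
    b: BinarySilhouette
    rotation_deg: float
    candidate_index: int
    mode: str           # "principal-axes" | "centroid-only"
    mm_per_px: float

    def __iter__(self):
        return iter((self.a, self.b))


def _moments(mask: np.ndarray):
    idx = np.argwhere(mask).astype(float)
    cen = idx.mean(axis=0)
    d = idx - cen
    mu = d.T @ d / len(d)
    return cen, mu


def _principal_angle(mu: np.ndarray) -> float:
    return 0.5 * np.arctan2(2.0 * mu[0, 1], mu[0, 0] - mu[1, 1])


def _resample_to(mask: np.ndarray, src_mpp: float, dst_mpp: float) -> np.ndarray:
    if abs(src_mpp - dst_mpp) <= 1e-12 * src_mpp:
        return mask
    ratio = src_mpp / dst_mpp
    if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
        return np.kron(mask, np.ones((int(round(ratio)),) * 2, dtype=bool))
    return ndimage.zoom(mask.astype(np.uint8), ratio, order=0) > 0


def _place(mask: np.ndarray, cen: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    shift = (np.array(shape) / 2 - cen).round().astype(int)
    src = np.argwhere(mask) + shift
    keep = np.all((src >= 0) & (src < np.array(shape)), axis=1)
    src = src[keep]
    out[src[:, 0], src[:, 1]] = True
    return out


def align_silhouettes(a: BinarySilhouette, b: BinarySilhouette) -> AlignedPair:
    """Superpose two silhouettes for 2D DSC.

    Both are resampled to the finer pixel scale, centroids are superposed and
    ``b`` is rotated so its 2D principal axis matches ``a``'s; the 180-degree
    axis-sign ambiguity is resolved by trying both proper-rotation candidates
    and keeping the one with the higher DSC (no mirror candidates: a
    photograph and a top-down render share handedness).  Ties break towards
    the first candidate.  Nearly isotropic shapes (degenerate principal axis)
    fall back to centroid-only alignment with a warning.
    """
    if not a.pixels.any() or not b.pixels.any():
        raise ValueError("cannot align an empty silhouette")
    mpp = min(a.mm_per_px, b.mm_per_px)
    pa = _resample_to(a.pixels, a.mm_per_px, mpp)
    pb = _resample_to(b.pixels, b.mm_per_px, mpp)

    cen_a, mu_a = _moments(pa)
    cen_b, mu_b = _moments(pb)
    iso_a = _anisotropy(mu_a)
    iso_b = _anisotropy(mu_b)
    if iso_a < 0.05 or iso_b < 0.05:
        warnings.warn("silhouette principal axis is degenerate (near-circular shape); "
                      "falling back to centroid-only alignment", stacklevel=2)
        base_angles = [0.0]
        mode = "centroid-only"
    else:
        delta = np.degrees(_principal_angle(mu_a) - _principal_angle(mu_b))
        base_angles = [delta, delta + 180.0]
        mode = "principal-axes"

    diag = int(np.ceil(np.hypot(*pa.shape) + np.hypot(*pb.shape)))
    shape = (diag, diag)
    a_placed = _place(pa, cen_a, shape)
    sa = BinarySilhouette(a_placed, mpp, a.provenance)

    best = None
    for k, ang in enumerate(base_angles):
        rb = ndimage.rotate(pb.astype(np.uint8), ang, order=0, reshape=True) > 0
        if not rb.any():
            continue
        cen_rb, _ = _moments(rb)
        sb = BinarySilhouette(_place(rb, cen_rb, shape), mpp, b.provenance)
        d = dsc_2d(sa, sb).dsc
        if best is None or d > best[0]:
            best = (d, k, ang, sb)
    _, k, ang, sb = best
    return AlignedPair(sa, sb, float(ang % 360.0), k, mode, mpp)


def _anisotropy(mu: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(mu)
    return float((ev[1] - ev[0]) / max(ev[1], 1e-12))
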