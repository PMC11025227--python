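"""Synthetic tibial-plateau phantom generator.

Each case emulates the paired data the validation pipeline consumes: a
gold-standard cartilage label volume in the "CT" frame (0.2 mm isotropic), a
degraded model volume in a separate "MRI" frame (0.4 mm isotropic) related to
the CT frame by a known rigid transform, a top-down binary "photograph" of the
specimen on calibrated grid paper, and six ordered fiducial landmarks in both
frames.

The cartilage is modelled as two smooth thickness fields (medial and lateral
condylar patches) over an elliptical plateau: full thickness over the patch
interior with a cosine-squared taper to zero at the patch rim, smoothed by a
fixed-width Gaussian, minus optional sharp full-thickness defect disks.  The
MRI-side model reproduces the characteristic failure mode of MRI-trained
segmentation — thickness underestimation — as a multiplicative bias
``thickness_bias`` (beta) on the thickness field, plus a smooth additive
boundary-noise field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .core.types import (
    BinarySilhouette,
    LabelVolume,
    LandmarkSet,
    LANDMARK_LABELS,
    RigidTransform,
)

__all__ = ["PhantomParams", "CohortRanges", "SyntheticCase",
           "generate_case", "generate_cohort"]

CT_SPACING_MM = 0.2
MRI_SPACING_MM = 0.4
_SMOOTH_SIGMA_MM = 1.0     # fixed height-map smoothing kernel
_NOISE_CORR_MM = 2.0       # correlation length of the boundary-noise field
_TAPER_START = 0.75        # fraction of the patch radius where the rim taper begins
_RIM_CUT_FRAC = 0.25       # taper terminates in a sharp step at this fraction of base
_GRID_MARGIN_MM = 3.0


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, degradation and reproducibility knobs for one case.

    ``thickness_bias`` is the multiplicative MRI-side thickness factor beta in
    (0, 1]; 1.0 is an unbiased model.  ``defect_specs`` are full-thickness
    cartilage defects as ``(cx, cy, radius)`` disks in CT-frame mm.
    """

    plateau_extent_mm: tuple[float, float] = (75.0, 50.0)
    patch_centers: tuple[tuple[float, float], ...] = ((-19.0, 0.0), (19.0, 0.0))
    patch_radii_mm: tuple[float, float] = (18.0, 16.0)
    base_thickness_mm: float = 2.2
    thickness_bias: float = 1.0
    defect_specs: tuple[tuple[float, float, float], ...] = ()
    boundary_noise_sd_mm: float = 0.3
    landmark_noise_sd_mm: float = 0.5
    photo_mm_per_px: float = 0.1
    true_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.thickness_bias <= 1.0):
            raise ValueError(f"thickness_bias must be in (0, 1], got {self.thickness_bias}")
        if min(self.patch_radii_mm) <= 0:
            raise ValueError("patch radii must be positive")
        if self.base_thickness_mm <= 0:
            raise ValueError("base thickness must be positive")
        if self.boundary_noise_sd_mm < 0 or self.landmark_noise_sd_mm < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def to_dict(self) -> dict:
        return {
            "plateau_extent_mm": list(self.plateau_extent_mm),
            "patch_centers": [list(c) for c in self.patch_centers],
            "patch_radii_mm": list(self.patch_radii_mm),
            "base_thickness_mm": self.base_thickness_mm,
            "thickness_bias": self.thickness_bias,
            "defect_specs": [list(d) for d in self.defect_specs],
            "boundary_noise_sd_mm": self.boundary_noise_sd_mm,
            "landmark_noise_sd_mm": self.landmark_noise_sd_mm,
            "photo_mm_per_px": self.photo_mm_per_px,
            "true_transform": self.true_transform.matrix.tolist(),
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "PhantomParams":
        return PhantomParams(
            plateau_extent_mm=tuple(d["plateau_extent_mm"]),
            patch_centers=tuple(tuple(c) for c in d["patch_centers"]),
            patch_radii_mm=tuple(d["patch_radii_mm"]),
            base_thickness_mm=d["base_thickness_mm"],
            thickness_bias=d["thickness_bias"],
            defect_specs=tuple(tuple(x) for x in d["defect_specs"]),
            boundary_noise_sd_mm=d["boundary_noise_sd_mm"],
            landmark_noise_sd_mm=d["landmark_noise_sd_mm"],
            photo_mm_per_px=d["photo_mm_per_px"],
            true_transform=RigidTransform.from_matrix(np.asarray(d["true_transform"])),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for :func:`generate_cohort`.

    Defaults emulate the study condition the pipeline is meant to expose:
    models that systematically under-estimate thickness (beta drawn from
    0.5-0.9), a handful of full-thickness defects per knee, and an unknown
    specimen pose within 25 degrees / 15 mm of the imaging frame.
    """

    beta_range: tuple[float, float] = (0.5, 0.9)
    n_defects_range: tuple[int, int] = (0, 3)
    defect_radius_mm_range: tuple[float, float] = (2.0, 6.0)
    patch_radius_jitter_frac: float = 0.15
    base_thickness_jitter_frac: float = 0.10
    rotation_max_deg: float = 25.0
    translation_max_mm: float = 15.0
    boundary_noise_sd_mm: float = 0.3
    landmark_noise_sd_mm: float = 0.5


@dataclass(frozen=True)
class SyntheticCase:
    """One paired phantom case plus its ground truth."""

    ct_volume: LabelVolume
    mri_volume: LabelVolume
    photo: BinarySilhouette
    landmarks_ct: LandmarkSet
    landmarks_mri: LandmarkSet
    truth: RigidTransform
    params: PhantomParams

    def sha256(self) -> str:
        """Digest of the fully serialised case (determinism check)."""
        h = hashlib.sha256()
        for vol in (self.ct_volume, self.mri_volume):
            h.update(np.ascontiguousarray(vol.voxels).tobytes())
            h.update(np.asarray([vol.spacing_mm], dtype=float).tobytes())
            h.update(np.ascontiguousarray(vol.origin_mm).tobytes())
        h.update(np.ascontiguousarray(self.photo.pixels).tobytes())
        h.update(np.ascontiguousarray(self.landmarks_ct.points).tobytes())
        h.update(np.ascontiguousarray(self.landmarks_mri.points).tobytes())
        h.update(np.ascontiguousarray(self.truth.matrix).tobytes())
        h.update(json.dumps(self.params.to_dict(), sort_keys=True).encode())
        return h.hexdigest()


# -- thickness-field construction ----------------------------------------

def _thickness_map(params: PhantomParams, x: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator):
    """Smoothed cartilage thickness field and MRI-side noise field on (x, y)."""
    xx, yy = np.meshgrid(x, y, indexing="ij")
    t = np.zeros_like(xx)
    for (cx, cy), R in zip(params.patch_centers, params.patch_radii_mm):
        r = np.hypot(xx - cx, yy - cy)
        profile = np.zeros_like(r)
        core = r <= _TAPER_START * R
        band = (r > _TAPER_START * R) & (r < R)
        profile[core] = 1.0
        s = (r[band] - _TAPER_START * R) / ((1.0 - _TAPER_START) * R)
        profile[band] = np.cos(0.5 * np.pi * s) ** 2
        t = np.maximum(t, params.base_thickness_mm * profile)
    sigma_px = _SMOOTH_SIGMA_MM / (x[1] - x[0])
    t = ndimage.gaussian_filter(t, sigma=sigma_px)
    # articular cartilage ends abruptly at its margin: terminate the smoothed
    # taper in a sharp step, so the footprint edge is stable under noise
    t[t < _RIM_CUT_FRAC * params.base_thickness_mm] = 0.0
    # smooth boundary-noise field (always drawn, to keep the rng stream fixed)
    white = rng.standard_normal(t.shape)
    noise = ndimage.gaussian_filter(white, sigma=_NOISE_CORR_MM / (x[1] - x[0]))
    sd = noise.std()
    noise = noise / sd * params.boundary_noise_sd_mm if sd > 0 else noise * 0.0
    # sharp full-thickness defects survive smoothing
    for (cx, cy, rad) in params.defect_specs:
        t[np.hypot(xx - cx, yy - cy) <= rad] = 0.0
    if not np.any(t >= CT_SPACING_MM / 2):
        raise ValueError("degenerate phantom: defects removed all cartilage")
    return t, noise


def generate_case(params: PhantomParams) -> SyntheticCase:
    """Generate one paired synthetic case (bit-deterministic under ``params.seed``)."""
    rng = np.random.default_rng(params.seed)
    ex, ey = params.plateau_extent_mm
    x = np.arange(-ex / 2 - _GRID_MARGIN_MM, ex / 2 + _GRID_MARGIN_MM, CT_SPACING_MM)
    y = np.arange(-ey / 2 - _GRID_MARGIN_MM, ey / 2 + _GRID_MARGIN_MM, CT_SPACING_MM)
    t, noise = _thickness_map(params, x, y, rng)

    # CT gold standard: indicator 0 <= z <= t(x, y), voxel centers at z = 0.1, 0.3, ...
    beta = params.thickness_bias
    t_top = max(t.max(), params.base_thickness_mm) + 2 * CT_SPACING_MM
    z = np.arange(CT_SPACING_MM / 2, t_top, CT_SPACING_MM)
    ct_fg = t[:, :, None] >= z[None, None, :]
    ct_volume = LabelVolume(ct_fg.astype(np.uint8), CT_SPACING_MM,
                            np.array([x[0], y[0], z[0]]), frame_id="CT")

    # MRI-side thickness field: multiplicative bias + smooth boundary noise,
    # confined to the true footprint
    t_mri = np.where(t > 0, np.clip(beta * t + noise, 0.0, None), 0.0)
    t_interp = RegularGridInterpolator((x, y), t_mri, bounds_error=False, fill_value=0.0)

    # MRI grid covers the cartilage mapped into the MRI frame (truth: MRI -> CT)
    inv = params.true_transform.inverse()
    corners_ct = np.array([[cx, cy, cz]
                           for cx in (x[0], x[-1])
                           for cy in (y[0], y[-1])
                           for cz in (0.0, t_top)])
    corners_mri = inv.apply(corners_ct)
    lo = corners_mri.min(axis=0) - 2.0
    hi = corners_mri.max(axis=0) + 2.0
    # snap voxel centers to half-spacing offsets so no center sits exactly on
    # the z = 0 cut plane (float-rounding there would drop a whole layer)
    lo = (np.floor(lo / MRI_SPACING_MM) + 0.5) * MRI_SPACING_MM
    axes_mri = [np.arange(lo[d], hi[d] + MRI_SPACING_MM, MRI_SPACING_MM) for d in range(3)]
    shape_mri = tuple(len(a) for a in axes_mri)
    mri_fg = np.zeros(shape_mri, dtype=bool)
    # map voxel centers to the CT frame slab-by-slab to bound memory
    gx, gy = np.meshgrid(axes_mri[0], axes_mri[1], indexing="ij")
    flat_xy = np.stack([gx.ravel(), gy.ravel()], axis=1)
    Rm = params.true_transform.rotation
    tm = params.true_transform.translation
    for k, zk in enumerate(axes_mri[2]):
        pts = np.concatenate([flat_xy, np.full((flat_xy.shape[0], 1), zk)], axis=1)
        ct_pts = pts @ Rm.T + tm
        zc = ct_pts[:, 2]
        cand = (zc >= 0.0) & (zc <= t_top)
        if not cand.any():
            continue
        tv = t_interp(ct_pts[cand, :2])
        fg = np.zeros(flat_xy.shape[0], dtype=bool)
        fg[cand] = (zc[cand] >= 0.0) & (zc[cand] <= tv) & (tv > 0)
        mri_fg[:, :, k] = fg.reshape(gx.shape)
    mri_volume = LabelVolume(mri_fg.astype(np.uint8), MRI_SPACING_MM,
                             np.array([axes_mri[0][0], axes_mri[1][0], axes_mri[2][0]]),
                             frame_id="MRI")

    # top-down specimen photograph: z-projection of the CT-frame cartilage
    footprint = ct_fg.any(axis=2)
    ratio = CT_SPACING_MM / params.photo_mm_per_px
    if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
        photo_px = np.kron(footprint, np.ones((int(round(ratio)),) * 2, dtype=bool))
    else:
        photo_px = ndimage.zoom(footprint.astype(np.uint8), ratio, order=0) > 0
    photo = BinarySilhouette(photo_px, params.photo_mm_per_px, provenance="photo")

    # six ordered landmarks in the CT frame; MRI-side copy gets measurement noise
    lm_ct = _place_landmarks(params, x, y, t)
    lm_noise = rng.normal(0.0, params.landmark_noise_sd_mm, size=(6, 3)) \
        if params.landmark_noise_sd_mm > 0 else np.zeros((6, 3))
    lm_mri = LandmarkSet(inv.apply(lm_ct.points) + lm_noise, LANDMARK_LABELS, "MRI")

    return SyntheticCase(ct_volume, mri_volume, photo, lm_ct, lm_mri,
                         params.true_transform, params)


def _place_landmarks(params: PhantomParams, x, y, t) -> LandmarkSet:
    ex, ey = params.plateau_extent_mm

    def height_at(px, py):
        i = int(np.clip(round((px - x[0]) / CT_SPACING_MM), 0, len(x) - 1))
        j = int(np.clip(round((py - y[0]) / CT_SPACING_MM), 0, len(y) - 1))
        return float(t[i, j])

    pts = []
    # anterior / posterior rim of the bony plateau (off-cartilage fiducials)
    pts.append([0.0, ey / 2, 0.0])
    for (cx, cy), R in zip(params.patch_centers, params.patch_radii_mm):
        for ang in (45.0, -45.0):
            px = cx + 0.6 * R * np.cos(np.deg2rad(ang))
            py = cy + 0.6 * R * np.sin(np.deg2rad(ang))
            pts.append([px, py, height_at(px, py)])
        if len(pts) == 3:       # posterior rim goes between the two patches
            pts.append([0.0, -ey / 2, 0.0])
    return LandmarkSet(np.asarray(pts, dtype=float), LANDMARK_LABELS, "CT")


# -- cohorts --------------------------------------------------------------

def _random_rigid(rng: np.random.Generator, rot_max_deg: float,
                  trans_max_mm: float) -> RigidTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, rot_max_deg)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    translation = direction * rng.uniform(0.0, trans_max_mm)
    return RigidTransform.from_axis_angle(axis, angle, translation)


def _draw_params(rng: np.random.Generator, ranges: CohortRanges,
                 base: PhantomParams, beta: float | None = None) -> PhantomParams:
    if beta is None:
        beta = rng.uniform(*ranges.beta_range)
    jitter = 1.0 + rng.uniform(-ranges.patch_radius_jitter_frac,
                               ranges.patch_radius_jitter_frac, size=2)
    radii = tuple(float(r * j) for r, j in zip(base.patch_radii_mm, jitter))
    thick = float(base.base_thickness_mm
                  * (1.0 + rng.uniform(-ranges.base_thickness_jitter_frac,
                                       ranges.base_thickness_jitter_frac)))
    n_def = int(rng.integers(ranges.n_defects_range[0], ranges.n_defects_range[1] + 1))
    defects = []
    for _ in range(n_def):
        which = int(rng.integers(0, len(base.patch_centers)))
        cx, cy = base.patch_centers[which]
        R = radii[which]
        off = rng.uniform(-0.5 * R, 0.5 * R, size=2)
        rad = rng.uniform(*ranges.defect_radius_mm_range)
        defects.append((float(cx + off[0]), float(cy + off[1]), float(rad)))
    truth = _random_rigid(rng, ranges.rotation_max_deg, ranges.translation_max_mm)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    return replace(base,
                   patch_radii_mm=radii,
                   base_thickness_mm=thick,
                   thickness_bias=float(beta),
                   defect_specs=tuple(defects),
                   boundary_noise_sd_mm=ranges.boundary_noise_sd_mm,
                   landmark_noise_sd_mm=ranges.landmark_noise_sd_mm,
                   true_transform=truth,
                   seed=seed)


def generate_cohort(n: int, ranges: CohortRanges | None = None, seed: int = 0,
                    base_params: PhantomParams | None = None,
                    beta: float | None = None) -> list[SyntheticCase]:
    """Generate ``n`` independent cases with per-case parameters drawn from ``ranges``.

    ``beta`` fixes the thickness bias across the whole cohort (otherwise it is
    drawn per case from ``ranges.beta_range``).  Reproducible bit-exactly under
    ``seed``.  At least two cases are required, since the downstream volume
    correlation is undefined for fewer.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 cases (Pearson correlation undefined)")
    ranges = ranges or CohortRanges()
    base = base_params or PhantomParams()
    rng = np.random.default_rng(seed)
    return [generate_case(_draw_params(rng, ranges, base, beta=beta)) for _ in range(n)]
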