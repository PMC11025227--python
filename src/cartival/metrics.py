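"""Overlap and association statistics.

The Dice similarity coefficient (DSC) between two binary masks A and B is
``2|A∩B| / (|A| + |B|)``, in [0, 1], 1 for identical non-empty masks.  The 3D
variant resamples the moving (MRI-frame) volume through the registration
transform onto the fixed (CT-frame) grid — the finer of the two, to minimise
resampling loss — and counts voxels there; the raw counts are always reported
so the quotient can be recomputed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core.geometry import resample_volume
from .core.types import BinarySilhouette, LabelVolume, RigidTransform

__all__ = ["OverlapResult", "dsc_2d", "dsc_3d", "cartilage_volume", "pearson_r"]


@dataclass(frozen=True)
class OverlapResult:
    """DSC plus the raw set counts it was computed from."""

    dsc: float
    intersection_count: int
    a_count: int
    b_count: int
    units: str  # "px" | "voxel"

    def __post_init__(self):
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError(f"DSC out of range: {self.dsc}")


def _overlap(a: np.ndarray, b: np.ndarray, units: str) -> OverlapResult:
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        raise ValueError("DSC is undefined for two empty masks (0/0)")
    ni = int(np.count_nonzero(a & b))
    return OverlapResult(2.0 * ni / (na + nb), ni, na, nb, units)


def dsc_2d(a: BinarySilhouette, b: BinarySilhouette) -> OverlapResult:
    """Pixel-wise DSC of two silhouettes on a common grid.

    Both inputs must share shape and pixel scale — use
    :func:`cartival.projection.align_silhouettes` first for images from
    different sources.  Symmetric in its arguments.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"silhouette shapes differ: {a.pixels.shape} vs {b.pixels.shape}; "
                         "align first")
    if abs(a.mm_per_px - b.mm_per_px) > 1e-9 * max(a.mm_per_px, b.mm_per_px):
        raise ValueError(f"pixel scales differ: {a.mm_per_px} vs {b.mm_per_px}; align first")
    return _overlap(a.pixels, b.pixels, "px")


def dsc_3d(a: LabelVolume, b: LabelVolume, T: RigidTransform,
           label: int = 1) -> OverlapResult:
    """Voxel-wise DSC of volume ``a`` registered onto volume ``b``.

    ``T`` maps the frame of ``a`` (the model under evaluation, e.g. MRI) onto
    the frame of ``b`` (the gold standard, e.g. CT); ``a`` is resampled with
    nearest-neighbour interpolation onto ``b``'s grid and compared there.
    """
    fa = a.voxels == label
    fb = b.voxels == label
    if not fa.any():
        raise ValueError("volume 'a' has empty foreground")
    if not fb.any():
        raise ValueError("volume 'b' has empty foreground")
    a_on_b = resample_volume(a, T, b)
    return _overlap(a_on_b.voxels == label, fb, "voxel")


def cartilage_volume(v: LabelVolume, label: int = 1) -> float:
    """Volume in mm^3 of ``label``: voxel count times spacing cubed.

    An absent label yields 0.0 with a warning (distinct from malformed input,
    which raises at construction time).
    """
    n = v.label_count(label)
    if n == 0:
        import warnings
        warnings.warn(f"label {label} absent from volume (frame {v.frame_id!r}); "
                      "volume is 0", stacklevel=2)
    return n * v.spacing_mm ** 3


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value (t, n-2 df).

    Requires equal-length samples of at least 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError(f"samples must be 1D and equal length, got {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant sample")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
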