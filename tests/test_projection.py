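"""Simulated photography: rectification symmetry, calibrated rendering,
binarization and silhouette alignment."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from cartival import (
    BinarySilhouette,
    CameraSpec,
    RigidTransform,
    SurfaceMesh,
    align_silhouettes,
    apply_transform,
    binarize_photo,
    dsc_2d,
    mask_to_mesh,
    pca_rectify,
    render_silhouette,
)
from cartival.projection import CanvasOverflowError
from conftest import random_rigid


def _box_mesh(extents=(30.0, 20.0, 4.0)) -> SurfaceMesh:
    tm = trimesh.creation.box(extents=extents)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _is_signed_permutation(R: np.ndarray) -> bool:
    return (np.allclose(np.abs(R), np.abs(R).round(), atol=1e-6)
            and np.allclose(np.sort(np.abs(R).ravel())[-3:], 1.0, atol=1e-6)
            and np.allclose(R @ R.T, np.eye(3), atol=1e-6))


def test_pca_rectify_axis_aligned_box_is_signed_permutation():
    _, T = pca_rectify(_box_mesh())
    assert _is_signed_permutation(T.rotation)


def test_pca_rectify_undoes_known_rotation_up_to_sign_symmetry(rng):
    box = _box_mesh()
    R = random_rigid(rng, max_angle_deg=170.0, max_trans_mm=30.0)
    rect, T = pca_rectify(apply_transform(R, box))
    combined = (T @ R).rotation  # original box frame -> rectified frame
    assert _is_signed_permutation(combined)
    ext = rect.vertices.max(axis=0) - rect.vertices.min(axis=0)
    assert np.allclose(ext, [30.0, 20.0, 4.0], atol=1e-6)


def test_pca_rectify_idempotent_and_diagonalises_covariance(moved_small_case):
    mesh = mask_to_mesh(moved_small_case.mri_volume)
    rect, _ = pca_rectify(mesh)
    Vc = rect.vertices - rect.vertices.mean(axis=0)
    cov = Vc.T @ Vc / len(Vc)
    off = cov - np.diag(np.diag(cov))
    assert np.abs(off).max() < 1e-6 * np.trace(cov)
    rect2, T2 = pca_rectify(rect)
    assert np.abs(T2.matrix - np.eye(4)).max() < 1e-6
    assert np.abs(rect2.vertices - rect.vertices).max() < 1e-6


def test_pca_rectify_rejects_coplanar_vertices():
    flat = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]),
                       np.array([[0, 1, 2], [1, 3, 2]]))
    with pytest.raises(ValueError, match="coplanar"):
        pca_rectify(flat)


def test_render_sphere_area_matches_analytic():
    tm = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    sil = render_silhouette(mesh, CameraSpec(mm_per_px=0.05))
    analytic = np.pi * 25.0
    assert abs(sil.area_mm2 - analytic) / analytic < 0.01


def test_render_empty_mesh_is_all_background():
    empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    sil = render_silhouette(empty)
    assert sil.foreground_count == 0


def test_render_area_invariant_under_inplane_rotation():
    box = _box_mesh()
    base = render_silhouette(box).area_mm2
    for ang in (20.0, 145.0):
        rot = apply_transform(RigidTransform.from_axis_angle([0, 0, 1], ang), box)
        area = render_silhouette(rot).area_mm2
        assert abs(area - base) / base < 0.01


def test_render_canvas_overflow_reports_required_size():
    with pytest.raises(CanvasOverflowError, match="30.0"):
        render_silhouette(_box_mesh(), CameraSpec(canvas_extent_mm=(10.0, 10.0)))


def test_grid_calibration_identity():
    cam = CameraSpec(mm_per_px=0.1, grid_pitch_mm=1.0)
    assert cam.grid_pitch_px == pytest.approx(10.0)


def test_orthographic_vs_pinhole_parallax_for_flat_specimen(ideal_small_case):
    """Silhouette boundary of a plateau lies near the grid plane, so the
    perspective error at 140 mm stays below 3% of the foreground."""
    mesh, _ = pca_rectify(mask_to_mesh(ideal_small_case.ct_volume))
    ortho = render_silhouette(mesh, CameraSpec(mode="orthographic"))
    pin = render_silhouette(mesh, CameraSpec(mode="pinhole"))
    pair = align_silhouettes(ortho, pin)
    xor = np.logical_xor(pair.a.pixels, pair.b.pixels).sum()
    assert xor / pair.a.pixels.sum() < 0.03


def test_pinhole_rejects_object_reaching_the_camera():
    tall = _box_mesh(extents=(10.0, 10.0, 400.0))
    with pytest.raises(ValueError, match="camera"):
        render_silhouette(tall, CameraSpec(mode="pinhole"))


def test_binarize_two_level_image_exact():
    img = np.zeros((20, 30)); img[5:15, 10:20] = 255.0
    sil = binarize_photo(img, threshold=128, mm_per_px=0.2)
    assert np.array_equal(sil.pixels, img > 128)
    assert sil.provenance == "photo"


def test_binarize_preserves_interior_holes():
    img = np.zeros((40, 40)); img[5:35, 5:35] = 255.0; img[15:25, 15:25] = 0.0
    sil = binarize_photo(img, threshold=128)
    assert not sil.pixels[20, 20]
    assert sil.pixels[6, 6]


def test_binarize_keeps_largest_component_only():
    img = np.zeros((40, 40)); img[2:30, 2:30] = 255.0; img[35:38, 35:38] = 255.0
    sil = binarize_photo(img, threshold=128)
    assert not sil.pixels[36, 36]


def test_binarize_otsu_matches_exhaustive_search(rng):
    a = rng.normal(60, 8, 600)
    b = rng.normal(190, 10, 400)
    img = np.concatenate([a, b]).clip(0, 255).reshape(25, 40)
    sil = binarize_photo(img, threshold="otsu")
    # brute-force inter-class variance maximisation over integer thresholds
    best_t, best_v = None, -1.0
    for t in range(1, 255):
        lo, hi = img[img <= t], img[img > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    assert np.array_equal(sil.pixels, img > best_t) or \
        abs((img > best_t).sum() - sil.foreground_count) <= 5


def test_binarize_empty_foreground_raises():
    with pytest.raises(ValueError, match="empty foreground"):
        binarize_photo(np.zeros((10, 10)), threshold=10)


@pytest.fixture
def blob():
    img = np.zeros((200, 120), bool)
    img[20:180, 30:90] = True
    img[30:80, 40:60] = False          # asymmetric hole
    return img


def test_align_recovers_translation(blob):
    a = BinarySilhouette(blob, 0.1, "photo")
    b = BinarySilhouette(np.roll(blob, (7, -9), axis=(0, 1)), 0.1, "photo")
    pair = align_silhouettes(a, b)
    assert dsc_2d(pair.a, pair.b).dsc > 0.999


@pytest.mark.parametrize("angle,floor", [(180.0, 0.999), (30.0, 0.97), (-50.0, 0.97)])
def test_align_recovers_rotation(blob, angle, floor):
    a = BinarySilhouette(blob, 0.1, "photo")
    rot = ndimage.rotate(blob.astype(np.uint8), angle, order=0, reshape=True) > 0
    pair = align_silhouettes(a, BinarySilhouette(rot, 0.1, "photo"))
    assert dsc_2d(pair.a, pair.b).dsc >= floor


def test_align_mixed_pixel_scales(blob):
    fine = np.kron(blob, np.ones((2, 2), bool))
    pair = align_silhouettes(BinarySilhouette(fine, 0.05, "photo"),
                             BinarySilhouette(blob, 0.1, "photo"))
    assert pair.mm_per_px == 0.05
    assert dsc_2d(pair.a, pair.b).dsc >= 0.98


def test_align_degenerate_disc_falls_back_to_centroid():
    yy, xx = np.mgrid[0:99, 0:99]
    disc = (xx - 49) ** 2 + (yy - 49) ** 2 <= 30 ** 2
    with pytest.warns(UserWarning, match="degenerate"):
        pair = align_silhouettes(BinarySilhouette(disc, 0.1, "photo"),
                                 BinarySilhouette(disc, 0.1, "photo"))
    assert pair.mode == "centroid-only"
    assert dsc_2d(pair.a, pair.b).dsc == 1.0


def test_align_empty_silhouette_raises(blob):
    empty = BinarySilhouette(np.zeros_like(blob), 0.1, "photo")
    with pytest.raises(ValueError, match="empty"):
        align_silhouettes(BinarySilhouette(blob, 0.1, "photo"), empty)
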