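"""Landmark alignment optimality and trimmed-ICP convergence/recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cartival import (
    ICPConfig,
    LandmarkSet,
    RigidTransform,
    icp_refine,
    landmark_align,
    surface_cloud,
)
from cartival.core.types import LabelVolume
from conftest import random_rigid, small_params


def test_landmark_align_identity_for_equal_sets(rng):
    pts = rng.uniform(-20, 20, (6, 3))
    res = landmark_align(pts, pts)
    assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-9
    assert res.rmsd_mm < 1e-9


@pytest.mark.parametrize("seed", range(8))
def test_landmark_align_recovers_exact_transform(seed):
    rng = np.random.default_rng(seed)
    src = rng.uniform(-30, 30, (6, 3))
    T = random_rigid(rng)
    res = landmark_align(src, T.apply(src))
    assert res.transform.geodesic_to(T) < 1e-9
    assert np.abs(res.transform.translation - T.translation).max() < 1e-9
    assert res.rmsd_mm < 1e-9


def _ssd(T: RigidTransform, src, dst) -> float:
    d = T.apply(src) - dst
    return float(np.sum(d * d))


@pytest.mark.parametrize("seed", range(5))
def test_landmark_align_matches_iterative_minimizer_under_noise(seed):
    """Closed-form solution agrees with an independent numerical optimiser."""
    rng = np.random.default_rng(100 + seed)
    src = rng.uniform(-30, 30, (6, 3))
    T = random_rigid(rng)
    dst = T.apply(src) + rng.normal(0, 0.5, (6, 3))
    closed = landmark_align(src, dst)

    def objective(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return float(np.sum((src @ R.T + x[3:] - dst) ** 2))

    best = np.inf
    for trial in range(6):
        x0 = np.concatenate([rng.normal(0, 1.5, 3), rng.normal(0, 10, 3)])
        r = minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, r.fun)
    assert _ssd(closed.transform, src, dst) <= best + 1e-6


def test_landmark_align_never_beaten_by_random_candidates(rng):
    src = rng.uniform(-30, 30, (6, 3))
    T = random_rigid(rng)
    dst = T.apply(src) + rng.normal(0, 0.5, (6, 3))
    closed = landmark_align(src, dst)
    ssd0 = _ssd(closed.transform, src, dst)
    for _ in range(300):
        assert _ssd(random_rigid(rng), src, dst) >= ssd0 - 1e-9


def test_landmark_align_rejects_collinear_points():
    line = np.outer(np.arange(6.0), [1.0, 0.5, -0.2])
    with pytest.raises(ValueError, match="collinear"):
        landmark_align(line, line + 1.0)


def test_landmark_align_enforces_proper_rotation_on_mirrored_data(rng):
    src = rng.uniform(-10, 10, (6, 3))
    dst = src * np.array([-1.0, 1.0, 1.0])     # reflection
    with pytest.warns(UserWarning, match="reflection"):
        res = landmark_align(src, dst)
    assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)


def test_landmark_align_accepts_landmark_sets(rng):
    pts = rng.uniform(-20, 20, (6, 3))
    T = random_rigid(rng)
    res = landmark_align(LandmarkSet(pts, frame_id="MRI"),
                         LandmarkSet(T.apply(pts), frame_id="CT"))
    assert res.transform.geodesic_to(T) < 1e-9


def test_icp_trivial_case_converges_immediately(rng):
    cloud = rng.uniform(-10, 10, (500, 3))
    res = icp_refine(cloud, cloud, RigidTransform.identity())
    assert res.diagnostics.termination == "converged"
    assert res.diagnostics.n_iterations <= 2
    assert res.diagnostics.final_rms_distance_mm < 1e-12


def test_icp_rejects_non_finite_and_empty_clouds(rng):
    cloud = rng.uniform(-1, 1, (50, 3))
    bad = cloud.copy(); bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        icp_refine(bad, cloud)
    with pytest.raises(ValueError, match="non-empty"):
        icp_refine(np.zeros((0, 3)), cloud)


def test_icp_recovers_truth_from_perturbed_init(moved_small_case):
    """Noise-free plateau surfaces, init off by ~10 deg / 5 mm."""
    case = moved_small_case
    src = surface_cloud(case.mri_volume, 5000, seed=0)
    dst = surface_cloud(case.ct_volume, 5000, seed=1)
    pert = RigidTransform.from_axis_angle([0, 1, 0], 9.0, [3.0, 1.0, -2.0])
    res = icp_refine(src, dst, pert @ case.truth)
    assert res.transform.geodesic_to(case.truth) < 1.0
    assert np.linalg.norm(res.transform.translation - case.truth.translation) < 0.2
    d = res.diagnostics.rms_distance_mm
    assert all(d[i + 1] <= d[i] + 1e-12 for i in range(len(d) - 1))


def test_icp_far_init_lands_in_flagged_local_optimum():
    """A 180-degree-off init on a medially/laterally asymmetric plateau sticks
    in a local optimum; the residual exposes the failure (no silent success)."""
    from cartival import generate_case
    params = small_params(seed=21, patch_radii_mm=(9.0, 5.5),
                          boundary_noise_sd_mm=0.0, landmark_noise_sd_mm=0.0)
    case = generate_case(params)
    src = surface_cloud(case.mri_volume, 3000, seed=0)
    dst = surface_cloud(case.ct_volume, 3000, seed=1)
    good = icp_refine(src, dst, RigidTransform.identity())
    far = icp_refine(src, dst, RigidTransform.from_axis_angle([0, 0, 1], 180.0))
    assert far.transform.geodesic_to(case.truth) > 90.0
    assert far.diagnostics.final_rms_distance_mm > \
        2 * good.diagnostics.final_rms_distance_mm


def test_surface_cloud_points_lie_on_cube_surface():
    n, s = 12, 0.4
    v = np.zeros((n + 4,) * 3, np.uint8)
    v[2:2 + n, 2:2 + n, 2:2 + n] = 1
    vol = LabelVolume(v, s, -s * np.array([2.0, 2.0, 2.0]))
    pts = surface_cloud(vol, 2000, seed=3)
    lo, hi = -s / 2, n * s - s / 2     # iso-surface is half a voxel outside centers
    inside = np.clip(pts, lo, hi)
    face_dist = np.min(np.minimum(np.abs(pts - lo), np.abs(pts - hi)), axis=1)
    assert np.abs(pts - inside).max() < 1e-6   # float32 mesh vertices
    assert face_dist.max() < s / 2 + 1e-6


def test_surface_cloud_determinism_and_oversampling(ideal_small_case):
    vol = ideal_small_case.ct_volume
    a = surface_cloud(vol, 100, seed=5)
    b = surface_cloud(vol, 100, seed=5)
    assert np.array_equal(a, b)
    many = surface_cloud(vol, 10 ** 6 // 4, seed=5)
    assert many.shape == (10 ** 6 // 4, 3)


def test_icp_config_validation():
    with pytest.raises(ValueError):
        ICPConfig(max_iter=0)
    with pytest.raises(ValueError):
        ICPConfig(outlier_trim_fraction=0.6)
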