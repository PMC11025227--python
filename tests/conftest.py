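import numpy as np
import pytest

from cartival import PhantomParams, RigidTransform, generate_case

#: scaled-down plateau used by unit tests (fast: ~0.03 s to generate)
SMALL_GEOMETRY = dict(
    plateau_extent_mm=(36.0, 26.0),
    patch_centers=((-9.0, 0.0), (9.0, 0.0)),
    patch_radii_mm=(8.0, 7.0),
)


def small_params(**overrides) -> PhantomParams:
    kw = dict(SMALL_GEOMETRY)
    kw.update(overrides)
    return PhantomParams(**kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture(scope="session")
def ideal_small_case():
    """Noise-free, unbiased, identity-transform small phantom."""
    return generate_case(small_params(seed=5, boundary_noise_sd_mm=0.0,
                                      landmark_noise_sd_mm=0.0))


@pytest.fixture(scope="session")
def moved_small_case():
    """Noise-free small phantom under a known non-trivial rigid motion."""
    T = RigidTransform.from_axis_angle([1.0, 0.5, 0.2], 15.0, [4.0, -6.0, 2.0])
    return generate_case(small_params(seed=11, true_transform=T,
                                      boundary_noise_sd_mm=0.0,
                                      landmark_noise_sd_mm=0.0))


def random_rigid(rng, max_angle_deg=180.0, max_trans_mm=20.0) -> RigidTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    t = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    return RigidTransform.from_axis_angle(axis, angle, t)
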