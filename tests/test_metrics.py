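"""Dice and correlation statistics against brute-force set counting."""

import numpy as np
import pytest

from cartival import (
    BinarySilhouette,
    LabelVolume,
    RigidTransform,
    cartilage_volume,
    dsc_2d,
    dsc_3d,
    pearson_r,
    resample_volume,
)


def _sil(px):
    return BinarySilhouette(px, 0.1, "photo")


def test_dsc2d_worked_example():
    a = np.zeros((4, 4), bool); a[0, :4] = True          # |A| = 4
    b = np.zeros((4, 4), bool); b[0, :2] = True          # |B| = 2, overlap 2
    res = dsc_2d(_sil(a), _sil(b))
    assert res.dsc == pytest.approx(2 * 2 / (4 + 2))
    assert (res.intersection_count, res.a_count, res.b_count) == (2, 4, 2)
    assert res.units == "px"


def test_dsc2d_self_disjoint_and_symmetry(rng):
    a = rng.random((20, 20)) > 0.5
    b = rng.random((20, 20)) > 0.5
    assert dsc_2d(_sil(a), _sil(a)).dsc == 1.0
    assert dsc_2d(_sil(a), _sil(~a)).dsc == 0.0
    assert dsc_2d(_sil(a), _sil(b)).dsc == dsc_2d(_sil(b), _sil(a)).dsc


def test_dsc2d_brute_force_equivalence(rng):
    """DSC equals explicit set counting over coordinates, to 1e-12."""
    for _ in range(50):
        a = rng.random((8, 8)) > rng.uniform(0.2, 0.8)
        b = rng.random((8, 8)) > rng.uniform(0.2, 0.8)
        if not (a.any() or b.any()):
            continue
        sa = {tuple(i) for i in np.argwhere(a)}
        sb = {tuple(i) for i in np.argwhere(b)}
        expected = 2 * len(sa & sb) / (len(sa) + len(sb))
        assert abs(dsc_2d(_sil(a), _sil(b)).dsc - expected) < 1e-12


def test_dsc2d_errors():
    empty = np.zeros((5, 5), bool)
    with pytest.raises(ValueError, match="empty"):
        dsc_2d(_sil(empty), _sil(empty))
    full = ~empty
    with pytest.raises(ValueError, match="shapes"):
        dsc_2d(_sil(full), _sil(np.ones((4, 5), bool)))
    with pytest.raises(ValueError, match="scales"):
        dsc_2d(_sil(full), BinarySilhouette(full, 0.2, "photo"))


def _vol(mask, spacing=0.2, origin=(0.0, 0.0, 0.0)):
    return LabelVolume(mask.astype(np.uint8), spacing, np.array(origin), "CT")


def test_dsc3d_identity_same_grid_is_one(rng):
    m = rng.random((10, 10, 10)) > 0.5
    if not m.any():
        m[0, 0, 0] = True
    res = dsc_3d(_vol(m), _vol(m), RigidTransform.identity())
    assert res.dsc == 1.0
    assert res.units == "voxel"


def test_dsc3d_degrades_strictly_under_shift():
    slab = np.zeros((60, 60, 30), bool)
    slab[5:55, 5:55, 2:27] = True                    # 5 mm-thick slab at 0.2 mm
    v = _vol(slab)
    shifted = RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
    d0 = dsc_3d(v, v, RigidTransform.identity()).dsc
    d1 = dsc_3d(v, v, shifted).dsc
    assert d0 == 1.0
    assert d1 < d0


def test_dsc3d_empty_foreground_raises():
    m = np.zeros((5, 5, 5), bool)
    f = m.copy(); f[2, 2, 2] = True
    with pytest.raises(ValueError, match="empty foreground"):
        dsc_3d(_vol(m), _vol(f), RigidTransform.identity())


def test_dsc_erosion_monotone():
    from scipy import ndimage
    m = np.zeros((40, 40, 40), bool)
    m[5:35, 5:35, 5:35] = True
    v = _vol(m)
    prev = 1.0
    eroded = m
    for _ in range(4):
        eroded = ndimage.binary_erosion(eroded)
        d = dsc_3d(_vol(eroded), v, RigidTransform.identity()).dsc
        assert d < prev
        prev = d


def test_cartilage_volume_arithmetic_and_absent_label():
    m = np.zeros((20, 20, 20), np.uint8)
    m.ravel()[:1000] = 1
    assert cartilage_volume(_vol(m)) == pytest.approx(1000 * 0.008)
    with pytest.warns(UserWarning, match="absent"):
        assert cartilage_volume(_vol(np.zeros((4, 4, 4), np.uint8))) == 0.0


def test_volume_invariant_under_rigid_resample(rng):
    m = np.zeros((40, 40, 40), np.uint8)
    m[10:30, 10:30, 10:30] = 1
    v = _vol(m, spacing=0.2, origin=(-4.0, -4.0, -4.0))
    T = RigidTransform.from_axis_angle([1, 1, 0], 15.0, [0.3, -0.2, 0.1])
    big = LabelVolume(np.zeros((80, 80, 80), np.uint8), 0.2,
                      np.array([-8.0, -8.0, -8.0]), "CT")
    out = resample_volume(v, T, big)
    side = 20 * 0.2
    assert abs(cartilage_volume(out) - cartilage_volume(v)) <= 6 * side ** 2 * 0.2


def test_pearson_perfect_linear_relations():
    x = np.arange(10.0)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0, abs=1e-12)
    r2, _ = pearson_r(x, -x)
    assert r2 == pytest.approx(-1.0, abs=1e-12)
    assert p < 1e-6


def test_pearson_matches_definitional_formula():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 6])
    r, _ = pearson_r(x, y)
    expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert abs(r - expected) < 1e-12


def test_pearson_affine_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r0, _ = pearson_r(x, y)
    r1, _ = pearson_r(3.5 * x + 7.0, y)
    r2, _ = pearson_r(x, 0.1 * y - 2.0)
    assert abs(r1 - r0) < 1e-12
    assert abs(r2 - r0) < 1e-12


def test_pearson_input_validation():
    with pytest.raises(ValueError, match="constant"):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="equal length"):
        pearson_r([1.0, 2.0, 3.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="at least 3"):
        pearson_r([1.0, 2.0], [3.0, 4.0])
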