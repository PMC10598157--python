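"""Voxel masses, CoM, inertia tensors, parallel axis, principal moments."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctbsp.calibration import DensityCalibration
from ctbsp.ct_io import CTVolume, VoxelMask
from ctbsp.errors import DegenerateDensityError
from ctbsp.inertial import (
    InertiaTensor,
    MassMap,
    center_of_mass,
    compute_voxel_masses,
    inertia_tensor_about,
    principal_moments,
    segment_mass_volume,
    translate_inertia_to_com,
)

# identity-like calibration: density == HU + 1000 on both segments
IDENT_CAL = DensityCalibration(0.0, 1.0, 1000.0, 1.0, 1000.0)


def _mask_volume(hu_values, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(hu_values, dtype=float)
    vol = CTVolume(data=data, spacing=np.asarray(spacing))
    return vol, VoxelMask(np.ones(data.shape, bool), vol)


def test_single_water_voxel_is_one_milligram():
    vol, mask = _mask_volume(np.zeros((1, 1, 1)))
    mm = compute_voxel_masses(vol, mask, IDENT_CAL)
    assert mm.masses[0] == pytest.approx(1e-6, rel=1e-12)


def test_air_voxels_get_mean_tissue_density():
    vol, mask = _mask_volume(np.array([0.0, 40.0, -900.0]).reshape(1, 1, 3))
    mm = compute_voxel_masses(vol, mask, IDENT_CAL, air_threshold=-500.0)
    # tissues at 1000 and 1040 kg/m^3 -> air voxel assigned 1020
    assert mm.masses[2] == pytest.approx(1020e-9, rel=1e-12)
    assert len(mm.masses) == 3  # air voxel still counts toward volume


def test_all_air_mask_raises():
    vol, mask = _mask_volume(np.full((2, 2, 2), -950.0))
    with pytest.raises(DegenerateDensityError):
        compute_voxel_masses(vol, mask, IDENT_CAL)


def test_total_mass_matches_per_voxel_oracle(rng):
    hu = rng.uniform(-400, 1500, (6, 7, 8))
    vol = CTVolume(data=hu, spacing=np.array([0.5, 0.7, 1.1]))
    mask = VoxelMask(rng.random(hu.shape) > 0.4, vol)
    mm = compute_voxel_masses(vol, mask, IDENT_CAL)
    expected = 0.0
    vv = 0.5 * 0.7 * 1.1
    for idx in np.argwhere(mask.data):
        expected += (hu[tuple(idx)] + 1000.0) * vv * 1e-9
    assert mm.masses.sum() == pytest.approx(expected, rel=1e-12)


def test_segment_mass_volume_units():
    mm = MassMap(masses=np.full(1000, 1e-6), positions=np.zeros((1000, 3)), voxel_volume_mm3=1.0)
    mass_g, vol_cm3 = segment_mass_volume(mm)
    assert mass_g == pytest.approx(1.0)
    assert vol_cm3 == pytest.approx(1.0)
    empty = MassMap(np.zeros(0), np.zeros((0, 3)), 1.0)
    assert segment_mass_volume(empty) == (0.0, 0.0)


def test_uniform_ellipsoid_mass_within_one_percent():
    a, b, c = 30.0, 20.0, 15.0
    sp = 0.5
    ax = np.arange(-32, 32.01, sp)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    rho = 1050.0
    mass = inside.sum() * sp**3 * 1e-9 * rho * 1e3  # g
    analytic = rho * 4 / 3 * np.pi * a * b * c * 1e-9 * 1e3
    assert mass == pytest.approx(analytic, rel=0.01)


def test_center_of_mass_cases():
    # uniform cube -> geometric center
    mm = MassMap(
        masses=np.ones(8),
        positions=np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float),
        voxel_volume_mm3=1.0,
    )
    np.testing.assert_allclose(center_of_mass(mm), [0.5, 0.5, 0.5])
    # masses (m, 2m) at x = 0 and 3 -> xbar = 2
    mm2 = MassMap(np.array([1.0, 2.0]), np.array([[0.0, 0, 0], [3.0, 0, 0]]), 1.0)
    assert center_of_mass(mm2)[0] == pytest.approx(2.0)
    with pytest.raises(DegenerateDensityError):
        center_of_mass(MassMap(np.zeros(2), np.zeros((2, 3)), 1.0))


def test_offset_core_composite_centroid():
    """Two-material sphere: dense offset core shifts the CoM analytically."""
    sp = 0.5
    ax = np.arange(-20, 20.01, sp)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    outer = X**2 + Y**2 + Z**2 <= 15.0**2
    core = (X - 5.0) ** 2 + Y**2 + Z**2 <= 5.0**2
    rho = np.where(core, 2000.0, 1000.0)
    masses = (rho * sp**3 * 1e-9)[outer]
    pts = np.column_stack([X[outer], Y[outer], Z[outer]])
    com = center_of_mass(MassMap(masses, pts, sp**3))
    m_out = 1000.0 * 4 / 3 * np.pi * 15.0**3
    m_core_extra = 1000.0 * 4 / 3 * np.pi * 5.0**3  # density excess * core volume
    expected_x = (m_core_extra * 5.0) / (m_out + m_core_extra)
    assert abs(com[0] - expected_x) < 0.5 * sp
    assert abs(com[1]) < 0.5 * sp and abs(com[2]) < 0.5 * sp


def test_point_mass_tensor():
    mm = MassMap(np.array([1.0]), np.array([[0.0, 100.0, 0.0]]), 1.0)
    t = inertia_tensor_about(mm, np.zeros(3))
    np.testing.assert_allclose(np.diag(t.components), [100.0, 0.0, 100.0], atol=1e-12)
    assert np.abs(t.components - np.diag(np.diag(t.components))).max() < 1e-12


def test_mirrored_masses_cancel_products_of_inertia():
    mm = MassMap(
        np.array([1.0, 1.0]),
        np.array([[3.0, 4.0, 5.0], [3.0, -4.0, 5.0]]),
        1.0,
    )
    t = inertia_tensor_about(mm, np.zeros(3))
    assert t.components[0, 1] == pytest.approx(0.0, abs=1e-12)  # I_xy
    assert t.components[1, 2] == pytest.approx(0.0, abs=1e-12)  # I_yz


def test_tensor_matches_brute_force_oracle(rng):
    m = rng.uniform(1e-6, 1e-3, 50)
    p = rng.normal(0, 80, (50, 3))
    about = rng.normal(0, 10, 3)
    t = inertia_tensor_about(MassMap(m, p, 1.0), about)
    oracle = np.zeros((3, 3))
    for mi, pi in zip(m, p):
        x, y, z = pi - about
        oracle += mi * np.array(
            [
                [y * y + z * z, -x * y, -x * z],
                [-x * y, x * x + z * z, -y * z],
                [-x * z, -y * z, x * x + y * y],
            ]
        )
    np.testing.assert_allclose(t.components, oracle * 1e-2, rtol=1e-9)


def test_parallel_axis_identities(rng):
    m = rng.uniform(1e-6, 1e-3, 200)
    p = rng.normal(0, 60, (200, 3))
    mm = MassMap(m, p, 1.0)
    com = center_of_mass(mm)
    t_origin = inertia_tensor_about(mm, np.zeros(3))
    t_translated = translate_inertia_to_com(t_origin, m.sum(), com)
    t_direct = inertia_tensor_about(mm, com)
    np.testing.assert_allclose(t_translated.components, t_direct.components, rtol=1e-9)
    # translating back recovers the origin tensor
    back = translate_inertia_to_com(
        InertiaTensor(t_translated.components + (m.sum() * (com @ com * np.eye(3) - np.outer(com, com)) * 1e-2), about=np.zeros(3)),
        m.sum(),
        np.zeros(3),
    )
    np.testing.assert_allclose(back.components, t_origin.components, rtol=1e-9)
    # zero displacement and self-translation of a point mass
    np.testing.assert_allclose(
        translate_inertia_to_com(t_origin, m.sum(), np.zeros(3)).components,
        t_origin.components,
    )
    pt = MassMap(np.array([2.0]), np.array([[7.0, -3.0, 2.0]]), 1.0)
    t_pt = translate_inertia_to_com(
        inertia_tensor_about(pt, np.zeros(3)), 2.0, np.array([7.0, -3.0, 2.0])
    )
    np.testing.assert_allclose(t_pt.components, np.zeros((3, 3)), atol=1e-12)


def test_principal_moments_sorting_and_sphere():
    moments, axes = principal_moments(InertiaTensor(np.diag([3.0, 1.0, 2.0])))
    np.testing.assert_allclose(moments, [1.0, 2.0, 3.0])
    np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-12)
    # uniform solid sphere, 1 kg, 0.1 m: (2/5) m R^2 = 4e-3 kg m^2 = 40 kg cm^2
    mm = 1.0
    R_mm = 100.0
    I = 0.4 * mm * R_mm**2 * 1e-2
    moments, _ = principal_moments(InertiaTensor(np.eye(3) * I))
    np.testing.assert_allclose(moments, [40.0, 40.0, 40.0])


def test_constructed_spectrum_recovered(rng):
    R = Rotation.random(random_state=5).as_matrix()
    if np.linalg.det(R) < 0:
        R[:, 0] = -R[:, 0]
    target = np.array([2.0, 5.0, 9.0])
    tensor = InertiaTensor(R @ np.diag(target) @ R.T)
    moments, axes = principal_moments(tensor)
    np.testing.assert_allclose(moments, target, atol=1e-8)
    for i in range(3):
        dot = abs(axes[i] @ R[:, i])
        assert dot == pytest.approx(1.0, abs=1e-8)


def test_principal_moments_rotation_invariant(rng):
    m = rng.uniform(1e-6, 1e-3, 300)
    p = rng.normal(0, 50, (300, 3))
    mm = MassMap(m, p, 1.0)
    com = center_of_mass(mm)
    base, _ = principal_moments(inertia_tensor_about(mm, com))
    T = Rotation.random(random_state=9).as_matrix()
    mm_rot = MassMap(m, p @ T.T, 1.0)
    rot, _ = principal_moments(inertia_tensor_about(mm_rot, center_of_mass(mm_rot)))
    np.testing.assert_allclose(rot, base, rtol=1e-6)


def test_mass_conservation_over_partition(rng):
    m = rng.uniform(1e-6, 1e-3, 100)
    p = rng.normal(0, 50, (100, 3))
    total = segment_mass_volume(MassMap(m, p, 2.0))[0]
    half = segment_mass_volume(MassMap(m[:50], p[:50], 2.0))[0]
    rest = segment_mass_volume(MassMap(m[50:], p[50:], 2.0))[0]
    assert total == pytest.approx(half + rest, rel=1e-12)


def test_voxelized_ellipsoid_moments_converge():
    """Principal moments of a uniform ellipsoid approach m/5*(b^2+c^2) etc.
    monotonically as the grid is refined."""
    a, b, c = 30.0, 20.0, 15.0
    rho = 1050.0
    m_kg = rho * 4 / 3 * np.pi * a * b * c * 1e-9
    analytic = np.sort(m_kg / 5.0 * np.array([b*b + c*c, a*a + c*c, a*a + b*b]) * 1e-2)
    errs = []
    for sp in (2.0, 1.0, 0.5):
        ax = np.arange(-31.0 + sp / 2, 31.0, sp)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
        masses = np.full(int(inside.sum()), rho * sp**3 * 1e-9)
        pts = np.column_stack([X[inside], Y[inside], Z[inside]])
        mm = MassMap(masses, pts, sp**3)
        moments, _ = principal_moments(inertia_tensor_about(mm, center_of_mass(mm)))
        errs.append(np.max(np.abs(moments - analytic) / analytic))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 0.02
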