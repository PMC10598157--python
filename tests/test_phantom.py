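"""Analytic solids oracle, phantom voxelization, and cohort generator."""

import numpy as np
import pytest

from ctbsp.ct_io import LandmarkSet
from ctbsp.errors import UnsupportedGeometryError
from ctbsp.phantom import (
    BACKGROUND_HU,
    PhantomSpec,
    PrimitiveSpec,
    analytic_properties,
    generate_cohort,
    generate_phantom,
    noise_sd_for_r_squared,
    pig_like_phantom,
)
from ctbsp.summary_stats import linear_fit


def _spec(primitives, regions, extent=((-60, -60, -60), (60, 60, 60)), **kw):
    return PhantomSpec(
        primitives=primitives,
        spacing=(1.0, 1.0, 1.0),
        extent=extent,
        landmarks=LandmarkSet(entries={}),
        regions=regions,
        **kw,
    )


def test_sphere_mass_closed_form():
    spec = _spec(
        [PrimitiveSpec("s", "sphere", (0, 0, 0), (50.0,), 1000.0)], {"all": ["s"]}
    )
    props = analytic_properties(spec, "all")
    assert props.mass_kg == pytest.approx(4 / 3 * np.pi * 0.05**3 * 1000.0, rel=1e-12)
    assert props.mass_kg == pytest.approx(0.5236, abs=5e-5)


def test_symmetric_sphere_pair_com_at_origin():
    spec = _spec(
        [
            PrimitiveSpec("a", "sphere", (-20, 0, 0), (10.0,), 1200.0),
            PrimitiveSpec("b", "sphere", (20, 0, 0), (10.0,), 1200.0),
        ],
        {"all": ["a", "b"]},
    )
    np.testing.assert_allclose(analytic_properties(spec, "all").com, np.zeros(3), atol=1e-12)


def test_ellipsoid_moments_match_fine_grid_numeric_oracle():
    a, b, c = 60.0, 40.0, 30.0
    rho = 1050.0
    spec = _spec(
        [PrimitiveSpec("e", "ellipsoid", (0, 0, 0), (a, b, c), rho)], {"all": ["e"]},
        extent=((-62, -42, -32), (62, 42, 32)),
    )
    props = analytic_properties(spec, "all")
    # independent numeric oracle: voxel summation at 0.25 mm, slab by slab
    sp = 0.25
    xs = np.arange(-a - sp, a + sp, sp) + sp / 2
    ys = np.arange(-b - sp, b + sp, sp) + sp / 2
    zs = np.arange(-c - sp, c + sp, sp) + sp / 2
    Y, Z = np.meshgrid(ys, zs, indexing="ij")
    mass = 0.0
    Ixx = Iyy = Izz = 0.0
    for x in xs:
        inside = (x / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
        n = inside.sum()
        if n == 0:
            continue
        dm = rho * sp**3 * 1e-9
        y2 = (Y[inside] ** 2).sum()
        z2 = (Z[inside] ** 2).sum()
        mass += n * dm
        Ixx += dm * (y2 + z2)
        Iyy += dm * (n * x * x + z2)
        Izz += dm * (n * x * x + y2)
    numeric = np.sort(np.array([Ixx, Iyy, Izz])) * 1e-2
    np.testing.assert_allclose(props.principal_moments_kg_cm2, numeric, rtol=2e-3)
    assert props.mass_kg == pytest.approx(mass, rel=2e-3)


def test_shell_primitive_equals_sphere_difference():
    shell = _spec(
        [PrimitiveSpec("sh", "spherical_shell", (5, -3, 2), (20.0, 15.0), 1700.0)],
        {"all": ["sh"]},
    )
    composite = _spec(
        [
            PrimitiveSpec("outer", "sphere", (5, -3, 2), (20.0,), 1700.0),
            PrimitiveSpec("inner", "sphere", (5, -3, 2), (15.0,), 0.0),
        ],
        {"all": ["outer"]},
    )
    a = analytic_properties(shell, "all")
    b = analytic_properties(composite, "all")
    assert a.mass_kg == pytest.approx(b.mass_kg, rel=1e-12)
    np.testing.assert_allclose(a.com, b.com, atol=1e-9)
    np.testing.assert_allclose(
        a.inertia_at_com.components, b.inertia_at_com.components, rtol=1e-12, atol=1e-15
    )


def test_partial_overlap_is_rejected():
    spec = _spec(
        [
            PrimitiveSpec("a", "sphere", (0, 0, 0), (20.0,), 1000.0),
            PrimitiveSpec("b", "sphere", (25, 0, 0), (10.0,), 1200.0),
        ],
        {"all": ["a", "b"]},
    )
    with pytest.raises(UnsupportedGeometryError):
        analytic_properties(spec, "all")


def test_noise_free_sphere_has_two_hu_values(exact_calibration):
    spec = _spec(
        [PrimitiveSpec("s", "sphere", (0, 0, 0), (25.0,), 1040.0)],
        {"all": ["s"]},
        extent=((-30, -30, -30), (30, 30, 30)),
    )
    vol, _ = generate_phantom(spec, exact_calibration)
    values = np.unique(vol.data)
    assert len(values) == 2
    assert BACKGROUND_HU in values


def test_generation_is_deterministic(exact_calibration):
    spec = pig_like_phantom(spacing=4.0, hu_noise_sd=10.0, seed=42)
    v1, _ = generate_phantom(spec, exact_calibration)
    v2, _ = generate_phantom(spec, exact_calibration)
    np.testing.assert_array_equal(v1.data, v2.data)
    v3, _ = generate_phantom(pig_like_phantom(spacing=4.0, hu_noise_sd=10.0, seed=43), exact_calibration)
    assert not np.array_equal(v1.data, v3.data)


def test_pig_phantom_regions_and_scale():
    spec = pig_like_phantom()
    head = analytic_properties(spec, "head")
    brain = analytic_properties(spec, "brain")
    assert 1.5 < head.mass_kg < 3.0    # pre-adolescent pig head scale
    assert 0.08 < brain.mass_kg < 0.13  # ~100 g brain
    # head inertia must dominate the brain's by orders of magnitude
    assert head.principal_moments_kg_cm2[0] > 50 * brain.principal_moments_kg_cm2[2]


def test_phantom_yaml_round_trip(tmp_path):
    spec = pig_like_phantom(spacing=2.0, hu_noise_sd=3.0, seed=7)
    back = PhantomSpec.from_yaml(spec.to_yaml(tmp_path / "spec.yaml"))
    assert [p.name for p in back.primitives] == [p.name for p in spec.primitives]
    for p, q in zip(spec.primitives, back.primitives):
        np.testing.assert_allclose(p.c, q.c)
        np.testing.assert_allclose(p.R, q.R)
        assert p.dimensions == q.dimensions and p.density == q.density
    assert back.hu_noise_sd == 3.0 and back.seed == 7
    np.testing.assert_allclose(back.landmarks["RZ"], spec.landmarks["RZ"])


def test_cohort_noise_free_recovers_line_exactly():
    df = generate_cohort(20, slope=75.0, intercept=100.0, noise_sd=0.0, seed=1)
    fit = linear_fit(df["body_mass_kg"], df["tissue_mass_g"])
    assert fit.slope == pytest.approx(75.0, rel=1e-9)
    assert fit.intercept == pytest.approx(100.0, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_cohort_deterministic_and_in_range():
    a = generate_cohort(50, 75.0, 100.0, 150.0, seed=3)
    b = generate_cohort(50, 75.0, 100.0, 150.0, seed=3)
    assert a.equals(b)
    assert a["body_mass_kg"].between(18, 48).all()


def test_noise_calibration_targets_r_squared():
    """sd from the variance decomposition yields the requested r^2."""
    slope, target = 75.0, 0.93
    sd = noise_sd_for_r_squared(slope, target)
    fits = [
        linear_fit(*generate_cohort(200, slope, 100.0, sd, seed=s).T.values)
        for s in range(100)
    ]
    mean_r2 = np.mean([f.r_squared for f in fits])
    assert abs(mean_r2 - target) < 0.05
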