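"""Geometric projector, attenuation weights, detector blur, subsets and
acquisition simulation."""

import math

import numpy as np
import pytest

from prcrecon.kernels import profile_fwhm
from prcrecon.phantoms import make_nema_iq
from prcrecon.projector import (
    PRModel,
    ProjectionData,
    ScannerGeometry,
    attenuation_factors,
    back_project,
    detector_blur,
    forward_project,
    partition_subsets,
    plane_system_matrix,
    simulate_acquisition,
)
from prcrecon.volume import ImageVolume


@pytest.fixture(scope="module")
def geom():
    return ScannerGeometry(n_angles=12, n_radial=16, radial_spacing=2.0, n_planes=4)


# ---------------------------------------------------------------------------
# X and its transpose
# ---------------------------------------------------------------------------


def test_zero_image_projects_to_zero(geom):
    proj = forward_project(geom.image_template(), geom)
    assert not proj.values.any()
    img = back_project(ProjectionData(np.zeros(geom.sinogram_shape), geom), geom)
    assert not img.values.any()


def test_axis_aligned_ray_through_unit_voxel_gives_edge_length(geom):
    tpl = geom.image_template()
    values = np.zeros(tpl.shape)
    values[5, 7, 2] = 1.0
    img = tpl.like(values)
    proj = forward_project(img, geom)
    x5 = img.axis_coords(0)[5]
    r_idx = int(np.flatnonzero(np.isclose(geom.radial_offsets, x5))[0])
    assert proj.values[0, r_idx, 2] == pytest.approx(2.0, abs=1e-12)


def test_uniform_disk_projects_to_chord_profile():
    geom = ScannerGeometry(n_angles=8, n_radial=64, radial_spacing=2.0, n_planes=1)
    tpl = geom.image_template()
    x, y, _ = tpl.meshgrid()
    radius = 40.0
    disk = ((x**2 + y**2) <= radius**2).astype(float)
    proj = forward_project(tpl.like(disk), geom)
    r = geom.radial_offsets
    analytic = 2.0 * np.sqrt(np.maximum(radius**2 - r**2, 0.0))
    inner = np.abs(r) <= 0.85 * radius
    for a in range(geom.n_angles):
        # voxelized-rim discretization error stays below ~1.5 voxel widths
        assert np.abs(proj.values[a, inner, 0] - analytic[inner]).max() < 3.0


def test_projector_adjoint_inner_product(geom, rng):
    x = rng.random((16, 16, 4))
    y = rng.random(geom.sinogram_shape)
    lhs = np.vdot(forward_project(geom.image_template().like(x), geom).values, y)
    rhs = np.vdot(x, back_project(ProjectionData(y, geom), geom).values)
    assert abs(lhs - rhs) <= 1e-10 * abs(lhs)


def test_single_bin_backprojects_onto_its_ray(geom):
    sino = np.zeros(geom.sinogram_shape)
    a, r_idx, p = 3, 8, 1
    sino[a, r_idx, p] = 1.0
    img = back_project(ProjectionData(sino, geom), geom)
    # the ray tracer's own intersection list for that LOR
    row = plane_system_matrix(geom)[a * geom.n_radial + r_idx]
    expected = np.zeros(16 * 16)
    expected[row.indices] = row.data
    np.testing.assert_array_equal(img.values[:, :, p].ravel(), expected)
    assert not img.values[:, :, [0, 2, 3]].any()


def test_fov_mismatch_raises(geom):
    bad = ImageVolume(np.zeros((8, 8, 4)), 2.0)
    with pytest.raises(ValueError, match="FOV"):
        forward_project(bad, geom)


# ---------------------------------------------------------------------------
# attenuation
# ---------------------------------------------------------------------------


def test_attenuation_identity_without_mu(geom):
    mu = geom.image_template().like(np.zeros((16, 16, 4)), content_kind="mu")
    np.testing.assert_array_equal(attenuation_factors(mu, geom), 1.0)


def test_attenuation_uniform_slab_closed_form():
    geom = ScannerGeometry(n_angles=4, n_radial=64, radial_spacing=2.0, n_planes=1)
    tpl = geom.image_template()
    x, _, _ = tpl.meshgrid()
    mu = tpl.like(np.where(np.abs(x) <= 50.0, 0.0096, 0.0), content_kind="mu")
    att = attenuation_factors(mu, geom)
    # the horizontal ray (angle pi/2) crosses the 100 mm slab once
    horiz = geom.n_angles // 2
    mid = geom.n_radial // 2
    assert att[horiz, mid, 0] == pytest.approx(math.exp(-0.96), rel=1e-12)


def test_attenuation_monotone_in_mu(geom, rng):
    mu1 = geom.image_template().like(rng.random((16, 16, 4)) * 0.005, content_kind="mu")
    mu2 = mu1.like(mu1.values * 2.0)
    assert np.all(attenuation_factors(mu2, geom) <= attenuation_factors(mu1, geom))
    with pytest.raises(ValueError, match="non-negative"):
        attenuation_factors(mu1.like(mu1.values - 1.0, content_kind="generic"), geom)


# ---------------------------------------------------------------------------
# detector blur
# ---------------------------------------------------------------------------


def test_detector_blur_zero_fwhm_is_identity(rng):
    img = ImageVolume(rng.random((9, 9, 5)), 2.0)
    np.testing.assert_array_equal(detector_blur(img, 0.0).values, img.values)
    with pytest.raises(ValueError, match="fwhm"):
        detector_blur(img, -1.0)


def test_detector_blur_measured_fwhm():
    img = ImageVolume(np.zeros((33, 33, 17)), 2.0)
    img.values[16, 16, 8] = 1.0
    blurred = detector_blur(img, 4.0)
    measured = profile_fwhm(blurred.values[:, 16, 8], 2.0)
    assert measured == pytest.approx(4.0, abs=0.2)


def test_detector_blur_conserves_interior_mass_and_is_self_adjoint(rng):
    values = np.zeros((21, 21, 21))
    values[6:15, 6:15, 6:15] = rng.random((9, 9, 9))
    img = ImageVolume(values, 2.0)
    out = detector_blur(img, 4.0)
    assert out.values.sum() == pytest.approx(values.sum(), abs=1e-9 * values.sum())
    x = rng.random((21, 21, 21))
    y = rng.random((21, 21, 21))
    lhs = np.vdot(detector_blur(img.like(x), 4.0).values, y)
    rhs = np.vdot(x, detector_blur(img.like(y), 4.0).values)
    assert abs(lhs - rhs) <= 1e-12 * abs(lhs)


# ---------------------------------------------------------------------------
# subsets
# ---------------------------------------------------------------------------


def test_partition_subsets_is_a_partition():
    geom = ScannerGeometry(n_angles=192, n_radial=8, radial_spacing=2.0, n_planes=1)
    scheme = partition_subsets(geom, 12)
    assert len(scheme.subsets) == 12
    assert all(len(s) == 16 for s in scheme.subsets)
    combined = np.sort(np.concatenate(scheme.subsets))
    np.testing.assert_array_equal(combined, np.arange(192))
    assert sorted(scheme.order) == list(range(12))


def test_single_subset_is_mlem_mode(geom):
    scheme = partition_subsets(geom, 1)
    np.testing.assert_array_equal(scheme.subsets[0], np.arange(12))


def test_indivisible_subsets_rejected(geom):
    with pytest.raises(ValueError, match="divisible"):
        partition_subsets(geom, 5)


def test_subset_order_spreads_angles():
    geom = ScannerGeometry(n_angles=120, n_radial=8, radial_spacing=2.0, n_planes=1)
    order = partition_subsets(geom, 12).order
    # consecutive subsets are never angular neighbours
    assert all(abs(a - b) > 1 for a, b in zip(order, order[1:]))


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_phantom_and_model():
    ph = make_nema_iq(
        shape=(48, 48, 8),
        voxel_size=2.0,
        body_diameter=80.0,
        ring_radius=22.0,
        sphere_diameters=(10.0, 12.0, 14.0),
        n_background_vois=3,
        background_voi_diameter=12.0,
        edge_margin=4.0,
    )
    from prcrecon.phantoms import hu_to_mu
    from prcrecon.projector import SystemModel

    geom = ScannerGeometry(n_angles=24, n_radial=48, radial_spacing=2.0, n_planes=8)
    model = SystemModel(geom, attenuation_factors(hu_to_mu(ph.hu), geom))
    return ph, model


def test_noiseless_acquisition_sums_to_total_counts(small_phantom_and_model):
    ph, model = small_phantom_and_model
    sino = simulate_acquisition(ph, model, total_counts=1e6, noiseless=True)
    assert sino.values.sum() == pytest.approx(1e6, rel=1e-6)
    assert not sino.is_noisy


def test_degenerate_model_gives_attenuated_line_integrals(small_phantom_and_model):
    ph, model = small_phantom_and_model
    sino = simulate_acquisition(ph, model, total_counts=None, noiseless=True)
    expected = model.lor_weights * forward_project(ph.activity, model.geometry).values
    np.testing.assert_allclose(sino.values, expected, rtol=1e-12)
    assert sino.count_scale == 1.0


def test_poisson_dispersion(small_phantom_and_model):
    """Sample variance/mean per bin over repeated draws is near 1."""
    ph, model = small_phantom_and_model
    expectation = simulate_acquisition(ph, model, total_counts=None, noiseless=True)
    # pick bins with expectation ~10 counts after scaling
    scale = 10.0 / np.median(expectation.values[expectation.values > 0])
    draws = np.stack(
        [
            simulate_acquisition(
                ph, model, total_counts=scale * expectation.values.sum(), seed=s
            ).values
            for s in range(100)
        ]
    )
    mean = draws.mean(axis=0)
    var = draws.var(axis=0, ddof=1)
    busy = mean > 5.0
    ratio = var[busy] / mean[busy]
    assert np.mean((ratio > 0.6) & (ratio < 1.4)) >= 0.95


def test_total_counts_must_be_positive(small_phantom_and_model):
    ph, model = small_phantom_and_model
    with pytest.raises(ValueError, match="positive"):
        simulate_acquisition(ph, model, total_counts=0.0)


def test_sinogram_hdf5_roundtrip(tmp_path, small_phantom_and_model):
    ph, model = small_phantom_and_model
    sino = simulate_acquisition(ph, model, total_counts=1e5, seed=9)
    path = tmp_path / "sino.h5"
    sino.save_hdf5(path)
    loaded = ProjectionData.load_hdf5(path)
    np.testing.assert_array_equal(loaded.values, sino.values)
    assert loaded.geometry == sino.geometry
    assert loaded.is_noisy and loaded.count_scale == pytest.approx(sino.count_scale)
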