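"""Positron-range kernel generation, composition and blurring."""

import math

import numpy as np
import pytest
from scipy.ndimage import convolve as dense_convolve

from prcrecon.kernels import (
    DEFAULT_MATERIALS,
    ELECTRON_MASS_MEV,
    FINE_STRUCTURE,
    I124,
    KernelBank,
    MaterialSpec,
    PositronSpectrum,
    PRKernel,
    SpatiallyVariantPRBlur,
    adjoint_pr_blur,
    apply_pr_blur,
    build_kernel_bank,
    build_uniform_kernel,
    compose_voxel_kernel,
    extrapolated_range_g_cm2,
    profile_fwhm,
    sample_annihilation_displacement,
    validate_material_partition,
)
from prcrecon.volume import ImageVolume

WATER = DEFAULT_MATERIALS[1]


# ---------------------------------------------------------------------------
# displacement sampling
# ---------------------------------------------------------------------------


def test_displacement_scales_exactly_with_inverse_density():
    d_water = sample_annihilation_displacement(I124, 1.0, np.random.default_rng(7), 5000)
    d_lung = sample_annihilation_displacement(I124, 0.26, np.random.default_rng(7), 5000)
    np.testing.assert_allclose(d_lung, d_water / 0.26, rtol=1e-12)


def test_displacement_vanishes_at_extreme_density():
    d = sample_annihilation_displacement(I124, 1e6, np.random.default_rng(0), 1000)
    assert np.linalg.norm(d, axis=1).max() < 1e-3  # << one voxel


def test_non_positive_density_rejected():
    with pytest.raises(ValueError, match="density"):
        sample_annihilation_displacement(I124, 0.0, np.random.default_rng(0))
    with pytest.raises(ValueError, match="density"):
        sample_annihilation_displacement(I124, -1.0, np.random.default_rng(0))


def test_mean_radial_displacement_matches_numeric_integration():
    """MC mean displacement vs direct quadrature of the same spectrum/range
    model, written out independently here."""
    n = 100_000
    disp = sample_annihilation_displacement(I124, 1.0, np.random.default_rng(11), n)
    radial = np.linalg.norm(disp, axis=1)

    # independent quadrature: allowed beta shape x Coulomb factor per branch
    def branch_mean_range(endpoint):
        t = np.linspace(1e-6, endpoint, 20_000)
        w = t + ELECTRON_MASS_MEV
        p = np.sqrt(w**2 - ELECTRON_MASS_MEV**2)
        beta = p / w
        eta = FINE_STRUCTURE * 52 / beta
        pdf = p * w * (endpoint - t) ** 2 * (2 * np.pi * eta) / np.expm1(
            np.clip(2 * np.pi * eta, None, 500.0)
        )
        r = 0.8 * 10.0 * extrapolated_range_g_cm2(t)  # mm in water
        return np.trapezoid(pdf * r, t) / np.trapezoid(pdf, t)

    fracs = np.array([f for _, f in I124.branches])
    fracs = fracs / fracs.sum()
    expected = sum(f * branch_mean_range(q) for (q, _), f in zip(I124.branches, fracs))
    se = radial.std() / math.sqrt(n)
    assert abs(radial.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# uniform kernels
# ---------------------------------------------------------------------------


def test_zero_energy_spectrum_gives_delta_kernel():
    cold = PositronSpectrum("degenerate", ((0.0, 1.0),))
    k = build_uniform_kernel(cold, WATER, kernel_size=(5, 5, 5), n_events=1000, seed=0)
    expected = np.zeros((5, 5, 5))
    expected[2, 2, 2] = 1.0
    np.testing.assert_array_equal(k.values, expected)


def test_kernel_unit_sum_and_mc_symmetry():
    n = 50_000
    k = build_uniform_kernel(I124, WATER, n_events=n, seed=3)
    assert abs(k.values.sum() - 1.0) < 1e-9
    flipped = k.values[::-1, ::-1, ::-1]
    # isotropy by construction: per-bin difference within 3 sigma of the
    # binomial error of the two bins
    sigma = np.sqrt((k.values + flipped) / n)
    assert np.all(np.abs(k.values - flipped) <= 3.0 * sigma + 1e-12)


def test_even_kernel_size_rejected():
    with pytest.raises(ValueError, match="odd"):
        build_uniform_kernel(I124, WATER, kernel_size=(4, 4, 4), n_events=10, seed=0)
    with pytest.raises(ValueError, match="odd"):
        PRKernel(np.ones((4, 5, 5)))


def test_kernel_records_discarded_fraction():
    lung = DEFAULT_MATERIALS[0]
    k = build_uniform_kernel(I124, lung, n_events=20_000, seed=5)
    assert 0.0 < k.discarded_fraction < 1.0
    assert abs(k.values.sum() - 1.0) < 1e-9  # renormalized after discarding


def test_profile_fwhm_on_known_gaussian():
    x = np.arange(-20, 21) * 1.0
    fwhm = 7.0
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    assert profile_fwhm(np.exp(-0.5 * (x / sigma) ** 2), 1.0) == pytest.approx(
        fwhm, abs=0.1
    )


# ---------------------------------------------------------------------------
# bank
# ---------------------------------------------------------------------------


def test_bank_roundtrip_hdf5(small_bank, tmp_path):
    path = tmp_path / "bank.h5"
    small_bank.save_hdf5(path)
    loaded = KernelBank.load_hdf5(path)
    assert [m.name for m in loaded.materials] == [m.name for m in small_bank.materials]
    for name, k in small_bank.kernels.items():
        # reload renormalizes; equality up to one ulp of the unit sum
        np.testing.assert_allclose(loaded.kernels[name].values, k.values, rtol=1e-12)
    assert loaded.seed == small_bank.seed and loaded.isotope == small_bank.isotope


def test_bank_text_export(small_bank, tmp_path):
    small_bank.write_text(tmp_path)
    for mat in small_bank.materials:
        text = (tmp_path / f"kernel_{mat.name}.txt").read_text()
        assert str(mat.mass_density) in text


def test_bank_determinism():
    b1 = build_kernel_bank(kernel_size=(5, 5, 5), n_events=5000, seed=42)
    b2 = build_kernel_bank(kernel_size=(5, 5, 5), n_events=5000, seed=42)
    for name in b1.kernels:
        np.testing.assert_array_equal(b1.kernels[name].values, b2.kernels[name].values)


def test_material_partition_validation():
    validate_material_partition(DEFAULT_MATERIALS)
    gap = (
        MaterialSpec("a", 1.0, (-math.inf, -100.0)),
        MaterialSpec("b", 1.0, (0.0, math.inf)),
    )
    with pytest.raises(ValueError, match="tile"):
        validate_material_partition(gap)
    with pytest.raises(ValueError, match="-inf"):
        validate_material_partition((MaterialSpec("a", 1.0, (0.0, math.inf)),))
    with pytest.raises(ValueError, match="positive"):
        MaterialSpec("x", 0.0, (-math.inf, math.inf))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("label,material", [(0, "lung"), (1, "soft")])
def test_uniform_map_composition_equals_material_kernel(small_bank, label, material):
    shape = (12, 12, 8)
    mmap = ImageVolume(np.full(shape, label, dtype=np.int8), 2.0, content_kind="label")
    k = compose_voxel_kernel(small_bank, mmap, (6, 6, 4))
    np.testing.assert_allclose(
        k.values, small_bank.kernels[material].values, rtol=0, atol=1e-15
    )


def test_interface_composition_matches_brute_force(small_bank):
    """3-voxel-thick lung/soft interface: composed kernel at an interface
    voxel equals an independent per-offset table lookup + renormalization."""
    shape = (12, 12, 8)
    labels = np.zeros(shape, dtype=np.int8)  # lung
    labels[6:, :, :] = 1  # soft half-space; interface plane at x = 6
    mmap = ImageVolume(labels, 2.0, content_kind="label")
    for j in [(6, 6, 4), (5, 6, 4), (0, 0, 0), (11, 11, 7)]:
        composed = compose_voxel_kernel(small_bank, mmap, j)
        brute = np.empty((5, 5, 5))
        for off in np.ndindex(5, 5, 5):
            dest = tuple(
                min(max(j[a] + off[a] - 2, 0), shape[a] - 1) for a in range(3)
            )
            name = small_bank.materials[labels[dest]].name
            brute[off] = small_bank.kernels[name].values[off]
        brute /= brute.sum()
        np.testing.assert_allclose(composed.values, brute, rtol=0, atol=1e-12)


def test_missing_label_raises(small_bank):
    mmap = ImageVolume(np.full((8, 8, 4), 3, dtype=np.int8), 2.0, content_kind="label")
    with pytest.raises(KeyError, match="3"):
        compose_voxel_kernel(small_bank, mmap, (4, 4, 2))
    img = ImageVolume(np.ones((8, 8, 4)), 2.0)
    with pytest.raises(KeyError, match="3"):
        apply_pr_blur(img, mmap, small_bank)


# ---------------------------------------------------------------------------
# blur operator
# ---------------------------------------------------------------------------


def test_delta_image_spreads_with_composed_kernel(small_bank, random_label_map):
    j = (8, 7, 4)
    delta = np.zeros(random_label_map.shape)
    delta[j] = 1.0
    out = apply_pr_blur(
        ImageVolume(delta, 2.0), random_label_map, small_bank
    ).values
    kern = compose_voxel_kernel(small_bank, random_label_map, j)
    expected = np.zeros_like(delta)
    for off in np.ndindex(5, 5, 5):
        dest = tuple(j[a] + off[a] - 2 for a in range(3))
        expected[dest] += kern.values[off]
    np.testing.assert_allclose(out, expected, atol=1e-14)


def test_uniform_map_blur_equals_dense_convolution(small_bank, rng):
    """On a homogeneous medium the spatially variant blur reduces to a
    shift-invariant convolution with the single material kernel."""
    shape = (32, 32, 8)
    mmap = ImageVolume(np.ones(shape, dtype=np.int8), 2.0, content_kind="label")
    img = rng.random(shape)
    out = apply_pr_blur(ImageVolume(img, 2.0), mmap, small_bank).values
    ref = dense_convolve(img, small_bank.kernels["soft"].values, mode="constant")
    np.testing.assert_allclose(out, ref, atol=1e-10)


def test_blur_conserves_interior_mass_and_nonnegativity(small_bank, random_label_map, rng):
    interior = np.zeros(random_label_map.shape)
    interior[3:13, 3:13, 2:6] = rng.random((10, 10, 4))
    img = ImageVolume(interior, 2.0)
    out = apply_pr_blur(img, random_label_map, small_bank)
    assert out.values.min() >= 0
    assert abs(out.values.sum() - interior.sum()) < 1e-6 * interior.sum()
    back = adjoint_pr_blur(out, random_label_map, small_bank)
    assert back.values.min() >= 0


def test_blur_adjoint_inner_product(small_bank, random_label_map, rng):
    op = SpatiallyVariantPRBlur(small_bank, random_label_map)
    x = rng.standard_normal(random_label_map.shape)
    y = rng.standard_normal(random_label_map.shape)
    lhs = np.vdot(op.apply(x), y)
    rhs = np.vdot(x, op.adjoint(y))
    assert abs(lhs - rhs) <= 1e-10 * abs(lhs)


def test_symmetric_kernel_uniform_map_self_adjoint(small_bank, rng):
    """A symmetric kernel on a homogeneous map gives a self-adjoint blur."""
    sym = {}
    for name, k in small_bank.kernels.items():
        v = (k.values + k.values[::-1, ::-1, ::-1]) / 2.0
        sym[name] = PRKernel(v, k.voxel_size, material_tag=name)
    bank = KernelBank(small_bank.materials, sym, seed=0)
    shape = (16, 16, 8)
    mmap = ImageVolume(np.ones(shape, dtype=np.int8), 2.0, content_kind="label")
    op = SpatiallyVariantPRBlur(bank, mmap)
    x = rng.random(shape)
    np.testing.assert_allclose(op.apply(x), op.adjoint(x), atol=1e-12)


def test_grid_mismatch_raises(small_bank, random_label_map):
    img = ImageVolume(np.ones((8, 8, 8)), 2.0)
    with pytest.raises(ValueError, match="grid"):
        apply_pr_blur(img, random_label_map, small_bank)
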