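"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is built from explicit dense matrices and elementary loops,
deliberately avoiding the package's fast paths, so the tests compare two
independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np

from prcrecon.kernels import KernelBank, compose_voxel_kernel
from prcrecon.projector import (
    ProjectionData,
    ScannerGeometry,
    SystemModel,
    forward_project,
    gaussian_blur_values,
    partition_subsets,
)
from prcrecon.volume import ImageVolume


class ToyPhantom:
    def __init__(self, activity):
        self.activity = activity


def make_toy_problem():
    """8x8x3 toy: attenuating body, bone wedge, 3^3 PR kernels, 3 mm PSF."""
    from prcrecon.kernels import build_kernel_bank
    from prcrecon.phantoms import hu_to_mu, segment_materials
    from prcrecon.projector import PRModel, attenuation_factors

    geom = ScannerGeometry(n_angles=12, n_radial=8, radial_spacing=2.0, n_planes=3)
    tpl = geom.image_template()
    x, y, _ = tpl.meshgrid()
    body = (x**2 + y**2) <= 7.9**2
    hu = tpl.like(np.where(body, 0.0, -400.0), content_kind="hu")
    hu.values[5:, :, :] = np.where(body, 300.0, -400.0)[5:, :, :]  # bone wedge
    rng = np.random.default_rng(5)
    activity = np.where(body, 1.0 + rng.random(tpl.shape), 0.05)
    bank = build_kernel_bank(kernel_size=(3, 3, 3), n_events=20_000, seed=2)
    model = SystemModel(
        geometry=geom,
        attenuation=attenuation_factors(hu_to_mu(hu), geom),
        detector_fwhm=3.0,
        pr=PRModel(bank, segment_materials(hu)),
    )
    return geom, tpl, model, ToyPhantom(tpl.like(activity, content_kind="activity"))


def dense_geometric_matrix(geometry: ScannerGeometry, template: ImageVolume) -> np.ndarray:
    """Dense (n_lors, n_voxels) X from forward-projecting basis vectors."""
    n_vox = int(np.prod(template.shape))
    cols = []
    for j in range(n_vox):
        e = np.zeros(n_vox)
        e[j] = 1.0
        cols.append(
            forward_project(template.like(e.reshape(template.shape)), geometry).values.ravel()
        )
    return np.stack(cols, axis=1)


def dense_pr_matrix(bank: KernelBank, material_map: ImageVolume) -> np.ndarray:
    """Dense spatially variant PR blur matrix, column by column, from the
    per-voxel composed kernels (spread-from-source, truncated at the edge)."""
    shape = material_map.shape
    n_vox = int(np.prod(shape))
    ksize = bank.kernel_size
    r = tuple(s // 2 for s in ksize)
    h = np.zeros((n_vox, n_vox))
    for j in np.ndindex(shape):
        kern = compose_voxel_kernel(bank, material_map, j)
        col = np.ravel_multi_index(j, shape)
        for off in np.ndindex(ksize):
            dest = tuple(j[a] + off[a] - r[a] for a in range(3))
            if all(0 <= dest[a] < shape[a] for a in range(3)):
                h[np.ravel_multi_index(dest, shape), col] += kern.values[off]
    return h


def dense_gaussian_matrix(
    fwhm: float, template: ImageVolume
) -> np.ndarray:
    """Dense stationary detector-blur matrix from basis vectors."""
    n_vox = int(np.prod(template.shape))
    cols = []
    for j in range(n_vox):
        e = np.zeros(n_vox)
        e[j] = 1.0
        cols.append(
            gaussian_blur_values(
                e.reshape(template.shape), fwhm, template.voxel_size
            ).ravel()
        )
    return np.stack(cols, axis=1)


def dense_variant_matrices(
    model: SystemModel, template: ImageVolume, prc_mode: str, psf_enabled: bool
):
    """(X, W diag, H_forward, H_back, H_sens) dense matrices for a variant.

    H_back / H_sens carry only the parts of H modelled in the back-projection
    and the sensitivity denominator for that variant: the full scheme uses
    all of H; the simplified scheme drops the PR factor there; the PSF factor
    follows psf_enabled everywhere.
    """
    n_vox = int(np.prod(template.shape))
    x = dense_geometric_matrix(model.geometry, template)
    w = model.lor_weights.ravel()
    identity = np.eye(n_vox)
    h_pr = (
        dense_pr_matrix(model.pr.bank, model.pr.material_map)
        if model.pr is not None and prc_mode != "none"
        else identity
    )
    h_det = (
        dense_gaussian_matrix(model.detector_fwhm, template)
        if psf_enabled
        else identity
    )
    h_fwd = h_det @ h_pr
    h_model = h_det @ h_pr if prc_mode == "full" else h_det
    return x, w, h_fwd, h_model


def subset_row_indices(geometry: ScannerGeometry, angles: np.ndarray) -> np.ndarray:
    """Raveled sinogram indices (angle-major, then radial, then plane)."""
    lor = (angles[:, None] * geometry.n_radial + np.arange(geometry.n_radial)[None, :]).ravel()
    return (
        lor[:, None] * geometry.n_planes + np.arange(geometry.n_planes)[None, :]
    ).ravel()


def dense_subset_sensitivity(
    model: SystemModel,
    template: ImageVolume,
    angles: np.ndarray,
    prc_mode: str,
    psf_enabled: bool,
) -> np.ndarray:
    """Sensitivity sum_i a_ij over one subset, via the dense matrices."""
    x, w, _, h_model = dense_variant_matrices(model, template, prc_mode, psf_enabled)
    rows = subset_row_indices(model.geometry, angles)
    wx = w[rows, None] * x[rows]
    return (h_model.T @ wx.sum(axis=0)).reshape(template.shape)


def dense_osem_iteration(
    proj: ProjectionData,
    model: SystemModel,
    template: ImageVolume,
    f0: np.ndarray,
    prc_mode: str,
    psf_enabled: bool,
    n_subsets: int,
    epsilon_scale: float = 1e-12,
) -> np.ndarray:
    """One full ordered-subsets EM iteration evaluated with dense matrices.

    The forward step uses the variant's full H; the back-projection and the
    sensitivity denominator use only the variant's modelled parts of H
    (transposed) — plain OSEM for the simplified scheme, all of H for the
    full scheme.
    """
    x, w, h_fwd, h_model = dense_variant_matrices(model, template, prc_mode, psf_enabled)
    m = proj.values.ravel()
    scheme = partition_subsets(model.geometry, n_subsets)
    epsilon = epsilon_scale * float(proj.values.mean())
    f = f0.ravel().copy()
    for _, angles in scheme.ordered():
        rows = subset_row_indices(model.geometry, angles)
        wx = w[rows, None] * x[rows]  # W_S X_S
        y = wx @ (h_fwd @ f)
        ratio = m[rows] / (y + epsilon)
        bp = h_model.T @ (wx.T @ ratio)
        sens = h_model.T @ wx.sum(axis=0)
        valid = sens > 1e-10 * sens.max()
        f = np.where(valid, f * np.divide(bp, sens, where=valid, out=np.ones_like(f)), 0.0)
    return f.reshape(template.shape)
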