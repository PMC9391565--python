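"""Factorized system model A = W X H for parallel-beam multi-slice PET.

``X`` is an exact line-integral projector (grid-crossing ray tracing with
per-voxel intersection lengths, held as one sparse matrix per transaxial
plane so the back-projector is the literal matrix transpose), ``W`` carries
per-LOR attenuation/normalization weights, and ``H`` is image-space
resolution blur (stationary isotropic detector PSF and/or the spatially
variant positron-range blur of :mod:`prcrecon.kernels`).

The geometry is a stacked-2D parallel-beam multi-slice ring: ``n_angles``
views over [0, pi), ``n_radial`` bins per view, one sinogram plane per image
slice.  The image grid implied by a geometry is ``n_radial x n_radial x
n_planes`` voxels with in-plane voxel edge ``radial_spacing``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .kernels import KernelBank, SpatiallyVariantPRBlur
from .volume import ImageVolume

GAUSS_SIGMA_PER_FWHM = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# geometry and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam multi-slice acquisition geometry.

    ``ring_radius`` is documentation only (parallel beams do not diverge).
    """

    n_angles: int = 120
    n_radial: int = 160
    radial_spacing: float = 2.0  # mm
    n_planes: int = 24
    ring_radius: float = 420.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial < 1 or self.n_planes < 1:
            raise ValueError("geometry counts must be >= 1")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * math.pi / self.n_angles

    @property
    def radial_offsets(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_spacing

    @property
    def n_lors_per_plane(self) -> int:
        return self.n_angles * self.n_radial

    @property
    def sinogram_shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_radial, self.n_planes)

    def image_template(self, voxel_z: float | None = None) -> ImageVolume:
        """Blank image on the grid this geometry projects."""
        vz = self.radial_spacing if voxel_z is None else voxel_z
        return ImageVolume(
            np.zeros((self.n_radial, self.n_radial, self.n_planes)),
            (self.radial_spacing, self.radial_spacing, vz),
        )


@dataclass
class ProjectionData:
    """Sinogram of LOR values, indexed [angle, radial, plane].

    ``count_scale`` records the factor by which the physical forward model
    was multiplied to reach the requested total counts; reconstructions of
    this data live on the activity scale times ``count_scale``.
    """

    values: np.ndarray
    geometry: ScannerGeometry
    is_noisy: bool = False
    count_scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("sinogram values must be finite and non-negative")

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            g = self.geometry
            f.attrs.update(
                n_angles=g.n_angles,
                n_radial=g.n_radial,
                radial_spacing=g.radial_spacing,
                n_planes=g.n_planes,
                ring_radius=g.ring_radius,
                is_noisy=self.is_noisy,
                count_scale=self.count_scale,
            )

    @classmethod
    def load_hdf5(cls, path) -> "ProjectionData":
        import h5py

        with h5py.File(path, "r") as f:
            geom = ScannerGeometry(
                int(f.attrs["n_angles"]),
                int(f.attrs["n_radial"]),
                float(f.attrs["radial_spacing"]),
                int(f.attrs["n_planes"]),
                float(f.attrs["ring_radius"]),
            )
            return cls(
                f["values"][()],
                geom,
                bool(f.attrs["is_noisy"]),
                float(f.attrs.get("count_scale", 1.0)),
            )


@dataclass
class SubsetScheme:
    """Disjoint equal-size angle subsets and their processing order."""

    subsets: list[np.ndarray]
    order: list[int]

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def ordered(self):
        for k in self.order:
            yield k, self.subsets[k]


def partition_subsets(geometry: ScannerGeometry, n_subsets: int = 12) -> SubsetScheme:
    """Interleaved angular subsets with maximal-angular-distance ordering.

    Subset ``k`` takes angles congruent to ``k`` modulo ``n_subsets``.  The
    processing order greedily maximizes the minimum circular distance (mod
    pi) to all previously processed subsets, which decorrelates consecutive
    updates in ordered-subsets reconstruction.
    """
    if geometry.n_angles % n_subsets != 0:
        raise ValueError(
            f"n_angles={geometry.n_angles} is not divisible by n_subsets={n_subsets}"
        )
    subsets = [
        np.arange(k, geometry.n_angles, n_subsets, dtype=np.int64)
        for k in range(n_subsets)
    ]
    # greedy maximal-angular-distance permutation over the subset indices
    # (circular distance in subset units); ties are broken by the distance
    # to the previously processed subset, then by the lower index
    def circ(a: int, b: int) -> int:
        d = abs(a - b) % n_subsets
        return min(d, n_subsets - d)

    order = [0]
    remaining = set(range(1, n_subsets))
    while remaining:
        best = max(
            sorted(remaining),
            key=lambda cand: (
                min(circ(cand, o) for o in order),
                circ(cand, order[-1]),
                -cand,
            ),
        )
        order.append(best)
        remaining.discard(best)
    return SubsetScheme(subsets, order)


# ---------------------------------------------------------------------------
# geometric projector X (sparse, exact intersection lengths)
# ---------------------------------------------------------------------------

_MATRIX_CACHE: dict[tuple, sparse.csr_matrix] = {}


def plane_system_matrix(geometry: ScannerGeometry) -> sparse.csr_matrix:
    """Sparse (n_angles*n_radial, n_radial^2) matrix of intersection lengths
    (mm) between each in-plane LOR and each voxel of the implied grid.

    Rays are parametrized ``p(t) = r u + t d`` with ``u = (cos a, sin a)``,
    ``d = (-sin a, cos a)``; all grid-line crossings are enumerated, sorted,
    and each inter-crossing segment is assigned to the voxel containing its
    midpoint — the classic exact-length (Siddon-type) traversal, vectorized
    over radial bins.
    """
    key = (geometry.n_angles, geometry.n_radial, geometry.radial_spacing)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    n = geometry.n_radial
    v = geometry.radial_spacing
    edges = (np.arange(n + 1) - n / 2.0) * v  # shared by x and y
    r = geometry.radial_offsets
    rows, cols, vals = [], [], []
    for a, theta in enumerate(geometry.angles):
        c, s = math.cos(theta), math.sin(theta)
        dx, dy = -s, c
        t_list = []
        for comp, d_comp in ((c, dx), (s, dy)):
            if abs(d_comp) > 1e-12:
                t_list.append((edges[None, :] - r[:, None] * comp) / d_comp)
        t = np.concatenate(t_list, axis=1)
        t = np.where(np.isfinite(t), t, np.inf)
        t.sort(axis=1)
        t0, t1 = t[:, :-1], t[:, 1:]
        seg = t1 - t0
        good = np.isfinite(t1) & (seg > 1e-9)
        tm = 0.5 * (t0 + t1)
        px = r[:, None] * c + tm * dx
        py = r[:, None] * s + tm * dy
        with np.errstate(invalid="ignore"):
            ix = np.floor((px - edges[0]) / v)
            iy = np.floor((py - edges[0]) / v)
        good &= (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
        rad_idx, _ = np.nonzero(good)
        rows.append(a * n + rad_idx)
        cols.append((ix[good] * n + iy[good]).astype(np.int64))
        vals.append(seg[good])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.n_lors_per_plane, n * n),
    ).tocsr()
    _MATRIX_CACHE[key] = mat
    return mat


def _check_image(image: ImageVolume, geometry: ScannerGeometry) -> None:
    nx, ny, nz = image.values.shape
    if nx != geometry.n_radial or ny != geometry.n_radial or nz != geometry.n_planes:
        raise ValueError(
            f"image grid {image.values.shape} does not match the geometry FOV "
            f"({geometry.n_radial}, {geometry.n_radial}, {geometry.n_planes})"
        )
    if not np.allclose(image.voxel_size[:2], geometry.radial_spacing):
        raise ValueError(
            f"in-plane voxel size {image.voxel_size[:2]} must equal the radial "
            f"spacing {geometry.radial_spacing}"
        )


def forward_project(image: ImageVolume, geometry: ScannerGeometry) -> ProjectionData:
    """Per-LOR line integrals (mm-weighted) of the image."""
    _check_image(image, geometry)
    x = plane_system_matrix(geometry)
    flat = np.asarray(image.values, dtype=np.float64).reshape(-1, geometry.n_planes)
    proj = x @ flat
    return ProjectionData(
        proj.reshape(geometry.sinogram_shape), geometry, is_noisy=False
    )


def back_project(
    proj: ProjectionData, geometry: ScannerGeometry, voxel_z: float | None = None
) -> ImageVolume:
    """Exact matrix transpose of :func:`forward_project`."""
    if proj.geometry != geometry:
        raise ValueError("projection geometry does not match")
    x = plane_system_matrix(geometry)
    flat = proj.values.reshape(geometry.n_lors_per_plane, geometry.n_planes)
    img = x.T @ flat
    template = geometry.image_template(voxel_z)
    return template.like(
        img.reshape(geometry.n_radial, geometry.n_radial, geometry.n_planes)
    )


def attenuation_factors(mu: ImageVolume, geometry: ScannerGeometry) -> np.ndarray:
    """Per-LOR survival factors exp(-integral mu dl), same ray tracer as X.

    ``mu`` is the 511 keV attenuation map in 1/mm.
    """
    if np.any(np.asarray(mu.values) < 0):
        raise ValueError("attenuation map must be non-negative")
    line_integrals = forward_project(mu, geometry).values
    return np.exp(-line_integrals)


# ---------------------------------------------------------------------------
# detector PSF (stationary isotropic image-space blur)
# ---------------------------------------------------------------------------


def _gauss_kernel_1d(fwhm: float, voxel: float) -> np.ndarray:
    sigma_vox = fwhm * GAUSS_SIGMA_PER_FWHM / voxel
    radius = max(1, int(math.ceil(3.5 * sigma_vox)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()


def gaussian_blur_values(
    values: np.ndarray, fwhm: float, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Separable truncated-Gaussian blur; symmetric, unit-sum, self-adjoint
    (zero-padded boundaries)."""
    if fwhm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm}")
    if fwhm == 0:
        return np.array(values, dtype=np.float64, copy=True)
    out = np.asarray(values, dtype=np.float64)
    for axis in range(3):
        out = ndimage.convolve1d(
            out, _gauss_kernel_1d(fwhm, voxel_size[axis]), axis=axis, mode="constant"
        )
    return out


def detector_blur(image: ImageVolume, fwhm: float) -> ImageVolume:
    """Isotropic stationary detector-resolution blur of the stated FWHM (mm).

    The discrete kernel is a truncated sampled Gaussian normalized to unit
    sum, so interior-supported images conserve their total.  The operator is
    its own exact adjoint (symmetric kernel, zero padding); ``fwhm = 0`` is
    the identity.
    """
    return image.like(gaussian_blur_values(image.values, fwhm, image.voxel_size))


# ---------------------------------------------------------------------------
# system model and acquisition simulation
# ---------------------------------------------------------------------------


@dataclass
class PRModel:
    """Positron-range factor of H: kernel bank + material-label map."""

    bank: KernelBank
    material_map: ImageVolume

    def operator(self) -> SpatiallyVariantPRBlur:
        return SpatiallyVariantPRBlur(self.bank, self.material_map)


@dataclass
class SystemModel:
    """The factorized system matrix A = W X H.

    ``attenuation`` holds the per-LOR survival factors in (0, 1] (None means
    no attenuation), ``norm`` optional per-LOR efficiencies (None means 1,
    i.e. perfect normalization), ``detector_fwhm`` the stationary PSF width
    in mm (0 disables resolution modelling), and ``pr`` the positron-range
    blur factor (None disables it).
    """

    geometry: ScannerGeometry
    attenuation: np.ndarray | None = None
    detector_fwhm: float = 0.0
    pr: PRModel | None = None
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.detector_fwhm < 0:
            raise ValueError("detector_fwhm must be >= 0")
        for name in ("attenuation", "norm"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != self.geometry.sinogram_shape:
                    raise ValueError(f"{name} shape does not match the geometry")
                if np.any(arr <= 0) or np.any(arr > 1.0 + 1e-12):
                    raise ValueError(f"{name} factors must lie in (0, 1]")
                setattr(self, name, arr)

    @property
    def lor_weights(self) -> np.ndarray:
        """Combined per-LOR weight w_ii (attenuation x normalization)."""
        w = np.ones(self.geometry.sinogram_shape)
        if self.attenuation is not None:
            w = w * self.attenuation
        if self.norm is not None:
            w = w * self.norm
        return w


def simulate_acquisition(
    phantom,
    model: SystemModel,
    total_counts: float | None = 2e7,
    seed: int = 0,
    noiseless: bool = False,
) -> ProjectionData:
    """Simulate an acquisition of a phantom through the system model.

    The expectation is ``W X (detector_blur . pr_blur)(activity)`` scaled so
    its sum equals ``total_counts`` (pass ``None`` to keep the raw forward
    model scale); the noisy case draws one independent Poisson variate per
    bin.  Ground-truth positron-range blur is applied when ``model.pr`` is
    configured.
    """
    if total_counts is not None and total_counts <= 0:
        raise ValueError("total_counts must be positive")
    activity = phantom.activity
    values = np.asarray(activity.values, dtype=np.float64)
    if model.pr is not None:
        values = model.pr.operator().apply(values)
    values = gaussian_blur_values(values, model.detector_fwhm, activity.voxel_size)
    proj = forward_project(activity.like(values), model.geometry)
    expectation = model.lor_weights * proj.values
    scale = 1.0
    if total_counts is not None:
        scale = total_counts / expectation.sum()
        expectation = expectation * scale
    if noiseless:
        return ProjectionData(expectation, model.geometry, is_noisy=False, count_scale=scale)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expectation).astype(np.float64)
    return ProjectionData(counts, model.geometry, is_noisy=True, count_scale=scale)
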