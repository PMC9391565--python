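"""Digital activity/attenuation phantoms and their evaluation VOIs.

Three phantom families are provided, emulating standard image-quality
hardware at desk scale:

* ``make_nema_iq`` — six hot spheres (10-37 mm) on a 57.2 mm ring in a warm
  water body, 30/6 kBq/ml hot/background (5:1 contrast),
* ``make_small_tumor`` — the same housing with sub-centimetre spheres
  (3.7-9.7 mm) at 25/1.2 kBq/ml,
* ``make_bone_lung`` — three cold 50 mm cylinders (lung -800 HU, bone
  +500/+1000 HU) each carrying two hot spheres (8.5/19.4 mm), in a warm
  water body.

The body shell is a cylinder rather than the torso-shaped shell: VOI
analysis is unaffected and the geometry stays analytic.  Spheres and
cylinders are voxelized with fractional sub-voxel sampling (3^3 subsamples
per voxel) so sub-voxel-scale spheres receive partial-volume-correct
activity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kernels import DEFAULT_MATERIALS, MaterialSpec, validate_material_partition
from .volume import ImageVolume

HU_AIR = -1000.0
HU_WATER = 0.0
MU_WATER_511KEV = 0.0096  # 1/mm
#: slope of the attenuation conversion above water, 1/mm per HU
MU_BONE_SLOPE = 4.8e-6


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereSpec:
    """A hot sphere: center (mm), diameter (mm), fill activity (kBq/ml)."""

    center: tuple[float, float, float]
    diameter: float
    activity: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"sphere diameter must be positive, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class VOI:
    """A spherical volume of interest (center mm, diameter mm)."""

    center: tuple[float, float, float]
    diameter: float
    label: str = ""

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class VOISet:
    """Sphere VOIs (one per hot sphere, diameter = sphere diameter) and
    background VOIs, used by the contrast-recovery / noise protocol."""

    sphere_vois: list[VOI]
    background_vois: list[VOI]

    def to_json(self, path: str | Path) -> None:
        def enc(v: VOI) -> dict:
            return {"center_mm": list(v.center), "diameter_mm": v.diameter, "label": v.label}

        Path(path).write_text(
            json.dumps(
                {
                    "sphere_vois": [enc(v) for v in self.sphere_vois],
                    "background_vois": [enc(v) for v in self.background_vois],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "VOISet":
        raw = json.loads(Path(path).read_text())

        def dec(d: dict) -> VOI:
            return VOI(tuple(d["center_mm"]), d["diameter_mm"], d.get("label", ""))

        return cls(
            [dec(d) for d in raw["sphere_vois"]],
            [dec(d) for d in raw["background_vois"]],
        )


@dataclass
class PhantomSet:
    """Activity + HU volumes with the matching VOI protocol."""

    activity: ImageVolume
    hu: ImageVolume
    vois: VOISet
    activity_ratio: float
    name: str = "phantom"
    spheres: list[SphereSpec] = field(default_factory=list)
    body_radius: float = 0.0

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.activity.to_nifti(directory / "activity.nii")
        self.hu.to_nifti(directory / "hu.nii")
        self.vois.to_json(directory / "vois.json")
        meta = {
            "name": self.name,
            "activity_ratio": self.activity_ratio,
            "body_radius_mm": self.body_radius,
            "spheres": [
                {"center_mm": list(s.center), "diameter_mm": s.diameter, "activity_kbq_ml": s.activity}
                for s in self.spheres
            ],
        }
        (directory / "phantom.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PhantomSet":
        directory = Path(directory)
        meta = json.loads((directory / "phantom.json").read_text())
        return cls(
            activity=ImageVolume.from_nifti(directory / "activity.nii", "activity"),
            hu=ImageVolume.from_nifti(directory / "hu.nii", "hu"),
            vois=VOISet.from_json(directory / "vois.json"),
            activity_ratio=meta["activity_ratio"],
            name=meta["name"],
            spheres=[
                SphereSpec(tuple(s["center_mm"]), s["diameter_mm"], s["activity_kbq_ml"])
                for s in meta["spheres"]
            ],
            body_radius=meta.get("body_radius_mm", 0.0),
        )


# ---------------------------------------------------------------------------
# voxelization helpers (fractional sub-voxel sampling)
# ---------------------------------------------------------------------------

_SUBSAMPLES = 3


def _sub_offsets(n: int) -> np.ndarray:
    return (np.arange(n) + 0.5) / n - 0.5


def _sphere_fraction(vol: ImageVolume, center, radius, subsamples: int = _SUBSAMPLES) -> np.ndarray:
    """Per-voxel fraction inside a sphere, by sub-voxel sampling.

    ``subsamples=1`` degenerates to the binary center-of-voxel rule (useful
    when the fill must match the VOI membership rule exactly).
    """
    frac = np.zeros(vol.shape)
    coords = [vol.axis_coords(a) for a in range(3)]
    lo = [
        int(np.searchsorted(coords[a], center[a] - radius - vol.voxel_size[a]))
        for a in range(3)
    ]
    hi = [
        int(np.searchsorted(coords[a], center[a] + radius + vol.voxel_size[a]))
        for a in range(3)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return frac
    sub = [_sub_offsets(subsamples) * vol.voxel_size[a] for a in range(3)]
    # sub-point coordinates relative to center, per axis
    ax = [
        (coords[a][lo[a] : hi[a], None] + sub[a][None, :] - center[a]) ** 2
        for a in range(3)
    ]
    d2 = (
        ax[0][:, None, None, :, None, None]
        + ax[1][None, :, None, None, :, None]
        + ax[2][None, None, :, None, None, :]
    )
    inside = (d2 <= radius**2).mean(axis=(3, 4, 5))
    frac[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return frac


def _cylinder_fraction_xy(vol: ImageVolume, center_xy, radius, subsamples: int = _SUBSAMPLES) -> np.ndarray:
    """Per-voxel fraction inside an axial (z-aligned) cylinder."""
    xs = vol.axis_coords(0)
    ys = vol.axis_coords(1)
    sub = [_sub_offsets(subsamples) * vol.voxel_size[a] for a in range(2)]
    dx2 = (xs[:, None] + sub[0][None, :] - center_xy[0]) ** 2
    dy2 = (ys[:, None] + sub[1][None, :] - center_xy[1]) ** 2
    d2 = dx2[:, None, :, None] + dy2[None, :, None, :]
    frac2d = (d2 <= radius**2).mean(axis=(2, 3))
    return np.repeat(frac2d[:, :, None], vol.shape[2], axis=2)


def _blend(base: np.ndarray, frac: np.ndarray, value: float) -> np.ndarray:
    return base * (1.0 - frac) + value * frac


def _ring_positions(radius: float, n: int, z: float, start_deg: float = 0.0):
    angles = np.deg2rad(start_deg + 360.0 * np.arange(n) / n)
    return [(radius * math.cos(a), radius * math.sin(a), z) for a in angles]


def _check_vois(
    vois: VOISet, body_radius: float, z_extent: tuple[float, float], spheres: list[SphereSpec]
) -> None:
    """Geometric sanity: VOIs inside the body, background clear of spheres."""
    for v in vois.sphere_vois + vois.background_vois:
        rho = math.hypot(v.center[0], v.center[1])
        if rho + v.radius > body_radius + 1e-6:
            raise ValueError(f"VOI {v.label or v.center} extends outside the body")
        if not z_extent[0] - 1e-6 <= v.center[2] <= z_extent[1] + 1e-6:
            raise ValueError(f"VOI {v.label or v.center} outside the axial extent")
    for v in vois.background_vois:
        for s in spheres:
            d = math.dist(v.center, s.center)
            if d < v.radius + s.radius:
                raise ValueError(
                    f"background VOI {v.label or v.center} overlaps sphere at {s.center}"
                )


# ---------------------------------------------------------------------------
# phantom builders
# ---------------------------------------------------------------------------

NEMA_SPHERE_DIAMETERS = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
SMALL_TUMOR_DIAMETERS = (3.7, 4.8, 6.5, 7.7, 8.9, 9.7)
SPHERE_RING_RADIUS = 57.2  # mm, standard sphere-center ring of the IQ housing


def _base_volumes(shape, voxel_size, body_radius: float, subsamples: int = _SUBSAMPLES):
    act = ImageVolume(np.zeros(shape), voxel_size, content_kind="activity")
    hu = ImageVolume(np.full(shape, HU_AIR), voxel_size, content_kind="hu")
    body = _cylinder_fraction_xy(act, (0.0, 0.0), body_radius, subsamples)
    if body[act.shape[0] // 2, act.shape[1] // 2, 0] < 1.0:
        raise ValueError("grid too small to contain the body contour")
    max_r = min(shape[0] * act.voxel_size[0], shape[1] * act.voxel_size[1]) / 2.0
    if body_radius > max_r + 1e-9:
        raise ValueError(
            f"body radius {body_radius} mm does not fit the {shape} grid"
        )
    return act, hu, body


def _require_spheres_fit(spheres, shape, voxel_size, body_radius):
    half_z = shape[2] * voxel_size[2] / 2.0
    for s in spheres:
        rho = math.hypot(s.center[0], s.center[1])
        if rho + s.radius > body_radius or abs(s.center[2]) + s.radius > half_z:
            raise ValueError(
                f"grid too small: sphere d={s.diameter} mm at {s.center} "
                f"does not fit inside the body/axial extent"
            )


def make_nema_iq(
    shape: tuple[int, int, int] = (160, 160, 24),
    voxel_size: float | tuple[float, float, float] = 2.0,
    sphere_activity: float = 30.0,
    background_activity: float = 6.0,
    body_diameter: float = 280.0,
    sphere_diameters: tuple[float, ...] = NEMA_SPHERE_DIAMETERS,
    ring_radius: float = SPHERE_RING_RADIUS,
    n_background_vois: int = 12,
    background_voi_diameter: float = 37.0,
    edge_margin: float = 15.0,
    subsamples: int = _SUBSAMPLES,
) -> PhantomSet:
    """Image-quality phantom: six hot spheres in a warm water body.

    Spheres (default 10/13/17/22/28/37 mm) sit co-planar on a ring in the
    central transaxial slice, filled at 30 kBq/ml over a 6 kBq/ml background
    (5:1).  Twelve 37 mm background VOIs are placed deterministically on a
    ring in the sphere plane, angularly interleaved with the spheres and
    ``edge_margin`` clear of the body edge.
    """
    body_r = body_diameter / 2.0
    act, hu, body = _base_volumes(shape, voxel_size, body_r, subsamples)
    z0 = float(act.axis_coords(2)[act.shape[2] // 2])  # sphere plane on a slice
    centers = _ring_positions(ring_radius, len(sphere_diameters), z0)
    spheres = [
        SphereSpec(c, d, sphere_activity) for c, d in zip(centers, sphere_diameters)
    ]
    _require_spheres_fit(spheres, act.shape, act.voxel_size, body_r)

    a = background_activity * body
    h = _blend(np.full(act.shape, HU_AIR), body, HU_WATER)
    for s in spheres:
        frac = _sphere_fraction(act, s.center, s.radius, subsamples)
        a = _blend(a, frac, s.activity)
    act = act.like(a)
    hu = hu.like(h)

    sphere_vois = [
        VOI(s.center, s.diameter, f"{s.diameter:g}mm") for s in spheres
    ]
    bg_ring = body_r - edge_margin - background_voi_diameter / 2.0
    n_sph = len(sphere_diameters)
    bg_vois = [
        VOI(c, background_voi_diameter, f"bg{i:02d}")
        for i, c in enumerate(
            _ring_positions(bg_ring, n_background_vois, z0, start_deg=180.0 / n_sph)
        )
    ]
    vois = VOISet(sphere_vois, bg_vois)
    half_z = act.shape[2] * act.voxel_size[2] / 2.0
    _check_vois(vois, body_r, (-half_z, half_z), spheres)
    return PhantomSet(
        act, hu, vois, sphere_activity / background_activity, "nema_iq", spheres, body_r
    )


def make_small_tumor(
    shape: tuple[int, int, int] = (160, 160, 24),
    voxel_size: float | tuple[float, float, float] = 2.0,
    sphere_activity: float = 25.0,
    background_activity: float = 1.2,
    body_diameter: float = 280.0,
    sphere_diameters: tuple[float, ...] = SMALL_TUMOR_DIAMETERS,
    ring_radius: float = SPHERE_RING_RADIUS,
) -> PhantomSet:
    """Small-tumor phantom: the IQ housing with sub-centimetre hot spheres
    (3.7-9.7 mm) at 25 kBq/ml over a 1.2 kBq/ml background, evaluated with
    ten 20 mm background VOIs."""
    phantom = make_nema_iq(
        shape,
        voxel_size,
        sphere_activity,
        background_activity,
        body_diameter,
        sphere_diameters,
        ring_radius,
        n_background_vois=10,
        background_voi_diameter=20.0,
    )
    phantom.name = "small_tumor"
    return phantom


BONE_LUNG_CYLINDER_HU = (-800.0, 500.0, 1000.0)
BONE_LUNG_SPHERE_DIAMETERS = (8.5, 19.4)


def make_bone_lung(
    shape: tuple[int, int, int] = (128, 128, 24),
    voxel_size: float | tuple[float, float, float] = 2.0,
    sphere_activity: float = 30.0,
    background_activity: float = 6.0,
    body_diameter: float = 230.0,
    cylinder_hu: tuple[float, ...] = BONE_LUNG_CYLINDER_HU,
    cylinder_diameter: float = 50.0,
    cylinder_ring_radius: float = 60.0,
    sphere_diameters: tuple[float, float] = BONE_LUNG_SPHERE_DIAMETERS,
    sphere_z_offset: float = 12.0,
) -> PhantomSet:
    """Bone-lung phantom: three cold 50 mm cylinders (lung -800 HU, bone
    +500 HU and +1000 HU) inside a warm water body, each carrying a hot
    8.5 mm and a hot 19.4 mm sphere (30 kBq/ml) on its axis.

    The cylinders are cold in activity (solid housing material); the spheres
    inside them are water-filled (HU 0).  Six 37 mm background VOIs sit on a
    ring angularly between the cylinders.
    """
    body_r = body_diameter / 2.0
    act, hu, body = _base_volumes(shape, voxel_size, body_r)
    cyl_r = cylinder_diameter / 2.0
    if cylinder_ring_radius + cyl_r > body_r:
        raise ValueError("grid too small: cylinders do not fit inside the body")

    a = background_activity * body
    h = _blend(np.full(act.shape, HU_AIR), body, HU_WATER)
    z0 = float(act.axis_coords(2)[act.shape[2] // 2])
    names = []
    for hu_val in cylinder_hu:
        names.append("lung" if hu_val < -150 else "bone")
    # disambiguate the two bone cylinders by their HU
    labels = [
        f"{n}{int(v):+d}HU" if names.count(n) > 1 else n
        for n, v in zip(names, cylinder_hu)
    ]

    centers_xy = [
        (c[0], c[1])
        for c in _ring_positions(cylinder_ring_radius, len(cylinder_hu), 0.0, 90.0)
    ]
    spheres: list[SphereSpec] = []
    sphere_vois: list[VOI] = []
    for (cx, cy), hu_val, lab in zip(centers_xy, cylinder_hu, labels):
        frac = _cylinder_fraction_xy(act, (cx, cy), cyl_r)
        a = _blend(a, frac, 0.0)  # cold cylinder
        h = _blend(h, frac, hu_val)
        for d, zoff in zip(sphere_diameters, (-sphere_z_offset, sphere_z_offset)):
            s = SphereSpec((cx, cy, z0 + zoff), d, sphere_activity)
            spheres.append(s)
            sphere_vois.append(VOI(s.center, d, f"{lab}_{d:g}mm"))
            sfrac = _sphere_fraction(act, s.center, s.radius)
            a = _blend(a, sfrac, s.activity)
            h = _blend(h, sfrac, HU_WATER)  # water-filled sphere
    _require_spheres_fit(spheres, act.shape, act.voxel_size, body_r)
    act = act.like(a)
    hu = hu.like(h)

    # six 37 mm background VOIs on two rings at the angles midway between
    # the cylinders (the 230 mm housing is tight around three 50 mm inserts)
    bg_centers = _ring_positions(50.0, 3, z0, start_deg=150.0) + _ring_positions(
        90.0, 3, z0, start_deg=150.0
    )
    bg_vois = [VOI(c, 37.0, f"bg{i:02d}") for i, c in enumerate(bg_centers)]
    vois = VOISet(sphere_vois, bg_vois)
    half_z = act.shape[2] * act.voxel_size[2] / 2.0
    _check_vois(vois, body_r, (-half_z, half_z), spheres)
    # background VOIs must also be clear of the cold cylinders
    for v in bg_vois:
        for cx, cy in centers_xy:
            if math.hypot(v.center[0] - cx, v.center[1] - cy) < v.radius + cyl_r:
                raise ValueError(f"background VOI {v.label} overlaps a cylinder")
    return PhantomSet(
        act, hu, vois, sphere_activity / background_activity, "bone_lung", spheres, body_r
    )


# ---------------------------------------------------------------------------
# HU conversions
# ---------------------------------------------------------------------------


def segment_materials(
    hu: ImageVolume, material_specs: tuple[MaterialSpec, ...] = DEFAULT_MATERIALS
) -> ImageVolume:
    """Label every voxel by the HU interval of the configured materials.

    Returns an integer label volume; label ``i`` refers to
    ``material_specs[i]``.  With the default specs, air falls in the lung
    interval (air is treated as lung material).
    """
    validate_material_partition(material_specs)
    values = np.asarray(hu.values, dtype=float)
    labels = np.zeros(hu.shape, dtype=np.int8)
    for i, mat in enumerate(material_specs):
        lo, hi = mat.hu_range
        labels[(values >= lo) & (values < hi)] = i
    return hu.like(labels, content_kind="label")


def hu_to_mu(hu: ImageVolume) -> ImageVolume:
    """Piecewise-linear (bilinear) HU -> 511 keV attenuation map (1/mm).

    Anchored at mu = 0 for air (-1000 HU) and mu = 0.0096/mm for water
    (0 HU); above water the slope is ``MU_BONE_SLOPE`` per HU (densifying
    trabecular/cortical bone more slowly than the water segment, as in
    standard CT-based attenuation conversion).  Monotone non-decreasing.
    """
    values = np.asarray(hu.values, dtype=float)
    below = MU_WATER_511KEV * np.clip((values + 1000.0) / 1000.0, 0.0, None)
    above = MU_WATER_511KEV + MU_BONE_SLOPE * values
    mu = np.where(values <= 0, below, above)
    return hu.like(mu, content_kind="mu")


# ---------------------------------------------------------------------------
# VOI sampling
# ---------------------------------------------------------------------------


def voi_mask(volume: ImageVolume, voi: VOI) -> np.ndarray:
    """Boolean voxel mask of a spherical VOI (voxel-center-inside rule)."""
    x, y, z = volume.meshgrid()
    d2 = (x - voi.center[0]) ** 2 + (y - voi.center[1]) ** 2 + (z - voi.center[2]) ** 2
    return d2 <= voi.radius**2


def voi_values(volume: ImageVolume, voi: VOI) -> np.ndarray:
    """Voxel values inside a VOI; error if the VOI voxelizes to nothing."""
    vals = volume.values[voi_mask(volume, voi)]
    if vals.size == 0:
        raise ValueError(f"VOI {voi.label or voi.center} contains no voxel centers")
    return vals
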