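"""3D voxel volumes with physical geometry.

:class:`ImageVolume` is the single in-memory container used throughout the
package for activity estimates (kBq/ml), CT numbers (HU), linear attenuation
maps (1/mm at 511 keV), material-label maps and sensitivity images.  The grid
is a regular axis-aligned lattice; ``origin`` is the physical coordinate (mm)
of the *center* of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

CONTENT_KINDS = ("activity", "hu", "mu", "label", "sensitivity", "generic")


@dataclass
class ImageVolume:
    """A 3D voxel grid with physical voxel size.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  Axis order is (x, y, z); the transaxial plane is
        (x, y) and z is the scanner axis.
    voxel_size : tuple of float
        Edge length of a voxel per axis, in mm.  Must be positive.
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    content_kind : str
        One of ``activity | hu | mu | label | sensitivity | generic``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]
    content_kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 per axis")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.origin is None:
            # default: volume centered on the physical origin
            self.origin = tuple(
                -(n - 1) / 2.0 * v for n, v in zip(self.values.shape, self.voxel_size)
            )
        self.origin = tuple(float(v) for v in self.origin)
        if self.content_kind not in CONTENT_KINDS:
            raise ValueError(f"unknown content_kind {self.content_kind!r}")
        if self.content_kind == "activity" and np.any(self.values < 0):
            raise ValueError("activity volumes must be non-negative")

    # -- geometry -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays (mm), shaped like ``values``."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def same_grid(self, other: "ImageVolume", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def like(self, values: np.ndarray, content_kind: str | None = None) -> "ImageVolume":
        """New volume on the same grid with different values."""
        return replace(
            self, values=values, content_kind=content_kind or self.content_kind
        )

    def copy(self) -> "ImageVolume":
        return replace(self, values=self.values.copy())

    # -- I/O ------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float64), affine)
        img.header["descrip"] = self.content_kind.encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, content_kind: str | None = None) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        voxel = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        if content_kind is None:
            descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode() or "generic"
            content_kind = descrip if descrip in CONTENT_KINDS else "generic"
        return cls(np.asarray(img.dataobj, dtype=np.float64), voxel, origin, content_kind)

    def to_raw(self, path: str | Path) -> None:
        """Flat binary (float64, C order) + JSON sidecar header fallback."""
        path = Path(path)
        np.asarray(self.values, dtype=np.float64).tofile(path)
        header = {
            "shape": list(self.values.shape),
            "voxel_size_mm": list(self.voxel_size),
            "origin_mm": list(self.origin),
            "content_kind": self.content_kind,
            "dtype": "float64",
            "order": "C",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def from_raw(cls, path: str | Path) -> "ImageVolume":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = np.fromfile(path, dtype=np.float64).reshape(header["shape"])
        return cls(
            values,
            tuple(header["voxel_size_mm"]),
            tuple(header["origin_mm"]),
            header["content_kind"],
        )
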