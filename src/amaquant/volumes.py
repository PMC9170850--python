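"""Image and geometry data model plus NIfTI / JSON input-output.

All physical coordinates are millimetres. Volumes use (x, y, z) axis order
with z the cranio-caudal (trans-axial slicing) axis; indices are 0-based and
a voxel is identified by its *center*:

    center(i, j, k) = origin + (i, j, k) * spacing

Only axis-aligned NIfTI affines are supported: an oblique affine would raise
resampling questions this tool deliberately does not address.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Aortic region tags, in cranio-caudal order.
REGION_LABELS = ("thoracic", "suprarenal", "neck", "aneurysm")


@dataclass(frozen=True)
class ScalarVolume:
    """A 3-D voxel grid of scalar intensities with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities — SUV for PET, Hounsfield units for CT.
    spacing : tuple of float
        Per-axis voxel edge length in mm; strictly positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D image, got {data.ndim}-D")
        n_bad = int(np.count_nonzero(~np.isfinite(data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must have 3 components")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates of all voxels along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) physical coordinates of the first and last voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """A new volume on the same grid with different data."""
        return ScalarVolume(data, self.spacing, self.origin)


def voxel_centers(vol: ScalarVolume) -> np.ndarray:
    """Physical centers of every voxel, shape ``(*vol.shape, 3)``."""
    ax = [vol.axis_coords(a) for a in range(3)]
    grids = np.meshgrid(*ax, indexing="ij")
    return np.stack(grids, axis=-1)


@dataclass(frozen=True)
class Sphere:
    """A sphere in physical space (mm)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        center = tuple(float(c) for c in self.center)
        if len(center) != 3:
            raise ValueError("sphere center must have 3 components")
        if self.radius < 0:
            raise ValueError(f"sphere radius must be >= 0, got {self.radius}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "radius", float(self.radius))

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0


@dataclass(frozen=True)
class Centerline:
    """Ordered polyline through a vessel lumen with per-point radius and region label.

    ``labels`` must form contiguous runs along the ordering (a region is a
    single stretch of the vessel, not an interleaving).
    """

    points: np.ndarray  # (n, 3) mm
    radii: np.ndarray  # (n,) mm
    labels: tuple[str, ...]

    def __post_init__(self):
        points = np.asarray(self.points, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        labels = tuple(str(l) for l in self.labels)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("centerline points must be an (n, 3) array")
        n = points.shape[0]
        if n < 2:
            raise ValueError("centerline needs at least 2 points")
        if radii.shape != (n,) or len(labels) != n:
            raise ValueError("points, radii and labels must have equal length")
        if np.any(radii <= 0):
            raise ValueError("all centerline radii must be > 0")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")
        seen: list[str] = []
        for lab in labels:
            if not seen or seen[-1] != lab:
                if lab in seen:
                    raise ValueError(f"label {lab!r} is not a contiguous run")
                seen.append(lab)
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def label_order(self) -> tuple[str, ...]:
        out: list[str] = []
        for lab in self.labels:
            if not out or out[-1] != lab:
                out.append(lab)
        return tuple(out)

    def for_label(self, label: str) -> "Centerline":
        """The contiguous sub-centerline carrying ``label``."""
        idx = np.flatnonzero(np.asarray(self.labels, dtype=object) == label)
        if idx.size == 0:
            raise KeyError(f"centerline has no points labelled {label!r}")
        if idx.size < 2:
            raise ValueError(f"label {label!r} covers fewer than 2 points")
        sl = slice(idx[0], idx[-1] + 1)
        return Centerline(self.points[sl], self.radii[sl], self.labels[sl])

    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class VOIMask:
    """Boolean voxel selection aligned to a specific volume's grid."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask.astype(bool)
        if mask.ndim != 3:
            raise ValueError("VOI mask must be 3-D")
        object.__setattr__(self, "mask", mask)

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


# --------------------------------------------------------------------------
# NIfTI I/O

def _check_axis_aligned(affine: np.ndarray) -> None:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > 1e-6:
        raise ValueError("oblique affine: only axis-aligned volumes are supported")
    if np.any(np.diag(rot) <= 0):
        raise ValueError("flipped axes: only positive axis-aligned affines are supported")


def read_volume(path) -> ScalarVolume:
    """Read a 3-D NIfTI-1 volume.

    Raises on missing files, non-3-D images, oblique affines and non-finite
    voxels (the error names the affected voxel count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D image, got {data.ndim}-D in {path}")
    affine = img.affine
    _check_axis_aligned(affine)
    spacing = tuple(float(s) for s in np.diag(affine)[:3])
    origin = tuple(float(o) for o in affine[:3, 3])
    return ScalarVolume(data, spacing, origin)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a volume as NIfTI-1, float32, spacing/origin encoded in the affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Geometry JSON I/O

def save_sphere(s: Sphere, path) -> None:
    Path(path).write_text(json.dumps({"center": list(s.center), "radius_mm": s.radius}))


def load_sphere(path) -> Sphere:
    d = json.loads(Path(path).read_text())
    return Sphere(tuple(d["center"]), float(d["radius_mm"]))


def save_centerline(line: Centerline, path) -> None:
    d = {
        "points": line.points.tolist(),
        "radii": line.radii.tolist(),
        "labels": list(line.labels),
    }
    Path(path).write_text(json.dumps(d))


def load_centerline(path) -> Centerline:
    d = json.loads(Path(path).read_text())
    return Centerline(np.asarray(d["points"]), np.asarray(d["radii"]), tuple(d["labels"]))
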