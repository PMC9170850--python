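"""Voxelization of geometric volumes of interest.

Every operation here converts a geometric description — sphere, tube swept
along a centerline, trans-axial disk slabs — into a boolean `VOIMask` on a
volume's grid. Voxel inclusion is strictly center-in-geometry: a voxel
belongs to a VOI iff its *center* satisfies the geometric predicate. There is
no partial-volume weighting, so every mask is exactly reproducible by an
exhaustive loop over voxel centers.

Boundary conventions: spheres select centers at distance strictly less than
the radius (so a zero-radius sphere is empty); tubes and disks select centers
at distance less than or equal to the local radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import Centerline, ScalarVolume, Sphere, VOIMask


@dataclass(frozen=True)
class SliceRegion:
    """A z-index range with one in-plane disk per trans-axial slice.

    ``centers[i]`` / ``radii[i]`` describe the disk on slice ``z_start + i``.
    """

    z_start: int
    z_end: int  # inclusive
    centers: np.ndarray  # (n, 2) in-plane (x, y) mm
    radii: np.ndarray  # (n,) mm

    def __post_init__(self):
        if self.z_start > self.z_end:
            raise ValueError("empty z-range: z_start > z_end")
        n = self.z_end - self.z_start + 1
        centers = np.asarray(self.centers, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if centers.shape != (n, 2) or radii.shape != (n,):
            raise ValueError("need one disk (center, radius) per slice in the range")
        if np.any(radii <= 0):
            raise ValueError("disk radii must be > 0")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)


def sphere_mask(vol: ScalarVolume, s: Sphere) -> VOIMask:
    """Select voxels whose centers lie strictly inside the sphere.

    The sphere must be interior to the grid: atrial blood-pool and threshold
    spheres are always placed well inside the field of view, so a clipped
    sphere indicates a placement error rather than a measurement choice.
    """
    lo, hi = vol.bounds
    c = np.asarray(s.center, dtype=float)
    half = np.asarray(vol.spacing) / 2.0
    if np.any(c + s.radius < lo - half) or np.any(c - s.radius > hi + half):
        raise ValueError("sphere entirely outside grid")
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError("sphere center outside the volume's physical bounds")
    d2 = _dist2_to_point(vol, c)
    mask = d2 < s.radius**2
    if s.radius > 0 and (np.any(c - s.radius < lo - half) or np.any(c + s.radius > hi + half)):
        inside = mask.sum() * vol.voxel_volume_mm3
        frac = max(0.0, 1.0 - inside / s.volume_mm3)
        raise ValueError(
            f"sphere partially outside grid (approx. {frac:.1%} of its volume clipped)"
        )
    prov = f"sphere(center={s.center}, radius={s.radius} mm)"
    return VOIMask(mask, prov)


def _dist2_to_point(vol: ScalarVolume, p: np.ndarray) -> np.ndarray:
    dx = vol.axis_coords(0) - p[0]
    dy = vol.axis_coords(1) - p[1]
    dz = vol.axis_coords(2) - p[2]
    return (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )


def tube_mask(
    vol: ScalarVolume, line: Centerline, fixed_radius: float | None = None
) -> VOIMask:
    """Sweep a tube along a centerline polyline.

    A voxel is selected iff its perpendicular projection onto some segment
    falls within that segment and its distance to the projected point is
    <= the local radius there. The sweep has no end caps — a straight
    two-point centerline of length h and radius r selects exactly the
    finite cylinder pi*r^2*h — matching how a vessel VOI terminates at its
    end planes. With ``fixed_radius`` the radius is constant (the
    uniform-cylinder mode); otherwise per-point radii are interpolated
    linearly in arc length along each segment. Ties between segments
    resolve to the earlier segment.
    """
    if len(line) < 2:
        raise ValueError("degenerate centerline: need at least 2 points")
    lo, hi = vol.bounds
    inside = np.all((line.points >= lo) & (line.points <= hi), axis=1)
    if inside.sum() < 2:
        raise ValueError("need at least 2 centerline points inside the grid")

    if fixed_radius is not None:
        if fixed_radius <= 0:
            raise ValueError("fixed_radius must be > 0")
        radii = np.full(len(line), float(fixed_radius))
    else:
        radii = line.radii
    rmax = float(radii.max())

    # restrict work to the tube's bounding box
    bb_lo = line.points.min(axis=0) - rmax
    bb_hi = line.points.max(axis=0) + rmax
    sl = []
    for a in range(3):
        coords = vol.axis_coords(a)
        idx = np.flatnonzero((coords >= bb_lo[a]) & (coords <= bb_hi[a]))
        if idx.size == 0:
            return VOIMask(np.zeros(vol.shape, dtype=bool), "tube(empty)")
        sl.append(slice(int(idx[0]), int(idx[-1]) + 1))

    ax = [vol.axis_coords(a)[sl[a]] for a in range(3)]
    grids = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)  # (m, 3)

    best_d2 = np.full(pts.shape[0], np.inf)
    best_r = np.zeros(pts.shape[0])
    for i in range(len(line) - 1):
        p0, p1 = line.points[i], line.points[i + 1]
        d = p1 - p0
        L2 = float(d @ d)
        t = (pts - p0) @ d / L2
        inband = (t >= 0.0) & (t <= 1.0)  # perpendicular band of this segment
        diff = pts - (p0[None, :] + t[:, None] * d[None, :])
        d2 = np.einsum("ij,ij->i", diff, diff)
        better = inband & (d2 < best_d2)  # strict: earlier segment wins ties
        best_d2[better] = d2[better]
        best_r[better] = radii[i] + t[better] * (radii[i + 1] - radii[i])

    sub = best_d2 <= best_r**2
    mask = np.zeros(vol.shape, dtype=bool)
    mask[sl[0], sl[1], sl[2]] = sub.reshape([s.stop - s.start for s in sl])
    mode = f"fixed_radius={fixed_radius}" if fixed_radius is not None else "variable_radius"
    prov = f"tube({len(line)} points, {mode})"
    return VOIMask(mask, prov)


def slice_disk_masks(
    vol: ScalarVolume, region: SliceRegion, slab_thickness_mm: float
) -> list[VOIMask]:
    """Tile a z-range into consecutive slabs of trans-axial disk ROIs.

    Each slab groups ``round(slab_thickness / z_spacing)`` consecutive slices
    (the last slab may be thinner); within a slab a voxel is selected iff its
    in-plane center lies within that slice's disk. Masks are returned in
    cranio-caudal order.
    """
    zsp = vol.spacing[2]
    if slab_thickness_mm < zsp:
        raise ValueError("slab thickness must be >= the grid's z spacing")
    per = max(1, int(round(slab_thickness_mm / zsp)))
    xs = vol.axis_coords(0)
    ys = vol.axis_coords(1)

    n = region.z_end - region.z_start + 1
    out: list[VOIMask] = []
    for start in range(0, n, per):
        stop = min(start + per, n)
        mask = np.zeros(vol.shape, dtype=bool)
        for i in range(start, stop):
            z = region.z_start + i
            cx, cy = region.centers[i]
            r = region.radii[i]
            d2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
            mask[:, :, z] = d2 <= r**2
        out.append(
            VOIMask(mask, f"disk_slab(z={region.z_start + start}..{region.z_start + stop - 1})")
        )
    return out


def subtract_mask(a: VOIMask, b: VOIMask) -> VOIMask:
    """a AND NOT b; used to carve exclusion zones (e.g. vertebral spill-over)."""
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return VOIMask(a.mask & ~b.mask, f"({a.provenance}) minus ({b.provenance})")


def slice_region_from_centerline(
    vol: ScalarVolume, line: Centerline, label: str | None = None
) -> SliceRegion:
    """Per-slice disks tracking a (z-monotonic) centerline.

    For every trans-axial slice whose z-center falls within the centerline's
    z extent, the disk center (x, y) and radius are interpolated along the
    polyline at that z. The centerline must be monotone in z, which holds for
    an aorta traced cranio-caudally.
    """
    if label is not None:
        line = line.for_label(label)
    z = line.points[:, 2]
    if np.any(np.diff(z) <= 0):
        order = np.argsort(z)
        z = z[order]
        pts = line.points[order]
        radii = line.radii[order]
        if np.any(np.diff(z) <= 0):
            raise ValueError("centerline must be strictly monotone in z for slice ROIs")
    else:
        pts, radii = line.points, line.radii
    zc = vol.axis_coords(2)
    sel = np.flatnonzero((zc >= z[0]) & (zc <= z[-1]))
    if sel.size == 0:
        raise ValueError("centerline z extent contains no slice centers")
    zq = zc[sel]
    cx = np.interp(zq, z, pts[:, 0])
    cy = np.interp(zq, z, pts[:, 1])
    rr = np.interp(zq, z, radii)
    return SliceRegion(int(sel[0]), int(sel[-1]), np.stack([cx, cy], axis=1), rr)
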