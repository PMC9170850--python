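"""Uptake measurement: background blood pool, thresholded accumulation, TBR and AMA.

Definitions
-----------
Cumulative SUV of a VOI is the voxel-volume-weighted sum, in SUV*cm^3, so
that cumulative / volume is the mean voxel SUV. With that convention:

* ``TBR_mean``  = (unweighted mean of per-slab SUV_mean) / background
* ``TBR_max``   = (max over slabs of SUV_max) / background
* ``AMA_mean``  = (cumulative SUV / volume) / background
* ``AMA_max``   = SUV_max / background

where background is the mean blood-pool SUV from two atrial spheres. The
upper-intensity threshold excludes voxels *strictly above* the threshold
from cumulative SUV, volume, mean and max — the voxel that defines the
threshold (the sphere's own max) is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .voi import (
    slice_disk_masks,
    slice_region_from_centerline,
    sphere_mask,
    subtract_mask,
    tube_mask,
)
from .volumes import Centerline, ScalarVolume, Sphere, VOIMask


@dataclass(frozen=True)
class BackgroundActivity:
    """Mean blood-pool SUV and the per-sphere bookkeeping behind it."""

    value: float  # mean blood-pool SUV
    sphere_cumulative_suv: tuple[float, ...]  # SUV*cm^3 per sphere
    sphere_volumes_cm3: tuple[float, ...]
    notes: tuple[str, ...] = ()

    @property
    def total_volume_cm3(self) -> float:
        return float(sum(self.sphere_volumes_cm3))


@dataclass(frozen=True)
class RegionResult:
    """Measurements for one aortic region under one method/option set."""

    label: str
    method: str  # "tbr" or "ama"
    cumulative_suv: float  # SUV*cm^3
    volume_cm3: float
    suv_mean: float
    suv_max: float
    threshold: float | None = None
    excluded_voxel_count: int = 0
    tbr_mean: float | None = None
    tbr_max: float | None = None
    ama_mean: float | None = None
    ama_max: float | None = None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "method": self.method,
            "cumulative_suv": self.cumulative_suv,
            "volume_cm3": self.volume_cm3,
            "suv_mean": self.suv_mean,
            "suv_max": self.suv_max,
            "threshold": self.threshold,
            "excluded_voxel_count": self.excluded_voxel_count,
            "tbr_mean": self.tbr_mean,
            "tbr_max": self.tbr_max,
            "ama_mean": self.ama_mean,
            "ama_max": self.ama_max,
        }


@dataclass(frozen=True)
class StudySpheres:
    """Sphere placements for a study: atrial blood pool pair, per-region threshold."""

    blood: tuple[Sphere, Sphere]
    threshold: dict = field(default_factory=dict)  # region label -> Sphere


def background_activity(pet: ScalarVolume, s1: Sphere, s2: Sphere) -> BackgroundActivity:
    """Mean blood-pool SUV from two spheres.

    The cumulative SUV across both spheres is divided by their total
    voxelized volume, i.e. the volume-weighted mean voxel SUV. Overlapping
    spheres are flagged in the notes but not fatal.
    """
    m1 = sphere_mask(pet, s1)
    m2 = sphere_mask(pet, s2)
    notes = []
    if np.any(m1.mask & m2.mask):
        notes.append("blood-pool spheres overlap")
    cums, vols = [], []
    for m in (m1, m2):
        if m.count == 0:
            raise ValueError("blood-pool sphere selects no voxels")
        vols.append(m.count * pet.voxel_volume_cm3)
        cums.append(float(pet.data[m.mask].sum()) * pet.voxel_volume_cm3)
    value = sum(cums) / sum(vols)
    return BackgroundActivity(value, tuple(cums), tuple(vols), tuple(notes))


def threshold_from_sphere(pet: ScalarVolume, s: Sphere) -> float:
    """Maximum SUV within a sphere, used as an upper-intensity threshold."""
    m = sphere_mask(pet, s)
    if m.count == 0:
        raise ValueError("threshold sphere selects no voxels")
    return float(pet.data[m.mask].max())


def accumulate(
    pet: ScalarVolume, voi: VOIMask, threshold: float | None = None
) -> tuple[float, float, float, float, int]:
    """(cumulative SUV, volume cm^3, SUV_mean, SUV_max, excluded count) over a VOI.

    With a threshold t, voxels with SUV > t are excluded from all four
    accumulated quantities (ties at t are retained).
    """
    if voi.shape != pet.shape:
        raise ValueError("VOI mask does not match the volume grid")
    if voi.count == 0:
        raise ValueError("VOI is empty")
    vals = pet.data[voi.mask]
    excluded = 0
    if threshold is not None:
        keep = vals <= threshold
        excluded = int(vals.size - keep.sum())
        vals = vals[keep]
        if vals.size == 0:
            raise ValueError("threshold removes entire region")
    vv = pet.voxel_volume_cm3
    volume = vals.size * vv
    cumulative = float(vals.sum()) * vv
    return cumulative, volume, cumulative / volume, float(vals.max()), excluded


def ama_region(
    pet: ScalarVolume,
    voi: VOIMask,
    bg: BackgroundActivity,
    threshold: float | None = None,
    label: str = "",
) -> RegionResult:
    """Microcalcification activity of one region's centerline VOI."""
    if bg.value <= 0:
        raise ValueError("background activity must be > 0")
    cum, vol, mean, mx, excl = accumulate(pet, voi, threshold)
    return RegionResult(
        label=label,
        method="ama",
        cumulative_suv=cum,
        volume_cm3=vol,
        suv_mean=mean,
        suv_max=mx,
        threshold=threshold,
        excluded_voxel_count=excl,
        ama_mean=mean / bg.value,
        ama_max=mx / bg.value,
    )


def tbr_region(
    pet: ScalarVolume,
    slabs: list[VOIMask],
    bg: BackgroundActivity,
    exclusion: VOIMask | None = None,
    label: str = "",
) -> RegionResult:
    """Tissue-to-background ratios from trans-axial slab ROIs.

    Per-slab SUV_mean / SUV_max are computed on the slab minus the exclusion
    mask (vertebral overspill carve-out); the region TBR_mean is the
    unweighted mean of slab means, TBR_max the global max. Slabs emptied by
    the exclusion are dropped and noted.
    """
    if bg.value <= 0:
        raise ValueError("background activity must be > 0")
    if not slabs:
        raise ValueError("no slabs given")
    means, maxes = [], []
    cum_total, vol_total = 0.0, 0.0
    dropped = 0
    for slab in slabs:
        if exclusion is not None:
            slab = subtract_mask(slab, exclusion)
        if slab.count == 0:
            dropped += 1
            continue
        cum, vol, mean, mx, _ = accumulate(pet, slab)
        means.append(mean)
        maxes.append(mx)
        cum_total += cum
        vol_total += vol
    if not means:
        raise ValueError("all slabs empty after exclusion")
    notes = (f"{dropped} slab(s) emptied by exclusion",) if dropped else ()
    suv_mean = float(np.mean(means))
    suv_max = float(np.max(maxes))
    return RegionResult(
        label=label,
        method="tbr",
        cumulative_suv=cum_total,
        volume_cm3=vol_total,
        suv_mean=suv_mean,
        suv_max=suv_max,
        tbr_mean=suv_mean / bg.value,
        tbr_max=suv_max / bg.value,
        notes=notes,
    )


def analyze_study(
    pet: ScalarVolume,
    ct: ScalarVolume | None,
    centerline: Centerline,
    spheres: StudySpheres,
    method: str,
    *,
    threshold: bool = False,
    variable_radius: bool = False,
    slab_thickness_mm: float = 3.0,
    exclusion: VOIMask | None = None,
    regions: tuple[str, ...] | None = None,
) -> list[RegionResult]:
    """Run one quantification method over every labelled aortic region.

    For AMA, the region VOI is the centerline tube — per-point radii when
    ``variable_radius`` is on, otherwise a uniform cylinder at the region's
    maximum annotated radius. With ``threshold`` on, each region's upper
    intensity threshold is the SUV_max of its configured threshold sphere.
    For TBR, the region is tiled into trans-axial disk slabs of
    ``slab_thickness_mm`` tracking the centerline, with an optional
    exclusion mask. The CT volume is carried for landmarking only and is not
    consumed by the measurements. Deterministic.
    """
    if method not in ("tbr", "ama"):
        raise ValueError(f"unknown method {method!r}")
    bg = background_activity(pet, *spheres.blood)
    wanted = regions if regions is not None else centerline.label_order
    results: list[RegionResult] = []
    for label in wanted:
        sub = centerline.for_label(label)  # KeyError if the label is missing
        if method == "ama":
            thr = None
            if threshold:
                if label not in spheres.threshold:
                    raise ValueError(f"missing threshold sphere for region {label!r}")
                thr = threshold_from_sphere(pet, spheres.threshold[label])
            fixed = None if variable_radius else float(sub.radii.max())
            voi = tube_mask(pet, sub, fixed_radius=fixed)
            results.append(ama_region(pet, voi, bg, thr, label))
        else:
            region = slice_region_from_centerline(pet, sub)
            slabs = slice_disk_masks(pet, region, slab_thickness_mm)
            results.append(tbr_region(pet, slabs, bg, exclusion, label))
    return results
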