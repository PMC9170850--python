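"""Synthetic co-registered PET/CT phantoms of an abdominal aorta.

The phantom emulates the imaging situation this tool is built for: an
infrarenal aorta whose radius swells smoothly into an aneurysm, filled with
blood-pool activity and wrapped in a higher-uptake wall, with a parallel
high-uptake vertebral column close behind it. Convolving with a Gaussian
point-spread function reproduces the spill-over of vertebral signal into the
aorta that motivates the maximum-threshold correction; the pre-blur image is
kept as ground truth so every measurement can be scored against a known
answer.

The radius profile is a Gaussian bulge on a constant neck radius,

    r(z) = r_neck + (r_max - r_neck) * exp(-(z - z_c)^2 / (2 * s^2)),

with ``s = extent / 2.355`` so that ``extent`` reads as the bulge's full
width at half maximum. Geometry is deliberately simple — straight vertical
centerline, single vertebral cylinder — because only the measurement
operations, not anatomy rendering, are under test here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .quant import StudySpheres
from .volumes import REGION_LABELS, Centerline, ScalarVolume, Sphere

FWHM_TO_SIGMA = 2.355  # full width at half maximum of a Gaussian, in sigmas

#: CT attenuation values (HU) used to encode the phantom geometry.
CT_BACKGROUND_HU = -50.0
CT_AORTA_HU = 45.0
CT_VERTEBRA_HU = 300.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the digital phantom; defaults give the standard study phantom.

    SUVs are the *true* (pre-blur, pre-noise) activities. The default blood
    SUV of 2 and wall SUV of 4 put TBR/AMA on the scale seen clinically
    (ratios around 1.5-2.5); the vertebral SUV of 20 (5x wall) reproduces the
    intense physiological vertebral uptake whose spill-over the threshold
    correction targets. The 4 mm point-spread sigma is of the order of a
    clinical PET reconstruction's effective resolution.
    """

    shape: tuple[int, int, int] = (80, 64, 80)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    blood_suv: float = 2.0
    wall_suv: float = 4.0
    vertebra_suv: float = 20.0
    neck_radius_mm: float = 10.0
    aneurysm_max_radius_mm: float = 20.0
    aneurysm_center_z_mm: float = 120.0
    aneurysm_extent_mm: float = 50.0
    # the aneurysm sac typically abuts the vertebral body: 1 mm gap at the belly
    vertebra_offset_mm: float = 36.0
    vertebra_radius_mm: float = 15.0
    pool_offset_mm: float = 41.0  # blood pool (atrial surrogate), +y of the aorta
    pool_radius_mm: float = 13.0
    wall_thickness_mm: float = 3.0
    psf_sigma_mm: float = 4.0
    noise_sd: float = 0.1
    seed: int = 0
    #: z boundaries (mm) of the four regions, cranio-caudal:
    #: thoracic | suprarenal | neck | aneurysm
    region_z_bounds_mm: tuple[float, ...] = (10.0, 40.0, 70.0, 90.0, 150.0)

    def __post_init__(self):
        for name in ("blood_suv", "wall_suv", "vertebra_suv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aneurysm_max_radius_mm < self.neck_radius_mm:
            raise ValueError("aneurysm_max_radius_mm must be >= neck_radius_mm")
        if self.psf_sigma_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma_mm and noise_sd must be >= 0")
        if len(self.region_z_bounds_mm) != len(REGION_LABELS) + 1:
            raise ValueError("region_z_bounds_mm needs one boundary per region edge")
        if np.any(np.diff(self.region_z_bounds_mm) <= 0):
            raise ValueError("region z boundaries must increase cranio-caudally")

    def radius_at(self, z) -> np.ndarray:
        """True aortic radius profile r(z) in mm."""
        z = np.asarray(z, dtype=float)
        s = self.aneurysm_extent_mm / FWHM_TO_SIGMA
        bulge = (self.aneurysm_max_radius_mm - self.neck_radius_mm) * np.exp(
            -((z - self.aneurysm_center_z_mm) ** 2) / (2.0 * s**2)
        )
        return self.neck_radius_mm + bulge


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth recorded from the pre-blur, pre-noise phantom."""

    blood_suv: float
    region_suv_mean: dict
    region_suv_max: dict
    region_z_bounds_mm: tuple[float, ...]
    profile_z_mm: np.ndarray
    profile_radius_mm: np.ndarray
    aorta_mask: np.ndarray  # bool, lumen + wall, congruent with the grid

    def region_mask(self, vol: ScalarVolume, label: str) -> np.ndarray:
        """Truth aortic voxels restricted to one region's z span."""
        i = REGION_LABELS.index(label)
        z0, z1 = self.region_z_bounds_mm[i], self.region_z_bounds_mm[i + 1]
        zc = vol.axis_coords(2)
        in_z = (zc >= z0) & (zc <= z1)
        out = self.aorta_mask.copy()
        out[:, :, ~in_z] = False
        return out


def aorta_axis(spec: PhantomSpec) -> tuple[float, float]:
    """In-plane (x, y) position of the aortic centerline, mm."""
    extent_x = (spec.shape[0] - 1) * spec.spacing[0]
    extent_y = (spec.shape[1] - 1) * spec.spacing[1]
    # center the aorta-vertebra pair in x, aorta on the left
    return (extent_x - spec.vertebra_offset_mm) / 2.0, extent_y / 2.0


def vertebra_axis(spec: PhantomSpec) -> tuple[float, float]:
    ax, ay = aorta_axis(spec)
    return ax + spec.vertebra_offset_mm, ay


def _pool_geometry(spec: PhantomSpec) -> tuple[float, float, float, float]:
    """(x, y, z_lo, z_hi) of the blood-pool cylinder."""
    ax, ay = aorta_axis(spec)
    z0 = spec.region_z_bounds_mm[0]
    return ax, ay + spec.pool_offset_mm, z0 + 5.0, z0 + 65.0


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, ScalarVolume, Centerline, PhantomTruth]:
    """Build the phantom: (PET, CT, centerline, truth). Deterministic per seed."""
    margin = 2.0 * spec.psf_sigma_mm
    ax_x, ax_y = aorta_axis(spec)
    px, py, pz0, pz1 = _pool_geometry(spec)
    lo_x = ax_x - spec.aneurysm_max_radius_mm
    hi_x = ax_x + spec.vertebra_offset_mm + spec.vertebra_radius_mm
    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    if lo_x < margin or hi_x > extent[0] - margin:
        raise ValueError("phantom geometry exceeds grid in x (including blur margin)")
    if ax_y - spec.aneurysm_max_radius_mm < margin:
        raise ValueError("phantom geometry exceeds grid in y (including blur margin)")
    if py + spec.pool_radius_mm > extent[1] - margin:
        raise ValueError("phantom geometry exceeds grid in y (including blur margin)")
    z0, z4 = spec.region_z_bounds_mm[0], spec.region_z_bounds_mm[-1]
    if z0 < margin or z4 > extent[2] - margin:
        raise ValueError("phantom geometry exceeds grid in z (including blur margin)")
    if spec.vertebra_offset_mm <= spec.aneurysm_max_radius_mm + spec.vertebra_radius_mm:
        raise ValueError("vertebra overlaps the aorta")
    if spec.pool_offset_mm <= spec.aneurysm_max_radius_mm + spec.pool_radius_mm:
        raise ValueError("blood pool overlaps the aorta")

    grid = ScalarVolume(np.zeros(spec.shape), spec.spacing)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    d_aorta = np.sqrt((xs[:, None] - ax_x) ** 2 + (ys[None, :] - ax_y) ** 2)
    d_vert = np.sqrt(
        (xs[:, None] - (ax_x + spec.vertebra_offset_mm)) ** 2 + (ys[None, :] - ax_y) ** 2
    )
    r_z = spec.radius_at(zs)
    in_z = (zs >= z0) & (zs <= z4)

    aorta = (d_aorta[:, :, None] <= r_z[None, None, :]) & in_z[None, None, :]
    lumen = (d_aorta[:, :, None] <= (r_z - spec.wall_thickness_mm)[None, None, :]) & in_z[
        None, None, :
    ]
    wall = aorta & ~lumen
    vert = (d_vert <= spec.vertebra_radius_mm)[:, :, None] & in_z[None, None, :]
    d_pool = np.sqrt((xs[:, None] - px) ** 2 + (ys[None, :] - py) ** 2)
    pool = (d_pool <= spec.pool_radius_mm)[:, :, None] & ((zs >= pz0) & (zs <= pz1))[
        None, None, :
    ]

    pet = np.zeros(spec.shape)
    pet[lumen] = spec.blood_suv
    pet[wall] = spec.wall_suv
    pet[pool] = spec.blood_suv
    pet[vert] = spec.vertebra_suv

    ct = np.full(spec.shape, CT_BACKGROUND_HU)
    ct[aorta] = CT_AORTA_HU
    ct[pool] = CT_AORTA_HU
    ct[vert] = CT_VERTEBRA_HU

    # ground truth from the pre-blur image
    region_mean: dict = {}
    region_max: dict = {}
    for i, label in enumerate(REGION_LABELS):
        b0, b1 = spec.region_z_bounds_mm[i], spec.region_z_bounds_mm[i + 1]
        sel = aorta & ((zs >= b0) & (zs <= b1))[None, None, :]
        region_mean[label] = float(pet[sel].mean())
        region_max[label] = float(pet[sel].max())
    truth = PhantomTruth(
        blood_suv=spec.blood_suv,
        region_suv_mean=region_mean,
        region_suv_max=region_max,
        region_z_bounds_mm=tuple(spec.region_z_bounds_mm),
        profile_z_mm=zs.copy(),
        profile_radius_mm=r_z.copy(),
        aorta_mask=aorta,
    )

    if spec.psf_sigma_mm > 0:
        sig = [spec.psf_sigma_mm / s for s in spec.spacing]
        pet = gaussian_filter(pet, sigma=sig, mode="constant")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pet = pet + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    step = 3.0  # mm between centerline samples; dense vs. the 20-50 mm regions
    cz = np.arange(z0, z4 + 1e-9, step)
    if cz[-1] < z4:
        cz = np.append(cz, z4)
    points = np.stack([np.full_like(cz, ax_x), np.full_like(cz, ax_y), cz], axis=1)
    bounds = np.asarray(spec.region_z_bounds_mm)
    labels = []
    for z in cz:
        i = int(np.clip(np.searchsorted(bounds, z, side="right") - 1, 0, len(REGION_LABELS) - 1))
        labels.append(REGION_LABELS[i])
    line = Centerline(points, spec.radius_at(cz), tuple(labels))

    pet_vol = ScalarVolume(pet, spec.spacing)
    ct_vol = ScalarVolume(ct, spec.spacing)
    return pet_vol, ct_vol, line, truth


def default_study_spheres(spec: PhantomSpec, sphere_radius_mm: float = 8.0) -> StudySpheres:
    """Standard sphere placements for a phantom study.

    Two blood-pool spheres (8 mm radius, the clinical convention) sit inside
    the blood-pool cylinder; one threshold sphere per region sits on the
    aortic wall at the region's mid-level, on the side *away* from the
    vertebra — the analyst's 'visually highest uptake area clearly distinct
    from the vertebra'.
    """
    px, py, pz0, pz1 = _pool_geometry(spec)
    zc = (pz0 + pz1) / 2.0
    blood = (
        Sphere((px, py, zc - 9.0), sphere_radius_mm),
        Sphere((px, py, zc + 9.0), sphere_radius_mm),
    )
    ax_x, ax_y = aorta_axis(spec)
    bounds = spec.region_z_bounds_mm
    threshold = {}
    for i, label in enumerate(REGION_LABELS):
        zm = (bounds[i] + bounds[i + 1]) / 2.0
        r = float(spec.radius_at(zm))
        # centered on the wall shell, vertebra-averted (-x) side
        threshold[label] = Sphere(
            (ax_x - r + spec.wall_thickness_mm / 2.0, ax_y, zm), 4.0
        )
    return StudySpheres(blood, threshold)


def vertebral_exclusion_line(spec: PhantomSpec) -> Centerline:
    """Centerline of the vertebral spill-over exclusion tube.

    Covers the vertebral cylinder plus one blur sigma of surrounding tissue;
    subtracting its tube mask from slice ROIs emulates the manual carve-out
    of vertebral overspill used with the TBR method.
    """
    vx, vy = vertebra_axis(spec)
    z0, z4 = spec.region_z_bounds_mm[0], spec.region_z_bounds_mm[-1]
    r = spec.vertebra_radius_mm + spec.psf_sigma_mm
    points = np.array([[vx, vy, z0 - spec.psf_sigma_mm], [vx, vy, z4 + spec.psf_sigma_mm]])
    return Centerline(points, np.array([r, r]), ("exclusion", "exclusion"))


def make_observer_replicates(
    truth_values, observer_sd: float, n_observers: int, seed: int
) -> np.ndarray:
    """Simulate repeated readings: truth + iid Gaussian observer error per cell.

    Returns a (n_subjects, n_observers) matrix; deterministic per seed. This
    is the substrate for intra-/inter-observer repeatability statistics.
    """
    truth_values = np.asarray(truth_values, dtype=float)
    if truth_values.size == 0:
        raise ValueError("truth_values is empty")
    if observer_sd < 0:
        raise ValueError("observer_sd must be >= 0")
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, observer_sd, size=(truth_values.size, n_observers))
    return truth_values[:, None] + noise
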