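# Methods

## Measurement model

All measurements operate on a 3-D PET volume in SUV units with physical
voxel spacing (mm), axis order (x, y, z), z being the cranio-caudal
(trans-axial slicing) axis. A voxel is identified by its center; a voxel
belongs to a geometric VOI iff its center satisfies the geometry predicate
(center-in selection, no partial-volume weighting). This makes every mask
exactly reproducible by an exhaustive loop over voxel centers, which is how
the test suite cross-checks the vectorized geometry.

Boundary conventions: sphere masks select centers at distance *strictly
less than* the radius (so a zero-radius sphere is empty); tube and disk
masks select at distance *less than or equal to* the local radius. Tube
VOIs are swept without end caps — a voxel must project perpendicularly onto
some centerline segment — so a straight two-point centerline of length h
and radius r voxelizes the finite cylinder π·r²·h, the way a vessel VOI
terminates at its end planes. Where two segments could claim a voxel the
earlier segment wins ties; the local radius is interpolated linearly in arc
length within the claiming segment. Only axis-aligned NIfTI affines are
accepted; oblique acquisitions would require resampling policy this tool
deliberately does not take on.

### Background blood pool

Mean blood SUV is measured in two 8-mm-radius spheres placed in the atria:
`bg = (Σ cumulative SUV) / (Σ voxelized sphere volume)`, i.e. the
volume-weighted mean voxel SUV over both spheres (identical to the mean of
per-sphere means only when the voxelized volumes coincide). The sphere
volume is always computed from geometry — a single ideal 8-mm sphere is
4/3·π·0.8³ ≈ 2.14 cm³ — never hard-coded. Overlapping spheres are flagged
in provenance but tolerated.

### TBR

The aortic cross-section is covered by a full disk (lumen + thrombus +
wall), interpolated per slice from the centerline; consecutive trans-axial
slabs of nominal 3 mm thickness tile the region (the last slab may be
thinner; slabs never overlap). Per-slab SUV_mean and SUV_max are computed
on the slab minus an optional exclusion mask (the vertebral overspill
carve-out, modelled as a tube of radius vertebra + 1σ of blur around the
vertebral axis). Region TBR_mean is the *unweighted* mean of slab means
divided by bg; TBR_max is the global max divided by bg. Unweighted
aggregation is the minimal assumption; slab volumes are near-equal by
construction, so the weighting question is third-order.

### AMA

The region VOI is the centerline tube; cumulative SUV is the
voxel-volume-weighted sum (SUV·cm³) so that cumulative/volume is the mean
voxel SUV and AMA_mean = (cumulative/volume)/bg is dimensionless and
directly comparable to TBR_mean, collapsing to exactly the same number on a
uniform region. AMA_max = SUV_max/bg, taken from the *unthresholded* VOI:
applying the upper threshold first would pin SUV_max to the threshold
itself and make the statistic degenerate.

### Spill-over threshold

Per region, the SUV_max inside a small sphere placed in the visually
hottest uptake clearly distinct from the vertebra becomes an upper voxel
threshold; voxels with SUV strictly above it are excluded from cumulative
SUV, volume, mean and max. Strict exclusion means the defining sphere's own
maximum never invalidates its region. A threshold of +∞ reproduces the
unthresholded accumulation bit-exactly; a threshold that removes the whole
region is an error, not a zero.

### Agreement statistics

ICC is the two-way, consistency, single-measurement form ICC(C,1) =
(MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error), computed through
pingouin with the F-distribution 95% CI; the estimate is identical under
the random- and mixed-effects two-way formulations. The degenerate case of
zero residual (raters identical up to a constant) returns ICC = 1 directly.
Reliability bands are half-open: poor < 0.5 ≤ moderate < 0.75 ≤ good
< 0.9 ≤ excellent. Bland–Altman uses differences b − a, bias ± 1.96 ×
sample sd (n−1); percentage differences use the pairwise mean as
denominator. Published tables in this field sometimes print limits of
agreement symmetric about zero despite a nonzero bias; this package always
reports bias-centred limits, which is the internally consistent form. The
coefficient of repeatability defaults to 1.96·sd(differences); an ANOVA
within-subject form 1.96·√(mean d²) — which folds a systematic offset into
the repeatability instead of discounting it — is available via
`form="anova"`.

## The phantom

The generator emulates the imaging situation the methods were built for. A
straight vertical aorta carries a Gaussian radius bulge

r(z) = r_neck + (r_max − r_neck)·exp(−(z − z_c)²/(2·(extent/2.355)²)),

parametrized by its full width at half maximum so "extent" reads as the
visible length of the sac. Lumen voxels hold blood SUV, a 3-mm wall shell
holds wall SUV, a parallel vertebral cylinder holds vertebral SUV, the
surrounding background is zero; an atrial-surrogate blood-pool cylinder
sits 41 mm anterior so background spheres sample clean blood. The PET
volume is convolved with an isotropic Gaussian point-spread function and
Gaussian voxel noise is added (deterministic per seed); ground truth
(per-region SUV statistics, radius profile, aortic voxel mask) is recorded
from the pre-blur image. The CT volume encodes the same geometry in
Hounsfield-like values and is carried for landmarking only.

Defaults, chosen once as the standard study conditions: 80×64×80 grid at
2 mm spacing; blood SUV 2, wall SUV 4, vertebra SUV 20 (10× blood, the
upper end of physiological vertebral NaF uptake); neck radius 10 mm,
aneurysm maximum radius 20 mm, extent 50 mm; the vertebral body abuts the
sac (1 mm gap at the belly), as it does anatomically — this is exactly why
spill-over is the dominant artifact clinically; PSF σ = 4 mm; noise sd
0.1 SUV. Region boundaries (thoracic | suprarenal | neck | aneurysm) are
fixed z-planes. Observer-replicate simulations use σ = 0.13 (intra-reader)
and 0.17 (inter-reader), back-calculated from repeatability coefficients
reported for trained readers via CR = 1.96·√2·σ.

### What the phantom does and does not show

The phantom exercises geometry, accumulation, thresholding and statistics
against exact ground truth; passing tests demonstrate the *operations* are
correct, not that the method is clinically accurate. Features of real data
deliberately not modelled: PET count statistics and reconstruction
artifacts (noise here is additive Gaussian), scatter/attenuation, tortuous
centerlines (the voxelizer supports bends and is tested on bent synthetic
centerlines directly, but the phantom's aorta is straight), soft-tissue
background uptake, respiratory motion, and registration error between PET
and CT (inputs are assumed co-registered).

Two quantitative consequences of the 4-mm blur on a 10–20 mm vessel are
worth stating plainly, because they shape every number the phantom
produces:

1. **Partial-volume compression.** The thin wall's excess uptake blurs
   outward across the VOI boundary, so measured TBR/AMA sit near 1.0 where
   the pre-blur truth is ~1.3–1.6, and between-subject differences in wall
   uptake are compressed by roughly a factor of four. Synthetic-cohort
   agreement numbers are therefore on the clinical *pattern* (means agree
   well, maxima moderately; variable radius beats the fixed cylinder) but
   not on the clinical *scale*, and simulated observer ICCs run below
   clinical reports because the between-subject spread is narrower while
   observer noise is held at its clinical value.
2. **What the threshold corrects.** Thresholding removes the vertebral
   spill *component*: on phantoms the thresholded AMA_mean lands much
   closer to the value measured on an identical vertebra-free phantom
   (error ~0.01 vs ~0.05 AMA units) and the residual below-threshold spill
   is the irreducible part. Thresholding cannot — and is not meant to —
   recover the pre-blur truth, because the dominant gap to truth is the
   vessel's own partial-volume loss, which removing hot voxels can only
   widen. Any validation of the threshold must therefore score it against
   a spill-free reference, not against pre-blur values.

## Numerical choices and degenerate inputs

- Thresholds are applied strictly (> t excluded, = t retained).
- With variable radius off, the fallback cylinder uses the region's maximum
  annotated radius — deliberately reproducing the extra-aortic-inclusion
  failure mode that the variable radius exists to fix.
- Slab partitioning groups round(thickness / z-spacing) slices; slabs
  emptied by the exclusion mask are dropped and counted in provenance.
- Empty VOIs, zero-variance correlations, incomplete rating matrices,
  spheres outside or clipped by the grid, and thresholds that empty a
  region all raise explicit errors rather than returning silent zeros.
- Exact agreement between AMA_mean and TBR_mean on uniform regions holds to
  1 ulp (the two routes sum identical voxels in different partitions).
- All randomness (phantom noise, observer replicates, cohort sampling)
  flows from explicit integer seeds; the CLI records seeds and config
  hashes in every output, and repeated runs are byte-identical.

## Cohort simulation (acceptance script)

25 subjects (the clinical study size), each a phantom with anatomy and
uptake drawn once per subject: neck radius N(10, 1) mm, maximum radius
N(20, 2) mm, extent N(50, 4) mm, blood SUV N(2.0, 0.15), wall SUV
log-normal around 4 with σ_log = 0.45 (a several-fold between-patient
spread, as in clinical NaF cohorts), vertebral SUV N(20, 3), vertebra
tracking the back of the sac. TBR (with vertebral exclusion) is compared
against AMA at each enhancement level over all four regions (n = 100
region-values) and over the aneurysm alone for the radius question
(n = 25); observer repeatability is simulated on subject-level optimised
AMA values. At this scale the thresholded-vs-plain ICC ordering can differ
from clinical reports: the comparator TBR already excludes spill by mask,
the phantom's spill contribution to the region *mean* is modest, and the
threshold estimate carries noise-driven variance of its own.

## Known limitations

- Straight-aorta phantom; bent-centerline behaviour is unit-tested but not
  exercised end-to-end.
- No DICOM, no registration, no reconstruction modelling; NIfTI in, tables
  out.
- The hollow-cylinder (wall-only) VOI variant is intentionally absent.
- Scan–rescan reproducibility is out of scope; only observer-level
  repeatability is simulated.
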