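import dataclasses

import numpy as np
import pytest

import amaquant as aq
from amaquant.phantom import default_study_spheres, vertebral_exclusion_line
from amaquant.quant import (
    accumulate,
    ama_region,
    analyze_study,
    background_activity,
    tbr_region,
    threshold_from_sphere,
)
from amaquant.voi import sphere_mask, tube_mask


def mask_from_indices(shape, idx):
    m = np.zeros(shape, dtype=bool)
    for i in idx:
        m[i] = True
    return aq.VOIMask(m)


@pytest.fixture(scope="module")
def study(std_phantom):
    spec, pet, ct, line, truth = std_phantom
    spheres = default_study_spheres(spec)
    bg = background_activity(pet, *spheres.blood)
    return spec, pet, ct, line, truth, spheres, bg


class TestBackgroundActivity:
    def test_uniform_volume(self, unit_grid):
        vol = unit_grid(shape=(30, 30, 30), fill=2.0)
        bg = background_activity(
            vol, aq.Sphere((8, 15, 15), 5.0), aq.Sphere((21, 15, 15), 5.0)
        )
        assert bg.value == pytest.approx(2.0)

    def test_volume_weighted_mean_of_two_blocks(self, unit_grid):
        # sphere 1 sits in a block of SUV 1, sphere 2 in a block of SUV 3
        vol = unit_grid(shape=(40, 20, 20), fill=1.0)
        data = vol.data.copy()
        data[20:, :, :] = 3.0
        vol = vol.like(data)
        bg = background_activity(
            vol, aq.Sphere((9, 10, 10), 5.0), aq.Sphere((29, 10, 10), 5.0)
        )
        assert bg.value == pytest.approx(2.0)
        assert bg.sphere_volumes_cm3[0] == bg.sphere_volumes_cm3[1]

    def test_eight_mm_sphere_volume(self, unit_grid):
        vol = unit_grid(shape=(30, 30, 30), fill=1.0)
        bg = background_activity(
            vol, aq.Sphere((10, 14, 14), 8.0), aq.Sphere((19, 14, 14), 8.0)
        )
        assert bg.sphere_volumes_cm3[0] == pytest.approx(2.14, rel=0.02)
        assert "overlap" in bg.notes[0]  # these two do overlap
        assert bg.total_volume_cm3 == pytest.approx(sum(bg.sphere_volumes_cm3))


class TestThresholdFromSphere:
    def test_uniform_and_single_hot_voxel(self, unit_grid):
        vol = unit_grid(shape=(20, 20, 20), fill=3.0)
        s = aq.Sphere((10, 10, 10), 5.0)
        assert threshold_from_sphere(vol, s) == 3.0
        data = vol.data.copy()
        data[10, 10, 10] = 7.0
        data[:, :, :] = np.where(data == 3.0, 2.0, data)
        assert threshold_from_sphere(vol.like(data), s) == 7.0

    def test_blurred_hotspot_is_attenuated(self, std_phantom):
        """The threshold sphere reads the blurred wall peak: below the true wall
        SUV (partial volume) but above the blood background."""
        spec, pet, ct, line, truth = std_phantom
        spheres = default_study_spheres(spec)
        thr = threshold_from_sphere(pet, spheres.threshold["aneurysm"])
        assert thr < spec.wall_suv
        assert thr > spec.blood_suv * 0.9


class TestAccumulate:
    def _four_voxel_vol(self):
        # voxel volume exactly 1 cm^3 so the arithmetic reads directly
        vol = aq.ScalarVolume(np.zeros((4, 1, 1)), (10.0, 10.0, 10.0))
        data = vol.data.copy()
        data[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        return vol.like(data), mask_from_indices((4, 1, 1), [(i, 0, 0) for i in range(4)])

    def test_unthresholded_arithmetic(self):
        vol, voi = self._four_voxel_vol()
        cum, volume, mean, mx, excl = accumulate(vol, voi)
        assert (cum, volume, mean, mx, excl) == (10.0, 4.0, 2.5, 4.0, 0)

    def test_threshold_excludes_strictly_above_and_keeps_ties(self):
        vol, voi = self._four_voxel_vol()
        cum, volume, mean, mx, excl = accumulate(vol, voi, threshold=3.0)
        assert (cum, volume, mean, mx, excl) == (6.0, 3.0, 2.0, 3.0, 1)

    def test_matches_brute_force_loop(self, std_phantom):
        spec, pet, ct, line, truth = std_phantom
        rng = np.random.default_rng(5)
        sel = rng.random(pet.shape) < 0.01
        voi = aq.VOIMask(sel)
        t = float(np.quantile(pet.data[sel], 0.9))
        cum, volume, mean, mx, excl = accumulate(pet, voi, threshold=t)
        b_cum = b_n = 0.0
        b_max = -np.inf
        b_excl = 0
        for i, j, k in zip(*np.nonzero(sel)):
            v = pet.data[i, j, k]
            if v > t:
                b_excl += 1
                continue
            b_cum += v * pet.voxel_volume_cm3
            b_n += 1
            b_max = max(b_max, v)
        assert cum == pytest.approx(b_cum)
        assert volume == pytest.approx(b_n * pet.voxel_volume_cm3)
        assert mx == b_max
        assert excl == b_excl

    def test_infinite_threshold_is_identity(self, std_phantom):
        spec, pet, ct, line, truth = std_phantom
        voi = tube_mask(pet, line.for_label("neck"))
        assert accumulate(pet, voi, threshold=np.inf) == accumulate(pet, voi)

    def test_threshold_removing_everything_errors(self):
        vol, voi = self._four_voxel_vol()
        with pytest.raises(ValueError, match="entire region"):
            accumulate(vol, voi, threshold=0.5)

    def test_empty_voi_errors(self, unit_grid):
        vol = unit_grid(shape=(4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            accumulate(vol, aq.VOIMask(np.zeros((4, 4, 4), bool)))


class TestAmaRegion:
    def test_uniform_region(self, unit_grid):
        vol = unit_grid(shape=(4, 4, 4), fill=4.0)
        voi = aq.VOIMask(np.ones((4, 4, 4), bool))
        bg = aq.BackgroundActivity(2.0, (1.0,), (0.5,))
        res = ama_region(vol, voi, bg)
        assert res.ama_mean == res.ama_max == 2.0

    def test_thresholded_arithmetic(self):
        vol = aq.ScalarVolume(np.zeros((3, 1, 1)), (10.0, 10.0, 10.0))
        vol = vol.like(np.array([2.0, 2.0, 8.0]).reshape(3, 1, 1))
        voi = aq.VOIMask(np.ones((3, 1, 1), bool))
        bg = aq.BackgroundActivity(2.0, (1.0,), (0.5,))
        res = ama_region(vol, voi, bg, threshold=4.0)
        assert res.ama_mean == 1.0
        assert res.ama_max == 1.0  # max of retained voxels is 2
        assert res.excluded_voxel_count == 1

    def test_unblurred_phantom_recovers_truth_mixture_exactly(self, clean_phantom):
        """On the unblurred phantom the tube VOI equals the truth mask, so
        AMA_mean is exactly the wall/blood mixture ratio from truth bookkeeping."""
        spec, pet, ct, line, truth = clean_phantom
        spheres = default_study_spheres(spec)
        bg = background_activity(pet, *spheres.blood)
        voi = aq.VOIMask(truth.region_mask(pet, "aneurysm"))
        res = ama_region(pet, voi, bg, None, "aneurysm")
        assert bg.value == spec.blood_suv
        assert res.ama_mean == pytest.approx(
            truth.region_suv_mean["aneurysm"] / spec.blood_suv, rel=1e-12
        )

    def test_nonpositive_background_rejected(self, unit_grid):
        vol = unit_grid(shape=(2, 2, 2), fill=1.0)
        voi = aq.VOIMask(np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError, match="background"):
            ama_region(vol, voi, aq.BackgroundActivity(0.0, (0.0,), (0.5,)))


class TestTbrRegion:
    def test_single_uniform_slab(self, unit_grid):
        vol = unit_grid(shape=(4, 4, 4), fill=3.0)
        slab = aq.VOIMask(np.ones((4, 4, 4), bool))
        bg = aq.BackgroundActivity(1.5, (1.0,), (0.5,))
        res = tbr_region(vol, [slab], bg)
        assert res.tbr_mean == res.tbr_max == 2.0

    def test_slab_aggregation_rule(self):
        """TBR_mean averages slab means unweighted; TBR_max takes the global max."""
        vol = aq.ScalarVolume(np.zeros((2, 1, 2)), (1, 1, 1))
        data = vol.data.copy()
        data[:, 0, 0] = [2.0, 2.0]  # slab 1: mean 2
        data[:, 0, 1] = [4.0, 4.0]  # slab 2: mean 4
        data[0, 0, 0] = 5.0 - 3.0  # keep slab1 mean 2 with max 5: {5, -1}
        data[1, 0, 0] = -1.0
        data[0, 0, 0] = 5.0
        data[0, 0, 1] = 6.0  # slab 2: {6, 2} mean 4, max 6
        data[1, 0, 1] = 2.0
        vol = vol.like(data)
        s1 = mask_from_indices((2, 1, 2), [(0, 0, 0), (1, 0, 0)])
        s2 = mask_from_indices((2, 1, 2), [(0, 0, 1), (1, 0, 1)])
        bg = aq.BackgroundActivity(2.0, (1.0,), (0.5,))
        res = tbr_region(vol, [s1, s2], bg)
        assert res.tbr_mean == pytest.approx(1.5)
        assert res.tbr_max == pytest.approx(3.0)

    def test_exclusion_lowers_tbr_under_spillover(self, study):
        spec, pet, ct, line, truth, spheres, bg = study
        excl = tube_mask(pet, vertebral_exclusion_line(spec))
        with_excl = analyze_study(pet, ct, line, spheres, "tbr", exclusion=excl)
        without = analyze_study(pet, ct, line, spheres, "tbr")
        a = {r.label: r.tbr_mean for r in with_excl}
        b = {r.label: r.tbr_mean for r in without}
        assert a["aneurysm"] < b["aneurysm"]


class TestAnalyzeStudy:
    def test_constant_radius_makes_variable_equal_fixed(self, unit_grid):
        spec = aq.PhantomSpec(
            aneurysm_max_radius_mm=10.0, psf_sigma_mm=0.0, noise_sd=0.0
        )
        pet, ct, line, truth = aq.make_phantom(spec)
        spheres = default_study_spheres(spec)
        on = analyze_study(pet, ct, line, spheres, "ama", variable_radius=True)
        off = analyze_study(pet, ct, line, spheres, "ama", variable_radius=False)
        for r_on, r_off in zip(on, off):
            assert r_on.ama_mean == r_off.ama_mean

    def test_fixed_radius_voi_contains_variable(self, study):
        spec, pet, ct, line, truth, spheres, bg = study
        sub = line.for_label("aneurysm")
        var = tube_mask(pet, sub)
        fix = tube_mask(pet, sub, fixed_radius=float(sub.radii.max()))
        assert np.all(fix.mask[var.mask])
        assert fix.count > var.count

    def test_missing_threshold_sphere_errors(self, study):
        spec, pet, ct, line, truth, spheres, bg = study
        bare = aq.StudySpheres(spheres.blood, {})
        with pytest.raises(ValueError, match="missing threshold sphere"):
            analyze_study(pet, ct, line, bare, "ama", threshold=True)

    def test_missing_region_errors(self, study):
        spec, pet, ct, line, truth, spheres, bg = study
        with pytest.raises(KeyError):
            analyze_study(pet, ct, line, spheres, "ama", regions=("arch",))

    def test_unknown_method_rejected(self, study):
        spec, pet, ct, line, truth, spheres, bg = study
        with pytest.raises(ValueError, match="unknown method"):
            analyze_study(pet, ct, line, spheres, "suvpeak")


class TestMeasurementProperties:
    def test_thresholded_invariants(self, study):
        """suv_max <= t and ama_mean <= t/bg whenever a threshold is applied."""
        spec, pet, ct, line, truth, spheres, bg = study
        res = analyze_study(pet, ct, line, spheres, "ama", threshold=True,
                            variable_radius=True)
        for r in res:
            assert r.suv_max <= r.threshold
            assert r.ama_mean <= r.threshold / bg.value
            assert r.suv_mean <= r.suv_max

    def test_ama_equals_tbr_on_uniform_unblurred_region(self):
        """With a uniform aorta the slab aggregation is irrelevant:
        AMA_mean == TBR_mean == tissue/blood exactly."""
        spec = aq.PhantomSpec(
            wall_suv=3.0, wall_thickness_mm=25.0,  # wall fills the aorta: uniform tissue
            psf_sigma_mm=0.0, noise_sd=0.0,
        )
        pet, ct, line, truth = aq.make_phantom(spec)
        spheres = default_study_spheres(spec)
        ama = analyze_study(pet, ct, line, spheres, "ama", variable_radius=True)
        tbr = analyze_study(pet, ct, line, spheres, "tbr")
        for ra, rt in zip(ama, tbr):
            # agreement to 1 ulp: the two routes sum the same voxels in
            # different partitions, so bit-identity is not guaranteed
            assert ra.ama_mean == pytest.approx(rt.tbr_mean, rel=1e-12)
            assert ra.ama_mean == pytest.approx(3.0 / 2.0, rel=1e-12)

    def test_threshold_corrects_vertebral_spillover(self, std_phantom):
        """Thresholding moves AMA_mean toward the spill-free reference — the
        same measurement on an identical phantom without the vertebra — which
        is the error component the threshold is designed to remove."""
        spec, pet, ct, line, truth = std_phantom
        spheres = default_study_spheres(spec)
        bg = background_activity(pet, *spheres.blood)
        ref_spec = dataclasses.replace(spec, vertebra_suv=0.0)
        pet_ref = aq.make_phantom(ref_spec)[0]
        bg_ref = background_activity(pet_ref, *spheres.blood)
        sub = line.for_label("aneurysm")
        voi = tube_mask(pet, sub)
        ref = ama_region(pet_ref, voi, bg_ref, None, "aneurysm").ama_mean
        thr = threshold_from_sphere(pet, spheres.threshold["aneurysm"])
        a_no = ama_region(pet, voi, bg, None, "aneurysm").ama_mean
        a_th = ama_region(pet, voi, bg, thr, "aneurysm").ama_mean
        assert abs(a_th - ref) < abs(a_no - ref)

    def test_variable_radius_voi_sensitivity_precision(self, study):
        spec, pet, ct, line, truth, spheres, bg = study
        sub = line.for_label("aneurysm")
        tm = truth.region_mask(pet, "aneurysm")
        var = tube_mask(pet, sub).mask
        fix = tube_mask(pet, sub, fixed_radius=float(sub.radii.max())).mask
        tp_var = (var & tm).sum()
        tp_fix = (fix & tm).sum()
        assert tp_var / tm.sum() >= 0.95  # sensitivity
        assert tp_var / var.sum() >= 0.95  # precision
        assert tp_fix / fix.sum() < 0.90  # fixed radius sweeps in extra-aortic tissue
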