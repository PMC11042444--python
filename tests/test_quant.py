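"""Quantitative PET metrics and Deauville conversion."""

import numpy as np
import pytest

from longipet.inference_post import LesionComponent, extract_components
from longipet.phantom import ORGAN_LABELS, PhantomSpec, ResponseModel, generate_cohort
from longipet.quant import (
    DS_BAND_LE2,
    QPET_CUTS,
    compute_delta_suvmax,
    compute_dmax,
    compute_dspleen,
    compute_mtv,
    compute_qpet,
    compute_suvmax,
    compute_tlg,
    ds_band_positive,
    patient_ds,
    qpet_to_ds,
    quantify_study,
)

SPACING = (2.0, 2.0, 2.0)


def comp(centroid=(0.0, 0.0, 0.0), volume_ml=1.0, suvmax=5.0, suvpeak=4.0,
         suvmean=3.0, lds=None, label=1, n_vox=1):
    return LesionComponent(label=label, voxels=np.zeros((n_vox, 3), int),
                           volume_ml=volume_ml, suvmax=suvmax, suvpeak=suvpeak,
                           suvmean=suvmean, centroid_mm=centroid, lds=lds)


def random_components(rng, n, spacing=SPACING):
    """Random labelled mask -> components, for oracle comparisons."""
    mask = np.zeros((16, 16, 16), np.int16)
    pet = rng.uniform(0.5, 15, mask.shape).astype(np.float32)
    placed = (rng.uniform(size=mask.shape) < n / 300.0)
    mask[placed] = 1
    return extract_components(mask, pet, spacing), mask, pet


class TestMTV:
    def test_empty(self):
        assert compute_mtv([]) == 0.0

    def test_thousand_voxels_at_2mm(self):
        comps, mask, _ = None, None, None
        c = comp(volume_ml=1000 * 8 / 1000.0)
        assert compute_mtv([c]) == pytest.approx(8.0)

    def test_matches_voxel_loop_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            comps, mask, pet = random_components(rng, 20)
            voxel_ml = np.prod(SPACING) / 1000.0
            oracle = sum(1 for idx in np.ndindex(mask.shape) if mask[idx] > 0) * voxel_ml
            assert compute_mtv(comps) == pytest.approx(oracle, abs=1e-9)

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(1)
        comps, _, _ = random_components(rng, 30)
        k = len(comps) // 2
        assert compute_mtv(comps) == pytest.approx(
            compute_mtv(comps[:k]) + compute_mtv(comps[k:]), abs=1e-12)


class TestTLG:
    def test_uniform_suv(self):
        c = comp(volume_ml=10.0, suvmean=5.0)
        assert compute_tlg([c]) == pytest.approx(50.0)

    def test_empty(self):
        assert compute_tlg([]) == 0.0

    def test_equals_voxelwise_integral(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            comps, mask, pet = random_components(rng, 25)
            voxel_ml = np.prod(SPACING) / 1000.0
            oracle = float(pet[mask > 0].sum() * voxel_ml)
            assert compute_tlg(comps) == pytest.approx(oracle, rel=1e-6)

    def test_tlg_at_least_mtv_times_min_suv(self):
        rng = np.random.default_rng(3)
        comps, mask, pet = random_components(rng, 25)
        if (mask > 0).any():
            min_suv = pet[mask > 0].min()
            assert compute_tlg(comps) >= compute_mtv(comps) * min_suv - 1e-9


class TestDmax:
    def test_single_lesion_zero(self):
        assert compute_dmax([comp()]) == 0.0

    def test_two_point_lesions(self):
        a = comp(centroid=(0.0, 0.0, 0.0))
        b = comp(centroid=(30.0, 0.0, 0.0))
        assert compute_dmax([a, b]) == pytest.approx(30.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        comps = [comp(centroid=tuple(rng.uniform(-100, 100, 3))) for _ in range(10)]
        oracle = max(
            np.linalg.norm(np.array(a.centroid_mm) - np.array(b.centroid_mm))
            for a in comps for b in comps)
        assert compute_dmax(comps) == pytest.approx(oracle, rel=1e-12)

    def test_triangle_consistency(self):
        rng = np.random.default_rng(5)
        comps = [comp(centroid=tuple(rng.uniform(-50, 50, 3))) for _ in range(6)]
        pts = [np.array(c.centroid_mm) for c in comps]
        path = sum(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(len(pts) - 1))
        assert compute_dmax(comps) <= path + 1e-9


class TestDspleen:
    def make_spleen(self, shape=(20, 20, 20)):
        m = np.zeros(shape, bool)
        m[8:12, 8:12, 8:12] = True
        return m

    def test_centroid_inside_spleen_is_zero(self):
        spleen = self.make_spleen()
        c = comp(centroid=(-1.0, -1.0, -1.0))  # center of a 20^3/2mm grid ~ (9.5)
        # voxel (9,9,9) in mm: (9-9.5)*2 = -1 -> inside the spleen block
        assert compute_dspleen([c], spleen, SPACING) == 0.0

    def test_point_lesion_at_distance(self):
        spleen = np.zeros((40, 40, 40), bool)
        spleen[20, 20, 20] = True  # at mm (0.5,0.5,0.5) for 40^3 grid, 2mm
        c = comp(centroid=(50.5, 0.5, 0.5))
        d = compute_dspleen([c], spleen, SPACING)
        assert d == pytest.approx(50.0, abs=1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        spleen = self.make_spleen()
        comps = [comp(centroid=tuple(rng.uniform(-18, 18, 3))) for _ in range(5)]
        surf = []
        from scipy import ndimage
        er = ndimage.binary_erosion(spleen)
        for idx in np.ndindex(spleen.shape):
            if spleen[idx] and not er[idx]:
                surf.append((np.array(idx) - 9.5) * 2.0)
        oracle = 0.0
        for c in comps:
            p = np.array(c.centroid_mm)
            vox = np.clip(np.round(p / 2.0 + 9.5).astype(int), 0, 19)
            if spleen[tuple(vox)]:
                d = 0.0
            else:
                d = min(np.linalg.norm(p - s) for s in surf)
            oracle = max(oracle, d)
        assert compute_dspleen(comps, spleen, SPACING) == pytest.approx(oracle, rel=1e-9)

    def test_no_lesions_zero(self):
        assert compute_dspleen([], self.make_spleen(), SPACING) == 0.0

    def test_empty_spleen_rejected(self):
        with pytest.raises(ValueError, match="spleen"):
            compute_dspleen([comp()], np.zeros((4, 4, 4), bool), SPACING)


class TestDeltaSuvmax:
    def test_drop_from_10_to_2(self):
        assert compute_delta_suvmax(10.0, 2.0) == pytest.approx(-80.0)

    def test_equal_values(self):
        assert compute_delta_suvmax(7.0, 7.0) == 0.0

    def test_no_residual_convention(self):
        assert compute_delta_suvmax(10.0, 0.0) == pytest.approx(-100.0)

    def test_nonpositive_baseline_missing(self):
        assert compute_delta_suvmax(0.0, 1.0) is None


class TestQpet:
    def liver(self, shape=(10, 10, 10)):
        m = np.zeros(shape, bool)
        m[2:5, 2:5, 2:5] = True
        return m

    def test_simple_ratio(self):
        pet = np.full((10, 10, 10), 2.0, np.float32)
        c = comp(suvpeak=2.6)
        qpet, flag = compute_qpet([c], self.liver(), pet)
        assert qpet == pytest.approx(1.3) and not flag

    def test_no_lesion_flag(self):
        pet = np.full((10, 10, 10), 2.0, np.float32)
        qpet, flag = compute_qpet([], self.liver(), pet)
        assert qpet == 0.0 and flag

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        pet = rng.uniform(1, 3, (10, 10, 10)).astype(np.float32)
        liver = self.liver()
        for c_scale in rng.uniform(0.1, 10, 5):
            comps = [comp(suvpeak=2.2)]
            scaled_comps = [comp(suvpeak=2.2 * c_scale)]
            q1, _ = compute_qpet(comps, liver, pet)
            q2, _ = compute_qpet(scaled_comps, liver, pet * c_scale)
            assert q2 == pytest.approx(q1, rel=1e-5)

    def test_empty_liver_rejected(self):
        with pytest.raises(ValueError, match="liver"):
            compute_qpet([comp()], np.zeros((4, 4, 4), bool),
                         np.ones((4, 4, 4), np.float32))


class TestDeauville:
    def test_no_lesion_band(self):
        assert qpet_to_ds(0.0) == DS_BAND_LE2

    def test_boundary_half_open(self):
        assert qpet_to_ds(QPET_CUTS["t34"]) == "4"
        assert qpet_to_ds(QPET_CUTS["t34"] - 1e-9) == "3"
        assert qpet_to_ds(QPET_CUTS["t23"]) == "3"
        assert qpet_to_ds(QPET_CUTS["t45"]) == "5"

    def test_monotone(self):
        order = {DS_BAND_LE2: 2, "3": 3, "4": 4, "5": 5}
        qs = np.linspace(0, 4, 100)
        bands = [order[qpet_to_ds(q)] for q in qs]
        assert all(a <= b for a, b in zip(bands, bands[1:]))

    def test_patient_ds_is_max_lds(self):
        assert patient_ds([comp(lds=3), comp(lds=4)]) == "4"
        assert patient_ds([]) == DS_BAND_LE2
        assert patient_ds([comp(lds=2)]) == DS_BAND_LE2

    def test_band_positivity(self):
        assert not ds_band_positive(DS_BAND_LE2, 3)
        assert ds_band_positive("3", 3)
        assert not ds_band_positive("3", 4)
        assert ds_band_positive("5", 4)


class TestCohortConsistency:
    def test_qpet_positive_implies_lds_route_positive(self):
        """On phantoms the two response-assessment routes are linked:
        a qPET at or above the DS3 cut requires a residual lesion, and
        every annotated residual lesion carries LDS >= 3, so the
        LDS-route positivity must hold whenever the qPET route fires."""
        studies = generate_cohort(PhantomSpec.compact(
            response_model=ResponseModel(resolve_prob=0.4)), 12, seed=31)
        checked = 0
        for s in studies:
            t2 = extract_components(s.mask2, s.pet2, s.spacing_mm,
                                    reference_lesions=s.lesions2)
            liver = s.organs == ORGAN_LABELS["liver"]
            qpet, flag = compute_qpet(t2, liver, s.pet2)
            qpet_pos = qpet >= QPET_CUTS["t23"]
            lds_pos = ds_band_positive(patient_ds(t2), 3)
            if qpet_pos:
                assert lds_pos
                checked += 1
            assert lds_pos == bool(s.lesions2)
        assert checked >= 1

    def test_quantify_study_full_panel(self):
        studies = generate_cohort(PhantomSpec.compact(
            response_model=ResponseModel(resolve_prob=0.2)), 3, seed=8)
        for s in studies:
            t1 = extract_components(s.mask1, s.pet1, s.spacing_mm,
                                    reference_lesions=s.lesions1)
            t2 = extract_components(s.mask2, s.pet2, s.spacing_mm,
                                    reference_lesions=s.lesions2)
            r = quantify_study(t1, t2, s.pet2, s.organs, s.spacing_mm, s.patient_id)
            assert r.mtv_ml >= 0 and r.tlg >= 0 and r.qpet is not None
            assert r.dmax_mm >= 0
            if r.n_lesions1 <= 1:
                assert r.dmax_mm == 0.0
            if r.delta_suvmax_pct is not None:
                assert r.delta_suvmax_pct >= -100.0

    def test_missing_organs_degrade_gracefully(self):
        studies = generate_cohort(PhantomSpec.compact(), 1, seed=9)
        s = studies[0]
        t1 = extract_components(s.mask1, s.pet1, s.spacing_mm)
        r = quantify_study(t1, [], s.pet2, None, s.spacing_mm, s.patient_id)
        assert r.qpet is None and r.dspleen_mm is None
        assert r.mtv_ml > 0
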