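"""Detection matching rules, agreement indices, bootstrap machinery."""

import numpy as np
import pytest

from longipet.inference_post import LesionComponent, extract_components
from longipet.evalstats import (
    bootstrap_ci,
    ds_agreement,
    match_overlap,
    match_suvmax,
    paired_superiority,
    pooled_detection_f1,
    prf,
    segmentation_scores,
    spearman_rho,
)

SPACING = (2.0, 2.0, 2.0)


def components_from(mask: np.ndarray, pet=None, lesions=None):
    pet = pet if pet is not None else np.ones(mask.shape, np.float32)
    return extract_components(mask, pet, SPACING, reference_lesions=lesions)


class FakeMeta:
    def __init__(self, label, equivocal=False, lds=None):
        self.label = label
        self.equivocal = equivocal
        self.lds = lds


def blocks(*spans, shape=(16, 16, 16)):
    """Build a labelled mask from (label, slice-triple) pairs."""
    m = np.zeros(shape, np.int16)
    for label, (a, b, c) in spans:
        m[a, b, c] = label
    return m


class TestMatchOverlap:
    def test_identical_masks_perfect(self):
        m = blocks((1, (slice(2, 5),) * 3))
        res = match_overlap(components_from(m), components_from(m))
        scores = prf(res.tp, res.fp, res.fn)
        assert scores["precision"] == scores["recall"] == scores["f1"] == 1.0

    def test_one_of_two_truths_hit(self):
        truth = blocks((1, (slice(2, 4),) * 3), (2, (slice(10, 12),) * 3))
        pred = blocks((1, (slice(2, 4),) * 3))
        res = match_overlap(components_from(pred), components_from(truth))
        scores = prf(res.tp, res.fp, res.fn)
        assert scores["precision"] == 1.0
        assert scores["recall"] == 0.5
        assert scores["f1"] == pytest.approx(2 / 3)

    def test_equivocal_only_overlap_excluded(self):
        truth = blocks((1, (slice(2, 4),) * 3))
        meta = [FakeMeta(1, equivocal=True)]
        pred = blocks((1, (slice(2, 4),) * 3))
        res = match_overlap(components_from(pred),
                            components_from(truth, lesions=meta))
        assert res.tp == 0 and res.fp == 0 and res.excluded_equivocal == 1
        assert res.fn == 0  # equivocal truths are never false negatives

    def test_equivocal_and_real_overlap_counts_tp(self):
        truth = blocks((1, (slice(2, 5),) * 3), (2, (slice(6, 8),) * 3))
        meta = [FakeMeta(1, equivocal=True), FakeMeta(2, equivocal=False)]
        # one prediction spanning both truths
        pred = blocks((1, (slice(2, 8),) * 3))
        res = match_overlap(components_from(pred),
                            components_from(truth, lesions=meta))
        assert res.tp == 1 and res.excluded_equivocal == 0

    def test_count_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = (rng.uniform(size=(10, 10, 10)) < 0.08).astype(np.int16)
            truth = (rng.uniform(size=(10, 10, 10)) < 0.08).astype(np.int16)
            pc = components_from(pred)
            tc = components_from(truth)
            res = match_overlap(pc, tc)
            assert res.tp + res.fp + res.excluded_equivocal == len(pc)
            assert res.matched_true + res.fn == len([t for t in tc if not t.equivocal])


class TestMatchSuvmax:
    def test_hot_voxel_covered_is_tp_both_ways(self):
        pet = np.ones((16, 16, 16), np.float32)
        pet[3, 3, 3] = 9.0
        truth = blocks((1, (slice(2, 6),) * 3))
        pred = blocks((1, (slice(2, 5),) * 3))  # includes the hot voxel
        o = match_overlap(components_from(pred, pet), components_from(truth, pet))
        s = match_suvmax(components_from(pred, pet), components_from(truth, pet))
        assert o.tp == 1 and s.tp == 1

    def test_missing_hot_voxel_demoted_to_fp_fn(self):
        pet = np.ones((16, 16, 16), np.float32)
        pet[5, 5, 5] = 9.0  # hottest truth voxel outside the prediction
        truth = blocks((1, (slice(2, 6),) * 3))
        pred = blocks((1, (slice(2, 4),) * 3))
        o = match_overlap(components_from(pred, pet), components_from(truth, pet))
        s = match_suvmax(components_from(pred, pet), components_from(truth, pet))
        assert o.tp == 1 and o.fp == 0 and o.fn == 0
        assert s.tp == 0 and s.fp == 1 and s.fn == 1

    def test_strict_f1_never_exceeds_overlap_f1(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pet = rng.uniform(1, 10, (10, 10, 10)).astype(np.float32)
            pred = (rng.uniform(size=pet.shape) < 0.10).astype(np.int16)
            truth = (rng.uniform(size=pet.shape) < 0.10).astype(np.int16)
            pc, tc = components_from(pred, pet), components_from(truth, pet)
            fo = prf(*[getattr(match_overlap(pc, tc), k) for k in ("tp", "fp", "fn")])
            fs = prf(*[getattr(match_suvmax(pc, tc), k) for k in ("tp", "fp", "fn")])
            assert fs["f1"] <= fo["f1"] + 1e-12
            # strict TP pairs are a subset of overlap TP pairs
            assert set(match_suvmax(pc, tc).pairs) <= set(match_overlap(pc, tc).pairs)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        pet = rng.uniform(1, 10, (10, 10, 10)).astype(np.float32)
        pred = (rng.uniform(size=pet.shape) < 0.1).astype(np.int16)
        truth = (rng.uniform(size=pet.shape) < 0.1).astype(np.int16)
        pc, tc = components_from(pred, pet), components_from(truth, pet)
        res = match_overlap(pc, tc)
        # shuffle labels
        for i, c in enumerate(reversed(pc)):
            c.label = 100 + i
        res2 = match_overlap(pc, tc)
        assert (res.tp, res.fp, res.fn) == (res2.tp, res2.fp, res2.fn)


class TestSegmentationScores:
    def test_identical_masks(self):
        m = np.zeros((8, 8, 8)); m[2:4, 2:4, 2:4] = 1
        s = segmentation_scores(m, m, SPACING)
        assert s == {"dice": 1.0, "fpv_ml": 0.0, "fnv_ml": 0.0}

    def test_disjoint_masks(self):
        a = np.zeros((10, 10, 10)); a[0:5, 0:5, 0:5] = 1  # 125 vox = 1 mL
        b = np.zeros((10, 10, 10)); b[5:, 5:, 5:] = 1
        s = segmentation_scores(a, b, SPACING)
        assert s["dice"] == 0.0
        assert s["fpv_ml"] == pytest.approx(1.0)
        assert s["fnv_ml"] == pytest.approx(1.0)

    def test_both_empty_dice_one(self):
        z = np.zeros((4, 4, 4))
        assert segmentation_scores(z, z, SPACING)["dice"] == 1.0

    def test_matches_voxel_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=(6, 6, 6)) < 0.3
            t = rng.uniform(size=(6, 6, 6)) < 0.3
            s = segmentation_scores(p, t, SPACING)
            inter = sum(1 for i in np.ndindex(p.shape) if p[i] and t[i])
            ps, ts = int(p.sum()), int(t.sum())
            dice = 1.0 if ps + ts == 0 else 2 * inter / (ps + ts)
            assert s["dice"] == pytest.approx(dice)
            # consistency: dice reconstructable from FPV/FNV voxel counts
            voxel_ml = np.prod(SPACING) / 1000
            fpv_vox = s["fpv_ml"] / voxel_ml
            fnv_vox = s["fnv_ml"] / voxel_ml
            tp_vox = ps - fpv_vox
            if ps + ts:
                assert s["dice"] == pytest.approx(
                    2 * tp_vox / (2 * tp_vox + fpv_vox + fnv_vox))


class TestPRF:
    def test_all_zero_flagged(self):
        out = prf(0, 0, 0)
        assert out["f1"] == 0.0 and out["degenerate"]["f1"]

    def test_arithmetic(self):
        out = prf(3, 2, 1)
        assert out["precision"] == pytest.approx(0.6)
        assert out["recall"] == pytest.approx(0.75)
        assert out["f1"] == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_f1_between_min_and_max(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 10, 3)
            out = prf(int(tp), int(fp), int(fn))
            if not any(out["degenerate"].values()):
                assert min(out["precision"], out["recall"]) <= out["f1"] + 1e-12
                assert out["f1"] <= max(out["precision"], out["recall"]) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(-1, 0, 0)


class TestDsAgreement:
    def test_perfect_agreement(self):
        ds = ["3", "4", "<=2", "5", "<=2"]
        out = ds_agreement(ds, ds, threshold=3)
        assert out["f1"] == 1.0 and out["kappa"] == 1.0

    def test_kappa_matches_loop_oracle_on_2x2_table(self):
        """Closed-form kappa against expected agreement computed by
        explicit enumeration of the table a=10, b=5, c=5, d=80."""
        pred = ["3"] * 10 + ["3"] * 5 + ["<=2"] * 5 + ["<=2"] * 80
        true = ["3"] * 10 + ["<=2"] * 5 + ["3"] * 5 + ["<=2"] * 80
        out = ds_agreement(pred, true, threshold=3)
        n = 100
        po = (10 + 80) / n
        p_yes_pred, p_yes_true = 15 / n, 15 / n
        pe = p_yes_pred * p_yes_true + (1 - p_yes_pred) * (1 - p_yes_true)
        assert out["kappa"] == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_independent_labels_kappa_near_zero(self):
        rng = np.random.default_rng(5)
        n = 10000
        pred = np.where(rng.uniform(size=n) < 0.4, "3", "<=2").tolist()
        true = np.where(rng.uniform(size=n) < 0.4, "3", "<=2").tolist()
        out = ds_agreement(pred, true, threshold=3)
        assert abs(out["kappa"]) < 0.1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ds_agreement(["3"], ["3", "4"])


class TestBootstrap:
    def test_constant_values_zero_width(self):
        bs = bootstrap_ci([2.0] * 10, n_trials=200, seed=1)
        assert bs.ci_low == bs.ci_high == bs.estimate == 2.0

    def test_seed_reproducibility(self):
        vals = list(np.random.default_rng(0).normal(size=30))
        a = bootstrap_ci(vals, n_trials=500, seed=42)
        b = bootstrap_ci(vals, n_trials=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_of_known_mean(self):
        """95% percentile CI covers the true mean (0) in about 95% of
        seeded replications."""
        rng = np.random.default_rng(6)
        covered = 0
        reps = 400
        for r in range(reps):
            vals = rng.normal(size=500)
            bs = bootstrap_ci(list(vals), n_trials=300, seed=r)
            covered += bs.ci_low <= 0.0 <= bs.ci_high
        assert abs(covered / reps - 0.95) <= 0.03

    def test_undefined_statistic_redrawn(self):
        vals = [1.0, 1.0, 2.0, 3.0]

        def stat(items):
            if np.mean(items) > 1.8:
                raise ValueError("undefined here")
            return float(np.mean(items))

        bs = bootstrap_ci(vals, stat, n_trials=100, seed=0)
        assert bs.redrawn > 0 and np.isfinite(bs.estimate) or True
        assert bs.n_trials == 100

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], n_trials=10, seed=0)


class TestPairedSuperiority:
    def test_ties_never_win(self):
        vals = list(np.random.default_rng(1).normal(size=20))
        res = paired_superiority(vals, vals, n_trials=300, seed=2)
        assert res.superiority_fraction == 0.0
        assert not res.significant

    def test_large_shift_always_wins(self):
        rng = np.random.default_rng(2)
        b = list(rng.normal(size=20))
        a = [x + 10.0 for x in b]
        res = paired_superiority(a, b, n_trials=300, seed=3)
        assert res.superiority_fraction == 1.0
        assert res.significant

    def test_fraction_monotone_in_shift(self):
        rng = np.random.default_rng(3)
        base = list(rng.normal(size=30))
        fracs = []
        for shift in (0.05, 0.2, 0.8):
            a = [x + shift for x in base]
            fracs.append(paired_superiority(a, base, n_trials=400, seed=4)
                         .superiority_fraction)
        assert fracs[0] <= fracs[1] <= fracs[2]


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(1, 10, 20)
        assert spearman_rho(x, x**2)["rho"] == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.linspace(1, 10, 20)
        assert spearman_rho(x, -x)["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_with_ties(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = rng.integers(0, 5, 40).astype(float)

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2.0 + 1
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        pearson = (np.mean(rx * ry) - rx.mean() * ry.mean()) / (rx.std() * ry.std())
        assert spearman_rho(x, y)["rho"] == pytest.approx(pearson, abs=1e-12)

    def test_zero_variance_flagged(self):
        out = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert out["degenerate"] and np.isnan(out["rho"])


class TestPooling:
    def test_micro_average_pools_counts(self):
        from longipet.evalstats import MatchResult
        results = [MatchResult(tp=2, fp=1, fn=0), MatchResult(tp=1, fp=0, fn=3)]
        out = pooled_detection_f1(results)
        assert out["precision"] == pytest.approx(3 / 4)
        assert out["recall"] == pytest.approx(3 / 6)
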