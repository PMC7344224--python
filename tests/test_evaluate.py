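"""Evaluation metrics against independent brute-force oracles."""

import math

import numpy as np
import pytest

from cmrseg.evaluate import (AgreementResult, bland_altman, clinical_params,
                             dice_3d, evaluate_dataset, spearman_r,
                             structure_volume_ml)
from cmrseg.phantom import PhantomConfig, generate_study, make_partial_labels
from cmrseg.train import mean_iou
from cmrseg.types import LV, MYO, RV, LabelMap, ValidationError


def _lm(arr, spacing=(8, 1.8, 1.8)):
    return LabelMap(np.asarray(arr, dtype=np.uint8), spacing)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def dice_oracle(a, b, cls):
    """Voxel-set Dice: build explicit index sets and count."""
    sa = {idx for idx, v in np.ndenumerate(a) if v == cls}
    sb = {idx for idx, v in np.ndenumerate(b) if v == cls}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def miou_oracle(pred, ref):
    ious = []
    for c in range(4):
        sa = {i for i, v in np.ndenumerate(pred) if v == c}
        sb = {i for i, v in np.ndenumerate(ref) if v == c}
        if sa or sb:
            ious.append(len(sa & sb) / len(sa | sb))
    return sum(ious) / len(ious)


def spearman_oracle_no_ties(a, b):
    """1 - 6*sum(d^2)/(n(n^2-1)) — valid for tie-free lists."""
    ra = np.argsort(np.argsort(a))
    rb = np.argsort(np.argsort(b))
    d2 = ((ra - rb) ** 2).sum()
    n = len(a)
    return 1 - 6 * d2 / (n * (n * n - 1))


def bland_altman_oracle(a, b):
    """Textbook computation with explicit loops and the IQR rule."""
    m = [(x + y) / 2 for x, y in zip(a, b)]
    d = [x - y for x, y in zip(a, b)]
    q1, q3 = np.percentile(m, [25, 75])
    iqr = q3 - q1
    kept = [(mi, di) for mi, di in zip(m, d)
            if q1 - 1.5 * iqr <= mi <= q3 + 1.5 * iqr]
    ds = [di for _, di in kept]
    md = sum(ds) / len(ds)
    sd = math.sqrt(sum((x - md) ** 2 for x in ds) / (len(ds) - 1)) if len(ds) > 1 else 0.0
    return md, sd, len(ds)


# ---------------------------------------------------------------------------
# dice / mean-iou
# ---------------------------------------------------------------------------

class TestDice:
    def test_identical_masks_give_one(self):
        m = _lm(np.random.default_rng(0).integers(0, 4, (3, 5, 5)))
        for c in (LV, MYO, RV):
            assert dice_3d(m, m, c) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((1, 2, 2)); a[0, 0, 0] = LV
        b = np.zeros((1, 2, 2)); b[0, 1, 1] = LV
        assert dice_3d(_lm(a), _lm(b), LV) == 0.0

    def test_half_overlap_constructed_case(self):
        a = np.zeros((2, 2, 2)); b = np.zeros((2, 2, 2))
        a[0] = LV          # |A| = 4
        b[:, 0, :] = LV    # |B| = 4, overlap = 2
        assert dice_3d(_lm(a), _lm(b), LV) == 0.5

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice_3d(_lm(np.zeros((1, 2, 2))), _lm(np.zeros((1, 3, 3))), LV)

    @pytest.mark.parametrize("shape,reps", [((4, 4, 4), 250), ((8, 8, 8), 50)])
    def test_matches_brute_force_oracle_on_random_masks(self, shape, reps):
        rng = np.random.default_rng(42)
        for _ in range(reps):
            a = rng.integers(0, 4, shape)
            b = rng.integers(0, 4, shape)
            cls = int(rng.integers(1, 4))
            assert dice_3d(_lm(a), _lm(b), cls) == pytest.approx(
                dice_oracle(a, b, cls), abs=1e-12)


class TestMeanIoU:
    def test_identity_gives_one(self):
        ref = np.random.default_rng(0).integers(0, 4, (2, 8, 8))
        assert mean_iou(ref, ref) == 1.0

    def test_all_background_degenerate_case(self):
        z = np.zeros((2, 4, 4), dtype=int)
        assert mean_iou(z, z) == 1.0

    def test_enumerated_two_class_case(self):
        ref = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        # IoU_BG = 1/2, IoU_LV = 2/3 -> mean 7/12
        assert mean_iou(pred, ref) == pytest.approx(7 / 12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            pred = rng.integers(0, 4, (3, 3, 3))
            ref = rng.integers(0, 4, (3, 3, 3))
            assert mean_iou(pred, ref) == pytest.approx(miou_oracle(pred, ref))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mean_iou(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# clinical parameters
# ---------------------------------------------------------------------------

class TestClinicalParams:
    def test_volume_formula(self):
        arr = np.full((10, 10, 10), LV)  # 1000 voxels of 10 mm^3 each
        lab = _lm(arr, spacing=(10, 1, 1))
        assert structure_volume_ml(lab, LV) == pytest.approx(10.0)  # 1000 x 10 mm^3

    def test_empty_structure_gives_zero_volume(self):
        lab = _lm(np.zeros((2, 4, 4)))
        assert structure_volume_ml(lab, LV) == 0.0

    def test_lvm_is_myo_volume_times_density(self):
        study, truth = generate_study(PhantomConfig(), seed=0)
        p = clinical_params(study.ed_label, study.es_label)
        myo_ml = structure_volume_ml(study.ed_label, MYO)
        assert p.LVM == pytest.approx(myo_ml * 1.05)
        assert p.LVM == pytest.approx(truth.lv_mass_g, rel=0.05)

    def test_missing_structures_are_none_not_zero(self):
        study, _ = generate_study(PhantomConfig(n_slices=3), seed=0)
        partial = make_partial_labels(study)
        p = clinical_params(partial.ed_label, partial.es_label,
                            availability=partial.available)
        assert p.RV_EDV is None and p.RV_ESV is None
        assert p.LV_EDV is not None and p.LV_ESV is not None and p.LVM is not None

    def test_volumes_scale_linearly_with_voxel_volume(self):
        arr = np.random.default_rng(1).integers(0, 4, (4, 6, 6))
        v1 = structure_volume_ml(_lm(arr, (8, 1, 1)), LV)
        v2 = structure_volume_ml(_lm(arr, (8, 2, 2)), LV)
        assert v2 == pytest.approx(4 * v1)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_pairs(self):
        r = bland_altman([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.mean_difference == 0 and r.sd_difference == 0
        assert (r.loa_lower, r.loa_upper) == (0, 0)

    def test_alternating_differences_hand_computed(self):
        # differences {+2,-2,+2,-2}: MD 0, sample sd = sqrt(16/3) ~ 2.309
        auto = [12.0, 9.0, 22.0, 19.0]
        manual = [10.0, 11.0, 20.0, 21.0]
        r = bland_altman(auto, manual)
        assert r.mean_difference == pytest.approx(0.0)
        assert r.sd_difference == pytest.approx(math.sqrt(16 / 3))
        assert r.loa_upper == pytest.approx(1.96 * math.sqrt(16 / 3))

    def test_extreme_mean_pair_is_removed(self):
        rng = np.random.default_rng(0)
        manual = rng.uniform(50, 100, 100)
        auto = manual + rng.normal(0, 2, 100)
        auto = np.append(auto, 1000.0)
        manual = np.append(manual, 990.0)
        r = bland_altman(auto, manual)
        assert r.n_removed == 1 and r.n_used == 100

    def test_outlier_removal_never_increases_sd_on_extreme_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            manual = rng.uniform(50, 100, 30)
            auto = manual + rng.normal(0, 2, 30)
            auto[0], manual[0] = 500.0, 480.0  # far-out mean, big difference
            with_rule = bland_altman(auto, manual, iqr_rule=True)
            without = bland_altman(auto, manual, iqr_rule=False)
            assert with_rule.sd_difference <= without.sd_difference + 1e-12

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            a = rng.normal(100, 20, n)
            b = a + rng.normal(0, 5, n)
            if rng.random() < 0.3:
                a[0] += 300  # sometimes inject an outlier
            r = bland_altman(a, b)
            md, sd, n_used = bland_altman_oracle(a, b)
            assert r.mean_difference == pytest.approx(md)
            assert r.sd_difference == pytest.approx(sd)
            assert r.n_used == n_used

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1, 2], [1, 2])


class TestSpearman:
    def test_monotone_lists(self):
        assert spearman_r([1, 2, 3, 5], [10, 20, 21, 40]) == pytest.approx(1.0)
        assert spearman_r([1, 2, 3, 5], [40, 21, 20, 10]) == pytest.approx(-1.0)

    def test_known_permutation_value(self):
        assert spearman_r([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_matches_closed_form_on_random_permutations(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            n = int(rng.integers(3, 30))
            a = rng.permutation(n).astype(float)
            b = rng.permutation(n).astype(float)
            assert spearman_r(a, b) == pytest.approx(spearman_oracle_no_ties(a, b))

    def test_constant_list_flagged(self):
        with pytest.raises(ValidationError):
            spearman_r([1.0, 1.0, 1.0], [1, 2, 3])


# ---------------------------------------------------------------------------
# dataset evaluation
# ---------------------------------------------------------------------------

class TestEvaluateDataset:
    def _cohort(self, n=6):
        out = []
        for i in range(n):
            cfg = PhantomConfig(n_slices=4, in_plane_shape=(60, 60),
                                r_base_mm=18 + i * 0.8)
            study, _ = generate_study(cfg, seed=i, subject_id=f"s{i}")
            out.append(study)
        return out

    def test_self_comparison_is_perfect(self):
        cohort = self._cohort()
        preds = {s.subject_id: (s.ed_label, s.es_label) for s in cohort}
        report = evaluate_dataset(preds, cohort)
        assert (report["dice"]["dice"] == 1.0).all()
        assert report["agreement"]["MD"].abs().max() == 0.0
        assert (report["agreement"]["spearman_r"] == 1.0).all()

    def test_dice_drops_monotonically_with_injected_noise(self):
        cohort = self._cohort()
        rng = np.random.default_rng(0)
        means = []
        for flip_frac in (0.0, 0.05, 0.15):
            preds = {}
            for s in cohort:
                ed = s.ed_label.labels.copy()
                es = s.es_label.labels.copy()
                for arr in (ed, es):
                    m = rng.random(arr.shape) < flip_frac
                    arr[m] = (arr[m] + 1) % 4  # corrupt a fraction of voxels
                preds[s.subject_id] = (_lm(ed, s.ed_label.spacing),
                                       _lm(es, s.es_label.spacing))
            report = evaluate_dataset(preds, cohort)
            means.append(report["dice"]["dice"].mean())
        assert means[0] > means[1] > means[2]

    def test_partial_labels_produce_no_rv_rows(self):
        cohort = [make_partial_labels(s) for s in self._cohort()]
        preds = {s.subject_id: (s.ed_label, s.es_label) for s in cohort}
        report = evaluate_dataset(preds, cohort)
        assert "RV" not in set(report["dice"]["structure"])
        es_myo = report["dice"].query("frame == 'ES' and structure == 'MYO'")
        assert es_myo.empty
        assert set(report["agreement"]["parameter"]) == {"LV_EDV", "LV_ESV", "LVM"}

    def test_no_overlapping_subjects_rejected(self):
        cohort = self._cohort(3)
        with pytest.raises(ValidationError):
            evaluate_dataset({"nope": (cohort[0].ed_label, cohort[0].es_label)}, cohort)
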