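"""Ternary barcodes: z-profiles, threshold scan, classification and validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import painmorph as pm
from painmorph.barcode import (
    DEFAULT_THETA,
    Classification,
    UnclassifiableError,
    classify_cohort,
    joint_entropy_bits,
    subject_barcodes,
)
from painmorph.confound import CorrectedGM


def _corrected(Y, groups):
    idx = [f"S{i:03d}" for i in range(len(Y))]
    data = pd.DataFrame(Y, index=idx, columns=[f"roi_{j + 1:03d}" for j in range(Y.shape[1])])
    return CorrectedGM(data=data, groups=pd.Series(groups, index=idx), covariates=[])


class TestZProfile:
    def test_basic_normalization(self):
        z = pm.zprofile([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=3, max_size=30
        ).filter(lambda xs: np.ptp(xs) > 1e-6),
        st.floats(min_value=-50, max_value=50),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_shift_and_positive_scale_invariance(self, xs, shift, scale):
        x = np.asarray(xs)
        base = pm.zprofile(x)
        np.testing.assert_allclose(pm.zprofile(x * scale + shift), base, atol=1e-6)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        np.testing.assert_allclose(
            pm.zprofile(x), (x - x.mean()) / x.std(ddof=1), atol=1e-12
        )

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pm.zprofile([0.4, 0.4, 0.4])


class TestTernarize:
    def test_reference_example(self):
        np.testing.assert_array_equal(
            pm.ternarize([1.0, -0.2, -0.9], 0.56), [1, 0, -1]
        )

    def test_huge_theta_gives_all_zero(self):
        assert (pm.ternarize(np.linspace(-3, 3, 20), 10.0) == 0).all()

    def test_theta_zero_is_sign_with_zero_fixed(self):
        np.testing.assert_array_equal(
            pm.ternarize([-1.5, 0.0, 2.0], 0.0), [-1, 0, 1]
        )

    def test_boundary_maps_to_zero(self):
        np.testing.assert_array_equal(pm.ternarize([0.56, -0.56], 0.56), [0, 0])

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            pm.ternarize([0.0], -0.1)


class TestGroupBarcode:
    def test_single_subject_group_equals_subject_barcode(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(4, 12))
        corrected = _corrected(Y, ["healthy", "healthy", "healthy", "CBP"])
        gb = pm.group_barcode(corrected, "CBP", theta=0.5)
        sb = subject_barcodes(corrected, theta=0.5).loc["S003"].to_numpy()
        np.testing.assert_array_equal(gb, sb)

    def test_identical_mean_profiles_give_identical_barcodes(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(3, 10))
        Y = np.vstack([block, block])
        corrected = _corrected(Y, ["healthy"] * 3 + ["CBP"] * 3)
        a = pm.group_barcode(corrected, "healthy", theta=0.5)
        b = pm.group_barcode(corrected, "CBP", theta=0.5)
        np.testing.assert_array_equal(a, b)

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(6, 10))
        corrected = _corrected(Y, ["OA"] * 6)
        perm = rng.permutation(6)
        shuffled = _corrected(Y[perm], ["OA"] * 6)
        np.testing.assert_array_equal(
            pm.group_barcode(corrected, "OA", 0.4),
            pm.group_barcode(shuffled, "OA", 0.4),
        )


class TestThresholdScan:
    def test_known_joint_entropy(self):
        codes = np.array([[1, -1, 1, -1], [1, -1, 1, -1]])
        assert joint_entropy_bits(codes) == pytest.approx(1.0)

    def test_joint_entropy_vanishes_for_all_zero(self):
        assert joint_entropy_bits(np.zeros((3, 10), dtype=int)) == pytest.approx(0.0)

    def test_mirrored_profiles_give_negative_sum_r(self):
        rng = np.random.default_rng(4)
        delta = rng.normal(size=20)
        Y = np.vstack([0.5 + delta + rng.normal(0, 1e-3, 20) for _ in range(3)]
                      + [0.5 - delta + rng.normal(0, 1e-3, 20) for _ in range(3)])
        corrected = _corrected(Y, ["healthy"] * 3 + ["CBP"] * 3)
        scan = pm.optimize_threshold(corrected, theta_grid=np.arange(0, 2, 0.05))
        star = scan.theta[np.flatnonzero(scan.theta == scan.theta_star)[0]]
        assert scan.sum_r[scan.theta == star][0] < 0

    def test_identical_groups_fall_back_to_entropy_maximum(self):
        rng = np.random.default_rng(5)
        block = rng.normal(size=(2, 15))
        Y = np.vstack([block, block])
        corrected = _corrected(Y, ["healthy"] * 2 + ["CBP"] * 2)
        grid = np.arange(0.0, 1.5, 0.1)
        scan = pm.optimize_threshold(corrected, theta_grid=grid)
        valid = ~np.isnan(scan.sum_r)
        assert np.allclose(scan.sum_r[valid], 1.0)  # one pair, r = 1 throughout
        h_at_star = scan.joint_entropy[scan.theta == scan.theta_star][0]
        assert h_at_star == pytest.approx(np.nanmax(scan.joint_entropy[valid]))

    def test_degenerate_grid_rejected(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(4, 10))
        corrected = _corrected(Y, ["healthy"] * 2 + ["CBP"] * 2)
        with pytest.raises(ValueError, match="degenerate|no valid"):
            pm.optimize_threshold(corrected, theta_grid=np.array([50.0]))


class TestClassify:
    def test_exact_match_wins_with_unit_correlation(self):
        anchors = {
            "healthy": np.array([1, -1, 0, 1, -1]),
            "CRPS": np.array([0, 1, -1, -1, 1]),
        }
        res = pm.classify(anchors["CRPS"].copy(), anchors)
        assert res.label == "CRPS"
        assert res.correlations["CRPS"] == pytest.approx(1.0)

    def test_negated_barcode_never_selected_over_better(self):
        anchors = {
            "healthy": np.array([1, 0, -1, 1, 0, -1]),
            "CBP": np.array([0, 1, 1, -1, -1, 0]),
        }
        res = pm.classify(-anchors["CBP"], anchors)
        assert res.correlations["CBP"] == pytest.approx(-1.0)
        assert res.label == "healthy"

    def test_correlations_match_definition_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.integers(-1, 2, 30)
            b = rng.integers(-1, 2, 30)
            if a.std() == 0 or b.std() == 0:
                continue
            res = pm.classify(a, {"healthy": b})
            am, bm = a - a.mean(), b - b.mean()
            expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
            assert res.correlations["healthy"] == pytest.approx(expected, abs=1e-12)

    def test_tie_broken_by_fixed_group_order_and_flagged(self):
        code = np.array([1, -1, 1, -1])
        anchors = {"OA": code.copy(), "CRPS": code.copy()}
        res = pm.classify(code, anchors)
        assert res.label == "CRPS"  # CRPS precedes OA in the canonical order
        assert res.tie

    def test_all_zero_subject_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            pm.classify(np.zeros(5, dtype=int), {"healthy": np.array([1, -1, 0, 1, -1])})


class TestConfusionMetrics:
    def test_perfect_prediction_scores_100(self):
        labels = ["healthy"] * 3 + ["CBP"] * 2 + ["OA"] * 2
        rep = pm.confusion_metrics(labels, labels)
        assert all(v == 100.0 for v in rep.sensitivity.values())
        assert all(v == 100.0 for v in rep.specificity.values())

    def test_hand_counted_two_class_example(self):
        true = ["healthy"] * 3 + ["CBP"] * 3
        pred = ["healthy", "healthy", "CBP", "CBP", "CBP", "CBP"]
        rep = pm.confusion_metrics(true, pred)
        assert rep.confusion.loc["healthy", "healthy"] == 2
        assert rep.sensitivity["healthy"] == pytest.approx(100 * 2 / 3)
        assert rep.specificity["healthy"] == pytest.approx(100.0)
        assert rep.sensitivity["CBP"] == pytest.approx(100.0)
        assert rep.specificity["CBP"] == pytest.approx(100 * 2 / 3)

    def test_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(8)
        true = rng.choice(pm.GROUPS, 50)
        pred = rng.choice(pm.GROUPS, 50)
        rep = pm.confusion_metrics(true, pred, classes=list(pm.GROUPS))
        for g in pm.GROUPS:
            assert rep.confusion.loc[g].sum() == (true == g).sum()

    def test_uniform_random_baseline_is_25_percent(self):
        rng = np.random.default_rng(9)
        true = rng.choice(pm.GROUPS, 10_000)
        pred = rng.choice(pm.GROUPS, 10_000)
        rep = pm.confusion_metrics(true, pred, classes=list(pm.GROUPS))
        mean_sens = np.mean(list(rep.sensitivity.values()))
        assert mean_sens == pytest.approx(25.0, abs=2.0)


class TestSubsampleValidation:
    def test_separable_construction_scores_100(self):
        # noiseless, strongly separated group profiles: held-out subjects
        # must classify perfectly for any training subset
        rng = np.random.default_rng(10)
        patterns = {g: rng.normal(size=24) for g in pm.GROUPS}
        Y = np.vstack([patterns[g] for g in pm.GROUPS for _ in range(6)])
        corrected = _corrected(Y, [g for g in pm.GROUPS for _ in range(6)])
        out = pm.subsample_validation(corrected, n_per_group=5, iterations=4, theta=0.5, seed=0)
        assert out["mean_sensitivity"] == pytest.approx(100.0)
        assert out["mean_specificity"] == pytest.approx(100.0)

    def test_fixed_seed_reproducible(self, corrected82):
        a = pm.subsample_validation(corrected82, n_per_group=5, iterations=3, seed=7)
        b = pm.subsample_validation(corrected82, n_per_group=5, iterations=3, seed=7)
        assert a == b

    def test_training_subjects_never_scored(self):
        # with a group of size n and n_per_group = n - 1, exactly one subject
        # per group is scored each iteration
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(12, 16)) + np.repeat(rng.normal(0, 2, (2, 16)), 6, axis=0)
        corrected = _corrected(Y, ["healthy"] * 6 + ["CBP"] * 6)
        out = pm.subsample_validation(corrected, n_per_group=5, iterations=2, theta=0.3, seed=1)
        assert out["iterations"] == 2

    def test_too_small_group_rejected(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(8, 10))
        corrected = _corrected(Y, ["healthy"] * 4 + ["CBP"] * 4)
        with pytest.raises(ValueError, match="n_per_group"):
            pm.subsample_validation(corrected, n_per_group=4)


class TestPipelineInvariance:
    def test_barcode_invariant_to_profile_shift_and_scale(self, corrected82):
        codes = subject_barcodes(corrected82, theta=DEFAULT_THETA)
        shifted = CorrectedGM(
            data=corrected82.data * 3.0 + 0.17,
            groups=corrected82.groups,
            covariates=corrected82.covariates,
        )
        codes2 = subject_barcodes(shifted, theta=DEFAULT_THETA)
        pd.testing.assert_frame_equal(codes, codes2)

    def test_full_cohort_classification_recovers_groups(self, corrected82):
        scan = pm.optimize_threshold(corrected82)
        result = classify_cohort(corrected82, theta=scan.theta_star)
        rep = pm.confusion_metrics(result["true"], result["pred"])
        assert np.mean(list(rep.sensitivity.values())) >= 70.0
        assert np.mean(list(rep.specificity.values())) >= 85.0
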