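"""Fold plans, AUC/accuracy, permutation & bootstrap tests, and the harness."""

import numpy as np
import pytest
from scipy import stats

import stainshift as ss
from stainshift.classifier import ScorerConfig
from stainshift.evaluate import (
    ExperimentConfig,
    build_manifest,
    cohort_accounting,
    render_report,
    run_study,
    validate_manifest,
)
from stainshift.gan import GanConfig
from stainshift.synthetic import SyntheticSlideStore


def pairwise_auc(scores, labels):
    """Double-loop Mann-Whitney oracle (ties count one half)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestFoldPlan:
    def test_printed_blocks_for_154_subjects(self):
        plan = ss.make_fold_plan(154, 36, 3)
        blocks = [tuple(test) for test, _ in plan.folds]
        assert blocks[0] == tuple(range(119, 155))
        assert blocks[1] == tuple(range(83, 119))
        assert blocks[2] == tuple(range(47, 83))
        for test, train in plan.folds:
            assert len(train) == 118
            assert not set(test) & set(train)

    def test_hand_enumerated_small_plan(self):
        plan = ss.make_fold_plan(10, 5, 2)
        assert [tuple(t) for t, _ in plan.folds] == [tuple(range(6, 11)), tuple(range(1, 6))]
        assert all(len(train) == 5 for _, train in plan.folds)

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError):
            ss.make_fold_plan(6, 3, 3)

    def test_test_blocks_disjoint(self):
        plan = ss.make_fold_plan(30, 7, 4)
        seen = set()
        for test, _ in plan.folds:
            assert not seen & set(test)
            seen |= set(test)


class TestRocAuc:
    def test_perfect_and_tied_cases(self):
        assert ss.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert ss.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert ss.roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.roc_auc([0.1, 0.2], [1, 1])


class TestRocPoints:
    def test_trapezoid_area_matches_auc_without_ties(self):
        from stainshift.evaluate import roc_points

        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(8, 40))
            scores = rng.permutation(np.linspace(0.01, 0.99, n))  # distinct
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pts = roc_points(scores, labels)
            area = np.trapezoid(pts.tpr, pts.fpr)
            assert area == pytest.approx(ss.roc_auc(scores, labels), abs=1e-12)
        assert pts.fpr.iloc[0] == 0 and pts.tpr.iloc[-1] == 1


class TestBinarizedAccuracy:
    def test_hand_case(self):
        assert ss.binarized_accuracy([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.5

    def test_perfect_case(self):
        assert ss.binarized_accuracy([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        a = ss.binarized_accuracy(scores, labels)
        b = ss.binarized_accuracy(scores, 1 - labels)
        assert a + b == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ss.binarized_accuracy([0.5], [1, 0])


class TestAucNullTest:
    def test_minimum_attainable_p_with_perfect_separation(self):
        labels = np.array([1] * 18 + [0] * 18)
        scores = np.where(labels == 1, 0.9, 0.1) + np.linspace(0, 0.01, 36)
        p = ss.auc_null_test(scores, labels, n_permutations=9999, seed=3)
        assert p == pytest.approx(1 / 10_000)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(8)
        labels = np.array([1] * 10 + [0] * 10)
        pvals = [
            ss.auc_null_test(rng.random(20), labels, n_permutations=499, seed=s)
            for s in range(200)
        ]
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.1

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        scores, labels = rng.random(20), np.tile([0, 1], 10)
        p1 = ss.auc_null_test(scores, labels, 999, seed=5)
        p2 = ss.auc_null_test(scores, labels, 999, seed=5)
        assert p1 == p2

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            ss.auc_null_test([0.1, 0.9], [0, 1], n_permutations=50, seed=0)


class TestCompareAucTest:
    def test_identical_scores_not_significant(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        labels = np.tile([0, 1], 15)
        for seed in range(5):
            p = ss.compare_auc_test(scores, scores, labels, n_bootstrap=499, seed=seed)
            assert p >= 0.4

    def test_dominated_difference_significant(self):
        labels = np.tile([0, 1], 20)
        good = np.where(labels == 1, 0.9, 0.1)
        bad = 1.0 - good
        p = ss.compare_auc_test(good, bad, labels, n_bootstrap=999, seed=1)
        assert p <= 0.01

    def test_deterministic_and_length_checked(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(20), rng.random(20)
        labels = np.tile([0, 1], 10)
        assert ss.compare_auc_test(x, y, labels, 199, seed=2) == ss.compare_auc_test(
            x, y, labels, 199, seed=2
        )
        with pytest.raises(ValueError):
            ss.compare_auc_test(x[:-1], y, labels, 199, seed=2)


class TestBonferroni:
    def test_printed_correction(self):
        assert ss.bonferroni_alpha(0.05, 4) == pytest.approx(0.0125)

    def test_identity_and_monotonicity(self):
        assert ss.bonferroni_alpha(0.04, 1) == 0.04
        alphas = [ss.bonferroni_alpha(0.05, m) for m in range(1, 8)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            ss.bonferroni_alpha(0.05, 0)


class TestBuildManifest:
    def test_stratified_blocks_are_class_balanced(self):
        patients = ss.sample_cohort(154, 63 / 154, 0.2, seed=3)
        manifest = build_manifest(patients, seed=3)
        validate_manifest(manifest)
        plan = ss.make_fold_plan(154, 36, 3)
        per_subject = manifest.drop_duplicates("patient_id").set_index("randomized_index")
        for test, _ in plan.folds:
            n_pos = int(per_subject.loc[list(test), "label"].sum())
            assert abs(n_pos - 36 * 63 / 154) <= 1.0

    def test_each_patient_has_both_batches(self):
        patients = ss.sample_cohort(12, 0.5, 0.2, seed=4)
        manifest = build_manifest(patients, seed=4)
        assert manifest.groupby("patient_id")["batch"].nunique().eq(2).all()
        assert sorted(manifest.randomized_index.unique()) == list(range(1, 13))


class TestCohortAccounting:
    def test_consistent_accounting(self):
        acc = cohort_accounting(198, 44, 63, 91)
        assert acc["n_qualifying"] == 154
        assert acc["class_counts_consistent"]

    def test_inconsistent_counts_flagged(self):
        assert not cohort_accounting(198, 44, 63, 90)["class_counts_consistent"]


@pytest.fixture(scope="module")
def tiny_setup():
    """8-patient cohort with identical batch profiles, small slides."""
    patients = ss.sample_cohort(8, 0.5, 0.6, seed=51)
    profile, _ = ss.default_profiles(noise_sd=0.02)
    store = SyntheticSlideStore(patients, profile, profile, 640, 640, seed=51)
    manifest = build_manifest(patients, seed=51)
    plan = ss.make_fold_plan(8, 2, 2)
    config = ExperimentConfig(
        tiles_per_slide=4,
        target_tiles_per_slide=3,
        scorer=ScorerConfig(learning_rate=3e-3, batch_size=8, epochs=2),
        gan=GanConfig(steps=25),
        n_permutations=199,
        n_bootstrap=199,
    )
    return patients, store, manifest, plan, config


class TestRunExperiment:
    def test_report_structure_and_invariants(self, tiny_setup):
        patients, store, manifest, plan, config = tiny_setup
        results, report = ss.run_experiment(
            manifest, store, "A", "none", plan, config, seed=1
        )
        assert len(results) == 2
        for r in results:
            assert 0.0 <= r.auc_same_batch <= 1.0
            assert 0.0 <= r.auc_cross_batch <= 1.0
            assert 0.0 < r.p_null_same <= 1.0
        assert set(report["columns"]) == {"A", "B"}
        assert report["mean_auc_same_batch"] == pytest.approx(
            np.mean([r.auc_same_batch for r in results])
        )

    def test_identical_profiles_make_batches_interchangeable(self, tiny_setup):
        patients, store, manifest, plan, config = tiny_setup
        _, rep_a = ss.run_experiment(manifest, store, "A", "none", plan, config, seed=1)
        # identical profiles: cross-batch slides are identical renderings,
        # so the two columns must agree exactly
        assert rep_a["columns"]["A"] == pytest.approx(rep_a["columns"]["B"])

    def test_traditional_arm_reports_comparison_p(self, tiny_setup):
        patients, store, manifest, plan, config = tiny_setup
        short_plan = ss.make_fold_plan(8, 2, 1)
        results, report = ss.run_experiment(
            manifest, store, "A", "traditional", short_plan, config, seed=2
        )
        assert results[0].p_compare_vs_original is not None
        assert 0.0 < results[0].p_compare_vs_original <= 1.0

    def test_generative_arm_runs_per_test_slide(self, tiny_setup):
        patients, store, manifest, plan, config = tiny_setup
        short_plan = ss.make_fold_plan(8, 2, 1)
        results, report = ss.run_experiment(
            manifest, store, "A", "generative", short_plan, config, seed=3
        )
        assert 0.0 <= results[0].auc_same_batch <= 1.0

    def test_missing_batch_detected(self, tiny_setup):
        patients, store, manifest, plan, config = tiny_setup
        broken = manifest[~((manifest.patient_id == patients[0].patient_id)
                            & (manifest.batch == "B"))]
        with pytest.raises(ValueError):
            ss.run_experiment(broken, store, "A", "none", plan, config, seed=1)

    def test_invalid_modes_rejected(self, tiny_setup):
        _, store, manifest, plan, config = tiny_setup
        with pytest.raises(ValueError):
            ss.run_experiment(manifest, store, "C", "none", plan, config, seed=1)
        with pytest.raises(ValueError):
            ss.run_experiment(manifest, store, "A", "zhistogram", plan, config, seed=1)

    def test_manifest_validation(self, tiny_setup):
        patients, store, manifest, *_ = tiny_setup
        dup = manifest.copy()
        dup = dup._append(dup.iloc[0])
        with pytest.raises(ValueError):
            validate_manifest(dup)

    def test_render_report_layout(self, tiny_setup):
        patients, store, manifest, plan, config = tiny_setup
        short_plan = ss.make_fold_plan(8, 2, 1)
        study = run_study(
            manifest, store, short_plan, "A", modes=("none",), config=config, seed=4
        )
        text = render_report(study)
        assert "Train on batch A" in text
        assert "Original H&E" in text
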