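"""ROC machinery, paired AUC comparison, cross-validation, stratification."""

import numpy as np
import pandas as pd
import pytest

from gsdi.evaluate import (compare_auc, loo_cv_scores, partial_auc, roc_curve,
                           sensitivity_at_specificity,
                           stage_stratified_performance)


def pair_counting_auc(scores, labels):
    """Exhaustive case-control pair counting with ties scored 1/2."""
    scores = np.asarray(scores, float)
    cases = scores[np.asarray(labels) == 1]
    controls = scores[np.asarray(labels) == 0]
    wins = 0.0
    for c in cases:
        for d in controls:
            wins += 1.0 if c > d else (0.5 if c == d else 0.0)
    return wins / (len(cases) * len(controls))


class TestROCCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=2000)
        labels = rng.permutation(np.repeat([0, 1], 1000))
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.04)

    def test_worked_example_by_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_curve(scores, labels).auc == pytest.approx(0.75)
        assert pair_counting_auc(scores, labels) == pytest.approx(0.75)

    def test_trapezoid_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = rng.integers(8, 60)
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                pair_counting_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], [1, 1])


class TestPartialAUC:
    def test_perfect_classifier_attains_band_width(self):
        roc = roc_curve([0, 0, 1, 1, 5, 6, 7, 8],
                        [0, 0, 0, 0, 1, 1, 1, 1])
        assert partial_auc(roc, 0.90, 1.00) == pytest.approx(0.100)

    def test_chance_diagonal_band_area(self):
        # integral of (1 - specificity) over the band = 0.1^2 / 2
        rng = np.random.default_rng(22)
        scores = rng.permutation(np.arange(4000, dtype=float))
        labels = np.repeat([0, 1], 2000)
        roc = roc_curve(scores, labels)
        assert partial_auc(roc, 0.90, 1.00) == pytest.approx(0.005, abs=0.002)

    def test_band_bounds_and_dominance(self):
        rng = np.random.default_rng(23)
        labels = np.repeat([0, 1], 300)
        weak = np.r_[rng.normal(0, 1, 300), rng.normal(0.8, 1, 300)]
        strong = np.r_[rng.normal(0, 1, 300), rng.normal(2.5, 1, 300)]
        p_weak = partial_auc(roc_curve(weak, labels), 0.9, 1.0)
        p_strong = partial_auc(roc_curve(strong, labels), 0.9, 1.0)
        assert 0.0 <= p_weak <= 0.1 and 0.0 <= p_strong <= 0.1
        assert p_strong > p_weak

    def test_improvement_arithmetic_on_reported_band_areas(self):
        assert round(100 * (0.082 - 0.064) / 0.064) == 28

    def test_inverted_band_rejected(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        with pytest.raises(ValueError):
            partial_auc(roc, 0.99, 0.90)


class TestSensitivityAtSpecificity:
    def test_perfect_classifier_full_sensitivity(self):
        roc = roc_curve([1, 2, 9, 10], [0, 0, 1, 1])
        for target, expected_thr in ((0.5, 2.0), (0.9, 9.0), (0.99, 9.0)):
            # smallest threshold whose specificity meets the target
            thr, sens = sensitivity_at_specificity(roc, target)
            assert sens == pytest.approx(1.0)
            assert thr == pytest.approx(expected_thr)

    def test_overlapping_ranges_against_exhaustive_scan(self):
        controls = np.arange(1, 101, dtype=float)
        cases = np.arange(50, 150, dtype=float)
        scores = np.r_[controls, cases]
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        roc = roc_curve(scores, labels)
        thr, sens = sensitivity_at_specificity(roc, 0.95)
        # exhaustive scan over candidate thresholds
        best = None
        for t in np.unique(scores):
            spec = (controls < t).mean()
            if spec >= 0.95 and (best is None or t < best):
                best = t
        assert thr == pytest.approx(best)
        assert sens == pytest.approx((cases >= best).mean())
        assert thr > 95

    def test_nested_specificity_targets(self):
        rng = np.random.default_rng(24)
        scores = np.r_[rng.normal(0, 1, 200), rng.normal(1.5, 1, 200)]
        labels = np.repeat([0, 1], 200)
        roc = roc_curve(scores, labels)
        _, s95 = sensitivity_at_specificity(roc, 0.95)
        _, s99 = sensitivity_at_specificity(roc, 0.99)
        assert s95 >= s99


class TestCompareAUC:
    def test_identical_scores_give_zero_delta_and_large_p(self):
        rng = np.random.default_rng(25)
        scores = np.r_[rng.normal(0, 1, 60), rng.normal(1, 1, 60)]
        labels = np.repeat([0, 1], 60)
        d, p = compare_auc(scores, scores, labels, seed=1)
        assert d == 0.0
        assert p > 0.8

    def test_informative_vs_noise_is_detected(self):
        rng = np.random.default_rng(26)
        hits = 0
        for rep in range(10):
            labels = np.repeat([0, 1], 250)
            good = labels * 1.5 + rng.normal(0, 1, 500)
            noise = rng.normal(0, 1, 500)
            d, p = compare_auc(good, noise, labels, n_resamples=400,
                               seed=rep)
            assert d > 0
            hits += p < 0.01
        assert hits >= 9

    def test_bootstrap_agrees_with_exhaustive_permutation_on_toy_data(self):
        rng = np.random.default_rng(27)
        labels = np.array([0] * 6 + [1] * 6)
        a = labels * 0.6 + rng.normal(0, 1, 12)
        b = labels * 0.5 + rng.normal(0, 1, 12)
        d_b, p_boot = compare_auc(a, b, labels, method="bootstrap",
                                  n_resamples=4000, seed=2)
        d_p, p_perm = compare_auc(a, b, labels, method="permutation", seed=2)
        assert d_b == pytest.approx(d_p)
        assert p_boot == pytest.approx(p_perm, abs=0.25)
        assert (p_boot > 0.05) == (p_perm > 0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matching length"):
            compare_auc([1, 2], [1, 2, 3], [0, 1, 1])


def _toy_feature_table(n_subjects=16, seed=0):
    """Minimal bilateral feature table with a real signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        label = int(s >= n_subjects // 2)
        subject_effect = rng.normal(0, 0.3)
        for eye in ("OD", "OS"):
            shift = label * 1.2 + subject_effect
            row = {"subject_id": f"S{s:03d}", "eye": eye,
                   "group": "PG" if label else "N", "label": label}
            for g in ("overall", "superior", "inferior"):
                row[f"z_nfl_{g}_um"] = -shift + rng.normal(0, 1)
                row[f"z_gcc_{g}_um"] = -shift + rng.normal(0, 1)
            for g in ("glv", "flv"):
                row[f"z_nfl_{g}_pct"] = shift + rng.normal(0, 1)
                row[f"z_gcc_{g}_pct"] = shift + rng.normal(0, 1)
            row["nfl_flv_pct"] = max(0.0, shift + rng.normal(0, 1))
            row["gcc_flv_pct"] = max(0.0, shift + rng.normal(0, 1))
            row["vcdr"] = float(np.clip(0.4 + 0.15 * label
                                        + rng.normal(0, 0.08), 0.05, 0.95))
            rows.append(row)
    return pd.DataFrame(rows)


class TestLooCV:
    def test_fold_count_equals_subject_count(self):
        table = _toy_feature_table()
        cv = loo_cv_scores(table)
        assert len(cv.fold_models) == table["subject_id"].nunique()
        assert cv.scores.notna().all()

    def test_repeated_runs_identical(self):
        table = _toy_feature_table()
        s1 = loo_cv_scores(table).scores
        s2 = loo_cv_scores(table).scores
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_eye_level_folds_differ_from_subject_level(self):
        table = _toy_feature_table()
        cv_subj = loo_cv_scores(table, unit="subject")
        cv_eye = loo_cv_scores(table, unit="eye")
        assert len(cv_eye.fold_models) == len(table)
        assert not np.allclose(cv_subj.scores, cv_eye.scores)

    def test_cv_auc_close_to_independent_cohort_auc(self):
        """Out-of-fold AUC tracks the generalization AUC of a model fit on
        an independent same-size cohort (repeated over fresh draws)."""
        from gsdi.index import apply_stage1, fit_gsdi, fit_stage1
        cv_aucs, holdout_aucs = [], []
        for rep in range(8):
            train = _toy_feature_table(n_subjects=20, seed=100 + rep)
            test = _toy_feature_table(n_subjects=20, seed=200 + rep)
            cv = loo_cv_scores(train)
            cv_aucs.append(roc_curve(cv.scores.to_numpy(),
                                     train["label"].to_numpy()).auc)
            w = fit_stage1(train)
            model = fit_gsdi(apply_stage1(train, w))
            scores = model.predict(apply_stage1(test, w))
            holdout_aucs.append(roc_curve(scores,
                                          test["label"].to_numpy()).auc)
        assert np.mean(cv_aucs) == pytest.approx(np.mean(holdout_aucs),
                                                 abs=0.06)

    def test_published_model_mode_skips_stage2_refits(self):
        table = _toy_feature_table()
        cv = loo_cv_scores(table, model="published")
        assert all(m.source == "published" for m in cv.fold_models.values())
        assert cv.scores.notna().all()

    def test_too_few_units_rejected(self):
        table = _toy_feature_table(n_subjects=16)
        one_case = table[table["subject_id"].isin(
            ["S000", "S001", "S002", "S008"])]
        with pytest.raises(ValueError, match="2 units per class"):
            loo_cv_scores(one_case)


class TestCVHygiene:
    def test_poisoned_held_out_subject_changes_only_its_own_score(self):
        table = _toy_feature_table(n_subjects=14, seed=3)
        victim = "S003"
        poisoned = table.copy()
        rows = poisoned["subject_id"] == victim
        for c in poisoned.columns:
            if c.startswith(("z_", "nfl_", "gcc_")) or c == "vcdr":
                poisoned.loc[rows, c] = 9.9
        clean = loo_cv_scores(table)
        audit = loo_cv_scores(table, score_table=poisoned)
        changed = clean.scores != audit.scores
        assert set(table.loc[changed.to_numpy(), "subject_id"]) == {victim}
        # the victim's own fold model never saw its data: bitwise identical
        assert np.array_equal(clean.fold_models[victim].params.to_numpy(),
                              audit.fold_models[victim].params.to_numpy())

    def test_fold_models_depend_only_on_training_rows(self):
        table = _toy_feature_table(n_subjects=14, seed=4)
        victim = "S002"
        corrupted = table.copy()
        rows = corrupted["subject_id"] == victim
        corrupted.loc[rows, "vcdr"] = 0.95
        m1 = loo_cv_scores(table).fold_models[victim]
        m2 = loo_cv_scores(corrupted).fold_models[victim]
        assert np.array_equal(m1.params.to_numpy(), m2.params.to_numpy())


class TestStageStratified:
    def test_counts_partition_cases_and_degenerate_single_stage(self):
        rng = np.random.default_rng(28)
        labels = np.repeat([0, 1], 100)
        scores = labels * 1.5 + rng.normal(0, 1, 200)
        stages = np.array([None] * 100 + ["2"] * 100, dtype=object)
        perf = stage_stratified_performance(scores, labels, stages,
                                            stage_order=["2"])
        assert len(perf) == 1 and perf[0].n_cases == 100
        assert perf[0].auc == pytest.approx(
            roc_curve(scores, labels).auc)

    def test_per_stage_counts_sum_to_total(self):
        rng = np.random.default_rng(29)
        labels = np.repeat([0, 1], 120)
        stages = np.array([None] * 120
                          + list(rng.choice(["1", "2", "3"], 120)),
                          dtype=object)
        scores = labels * 1.0 + rng.normal(0, 1, 240)
        perf = stage_stratified_performance(scores, labels, stages,
                                            stage_order=["1", "2", "3", "4"])
        assert sum(p.n_cases for p in perf) == 120
        empty = [p for p in perf if p.stage == "4"][0]
        assert empty.n_cases == 0 and np.isnan(empty.auc)

    def test_severity_scaled_effects_give_monotone_auc(self):
        rng = np.random.default_rng(30)
        labels = np.r_[np.zeros(150, int), np.ones(150, int)]
        stage = np.array([None] * 150 + list(rng.choice(["1", "2", "3"], 150)),
                         dtype=object)
        effect = {"1": 0.8, "2": 1.8, "3": 3.0}
        scores = rng.normal(0, 1, 300)
        for i in range(150, 300):
            scores[i] += effect[stage[i]]
        perf = stage_stratified_performance(scores, labels, stage,
                                            stage_order=["1", "2", "3"])
        aucs = [p.auc for p in perf]
        assert aucs == sorted(aucs)
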