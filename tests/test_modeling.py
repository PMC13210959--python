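"""Trial-level splitting, metrics, feature screening, benchmarking and
random-forest tuning."""

import numpy as np
import pandas as pd
import pytest

import emgintent as ei
from emgintent.datatypes import TrialAnnotation
from emgintent.modeling import (
    DEFAULT_FUSIONS,
    ClassifierSpec,
    CVSpec,
    SplitSpec,
    accuracy,
    aggregate_subject_table,
    benchmark_classifiers,
    confusion_and_per_class,
    default_benchmark_specs,
    evaluate_fusions,
    evaluate_single_features,
    fit_and_evaluate,
    grid_search_rf,
    split_trial_ids,
    split_trials,
    trial_folds,
)


def _annotations(per_class, classes=ei.MOTION_CLASSES):
    anns, tid, pos = [], 0, 0
    for c in classes:
        for _ in range(per_class):
            anns.append(TrialAnnotation(tid, c, pos, pos + 100))
            tid += 1
            pos += 200
    return anns


class TestSplitTrials:
    def test_ten_trials_per_class_at_90_10_leaves_one_test_trial(self):
        anns = _annotations(10)
        train, test = split_trials(anns, SplitSpec(0.9, seed=0))
        labels = {a.trial_id: a.label for a in anns}
        per_class_test = {c: 0 for c in ei.MOTION_CLASSES}
        for t in test:
            per_class_test[labels[t]] += 1
        assert all(v == 1 for v in per_class_test.values())
        assert sorted(train + test) == sorted(a.trial_id for a in anns)

    def test_half_split_of_four_trials_is_two_two(self):
        anns = _annotations(4, classes=("y1",)) + _annotations(0)
        # single-class data: unstratified split
        train, test = split_trial_ids(
            [a.trial_id for a in anns], [a.label for a in anns],
            SplitSpec(0.5, stratify=False, seed=3),
        )
        assert len(train) == 2 and len(test) == 2

    def test_same_seed_reproduces_split(self):
        anns = _annotations(10)
        s1 = split_trials(anns, SplitSpec(seed=1))
        s2 = split_trials(anns, SplitSpec(seed=1))
        s3 = split_trials(anns, SplitSpec(seed=2))
        assert s1 == s2
        assert s1 != s3  # overwhelmingly likely with 40 trials

    def test_stratified_split_needs_two_trials_per_class(self):
        anns = _annotations(1)
        with pytest.raises(ValueError, match="at least 2"):
            split_trials(anns, SplitSpec())

    def test_train_and_test_are_disjoint_and_exhaustive(self):
        anns = _annotations(7)
        train, test = split_trials(anns, SplitSpec(0.8, seed=9))
        assert not set(train) & set(test)
        assert set(train) | set(test) == {a.trial_id for a in anns}


class TestAccuracy:
    def test_fraction_correct(self):
        pred = [1, 1, 1, 1, 1, 1, 1, 1, 1, 0]
        true = [1] * 10
        assert accuracy(pred, true) == pytest.approx(0.9)
        assert accuracy(true, true) == 1.0

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(50):
            n = rng.integers(1, 200)
            pred = rng.integers(0, 4, n)
            true = rng.integers(0, 4, n)
            brute = sum(1 for p, t in zip(pred, true) if p == t) / n
            assert accuracy(pred, true) == pytest.approx(brute)

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])
        with pytest.raises(ValueError):
            accuracy([1], [1, 2])

    def test_published_style_row_mean(self):
        # mean of four per-class accuracies as used in fusion tables
        row = pd.Series([0.964, 0.945, 0.936, 0.943])
        assert row.mean() == pytest.approx(0.947)


class TestConfusion:
    def test_perfect_predictions_give_diagonal_matrix(self):
        y = ["y1", "y2", "y3", "y4"] * 5
        rep = confusion_and_per_class(y, y)
        assert np.all(np.diag(rep.confusion.to_numpy()) == 5)
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.per_class_accuracy.values())

    def test_collapsed_predictions_put_all_mass_in_one_column(self):
        true = ["y1"] * 3 + ["y2"] * 3 + ["y3"] * 3 + ["y4"] * 3
        pred = ["y1"] * 12
        rep = confusion_and_per_class(pred, true)
        cm = rep.confusion
        assert cm["y1"].sum() == 12
        assert rep.per_class_accuracy["y1"] == 1.0
        assert all(rep.per_class_accuracy[c] == 0.0 for c in ("y2", "y3", "y4"))

    def test_hand_built_matrix_matches_brute_force_counts(self, rng):
        classes = ei.MOTION_CLASSES
        true = rng.choice(classes, 200)
        pred = rng.choice(classes, 200)
        rep = confusion_and_per_class(pred, true)
        cm = rep.confusion.to_numpy()
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                brute = sum(1 for t, p in zip(true, pred) if t == ci and p == cj)
                assert cm[i, j] == brute
        assert cm.sum() == 200
        assert rep.overall_accuracy == pytest.approx(np.trace(cm) / 200)
        for i, c in enumerate(classes):
            assert rep.per_class_accuracy[c] == pytest.approx(
                cm[i, i] / cm[i].sum()
            )


class TestAggregation:
    def test_column_means_of_subject_table(self):
        table = pd.DataFrame(
            {"y1": [0.9, 1.0], "Mean Value": [0.95, 0.85]},
            index=["s1", "s2"],
        )
        agg = aggregate_subject_table(table)
        assert agg["y1"] == pytest.approx(0.95)
        assert agg["Mean Value"] == pytest.approx(0.9)


class TestSingleFeatureScreening:
    def test_eight_rows_with_mean_column(self, small_batch):
        table = evaluate_single_features(
            small_batch, ClassifierSpec("RandomForest", {"n_estimators": 25}, 0),
            SplitSpec(seed=5),
        )
        assert table.shape == (8, 5)
        for _, row in table.iterrows():
            assert row["Mean Value"] == pytest.approx(
                row[list(ei.MOTION_CLASSES)].mean()
            )

    def test_amplitude_features_separate_amplitude_coded_classes(self, small_batch):
        table = evaluate_single_features(
            small_batch, ClassifierSpec("RandomForest", {"n_estimators": 25}, 0),
            SplitSpec(seed=5),
        )
        assert table.loc["RMS", "Mean Value"] >= 0.9
        assert table.loc["RMS", "Mean Value"] >= table.loc["VAR", "Mean Value"] - 0.02

    def test_single_class_data_rejected(self, small_batch):
        import dataclasses

        mask = small_batch.labels == "y1"
        degenerate = dataclasses.replace(
            small_batch,
            data=small_batch.data[mask],
            labels=small_batch.labels[mask],
            trial_ids=small_batch.trial_ids[mask],
            start_samples=small_batch.start_samples[mask],
        )
        with pytest.raises(ValueError, match="fewer than two classes"):
            evaluate_single_features(degenerate)


class TestFusions:
    def test_default_list_contains_selected_triplet(self):
        assert ("IF", "CF", "RMS") in DEFAULT_FUSIONS
        assert len(DEFAULT_FUSIONS) == 11

    def test_fusion_table_rows_and_mean(self, small_batch):
        combos = [("RMS", "IF"), ("IF", "CF", "RMS")]
        table = evaluate_fusions(
            small_batch, combos,
            ClassifierSpec("RandomForest", {"n_estimators": 25}, 0),
            SplitSpec(seed=5),
        )
        assert list(table.index) == ["RMS + IF", "IF + CF + RMS"]
        for _, row in table.iterrows():
            assert row["Mean Value"] == pytest.approx(
                row[list(ei.MOTION_CLASSES)].mean()
            )

    def test_duplicate_feature_in_combo_deduplicated(self, small_batch, caplog):
        with caplog.at_level("WARNING"):
            table = evaluate_fusions(
                small_batch, [("RMS", "RMS", "IF")],
                ClassifierSpec("RandomForest", {"n_estimators": 10}, 0),
                SplitSpec(seed=5),
            )
        assert list(table.index) == ["RMS + IF"]
        assert "duplicate" in caplog.text

    def test_empty_combo_rejected(self, small_batch):
        with pytest.raises(ValueError):
            evaluate_fusions(small_batch, [()])


class TestBenchmark:
    def test_single_spec_gives_single_sorted_report(self, small_batch):
        fm = ei.extract_features(small_batch, ["RMS", "IF", "CF"])
        reports = benchmark_classifiers(
            fm, [ClassifierSpec("RandomForest", {"n_estimators": 25}, 0)],
            SplitSpec(seed=4),
        )
        assert len(reports) == 1
        assert reports[0].provenance["classifier"] == "RandomForest"

    def test_reports_identical_across_reruns(self, small_batch):
        fm = ei.extract_features(small_batch, ["RMS", "IF", "CF"])
        specs = [
            ClassifierSpec("RandomForest", {"n_estimators": 25}, 7),
            ClassifierSpec("LDA", seed=7),
        ]
        r1 = benchmark_classifiers(fm, specs, SplitSpec(seed=4))
        r2 = benchmark_classifiers(fm, specs, SplitSpec(seed=4))
        for a, b in zip(r1, r2):
            assert a.overall_accuracy == b.overall_accuracy
            pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_overlapping_train_test_sets_rejected(self, small_batch):
        fm = ei.extract_features(small_batch, ["RMS"])
        with pytest.raises(ValueError, match="overlap"):
            fit_and_evaluate(fm, [0, 1], [1, 2], ClassifierSpec())


class TestLeakageGuard:
    def test_no_window_shared_between_train_and_test_over_100_splits(
        self, small_batch
    ):
        for seed in range(100):
            train, test = split_trial_ids(
                small_batch.trial_ids, small_batch.labels, SplitSpec(seed=seed)
            )
            train_windows = set(
                np.flatnonzero(np.isin(small_batch.trial_ids, train))
            )
            test_windows = set(
                np.flatnonzero(np.isin(small_batch.trial_ids, test))
            )
            assert not train_windows & test_windows
            assert len(train_windows | test_windows) == len(small_batch)


class TestGridSearch:
    def test_one_by_one_grid_returns_that_cell(self, small_batch):
        fm = ei.extract_features(small_batch, ["RMS", "IF", "CF"])
        n, d, surface = grid_search_rf(fm, CVSpec(2, (25,), (7,)), seed=0)
        assert (n, d) == (25, 7)
        assert surface.shape == (1, 1)

    def test_fold_assignment_keeps_trials_atomic(self, small_batch):
        folds = trial_folds(small_batch.trial_ids, small_batch.labels, 3, seed=1)
        seen = [t for f in folds for t in f]
        assert sorted(seen) == sorted(set(small_batch.trial_ids))
        for fold in folds:
            members = np.isin(small_batch.trial_ids, fold)
            # each trial's windows are wholly inside exactly one fold
            for tid in fold:
                assert np.all(members[small_batch.trial_ids == tid])

    def test_more_folds_than_trials_rejected(self, small_batch):
        with pytest.raises(ValueError, match="fold"):
            trial_folds(small_batch.trial_ids, small_batch.labels, 50, seed=0)

    def test_accuracy_stabilises_with_more_trees_on_noisy_data(self):
        proto = ei.ProtocolSpec(
            n_blocks=1, trials_per_class_per_block=6,
            prep_duration=1.0, execution_duration=2.0, return_duration=1.0,
        )
        rec, anns = ei.generate_session(
            proto, ei.default_profiles(overlap=0.8),
            ei.ContaminantSpec(noise_std=0.3), seed=21,
        )
        clean, _ = ei.preprocess_recording(rec)
        batch = ei.slide_session(ei.extract_effective(clean, anns),
                                 ei.WindowSpec(fs=rec.fs))
        fm = ei.extract_features(batch, ["RMS", "IF", "CF"])
        _, _, surface = grid_search_rf(fm, CVSpec(3, (10, 200), (None,)), seed=2)
        acc10 = surface.loc[10, "None"]
        acc200 = surface.loc[200, "None"]
        assert acc200 >= acc10 - 0.02

    def test_tie_break_prefers_smaller_parameters(self, small_batch):
        # easy data: every cell saturates, so the smallest pair must win
        fm = ei.extract_features(small_batch, ["RMS", "IF", "CF"])
        n, d, surface = grid_search_rf(
            fm, CVSpec(2, (10, 50), (5, None)), seed=0
        )
        if surface.to_numpy().max() == surface.to_numpy().min():
            assert (n, d) == (10, 5)


class TestDefaultSpecs:
    def test_five_classifier_kinds(self):
        kinds = [s.kind for s in default_benchmark_specs(0)]
        assert kinds == [
            "SVM-RBF", "LDA", "QDA", "GradientBoosting", "RandomForest"
        ]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("DeepNet")

    def test_default_grids_include_published_optimum(self):
        cv = CVSpec()
        assert 181 in cv.n_estimators_grid
        assert 131 in cv.max_depth_grid
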