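import numpy as np
import pandas as pd
import pytest

from octradiomics.classify import (
    evaluate_ovr,
    make_split,
    negative_control,
    train_rfe,
    train_robust,
)


def _manifest(counts: dict[str, int]) -> pd.DataFrame:
    rows = [
        (f"{label}{i}", label) for label, n in counts.items() for i in range(n)
    ]
    return pd.DataFrame(rows, columns=["scan_id", "class_label"])


class TestMakeSplit:
    def test_study_cohort_split_is_stratified_70_30(self):
        manifest = _manifest({"bcc": 63, "bowen": 31, "nevus": 40})
        plan = make_split(manifest, seed=7)
        assert abs(len(plan.test_ids) - 0.3 * 134) <= 1
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        labels = dict(zip(manifest["scan_id"], manifest["class_label"]))
        test_counts = pd.Series([labels[i] for i in plan.test_ids]).value_counts()
        for cls, n in (("bcc", 63), ("bowen", 31), ("nevus", 40)):
            assert abs(test_counts[cls] - 0.3 * n) <= 1

    def test_same_seed_reproduces_the_plan(self):
        manifest = _manifest({"a": 20, "b": 15})
        assert make_split(manifest, seed=3) == make_split(manifest, seed=3)

    def test_two_class_manifest_is_valid(self):
        plan = make_split(_manifest({"a": 20, "b": 15}), seed=1)
        assert len(plan.folds) == 5

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            make_split(_manifest({"a": 20, "b": 5}), seed=1)

    def test_folds_cover_training_ids_exactly_once_as_validation(self):
        manifest = _manifest({"a": 25, "b": 20, "c": 15})
        plan = make_split(manifest, seed=2)
        val_ids = [i for _, val in plan.folds for i in val]
        assert sorted(val_ids) == sorted(plan.train_ids)
        for tr, val in plan.folds:
            assert set(tr).isdisjoint(val)
            assert set(tr) | set(val) == set(plan.train_ids)


class TestEvaluateOvr:
    def test_perfect_scores_give_unit_metrics(self):
        y = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0])
        scores = np.eye(3)[y]
        frame, acc, macro = evaluate_ovr(scores, y, ("a", "b", "c"), n_boot=50)
        assert acc == 1.0
        assert macro == 1.0
        assert (frame["auc"] == 1.0).all()
        assert (frame["f1"] == 1.0).all()
        assert (frame["auc_lo"] <= frame["auc"]).all()
        assert (frame["auc"] <= frame["auc_hi"]).all()

    def test_label_independent_scores_are_chance_level(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, size=600)
        scores = rng.random((600, 3))
        _, acc, macro = evaluate_ovr(scores, y, ("a", "b", "c"), n_boot=10)
        assert macro == pytest.approx(0.5, abs=0.06)
        assert acc == pytest.approx(1 / 3, abs=0.08)

    def test_confusion_toy_matches_hand_computation(self):
        # 4 a's predicted a; 3 b's predicted b; 1 b predicted a; 2 c's predicted c
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2])
        pred = np.array([0, 0, 0, 0, 1, 1, 1, 0, 2, 2])
        scores = np.eye(3)[pred]
        frame, acc, _ = evaluate_ovr(scores, y, ("a", "b", "c"), n_boot=10)
        assert acc == pytest.approx(0.9)
        assert frame.loc["a", "precision"] == pytest.approx(4 / 5)
        assert frame.loc["a", "recall"] == pytest.approx(1.0)
        assert frame.loc["b", "precision"] == pytest.approx(1.0)
        assert frame.loc["b", "recall"] == pytest.approx(3 / 4)
        assert frame.loc["c", "f1"] == pytest.approx(1.0)

    def test_absent_class_gets_nan_auc(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        scores = np.random.default_rng(1).random((6, 3))
        frame, _, _ = evaluate_ovr(scores, y, ("a", "b", "c"), n_boot=10)
        assert np.isnan(frame.loc["c", "auc"])


def _toy_features(seed=0, n_per_class=30, n_noise=5):
    """Well-separated dataset needing both informative features, plus noise."""
    rng = np.random.default_rng(seed)
    centers = {0: (0.0, 0.0), 1: (4.0, 0.0), 2: (0.0, 4.0)}
    rows, labels, ids = [], [], []
    for c, label in enumerate(("a", "b", "c")):
        for i in range(n_per_class):
            rows.append(
                np.concatenate(
                    [
                        rng.normal(centers[c], 0.7),
                        rng.normal(size=n_noise),
                    ]
                )
            )
            labels.append(label)
            ids.append(f"{label}{i}")
    features = pd.DataFrame(
        rows, index=ids, columns=[f"inf{i}" for i in range(2)] + [f"noise{i}" for i in range(n_noise)]
    )
    manifest = pd.DataFrame({"scan_id": ids, "class_label": labels})
    return features, pd.Series(labels, index=ids), manifest


class TestTraining:
    def test_robust_model_separates_well_separated_classes(self):
        features, labels, manifest = _toy_features()
        plan = make_split(manifest, seed=7)
        _, report = train_robust(features, labels, plan, {"inf0", "inf1"})
        assert report.macro_auc >= 0.95
        rerun = train_robust(features, labels, plan, {"inf0", "inf1"})[1]
        assert rerun.macro_auc == report.macro_auc
        assert rerun.per_class.equals(report.per_class)

    def test_empty_core_and_single_class_error(self):
        features, labels, manifest = _toy_features()
        plan = make_split(manifest, seed=7)
        with pytest.raises(ValueError):
            train_robust(features, labels, plan, set())
        with pytest.raises(ValueError):
            train_robust(features, pd.Series("a", index=labels.index), plan, {"inf0"})

    def test_rfe_discards_most_noise_features(self):
        features, labels, manifest = _toy_features(n_noise=8)
        plan = make_split(manifest, seed=7)
        _, report = train_rfe(features, labels, plan)
        selected = set(report.selected_features)
        assert len(selected) <= features.shape[1]
        assert {"inf0", "inf1"} <= selected
        noise_kept = sum(f.startswith("noise") for f in selected)
        assert noise_kept <= 4  # most pure-noise columns eliminated

    def test_rfe_selection_ignores_test_rows(self):
        features, labels, manifest = _toy_features()
        plan = make_split(manifest, seed=7)
        _, report1 = train_rfe(features, labels, plan)
        corrupted = features.copy()
        test_ids = list(plan.test_ids)
        corrupted.loc[test_ids] = np.random.default_rng(9).normal(
            size=(len(test_ids), features.shape[1])
        )
        _, report2 = train_rfe(corrupted, labels, plan)
        assert report1.selected_features == report2.selected_features

    def test_negative_control_is_chance_level_and_permutation_is_frozen(self):
        features, labels, manifest = _toy_features()
        plan = make_split(manifest, seed=7)
        _, report, permuted = negative_control(features, labels, plan, {"inf0", "inf1"})
        assert 0.2 <= report.macro_auc <= 0.8
        # only training labels were permuted; the test labels stay true
        assert (permuted.loc[list(plan.test_ids)] == labels.loc[list(plan.test_ids)]).all()
        assert sorted(permuted.loc[list(plan.train_ids)]) == sorted(
            labels.loc[list(plan.train_ids)]
        )
        _, _, permuted_again = negative_control(
            features, labels, plan, {"inf0", "inf1"}
        )
        assert (permuted == permuted_again).all()

    def test_negative_control_seed_changes_permutation_not_conclusion(self):
        features, labels, manifest = _toy_features()
        plan = make_split(manifest, seed=7)
        _, rep1, p1 = negative_control(features, labels, plan, {"inf0", "inf1"}, seed=1)
        _, rep2, p2 = negative_control(features, labels, plan, {"inf0", "inf1"}, seed=2)
        assert not (p1 == p2).all()
        assert 0.2 <= rep1.macro_auc <= 0.8
        assert 0.2 <= rep2.macro_auc <= 0.8
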