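"""Model registry, cross-validation protocol, metrics, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from erpscreen.evaluation import (
    MODEL_NAMES,
    ConfusionMatrix,
    CVSpec,
    cross_validate,
    make_folds,
    make_model,
    make_models,
    metrics,
    roc_auc,
)
from erpscreen.features import FEATURE_NAMES


def make_table(n_subjects=20, effect=0.0, seed=0, records_per_subject=2):
    """Synthetic feature table: canonical columns, Gaussian features, one
    optionally informative column (ABP-0, shifted by +-effect per class)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        group = "ADHD" if i < n_subjects // 2 else "control"
        shift = effect if group == "ADHD" else -effect
        for r in range(records_per_subject):
            row = {
                "subject_id": f"S{i:03d}",
                "modality": "auditory",
                "electrode": "Cz" if r == 0 else "Pz",
                "group": group,
            }
            for name in FEATURE_NAMES:
                row[name] = rng.normal()
            row["ABP-0"] = rng.normal(shift, 1.0)
            rows.append(row)
    cols = ["subject_id", "modality", "electrode", "group"] + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols)


class TestModelRegistry:
    def test_all_seven_models_constructible(self):
        models = make_models(seed=0)
        assert set(models) == set(MODEL_NAMES)

    def test_printed_hyperparameters(self):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.tree import DecisionTreeClassifier

        rf = make_model("RF")
        assert isinstance(rf, RandomForestClassifier)
        assert rf.n_estimators == 100 and rf.max_depth == 10
        dt = make_model("DT")
        assert isinstance(dt, DecisionTreeClassifier)
        assert dt.max_depth == 20
        dl = make_model("DL")[-1]
        assert len(dl.hidden_layer_sizes) == 50
        assert dl.activation == "relu"
        svm = make_model("SVM")[-1]
        assert svm.kernel == "linear"

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_model("KNN")


class TestMetrics:
    def test_printed_formulas(self):
        m = metrics(ConfusionMatrix(tp=50, tn=40, fp=5, fn=5))
        assert m.accuracy == pytest.approx(90.0)
        assert m.classification_error == pytest.approx(10.0)
        assert m.precision == pytest.approx(100.0 * 50 / 55)
        assert m.sensitivity == pytest.approx(50 / 55)
        assert m.specificity == pytest.approx(40 / 45)

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=30, tn=30, fp=0, fn=0))
        assert m.accuracy == 100.0 and m.classification_error == 0.0

    def test_undefined_ratios_flagged_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=5))
        assert m.precision is None
        m2 = metrics(ConfusionMatrix(tp=0, tn=10, fp=3, fn=0))
        assert m2.sensitivity is None

    def test_accuracy_plus_error_is_100(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
            assert m.accuracy + m.classification_error == pytest.approx(100.0)

    def test_matches_brute_force_recount(self, rng):
        truth = rng.random(200) < 0.5
        pred = rng.random(200) < 0.5
        cm = ConfusionMatrix(
            tp=int(np.sum(pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )
        assert cm.total == 200
        assert metrics(cm).accuracy == pytest.approx(100.0 * np.mean(pred == truth))


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9]), labels)
        assert auc == 1.0

    def test_anti_ranking(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        _, auc = roc_auc(np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1]), labels)
        assert auc == 0.0

    def test_random_scores_near_half(self, rng):
        labels = rng.random(1000) < 0.5
        _, auc = roc_auc(rng.random(1000), labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_equals_mann_whitney_normalization(self, rng):
        """AUC is the normalized Mann-Whitney U statistic of the scores."""
        labels = rng.random(300) < 0.4
        scores = rng.normal(size=300) + labels
        scores = np.round(scores, 1)  # force ties
        _, auc = roc_auc(scores, labels)
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        expected = u / (labels.sum() * (~labels).sum())
        assert auc == pytest.approx(expected, abs=1e-9)

    def test_monotone_path_from_origin_to_corner(self, rng):
        labels = rng.random(50) < 0.5
        pts, _ = roc_auc(rng.normal(size=50), labels)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestCrossValidation:
    def test_grouped_folds_keep_subjects_together(self):
        table = make_table(n_subjects=20)
        y = table["group"].to_numpy()
        g = table["subject_id"].to_numpy()
        folds = make_folds(y, g, CVSpec(n_folds=5, grouped=True, seed=1))
        for train, test in folds:
            assert set(g[train]).isdisjoint(set(g[test]))

    def test_record_level_folds_may_split_subjects(self):
        table = make_table(n_subjects=20)
        y = table["group"].to_numpy()
        g = table["subject_id"].to_numpy()
        folds = make_folds(y, g, CVSpec(n_folds=5, grouped=False, seed=1))
        split = any(
            not set(g[train]).isdisjoint(set(g[test])) for train, test in folds
        )
        assert split

    def test_every_sample_tested_exactly_once(self):
        table = make_table(n_subjects=20)
        folds = make_folds(
            table["group"].to_numpy(),
            table["subject_id"].to_numpy(),
            CVSpec(n_folds=5, seed=0),
        )
        tested = np.concatenate([test for _, test in folds])
        assert sorted(tested) == list(range(len(table)))

    def test_perfectly_separated_cohort_reaches_100(self):
        table = make_table(n_subjects=20, effect=10.0)
        res = cross_validate(
            make_model("GLM"), table, ("ABP-0",), CVSpec(n_folds=5, seed=0)
        )
        assert res.metrics.accuracy == 100.0
        assert res.metrics.classification_error == 0.0
        assert res.auc == 1.0

    def test_deterministic_given_seed(self):
        table = make_table(n_subjects=16, effect=0.5)
        kwargs = dict(cv_spec=CVSpec(n_folds=4, seed=3))
        r1 = cross_validate(make_model("GLM"), table, ("ABP-0", "FD"), **kwargs)
        r2 = cross_validate(make_model("GLM"), table, ("ABP-0", "FD"), **kwargs)
        assert r1.metrics == r2.metrics
        assert r1.auc == r2.auc

    def test_holdout_mode_single_split(self):
        table = make_table(n_subjects=20, effect=10.0)
        res = cross_validate(
            make_model("LR"),
            table,
            ("ABP-0",),
            CVSpec(mode="holdout", grouped=False, train_fraction=0.7, seed=0),
        )
        assert res.confusion.total == pytest.approx(0.3 * len(table), abs=2)
        assert res.metrics.accuracy == 100.0

    def test_unknown_feature_rejected(self):
        table = make_table(n_subjects=8)
        with pytest.raises(ValueError, match="unknown feature"):
            cross_validate(make_model("GLM"), table, ("NotAFeature",))

    def test_missing_class_in_training_fold_raises(self):
        table = make_table(n_subjects=4, records_per_subject=1)
        # one fold per record: some training splits lose a class
        bad = table[table.group == "ADHD"]
        with pytest.raises(ValueError):
            cross_validate(
                make_model("GLM"),
                bad,
                ("ABP-0",),
                CVSpec(n_folds=2, grouped=False, seed=0),
            )
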