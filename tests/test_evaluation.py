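import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from tapcrnn.evaluation import (
    ConfusionCounts,
    MetricReport,
    auc_trapezoid,
    confusion_from_predictions,
    kfold_split,
    roc_points,
    split_train_test,
)


def make_manifest(n_murmur: int, n_normal: int, clips_per_subject: int = 10) -> pd.DataFrame:
    rows = []
    for label, n, tag in (("murmur", n_murmur, "m"), ("normal", n_normal, "n")):
        for i in range(n):
            for k in range(clips_per_subject):
                rows.append(
                    {
                        "path": f"{tag}{i}_{k}.wav",
                        "subject_id": f"{tag}{i}",
                        "site": "erb",
                        "label": label,
                    }
                )
    return pd.DataFrame(rows)


class TestMetricArithmetic:
    def test_perfect_classifier(self):
        r = MetricReport.from_counts(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (r.accuracy, r.sensitivity, r.specificity, r.ppv, r.npv) == (
            100.0,
            100.0,
            100.0,
            100.0,
            100.0,
        )

    def test_published_style_test_composition(self):
        """Counts reconstructed from a 178-murmur / 60-normal test set
        reproduce the corresponding percentage table row."""
        r = MetricReport.from_counts(ConfusionCounts(tp=172, tn=59, fp=1, fn=6))
        assert round(r.sensitivity, 1) == 96.6
        assert round(r.specificity, 1) == 98.3
        assert round(r.accuracy, 1) == 97.1
        assert round(r.ppv, 1) == 99.4

    def test_undefined_metric_is_none_not_zero(self):
        r = MetricReport.from_counts(ConfusionCounts(tp=5, tn=0, fp=0, fn=1))
        assert r.specificity is None
        assert r.npv == 0.0

    def test_identities_against_recount(self, rng):
        """Metric identities on 100 random label/prediction vectors,
        recounted by brute force."""
        for _ in range(100):
            n = int(rng.integers(2, 40))
            y = rng.choice(["murmur", "normal"], size=n)
            p = rng.choice(["murmur", "normal"], size=n)
            c = confusion_from_predictions(y, p)
            assert c.total == n
            tp = sum(1 for a, b in zip(y, p) if a == b == "murmur")
            tn = sum(1 for a, b in zip(y, p) if a == b == "normal")
            assert (c.tp, c.tn) == (tp, tn)
            r = MetricReport.from_counts(c)
            if r.accuracy is not None:
                assert r.accuracy * c.total / 100 == pytest.approx(tp + tn)
            # sensitivity depends only on (tp, fn); specificity on (tn, fp)
            if c.tp + c.fn:
                assert r.sensitivity == pytest.approx(100 * c.tp / (c.tp + c.fn))
            if c.tn + c.fp:
                assert r.specificity == pytest.approx(100 * c.tn / (c.tn + c.fp))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        y = np.array(["murmur", "murmur", "normal", "normal"])
        s = np.array([0.9, 0.8, 0.1, 0.2])
        assert auc_trapezoid(roc_points(y, s)) == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        y = np.array(["murmur", "normal", "murmur", "normal"])
        s = np.full(4, 0.5)
        assert auc_trapezoid(roc_points(y, s)) == pytest.approx(0.5)

    def test_monotone_points_and_range(self, rng):
        y = rng.choice(["murmur", "normal"], size=50)
        y[:2] = ["murmur", "normal"]
        s = rng.random(50)
        roc = roc_points(y, s)
        assert (np.diff(roc["fpr"]) >= -1e-12).all()
        assert (np.diff(roc["tpr"]) >= -1e-12).all()
        assert 0.0 <= auc_trapezoid(roc) <= 1.0

    def test_matches_sklearn(self, rng):
        """Hand-rolled sweep and trapezoid AUC agree with scikit-learn."""
        for _ in range(10):
            y = rng.choice(["murmur", "normal"], size=30)
            y[:2] = ["murmur", "normal"]
            s = rng.random(30)
            ours = auc_trapezoid(roc_points(y, s))
            fpr, tpr, _ = sk_roc_curve(y == "murmur", s)
            assert ours == pytest.approx(sk_auc(fpr, tpr), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(np.array(["murmur", "murmur"]), np.array([0.5, 0.6]))


class TestSplitTrainTest:
    def test_subject_exclusive(self):
        manifest = make_manifest(7, 5)
        plan = split_train_test(manifest, 0.7, seed=3)
        assert not plan.train_subjects & plan.test_subjects
        assert plan.train_subjects | plan.test_subjects == set(manifest["subject_id"])

    def test_clip_fraction_near_target(self):
        manifest = make_manifest(10, 10)
        plan = split_train_test(manifest, 0.7, seed=0)
        frac = manifest["subject_id"].isin(plan.train_subjects).mean()
        assert abs(frac - 0.7) <= 0.05

    def test_deterministic(self):
        manifest = make_manifest(6, 6)
        a = split_train_test(manifest, 0.7, seed=5)
        b = split_train_test(manifest, 0.7, seed=5)
        assert a.train_subjects == b.train_subjects

    def test_single_subject_class_rejected(self):
        manifest = make_manifest(1, 5)
        with pytest.raises(ValueError, match="murmur"):
            split_train_test(manifest, 0.7, seed=0)


class TestKFold:
    def test_fourfold_balance_on_51_25(self):
        """51 murmur + 25 normal subjects, K=4: per-fold murmur counts in
        {12, 13} and normal counts in {6, 7}, disjoint, full coverage."""
        manifest = make_manifest(51, 25, clips_per_subject=2)
        plan = kfold_split(manifest, 4, seed=1)
        assert len(plan.folds) == 4
        murmur = {s for s in manifest[manifest.label == "murmur"]["subject_id"]}
        normal = {s for s in manifest[manifest.label == "normal"]["subject_id"]}
        all_assigned = set()
        for fold in plan.folds:
            assert len(fold & murmur) in (12, 13)
            assert len(fold & normal) in (6, 7)
            assert not all_assigned & fold
            all_assigned |= fold
        assert all_assigned == murmur | normal

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(make_manifest(4, 4), 1, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="fewer than K"):
            kfold_split(make_manifest(3, 8), 4, seed=0)
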