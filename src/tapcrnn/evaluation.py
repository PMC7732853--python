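"""Subject-exclusive splitting, training drivers, and evaluation metrics.

The murmur class is the positive class throughout:

* accuracy    = (Tp + Tn) / (Tp + Tn + Fp + Fn)
* sensitivity = Tp / (Tp + Fn)         (murmur recall)
* specificity = Tn / (Fp + Tn)         (normal recall)
* PPV         = Tp / (Tp + Fp)
* NPV         = Tn / (Fn + Tn)

Metrics are reported as percentages to one decimal place, the ROC is a
sweep over the murmur posterior, and AUC is the trapezoid rule over the
sorted ROC points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Spectrogram, standardize, stft_logpower
from .models import _SequenceClassifier, make_classifier
from .synth import SITES, PCGClip


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


@dataclass
class MetricReport:
    """Accuracy/sensitivity/specificity/PPV/NPV in percent, plus AUC.

    A metric whose denominator is empty (e.g. specificity at a site with
    no normal clips) is ``None``, not zero.
    """

    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auc: float | None = None
    per_site: dict[str, "MetricReport"] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, auc: float | None = None) -> "MetricReport":
        return cls(
            counts=counts,
            accuracy=_pct(counts.tp + counts.tn, counts.total),
            sensitivity=_pct(counts.tp, counts.tp + counts.fn),
            specificity=_pct(counts.tn, counts.fp + counts.tn),
            ppv=_pct(counts.tp, counts.tp + counts.fp),
            npv=_pct(counts.tn, counts.fn + counts.tn),
            auc=auc,
        )

    def as_row(self) -> dict[str, float | None]:
        row = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }
        return {
            k: (round(v, 1) if v is not None else None) for k, v in row.items()
        } | {"auc": round(self.auc, 3) if self.auc is not None else None}


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = "murmur"
) -> ConfusionCounts:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def roc_points(
    y_true: np.ndarray, scores: np.ndarray, positive: str = "murmur"
) -> pd.DataFrame:
    """Threshold sweep over the positive-class score.

    Returns a DataFrame (threshold, fpr, tpr) with one row per distinct
    score plus the two trivial endpoints, sorted from the strictest to
    the most permissive threshold.
    """
    y = np.asarray(y_true) == positive
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the evaluated set")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    rows = [(np.inf, 0.0, 0.0)] + [
        (s_sorted[i], fps[i] / n_neg, tps[i] / n_pos) for i in distinct
    ]
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def auc_trapezoid(roc: pd.DataFrame) -> float:
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


# ---------------------------------------------------------------------------
# Subject-exclusive splits


@dataclass
class SplitPlan:
    """Subject-id sets for either a train/test split or K folds."""

    train_subjects: set[str] = field(default_factory=set)
    test_subjects: set[str] = field(default_factory=set)
    folds: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subjects overlap")
        for i, a in enumerate(self.folds):
            for b in self.folds[i + 1 :]:
                if a & b:
                    raise ValueError("folds overlap")


def _subjects_by_class(manifest: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for label, grp in manifest.groupby("label"):
        out[str(label)] = sorted(grp["subject_id"].unique())
    return out


def split_train_test(
    manifest: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Split at the subject level, stratified by class.

    Subjects of each class are shuffled and assigned so that the train
    side holds ``round(train_fraction * n_subjects)`` subjects per class;
    with roughly equal clips per subject the realized clip fraction stays
    within a few points of the target.
    """
    rng = np.random.default_rng(seed)
    train, test = set(), set()
    for label, subjects in _subjects_by_class(manifest).items():
        if len(subjects) < 2:
            raise ValueError(
                f"class {label!r} has {len(subjects)} subject(s); "
                "subject-exclusive splitting needs at least 2"
            )
        order = rng.permutation(subjects)
        k = int(round(train_fraction * len(subjects)))
        k = min(max(k, 1), len(subjects) - 1)
        train.update(order[:k])
        test.update(order[k:])
    return SplitPlan(train_subjects=train, test_subjects=test)


def kfold_split(manifest: pd.DataFrame, k: int = 4, seed: int = 0) -> SplitPlan:
    """K subject-exclusive folds with per-class counts differing by <= 1."""
    if k < 2:
        raise ValueError("K-fold cross-validation requires K >= 2")
    rng = np.random.default_rng(seed)
    folds: list[set[str]] = [set() for _ in range(k)]
    for label, subjects in _subjects_by_class(manifest).items():
        if len(subjects) < k:
            raise ValueError(
                f"class {label!r} has {len(subjects)} subjects, fewer than K={k}"
            )
        order = rng.permutation(subjects)
        for part, fold in zip(np.array_split(order, k), folds):
            fold.update(part)
    return SplitPlan(folds=folds)


# ---------------------------------------------------------------------------
# Feature pipeline + training/evaluation drivers


@dataclass(frozen=True)
class FeatureConfig:
    frame_length: int = 512
    frame_shift: int = 256
    log_floor: float = 1e-10
    window: str = "hann"
    standardize: bool = True


def featurize(clip: PCGClip, feat: FeatureConfig = FeatureConfig()) -> Spectrogram:
    spec = stft_logpower(
        clip,
        frame_length=feat.frame_length,
        frame_shift=feat.frame_shift,
        log_floor=feat.log_floor,
        window=feat.window,
    )
    return standardize(spec) if feat.standardize else spec


def featurize_all(
    clips: list[PCGClip], feat: FeatureConfig = FeatureConfig()
) -> list[np.ndarray]:
    return [featurize(c, feat).frames for c in clips]


def train_model(
    clips: list[PCGClip],
    architecture: str = "tap_crnn",
    feat: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    **estimator_kwargs,
) -> _SequenceClassifier:
    """Featurize clips and fit a classifier of the requested architecture."""
    labels = np.array([c.label for c in clips])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    est = make_classifier(architecture, random_state=seed, **estimator_kwargs)
    groups = np.array([c.subject_id for c in clips])
    est.fit(featurize_all(clips, feat), labels, groups=groups)
    return est


def evaluate(
    model: _SequenceClassifier,
    clips: list[PCGClip],
    feat: FeatureConfig = FeatureConfig(),
) -> tuple[ConfusionCounts, MetricReport, pd.DataFrame]:
    """Confusion counts, metric report with per-site breakdown, ROC points."""
    if not clips:
        raise ValueError("test set is empty")
    X = featurize_all(clips, feat)
    y = np.array([c.label for c in clips])
    pred = model.predict(X)
    scores = model.murmur_score(X)
    counts = confusion_from_predictions(y, pred)
    both = len(np.unique(y)) == 2
    roc = roc_points(y, scores) if both else None
    report = MetricReport.from_counts(
        counts, auc=auc_trapezoid(roc) if both else None
    )
    sites = np.array([c.site for c in clips])
    for site in SITES:
        m = sites == site
        if not m.any():
            continue
        sc = confusion_from_predictions(y[m], pred[m])
        s_auc = None
        if len(np.unique(y[m])) == 2:
            s_auc = auc_trapezoid(roc_points(y[m], scores[m]))
        report.per_site[site] = MetricReport.from_counts(sc, auc=s_auc)
    return counts, report, roc if both else pd.DataFrame(columns=["threshold", "fpr", "tpr"])


def _select(clips: list[PCGClip], subjects: set[str]) -> list[PCGClip]:
    return [c for c in clips if c.subject_id in subjects]


def run_protocol(
    clips: list[PCGClip],
    manifest: pd.DataFrame,
    protocol: str = "split",
    architectures: tuple[str, ...] = ("cnn", "crnn", "tap_crnn"),
    train_fraction: float = 0.7,
    k: int = 4,
    feat: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    **estimator_kwargs,
) -> dict[str, pd.DataFrame]:
    """Run a train/test split or K-fold protocol end to end.

    Returns a dict of report tables: ``"metrics"`` (rows = architecture,
    or fold + average), ``"per_site"`` and ``"roc"`` where applicable.
    """
    if protocol == "split":
        plan = split_train_test(manifest, train_fraction, seed)
        train = _select(clips, plan.train_subjects)
        test = _select(clips, plan.test_subjects)
        rows, site_rows, roc_frames = [], [], []
        for arch in architectures:
            model = train_model(train, arch, feat, seed=seed, **estimator_kwargs)
            _, report, roc = evaluate(model, test, feat)
            rows.append({"model": arch} | report.as_row())
            for site, sr in report.per_site.items():
                site_rows.append({"model": arch, "site": site} | sr.as_row())
            roc = roc.copy()
            roc.insert(0, "model", arch)
            roc_frames.append(roc)
        return {
            "metrics": pd.DataFrame(rows),
            "per_site": pd.DataFrame(site_rows),
            "roc": pd.concat(roc_frames, ignore_index=True),
        }
    if protocol == "kfold":
        plan = kfold_split(manifest, k, seed)
        tables = {}
        for arch in architectures:
            rows = []
            for i, fold in enumerate(plan.folds):
                train = [c for c in clips if c.subject_id not in fold]
                test = _select(clips, fold)
                model = train_model(train, arch, feat, seed=seed + i, **estimator_kwargs)
                _, report, _ = evaluate(model, test, feat)
                rows.append({"fold": f"fold{i + 1}"} | report.as_row())
            table = pd.DataFrame(rows)
            avg = {
                "fold": "average",
                **{
                    c: round(table[c].astype(float).mean(), 2)
                    for c in table.columns
                    if c != "fold"
                },
            }
            tables[arch] = pd.concat(
                [table, pd.DataFrame([avg])], ignore_index=True
            )
        return tables
    raise ValueError(f"unknown protocol {protocol!r}")
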