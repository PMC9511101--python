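"""Classifier harness, stratified cross-validation and evaluation metrics.

Metrics follow the standard confusion-matrix definitions with the
positive class = sucrose transporter:

    SN  = TP / (TP + FN)                     (sensitivity / recall)
    SP  = TN / (TN + FP)                     (specificity)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    PR  = TP / (TP + FP)                     (precision)
    F   = 2 * SN * PR / (SN + PR)

Cross-validation pools confusion counts over folds and computes the
metrics once on the pooled counts (the convention of WEKA-style
toolchains), rather than averaging per-fold metrics. Class rebalancing
can be placed inside each training fold (``per_fold``, leak-safe
default), applied globally before folding (``global_before_cv``, the
protocol of WEKA-era transporter studies, which leaks synthetic
neighbours into test folds and is labeled as such in reports), or
skipped (``none``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .balancing import borderline_smote, is_synthetic_id
from .containers import LabeledFeatureMatrix

logger = logging.getLogger(__name__)

CLASSIFIERS = ("rf", "svm", "nb", "sgd")
BALANCING_MODES = ("none", "global_before_cv", "per_fold")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary confusion counts (positive class = transporter)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass
class EvaluationReport:
    """Metrics, ROC and provenance of one evaluation run."""

    counts: ConfusionCounts
    SN: float
    SP: float
    ACC: float
    MCC: float
    precision: float
    F_measure: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    degenerate_denominators: list[str] = field(default_factory=list)
    config_fingerprint: str = ""

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Evaluation report",
            f"  counts : TP={c.TP} TN={c.TN} FP={c.FP} FN={c.FN} (n={c.total})",
            f"  SN     : {self.SN:.3f}",
            f"  SP     : {self.SP:.3f}",
            f"  ACC    : {self.ACC:.3f}",
            f"  MCC    : {self.MCC:.3f}",
            f"  PR     : {self.precision:.3f}",
            f"  F      : {self.F_measure:.3f}",
        ]
        if not math.isnan(self.auc):
            lines.append(f"  AUC    : {self.auc:.3f}")
        if self.degenerate_denominators:
            lines.append(f"  flags  : zero denominator in "
                         f"{','.join(self.degenerate_denominators)}")
        if self.config_fingerprint:
            lines.append(f"  config : {self.config_fingerprint}")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "counts": asdict(self.counts),
            "SN": self.SN, "SP": self.SP, "ACC": self.ACC,
            "MCC": self.MCC, "precision": self.precision,
            "F_measure": self.F_measure,
            "roc_points": [list(p) for p in self.roc_points],
            "auc": None if math.isnan(self.auc) else self.auc,
            "degenerate_denominators": self.degenerate_denominators,
            "config_fingerprint": self.config_fingerprint,
        }


@dataclass
class CvConfig:
    """Cross-validation configuration."""

    folds: int = 10
    seed: int = 0
    classifier: str = "rf"
    classifier_params: dict[str, Any] = field(default_factory=dict)
    balancing: str = "per_fold"
    balancing_k: int = 5

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}; "
                             f"choose from {CLASSIFIERS}")
        if self.balancing not in BALANCING_MODES:
            raise ValueError(f"unknown balancing mode {self.balancing!r}")

    def fingerprint(self, extra: dict[str, Any] | None = None) -> str:
        payload = {**asdict(self), **(extra or {})}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        return f"{self.classifier}/{self.balancing}/folds={self.folds}/" \
               f"seed={self.seed}/{digest}"


def make_classifier(name: str, seed: int, params: dict[str, Any] | None = None):
    """Instantiate one of the four supported learners.

    rf: 100-tree random forest; svm: linear-kernel SVC (SMO-style
    margin learner); nb: Gaussian naive Bayes; sgd: hinge-loss linear
    model trained by stochastic gradient descent.
    """
    params = dict(params or {})
    if name == "rf":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if name == "svm":
        params.setdefault("kernel", "linear")
        return SVC(random_state=seed, **params)
    if name == "nb":
        return GaussianNB(**params)
    if name == "sgd":
        params.setdefault("loss", "hinge")
        return SGDClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous decision scores: vote fraction for forests,
    decision function for margin models."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, list(model.classes_).index(1)]
    return model.decision_function(X)


def compute_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Derive SN/SP/ACC/MCC/precision/F from pooled confusion counts.

    A metric whose denominator is zero is reported as 0 and its name
    recorded in ``degenerate_denominators``.
    """
    if counts.total == 0:
        raise ValueError("no samples evaluated (all counts zero)")
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    flags: list[str] = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sn = _ratio(TP, TP + FN, "SN")
    sp = _ratio(TN, TN + FP, "SP")
    acc = (TP + TN) / counts.total
    pr = _ratio(TP, TP + FP, "PR")
    mcc_den = math.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    if mcc_den == 0:
        flags.append("MCC")
        mcc = 0.0
    else:
        mcc = (TP * TN - FP * FN) / mcc_den
    f = _ratio(2 * sn * pr, sn + pr, "F")
    return EvaluationReport(counts, sn, sp, acc, mcc, pr, f,
                            degenerate_denominators=flags)


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Assign each sample to one of ``folds`` folds, preserving class
    proportions to within one sample per fold. Deterministic per seed.
    """
    y = np.asarray(y)
    assignment = np.empty(len(y), dtype=int)
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise ValueError(f"class {cls} has {len(idx)} samples, "
                             f"fewer than {folds} folds")
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def stratified_split(
    data: LabeledFeatureMatrix, test_frac: float, seed: int
) -> tuple[LabeledFeatureMatrix, LabeledFeatureMatrix]:
    """Stratified train/test split; per-class test size is
    floor(n_class * test_frac)."""
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in np.unique(data.y):
        idx = rng.permutation(np.flatnonzero(data.y == cls))
        n_test = int(len(idx) * test_frac)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (data.subset(np.sort(np.concatenate(train_idx))),
            data.subset(np.sort(np.concatenate(test_idx))))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _roc(y_true: np.ndarray, scores: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    fpr, tpr, _ = roc_curve(y_true, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def run_cv(data: LabeledFeatureMatrix, cfg: CvConfig) -> EvaluationReport:
    """Stratified k-fold cross-validation with configurable balancing
    placement; confusion counts pooled over folds, ROC from pooled
    decision scores.
    """
    working = data
    if cfg.balancing == "global_before_cv":
        working, _ = borderline_smote(data, k=cfg.balancing_k, seed=cfg.seed)

    assignment = stratified_folds(working.y, cfg.folds, cfg.seed)
    counts = ConfusionCounts(0, 0, 0, 0)
    pooled_scores = np.empty(working.n_samples)
    for fold in range(cfg.folds):
        test_mask = assignment == fold
        train = working.subset(np.flatnonzero(~test_mask))
        test = working.subset(np.flatnonzero(test_mask))
        if cfg.balancing == "per_fold":
            train, _ = borderline_smote(train, k=cfg.balancing_k, seed=cfg.seed + fold)
            assert not any(is_synthetic_id(i) for i in test.ids)
        model = make_classifier(cfg.classifier, cfg.seed, cfg.classifier_params)
        model.fit(train.X, train.y)
        pred = model.predict(test.X)
        counts = counts + _confusion(test.y, pred)
        pooled_scores[test_mask] = _scores(model, test.X)
        logger.info("fold %d/%d: n_train=%d n_test=%d", fold + 1, cfg.folds,
                    train.n_samples, test.n_samples)

    report = compute_metrics(counts)
    report.roc_points, report.auc = _roc(working.y, pooled_scores)
    report.config_fingerprint = cfg.fingerprint({"n": data.n_samples,
                                                 "d": data.n_features})
    return report


def train_final(
    data: LabeledFeatureMatrix,
    cfg: CvConfig,
    test_frac: float = 0.2,
) -> tuple[Any, EvaluationReport]:
    """Train on a stratified (1 - test_frac) split — optionally balanced
    — and evaluate on the untouched holdout. Returns the fitted model
    (with schema and fingerprint attached) and the holdout report.
    """
    train, test = stratified_split(data, test_frac, cfg.seed)
    if cfg.balancing != "none":
        train, _ = borderline_smote(train, k=cfg.balancing_k, seed=cfg.seed)
    model = make_classifier(cfg.classifier, cfg.seed, cfg.classifier_params)
    model.fit(train.X, train.y)
    pred = model.predict(test.X)
    report = compute_metrics(_confusion(test.y, pred))
    report.roc_points, report.auc = _roc(test.y, _scores(model, test.X))
    report.config_fingerprint = cfg.fingerprint(
        {"n": data.n_samples, "d": data.n_features, "test_frac": test_frac})
    model.feature_schema_ = list(data.schema)
    model.config_fingerprint_ = report.config_fingerprint
    return model, report
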