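"""Rhythm-label merging, splitting, classification metrics and a pluggable
cross-validated evaluation harness.

The database distinguishes 11 rhythm labels; rare ones are hierarchically
merged into four groups for classification:

    SB -> SB;  AFIB, AF -> AFIB;  SVT, AT, SAAWR, ST, AVNRT, AVRT -> GSVT;
    SR, SI -> SR.

Evaluation follows the standard one-vs-rest multiclass conventions:

    Precision = TP / (TP + FP),  Recall = TP / (TP + FN),
    F1 = 2 * Precision * Recall / (Precision + Recall),

with macro (unweighted class mean), micro (pooled counts) and weighted
(support-weighted) averages.  For single-label multiclass problems the
micro-averaged precision, recall and F1 all equal the overall accuracy.

"k-fold cross-validation with 20% testing data" is realized as a stratified
80/20 split followed by stratified k-fold CV inside the training portion;
both the CV fold means and the held-out-test metrics are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .io import DiagnosticsRow

logger = logging.getLogger(__name__)

RHYTHM_ACRONYMS = (
    "SB", "SR", "AFIB", "ST", "AF", "SI", "SVT", "AT", "AVNRT", "AVRT", "SAAWR",
)

GROUPS = ("SB", "AFIB", "GSVT", "SR")

#: 11 -> 4 merge map.
DEFAULT_GROUP_MAP: dict[str, str] = {
    "SB": "SB",
    "AFIB": "AFIB", "AF": "AFIB",
    "SVT": "GSVT", "AT": "GSVT", "SAAWR": "GSVT", "ST": "GSVT",
    "AVNRT": "GSVT", "AVRT": "GSVT",
    "SR": "SR", "SI": "SR",
}


class LabelError(ValueError):
    """Unknown rhythm acronym or group label."""


def merge_rhythm(label: str, group_map: Mapping[str, str] = DEFAULT_GROUP_MAP) -> str:
    """Map one rhythm acronym to its merged group."""
    key = label.strip().upper()
    try:
        return group_map[key]
    except KeyError:
        raise LabelError(
            f"unknown rhythm {label!r}; valid acronyms: {sorted(group_map)}"
        ) from None


def group_counts(diagnostics: Sequence[DiagnosticsRow],
                 group_map: Mapping[str, str] = DEFAULT_GROUP_MAP) -> dict[str, int]:
    """Record counts per merged group (a partition of the input)."""
    counts = {g: 0 for g in dict.fromkeys(group_map.values())}
    for row in diagnostics:
        counts[merge_rhythm(row.Rhythm, group_map)] += 1
    return counts


def split_train_test(labels: Sequence[str], train_frac: float = 0.8,
                     seed: int = 0, stratified: bool = True
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded, stratified train/test split.

    Per-group train size is ``round(train_frac * group size)`` to the
    nearest integer, the remainder is test.  Groups with fewer than two
    members cannot be stratified and are kept whole in the training set
    (with a logged warning).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    group_names = (pd.unique(labels) if stratified else np.array(["all"], dtype=object))
    for g in group_names:
        idx = np.flatnonzero(labels == g) if stratified else np.arange(labels.size)
        if stratified and idx.size < 2:
            logger.warning("group %r has %d member(s); kept whole in train", g, idx.size)
            train_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_frac * idx.size + 0.5))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], dtype=int)
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    return train.astype(int), test.astype(int)


def confusion_matrix(truth: Sequence[str], predicted: Sequence[str],
                     classes: Sequence[str]) -> np.ndarray:
    """Counts matrix with rows = truth, columns = predicted."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted differ in length")
    pos = {c: k for k, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in pos or p not in pos:
            raise LabelError(f"label outside class order: truth={t!r} pred={p!r}")
        m[pos[t], pos[p]] += 1
    return m


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2 * Precision * Recall / (Precision + Recall); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(confusion: np.ndarray, classes: Sequence[str]) -> pd.DataFrame:
    """Per-class one-vs-rest metrics plus macro/micro/weighted averages.

    Returns a DataFrame indexed by class name and the three average rows,
    with columns F1-score / Precision / Recall / Support.  Zero-denominator
    cases yield 0 with a logged note.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(classes):
        raise ValueError("confusion matrix must be square and match the class order")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    support = m.sum(axis=1)

    def _safe(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if not ok.all():
            logger.info("%s undefined (zero denominator) for class(es) %s; reported as 0",
                        what, [c for c, o in zip(classes, ok) if not o])
        return out

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = np.array([f1_from_precision_recall(p, r) for p, r in zip(precision, recall)])

    total = m.sum()
    micro = (tp.sum() / total) if total > 0 else 0.0
    wsum = support.sum()
    weights = support / wsum if wsum > 0 else np.zeros_like(support)
    rows = {c: (f1[k], precision[k], recall[k], support[k]) for k, c in enumerate(classes)}
    rows["macro avg"] = (f1.mean(), precision.mean(), recall.mean(), wsum)
    rows["micro avg"] = (micro, micro, micro, wsum)
    rows["weighted avg"] = (
        float(weights @ f1), float(weights @ precision), float(weights @ recall), wsum)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["F1-score", "Precision", "Recall", "Support"])


def overall_accuracy(confusion: np.ndarray) -> float:
    m = np.asarray(confusion, dtype=float)
    total = m.sum()
    return float(np.trace(m) / total) if total > 0 else 0.0


class Learner(Protocol):
    """Anything with sklearn-style fit/predict."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


def default_learner(seed: int = 0) -> Learner:
    """Gradient-boosted tree classifier with fixed, modest hyperparameters."""
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=100, max_depth=6, learning_rate=0.3,
        tree_method="hist", random_state=seed, n_jobs=1, verbosity=0)


@dataclass
class EvalReport:
    """Cross-validated and held-out evaluation results."""

    classes: tuple[str, ...]
    cv_confusion: np.ndarray            # pooled over folds
    cv_metrics: pd.DataFrame            # from the pooled confusion matrix
    cv_fold_metrics: list[pd.DataFrame] # one table per fold
    cv_accuracy: float
    test_confusion: np.ndarray | None = None
    test_metrics: pd.DataFrame | None = None
    test_accuracy: float | None = None

    @property
    def fold_macro_f1(self) -> np.ndarray:
        return np.array([t.loc["macro avg", "F1-score"] for t in self.cv_fold_metrics])

    def summary(self) -> str:
        lines = ["Cross-validation (pooled over folds)",
                 self.cv_metrics.round(3).to_string(),
                 f"overall accuracy: {self.cv_accuracy:.3f}"]
        if self.test_metrics is not None:
            lines += ["", "Held-out test split",
                      self.test_metrics.round(3).to_string(),
                      f"overall accuracy: {self.test_accuracy:.3f}"]
        return "\n".join(lines)


def _encode_labels(y: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    pos = {c: k for k, c in enumerate(classes)}
    try:
        return np.array([pos[v] for v in y], dtype=int)
    except KeyError as exc:
        raise LabelError(f"label {exc.args[0]!r} outside class order") from None


def crossval_evaluate(
    X: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    learner_factory=None,
    k: int = 10,
    seed: int = 0,
    test_frac: float | None = 0.2,
) -> EvalReport:
    """Stratified k-fold CV (within the training portion) plus held-out test.

    ``learner_factory`` is a zero-argument callable returning a fresh
    fit/predict learner for every fold; the default is a gradient-boosted
    tree.  ``test_frac=None`` skips the held-out split and cross-validates
    the whole table.  NaN feature entries are imputed with the training-fold
    column means before fitting (tree learners tolerate NaN, arbitrary
    pluggable learners need not).
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
    y = np.asarray(list(groups), dtype=object)
    classes = tuple(dict.fromkeys(y))
    y_enc = _encode_labels(y, classes)
    if learner_factory is None:
        learner_factory = lambda: default_learner(seed)  # noqa: E731

    if test_frac is not None:
        train_idx, test_idx = split_train_test(y, 1.0 - test_frac, seed=seed)
    else:
        train_idx, test_idx = np.arange(y.size), np.array([], dtype=int)
    Xtr, ytr = X[train_idx], y_enc[train_idx]

    def _impute(train_block: np.ndarray, *blocks: np.ndarray) -> list[np.ndarray]:
        mean = np.nanmean(train_block, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        out = []
        for b in (train_block, *blocks):
            b = b.copy()
            nan = np.isnan(b)
            b[nan] = np.take(mean, np.nonzero(nan)[1])
            out.append(b)
        return out

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    fold_metrics: list[pd.DataFrame] = []
    for fold, (fit_i, val_i) in enumerate(skf.split(Xtr, ytr)):
        try:
            Xf, Xv = _impute(Xtr[fit_i], Xtr[val_i])
            model = learner_factory()
            model.fit(Xf, ytr[fit_i])
            pred = np.asarray(model.predict(Xv), dtype=int)
        except Exception as exc:
            raise RuntimeError(f"learner failed on fold {fold}: {exc}") from exc
        cm = confusion_matrix([classes[v] for v in ytr[val_i]],
                              [classes[v] for v in pred], classes)
        pooled += cm
        fold_metrics.append(precision_recall_f1(cm, classes))

    report = EvalReport(
        classes=classes,
        cv_confusion=pooled,
        cv_metrics=precision_recall_f1(pooled, classes),
        cv_fold_metrics=fold_metrics,
        cv_accuracy=overall_accuracy(pooled),
    )
    if test_idx.size:
        Xf, Xt = _impute(Xtr, X[test_idx])
        model = learner_factory()
        model.fit(Xf, ytr)
        pred = np.asarray(model.predict(Xt), dtype=int)
        cm = confusion_matrix([classes[v] for v in y_enc[test_idx]],
                              [classes[v] for v in pred], classes)
        report.test_confusion = cm
        report.test_metrics = precision_recall_f1(cm, classes)
        report.test_accuracy = overall_accuracy(cm)
    return report
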