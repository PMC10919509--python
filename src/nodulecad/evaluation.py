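"""Metrics and experiment harness.

Confusion-matrix metrics, ROC/AUC by threshold sweep, the train/test split
ladder, stratified k-fold cross-validation, and the paired with/without-LDA
ablation. Internally everything is a proportion in [0, 1]; the reporting
helpers format percentages to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from . import lda as lda_mod
from .classifiers import build_classifier
from .errors import UndefinedMetricError, ValidationError


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    split: str = ""
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    def percentages(self) -> dict[str, str]:
        """Table-style formatting: percentages to 2 decimals."""
        return {
            k: f"{getattr(self, k) * 100:.2f}"
            for k in ("accuracy", "sensitivity", "specificity")
        }


def confusion_metrics(y_true, y_pred, positive_label) -> dict[str, float]:
    """Accuracy, sensitivity (= recall), specificity, precision, F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    pos = y_true == positive_label
    if not pos.any():
        raise UndefinedMetricError(
            "sensitivity undefined: no positive samples in y_true"
        )
    if pos.all():
        raise UndefinedMetricError(
            "specificity undefined: no negative samples in y_true"
        )
    pred_pos = y_pred == positive_label
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "recall": sensitivity,
        "f1": f1,
    }


def roc_auc(y_true, scores, positive_label) -> tuple[list[tuple[float, float]], float]:
    """ROC by sweeping thresholds over the unique scores; AUC by trapezoid.

    Returns (points, auc) with points ordered from (0,0) to (1,1). With
    ties handled by the sweep, the trapezoid area equals the Mann-Whitney
    U statistic divided by n+ * n-.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    pos = y_true == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    # cumulative counts at each unique-score threshold boundary
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(p)[distinct]
    fps = np.cumsum(~p)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _fit_eval(model_spec, Xtr, ytr, Xte, yte, positive_label, split, seed) -> EvalReport:
    model = _make_model(model_spec)
    model.fit(Xtr, ytr)
    y_pred = model.predict(Xte)
    m = confusion_metrics(yte, y_pred, positive_label)
    roc, auc = [], None
    try:
        roc, auc = roc_auc(yte, np.asarray(model.scores(Xte), float), positive_label)
    except (ValidationError, AttributeError, NotImplementedError):
        pass
    return EvalReport(**m, roc=roc, auc=auc, split=split, seed=seed)


def _make_model(model_spec):
    if callable(model_spec):
        return model_spec()
    if isinstance(model_spec, str):
        return build_classifier(model_spec)
    kind, params = model_spec
    return build_classifier(kind, **params)


def split_ladder(
    X,
    y,
    ratios=((20, 80), (40, 60), (50, 50), (60, 40), (80, 20)),
    model_spec="svm",
    seed: int = 0,
    positive_label=None,
) -> list[EvalReport]:
    """Train/test ladder: one stratified split + evaluation per ratio."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if positive_label is None:
        positive_label = np.unique(y).max()
    reports = []
    for train_pct, test_pct in ratios:
        frac = train_pct / (train_pct + test_pct)
        classes, counts = np.unique(y, return_counts=True)
        if min(counts) * min(frac, 1 - frac) < 1:
            raise ValidationError(
                f"ratio {train_pct}/{test_pct} leaves a class empty"
            )
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=frac, stratify=y, random_state=seed
        )
        reports.append(
            _fit_eval(
                model_spec,
                Xtr,
                ytr,
                Xte,
                yte,
                positive_label,
                split=f"{train_pct}/{test_pct}",
                seed=seed,
            )
        )
    return reports


def kfold_cv(
    X, y, k: int = 5, model_spec="svm", seed: int = 0, positive_label=None
) -> dict:
    """k-fold cross-validation (stratified whenever k allows it).

    Per-fold accuracies are aggregated as mean/std; the confusion metrics
    are computed once on the pooled out-of-fold predictions so the result
    remains defined even for single-sample folds (leave-one-out, k = n).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(y):
        raise ValidationError("k must not exceed the sample count")
    if positive_label is None:
        positive_label = np.unique(y).max()
    _, counts = np.unique(y, return_counts=True)
    if k <= counts.min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    y_pred_oof = np.empty_like(y)
    folds = 0
    for tr, te in splitter.split(X, y):
        if np.unique(y[tr]).size < 2:
            raise ValidationError("a training fold lacks one of the classes")
        model = _make_model(model_spec)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        y_pred_oof[te] = pred
        fold_acc.append(float(np.mean(pred == y[te])))
        folds += 1
    pooled = confusion_metrics(y, y_pred_oof, positive_label)
    return {
        "n_folds": folds,
        "fold_sizes": [len(te) for _, te in splitter.split(X, y)],
        "accuracy": {
            "mean": float(np.mean(fold_acc)),
            "std": float(np.std(fold_acc)),
        },
        "pooled": pooled,
    }


def ablation_lda(
    X,
    y,
    model_spec="svm",
    seed: int = 0,
    test_size: float = 0.3,
    n_components: int | None = None,
    positive_label=None,
) -> dict:
    """Paired comparison: the same split evaluated with and without LDA."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if positive_label is None:
        positive_label = np.unique(y).max()
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_size, stratify=y, random_state=seed)
    without = _fit_eval(
        model_spec, X[tr], y[tr], X[te], y[te], positive_label, "no-lda", seed
    )
    proj = lda_mod.fit_lda(X[tr], y[tr], n_components=n_components)
    Ztr = lda_mod.transform(proj, X[tr])
    Zte = lda_mod.transform(proj, X[te])
    with_ = _fit_eval(
        model_spec, Ztr, y[tr], Zte, y[te], positive_label, "lda", seed
    )
    return {
        "with_lda": with_,
        "without_lda": without,
        "delta_accuracy": with_.accuracy - without.accuracy,
        "test_indices": te.tolist(),
    }
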