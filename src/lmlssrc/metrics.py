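"""Evaluation metrics, stratified cross-validation and grid search.

Six indicators are reported, all as percentages: accuracy, sensitivity,
specificity, precision, F1-score and G-mean.  For K > 2 classes,
sensitivity / specificity / precision / F1 are computed one-vs-rest per
class and macro-averaged — the only convention that keeps "specificity"
meaningful for multiclass — and the G-mean is
sqrt(macro_sensitivity * macro_specificity), which reduces to the standard
binary G-mean.

0/0 conventions (deterministic and conservative): a class absent from the
truth contributes sensitivity 0 unless it is also absent from the
predictions, in which case it is excluded from the macro averages; an
undefined precision (no predictions for the class) counts as 0 with a
warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import LargeMarginLocalSRC
from .solver import Hyperparameters, NumericalError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CVResult",
    "confusion_matrix",
    "compute_metrics",
    "evaluate_predictions",
    "stratified_kfold_evaluate",
    "grid_search",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "g_mean")


@dataclass(frozen=True)
class ConfusionCounts:
    """K x K counts; rows index the true class, columns the predicted."""

    matrix: np.ndarray
    class_ids: np.ndarray

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    g_mean: float
    per_class: dict
    n_samples: int

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {
            "n_samples": self.n_samples
        }

    def __str__(self) -> str:
        return "  ".join(f"{n}={getattr(self, n):.2f}" for n in METRIC_NAMES)


@dataclass
class CVResult:
    train_reports: list[MetricReport]
    test_reports: list[MetricReport]
    fold_assignment: np.ndarray
    seed: int
    mean: dict = field(init=False)
    std: dict = field(init=False)

    def __post_init__(self) -> None:
        self.mean, self.std = {}, {}
        for split, reports in (("train", self.train_reports),
                               ("test", self.test_reports)):
            for name in METRIC_NAMES:
                vals = np.array([getattr(r, name) for r in reports])
                self.mean[f"{split}_{name}"] = float(vals.mean())
                # sample standard deviation, as reported alongside means
                self.std[f"{split}_{name}"] = float(vals.std(ddof=1))


def confusion_matrix(true_labels, predicted_labels, class_ids=None) -> ConfusionCounts:
    """Count matrix[i, j] = #{samples of true class i predicted as class j}."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ValueError("empty label arrays")
    if t.shape != p.shape:
        raise ValueError("true and predicted labels differ in length")
    if class_ids is None:
        class_ids = np.unique(np.concatenate([t, p]))
    else:
        class_ids = np.asarray(class_ids)
        for arr, which in ((t, "true"), (p, "predicted")):
            unknown = np.setdiff1d(arr, class_ids)
            if unknown.size:
                raise ValueError(f"unknown {which} label(s): {unknown.tolist()}")
    lookup = {c: i for i, c in enumerate(class_ids.tolist())}
    K = class_ids.size
    cm = np.zeros((K, K), dtype=int)
    for ti, pi in zip(t.tolist(), p.tolist()):
        cm[lookup[ti], lookup[pi]] += 1
    return ConfusionCounts(matrix=cm, class_ids=class_ids)


def compute_metrics(cm: ConfusionCounts) -> MetricReport:
    """One-vs-rest metrics from a confusion matrix, macro-averaged, in %."""
    M = cm.matrix
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(M) / total

    per_class: dict = {}
    sens_list, spec_list, prec_list, f1_list = [], [], [], []
    for k, cid in enumerate(cm.class_ids.tolist()):
        tp = M[k, k]
        fn = M[k, :].sum() - tp
        fp = M[:, k].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            if fp == 0:
                # class absent from truth and predictions: excluded
                per_class[cid] = {"excluded": True}
                continue
            sens = 0.0
        else:
            sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        if tp + fp == 0:
            warnings.warn(
                f"precision undefined for class {cid!r} (no predictions); using 0",
                RuntimeWarning,
                stacklevel=2,
            )
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        per_class[cid] = {
            "sensitivity": 100 * sens,
            "specificity": 100 * spec,
            "precision": 100 * prec,
            "f1": 100 * f1,
        }
        sens_list.append(sens)
        spec_list.append(spec)
        prec_list.append(prec)
        f1_list.append(f1)

    macro_sens = float(np.mean(sens_list))
    macro_spec = float(np.mean(spec_list))
    return MetricReport(
        accuracy=100 * accuracy,
        sensitivity=100 * macro_sens,
        specificity=100 * macro_spec,
        precision=100 * float(np.mean(prec_list)),
        f1=100 * float(np.mean(f1_list)),
        g_mean=100 * float(np.sqrt(macro_sens * macro_spec)),
        per_class=per_class,
        n_samples=total,
    )


def evaluate_predictions(true_labels, predicted_labels, class_ids=None) -> MetricReport:
    return compute_metrics(confusion_matrix(true_labels, predicted_labels, class_ids))


def stratified_kfold_evaluate(
    X,
    labels,
    hp: Hyperparameters | None = None,
    n_folds: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> CVResult:
    """Seeded stratified k-fold CV; reports metrics on both splits per fold.

    ``X`` is (n_samples, n_features).  Raises if any class has fewer
    samples than ``n_folds``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    small = ids[counts < n_folds]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than {n_folds} samples"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    train_reports, test_reports = [], []
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        assignment[te] = fold
        model = LargeMarginLocalSRC(X[tr], labels[tr], hp=hp, **model_kwargs)
        res = model.fit()
        for idx, bucket in ((tr, train_reports), (te, test_reports)):
            pred = res.predict(X[idx])
            bucket.append(evaluate_predictions(labels[idx], pred.labels, ids))
    return CVResult(
        train_reports=train_reports,
        test_reports=test_reports,
        fold_assignment=assignment,
        seed=seed,
    )


DEFAULT_GRID = tuple(10.0**e for e in range(-3, 4))


def grid_search(
    X,
    labels,
    axes: dict[str, list[float]],
    base_hp: Hyperparameters | None = None,
    n_folds: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> tuple[Hyperparameters, list[dict]]:
    """Exhaustive CV search over the requested lambda axes.

    ``axes`` maps hyperparameter names (``lambda1``..``lambda5``) to value
    lists; unlisted parameters stay at their ``base_hp`` values.  Returns
    the best Hyperparameters (maximum mean test accuracy; earlier grid
    points win ties) and the full table of per-point CV summaries for
    sensitivity plots.
    """
    if not axes or any(len(v) == 0 for v in axes.values()):
        raise ValueError("grid axes must be non-empty")
    for name in axes:
        if name not in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            raise ValueError(f"unknown grid axis {name!r}")
    base = base_hp if base_hp is not None else Hyperparameters()
    names = list(axes)
    table: list[dict] = []
    best_hp, best_acc = None, -np.inf
    for values in itertools.product(*(axes[n] for n in names)):
        hp = Hyperparameters(**(base.to_dict() | dict(zip(names, values))))
        try:
            cv = stratified_kfold_evaluate(
                X, labels, hp=hp, n_folds=n_folds, seed=seed, **model_kwargs
            )
        except NumericalError as exc:
            # indefinite corner of the grid (margin weight overwhelming the
            # l2,1 regularisation): record and move on
            warnings.warn(f"grid point {dict(zip(names, values))} skipped: {exc}",
                          RuntimeWarning, stacklevel=2)
            table.append(dict(zip(names, values)) | {
                "mean_test_accuracy": float("nan"),
                "std_test_accuracy": float("nan"),
                "mean_train_accuracy": float("nan"),
            })
            continue
        row = dict(zip(names, values)) | {
            "mean_test_accuracy": cv.mean["test_accuracy"],
            "std_test_accuracy": cv.std["test_accuracy"],
            "mean_train_accuracy": cv.mean["train_accuracy"],
        }
        table.append(row)
        if cv.mean["test_accuracy"] > best_acc:
            best_acc = cv.mean["test_accuracy"]
            best_hp = hp
    return best_hp, table
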