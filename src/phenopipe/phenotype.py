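"""Downstream patient classification: cohort splits, classifier bank with
cross-validated hyperparameter selection, stacking ensemble, and the six
evaluation metrics.

The split protocol mirrors the study design: 80% of the positive patients
plus an equal number of undersampled negatives form a balanced training set;
the remaining positives appear in *both* test sets — once with an equal
number of unused negatives (balanced test) and once with enough additional
unused negatives to approximate a 30% positive prevalence (unbalanced test).
No negative patient is reused across sets.

Metrics: accuracy, precision, recall, F1, negative predictive value and
specificity, all from the confusion matrix; zero-denominator cases are
reported as undefined (None), never coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "SplitSpec",
    "CohortSplit",
    "ConfusionMatrix",
    "make_splits",
    "DEFAULT_MENU",
    "train_bank",
    "compute_metrics",
    "reconstruct_confusion",
    "check_metric_row_consistency",
    "evaluate",
    "render_report_tsv",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "npv", "specificity")


# ---------------------------------------------------------------------------
# Splits

@dataclass(frozen=True)
class SplitSpec:
    train_fraction_positives: float = 0.8
    unbalanced_prevalence: float = 0.30
    n_unbalanced_negatives: int | None = None  # explicit override
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction_positives < 1:
            raise ValueError("train_fraction_positives must lie in (0, 1)")
        if not 0 < self.unbalanced_prevalence < 1:
            raise ValueError("unbalanced_prevalence must lie in (0, 1)")


@dataclass
class CohortSplit:
    """Patient-id lists for the three sets; positives in both test sets are
    identical by design; negatives never repeat across sets."""

    train: list
    balanced_test: list
    unbalanced_test: list
    labels: dict


def make_splits(labels: dict, spec: SplitSpec = SplitSpec()) -> CohortSplit:
    """Apply the split protocol to ``{patient_id: bool_label}``.

    Training: floor(0.8 * n_pos) positives + as many undersampled negatives.
    Balanced test: remaining positives + an equal number of unused negatives.
    Unbalanced test: the same positives + round(n_test_pos * (1-p)/p) further
    unused negatives (or the explicit override).  Deterministic under seed.
    """
    rng = np.random.default_rng(spec.seed)
    pos = sorted(p for p, lab in labels.items() if lab)
    neg = sorted(p for p, lab in labels.items() if not lab)
    if len(pos) < 2:
        raise ValueError("need at least 2 positive patients")
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]

    n_train_pos = int(np.floor(spec.train_fraction_positives * len(pos)))
    train_pos, test_pos = pos[:n_train_pos], pos[n_train_pos:]
    p = spec.unbalanced_prevalence
    n_unbal_neg = (
        spec.n_unbalanced_negatives
        if spec.n_unbalanced_negatives is not None
        else int(round(len(test_pos) * (1 - p) / p))
    )
    needed = n_train_pos + len(test_pos) + n_unbal_neg
    if len(neg) < needed:
        raise ValueError(
            f"insufficient negative patients: need {needed}, have {len(neg)}"
        )
    train_neg = neg[:n_train_pos]
    bal_neg = neg[n_train_pos : n_train_pos + len(test_pos)]
    unbal_neg = neg[n_train_pos + len(test_pos) : needed]

    return CohortSplit(
        train=sorted(train_pos + train_neg),
        balanced_test=sorted(test_pos + bal_neg),
        unbalanced_test=sorted(test_pos + unbal_neg),
        labels=dict(labels),
    )


# ---------------------------------------------------------------------------
# Classifier bank

def _menu(seed: int) -> dict:
    """Model menu with small, versioned hyperparameter grids."""
    return {
        "Logistic Regression": (
            LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "SVM": (
            SVC(random_state=seed),
            {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
        ),
        "Decision Tree": (
            DecisionTreeClassifier(random_state=seed),
            {"max_depth": [2, 3, 5, None]},
        ),
        "Random Forest": (
            RandomForestClassifier(n_estimators=100, random_state=seed),
            {"max_depth": [3, 5, None]},
        ),
        "KNN": (
            KNeighborsClassifier(),
            {"n_neighbors": [3, 5, 7]},
        ),
        "XGBoost": (
            XGBClassifier(eval_metric="logloss", random_state=seed,
                          n_jobs=1, verbosity=0),
            {"n_estimators": [50, 100], "max_depth": [2, 3]},
        ),
        "AdaBoost": (
            AdaBoostClassifier(random_state=seed),
            {"n_estimators": [50, 100]},
        ),
    }


DEFAULT_MENU = tuple(_menu(0))


@dataclass
class FittedBank:
    models: dict  # name -> fitted estimator (includes "Stacking Classifier")
    chosen_params: dict = field(default_factory=dict)


def train_bank(
    X: np.ndarray,
    y: np.ndarray,
    menu=DEFAULT_MENU,
    cv_folds: int = 5,
    seed: int = 0,
) -> FittedBank:
    """Fit the classifier bank on patient vectors.

    Each model's hyperparameters are selected by stratified k-fold
    cross-validation on the training set only, then the model is refit on the
    full training set; a stacking ensemble (logistic-regression meta-learner
    over the tuned models) is added when the menu has >= 2 models.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv_folds:
        raise ValueError(
            f"stratified {cv_folds}-fold CV impossible: minority class has "
            f"{counts.min()} samples"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    full_menu = _menu(seed)
    unknown = set(menu) - set(full_menu)
    if unknown:
        raise ValueError(f"unknown models in menu: {sorted(unknown)}")

    fitted, chosen, tuned = {}, {}, []
    for name in menu:
        est, grid = full_menu[name]
        search = GridSearchCV(est, grid, cv=cv, scoring="accuracy", n_jobs=1)
        search.fit(X, y)
        fitted[name] = search.best_estimator_
        chosen[name] = dict(search.best_params_)
        tuned.append((name.lower().replace(" ", "_"), clone(search.best_estimator_)))

    if len(tuned) >= 2:
        stack = StackingClassifier(
            estimators=tuned,
            final_estimator=LogisticRegression(max_iter=2000, random_state=seed),
            cv=cv,
        )
        stack.fit(X, y)
        fitted["Stacking Classifier"] = stack
    else:
        warnings.warn("menu has fewer than 2 models; stacking skipped")
    return FittedBank(models=fitted, chosen_params=chosen)


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int((t & p).sum()),
            tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
        )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """The six evaluation metrics; zero-denominator cases are None."""
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
    }


def reconstruct_confusion(
    n_pos: int, n_neg: int, precision: float, recall: float
) -> ConfusionMatrix:
    """Recover integer TP/FP/FN/TN from printed precision/recall and the
    test-set class sizes (counts rounded to the nearest integer)."""
    tp = int(round(recall * n_pos))
    fn = n_pos - tp
    fp = int(round(tp / precision)) - tp if precision > 0 else n_neg
    tn = n_neg - fp
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def check_metric_row_consistency(
    n_pos: int, n_neg: int, reported: dict, places: int = 4
) -> dict:
    """Compare a reported metric row against recomputation from the confusion
    matrix implied by its own precision/recall; returns per-metric booleans.
    Useful for auditing published tables for internally inconsistent columns.
    """
    cm = reconstruct_confusion(n_pos, n_neg, reported["precision"],
                               reported["recall"])
    recomputed = compute_metrics(cm)
    out = {}
    # printed values are rounded to `places`; accept any value within half an
    # ulp of the print precision (covers half-up vs half-even conventions)
    tol = 0.5 * 10 ** -places + 1e-12
    for name in METRIC_NAMES:
        if name in reported and reported[name] is not None:
            out[name] = abs(recomputed[name] - reported[name]) <= tol
    return out


# ---------------------------------------------------------------------------
# Evaluation

def evaluate(
    bank: FittedBank, test_sets: dict, vectors: dict, labels: dict
) -> dict:
    """Evaluate every fitted model on every test set.

    ``test_sets`` maps a set name to a list of patient ids; ``vectors`` maps
    patient id to an 8-element vector.  Returns
    ``{set_name: {model_name: {"cm": ConfusionMatrix, "metrics": {...}}}}``.
    """
    report: dict = {}
    for set_name, pids in test_sets.items():
        X = np.array([vectors[p] for p in pids], dtype=np.float64)
        y = np.array([labels[p] for p in pids], dtype=int)
        per_model = {}
        for model_name, model in bank.models.items():
            pred = model.predict(X)
            cm = ConfusionMatrix.from_predictions(y, pred)
            per_model[model_name] = {"cm": cm, "metrics": compute_metrics(cm)}
        report[set_name] = per_model
    return report


def render_report_tsv(per_model: dict) -> str:
    """One evaluation table as TSV: model rows x six metric columns."""
    header = "Model\tAccuracy\tPrecision\tRecall\tF1\tNPV\tSpecificity"
    lines = [header]
    for model_name, entry in per_model.items():
        cells = [
            "undefined" if entry["metrics"][m] is None
            else f"{entry['metrics'][m]:.4f}"
            for m in METRIC_NAMES
        ]
        lines.append(model_name + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
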