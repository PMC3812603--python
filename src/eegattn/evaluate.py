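"""Evaluation protocol: stratified k-fold, AR/IR, ablation, grouping.

Model quality is summarised with class-conditional accuracies. With TA/TI
the number of truly attentive/inattentive test rows and CA/CI the number
of each predicted correctly,

    AR = CA/TA × 100 %   (attention rate — sensitivity for attentive)
    IR = CI/TI × 100 %   (inattention rate — sensitivity for inattentive)

and a prevalence-weighted overall accuracy AR·(1−p) + IR·p for an assumed
inattentive proportion p. Cross-validation is stratified k-fold (k = 5 by
default); AR/IR are pooled over the k test folds, and resubstitution
("training") accuracy is reported alongside to mirror the usual
training/k-fold report layout. The feature-ablation grid evaluates all
five features plus each leave-one-out subset, for both polynomial
kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_COLUMNS
from .io import ATTENTIVE, INATTENTIVE
from .kernels import KernelSpec
from .svm import AttentionSVC

logger = logging.getLogger(__name__)

#: the ablation grid: all five features, then each leave-one-out subset
ABLATION_SUBSETS: list[tuple[str, ...]] = [tuple(FEATURE_COLUMNS)] + [
    tuple(c for c in FEATURE_COLUMNS if c != dropped) for dropped in FEATURE_COLUMNS
]


@dataclass
class ConfusionCounts:
    """Attentive/inattentive tallies: totals (TA, TI) and correct (CA, CI)."""

    TA: int = 0
    TI: int = 0
    CA: int = 0
    CI: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.CA <= self.TA and 0 <= self.CI <= self.TI):
            raise ValueError(f"inconsistent counts {self}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            TA=self.TA + other.TA,
            TI=self.TI + other.TI,
            CA=self.CA + other.CA,
            CI=self.CI + other.CI,
        )

    @property
    def accuracy(self) -> float:
        """Overall percent correct across both classes."""
        total = self.TA + self.TI
        if total == 0:
            raise ZeroDivisionError("no test rows")
        return 100.0 * (self.CA + self.CI) / total


@dataclass
class EvaluationReport:
    """Per-fold and pooled results of one cross-validated configuration."""

    per_fold_accuracy: list[float]
    per_fold_counts: list[ConfusionCounts]
    per_fold_train_accuracy: list[float]
    pooled: ConfusionCounts
    resubstitution: ConfusionCounts
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def best_accuracy(self) -> float:
        return float(np.max(self.per_fold_accuracy))

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean(self.per_fold_train_accuracy))

    @property
    def best_train_accuracy(self) -> float:
        return float(np.max(self.per_fold_train_accuracy))

    @property
    def AR(self) -> float:
        return attention_rate(self.pooled)

    @property
    def IR(self) -> float:
        return inattention_rate(self.pooled)

    @property
    def pooled_accuracy_ci95(self) -> tuple[float, float]:
        """Normal-approximation 95% binomial CI on the pooled accuracy (%)."""
        n = self.pooled.TA + self.pooled.TI
        p = self.pooled.accuracy / 100.0
        half = 196.0 * np.sqrt(p * (1 - p) / n)
        return (max(0.0, 100 * p - half), min(100.0, 100 * p + half))

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": self.per_fold_accuracy,
            "per_fold_train_accuracy": self.per_fold_train_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "best_accuracy": self.best_accuracy,
            "mean_train_accuracy": self.mean_train_accuracy,
            "best_train_accuracy": self.best_train_accuracy,
            "AR": self.AR,
            "IR": self.IR,
            "pooled_accuracy_ci95": list(self.pooled_accuracy_ci95),
            "resubstitution_AR": attention_rate(self.resubstitution),
            "resubstitution_IR": inattention_rate(self.resubstitution),
            "config": self.config,
        }


def stratified_kfold(data: pd.DataFrame, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint, class-balanced test-index sets covering every row once."""
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    y = data["label"].to_numpy()
    smallest = pd.Series(y).value_counts().min()
    if k > smallest:
        raise ValueError(f"k={k} exceeds smallest class size {smallest}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


def confusion(pred, truth) -> ConfusionCounts:
    """Tally TA/TI/CA/CI from predicted and true labels."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    att = truth == ATTENTIVE
    inatt = truth == INATTENTIVE
    return ConfusionCounts(
        TA=int(att.sum()),
        TI=int(inatt.sum()),
        CA=int((att & (pred == truth)).sum()),
        CI=int((inatt & (pred == truth)).sum()),
    )


def attention_rate(c: ConfusionCounts) -> float:
    """AR = CA/TA × 100 %."""
    if c.TA == 0:
        raise ZeroDivisionError("attention rate undefined: no attentive rows")
    return 100.0 * c.CA / c.TA


def inattention_rate(c: ConfusionCounts) -> float:
    """IR = CI/TI × 100 %."""
    if c.TI == 0:
        raise ZeroDivisionError("inattention rate undefined: no inattentive rows")
    return 100.0 * c.CI / c.TI


def weighted_accuracy(AR: float, IR: float, p_inattentive: float) -> float:
    """Prevalence-weighted overall accuracy AR·(1−p) + IR·p."""
    if not 0 <= p_inattentive <= 1:
        raise ValueError(f"p_inattentive must lie in [0, 1], got {p_inattentive}")
    return AR * (1 - p_inattentive) + IR * p_inattentive


def evaluate(
    data: pd.DataFrame,
    spec: KernelSpec | None = None,
    C: float = 1.0,
    k: int = 5,
    seed: int = 0,
    features: tuple[str, ...] | list[str] | None = None,
    standardize: bool = True,
) -> EvaluationReport:
    """Stratified k-fold evaluation of one kernel/C/feature configuration.

    Per fold, a fresh SVM is trained on the other k−1 folds using only the
    named feature columns; fold accuracy, fold-training (resubstitution on
    the training folds) accuracy and pooled AR/IR are reported, plus
    full-data resubstitution counts.
    """
    features = tuple(FEATURE_COLUMNS) if features is None else tuple(features)
    if not features:
        raise ValueError("feature subset must be nonempty")
    unknown = set(features) - set(FEATURE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")

    X = data[list(features)].to_numpy()
    y = data["label"].to_numpy()

    def make_model() -> AttentionSVC:
        s = spec or KernelSpec()
        return AttentionSVC(
            kernel=s.kind, degree=s.degree, C=C, standardize=standardize
        )

    fold_acc: list[float] = []
    fold_train_acc: list[float] = []
    fold_counts: list[ConfusionCounts] = []
    for test_idx in stratified_kfold(data, k=k, seed=seed):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        model = make_model().fit(X[~mask], y[~mask])
        counts = confusion(model.predict(X[mask]), y[mask])
        fold_counts.append(counts)
        fold_acc.append(counts.accuracy)
        fold_train_acc.append(confusion(model.predict(X[~mask]), y[~mask]).accuracy)

    pooled = sum(fold_counts, ConfusionCounts())
    resub_model = make_model().fit(X, y)
    resub = confusion(resub_model.predict(X), y)
    s = spec or KernelSpec()
    return EvaluationReport(
        per_fold_accuracy=fold_acc,
        per_fold_counts=fold_counts,
        per_fold_train_accuracy=fold_train_acc,
        pooled=pooled,
        resubstitution=resub,
        config={
            "kernel": s.kind,
            "degree": s.degree,
            "C": C,
            "k": k,
            "seed": seed,
            "features": list(features),
            "standardize": standardize,
            "n_rows": len(y),
        },
    )


def ablation(
    data: pd.DataFrame,
    C: float = 1.0,
    k: int = 5,
    seed: int = 0,
    degree: int = 2,
    kernels: tuple[str, ...] = ("polykernel", "normalized_polykernel"),
    standardize: bool = True,
) -> pd.DataFrame:
    """Leave-one-feature-out accuracy grid over both kernels.

    Rows: mean/highest accuracy for fold-training and for k-fold testing;
    columns: the six feature subsets × the kernels. Cell values are
    percentages.
    """
    records = []
    for subset in ABLATION_SUBSETS:
        for kern in kernels:
            rep = evaluate(
                data,
                spec=KernelSpec(kind=kern, degree=degree),
                C=C,
                k=k,
                seed=seed,
                features=subset,
                standardize=standardize,
            )
            name = "+".join(f.split("_")[-1] for f in subset)
            records.append(
                {
                    "subset": name,
                    "kernel": kern,
                    "mean_train_accuracy": rep.mean_train_accuracy,
                    "mean_kfold_accuracy": rep.mean_accuracy,
                    "best_train_accuracy": rep.best_train_accuracy,
                    "best_kfold_accuracy": rep.best_accuracy,
                }
            )
    return pd.DataFrame.from_records(records)


def grouped_evaluate(
    data: pd.DataFrame, group_field: str = "group", **kwargs
) -> dict[str, EvaluationReport]:
    """Independent evaluation per group value (e.g. one classifier per gender).

    Groups lacking both classes (or with fewer than two rows per class)
    are skipped with a warning; no information crosses group boundaries.
    """
    out: dict[str, EvaluationReport] = {}
    for value, sub in data.groupby(group_field, sort=True):
        counts = sub["label"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            logger.warning(
                "group %r skipped: needs >= 2 rows in each class, has %s",
                value,
                counts.to_dict(),
            )
            continue
        out[str(value)] = evaluate(sub.reset_index(drop=True), **kwargs)
    return out
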