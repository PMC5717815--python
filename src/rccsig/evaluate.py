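"""Confusion accounting, diagnostic-panel metrics, repeated cross-validation.

Per-class sensitivity is TP_c / n_c (n_c = reference-positive count) and
specificity is (N - n_c - FP_c) / (N - n_c), where FP_c counts samples
predicted as class c whose reference diagnosis differs — the standard
diagnostic-panel reading where every misassigned sample is a false
positive for the class it was called as. Overall accuracy is the
confusion-matrix trace over the total, with a Wilson score interval.
Cross-validation is stratified k-fold, repeated with fresh partitions,
with an empirical-percentile interval over the repeat accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from .classify import fit_bank, predict
from .data import ExpressionMatrix, GeneSignature
from .signature import select_signature


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = reference diagnosis, columns = predicted."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.labels)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class MetricsReport:
    """Per-class sensitivity/specificity plus overall accuracy and CI."""

    labels: list[str]
    sensitivity: dict[str, float | None]  # None where no reference positives
    specificity: dict[str, float]
    accuracy: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CVResult:
    """Repeated stratified k-fold cross-validation accuracies."""

    accuracies: np.ndarray
    k: int
    repeats: int
    seed: int
    mode: str

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [2.5, 97.5])
        return float(lo), float(hi)


def confusion(true_labels, predicted_labels, label_order: list[str] | None = None,
              ) -> ConfusionMatrix:
    """Tabulate reference vs predicted labels.

    Classes that appear only among predictions (a panel class absent from
    the cohort, e.g. a benign mimic never present in the reference set)
    get an all-zero reference row.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("length mismatch between truth and predictions")
    if not true_labels:
        raise ValueError("empty input")
    if label_order is None:
        label_order = sorted(set(true_labels) | set(predicted_labels))
    else:
        extra = sorted((set(true_labels) | set(predicted_labels)) - set(label_order))
        label_order = list(label_order) + extra
    idx = {c: i for i, c in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(labels=label_order, counts=counts)


def class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class sensitivity/specificity plus Wilson-interval accuracy."""
    N = cm.total
    sens: dict[str, float | None] = {}
    spec: dict[str, float] = {}
    for i, cls in enumerate(cm.labels):
        n_c = int(cm.counts[i].sum())              # reference positives
        tp = int(cm.counts[i, i])
        fp = int(cm.counts[:, i].sum() - tp)       # predicted-c, truth != c
        sens[cls] = tp / n_c if n_c else None
        negatives = N - n_c
        spec[cls] = (negatives - fp) / negatives if negatives else 1.0
    acc, (lo, hi) = overall_accuracy(cm)
    return MetricsReport(labels=list(cm.labels), sensitivity=sens,
                         specificity=spec, accuracy=acc, ci_low=lo, ci_high=hi,
                         n=N)


def overall_accuracy(cm: ConfusionMatrix) -> tuple[float, tuple[float, float]]:
    """trace/total with a 95% Wilson score interval."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = cm.correct / cm.total
    lo, hi = proportion_confint(cm.correct, cm.total, alpha=0.05, method="wilson")
    return acc, (float(lo), float(hi))


def repeated_cv(matrix: ExpressionMatrix, labels, k: int = 5, repeats: int = 1000,
                seed: int = 0, mode: str = "fixed_signature",
                signature: GeneSignature | None = None,
                n_select: int = 10, C: float = 1.0) -> CVResult:
    """Stratified k-fold cross-validation, repeated with fresh partitions.

    Per repeat the cohort is split into k stratified folds (per-class fold
    occupancy differs by at most 1); each fold is predicted by a bank
    trained on the other k-1 folds, and the pooled full-cohort accuracy is
    recorded. ``fixed_signature`` reuses a precomputed gene panel in every
    split; ``select_in_fold`` reruns one-vs-all SVM-RFE selection inside
    each training split (unbiased but far slower). The percentile 95%
    interval over repeats is reported. Fully reproducible from ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    if mode not in ("fixed_signature", "select_in_fold"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed_signature" and signature is None:
        raise ValueError("fixed_signature mode needs a signature")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < k]
    if len(small):
        raise ValueError(
            f"class(es) smaller than k={k}: {sorted(small.index.tolist())}")

    rng = np.random.default_rng(seed)
    accuracies = np.empty(repeats)
    X_cols = matrix.values
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        correct = 0
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            train = matrix.copy_with(values=X_cols[:, train_idx],
                                     sample_ids=[matrix.sample_ids[i] for i in train_idx])
            test = matrix.copy_with(values=X_cols[:, test_idx],
                                    sample_ids=[matrix.sample_ids[i] for i in test_idx])
            sig = signature
            if mode == "select_in_fold":
                sig = select_signature(train, labels[train_idx], k=n_select, C=C)
            bank = fit_bank(train, labels[train_idx], sig, C=C)
            calls = predict(bank, test.restrict_genes(bank.gene_symbols))
            correct += int((calls["predicted_label"].values
                            == labels[test_idx]).sum())
        accuracies[rep] = correct / len(labels)
    return CVResult(accuracies=accuracies, k=k, repeats=repeats, seed=seed,
                    mode=mode)
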