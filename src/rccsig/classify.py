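"""One-versus-all classifier bank and highest-confidence assignment.

One linear SVM is trained per subtype (that subtype vs all others, over
the signature genes); a test sample is assigned to the class whose model
gives it the largest signed decision value. Confidence is the raw margin,
not a calibrated probability; an optional sigmoid hook is available for
users who need probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSignature, SUBTYPES
from .signature import LinearModel, train_linear_svm


@dataclass
class ClassifierBank:
    """One linear model per class, all over the same signature gene order."""

    classes: list[str]
    models: dict[str, LinearModel]
    signature: GeneSignature
    train_mean: np.ndarray  # per-gene stats of the training matrix, for
    train_sd: np.ndarray    # optional reference-mode projection

    @property
    def gene_symbols(self) -> list[str]:
        return self.signature.unique_genes

    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes,
            "signature": self.signature.entries,
            "signature_k": self.signature.k,
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "models": {c: {"weights": m.weights.tolist(), "bias": m.bias,
                           "C": m.C, "n_samples": m.n_samples}
                       for c, m in self.models.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ClassifierBank":
        with open(path) as fh:
            payload = json.load(fh)
        sig = GeneSignature([tuple(e) for e in payload["signature"]],
                            k=payload["signature_k"])
        models = {
            c: LinearModel(weights=np.asarray(d["weights"]), bias=d["bias"],
                           positive_class=c, C=d["C"], n_samples=d["n_samples"],
                           gene_symbols=sig.unique_genes)
            for c, d in payload["models"].items()}
        return cls(classes=payload["classes"], models=models, signature=sig,
                   train_mean=np.asarray(payload["train_mean"]),
                   train_sd=np.asarray(payload["train_sd"]))


def fit_bank(matrix: ExpressionMatrix, labels: np.ndarray,
             signature: GeneSignature, C: float = 1.0) -> ClassifierBank:
    """Train one one-vs-rest linear SVM per class over the signature genes.

    ``matrix`` must be standardized; it is restricted to the signature's
    unique genes (in signature order) before training. Per-gene training
    means/SDs are stored so new cohorts can optionally be projected onto
    the training scale.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != matrix.n_samples:
        raise ValueError("labels must match sample count")
    classes = sorted(set(labels),
                     key=lambda c: (SUBTYPES.index(c) if c in SUBTYPES else 99, c))
    small = [c for c in classes if (labels == c).sum() < 2]
    if small:
        raise ValueError(f"class(es) with fewer than 2 samples: {small}")

    sub = matrix.restrict_genes(signature.unique_genes)
    X = sub.values.T  # samples x genes
    models = {}
    for cls in classes:
        y = np.where(labels == cls, 1, -1)
        models[cls] = train_linear_svm(X, y, C=C, positive_class=cls,
                                       gene_symbols=sub.gene_symbols)
    return ClassifierBank(classes=classes, models=models, signature=signature,
                          train_mean=sub.values.mean(axis=1),
                          train_sd=sub.values.std(axis=1))


def predict(bank: ClassifierBank, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Assign each sample to the class with the highest decision value.

    ``matrix`` must already be projected onto the bank's signature genes
    (same genes, same order). Returns a frame with one row per sample:
    predicted_label, one confidence column per class (raw signed margins),
    tie_flag (exact top-two tie, resolved by bank class order) and
    reject_flag (every margin negative — the sample resembles no training
    class, but the forced-choice argmax label is still reported).
    """
    if list(matrix.gene_symbols) != bank.gene_symbols:
        raise ValueError("matrix gene order does not match the classifier bank")
    X = matrix.values.T
    conf = np.column_stack([bank.models[c].decision(X) for c in bank.classes])
    best = conf.argmax(axis=1)  # argmax takes the first maximum: bank order
    ties = (conf == conf[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    reject = (conf < 0).all(axis=1)
    out = pd.DataFrame({"sample_id": matrix.sample_ids,
                        "predicted_label": [bank.classes[i] for i in best]})
    for j, c in enumerate(bank.classes):
        out[f"confidence_{c}"] = conf[:, j]
    out["tie_flag"] = ties
    out["reject_flag"] = reject
    return out
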