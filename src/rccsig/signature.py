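"""Linear SVM training, recursive feature elimination, signature assembly.

Feature selection follows the SVM-RFE scheme: train a linear soft-margin
SVM on the surviving genes, score each gene by its squared weight, drop
the weakest block, repeat until all genes are ordered. Per-class gene
lists are built one-vs-all and merged into a multi-class signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .data import ExpressionMatrix, GeneSignature

#: genes surviving above this count are eliminated in halving blocks;
#: at or below it, one gene is removed per step
BLOCK_THRESHOLD = 64


@dataclass
class LinearModel:
    """Linear soft-margin SVM: decision value for sample x is w·x + b."""

    weights: np.ndarray
    bias: float
    positive_class: str
    C: float
    n_samples: int
    gene_symbols: list[str] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        """X is samples x genes; returns one signed margin per sample."""
        return X @ self.weights + self.bias


@dataclass
class RankedGeneList:
    """Genes ordered from most to least important, with elimination steps."""

    genes: list[str]                 # rank 1 first
    elimination_step: dict[str, int]  # step at which each gene was removed

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                     positive_class: str = "+1",
                     gene_symbols: list[str] | None = None,
                     max_iter: int = 50_000) -> LinearModel:
    """Fit a linear SVM minimizing (1/2)||w||^2 + C * sum hinge(y_i(w·x_i+b)).

    X is samples x genes; y is ±1. Deterministic for fixed input and C.
    ``max_iter`` bounds the dual solver; informative problems converge to
    the 1e-6 KKT tolerance orders of magnitude below the cap, which only
    truncates the solver's asymptotic tail on pure-noise inseparable
    inputs where the weight vector has long since stabilized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be samples x genes")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("y must contain both classes coded -1/+1")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    if np.all(X == X[0]):
        raise ValueError("all samples identical; SVM problem degenerate")
    if C <= 0:
        raise ValueError("C must be positive")
    svc = SVC(kernel="linear", C=C, tol=1e-6, shrinking=False, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    # libsvm orients the decision function by sorted class order [-1, +1]
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    return LinearModel(weights=w, bias=b, positive_class=positive_class, C=C,
                       n_samples=X.shape[0],
                       gene_symbols=list(gene_symbols or []))


def default_schedule(n_genes: int, block_threshold: int = BLOCK_THRESHOLD) -> list[int]:
    """Number of genes removed at each elimination step.

    Halve the surviving set while more than ``block_threshold`` genes
    survive, then remove one gene per step; the final survivor is never
    removed (it holds rank 1).
    """
    steps = []
    remaining = n_genes
    while remaining > 1:
        if remaining > block_threshold:
            drop = min(remaining // 2, remaining - block_threshold)
            drop = max(drop, 1)
        else:
            drop = 1
        steps.append(drop)
        remaining -= drop
    return steps


def rfe_rank(X: np.ndarray, y: np.ndarray, gene_symbols: list[str],
             C: float = 1.0, schedule: list[int] | None = None) -> RankedGeneList:
    """Rank genes by recursive elimination of the smallest squared SVM weight.

    At each step a linear SVM is trained on the surviving genes and the
    block of genes with the smallest w_g^2 is removed. Ties in w^2 are
    broken lexicographically: the later-alphabet gene is removed first.
    Genes removed later outrank genes removed earlier; within a removed
    block, higher w^2 ranks better.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(gene_symbols):
        raise ValueError("gene_symbols must match X columns")
    if len(gene_symbols) < 2:
        raise ValueError("need at least 2 genes to rank")
    if schedule is None:
        schedule = default_schedule(len(gene_symbols))

    surviving = list(range(len(gene_symbols)))
    removed_blocks: list[list[int]] = []  # per step, column indices removed
    for step, drop in enumerate(schedule):
        model = train_linear_svm(X[:, surviving], y, C=C)
        scores = model.weights ** 2
        # remove-first order: ascending score, later-alphabet symbol first
        # two-pass stable sort: later-alphabet first within equal scores
        order = sorted(range(len(surviving)),
                       key=lambda j: gene_symbols[surviving[j]], reverse=True)
        order.sort(key=lambda j: scores[j])
        # rank within the removed block: higher score first, earlier alphabet first
        block = sorted(order[:drop], key=lambda j: (-scores[j],
                                                    gene_symbols[surviving[j]]))
        block_cols = [surviving[j] for j in block]
        removed_blocks.append(block_cols)
        dropped = set(block_cols)
        surviving = [c for c in surviving if c not in dropped]
    assert len(surviving) == 1

    genes: list[str] = [gene_symbols[surviving[0]]]
    elimination_step = {genes[0]: len(schedule)}  # survivor outlives all steps
    for step_idx in range(len(removed_blocks) - 1, -1, -1):
        for col in removed_blocks[step_idx]:
            genes.append(gene_symbols[col])
            elimination_step[gene_symbols[col]] = step_idx
    return RankedGeneList(genes=genes, elimination_step=elimination_step)


def select_signature(matrix: ExpressionMatrix, labels: np.ndarray, k: int = 10,
                     C: float = 1.0, balanced: bool = False,
                     schedule: list[int] | None = None) -> GeneSignature:
    """One-vs-all SVM-RFE signature: top-k genes per class, merged.

    For each class the samples are relabelled class-vs-rest (±1), genes are
    RFE-ranked, and the k best are kept; the per-class lists are
    concatenated in class order (classes sorted by the canonical subtype
    order, then alphabetically) and deduplicated preserving first
    occurrence. Every (gene, class, rank) entry is recorded, including
    duplicate genes contributed by several classes.
    """
    from .data import SUBTYPES

    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels),
                     key=lambda c: (SUBTYPES.index(c) if c in SUBTYPES else 99, c))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds gene count {matrix.n_genes}")

    X = matrix.values.T  # samples x genes
    entries: list[tuple[str, str, int]] = []
    for cls in classes:
        y = np.where(labels == cls, 1, -1)
        C_cls = C
        if balanced:
            # inverse-frequency rescaling keeps rare classes from being ignored
            pos_frac = (y == 1).mean()
            C_cls = C / (2 * pos_frac)
        ranking = rfe_rank(X, y, matrix.gene_symbols, C=C_cls, schedule=schedule)
        for rank, gene in enumerate(ranking.top(k), start=1):
            entries.append((gene, cls, rank))
    return GeneSignature(entries, k=k)
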