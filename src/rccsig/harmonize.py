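"""Per-sample normalization, gene standardization and batch adjustment.

The pipeline assumes log2-scale expression. Cohorts from different
platforms are brought onto a comparable footing by (1) log2 transform of
raw values, (2) quantile normalization across samples, (3) gene-wise
z-scoring, and (4) empirical-Bayes location/scale batch adjustment
(parametric, gene-wise batch effects shrunk across genes). New cohorts are
projected onto a trained signature space by restriction + standardization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .data import ExpressionMatrix, GeneSignature, SampleAnnotation

logger = logging.getLogger(__name__)

#: fixed-point iteration tolerance / cap for the EB shrinkage solver
EB_CONV_TOL = 1e-4
EB_MAX_ITER = 100


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); no-op with a warning on already-log2 input."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if matrix.scale == "log2":
        warnings.warn("matrix already on log2 scale; log2_transform is a no-op")
        return matrix
    if matrix.scale != "raw":
        raise ValueError(f"cannot log2-transform a {matrix.scale} matrix")
    if (matrix.values < 0).any():
        raise ValueError("negative values on raw scale")
    return matrix.copy_with(values=np.log2(matrix.values + pseudocount), scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    After normalization every column holds the identical sorted multiset
    (the across-sample mean of order statistics); within-column rank order
    is preserved, and a tie group is assigned the mean of the reference
    values its ranks span.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    V = matrix.values
    ref = np.sort(V, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(V)
    for j in range(matrix.n_samples):
        col = V[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        assigned = ref.copy()
        # average the reference over each run of tied values
        start = 0
        for end in range(1, len(sorted_vals) + 1):
            if end == len(sorted_vals) or sorted_vals[end] != sorted_vals[start]:
                if end - start > 1:
                    assigned[start:end] = ref[start:end].mean()
                start = end
        out[order, j] = assigned
    return matrix.copy_with(values=out)


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and rescale to population SD 1.

    Constant genes cannot be rescaled; they are set to all-zeros and
    reported via a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    V = matrix.values
    mean = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)  # population SD
    constant = (sd[:, 0] == 0)
    sd[constant] = 1.0
    out = (V - mean) / sd
    out[constant] = 0.0
    if constant.any():
        names = [g for g, c in zip(matrix.gene_symbols, constant) if c]
        warnings.warn(f"{len(names)} constant gene(s) set to zero: {names[:10]}")
    return matrix.copy_with(values=out, scale="zscored")


@dataclass
class BatchModel:
    """Fitted gene-wise batch-effect model.

    Per gene g and batch i the model records the raw location/scale batch
    effect estimates (``gamma_hat``, ``delta2_hat``) and their
    empirical-Bayes shrunk counterparts (``gamma_star``, ``delta2_star``),
    plus the per-gene grand mean ``alpha_hat`` and pooled variance
    ``sigma2_hat`` used for standardization, and the per-batch prior
    hyperparameters (normal prior on location, inverse-gamma on scale,
    moment-matched).
    """

    batches: list[str]
    gene_symbols: list[str]
    gamma_hat: np.ndarray    # (n_batches, n_genes)
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    alpha_hat: np.ndarray    # (n_genes,)
    sigma2_hat: np.ndarray
    gamma_bar: np.ndarray    # (n_batches,) prior means
    tau2: np.ndarray         # (n_batches,) prior variances
    a_prior: np.ndarray
    b_prior: np.ndarray
    n_iter: int = 0

    def to_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "BatchModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {"gamma_hat", "delta2_hat", "gamma_star", "delta2_star",
                  "alpha_hat", "sigma2_hat", "gamma_bar", "tau2",
                  "a_prior", "b_prior"}
        return cls(**{k: (np.asarray(v) if k in arrays else v)
                      for k, v in payload.items()})


def _design_matrix(batches: np.ndarray, covariate: np.ndarray | None):
    batch_levels = sorted(set(batches))
    B = np.column_stack([(batches == b).astype(float) for b in batch_levels])
    X = np.empty((len(batches), 0))
    if covariate is not None:
        cov_levels = sorted(set(covariate))
        # reference coding, first level dropped (batch columns absorb it)
        X = np.column_stack([(covariate == c).astype(float) for c in cov_levels[1:]]) \
            if len(cov_levels) > 1 else X
    D = np.hstack([B, X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate is confounded with batch; cannot adjust")
    return batch_levels, B, D


def combat_adjust(matrix: ExpressionMatrix, annotations: SampleAnnotation,
                  covariate: bool | None = None,
                  ) -> tuple[ExpressionMatrix, BatchModel]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Each gene is standardized against its model-fitted grand mean and
    pooled variance (class-label effects are retained when ``covariate``
    is on); per-batch gene-wise location and scale effects are estimated,
    shrunk across genes toward moment-matched priors (normal on location,
    inverse-gamma on scale) by fixed-point iteration, then removed and the
    grand mean/variance restored.

    ``covariate=None`` (default) protects the subtype label whenever every
    sample carries one; ``True``/``False`` force the choice.
    """
    if matrix.scale not in ("log2", "zscored"):
        raise ValueError("batch adjustment expects log2-scale input")
    batches = annotations.batches_for(matrix.sample_ids)
    labels = None
    if covariate is not False:
        lab = annotations.labels_for(matrix.sample_ids)
        have_all = all(l not in ("", None) for l in lab)
        if covariate is True and not have_all:
            raise ValueError("covariate requested but some samples lack a label")
        if have_all and len(set(lab)) > 1:
            labels = lab
        elif covariate is True:
            raise ValueError("covariate requested but label is constant")

    counts = {b: int((batches == b).sum()) for b in set(batches)}
    singletons = [b for b, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"batch(es) with a single sample: {sorted(singletons)}")

    Y = matrix.values  # genes x samples
    G, n = Y.shape
    batch_levels, B, D = _design_matrix(batches, labels)
    n_batches = len(batch_levels)
    n_per = np.array([counts[b] for b in batch_levels], dtype=float)

    if n_batches == 1:
        model = BatchModel(
            batches=batch_levels, gene_symbols=list(matrix.gene_symbols),
            gamma_hat=np.zeros((1, G)), delta2_hat=np.ones((1, G)),
            gamma_star=np.zeros((1, G)), delta2_star=np.ones((1, G)),
            alpha_hat=Y.mean(axis=1), sigma2_hat=Y.var(axis=1),
            gamma_bar=np.zeros(1), tau2=np.zeros(1),
            a_prior=np.zeros(1), b_prior=np.zeros(1))
        return matrix.copy_with(values=Y.copy()), model

    # per-gene OLS fit on the full design
    beta_hat, *_ = np.linalg.lstsq(D, Y.T, rcond=None)  # (p, G)
    batch_coefs = beta_hat[:n_batches]                  # batch means (adjusted)
    alpha_hat = (n_per / n) @ batch_coefs               # grand mean, (G,)

    fitted = (D @ beta_hat).T
    sigma2_hat = ((Y - fitted) ** 2).mean(axis=1)       # pooled variance, (G,)
    if (sigma2_hat == 0).any():
        bad = [g for g, s in zip(matrix.gene_symbols, sigma2_hat) if s == 0]
        raise ValueError(f"zero residual variance for gene(s) {bad[:5]}")

    # standardized data: remove grand mean + covariate effects, keep batch shifts
    stand_mean = alpha_hat[:, None] + (
        (D[:, n_batches:] @ beta_hat[n_batches:]).T if D.shape[1] > n_batches
        else 0.0)
    Z = (Y - stand_mean) / np.sqrt(sigma2_hat)[:, None]

    masks = [batches == b for b in batch_levels]
    gamma_hat = np.vstack([Z[:, m].mean(axis=1) for m in masks])       # (I, G)
    delta2_hat = np.vstack([Z[:, m].var(axis=1, ddof=1) for m in masks])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m_d = delta2_hat.mean(axis=1)
    s2_d = delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * s2_d + m_d ** 2) / s2_d
        b_prior = (m_d * s2_d + m_d ** 3) / s2_d

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    total_iter = 0
    for i, mask in enumerate(masks):
        ni = mask.sum()
        if s2_d[i] == 0:
            # degenerate scale prior (all genes identical): no shrinkage signal
            g_new = (tau2[i] * ni * gamma_hat[i] + delta2_hat[i] * gamma_bar[i]) \
                / (tau2[i] * ni + delta2_hat[i])
            gamma_star[i], delta2_star[i] = g_new, delta2_hat[i]
            continue
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        Zi = Z[:, mask]
        for it in range(EB_MAX_ITER):
            g_new = (tau2[i] * ni * gamma_hat[i] + d_old * gamma_bar[i]) \
                / (tau2[i] * ni + d_old)
            sum2 = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior[i]) / (ni / 2 + a_prior[i] - 1)
            change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                         if np.abs(g_old).max() > 0 else 0.0,
                         np.abs(d_new - d_old).max() / np.abs(d_old).max())
            g_old, d_old = g_new, d_new
            if change < EB_CONV_TOL:
                break
        total_iter += it + 1
        gamma_star[i], delta2_star[i] = g_old, d_old

    # remove shrunk batch effects and restore the grand scale
    Z_adj = Z.copy()
    for i, mask in enumerate(masks):
        Z_adj[:, mask] = (Z[:, mask] - gamma_star[i][:, None]) \
            / np.sqrt(delta2_star[i])[:, None]
    adjusted = Z_adj * np.sqrt(sigma2_hat)[:, None] + stand_mean

    model = BatchModel(
        batches=batch_levels, gene_symbols=list(matrix.gene_symbols),
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta2_star=delta2_star,
        alpha_hat=alpha_hat, sigma2_hat=sigma2_hat,
        gamma_bar=gamma_bar, tau2=tau2, a_prior=a_prior, b_prior=b_prior,
        n_iter=total_iter)
    return matrix.copy_with(values=adjusted), model


def project_onto_signature(matrix: ExpressionMatrix, signature: GeneSignature,
                           reference_stats: tuple[np.ndarray, np.ndarray] | None = None,
                           mode: str = "self") -> ExpressionMatrix:
    """Restrict to signature genes and standardize per gene.

    mode="self" (default) z-scores each gene within the new cohort, so no
    shared scale with the training platform is needed; mode="reference"
    standardizes with supplied training (mean, SD) arrays aligned to the
    signature's unique gene order. Signature genes missing from the matrix
    are zero-filled after standardization (reported via warning); more than
    25% missing makes the panel unusable and is an error.
    """
    genes = signature.unique_genes
    index = {g: i for i, g in enumerate(matrix.gene_symbols)}
    missing = [g for g in genes if g not in index]
    if len(missing) > 0.25 * len(genes):
        raise ValueError(
            f"{len(missing)}/{len(genes)} signature genes missing — panel unusable")
    if missing:
        warnings.warn(f"signature genes missing, zero-filled: {missing}")

    present = [g for g in genes if g in index]
    sub = matrix.values[[index[g] for g in present]]
    if mode == "self":
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        std = (sub - mean) / sd
    elif mode == "reference":
        if reference_stats is None:
            raise ValueError("reference mode needs reference_stats (mean, sd)")
        ref_mean, ref_sd = (np.asarray(a, dtype=float) for a in reference_stats)
        if len(ref_mean) != len(genes):
            raise ValueError("reference_stats must align with signature genes")
        pos = {g: i for i, g in enumerate(genes)}
        rows = [pos[g] for g in present]
        sd = ref_sd[rows].copy()
        sd[sd == 0] = 1.0
        std = (sub - ref_mean[rows][:, None]) / sd[:, None]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = np.zeros((len(genes), matrix.n_samples))
    row_of = {g: i for i, g in enumerate(present)}
    for i, g in enumerate(genes):
        if g in row_of:
            out[i] = std[row_of[g]]
    return ExpressionMatrix(gene_symbols=genes, sample_ids=list(matrix.sample_ids),
                            values=out, platform=matrix.platform, scale="zscored")
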