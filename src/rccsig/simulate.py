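"""Seeded synthetic multi-subtype, multi-batch, multi-platform cohorts.

The generator emulates the structure of a multi-cohort renal-tumour
expression study with known ground truth: five sample classes (three
carcinoma subtypes, a benign mimic and adjacent normal tissue), each with
a planted set of marker genes elevated by a configurable effect size;
gene-wise additive and multiplicative batch effects across several
batches; and three platform flavors — continuous log-intensities
(microarray-like), Poisson count-derived log values (RNA-seq-like), and a
small signature-restricted panel with extra measurement noise
(qRT-PCR-like, mimicking -dCt values). The chromophobe/benign-mimic class
pair shares a configurable fraction of markers, reproducing the
near-identical expression profiles of those related neoplasms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSignature, SampleAnnotation, SUBTYPES

#: training-cohort class sizes (ccRCC, pRCC, chRCC, oncocytoma, normal)
DEFAULT_CLASS_SIZES = {"ccRCC": 106, "pRCC": 66, "chRCC": 42,
                       "oncocytoma": 46, "normal": 35}

#: test-cohort class sizes mirroring the two validation designs at a
#: fraction of their real scale; the RNA-seq-like cohort has no benign
#: mimic, the qPCR-like cohort covers all five classes
TEST1_CLASS_SIZES = {"ccRCC": 107, "pRCC": 58, "chRCC": 13, "normal": 26}
TEST2_CLASS_SIZES = {"ccRCC": 26, "pRCC": 28, "chRCC": 40,
                     "oncocytoma": 27, "normal": 8}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for cohort generation.

    Defaults mirror the training-cohort composition of a five-class,
    295-sample multi-batch design, with 10 planted markers per class at
    effect size 2 SD, unit within-class noise, and the
    chromophobe/benign-mimic pair sharing half their markers.
    """

    n_genes: int = 2000
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    markers_per_class: int = 10
    effect_size: float = 2.0          # marker elevation, in SD units
    within_sd: float = 1.0
    correlated_pair: tuple[str, str] = ("chRCC", "oncocytoma")
    shared_fraction: float = 0.5      # of the pair's markers
    n_batches: int = 2
    batch_shift_range: tuple[float, float] = (-1.0, 1.0)
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    platform: str = "microarray"
    baseline_mean: float = 7.0        # log2-scale grand mean of gene baselines
    baseline_sd: float = 1.0
    qpcr_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or any(n < 1 for n in self.class_sizes.values()):
            raise ValueError("counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared fraction must be in [0, 1]")
        if self.markers_per_class * len(self.class_sizes) > self.n_genes:
            raise ValueError("too many markers for the gene count")
        if self.platform not in ("microarray", "rnaseq", "qpcr"):
            raise ValueError(f"unknown platform {self.platform!r}")

    def class_order(self) -> list[str]:
        return [c for c in SUBTYPES if c in self.class_sizes] + \
            sorted(set(self.class_sizes) - set(SUBTYPES))


def gene_names(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def plant_markers(config: SyntheticConfig,
                  rng: np.random.Generator) -> dict[str, list[str]]:
    """Assign per-class marker sets, disjoint except that the configured
    correlated pair shares ``shared_fraction`` of its markers."""
    names = gene_names(config.n_genes)
    pool = list(rng.permutation(config.n_genes))
    m = config.markers_per_class
    markers = {cls: [names[pool.pop()] for _ in range(m)]
               for cls in config.class_order()}
    a, b = config.correlated_pair
    if a in markers and b in markers and config.shared_fraction > 0:
        n_shared = int(round(config.shared_fraction * m))
        markers[b] = markers[a][:n_shared] + markers[b][n_shared:]
    return markers


def generate_cohort(config: SyntheticConfig,
                    signature: GeneSignature | None = None,
                    cohort: str = "train",
                    markers: dict[str, list[str]] | None = None,
                    baseline: np.ndarray | None = None,
                    ) -> tuple[ExpressionMatrix, SampleAnnotation, dict[str, list[str]]]:
    """Generate one cohort: expression matrix, annotation, marker truth.

    Model (log2 scale): per-gene baseline ~ Normal(baseline_mean,
    baseline_sd); a sample's value adds ``effect_size`` for markers of its
    class, a per-(gene, batch) additive shift drawn uniformly from
    ``batch_shift_range``, and Normal(0, within_sd x batch scale factor)
    noise. The RNA-seq flavor converts means to Poisson counts and
    re-logs; the qPCR flavor restricts to signature genes and adds panel
    noise. Deterministic per seed. ``markers``/``baseline`` can be
    supplied to share ground truth across cohorts.
    """
    rng = np.random.default_rng(config.seed)
    if markers is None:
        markers = plant_markers(config, rng)
    else:
        rng.permutation(config.n_genes)  # keep the stream position fixed
    names = gene_names(config.n_genes)
    if baseline is None:
        baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                              config.n_genes)
    else:
        rng.normal(size=config.n_genes)

    sample_ids, labels = [], []
    for cls in config.class_order():
        for i in range(config.class_sizes[cls]):
            sample_ids.append(f"{cohort}_{cls}_{i:03d}")
            labels.append(cls)
    n = len(sample_ids)
    batch_names = [f"batch{i + 1}" for i in range(config.n_batches)]
    batches = [batch_names[i % config.n_batches] for i in range(n)]

    lo, hi = config.batch_shift_range
    shift = rng.uniform(lo, hi, size=(config.n_genes, config.n_batches))
    slo, shi = config.batch_scale_range
    scale = rng.uniform(slo, shi, size=config.n_batches)

    row_of = {g: i for i, g in enumerate(names)}
    marker_rows = {cls: [row_of[g] for g in mk if g in row_of]
                   for cls, mk in markers.items()}
    values = np.empty((config.n_genes, n))
    for j, (cls, batch) in enumerate(zip(labels, batches)):
        bi = batch_names.index(batch)
        mean = baseline + shift[:, bi]
        if cls in marker_rows:
            mean = mean.copy()
            mean[marker_rows[cls]] += config.effect_size
        values[:, j] = mean + rng.normal(0.0, config.within_sd * scale[bi],
                                         config.n_genes)

    genes = names
    if config.platform == "rnaseq":
        counts = rng.poisson(np.maximum(2.0 ** values, 0.0))
        values = np.log2(counts + 1.0)
    elif config.platform == "qpcr":
        if signature is None:
            raise ValueError("qpcr platform needs a signature to restrict to")
        keep = [g for g in signature.unique_genes if g in row_of]
        if not keep:
            raise ValueError("signature shares no genes with the cohort")
        values = values[[row_of[g] for g in keep]] \
            + rng.normal(0.0, config.qpcr_noise_sd, size=(len(keep), n))
        genes = keep

    matrix = ExpressionMatrix(gene_symbols=genes, sample_ids=sample_ids,
                              values=values, platform=config.platform,
                              scale="log2")
    ann = SampleAnnotation(pd.DataFrame({
        "sample_id": sample_ids, "label": labels, "batch": batches,
        "cohort": cohort}))
    return matrix, ann, markers


def generate_multiplatform(config: SyntheticConfig,
                           signature: GeneSignature | None = None) -> dict:
    """Train/test trio sharing marker truth across platform flavors.

    Returns {"train": ..., "test1": ..., "test2": ...} where each value is
    a (matrix, annotation, markers) triple. "train" is microarray-like
    with the default five-class composition; "test1" is RNA-seq-like with
    no benign-mimic class; "test2" is qPCR-like over all five classes,
    restricted to ``signature`` (the planted markers when none is given).
    Marker truth and gene baselines are shared; noise, batches and
    platform distortions differ per cohort.
    """
    rng = np.random.default_rng(config.seed)
    markers = plant_markers(config, rng)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_genes)
    seeds = rng.integers(2 ** 31 - 1, size=3)

    if signature is None:
        signature = GeneSignature(
            [(g, cls, rank + 1) for cls, mk in markers.items()
             for rank, g in enumerate(mk)], k=config.markers_per_class)

    out = {}
    out["train"] = generate_cohort(
        replace(config, platform="microarray", seed=int(seeds[0])),
        cohort="train", markers=markers, baseline=baseline)
    out["test1"] = generate_cohort(
        replace(config, platform="rnaseq", class_sizes=dict(TEST1_CLASS_SIZES),
                seed=int(seeds[1])),
        cohort="test1", markers=markers, baseline=baseline)
    out["test2"] = generate_cohort(
        replace(config, platform="qpcr", class_sizes=dict(TEST2_CLASS_SIZES),
                seed=int(seeds[2])),
        signature=signature, cohort="test2", markers=markers, baseline=baseline)
    return out
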