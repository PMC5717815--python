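# Methods

`rccsig` implements a multi-platform expression-classification pipeline for
renal tumour subtypes: harmonize cohorts onto a common scale, discover a
compact gene signature by one-versus-all SVM-RFE, classify new samples by
highest-confidence assignment, and quantify performance with
diagnostic-panel metrics and repeated stratified cross-validation. This
note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Problem setting

Five sample classes are handled: clear cell (ccRCC), papillary (pRCC) and
chromophobe (chRCC) renal cell carcinoma, benign oncocytoma, and adjacent
normal tissue. Inputs are gene-level log2 expression matrices
(genes × samples) from heterogeneous platforms — continuous microarray
log-intensities, log-transformed RNA-seq counts, or small qRT-PCR panels
(−ΔCt relative to a control gene, supplied as a numeric matrix; Ct calling
is out of scope). Gene identity is the uppercase symbol string; no alias
resolution is attempted, and duplicate symbols are collapsed by per-gene
maximum at ingestion (the usual probe-collapse convention; deterministic).

## Harmonization

* **log2 transform** — `log2(x + pseudocount)`, pseudocount 1 by default.
* **Quantile normalization** — every sample column is mapped onto the
  across-sample mean of order statistics; tie groups receive the mean of
  the reference values their ranks span. This is the package's
  distribution-equalizing step for gene-level matrices (probe-level
  single-channel normalization is out of scope since inputs are gene-level).
* **Gene z-scoring** — mean 0, *population* SD 1 per gene. Population
  rather than sample SD keeps "rescaled to SD = 1" exact at small n and is
  applied consistently everywhere (selection, classification, clustering).
  Constant genes are zeroed and reported.
* **Batch adjustment** — the parametric empirical-Bayes location/scale
  model: per gene, standardize against the model-fitted grand mean and
  pooled variance (retaining class-label effects when a covariate is
  protected), estimate per-batch gene-wise location (γ̂) and scale (δ̂²),
  shrink across genes (normal prior on location, inverse-gamma on scale,
  hyperparameters by moment matching) by fixed-point iteration
  (tolerance 1e−4, cap 100 iterations), remove the shrunk effects and
  restore the grand scale. The implementation reproduces the Bioconductor
  reference (`sva::ComBat`, parametric) to ≈1e−5 without covariates and to
  machine precision with them; that reference serves only as a test
  oracle. By default the subtype label is protected as a covariate
  whenever every sample carries one — the alternative (no protection)
  is exposed, since with confounded designs protection is the safer
  default. Single-batch input is returned unchanged.
  Note that EB shrinkage trades per-gene exactness for stability: after
  adjustment the *mean* between-batch gap vanishes, but per-gene residual
  gaps remain at the (1 − shrinkage weight) scale even for an exactly
  constant planted shift.
* **Signature projection** — a new cohort is restricted to the signature
  genes and standardized per gene. Default mode is per-cohort
  self-standardization ("self"), the only mode needing no shared scale
  between training and test platforms; "reference" mode (training
  means/SDs) is retained for ablation. Missing panel genes are zero-filled
  (i.e. imputed at the cohort mean) and reported; more than 25% missing
  makes the panel unusable and is an error.

## Signature discovery (one-vs-all SVM-RFE)

For each class, samples are relabelled class-vs-rest (±1) and a linear
soft-margin SVM — minimizer of ½‖w‖² + C·Σ hinge — is trained on the
surviving genes; genes are scored by w², the canonical RFE criterion, and
the weakest block is removed. The default schedule halves the surviving
set while more than 64 genes survive, then removes one gene per step;
64 balances fidelity of the one-at-a-time tail against runtime, and both
the threshold and the schedule are arguments. Exact w² ties are broken
lexicographically (later-alphabet gene removed first), making rankings
reproducible and order-invariant. The top k = 10 genes per class are
concatenated in canonical class order and deduplicated preserving first
occurrence; every (gene, class, rank) entry is retained so per-class
provenance survives deduplication.

Parameters: C defaults to 1.0 on z-scored data (the elimination criterion
is scale-sensitive, so standardization is a precondition); `balanced`
rescales C by inverse class frequency for the positive class. Selection is
performed on the full training set by default, mirroring the protocol of
building the final model on all training data; selection inside CV folds
is available (`mode="select_in_fold"`) because fixed-signature CV is
optimistically biased — at zero effect size a full-cohort-selected panel
inflates CV accuracy from the chance-agreement rate (~0.22 at the default
class proportions) to ~0.53.

The SVM trainer (sklearn's libsvm backend, KKT tolerance 1e−6) carries a
50 000-iteration cap: on tiny, pure-noise, inseparable problems libsvm's
asymptotic tail otherwise costs minutes while the weight vector has long
since stabilized; converged problems never reach the cap. The w² rule is a
surrogate for the exact greedy rule (remove the gene whose deletion least
degrades the objective); agreement on random separable toys is high but
not total, and is tracked by a test rather than asserted at 100%.

## Classification

One linear model per class over the signature genes; a sample's
confidence for class c is the raw signed decision value w_c·x + b_c and
the assigned label is the argmax (ties resolve to the first class in bank
order and are flagged). Confidence is deliberately not a calibrated
probability — the raw margin is parameter-free and monotone in distance
from the separating plane. When every margin is negative the sample
resembles no training class; it is flagged as a rejection candidate but
still receives the forced-choice argmax label, matching the behaviour of
applying a fixed panel to a cohort that may lack some classes.

## Evaluation

Confusion matrices are reference × predicted; classes that appear only
among predictions get an all-zero reference row. Per class,
sensitivity = TP_c / n_c and specificity = (N − n_c − FP_c)/(N − n_c),
where FP_c counts samples called c whose reference differs. This reading
of "(1 − false positive)/(total tested − total positive)" exactly
reproduces every self-consistent published worked-example cell and is the
standard diagnostic-panel convention. Overall accuracy is trace/total with
a 95% Wilson score interval (which reproduces the published interval for
the 1020-sample worked example to three decimals). Cross-validation is
stratified k-fold (per-class fold occupancy differs by ≤1), repeated with
fresh partitions from a seeded generator; the CI is the 2.5/97.5
percentile of the repeat accuracies. Results are bit-reproducible from
the seed.

## Clustering

Distance is 1 − Pearson r between z-scored profiles; agglomeration is
UPGMA (size-weighted average linkage, i.e. mean pairwise leaf distance),
chosen over WPGMA where "average linkage" was ambiguous; ties break to the
smallest index pair so heatmaps are reproducible. A k-group partition
undoes the last k−1 merges. The implementation is checked against both a
definition-level brute-force oracle (≤6 leaves) and SciPy's average
linkage (heights on tie-free data). Trees export to Newick with branch
lengths equal to merge-height differences.

## Enrichment and networks

Over-representation uses the exact upper-tail hypergeometric probability
with Benjamini–Hochberg FDR across all tested sets; the background
universe is a mandatory user input (measured-gene universes and
whole-genome universes give very different p-values, and no default is
defensible). Published database-dependent p-values are not reproduction
targets; the module reproduces the procedure on user-supplied GMT/SIF
files. Seed-connecting subnetworks use the classic metric-closure MST
Steiner approximation (2-approximation on connector count; exact search
only in tests on ≤12-node graphs), with all ties resolved by symbol order.
Seeds spanning several components are connected within each component.

## Synthetic cohorts

The generator emulates the multi-cohort study design with known ground
truth. Log2-scale model: gene baseline ~ N(7, 1); a sample adds the
effect size δ (default 2.0 SD) on its class's m = 10 planted markers,
a per-(gene, batch) additive shift uniform on ±1, and N(0, σ·s_b) noise
with σ = 1 and batch scale factor s_b uniform on [0.8, 1.25] over 2
batches. Class sizes default to 106/66/42/46/35
(ccRCC/pRCC/chRCC/oncocytoma/normal, 295 samples), mirroring the
five-class training composition. The chRCC–oncocytoma pair shares ρ = 0.5
of its markers, reproducing the near-identical profiles of these related
neoplasms (they fuse first in centroid clustering and dominate the
confusion structure at high ρ). Platform flavors: microarray-like values
are used as-is; RNA-seq-like values pass through Poisson(2^x) counts and
are re-logged; qPCR-like cohorts are restricted to a signature panel with
N(0, 0.25) measurement noise. The multiplatform trio shares marker truth
and baselines across a microarray-like training cohort (295), an
RNA-seq-like test cohort (204; no oncocytoma, mirroring the validation
design that lacked it) and a qPCR-like test cohort (129; all five
classes).

A Gaussian log-scale model was chosen over a count-level simulator
because every pipeline stage consumes z-scored log values, so only the
relative class/batch/noise structure matters; the simplification buys
exact control of effect sizes. What passing tests on these cohorts show
is that the machinery recovers planted structure under known distortions;
they do not certify performance on real cohorts, whose correlation
structure, dropout and annotation noise the generator does not model.

## Numerical choices and degenerate inputs

Duplicate symbols collapse by maximum; missing values are rejected at
ingestion (imputation is not silently applied); constant genes are zeroed
in z-scoring and are an error in correlation clustering (Pearson
undefined); empty matrices are refused on write; a batch with one sample
and a class with fewer samples than folds are errors naming the offender;
EB iteration tolerance 1e−4; SVM KKT tolerance 1e−6 with the iteration
cap above; exact argmax ties in classification and w² ties in RFE have
the deterministic resolutions described.

## Known limitations

Probe-level CEL processing, RNA-seq quantification, kernel SVMs,
calibrated probabilities, nonparametric EB batch adjustment and GO-graph
traversal are out of scope. The zero-fill for missing panel genes biases
margins toward the training mean. The fixed-signature CV mode inherits
the optimism of full-cohort selection (quantified above); the unbiased
mode is provided but slower. The packaged 44-gene panel ships without
per-class provenance because its published description does not record
which subtype's ranking contributed each gene.
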