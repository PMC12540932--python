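# Methods

## Overview

`scexplain` implements an explainable machine-learning route to disease-gene
discovery from single-cell / single-nucleus transcriptomes. Instead of asking
"which genes differ on average between case and control cells" (classical
differential expression), it asks "which genes does a classifier rely on to
recognize a diseased cell", and then compresses that answer into a minimal,
transferable gene signature. The stages are:

1. **Classification.** Cell-by-gene expression (QC-filtered, depth-normalized,
   log-transformed) is split 80/20 into train/test, stratified by condition.
   Feature selection is fit on the training split only. Five stratified
   cross-validation folds yield five models per classifier family, each
   evaluated independently on the held-out 20% with balanced accuracy

       BA = 1/2 ( TP/(TP+FN) + TN/(TN+FP) ),

   with *case* the positive class throughout.
2. **Explanation.** Each correctly classified case cell in the test split is
   explained with a local-surrogate (LIME-style) model; signed per-gene
   importances are aggregated into per-gene Z-scores (below).
3. **Gene-set selection.** Genes with mean importance Z > 1.00 form a ranked
   candidate pool; a percentile-elimination permutation test against
   random-gene benchmarks selects the smallest set maximizing the accuracy
   advantage over random sets.
4. **Validation and prioritization.** Label-randomization controls,
   leave-one-subject-out evaluation, transfer to independent datasets,
   fold-change/importance/annotation filters, and rare-variant burden
   testing of nominated genes.

## Classifier families

Four fixed-hyperparameter families (scikit-learn implementations):

| family | hyperparameters |
|---|---|
| `nn` | one hidden layer, 100 rectified-linear units, Adam, 500-iteration cap |
| `lr` | L1 penalty, inverse regularization strength C = 2.0, liblinear, 100 iterations |
| `rf` | 100 trees, Gini impurity, min split 2, min leaf 1, bootstrap |
| `svm` | linear kernel, C = 1, no iteration cap (probability outputs enabled) |

No hyperparameter search is performed; cross-validation is used for model
multiplicity (five models whose explanations are averaged), not tuning.
Neural-network weight initialization is seeded per fold from the run seed.
Convergence-based stopping (loss-improvement tolerance) is left at the
library default; validation-based early stopping is disabled.

## Feature selection

- **HVG** (default): dispersion-based selection via scanpy's Seurat flavor —
  per-gene mean and dispersion of de-logged normalized expression, dispersion
  z-standardized within 20 mean-bins, keep mean ∈ [0.0125, 3] and normalized
  dispersion ≥ 0.5. Threshold-free: the gene list length is data-driven.
- **PCA**: centered, unit-scaled, on the training split. The retained
  component count comes from a jackstraw-style permutation test: each of
  (default) 100 permutations scrambles 1% of genes across cells and refits
  the PCA; scrambled-gene squared loadings form the per-component null. A
  component's P-value is a one-sided binomial test of the excess of genes
  whose empirical p (against the pooled null) falls below α = 0.05.
  Components are retained in order up to the first with P ≥ 0.05. The
  binomial proportion score was chosen over averaging per-gene p-values
  because a factor loading on a gene subset leaves most genes null, which
  dilutes a mean but not a count of exceedances.
- **NMF**: coordinate-descent factorization (nndsvda initialization, seeded);
  the rank is the Unit Invariant Knee of the reconstruction-error curve over
  k = 1..100 — both axes rescaled to the unit square, knee at the point of
  maximum perpendicular distance to the first-to-last chord.
- External topic-model (or any other) cell-by-factor matrices can be
  substituted at the file boundary between pipeline stages; training such
  models is out of scope.

Whether dimensionality reduction runs on all genes or the HVG subset is
configurable (`genes=` argument); HVG-restricted is the suggested use.

## The local-surrogate explainer

The explainer is implemented natively, following the canonical tabular
recipe, with every knob exposed in `LimeConfig`:

- **Perturbation.** Default: quartile discretization. Each of n (default
  5000) samples redraws every feature's quartile bin uniformly; the
  interpretable representation is the binary vector "same bin as the
  explained cell", and the value fed to the model is the training-split mean
  of the drawn bin. Alternatively (`discretize=False`) perturbations are
  Gaussian in units of each feature's training standard deviation.
  Zero-variance features are never perturbed and receive importance 0.
- **Weighting.** exp(−d²/w²) on Euclidean distance in the interpretable
  representation; kernel width w defaults to 0.75·√(#features).
- **Surrogate.** Ridge regression (penalty 1.0) on the model's case
  probability, weighted by the kernel; the coefficients are the signed
  importances, one per input feature (no top-k truncation).

Explanations are requested from each cross-validation model that classified
the cell correctly, and averaged across models; only test-split cells of
case subjects are explained. Fidelity is verified against linear classifiers
(rank correlation of mean |importance| with |coefficient|·feature scale
≥ 0.9 in the seeded suite).

## Importance aggregation

For subject i with N_i explained cells, gene j:

    F_ij = (1/N_i) Σ_k |LIME_ijk|          (per-subject mean absolute importance)
    F_j  = (1/M)  Σ_i F_ij                 (equal weight per case subject, M subjects)
    P_j  = 100 · C_j / C                   (percent of cells expressing gene j, raw counts)
    N_j  = P_j / Σ_l P_l                   (normalized percent expression, Σ N_j = 1)
    W_j  = N_j · F_j                       (expression-weighted importance)
    Z_j  = (W_j − mean W) / sd W           (population sd over genes; switchable)

Weighting by N_j discourages sparsely expressed genes whose importances
cannot generalize. Genes never observed in the cell type (P_j = 0) get
W_j = 0 and are flagged. The table invariants (Σ N_j = 1; Z mean 0, sd 1 to
1e-9) are asserted in the test suite after every pipeline run.

## Optimal gene sets

Cell type-specific Z-scores are averaged across exploratory datasets
(intersection membership by default; a single dataset passes through with a
warning, as for cell types present in only one dataset). Genes with mean
Z > 1.00 are ranked by descending Z (ties broken lexicographically by gene
id) and given percentile ranks over all scored genes. From the percentile of
Z = 1.00 to 1.00 in steps of 0.001 — thresholds that do not change the
surviving gene count are evaluated once, which is equivalent by construction
— the classifier is retrained on the surviving genes and on (default) 10
equal-size random gene sets, each drawn with a distinct sub-seed from all
detected genes. With ML_LIME and ML_gene the balanced accuracies of the
ranked and random inputs and ΔACC = ML_LIME − ML_gene, the optimal set is

    argmax over the nested threshold family of  Σ_datasets ΔACC_dataset,

ties resolved toward the smallest set. The argmax domain is the nested
family of threshold-induced sets, so every smaller candidate set is a subset
of every larger one.

**Transfer evaluation** retrains the classifier on an independent target
dataset with the optimal set and with random equal-size sets over (default)
10 permutations, optionally down-sampling the majority condition first, and
compares the two accuracy samples with a two-sided rank-sum test.
**Leave-one-subject-out** trains on all subjects but one and scores the
held-out subject's cells; per-subject accuracy is the raw fraction correct
(a subject carries a single condition, so balanced accuracy is undefined at
subject level); medians and mean absolute deviations over re-seeded
training permutations are reported.

## Differential expression and prioritization

The native DE route is the per-cell two-sided rank-sum test on normalized
expression, restricted to genes expressed in ≥ 1% of case or control cells,
Bonferroni-corrected over tested genes; DEGs are adjusted P < 0.05 with
|Log2FC| > 1. Log2FC is the log2 ratio of de-logged normalized means
(case/control) with a 1e-9 pseudocount, pooling datasets when several are
present. Subject-level pseudobulk count tables are exported for external
count-model DE tools (hurdle or negative-binomial models are deliberately
not reimplemented). Cross-dataset consistency is the Jaccard overlap of two
datasets' hit lists (per-set proportions also reported, since "proportion of
overlapping genes" admits either denominator).

Prioritization keeps, per cell type's optimal set: genes that are not
flagged mitochondrial/ribosomal/sex-linked/non-coding (GWAS-implicated genes
are exempt from exclusion), with |Log2FC| > 0.25, and with mean Z > 5.00 in
that cell type or Z > 2.00 plus membership in ≥ 3 cell types' optimal sets.

## Rare-variant burden testing

Missense variants are damaging iff AlphaMissense labels them "pathogenic",
or "ambiguous" with CADD > 20.0 (strict); missing annotations are
conservative (not damaging, warned). Variants with reference allele
frequency ≥ 0.01 are removed (strict <; missing frequency is kept as rare
and flagged). Counting is carrier-based (dominant): carrier counts are
summed over qualifying variants per cohort arm, which assumes carriers of
distinct rare variants are distinct subjects — the approximation forced by
(and appropriate for) public variant-browser count tables. Per cohort, a
two-sided Fisher exact test (P by summation of hypergeometric probabilities
≤ the observed table's; OR = ad/bc, Haldane-corrected on zero margins, via
scipy); across cohorts, the Cochran–Mantel–Haenszel 1-df test with the
Mantel–Haenszel common odds ratio (statsmodels), optional continuity
correction (off by default), empty strata dropped with a warning.
Loss-of-function categories are excluded from reports by default since a
singleton variant category carries no test information.

## Synthetic data generator

The generator emulates the statistical features the pipeline must cope with
in a multi-subject case/control study; it makes no attempt at gene-gene
correlation structure, ambient RNA, or doublets, so passing tests certify
the pipeline's statistical behavior, not robustness to those artifacts.

Count model for cell c of subject i, cell type t, gene g:

    mu[c,g]   = base[g] · subj[i,g] · 2^{effect(t, cond(i), g)} · lib[c]
    count     ~ NB(mean = mu, dispersion θ),   var = mu + mu²/θ

Reference conditions (the defaults, used by the seeded suites and the
acceptance script): 6 case + 6 control subjects × 150 cells, 2000 genes, one
cell type, 20 planted genes at log2 effect 1.0 (two-fold, case cells only).
Unstated parameters were fixed once on field realism:

| parameter | default | rationale |
|---|---|---|
| baseline mean | lognormal(ln 0.5, 1.0) counts/cell | typical snRNA-seq per-gene depth for analysis-grade genes |
| NB dispersion θ | 2.0 | overdispersion in the range reported for UMI counts |
| subject effect | lognormal, sd 0.15 per (subject, gene) | moderate inter-individual variability; creates within-subject correlation that LOSO probes |
| library size | lognormal, sd 0.35 | realistic depth spread |
| planted genes | drawn from the upper half of baseline expression | disease markers must be detectably expressed to be discoverable |

Label randomization redraws a chosen fraction of condition labels uniformly
from {case, control} (a cell may keep its label); a flip mode is available
since either reading of "randomization" is defensible.

## Numerical and design choices

- **Normalization target**: median library size by default (the scanpy
  convention). A fixed 10,000 target is available, but on small simulated
  panels it inflates per-gene normalized means beyond the HVG mean window
  and silently empties the selection; median scaling is invariant to panel
  size.
- **Stratified splits and folds**: the paper's evaluation metric is balanced
  accuracy, which a skewed split degrades; unstratified splitting is behind
  a flag.
- **Model-averaged explanations**: five CV models exist per run; their
  explanations of a cell are averaged before aggregation (per-model output
  is also reachable through `explain_cell`).
- **Population sd in Z**: n-denominator, switchable to n−1.
- **Tie-breaks**: gene-id lexicographic everywhere a ranking can tie, so
  every ranking is deterministic.
- **Degenerate inputs**: zero-total cells normalize to all-zero rows
  (warned); constant-output models yield zero explanations (warned); sd(W)=0
  importance tables and all-below-threshold pools raise.

## Problem sizes in the seeded suites

The test suite and acceptance script run the reference conditions end to end
with these scaling choices (the package's own defaults for batch
experimentation): 1000 surrogate perturbations with at most 15 explained
cells per subject per model in pipeline-level runs (5000 perturbations are
used where fidelity itself is measured); the L1 logistic-regression family
drives the many hundreds of retrainings inside elimination curves and
transfer benchmarks, while the neural network is used for the headline
classification and randomization quantities; elimination and transfer use 10
random-set permutations; calibration checks use 2000 replicates (CMH type-I
error) and 2000 genes (rank-sum null uniformity).

## Known limitations

- Gene-level explanations inherit the classifier's biases; correlated genes
  share credit unpredictably, and the surrogate is only locally faithful.
- The carrier-sum approximation in burden tables can overcount if one
  subject carries several qualifying variants.
- Percent expression is computed on the full matrix (all splits) of the cell
  type, which is a population descriptor, not a fitted parameter — it does
  not leak labels, but it does use test-cell expression.
- The generator's independence across genes makes recovery tests easier than
  real co-expressed modules would be.
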