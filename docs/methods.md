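# Methods

`mwaskit` implements a metagenome-wide association study (MWAS) workflow for
case/control gut-microbiome cohorts: gene-level relative-abundance profiles
are clustered into metagenomic linkage groups (MLGs), tested for differential
enrichment, connected into co-occurrence networks, summarized into
functional-module reporter scores, and mined for cross-validated
random-forest marker panels, with medication-confounder and clinical-index
analyses on top. A synthetic-cohort generator with planted ground truth makes
every stage testable end to end.

## The synthetic cohort generator

The generator is the package's study system, and its assumptions bound what
passing tests demonstrate.

**Community model.** Each genome *g* receives a latent per-sample abundance
`exp(b_g + e_gs)` with a fixed log-location `b_g` (default drawn N(0, 1.5),
giving the heavy-tailed rank-abundance profile typical of gut communities)
and i.i.d. log-normal sample noise `e_gs ~ N(0, dispersion)`, dispersion 1.0
by default. Case samples multiply selected genomes by `2^lfc`
(`case_log2_fold_change`); drug-treated case samples apply additional
per-drug shifts; controls are untreated by construction.

**Gene level.** Each gene carries a fixed log-normal weight
(`gene_weight_sd`, default 1.0). The expected share of gene *i* in sample
*s* is proportional to (genome abundance × gene weight), and counts are
drawn by a single multinomial per sample at `sequencing_depth` (default
100 000 reads over a toy catalog of ~10⁴ genes). Genes of one genome are
therefore exactly proportional in expectation — the co-abundance signal MLG
binning needs — while multinomial noise and optional per-cell zero inflation
(default 0.02 in the pipeline) create the detection dropouts that motivate
the prevalence filter.

**Clinical indices and metadata.** An index tied to a genome is a linear
response to the standardized log relative abundance of that genome plus
Gaussian noise; additional null indices are pure noise. Metadata carries
group, a nominal case subtype, per-drug 0/1 flags, and the indices.

**What it does not emulate.** Read-level noise, strain-level SNP structure,
gene sharing between genomes (each gene belongs to exactly one genome),
compositional interactions beyond closure, covariate structure (age, BMI as
confounders), and batch effects. Passing recovery tests therefore shows the
algorithms are correct under the stated generative model, not that they are
robust to everything real cohorts contain.

**Cohort sizes.** `simulate_cohort` takes explicit case/control counts; the
default pipeline cohort uses 50 genomes of 100–300 genes and 60/60 samples,
a size chosen so a complete run finishes in a few minutes on one core while
keeping per-group n large enough for rank tests and cross-validation.

## Profiles

Relative abundance is per-sample closure (column / column sum); an all-zero
sample is an error. The prevalence filter drops genes detected (abundance
strictly > 0) in fewer than `min_samples` samples (default 10) and does
*not* renormalize afterwards, so MLG sums remain comparable to the full
profile; a flag enables renormalization for sensitivity analysis. Feature
aggregation (genus, KO, enzyme family, virus) sums member-gene abundances
and silently drops unannotated mass — column totals after aggregation are
only the annotated fraction, which is stated here once instead of being
hidden by renormalization. Alignment hit tables reduce to one best
assignment per gene with strict thresholds (identity > 35 %, bit score
> 60, E < 10⁻³ for protein annotation; identity > 65 %, score > 60 for
nucleotide/virus annotation), ties broken by identity then target id.

## MLG binning

The clustering procedure is a deliberately simple, reproducible stand-in for
co-abundance binning: (1) Spearman correlation (midranks) between all gene
pairs; (2) edges at `cc >= cc_threshold` (default 0.6), connected
components; (3) average-linkage agglomeration within each component on
distance `1 − cc`, cut at `1 − cc_threshold`; (4) keep clusters with
strictly more than `min_genes` genes (default 100, so ≥ 101). Genes are
sorted lexicographically before clustering, making the output independent of
input row order; the `seed` parameter exists for interface uniformity only.
Correlations are computed in float32 (the binning decision margin is far
above float32 precision; a 10⁴-gene matrix stays under 1 GB).

Genomes whose latent abundance sits near the detection floor produce
mostly-zero count rows whose rank correlations are weak; such genomes stay
unbinned, exactly as rare organisms do in real co-abundance binning. The
recovery tests therefore score the adjusted Rand index between recovered and
planted partitions **on the binned genes**.

Taxonomy is a reference vote: the fraction of an MLG's genes (annotated or
not) assigned to each candidate genome; assignment requires a strict
majority (> 0.5), and the top three genomes with mean percent identity are
always reported. An optional species-level mean-identity floor is available
but off by default.

## Statistics

* **Differential abundance**: two-sided Wilcoxon rank-sum per feature
  (scipy, exact for small untied samples), Benjamini–Hochberg q-values
  (statsmodels), direction from the rank-sum sign. q-values are computed
  within each feature space (MLGs, genera, KOs, genes) separately.
* **Networks**: Spearman edges at |cc| ≥ 0.3, computed per sample subset
  (case and control networks separately); weight classes thick (> 0.7),
  medium (0.5–0.7), thin (0.3–0.5).
* **Distances**: Bray–Curtis on profiles as given; Jensen–Shannon divergence
  in nats on pseudocounted (10⁻⁹), renormalized profiles; the metric square
  root is available by flag.
* **PERMANOVA**: one-way pseudo-F from among/within sums of squared
  distances, permutation p with the plus-one rule
  `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` — never zero. 999
  permutations by default.
* **Ordination**: PCA by SVD of centered sample profiles, sign fixed so each
  component's largest-magnitude loading is positive. dbRDA embeds the
  distance by principal coordinates (negative eigenvalues dropped, their
  inertia reported; no Lingoes correction), regresses the coordinates on the
  centered group indicator, and SVDs the fitted values into CAP axes;
  feature weights are post-hoc Pearson correlations with axis scores.
* **Reporter scores**: KOs present in strictly more than 5 samples get a
  signed Z from the smaller of the two one-sided Wilcoxon p-values
  (`Z = Φ⁻¹(1 − p)`, positive = case-enriched, clamped at |Z| ≤ 8 to keep
  p ≈ 0 finite). A module of k scored KOs aggregates `Z_raw = ΣZ/√k`,
  corrected by the mean/SD of 1000 random k-sized KO sets. |score| ≥ 1.6
  (one-sided 95 %) flags a module; 1.96 is the two-sided band drawn on
  plots. Z is computed from raw one-tail p by default; a flag switches to
  BH-adjusted p, since the conventional description is ambiguous on the
  order of adjustment. The background-set count (1000) is our default.
* **Permutational Spearman**: |cc|-based label-permutation p, plus-one rule;
  missing values dropped pairwise; constant vectors are an error.
* **Fisher gene content**: two-sided exact test per gene on the 2×2
  occurrence table (scipy), BH across genes.

## Marker selection (RFCV)

Stratified k-fold cross-validation (default 5 folds) repeated (default 5 in
the library function, 3 in the pipeline defaults): inside each training
fold a random forest ranks features by impurity importance — ranking inside
the fold, not once globally, avoids selection leakage, at the cost of a
possible divergence from implementations that rank once; nested top-k panels
(k = 1..max_panel, default 25) are refit and scored on the held-out fold by
misclassification rate. Curves are averaged over folds × repeats; the cutoff
is the curve minimum plus the SD of per-fold errors at that point; the
chosen panel is the smallest size under the cutoff, realized on the
cross-fold aggregate importance ranking. Out-of-fold probabilities are fully nested: each
probability fold re-ranks features on its own training data and refits on
its own top-k (k fixed by the cutoff rule), so neither the panel identity
nor the model fit ever sees the held-out samples — reusing the globally
chosen panel instead inflates null AUCs to ~0.6 through feature-selection
leakage. Forest defaults: 500 trees, √p feature subsampling
(conventional; the pipeline default uses 200 trees for single-core
practicality — both are configuration). Multi-class problems use a
multiclass forest with per-fold downsampling to the smallest class when
`balance=True` (balancing by downsampling rather than explicit one-vs-rest
fits; same intent, fewer moving parts). Regression mode (for clinical
indices) uses regression forests with mean-squared error curves and p/3
feature subsampling.

ROC summaries use the rank-statistic AUC (ties ½), a DeLong asymptotic 95 %
CI, and Youden's index with ties broken toward the lower cutoff (favoring
sensitivity). The TMA-lyase classifier is the same RFCV machinery restricted
to the 4-feature enzyme matrix (CutC/D, YeaW/X); with ≤ 4 features the panel
search is trivially bounded.

## Group LASSO

Implemented in-package (no installed dependency provides group-penalized
logistic regression): proximal gradient (ISTA) with step 1/L from the design
spectral norm, group soft-thresholding with weights √p_g, unpenalized
intercept, warm-started geometric penalty path (20 values from a data-driven
λ_max), λ chosen by 5-fold cross-validated loss, and selection stability
from refits on bootstrap resamples (default 10). The objective decreases
monotonically along iterations (asserted in tests). Logistic loss for binary
responses, squared loss for clinical indices.

## Clinical-index and medication analyses

Per index: regression RFCV pre-selects an MLG panel, then pairs must pass
the permutational Spearman filter (p < 0.05 and |cc| ≥ 0.2; |cc| > 0.25
flagged "strong"). Per drug: three two-way classifiers — treated cases vs
controls, untreated cases vs controls, treated vs untreated cases — each
with AUC and Youden's index (strata smaller than the fold count are marked
not computed), plus a Jensen–Shannon PERMANOVA among cases. The comparison
logic: when disease, not medication, drives the microbiome signal, both
case-vs-control AUCs exceed the treated-vs-untreated AUC.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` generators passed
  explicitly; same seed ⇒ bit-identical outputs; no global state.
* Printed thresholds are implemented exactly as printed and strictly
  (> 35 %, > 60, < 10⁻³, > 100 genes, > 0.5 vote, > 5 samples).
* Differential-abundance FDR calibration is assessed on global-null cohorts:
  planting unbalanced fold changes shifts the *relative* abundance of every
  genome (compositional closure), so non-planted genomes in a planted cohort
  are genuinely non-null in the measured space. The elevated false-discovery
  proportion there (~0.2 in our simulations) is a property of
  relative-abundance MWAS, not of the testing machinery, which is verified
  against exhaustive enumeration and hand-computed BH examples.
* Test and acceptance problem sizes (50 genomes × 100–300 genes × 120
  samples for binning; n = 100/100 for power; 200 samples × 205 features for
  classifier calibration; 5–20 seeds per property) were chosen as the
  smallest scales at which the tested properties are statistically stable.

## Known limitations

* The co-abundance clustering is a documented stand-in for canonical-but-
  unpublished binning heuristics; on real 10⁶–10⁷-gene catalogs the dense
  correlation step would need blocking or sparsification.
* Genus/KO aggregation drops unannotated mass without renormalizing.
* The generator's log-normal independence between genomes understates real
  ecological covariance; co-occurrence networks on synthetic data mostly
  reflect planted fold changes and closure, not interactions.
* dbRDA reports but does not correct negative eigenvalues.
* DeLong CIs assume large-ish samples; a bootstrap CI flag exists for small
  panels.
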