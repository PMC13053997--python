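# Methods

`fittriage` re-implements, as a tested library, a biomarker-discovery and
classification workflow for triaging FIT-positive colorectal-cancer
screening samples from a label-free stool-proteomics abundance matrix. The
clinical question: among people with a positive fecal immunochemical test
(FIT), separate the false positives (G1, no lesion at colonoscopy) from
those with an advanced adenoma (G2) or colorectal cancer (G3), using the
proteins quantifiable in the leftover FIT sample itself. Cases are G2 ∪ G3
throughout; the classifiers output P(case).

This note records the models, the defaults and why they are what they are,
what the synthetic cohort does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## The synthetic cohort

Real cohorts of this kind are not redistributable, so `fittriage.simulate`
generates matrices with the statistical structure the downstream analysis
assumes, plus the ground truth needed for recovery testing. The default
configuration is the study design the pipeline was built around: 141
samples (50 G1 / 45 G2 / 46 G3), 334 protein groups, 4 acquisition batches
balanced by round-robin assignment within group, and an overall
quantification rate of 78%.

The generative model, on the log2 scale:

- **Base signal.** Each protein has location μ_p ~ N(20, 2.5²) and noise
  SD σ_p ~ U(0.6, 1.4); intensities are 2^(signal), giving the heavy right
  tail of LFQ data. These two hyperpriors are placeholders — per-protein
  variance structure of the real data is unpublished.
- **Planted markers.** 15 proteins receive signed log2 shifts in cases
  (magnitudes 1.2–2.4, 8 up / 7 down). G2 receives 0.6× the G3 shift,
  reflecting the subtler proteomic alterations of adenomas. Marker
  locations are drawn from the upper half of the abundance range: a marker
  below the quantification floor is undiscoverable by construction and
  would test the 50% filter rather than the statistics.
- **Collinear block.** Five proteins share a per-sample latent factor with
  target pairwise correlation ρ = 0.998, emulating hemoglobin protein
  groups quantified from overlapping peptide evidence (near-duplicate
  measurements). Because hemoglobin is the FIT analyte, the block sits in
  the high-abundance tail (μ + 2σ), has a wide cross-sample spread
  (σ ~ U(2, 3); fecal hemoglobin varies over orders of magnitude between
  FIT-positive individuals), and receives nuisance effects (batch,
  outliers) coherently — one analyte, one artifact. The block also carries
  a shared case effect (+1.3 log2 in G3).
- **Batch effects.** 25% of proteins get per-batch location shifts
  (SD 0.7 log2) and log-scale factors (SD 0.15). The shift SD is calibrated
  so a one-way F-test flags ≈25% of proteins before correction — partial
  power on small draws plus the α = 0.05 background on unaffected proteins.
- **Missingness.** Cell-wise Bernoulli with logit linear in the centered
  log2 intensity: logit p = a − 4·w·z, where w is `mnar_weight` (default
  0.5) and the intercept a is solved by bisection so the expected missing
  fraction hits the target (default 0.22). The slope constant 4/SD gives
  the steep abundance dependence of DIA label-free data: low-abundance
  cells are preferentially missing and the high-abundance block is ~1%
  missing.
- **Outliers.** A fraction 0.002 of cells get a ±(4–8) log2 bump.

What the generator does **not** emulate: peptide/precursor structure,
retention time, correlated missingness between co-eluting peptides,
microbiome composition, sample-level covariates (age, sex, FIT titre), or
any real biological covariance beyond the planted block. Tests passing on
this cohort therefore demonstrate that the pipeline recovers the structure
it assumes, not that the real data contain that structure.

## Preprocessing

`filter_proteins` keeps proteins quantified in ≥50% of samples (inclusive
boundary) that are inferred to human, exclusively or co-inferred with a
dietary species. The five processing steps then run in a fixed order,
enforced by a `scale_state` tag that refuses out-of-order application:

1. **log2** on observed cells.
2. **Quantile normalization**, tolerant of missing cells: each observed
   value is projected onto the across-column mean quantile curve at its
   within-column rank position; ties receive the average of their target
   quantiles. Complete columns end up with identical sorted values and the
   operation is idempotent. (Treating missing cells as zeros instead is
   possible upstream by filling the matrix before the call; skipping them
   is the default because normalization precedes imputation here.)
3. **Batch correction** by parametric empirical-Bayes location/scale
   adjustment (the ComBat model): standardize each protein using
   size-weighted grand means and pooled variances, estimate per-batch
   per-protein γ and δ², shrink toward batch-level moment-matched
   normal / inverse-gamma priors by fixed-point iteration, adjust, restore.
   Diagnostic group is deliberately not a covariate; when batch and group
   are confounded this removes group signal — with the balanced default
   design they are not. A nonparametric likelihood-weighted prior is
   available behind `parametric=False`. The implementation is cross-checked
   against Bioconductor `sva::ComBat` in the test suite. `assess_batch`
   reports the fraction of proteins with a one-way F-test p < 0.05 before
   and after (≈0.25 → ≤0.07 on the default cohort).
4. **KNN imputation** (k = 10). Default axis: a missing cell (p, s) is the
   mean of the k proteins nearest to p (RMS difference over mutually
   observed samples) that are observed at s — the behavior of the
   Bioconductor impute package, and the reason tightly co-quantified
   families keep their mutual correlation through imputation. The
   transposed variant (nearest samples) is available via
   `axis="samples"`. Distances rescale by the observed-fraction square
   root to correct for unequal overlap; cells with no usable neighbor fall
   back to the protein mean. Observed cells are never altered.
5. **z-score** per protein with population (1/n) SD. The convention is
   irrelevant downstream but fixed for reproducibility; PCA uses the
   matching population covariance so a z-scored panel's eigenvalues sum to
   the feature count.

## Differential abundance

Per protein, a two-sided Mann–Whitney U test of cases vs controls: exact
enumeration for tie-free combined samples ≤12, otherwise the normal
approximation with tie and continuity correction. Fold changes are
case-minus-control means on the log2 (pre-z-score) matrix, where they are
interpretable; the rank test itself is invariant to the per-protein
monotone rescaling.

Multiplicity uses the Benjamini–Krieger–Yekutieli two-stage step-up: BH at
q′ = q/(1+q) estimates m̂₀ = m − r₁, then BH again at q′·m/m̂₀. Whenever
0 < r₁ < m this rejects a superset of plain BH. Per-protein q-values are
defined operationally — the smallest nominal level at which the two-stage
procedure rejects that test — and found by bisection to 1e-6, since BKY is
a rejection procedure rather than a q-value formula. Rejections are
cross-checked against `statsmodels` `fdr_tsbky` in the tests.

## PCA benchmark

The benchmark classifier takes the q < 0.05 panel (after collapsing a
designated redundant family to its representative), runs PCA (SVD of the
population covariance; loading signs fixed so each component's
largest-|loading| entry is positive), retains components by Horn-style
parallel analysis — the leading run of eigenvalues exceeding the 95th
percentile of position-matched eigenvalues from standard-normal matrices
of the same shape (default 1000 simulations; the count is not prescribed
anywhere authoritative) — and fits a maximum-likelihood logistic regression
(IRLS) on the retained scores. On separation a 1e-8 ridge stabilizer is
added and flagged. The benchmark is fit on the full dataset with no split
on purpose: it is an optimistic reference, labeled as such in every
report, never a deployable model.

## Ensemble feature selection

Five selectors run on the training partition only, each `n_runs` times
(default 50) with distinct seeds:

- **rf** — random forest, impurity (Gini) importance by default. This
  matches the R randomForest convention; permutation importance is behind
  `importance="permutation"`.
- **rrf** — a regularized tree ensemble built here on scikit-learn trees:
  features already used by the ensemble are always available to later
  trees, new features enter a tree's candidate set only with probability
  γ = 0.3; importance is accumulated impurity decrease. This penalizes
  redundant feature entry in the spirit of regularized random forests (no
  Python implementation exists); it is deliberately the least stable
  selector.
- **boruta** — shadow-feature permutation testing on scikit-learn forests:
  each iteration appends a shuffled copy of every feature and a feature
  scores a hit when it beats the best shadow importance. Importance = hit
  fraction; confirmed/tentative/rejected status from a two-sided binomial
  test at 15 iterations (enough for the binomial test to separate clear
  hits from clear misses).
- **svm_rfe** — recursive-elimination ranking for an RBF SVM. Kernel SVMs
  expose no coefficients, so the per-feature ranking uses the ROC-AUC
  filter averaged over stratified bootstrap resamples (this is also what
  caret's `rfe` does for `svmRadial`); the SVM itself is cross-validated
  over candidate subset sizes and the chosen size recorded.
- **lasso** — L1 logistic path, 3-fold CV over a log-spaced C grid,
  importance = |coefficient| at the chosen penalty.

Each run's ranking is aggregated by truncated Borda count: rank r ≤ K earns
K − r + 1 points (K = 25), 0 beyond; ties break by mean rank then feature
id. The per-algorithm consensus lists feed a second, identical Borda round
for the final top-25 consensus.

**Stability curves.** For k = 3..25, the mean pairwise Spearman correlation
over runs is computed on the features both runs placed in their top-k,
using full-ranking positions; pairs sharing fewer than two features
contribute 0. Padding absentees with a sentinel rank — or restricting to
the union of the top-k sets — makes independent random rankings strongly
anti-correlated (union membership itself conditions on being top-ranked in
exactly one list); the intersection form is the one whose null sits at
zero, which is what a stability score should do.

## Panel filtering

- **Exclusion list.** Manual spectral review happens upstream of this
  package; its verdict arrives as a list of ids removed by set difference
  (unknown ids warn).
- **VIF pruning.** VIF_j = 1/(1−R²_j) from regressing feature j on the
  rest; the highest-VIF unprotected feature is removed and VIFs recomputed
  until all are below 10. Designated representatives (the hemoglobin stand-
  in) are protected. Perfect collinearity reports +inf and goes first. On
  the default cohort the block's post-processing collinearity sits near the
  VIF-10 boundary — quantile-rank discretization at the abundance tail and
  k = 10 imputation with only four sibling donors attenuate a planted
  ρ ≈ 1 to pairwise r ≈ 0.88–0.97 depending on the seed — so whether the
  final block pair crosses 10 is seed-dependent; on the default seed the
  block collapses exactly to its representative. The real study sat near
  the same boundary (immunoglobulins at VIF 4–6 were kept, hemoglobins
  above 10 removed).
- **ROUT outliers**, constant-model form, per feature within each class
  (G1 and G2/G3): robust location = median, robust scale RSDR = 68.27th
  percentile of |residuals| × n/(n−1), residuals tested outermost-first
  against α_i = Q·(n−i+1)/n using a t tail with n−1 df, stopping at the
  first failure (step-down FDR at Q = 1%). The original software's exact
  small-n constants are unpublished; this formula is the documented one
  here, and Q is exposed. Flags are reported, never auto-removed
  (configurable winsorize/remove/keep, default keep).

## Classification

Stratified 80/20 split with per-class round-half-up train counts — the
unique rule reproducing 113/28 with test counts (10, 9, 9) from class sizes
(50, 45, 46). Events per variable for the default panel: 73 positive
training cases / 16 features ≈ 4.6.

Six algorithms share one contract (fit + class-probability prediction):
random forest, XGBoost, k-NN, penalized logistic regression, polynomial-
kernel SVM (Platt-scaled on held-out folds), and Gaussian naive Bayes.
The penalized logistic model is parametrized like glmnet — mixing α and
penalty λ, mapped to scikit-learn via C = 1/(λn); the pure-ridge and
pure-lasso corners use exact solvers, mixed penalties use saga.

Tuning: 10-fold × 3-repeat stratified CV maximizing AUROC over a grid.
The published study's exact grids live in its supplement and are not
reproduced here; the defaults are conventional (elastic net:
α ∈ {0, .25, .5, .75, 1} × 20 log-spaced λ in [1e-4, 1]) and overridable.
Exact mean-AUROC ties break toward the simpler / more strongly regularized
setting, making tuning deterministic. Overfitting is reported as
Δ = train AUROC − CV AUROC and Δ as a percent of CV AUROC, with <5%
flagged as stable generalization (flag withheld when CV AUROC ≤ 0.5).

Hybrid learning curves: for each training fraction f ∈ {0.1..0.9} and
repeat (default 10), a stratified subsample of size f is fit with the
*fixed* tuned hyperparameters and scored on the complementary hold-out;
mean ± SEM per fraction. Fractions leaving a single-class side are skipped
with a warning.

The held-out 20% is read exactly once, by the final evaluation stage; the
orchestrator's partition accessor counts reads and the report records the
count.

## Evaluation

Confusion counts at threshold 0.5; sensitivity, specificity, balanced
accuracy stored at full precision with whole-percent display by round-half-
up. AUROC by the rank formulation with half credit for ties, 95% CI from
the DeLong structural-components variance; ROC coordinates at every
distinct score. Youden's J picks operating thresholds (ties → lowest
threshold). Correlated ROC curves are compared with the paired DeLong test
(identical scores → p = 1 by convention, zero-variance guard), adjusted
across comparisons by Benjamini–Hochberg. Subgroup reports (G2-only and
G3-only vs G1) accompany every evaluation.

## Interpretation

Kernel SHAP in the weighted-least-squares formulation: coalition values
are marginal expectations of the model output over a background dataset
(default: the training set, which is also the explained set); attributions
solve the Shapley-kernel weighted regression with the local-accuracy
constraint eliminated into the design, so base value + Σφ equals the model
output exactly. Coalitions are enumerated exhaustively when 2^m − 2 fits
the budget and otherwise sampled in complement pairs with size
probabilities proportional to the kernel mass (deterministic given the
seed). Explanations are on the probability scale: φ_j = +0.05 means the
feature raised that sample's predicted G2/G3 probability by five points
relative to the background average. Exactness for linear models and
agreement with exhaustive Shapley enumeration on small feature sets are
asserted in the tests.

## Orchestration and problem sizes

`run_pipeline` chains all stages and writes a JSON + Markdown report with a
manifest (config hash, seed); identical configs reproduce byte-identical
reports. The acceptance script runs the full default cohort with 50
selection runs per algorithm; the end-to-end determinism check and the CLI
examples use a scaled cohort (44 samples, 60 proteins, 3 selection runs)
— determinism and interface contracts do not depend on cohort size, and
the scaled run keeps the whole suite fast.

## Known limitations

- Generator effect sizes and variance hyperpriors are plausible
  placeholders, not estimates from the real data.
- Nested cross-validation is not implemented (single-level tuning is
  knowingly optimistic); probability calibration is out of scope.
- The BKY q-value bisection treats per-test rejection as monotone in the
  nominal level, which holds for the two-stage procedure except at
  measure-zero ties.
- `assess_batch` uses a plain one-way F-test, not a moderated-variance
  test; the quantity is descriptive.
- Kernel SHAP with sampled coalitions is exact for linear models but only
  approximate for others; the exact flag enumerates 2^m coalitions and is
  impractical above ~16 features.
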