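# Methods

## Data model and normalisation

Counts are integer gene × sample matrices. The bulk (mixed-cell) matrix
*M* and the per-cell-type observed matrices are linked by the mixture
model *M ≈ H × F* (fractions *F*, population profiles *H*); the object
being imputed is the sample-indexed tensor *G* (gene × cell type ×
sample).

Low-expressed genes are removed on **raw counts**, before normalisation:
a gene is kept iff its CPM reaches the threshold (default 0.836,
equivalent to 10 reads in an 11.95-million-read library) in at least
`min_samples` samples (default 96) **and** its total count is at least
`min_total` (default 15). The full group-size heuristic of
`filterByExpr`-style filtering is deliberately reduced to these three
explicit parameters: the printed rule is exactly reproducible, the
internal heuristic is not. Group labels (e.g. cell type per column) are
accepted and logged for provenance only.

TPM is computed on the filtered gene set (counts divided by gene length
in bp, column-scaled to 1e6; gene lengths are supplied as a table — the
package takes no position on transcript- vs union-exon length), and all
modelling happens on log2(TPM+1). The pseudocount is 1.

## Pseudobulk simulator

The generator emulates the construction of pseudobulk mixtures from
single-cell data with known composition:

* **Cell pools.** For each cell type × condition (untreated `UT` vs
  stimulated `3hCA`) × chemistry batch (`V2`/`V3`), a pool of
  `pool_cells` cells is simulated with negative-binomial counts
  (Gamma–Poisson; dispersion = NB size, `inf` → Poisson) around
  mean = μ_gc × conditionEffect_g × batchFactor_g × cellSizeFactor.
* **Sharp nulls by common random numbers.** Within each (cell type,
  batch), the stimulated pool reuses the untreated pool's cells for
  unaffected genes; only condition-affected gene columns are
  re-simulated at the scaled mean 2^lfc. With independent pools, every
  unaffected gene would inherit a shared finite-pool mean offset between
  conditions (all samples draw from the same pools), which at n = 160 is
  reliably detectable and would contaminate the null. Sharing the cells
  makes the condition null exact by construction.
* **Fractions.** Per-sample fractions are drawn component-wise
  Normal(mean_c, sd_c) with the per-type means (SD) 42.74 (4.30), 28.12
  (2.40), 26.29 (6.21), 2.85 (0.36) percent for CD4/CD8/CD14/CD19,
  truncated at 0 and renormalised to sum to 1 (an all-non-positive draw
  is redrawn and logged; at these parameters this is astronomically
  rare). Note the renormalised means carry a small deterministic ratio
  bias relative to the source means (delta method: −σ_c²/S² + m_c·σ²_tot/S³,
  at most ~0.3 percentage points here); tests assert against this
  expectation, not the raw means.
* **Assembly.** A sample's ground-truth slab for cell type c is the sum
  of counts over `cells_per_type` (default 5000) cells drawn from the
  pool matching its condition and batch; its bulk column is the sum over
  cell types of counts from `largest_remainder(fractions × mixture_total_cells)`
  cells (default total 5000, chosen symmetric with the per-type sum so
  library sizes stay comparable; remainder ties go to the later
  component). Mixture cells are by default drawn from the full pool
  independently of the truth draw — the conservative reading of "drawn
  from the cell-type expressions obtained in the previous step" — with a
  `shared_draws` mode drawing them from the truth subset instead.
  Sampling is without replacement whenever the source suffices, else
  with replacement (warned). Conditions and batches are assigned to
  samples by seeded fair coin flips.
* **Split.** The first half of samples is the training superset, the
  second half the fixed test set; training-size sweeps subsample the
  training half only, so all sweep points share one test set.

### Default parameters (desk scale)

The default study has 160 samples (80/80 split), 4 cell types and
`n_genes = 300` — a deliberately down-scaled transcriptome that keeps a
full two-method, four-cell-type study to a couple of minutes on one CPU.
Gene base means are log-normal(log 0.02, sd 1.8) transcripts per cell
(UMI-scale sparsity: median ~0.02, long right tail), modulated per cell
type by log-normal(0, 0.5); NB dispersion 0.5; per-cell size factors
log-normal(0, 0.3); batch factor per gene log-normal(0, 0.15) for V3;
10% of genes per cell type are condition-affected with
log2FC ~ N(0, 0.5) resampled to |lfc| ≥ 0.25. The floor keeps affected
genes separable in principle from the compositional shifts TPM induces
in unaffected genes (every gene moves when the library total moves —
with 300 genes these shifts reach a few hundredths of a log2 unit, so
arbitrarily small planted effects would be unidentifiable at any n).
Pools hold 20,000 cells so the 5000-cell draws are a minority fraction.

### What the simulator does not emulate

All samples of a condition/batch stratum draw from the same cell pools,
so between-sample biological variation (eQTLs, individual effects) is
absent — between-sample noise is purely subsampling noise. There are
only two conditions, no doublets or ambient RNA, no empirical
mean–dispersion relationship, and 300 genes rather than ~15,000.
Passing tests therefore demonstrate correctness of the machinery and
qualitative behaviour (attenuation, sensitivity/specificity trade-offs),
not real-data performance levels.

## Chunking

Genes are sorted lexicographically by id (making the partition invariant
to input order), then clustered by complete-linkage agglomeration on
Euclidean distances between training expression profiles. The dendrogram
is cut statically into ⌈n/500⌉ groups (the minimum multiple of the
500-gene bound holding all genes). Each oversized group is re-clustered
and re-cut with a minimum-cluster-size constraint starting at 250 and
relaxing by 5 until a cut exists whose groups all fit the bound; if none
exists even at minimum size 1, the group is hard-bisected by dendrogram
leaf order (warned). The bound is inclusive (≤ 500) and parameterised.
This height-based constrained re-cut approximates the published dynamic
hybrid tree-cut; the contract relied on downstream — a disjoint,
exhaustive partition with bounded, co-expression-coherent chunks — is
identical, and exact replication of that algorithm is out of scope.

## Penalised multi-response fitting

Predictors (all bulk genes) are standardised on training data (zero
mean, unit population variance); responses are centred via the
intercept. The objective is (1/2n)Σ‖y − β₀ − Bᵀx‖² + λP(B) with
P = Σⱼ‖Bⱼ·‖₂ for the group LASSO (solved by scikit-learn's multi-task
coordinate descent) and P = ½‖B‖²_F for ridge (solved in closed form via
one SVD for the whole path). Coefficients are mapped back to the
original predictor scale; exact group sparsity is preserved in the
mapping.

The λ path is log-spaced over `n_lambda` values (default 100 for the
standalone fitter, 50 in the pipeline) from λ_max — the smallest λ with
an all-zero group-LASSO solution, maxⱼ‖xⱼᵀY_c‖₂/n — down to
λ_max × `min_ratio` (default 0.01 when n < p, else 1e-4). Ridge shares
the same grid divided by a reference mixing constant of 1e-3 (a pure L2
penalty has no finite λ_max). λ is chosen as the arg-min of mean 5-fold
cross-validated MSE (no one-standard-error rule), ties to the larger λ;
folds are contiguous blocks of a single seeded shuffle, with the fold
seed offset by chunk index. The final model is refit on all training
samples at the selected λ.

Coordinate-descent tolerance is 1e-3 (scikit-learn's duality-gap-scaled
criterion) with at most 10,000 passes: on these strongly correlated
expression designs, 1e-3 yields fits prediction-indistinguishable from
1e-5 (in-sample R² agreeing to 5 decimals) at ~70× less cost; tests that
need certified optima pass tighter tolerances explicitly. Predictions
are not clipped at zero by default (log2(TPM+1) targets are non-negative
but linear predictions may dip below); `clip_at_zero` is available.

The **baseline mean predictor** returns the training mean profile for
every test sample. Its per-gene correlation with observed test
expression is undefined (zero prediction variance) and is reported
missing; where an ordering against it is needed, the undefined
correlation is treated as 0.

## Differential expression

Per-gene OLS against a shared design (intercept + tested phenotype +
optional covariates; rank-deficiency is an error naming the collinear
columns), followed by empirical-Bayes moderation: the prior (d₀, s₀²) is
estimated by moment matching on log residual variances (digamma/trigamma
inversion, Newton); the posterior variance is
(d₀s₀² + d·s_g²)/(d₀ + d); moderated t is referred to a t distribution
with d₀ + d degrees of freedom, capped at the pooled residual df across
genes. When the observed variances are no more dispersed than sampling
noise (d₀ = ∞) the prior variance is the plain mean of the sample
variances, so equal variances pass through unshrunk. Zero-variance genes
are excluded from prior estimation (logged). Only the phenotype
coefficient is tested; no trend or robust variants. BH step-up adjusts
p-values. The implementation is cross-checked in the test suite against
a naive per-gene reimplementation (1e-8) and against the reference R
implementation of moderated t statistics (1e-6).

## Recovery evaluation

Ten phenotypes are simulated from PCA of the observed cell-type
expression over all samples (genes centred, not scaled; samples as
observations; PCs 1–10): continuous = raw PC score + standard normal
error (noise added to unscaled scores, as literally specified; a
scale-relative option exists but is off); binary = 1 where score > 0
(exact zero → control). The pipeline's default phenotype is the
stimulation condition itself, with batch as optional covariate.

Arm 1 of the paired DGE uses observed expression for all samples; arm 2
substitutes imputed expression for test samples only; both share one
design and the gene intersection of the two data sets. Per-gene recovery
status at thresholds (fdr_obs = 0.05, fdr_imp): **Yes-Sig** (significant
in both, same effect direction), **Yes-NS** (non-significant in both),
**No** (everything else). Sensitivity = Yes-Sig / observed-significant;
specificity = Yes-NS / observed-non-significant; Err = No / all.
Sweeping fdr_imp over 0:0.05:1 gives ROC points (1 − spec, sens),
anchored at (0,0) and (1,1) before trapezoidal integration (direction
mismatches can keep the empirical curve from reaching (1,1)).
Log-fold-change attenuation is the OLS slope of imputed on observed
logFC.

### Known limitation: the baseline is strong on recovery AUC

The mean-profile baseline's arm 2 still contains all observed training
samples, so it amounts to "truth at half the sample size", and its
constant test half can generate no false positives — it holds
specificity 1.0 deep into the FDR sweep. Trained models impute genuine
test-half signal (much higher sensitivity at FDR 0.05, e.g. ~0.9 vs
~0.5) but import bulk-borne compositional and cross-cell-type condition
signal as false positives. On the coarse 21-point FDR grid, whose first
informative threshold is 0.05, the models' discrimination is largely
spent below the first grid point, and the end-to-end suite finds their
recovery AUC does **not** uniformly exceed the baseline's, while their
median per-gene correlation always does. The recovery AUC should
therefore be read alongside sensitivity/specificity at the operating
threshold, not alone.

## Reproducibility

Every stochastic step takes an explicit seed; the pipeline expands one
global seed into per-stage seeds by fixed offsets (simulation +0,
training +10,000 + 1000·cell-type + 500·lasso + chunk index, phenotypes
+7,001, derangement pairing +9,002) and records them in `manifest.json`.
Re-running a config reproduces all artefacts; completed stages are
skipped unless forced.
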