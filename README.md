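# ctimpute

Imputation of **sample-level cell-type-specific gene expression** from
mixed-cell (bulk) RNA-seq, using chunked multi-response penalised
regression, together with a pseudobulk simulator with known ground truth
and an evaluation framework built around a differential-gene-expression
(DGE) *recovery* statistic.

## The problem

Bulk RNA-seq of mixed cell populations (e.g. PBMC) is cheap, but masks
expression patterns confined to individual cell populations.
Deconvolution methods estimate cell fractions and population-average
cell-type profiles from the mixture model *m = H × f* (observed bulk
profile *m*, latent gene × cell-type expression *H*, cell fractions *f*),
but per-individual cell-type profiles — the gene × cell-type × sample
tensor *G* — are needed for downstream analyses such as relating
cell-type expression to quantitative traits.

`ctimpute` takes a different, training-based route: given a training set
of subjects with **both** bulk and sorted-cell (CD4/CD8 T cells, CD14
monocytes, CD19 B cells) RNA-seq, it learns, per cell type, a direct
regression from bulk expression to cell-type expression and applies it to
subjects with bulk data only.

## The model

For each cell type, target genes are first partitioned into
**co-expression chunks** of at most 500 genes (hierarchical clustering of
training expression profiles on Euclidean distance, with a recursive
minimum-cluster-size re-cut for oversized groups). For each chunk, a
**multi-response penalised linear model** maps bulk expression of *all*
genes x to the chunk's cell-type expression y on the log2(TPM+1) scale:

    minimise (1/2n) Σᵢ ‖yᵢ − β₀ − Bᵀxᵢ‖²  +  λ·P(B)

with either the group-LASSO penalty P(B) = Σⱼ ‖Bⱼ·‖₂ (`lasso`; a
predictor's coefficients are zero for *all* chunk genes or nonzero for
all, sharing information across correlated targets) or the ridge penalty
P(B) = ½‖B‖²_F (`ridge`). λ is selected by 5-fold cross-validation
minimising mean squared error over a log-spaced path, and the model is
refit on all training samples.

Evaluation compares imputed with observed cell-type expression via
per-gene / per-subject Pearson correlation and standardised RMSE, and via
**DGE recovery**: differential expression (per-gene linear models with
empirical-Bayes moderated standard errors and Benjamini–Hochberg FDR) is
run twice — on fully observed data (truth, FDR 0.05) and on observed
training + imputed test data — and the agreement of the calls, swept over
the imputed-data FDR threshold from 0 to 1 in steps of 0.05, is
summarised as an ROC curve and its AUC.

## Worked example

A complete simulated study — pseudobulk generation, filtering and TPM
normalisation, chunking, training, imputation and evaluation — in a few
lines (about a minute on one CPU):

```python
from ctimpute import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo", seed=7, n_samples=60,
    sim=dict(n_genes=120, pool_cells=4000, cells_per_type=1500,
             mixture_total_cells=1500),
    alphas=("ridge", "lasso"), n_lambda=30, min_samples=60,
)
summary = run_pipeline(cfg, force=True)
cols = ["method", "cell_type", "median_r_gene", "median_r_subject",
        "auc", "lfc_slope"]
print(summary[cols].round(3).to_string(index=False))
```

prints

```
  method cell_type  median_r_gene  median_r_subject   auc  lfc_slope
   ridge       CD4          0.785             0.980 0.833      0.710
   lasso       CD4          0.797             0.981 0.833      0.753
   ridge       CD8          0.518             0.971 0.968      0.797
   lasso       CD8          0.496             0.974 0.968      0.852
   ridge      CD14          0.651             0.974 0.819      0.793
   lasso      CD19          0.579             0.979 0.833      0.735
   ...
baseline       CD4            NaN             0.979 0.889      0.489
```

Reading the numbers: `median_r_gene` is the median across genes of the
correlation between observed and imputed test expression (the baseline —
the training mean profile repeated for every test subject — has no
between-sample variation, so its per-gene correlation is undefined);
`median_r_subject` is the same across genes within a subject, and is high
for every method because cell-type identity dominates expression
variance; `auc` is the DGE-recovery AUC for the stimulation-condition
phenotype; `lfc_slope` is the regression slope of imputed on observed
log2 fold changes — below 1, showing the characteristic attenuation of
effect sizes in imputed data (mean-profile imputation halves them;
trained models recover ~0.7–0.85).

The same run is available from the shell:

```sh
ctimpute run-all --out demo --seed 7 --config demo.yaml
```

Each run directory contains the simulated data, chunk tables, serialised
models, imputed expression matrices, per-phenotype recovery curves, a
summary TSV and a `manifest.json` recording every stage seed.

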