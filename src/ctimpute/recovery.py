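"""Evaluation of imputed cell-type expression: correlation/RMSE metrics,
PCA-derived phenotype simulation, paired differential-expression analysis,
recovery classification and the FDR-sweep ROC/AUC statistic.

The recovery statistic asks: if differential-expression analysis on fully
observed cell-type data (training + test samples) is the truth at FDR
0.05, how well does the real-world analysis — observed training data plus
*imputed* test data — recover those calls?  Sweeping the FDR threshold of
the imputed-data arm from 0 to 1 in steps of 0.05 traces an ROC curve
whose AUC summarises recovery for one simulated phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .dge import DesignMatrix, ModeratedResult, run_dge

logger = logging.getLogger("ctimpute")

DEFAULT_FDR_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSet:
    """Simulated phenotypes correlated with observed cell-type expression.

    Phenotype j is derived from principal component j of the observed
    expression (samples as observations, genes centred): the continuous
    version is the PC score plus standard normal noise; the binary version
    is 1 where the score is strictly positive, else 0.
    """

    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_phenotypes) raw PC scores
    continuous: np.ndarray
    binary: np.ndarray
    seed: int

    @property
    def n_phenotypes(self) -> int:
        return self.scores.shape[1]


def simulate_phenotypes(
    expr: np.ndarray, sample_ids, n_phenotypes: int = 10, seed: int = 0
) -> PhenotypeSet:
    """PCA-derived continuous and binary phenotypes for every sample.

    ``expr`` is the gene x sample observed log2 expression over *all*
    samples (training + test).  Genes are centred but not scaled.
    """
    expr = np.asarray(expr, dtype=float)
    n_samples = expr.shape[1]
    if n_samples <= n_phenotypes:
        raise ValueError("need more samples than phenotypes")
    if np.allclose(expr, expr[:, [0]]):
        raise ValueError("constant expression matrix: PCA undefined")
    X = expr.T  # samples x genes; PCA centres columns (genes)
    scores = PCA(n_components=n_phenotypes, svd_solver="full").fit_transform(X)
    rng = np.random.default_rng(seed)
    continuous = scores + rng.standard_normal(scores.shape)
    binary = (scores > 0).astype(int)  # exact zero -> control
    return PhenotypeSet(list(sample_ids), scores, continuous, binary, seed)


# ---------------------------------------------------------------------------
# paired DGE
# ---------------------------------------------------------------------------

def run_paired_dge(
    obs_slab: np.ndarray,
    obs_gene_ids,
    imp_slab: np.ndarray,
    imp_gene_ids,
    sample_ids,
    train_ids,
    test_ids,
    phenotype: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
) -> tuple[ModeratedResult, ModeratedResult]:
    """Differential expression on observed vs train-observed + test-imputed data.

    Arm 1 (truth) uses observed expression for all samples; arm 2 replaces
    the test-sample columns with imputed expression.  Both arms share the
    same design and the same gene set (the intersection of observed and
    imputed genes).  ``phenotype`` and covariate vectors align with
    ``sample_ids`` = training + test order.
    """
    obs_slab = np.asarray(obs_slab, dtype=float)
    imp_slab = np.asarray(imp_slab, dtype=float)
    common = [g for g in obs_gene_ids if g in set(imp_gene_ids)]
    if not common:
        raise ValueError("no genes common to observed and imputed data")
    obs_pos = {g: i for i, g in enumerate(obs_gene_ids)}
    imp_pos = {g: i for i, g in enumerate(imp_gene_ids)}
    obs = obs_slab[[obs_pos[g] for g in common]]
    imp = imp_slab[[imp_pos[g] for g in common]]

    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    tr = [sample_pos[s] for s in train_ids]
    te = [sample_pos[s] for s in test_ids]
    order = tr + te
    expr_obs = obs[:, order]
    imp_sample_pos = {s: i for i, s in enumerate(test_ids)}
    expr_mix = np.concatenate(
        [obs[:, tr], imp[:, [imp_sample_pos[s] for s in test_ids]]], axis=1
    )

    ordered_ids = [sample_ids[i] for i in order]
    pheno = np.asarray(phenotype, dtype=float)[order]
    covs = {k: np.asarray(v, dtype=float)[order] for k, v in (covariates or {}).items()}
    design = DesignMatrix.build(ordered_ids, pheno, covs)
    return run_dge(expr_obs, common, design), run_dge(expr_mix, common, design)


# ---------------------------------------------------------------------------
# recovery classification and ROC
# ---------------------------------------------------------------------------

@dataclass
class RecoveryClassification:
    """Per-gene recovery statuses and summary rates at fixed FDR thresholds."""

    gene_ids: list[str]
    status: np.ndarray  # "Yes-Sig" | "Yes-NS" | "No"
    sensitivity: float | None  # None when no observed-significant genes
    specificity: float | None
    err: float


@dataclass
class RecoveryCurve:
    """Sensitivity/specificity over the imputed-FDR grid, plus AUC."""

    fdr_obs: float
    grid: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fdr_imputed": self.grid, "sensitivity": self.sensitivity,
             "specificity": self.specificity}
        )


def classify_recovery(
    obs: ModeratedResult,
    imp: ModeratedResult,
    fdr_obs: float = 0.05,
    fdr_imp: float = 0.05,
) -> RecoveryClassification:
    """Classify each gene as Yes-Sig, Yes-NS or No.

    Yes-Sig: significant in both arms with the same effect direction;
    Yes-NS: non-significant in both arms; No: everything else (error).
    Sensitivity = Yes-Sig / observed-significant; specificity =
    Yes-NS / observed-non-significant; Err = No / all genes.
    """
    if list(obs.gene_ids) != list(imp.gene_ids):
        raise ValueError("observed and imputed results must cover the same genes")
    obs_sig = obs.fdr < fdr_obs
    imp_sig = imp.fdr < fdr_imp
    same_dir = np.sign(obs.logfc) == np.sign(imp.logfc)
    yes_sig = obs_sig & imp_sig & same_dir
    yes_ns = ~obs_sig & ~imp_sig
    status = np.where(yes_sig, "Yes-Sig", np.where(yes_ns, "Yes-NS", "No"))
    n_obs_sig = int(obs_sig.sum())
    n_obs_ns = int((~obs_sig).sum())
    sens = float(yes_sig.sum() / n_obs_sig) if n_obs_sig else None
    spec = float(yes_ns.sum() / n_obs_ns) if n_obs_ns else None
    err = float((status == "No").sum() / len(status))
    return RecoveryClassification(list(obs.gene_ids), status, sens, spec, err)


def recovery_curve(
    obs: ModeratedResult,
    imp: ModeratedResult,
    fdr_obs: float = 0.05,
    grid: np.ndarray = DEFAULT_FDR_GRID,
) -> RecoveryCurve:
    """ROC over the imputed-data FDR grid; AUC by trapezoid.

    ROC points are (1 - specificity, sensitivity) per grid threshold,
    anchored at (0, 0) and (1, 1) before integration (direction mismatch
    can keep the empirical curve from reaching (1, 1)).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted ascending")
    sens = np.empty(grid.size)
    spec = np.empty(grid.size)
    for i, thr in enumerate(grid):
        cls = classify_recovery(obs, imp, fdr_obs=fdr_obs, fdr_imp=thr)
        if cls.sensitivity is None:
            raise ValueError("no observed-significant genes: curve undefined")
        sens[i] = cls.sensitivity
        spec[i] = 1.0 if cls.specificity is None else cls.specificity
    x = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    y = np.concatenate([[0.0], sens, [1.0]])
    order = np.lexsort((y, x))
    auc = float(np.trapezoid(y[order], x[order]))
    return RecoveryCurve(fdr_obs, grid, sens, spec, auc)


# ---------------------------------------------------------------------------
# correlation / RMSE metrics
# ---------------------------------------------------------------------------

def _aligned_test(obs_slab, obs_gene_ids, obs_sample_ids,
                  imp_slab, imp_gene_ids, imp_sample_ids, test_ids):
    common = [g for g in obs_gene_ids if g in set(imp_gene_ids)]
    obs_pos = {g: i for i, g in enumerate(obs_gene_ids)}
    imp_pos = {g: i for i, g in enumerate(imp_gene_ids)}
    so = {s: i for i, s in enumerate(obs_sample_ids)}
    si = {s: i for i, s in enumerate(imp_sample_ids)}
    O = np.asarray(obs_slab, float)[np.ix_([obs_pos[g] for g in common],
                                           [so[s] for s in test_ids])]
    I = np.asarray(imp_slab, float)[np.ix_([imp_pos[g] for g in common],
                                           [si[s] for s in test_ids])]
    return common, O, I


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r per row; NaN where either row has (numerically) zero variance."""
    def _centred_and_degenerate(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        ss = (Mc**2).sum(axis=1)
        scale = np.abs(M).max(axis=1, initial=0.0)
        degenerate = ss <= (1e-9 * scale) ** 2 * M.shape[1]
        return Mc, ss, degenerate

    Ac, ssa, dega = _centred_and_degenerate(A)
    Bc, ssb, degb = _centred_and_degenerate(B)
    num = (Ac * Bc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(ssa * ssb)
    r[dega | degb] = np.nan
    return r


def per_gene_metrics(
    obs_slab, obs_gene_ids, obs_sample_ids,
    imp_slab, imp_gene_ids, imp_sample_ids, test_ids,
) -> pd.DataFrame:
    """Per-gene Pearson r and standardised RMSE across test samples.

    RMSE is divided by the gene's mean observed expression.  Genes whose
    observed (or imputed) test expression has zero variance get r = NaN.
    """
    if len(test_ids) < 3:
        raise ValueError("need at least 3 test samples")
    genes, O, I = _aligned_test(obs_slab, obs_gene_ids, obs_sample_ids,
                                imp_slab, imp_gene_ids, imp_sample_ids, test_ids)
    r = _rowwise_pearson(O, I)
    rmse = np.sqrt(((O - I) ** 2).mean(axis=1))
    mean_obs = O.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmse_std = rmse / mean_obs
    rmse_std[mean_obs == 0] = np.nan
    return pd.DataFrame({"gene": genes, "r": r, "rmse_std": rmse_std})


def per_subject_metrics(
    obs_slab, obs_gene_ids, obs_sample_ids,
    imp_slab, imp_gene_ids, imp_sample_ids, test_ids,
) -> pd.DataFrame:
    """Per-subject Pearson r and RMSE across genes (one estimate per subject)."""
    if len(test_ids) < 1:
        raise ValueError("need at least 1 test sample")
    genes, O, I = _aligned_test(obs_slab, obs_gene_ids, obs_sample_ids,
                                imp_slab, imp_gene_ids, imp_sample_ids, test_ids)
    if len(genes) < 3:
        raise ValueError("need at least 3 common genes")
    r = _rowwise_pearson(O.T, I.T)
    rmse = np.sqrt(((O - I) ** 2).mean(axis=0))
    return pd.DataFrame({"sample": list(test_ids), "r": r, "rmse": rmse})


def _seeded_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least 2 subjects for a derangement")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def baseline_correlations(
    obs_slab, obs_gene_ids, obs_sample_ids,
    imp_slab, imp_gene_ids, imp_sample_ids, test_ids, seed: int = 0,
) -> pd.DataFrame:
    """Mismatched-subject baseline correlations.

    Two baselines per test subject i, under a seeded derangement j(i) != i:
    (a) observed profile of subject i vs *imputed* profile of subject j(i);
    (b) observed profile of subject i vs *observed* profile of subject j(i).
    """
    genes, O, I = _aligned_test(obs_slab, obs_gene_ids, obs_sample_ids,
                                imp_slab, imp_gene_ids, imp_sample_ids, test_ids)
    rng = np.random.default_rng(seed)
    perm = _seeded_derangement(len(test_ids), rng)
    r_obs_imp = _rowwise_pearson(O.T, I.T[perm])
    r_obs_obs = _rowwise_pearson(O.T, O.T[perm])
    return pd.DataFrame(
        {"sample": list(test_ids),
         "mismatched_sample": [test_ids[j] for j in perm],
         "r_obs_vs_imp_mismatched": r_obs_imp,
         "r_obs_vs_obs_mismatched": r_obs_obs}
    )


def attenuation_slope(obs_logfc: np.ndarray, imp_logfc: np.ndarray) -> tuple[float, float]:
    """OLS slope (and R^2) of imputed log2 fold changes on observed ones.

    A slope below 1 indicates shrinkage of effect sizes in imputed data.
    """
    obs_logfc = np.asarray(obs_logfc, dtype=float)
    imp_logfc = np.asarray(imp_logfc, dtype=float)
    if obs_logfc.size < 3:
        raise ValueError("need at least 3 genes")
    if np.var(obs_logfc) == 0:
        raise ValueError("zero variance in observed log fold changes")
    fit = stats.linregress(obs_logfc, imp_logfc)
    return float(fit.slope), float(fit.rvalue**2)
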