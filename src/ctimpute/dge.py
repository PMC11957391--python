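"""Per-gene linear-model differential expression with moderated standard errors.

For each gene, ordinary least squares is fit against a shared design matrix
(intercept + tested phenotype + optional nuisance covariates) on log2-scale
expression.  Residual variances are then shrunk towards a common prior by
empirical Bayes: the prior degrees of freedom d0 and prior variance s0^2
are estimated by moment matching on log residual variances
(digamma/trigamma inversion), the posterior variance of gene g is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t statistic coef_g / (s~_g * sqrt(v_g)) is referred to a
t distribution with d0 + d_g degrees of freedom.  Multiplicity is handled
by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("ctimpute")


@dataclass
class DesignMatrix:
    """Sample x coefficient design; ``phenotype`` names the tested column."""

    sample_ids: list[str]
    matrix: np.ndarray  # (n_samples, n_coefs)
    columns: list[str]
    phenotype: str = "phenotype"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("design shape does not match ids/columns")
        if self.phenotype not in self.columns:
            raise ValueError(f"tested column {self.phenotype!r} not in design")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < len(self.columns):
            # name columns involved in the collinearity via QR diagonal
            _, R = np.linalg.qr(self.matrix)
            diag = np.abs(np.diag(R))
            bad = [self.columns[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
            raise ValueError(f"rank-deficient design; collinear column(s): {bad}")

    @classmethod
    def build(cls, sample_ids, phenotype_values, covariates=None,
              phenotype: str = "phenotype") -> "DesignMatrix":
        """Intercept + phenotype + optional covariates (dict name -> values)."""
        cols = {"intercept": np.ones(len(sample_ids)), phenotype: phenotype_values}
        for name, vals in (covariates or {}).items():
            cols[name] = np.asarray(vals, dtype=float)
        return cls(
            list(sample_ids),
            np.column_stack(list(cols.values())),
            list(cols.keys()),
            phenotype=phenotype,
        )


@dataclass
class LinearFits:
    """Per-gene OLS results for the tested coefficient."""

    gene_ids: list[str]
    coef: np.ndarray  # tested coefficient per gene (log2 units)
    sigma2: np.ndarray  # residual variance per gene
    df_resid: float  # n - rank(design), shared
    v_unscaled: float  # unscaled variance of the tested coefficient, shared


@dataclass
class ModeratedResult:
    """Moderated-t differential-expression results."""

    gene_ids: list[str]
    logfc: np.ndarray
    sigma2: np.ndarray
    df_resid: float
    t: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    d0: float
    s02: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "logFC": self.logfc, "t": self.t,
             "p": self.p, "fdr": self.fdr}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def fit_gene_linear_models(
    expr: np.ndarray, gene_ids, design: DesignMatrix
) -> LinearFits:
    """Vectorised per-gene OLS of log2 expression on the design matrix."""
    expr = np.asarray(expr, dtype=float)
    X = design.matrix
    n, p = X.shape
    if expr.shape[1] != n:
        raise ValueError("expression columns must align with design rows")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ expr.T  # (p, n_genes)
    resid = expr.T - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    j = design.columns.index(design.phenotype)
    return LinearFits(
        gene_ids=list(gene_ids),
        coef=beta[j],
        sigma2=sigma2,
        df_resid=float(df),
        v_unscaled=float(XtX_inv[j, j]),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from residual variances.

    Matches the mean and variance of log sigma^2 under the scaled-F model:
    with e_g = log s_g^2 - digamma(d/2) + log(d/2), the excess variance of
    e over trigamma(d/2) identifies trigamma(d0/2), and the mean identifies
    s0^2.  Returns d0 = inf when the observed variances are no more
    dispersed than sampling noise alone.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.size < 2:
        raise ValueError("need at least 2 genes to estimate the prior")
    z = np.log(sigma2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    evar = evar - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # variances no more dispersed than sampling noise: infinite prior df,
        # prior variance = plain mean of the sample variances
        d0 = np.inf
        s02 = float(sigma2.mean())
    return d0, s02


def ebayes_moderate(fits: LinearFits) -> ModeratedResult:
    """Empirical-Bayes moderation of per-gene residual variances."""
    sigma2 = fits.sigma2
    positive = sigma2 > 0
    n_zero = int((~positive).sum())
    if n_zero == sigma2.size:
        raise ValueError("all residual variances are zero")
    if n_zero:
        logger.info("ebayes_moderate: %d zero-variance genes excluded from prior "
                    "estimation", n_zero)
    d0, s02 = estimate_prior(sigma2[positive], fits.df_resid)
    d = fits.df_resid
    if np.isinf(d0):
        post_var = np.full_like(sigma2, s02)
    else:
        post_var = (d0 * s02 + d * sigma2) / (d0 + d)
    # total df capped at the pooled residual df across genes, so an
    # infinite prior df still yields a proper (if nearly normal) reference
    df_pooled = d * sigma2.size
    df_total = min(d0 + d, df_pooled)
    t = fits.coef / np.sqrt(post_var * fits.v_unscaled)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    fdr = bh_adjust(p)
    return ModeratedResult(
        gene_ids=list(fits.gene_ids),
        logfc=fits.coef,
        sigma2=sigma2,
        df_resid=d,
        t=t,
        p=p,
        fdr=fdr,
        d0=float(d0),
        s02=float(s02),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_dge(
    expr: np.ndarray, gene_ids, design: DesignMatrix
) -> ModeratedResult:
    """OLS fit + empirical-Bayes moderation + BH in one call."""
    return ebayes_moderate(fit_gene_linear_models(expr, gene_ids, design))
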