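"""Chunked multi-response penalised regression for cell-type expression imputation.

For each co-expression chunk of target genes in one cell type, a
multi-response linear model maps mixed-cell (bulk) expression of *all*
genes to the cell-type-specific expression of the chunk genes, on the
log2(TPM+1) scale.  Two penalties are supported:

* ``alpha=1`` — group LASSO across responses: the objective is
  ``(1/2n) * sum_i ||y_i - b0 - B^T x_i||^2 + lambda * sum_j ||B_j.||_2``,
  so a predictor's coefficient row is zero for all targets or nonzero for
  all targets (information sharing between correlated genes).
* ``alpha=0`` — ridge: penalty ``(lambda/2) * ||B||_F^2``, solved in closed
  form via SVD for the whole lambda path at once.

The penalty strength is chosen by k-fold cross-validation minimising mean
squared error over a log-spaced lambda grid, then the model is refit on
all training samples at the selected lambda.  Predictors are standardised
internally on training data; coefficients are reported on the original
scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import MultiTaskLasso

logger = logging.getLogger("ctimpute")

#: reference mixing value used to scale the ridge lambda grid up from the
#: group-LASSO lambda_max (the pure-ridge lambda_max is infinite, so the
#: grid is anchored at lambda_max(lasso) / RIDGE_GRID_MIXING)
RIDGE_GRID_MIXING = 1e-3

DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ChunkModel:
    """Fitted multi-response model for one chunk of target genes."""

    chunk_index: int
    predictor_gene_ids: list[str]
    target_gene_ids: list[str]
    intercepts: np.ndarray  # (n_targets,)
    coef: np.ndarray  # (n_predictors, n_targets), original predictor scale
    alpha: int  # 1 = group LASSO, 0 = ridge
    lambda_selected: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray  # mean CV MSE per grid lambda
    seed: int

    def __post_init__(self) -> None:
        if self.alpha == 1:
            active = np.linalg.norm(self.coef, axis=1) > 0
            # group sparsity: a predictor row is all-zero or all-nonzero;
            # an exactly-zero entry inside an active row can only arise from
            # exact numeric cancellation
            if active.any() and not (self.coef[active] != 0).all():
                logger.warning(
                    "ChunkModel %d: exact zero inside an active predictor row",
                    self.chunk_index,
                )

    @property
    def active_predictors(self) -> np.ndarray:
        return np.linalg.norm(self.coef, axis=1) > 0


@dataclass
class ImputerBundle:
    """All chunk models of one cell type plus training-scale metadata."""

    cell_type: str
    predictor_gene_ids: list[str]
    chunk_models: list[ChunkModel]
    alpha: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.chunk_models:
            overlap = seen.intersection(m.target_gene_ids)
            if overlap:
                raise ValueError(
                    f"duplicate target gene(s) across chunks: {sorted(overlap)[:5]}"
                )
            seen.update(m.target_gene_ids)

    @property
    def target_gene_ids(self) -> list[str]:
        return [g for m in self.chunk_models for g in m.target_gene_ids]


@dataclass
class CellTypeExpressionTensor:
    """Gene x cell-type x sample expression on the log2(TPM+1) scale."""

    gene_ids: list[str]
    cell_types: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_genes, n_cell_types, n_samples)
    provenance: str = "observed"  # or "imputed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.gene_ids), len(self.cell_types), len(self.sample_ids))
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")

    def slab(self, cell_type: str) -> np.ndarray:
        """Gene x sample matrix for one cell type."""
        return self.values[:, self.cell_types.index(cell_type), :]


# ---------------------------------------------------------------------------
# lambda path
# ---------------------------------------------------------------------------

def lambda_path(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: int,
    n_lambda: int = 100,
    min_ratio: float | None = None,
) -> np.ndarray:
    """Descending log-spaced lambda grid.

    ``lambda_max`` is the smallest lambda at which the group-LASSO solution
    is exactly zero: the max over predictors j of ``||x_j^T Yc||_2 / n``
    with standardised predictors and centred responses.  For ridge the same
    grid is divided by :data:`RIDGE_GRID_MIXING` (a pure L2 penalty never
    reaches an exactly-zero solution at finite lambda, so the grid is
    anchored to the group-LASSO scale).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    Xs, _, _ = _standardise(X)
    Yc = Y - Y.mean(axis=0)
    if not np.any(Yc):
        warnings.warn("constant response matrix: single-lambda grid")
        return np.array([1.0])
    lam_max = float(np.max(np.linalg.norm(Xs.T @ Yc, axis=1)) / n)
    if min_ratio is None:
        min_ratio = 0.01 if n < X.shape[1] else 1e-4
    grid = np.geomspace(lam_max, lam_max * min_ratio, n_lambda)
    if alpha == 0:
        grid = grid / RIDGE_GRID_MIXING
    return grid


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _fit_path(
    Xs: np.ndarray,
    Yc: np.ndarray,
    lambdas: np.ndarray,
    alpha: int,
    tol: float,
    max_iter: int,
) -> list[np.ndarray]:
    """Coefficient matrices (p x q, standardised scale) along the lambda path."""
    n = Xs.shape[0]
    if alpha == 0:
        U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
        UtY = U.T @ Yc
        # (1/2n)||Yc - Xs B||^2 + (lam/2)||B||_F^2  =>  B = V diag(d/(d^2+n*lam)) U^T Yc
        return [Vt.T @ ((d / (d**2 + n * lam))[:, None] * UtY) for lam in lambdas]
    coefs = []
    model = MultiTaskLasso(
        alpha=float(lambdas[0]), fit_intercept=False, warm_start=True,
        tol=tol, max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Objective did not converge.*")
        for lam in lambdas:
            model.set_params(alpha=float(lam))
            model.fit(Xs, Yc)
            coefs.append(model.coef_.T.copy())  # (p, q)
    return coefs


def fit_multiresponse_cv(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: int,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    predictor_gene_ids: Sequence[str] | None = None,
    target_gene_ids: Sequence[str] | None = None,
    chunk_index: int = 0,
    lambdas: np.ndarray | None = None,
) -> ChunkModel:
    """Cross-validated multi-response penalised fit for one chunk.

    Samples are shuffled once with the given seed and split into
    ``n_folds`` contiguous folds; the lambda minimising the mean
    cross-validated MSE is selected and the model refit on all samples.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of samples (rows)")
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in X or Y")
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 (ridge) or 1 (group LASSO)")

    if lambdas is None:
        lambdas = lambda_path(X, Y, alpha, n_lambda=n_lambda, min_ratio=min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    sq_err = np.zeros(len(lambdas))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, Ytr = X[mask], Y[mask]
        Xs, mx, sx = _standardise(Xtr)
        my = Ytr.mean(axis=0)
        coefs = _fit_path(Xs, Ytr - my, lambdas, alpha, tol, max_iter)
        Xv = (X[fold] - mx) / sx
        for i, B in enumerate(coefs):
            pred = Xv @ B + my
            sq_err[i] += float(((Y[fold] - pred) ** 2).sum())
    cv_mse = sq_err / (n * q)

    best = int(np.argmin(cv_mse))  # ties -> largest lambda (first in order)
    lam_sel = float(lambdas[best])

    Xs, mx, sx = _standardise(X)
    my = Y.mean(axis=0)
    coefs = _fit_path(Xs, Y - my, lambdas[: best + 1], alpha, tol, max_iter)
    B_std = coefs[-1]
    B = B_std / sx[:, None]  # back to original predictor scale
    if alpha == 1:
        # keep exact group sparsity on the original scale
        B[np.linalg.norm(B_std, axis=1) == 0] = 0.0
    b0 = my - mx @ B

    if predictor_gene_ids is None:
        predictor_gene_ids = [f"p{j}" for j in range(p)]
    if target_gene_ids is None:
        target_gene_ids = [f"t{j}" for j in range(q)]
    return ChunkModel(
        chunk_index=chunk_index,
        predictor_gene_ids=list(predictor_gene_ids),
        target_gene_ids=list(target_gene_ids),
        intercepts=b0,
        coef=B,
        alpha=alpha,
        lambda_selected=lam_sel,
        lambda_grid=lambdas,
        cv_mse=cv_mse,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_chunk(
    model: ChunkModel,
    X_test: np.ndarray,
    predictor_gene_ids: Sequence[str],
    clip_at_zero: bool = False,
) -> np.ndarray:
    """Predict the chunk's target genes for test samples (samples x targets).

    Test predictors are matched to the model's predictors by gene id, not
    by position; predictions are on the log2(TPM+1) scale and may dip
    below zero unless ``clip_at_zero``.
    """
    pos = {g: i for i, g in enumerate(predictor_gene_ids)}
    missing = [g for g in model.predictor_gene_ids if g not in pos]
    if missing:
        raise ValueError(f"missing predictor gene(s): {missing[:10]}")
    idx = [pos[g] for g in model.predictor_gene_ids]
    X = np.asarray(X_test, dtype=float)[:, idx]
    pred = X @ model.coef + model.intercepts
    if clip_at_zero:
        pred = np.clip(pred, 0.0, None)
    return pred


def train_imputer(
    bulk_train: np.ndarray,
    bulk_gene_ids: Sequence[str],
    celltype_train: np.ndarray,
    celltype_gene_ids: Sequence[str],
    chunks,
    alpha: int,
    seed: int = 0,
    **fit_kwargs,
) -> ImputerBundle:
    """Fit one ChunkModel per chunk; all bulk genes are predictors for every chunk.

    ``bulk_train`` and ``celltype_train`` are gene x sample matrices over
    the same training samples (column-aligned).  The fold shuffle seed for
    chunk i is ``seed + i`` so folds are reproducible per chunk.
    """
    bulk_train = np.asarray(bulk_train, dtype=float)
    celltype_train = np.asarray(celltype_train, dtype=float)
    if bulk_train.shape[1] != celltype_train.shape[1]:
        raise ValueError("bulk and cell-type training matrices must share samples")
    target_pos = {g: i for i, g in enumerate(celltype_gene_ids)}
    X = bulk_train.T  # samples x predictors
    models = []
    for i, chunk_genes in enumerate(chunks.chunks):
        if not chunk_genes:
            raise ValueError(f"chunk {i} has zero target genes")
        rows = [target_pos[g] for g in chunk_genes]
        Y = celltype_train[rows].T  # samples x targets
        models.append(
            fit_multiresponse_cv(
                X, Y, alpha, seed=seed + i,
                predictor_gene_ids=bulk_gene_ids,
                target_gene_ids=chunk_genes,
                chunk_index=i,
                **fit_kwargs,
            )
        )
    return ImputerBundle(
        cell_type=chunks.cell_type,
        predictor_gene_ids=list(bulk_gene_ids),
        chunk_models=models,
        alpha=alpha,
    )


def impute(
    bundle: ImputerBundle,
    bulk_test: np.ndarray,
    bulk_gene_ids: Sequence[str],
    test_sample_ids: Sequence[str],
    clip_at_zero: bool = False,
) -> CellTypeExpressionTensor:
    """Assemble per-chunk predictions into one imputed cell-type slab."""
    X = np.asarray(bulk_test, dtype=float).T  # samples x genes
    gene_ids: list[str] = []
    blocks = []
    for model in bundle.chunk_models:
        pred = predict_chunk(model, X, bulk_gene_ids, clip_at_zero=clip_at_zero)
        gene_ids.extend(model.target_gene_ids)
        blocks.append(pred.T)  # genes x samples
    values = np.vstack(blocks)[:, None, :]
    return CellTypeExpressionTensor(
        gene_ids=gene_ids,
        cell_types=[bundle.cell_type],
        sample_ids=list(test_sample_ids),
        values=values,
        provenance="imputed",
    )


class BaselineMeanPredictor:
    """Constant predictor: the training mean profile for every test sample.

    The floor every trained model must beat — it carries cell-type identity
    but no between-sample information, so its per-gene correlation with
    observed test expression is undefined (zero prediction variance).
    """

    def __init__(self, celltype_train: np.ndarray, gene_ids: Sequence[str],
                 cell_type: str = ""):
        self.mean_profile = np.asarray(celltype_train, dtype=float).mean(axis=1)
        self.gene_ids = list(gene_ids)
        self.cell_type = cell_type

    def predict(self, test_sample_ids: Sequence[str]) -> CellTypeExpressionTensor:
        values = np.repeat(
            self.mean_profile[:, None, None], len(test_sample_ids), axis=2
        )
        return CellTypeExpressionTensor(
            gene_ids=list(self.gene_ids),
            cell_types=[self.cell_type],
            sample_ids=list(test_sample_ids),
            values=values,
            provenance="imputed",
        )


def baseline_mean_predictor(
    celltype_train: np.ndarray, gene_ids: Sequence[str], cell_type: str = ""
) -> BaselineMeanPredictor:
    return BaselineMeanPredictor(celltype_train, gene_ids, cell_type)


# ---------------------------------------------------------------------------
# on-disk bundle layout: bundle.json manifest + one coefficient TSV per chunk
# (first row "(intercept)", then one row per predictor gene, columns = targets)
# ---------------------------------------------------------------------------

def save_bundle(bundle: ImputerBundle, outdir) -> None:
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cell_type": bundle.cell_type,
        "alpha": bundle.alpha,
        "predictor_gene_ids": bundle.predictor_gene_ids,
        "chunks": [
            {
                "chunk_index": m.chunk_index,
                "coef_file": f"chunk_{m.chunk_index:04d}_coef.tsv",
                "lambda_selected": m.lambda_selected,
                "lambda_grid": m.lambda_grid.tolist(),
                "cv_mse": m.cv_mse.tolist(),
                "seed": m.seed,
            }
            for m in bundle.chunk_models
        ],
    }
    (out / "bundle.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for m in bundle.chunk_models:
        df = pd.DataFrame(
            np.vstack([m.intercepts, m.coef]),
            index=["(intercept)"] + m.predictor_gene_ids,
            columns=m.target_gene_ids,
        )
        df.index.name = "predictor"
        df.to_csv(out / f"chunk_{m.chunk_index:04d}_coef.tsv", sep="\t",
                  lineterminator="\n")


def load_bundle(indir) -> ImputerBundle:
    import json
    from pathlib import Path

    import pandas as pd

    src = Path(indir)
    manifest = json.loads((src / "bundle.json").read_text())
    models = []
    for ch in manifest["chunks"]:
        df = pd.read_csv(src / ch["coef_file"], sep="\t", index_col=0)
        models.append(
            ChunkModel(
                chunk_index=ch["chunk_index"],
                predictor_gene_ids=list(df.index[1:].astype(str)),
                target_gene_ids=list(df.columns.astype(str)),
                intercepts=df.iloc[0].to_numpy(),
                coef=df.iloc[1:].to_numpy(),
                alpha=manifest["alpha"],
                lambda_selected=ch["lambda_selected"],
                lambda_grid=np.asarray(ch["lambda_grid"]),
                cv_mse=np.asarray(ch["cv_mse"]),
                seed=ch["seed"],
            )
        )
    return ImputerBundle(
        cell_type=manifest["cell_type"],
        predictor_gene_ids=list(manifest["predictor_gene_ids"]),
        chunk_models=models,
        alpha=manifest["alpha"],
    )
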