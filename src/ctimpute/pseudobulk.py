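"""Pseudobulk simulation: paired bulk + ground-truth cell-type count data.

The generator emulates how pseudobulk mixtures are built from single-cell
data: per-cell-type cell pools are simulated under two conditions
(untreated ``UT`` vs stimulated ``3hCA``) and two chemistry batches
(``V2``/``V3``); per-sample cell-type fractions are drawn Normal per cell
type and renormalised to sum to 1; a sample's ground-truth cell-type
expression is the sum of counts over ``cells_per_type`` cells from the
matching pool, and its bulk column is the sum over cell types of counts
from cell numbers proportional to the fractions.

Per-cell counts are negative binomial around a gene x cell-type mean
surface, with multiplicative condition effects on a designated subset of
genes (the differential-expression ground truth), a multiplicative batch
factor, and per-cell size factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation

logger = logging.getLogger("ctimpute")

CELL_TYPES = ("CD4", "CD8", "CD14", "CD19")
CONDITIONS = ("UT", "3hCA")
BATCHES = ("V2", "V3")

#: mean percentage and SD of each cell-type fraction (CD4, CD8, CD14, CD19)
DEFAULT_FRACTION_MEANS = (42.74, 28.12, 26.29, 2.85)
DEFAULT_FRACTION_SDS = (4.30, 2.40, 6.21, 0.36)


@dataclass
class FractionMatrix:
    """Sample x cell-type fractions; every row sums to 1."""

    sample_ids: list[str]
    cell_types: list[str]
    fractions: np.ndarray  # (n_samples, n_cell_types)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValueError("fractions shape does not match id lists")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_types)


@dataclass
class CellPool:
    """Simulated single cells of one (cell type, condition, batch) stratum."""

    cell_type: str
    condition: str
    batch: str
    counts: np.ndarray  # (n_cells, n_genes)

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1:
            raise ValueError("pool must contain at least one cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


@dataclass
class SimParams:
    """Parameters of the synthetic single-cell / pseudobulk generator.

    ``mu`` is the gene x cell-type matrix of per-cell baseline mean counts.
    ``dispersion`` is the negative-binomial size parameter (``inf`` gives
    Poisson counts).  ``de_proportion`` of genes per cell type receive a
    multiplicative condition effect of ``2**lfc`` in the stimulated
    condition, with log2 fold changes drawn N(0, ``de_lfc_sd``) and
    resampled until |lfc| >= ``de_lfc_min``.
    """

    n_genes: int = 300
    cell_types: tuple[str, ...] = CELL_TYPES
    mu: np.ndarray | None = None  # (n_genes, n_cell_types) per-cell means
    dispersion: float = 0.5
    fraction_means: tuple[float, ...] = DEFAULT_FRACTION_MEANS
    fraction_sds: tuple[float, ...] = DEFAULT_FRACTION_SDS
    de_proportion: float = 0.10
    de_lfc_sd: float = 0.5
    de_lfc_min: float = 0.25
    batch_lsd: float = 0.15  # SD of log batch factor (V3 relative to V2)
    cell_size_lsd: float = 0.3  # SD of log per-cell size factors
    pool_cells: int = 20000
    cells_per_type: int = 5000
    mixture_total_cells: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.cells_per_type < 1:
            raise ValueError("cells_per_type must be >= 1")
        if any(s < 0 for s in self.fraction_sds):
            raise ValueError("fraction SDs must be non-negative")
        if any(m <= 0 for m in self.fraction_means):
            raise ValueError("fraction means must be positive")
        if self.mu is None:
            self.mu = _default_mu(self.n_genes, len(self.cell_types), self.seed)
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any(self.mu <= 0):
            raise ValueError("baseline means must be positive")
        if self.mu.shape != (self.n_genes, len(self.cell_types)):
            raise ValueError("mu shape must be (n_genes, n_cell_types)")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


def _default_mu(n_genes: int, n_types: int, seed: int) -> np.ndarray:
    """Log-normal per-gene base means with per-cell-type modulation."""
    rng = np.random.default_rng(seed + 101)
    base = rng.lognormal(mean=np.log(0.02), sigma=1.8, size=n_genes)
    mod = rng.lognormal(mean=0.0, sigma=0.5, size=(n_genes, n_types))
    return base[:, None] * mod


def simulate_annotation(params: SimParams) -> GeneAnnotation:
    """Synthetic gene lengths (uniform 500-5000 bp), seeded from params."""
    rng = np.random.default_rng(params.seed + 202)
    lengths = rng.integers(500, 5001, size=params.n_genes)
    return GeneAnnotation(dict(zip(params.gene_ids, (int(x) for x in lengths))))


# ---------------------------------------------------------------------------
# fractions
# ---------------------------------------------------------------------------

def simulate_fractions(
    means: Sequence[float],
    sds: Sequence[float],
    n_samples: int,
    seed: int,
    cell_types: Sequence[str] = CELL_TYPES,
    sample_ids: Sequence[str] | None = None,
) -> FractionMatrix:
    """Draw per-sample cell-type fractions Normal(mean, sd) per type and renormalise.

    Negative draws are truncated to 0 before dividing each row by its sum;
    a row whose components are all <= 0 is redrawn (count logged).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if len(means) != len(sds) or len(means) != len(cell_types):
        raise ValueError("means, sds and cell_types must have equal length")
    rng = np.random.default_rng(seed)
    means_a = np.asarray(means, dtype=float)
    sds_a = np.asarray(sds, dtype=float)
    rows = np.empty((n_samples, len(means_a)))
    n_redraws = 0
    for i in range(n_samples):
        while True:
            draw = rng.normal(means_a, sds_a)
            draw = np.clip(draw, 0.0, None)
            if draw.sum() > 0:
                break
            n_redraws += 1
        rows[i] = draw / draw.sum()
    if n_redraws:
        logger.info("simulate_fractions: %d redraws of all-non-positive rows", n_redraws)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    return FractionMatrix(list(sample_ids), list(cell_types), rows)


# ---------------------------------------------------------------------------
# cell pools
# ---------------------------------------------------------------------------

def simulate_cell_pools(
    params: SimParams,
) -> tuple[dict[tuple[str, str, str], CellPool], dict[str, dict[str, float]]]:
    """Simulate per-(cell type, condition, batch) cell pools.

    Returns the pools keyed by (cell_type, condition, batch) and the
    differential-expression ground truth: per cell type, a mapping from
    affected gene id to its log2 fold change (stimulated vs untreated).
    """
    rng = np.random.default_rng(params.seed + 303)
    gene_ids = params.gene_ids
    n_types = len(params.cell_types)

    # condition-affected genes and their log2 fold changes, per cell type
    n_de = int(round(params.de_proportion * params.n_genes))
    truth_de: dict[str, dict[str, float]] = {}
    cond_factor = np.ones((params.n_genes, n_types))
    for c, ct in enumerate(params.cell_types):
        idx = rng.choice(params.n_genes, size=n_de, replace=False)
        lfcs = rng.normal(0.0, params.de_lfc_sd, size=n_de)
        while params.de_lfc_sd > 0 and np.any(np.abs(lfcs) < params.de_lfc_min):
            small = np.abs(lfcs) < params.de_lfc_min
            lfcs[small] = rng.normal(0.0, params.de_lfc_sd, size=small.sum())
        truth_de[ct] = {gene_ids[g]: float(l) for g, l in zip(idx, lfcs)}
        cond_factor[idx, c] = 2.0 ** lfcs

    batch_factor = rng.lognormal(0.0, params.batch_lsd, size=params.n_genes)

    def _draw_counts(cell_means: np.ndarray) -> np.ndarray:
        if np.isinf(params.dispersion):
            return rng.poisson(cell_means)
        shape = params.dispersion
        lam = rng.gamma(shape, cell_means / shape)
        return rng.poisson(lam)

    # The stimulated pool of each (cell type, batch) stratum reuses the
    # untreated pool's cells for unaffected genes and re-simulates only the
    # condition-affected gene columns at the scaled mean.  This makes the
    # null exact by construction: unaffected genes are identically
    # distributed (indeed identical) across conditions, so condition
    # differences detected for them in downstream DGE are genuine false
    # positives, not artefacts of finite-pool sampling.
    pools: dict[tuple[str, str, str], CellPool] = {}
    for c, ct in enumerate(params.cell_types):
        affected = np.flatnonzero(cond_factor[:, c] != 1.0)
        for batch in BATCHES:
            mean_g = params.mu[:, c].copy()
            if batch == "V3":
                mean_g = mean_g * batch_factor
            size_f = rng.lognormal(0.0, params.cell_size_lsd, size=params.pool_cells)
            ut_counts = _draw_counts(size_f[:, None] * mean_g[None, :])
            stim_counts = ut_counts.copy()
            if affected.size:
                stim_means = (size_f[:, None]
                              * (mean_g[affected] * cond_factor[affected, c])[None, :])
                stim_counts[:, affected] = _draw_counts(stim_means)
            pools[(ct, "UT", batch)] = CellPool(ct, "UT", batch,
                                                ut_counts.astype(np.int32))
            pools[(ct, "3hCA", batch)] = CellPool(ct, "3hCA", batch,
                                                  stim_counts.astype(np.int32))
    return pools, truth_de


# ---------------------------------------------------------------------------
# mixture assembly
# ---------------------------------------------------------------------------

def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``fractions``.

    Floors the exact quotas, then distributes the remaining units to the
    largest fractional remainders (ties broken toward the later component).
    """
    quotas = np.asarray(fractions, dtype=float) * total
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    if short:
        order = np.argsort(quotas - base, kind="stable")[::-1]
        base[order[:short]] += 1
    return base


def make_design(
    sample_ids: Sequence[str], seed: int, n_train: int | None = None
) -> pd.DataFrame:
    """Assign condition and batch by seeded fair coin flips; first half = train."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    if n_train is None:
        n_train = n // 2
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "condition": rng.choice(CONDITIONS, size=n),
            "batch": rng.choice(BATCHES, size=n),
            "split": ["train"] * n_train + ["test"] * (n - n_train),
        }
    )


@dataclass
class PseudobulkDataset:
    """Paired bulk + ground-truth cell-type counts with known composition."""

    gene_ids: list[str]
    sample_ids: list[str]
    cell_types: list[str]
    bulk: CountMatrix
    truth: dict[str, CountMatrix]  # cell type -> gene x sample counts
    fractions: FractionMatrix
    design: pd.DataFrame
    truth_de_genes: dict[str, dict[str, float]]
    annotation: GeneAnnotation | None = None

    @property
    def train_ids(self) -> list[str]:
        return list(self.design.loc[self.design["split"] == "train", "sample_id"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.design.loc[self.design["split"] == "test", "sample_id"])

    def write(self, outdir) -> None:
        """Write bulk, per-cell-type truth, fractions and design as TSVs."""
        from pathlib import Path
        from .io import write_matrix

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.bulk, out / "bulk_counts.tsv")
        for ct, cm in self.truth.items():
            write_matrix(cm, out / f"truth_counts_{ct}.tsv")
        df = self.fractions.to_frame()
        df.index.name = "sample_id"
        df.to_csv(out / "fractions.tsv", sep="\t", lineterminator="\n")
        self.design.to_csv(out / "design.tsv", sep="\t", index=False, lineterminator="\n")
        if self.annotation is not None:
            self.annotation.write_tsv(out / "gene_annotation.tsv")
        de = [
            {"cell_type": ct, "gene_id": g, "log2fc": l}
            for ct, d in self.truth_de_genes.items()
            for g, l in d.items()
        ]
        pd.DataFrame(de).to_csv(out / "truth_de_genes.tsv", sep="\t", index=False,
                                lineterminator="\n")


def assemble_pseudobulk(
    pools: Mapping[tuple[str, str, str], CellPool],
    fractions: FractionMatrix,
    design: pd.DataFrame,
    cells_per_type: int = 5000,
    mixture_total_cells: int = 5000,
    seed: int = 0,
    shared_draws: bool = False,
    truth_de_genes: dict[str, dict[str, float]] | None = None,
    annotation: GeneAnnotation | None = None,
    gene_ids: Sequence[str] | None = None,
) -> PseudobulkDataset:
    """Assemble per-sample ground truth and bulk mixture from cell pools.

    For each sample: the truth slab for cell type ``c`` is the sum of counts
    over ``cells_per_type`` cells drawn from the pool matching the sample's
    condition and batch; the bulk column is the sum over cell types of
    counts from ``largest_remainder(fractions, mixture_total_cells)`` cells.
    With ``shared_draws=False`` (default) the mixture cells are drawn from
    the full pool independently of the truth draw; with ``shared_draws=True``
    they are drawn from the truth subset of cells.  Sampling is without
    replacement when the source is large enough, else with replacement
    (warned).
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        any_pool = next(iter(pools.values()))
        gene_ids = [f"g{i:0{len(str(any_pool.counts.shape[1]-1))}d}"
                    for i in range(any_pool.counts.shape[1])]
    gene_ids = list(gene_ids)
    sample_ids = list(design["sample_id"])
    cell_types = list(fractions.cell_types)
    n_genes = len(gene_ids)

    for _, row in design.iterrows():
        for ct in cell_types:
            if (ct, row["condition"], row["batch"]) not in pools:
                raise KeyError(
                    f"no pool for ({ct}, {row['condition']}, {row['batch']})"
                )

    def _draw(pool_counts: np.ndarray, k: int) -> np.ndarray:
        n = pool_counts.shape[0]
        if k == 0:
            return np.zeros(n_genes, dtype=np.int64)
        if k <= n:
            idx = rng.choice(n, size=k, replace=False)
        else:
            logger.warning(
                "assemble_pseudobulk: pool of %d cells < requested %d; "
                "sampling with replacement", n, k
            )
            idx = rng.choice(n, size=k, replace=True)
        return pool_counts[idx].sum(axis=0, dtype=np.int64)

    bulk = np.zeros((n_genes, len(sample_ids)), dtype=np.int64)
    truth = {ct: np.zeros((n_genes, len(sample_ids)), dtype=np.int64)
             for ct in cell_types}
    frac = fractions.fractions
    for s, (_, row) in enumerate(design.iterrows()):
        n_cells_mix = largest_remainder(frac[s], mixture_total_cells)
        for c, ct in enumerate(cell_types):
            pool = pools[(ct, row["condition"], row["batch"])]
            n = pool.n_cells
            k_truth = cells_per_type
            if k_truth <= n:
                truth_idx = rng.choice(n, size=k_truth, replace=False)
            else:
                logger.warning(
                    "assemble_pseudobulk: pool of %d cells < cells_per_type %d; "
                    "sampling with replacement", n, k_truth
                )
                truth_idx = rng.choice(n, size=k_truth, replace=True)
            truth[ct][:, s] = pool.counts[truth_idx].sum(axis=0, dtype=np.int64)
            source = pool.counts[truth_idx] if shared_draws else pool.counts
            bulk[:, s] += _draw(source, int(n_cells_mix[c]))

    return PseudobulkDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        cell_types=cell_types,
        bulk=CountMatrix(gene_ids, sample_ids, bulk),
        truth={ct: CountMatrix(gene_ids, sample_ids, m) for ct, m in truth.items()},
        fractions=fractions,
        design=design.reset_index(drop=True),
        truth_de_genes=truth_de_genes or {},
        annotation=annotation,
    )


def simulate_dataset(params: SimParams, n_samples: int = 160) -> PseudobulkDataset:
    """One-call generator: pools + fractions + design + assembled pseudobulk."""
    fractions = simulate_fractions(
        params.fraction_means, params.fraction_sds, n_samples,
        seed=params.seed, cell_types=params.cell_types,
    )
    design = make_design(fractions.sample_ids, seed=params.seed + 404)
    pools, truth_de = simulate_cell_pools(params)
    return assemble_pseudobulk(
        pools,
        fractions,
        design,
        cells_per_type=params.cells_per_type,
        mixture_total_cells=params.mixture_total_cells,
        seed=params.seed + 505,
        truth_de_genes=truth_de,
        annotation=simulate_annotation(params),
        gene_ids=params.gene_ids,
    )


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_train_test(
    sample_ids: Sequence[str],
    train_size: int | float | None = None,
    mode: str = "fixed-test",
) -> tuple[list[str], list[str]]:
    """First half of samples = training superset; second half = fixed test set.

    In ``fixed-test`` mode, ``train_size`` (an integer count or a fraction
    of the training superset) subsamples the *first* ``train_size`` samples
    of the training half while the test half is unchanged — so sweeps over
    training size share one test set.
    """
    n = len(sample_ids)
    half = n // 2
    train_superset = list(sample_ids[:half])
    test = list(sample_ids[half:])
    if train_size is None:
        return train_superset, test
    if isinstance(train_size, float):
        k = int(round(train_size * half))
    else:
        k = int(train_size)
    if k <= 0:
        raise ValueError("train size must be positive")
    if mode == "fixed-test" and k > half:
        raise ValueError(f"requested train size {k} exceeds training half {half}")
    return train_superset[:k], test
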