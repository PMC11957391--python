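"""Reading, writing, normalisation and filtering of gene x sample count matrices.

Counts are kept as integer gene x sample tables.  Normalised expression is
carried on one of two scales: ``TPM`` (columns sum to 1e6) or ``log2TPM1``
(log2(TPM + 1), all values >= 0).  Filtering of low-expressed genes happens
on raw counts, before any normalisation, mirroring the usual
CPM-threshold / minimum-total-count rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ctimpute")

SCALE_TPM = "TPM"
SCALE_CPM = "CPM"
SCALE_LOG2TPM1 = "log2TPM1"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:10]}")


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample read-count matrix.

    Holds either a mixed-cell (bulk) matrix or a per-cell-type observed
    count matrix; the mixture model treats the bulk column for one sample
    as the fraction-weighted combination of per-cell-type expression.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in mask_or_ids])
        return CountMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class GeneAnnotation:
    """Gene lengths in base pairs, used for TPM length normalisation."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = [g for g, L in self.lengths.items() if L < 1]
        if bad:
            raise ValueError(f"non-positive gene lengths for: {bad[:10]}")

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError("annotation table needs columns gene_id, length")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.lengths), "length": list(self.lengths.values())}
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression on a declared scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = SCALE_TPM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if self.scale == SCALE_LOG2TPM1 and np.any(self.values < -1e-12):
            raise ValueError("log2(TPM+1) values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.scale
        )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def compute_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: each column scaled to sum to 1e6."""
    colsums = counts.counts.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = counts.counts / colsums * 1e6
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), cpm, scale=SCALE_CPM
    )


def compute_tpm(counts: CountMatrix, annot: GeneAnnotation) -> ExpressionMatrix:
    """Transcripts per million: counts length-normalised, then column-scaled to 1e6."""
    missing = [g for g in counts.gene_ids if g not in annot.lengths]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    lengths = np.array([annot.lengths[g] for g in counts.gene_ids], dtype=float)
    rate = counts.counts / lengths[:, None]
    ratesums = rate.sum(axis=0)
    zero = np.flatnonzero(ratesums == 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero column(s) for sample(s): {bad}")
    tpm = rate / ratesums * 1e6
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), tpm, scale=SCALE_TPM
    )


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1)."""
    if expr.scale != SCALE_TPM:
        raise ValueError(f"log_transform expects scale {SCALE_TPM!r}, got {expr.scale!r}")
    return ExpressionMatrix(
        list(expr.gene_ids),
        list(expr.sample_ids),
        np.log2(expr.values + 1.0),
        scale=SCALE_LOG2TPM1,
    )


def filter_low_expressed(
    counts: CountMatrix,
    cpm_threshold: float = 0.836,
    min_samples: int = 96,
    min_total: int = 15,
    group: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Boolean keep-mask over genes.

    A gene is kept iff its CPM reaches ``cpm_threshold`` in at least
    ``min_samples`` samples AND its total count across samples is at least
    ``min_total``.  The defaults correspond to 10 reads in a 11.95-million-read
    library (CPM 0.836), 96 samples and 15 total reads.  ``group`` (e.g. the
    cell type of each sample) is recorded in the log for provenance only; the
    thresholds themselves are explicit rather than derived from group sizes.
    """
    if cpm_threshold <= 0 or min_samples <= 0 or min_total <= 0:
        raise ValueError("thresholds must be positive")
    if min_samples > counts.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds n_samples={counts.n_samples}"
        )
    if group is not None:
        labels = sorted(set(group.values()))
        logger.info("filter_low_expressed: sample groups recorded: %s", labels)
    cpm = compute_cpm(counts).values
    n_pass = (cpm >= cpm_threshold).sum(axis=1)
    totals = counts.counts.sum(axis=1)
    keep = (n_pass >= min_samples) & (totals >= min_total)
    logger.info(
        "filter_low_expressed: keeping %d / %d genes", int(keep.sum()), counts.n_genes
    )
    return keep


# ---------------------------------------------------------------------------
# tab-separated text IO
# ---------------------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    """Read a tab-separated gene x sample count table (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (missing header?)")
    if df.index.hasnans or any(str(c).startswith("Unnamed") for c in df.columns):
        raise ValueError(f"{path}: malformed header row")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value(s) in column {col!r}, "
                f"e.g. row {bad.index[0]!r} = {bad.iloc[0]!r}"
            )
    _check_unique(list(df.index.astype(str)), f"gene ids in {path}")
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       df.to_numpy())


def write_matrix(matrix: CountMatrix | ExpressionMatrix, path) -> None:
    """Write a matrix as UTF-8, Unix-newline TSV (first column gene id)."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
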