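"""Partition target genes into bounded-size co-expression chunks.

Genes are hierarchically clustered (Euclidean distance between their
training expression profiles, complete linkage), the dendrogram is cut
statically into the minimum number of groups that could hold all genes at
the size bound, and any oversized group is re-clustered and re-cut under a
minimum-cluster-size constraint that relaxes stepwise until the bound is
met.  The procedure is deterministic and order-invariant: genes are sorted
lexicographically by id before clustering so distance ties cannot depend
on input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

logger = logging.getLogger("ctimpute")


@dataclass
class ChunkAssignment:
    """Partition of target genes into chunks for one cell type."""

    cell_type: str
    chunks: list[list[str]]  # gene ids per chunk

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ch in self.chunks:
            if not ch:
                raise ValueError("empty chunk")
            overlap = seen.intersection(ch)
            if overlap:
                raise ValueError(f"genes in more than one chunk: {sorted(overlap)[:5]}")
            seen.update(ch)

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.chunks]

    @property
    def mapping(self) -> dict[str, int]:
        return {g: i for i, ch in enumerate(self.chunks) for g in ch}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "cell_type": self.cell_type, "chunk_index": i}
            for i, ch in enumerate(self.chunks)
            for g in ch
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path) -> "ChunkAssignment":
        df = pd.read_csv(path, sep="\t")
        ct = str(df["cell_type"].iloc[0]) if len(df) else ""
        chunks = [
            list(sub["gene_id"].astype(str))
            for _, sub in df.groupby("chunk_index", sort=True)
        ]
        return cls(ct, chunks)


def initial_chunk_count(n_genes: int, max_size: int = 500) -> int:
    """Smallest k with k * max_size >= n_genes (minimum multiple of the bound)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return math.ceil(n_genes / max_size)


def _cut_with_min_size(
    Z: np.ndarray, m: int, max_size: int, min_split_size: int, split_step: int
) -> list[np.ndarray] | None:
    """Cut a dendrogram so every group is <= max_size and >= a minimum size.

    Tries the minimum-size constraint at ``min_split_size`` first, relaxing
    by ``split_step`` down to 1; for each constraint value, static cuts with
    an increasing number of groups are attempted.  Returns index groups, or
    None if no admissible cut exists.
    """
    k_min = max(2, math.ceil(m / max_size))
    min_sizes = list(range(min_split_size, 0, -split_step))
    if min_sizes[-1] != 1:
        min_sizes.append(1)
    for min_size in min_sizes:
        k_max = m // max(min_size, 1)
        for k in range(k_min, k_max + 1):
            labels = fcluster(Z, t=k, criterion="maxclust")
            sizes = np.bincount(labels)[1:]
            sizes = sizes[sizes > 0]
            if sizes.max() <= max_size and sizes.min() >= min_size:
                return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    return None


def chunk_genes(
    gene_ids: Sequence[str],
    values: np.ndarray,
    cell_type: str = "",
    max_size: int = 500,
    min_split_size: int = 250,
    split_step: int = 5,
) -> ChunkAssignment:
    """Cluster gene expression profiles into chunks of at most ``max_size`` genes.

    ``values`` is the gene x training-sample expression matrix (log2(TPM+1)),
    row-aligned with ``gene_ids``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(gene_ids):
        raise ValueError("values must be gene x sample, aligned with gene_ids")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 training samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression contains non-finite values")

    # lexicographic gene order makes the partition input-order invariant
    order = np.argsort(np.asarray(gene_ids, dtype=object), kind="stable")
    gene_ids_sorted = [gene_ids[i] for i in order]
    X = values[order]
    n = len(gene_ids_sorted)

    if n <= max_size:
        return ChunkAssignment(cell_type, [list(gene_ids_sorted)])

    k0 = initial_chunk_count(n, max_size)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k0, criterion="maxclust")
    groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]

    final: list[np.ndarray] = []
    stack = list(groups)
    while stack:
        idx = stack.pop(0)
        if idx.size <= max_size:
            final.append(idx)
            continue
        Zg = linkage(X[idx], method="complete", metric="euclidean")
        sub = _cut_with_min_size(Zg, idx.size, max_size, min_split_size, split_step)
        if sub is None:
            logger.warning(
                "chunk_genes: no admissible min-size cut for a group of %d genes; "
                "hard bisection by dendrogram order", idx.size
            )
            leaf_order = leaves_list(Zg)
            n_parts = math.ceil(idx.size / max_size)
            sub = [np.sort(part) for part in np.array_split(leaf_order, n_parts)]
        for part in sub:
            stack.append(idx[part])

    # stable chunk order: by first (lexicographically smallest) member
    final.sort(key=lambda idx: gene_ids_sorted[idx[0]])
    chunks = [[gene_ids_sorted[i] for i in idx] for idx in final]
    assign = ChunkAssignment(cell_type, chunks)
    assert sum(assign.sizes) == n and max(assign.sizes) <= max_size
    return assign
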