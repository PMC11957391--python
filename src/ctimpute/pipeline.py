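"""End-to-end orchestration: simulate -> filter/normalise -> chunk -> train
-> impute -> evaluate, as reproducible seeded runs.

A run is driven by a :class:`RunConfig` (serialisable to YAML); every stage
writes its artefacts under the run directory and records its inputs,
outputs and seeds in ``manifest.json``.  A single global seed expands into
per-stage seeds by fixed documented offsets, so stages are independently
reproducible.  Completed stages are detected by their outputs and skipped
on re-run unless ``force`` is set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import pseudobulk as pb
from .chunking import ChunkAssignment, chunk_genes
from .imputation import (
    ImputerBundle,
    baseline_mean_predictor,
    impute,
    load_bundle,
    save_bundle,
    train_imputer,
)
from .recovery import (
    attenuation_slope,
    per_gene_metrics,
    per_subject_metrics,
    recovery_curve,
    run_paired_dge,
)

logger = logging.getLogger("ctimpute")

# per-stage seed offsets from the global run seed
SEED_OFFSETS = {
    "simulate": 0,
    "train": 10_000,  # + 1000 * cell_type_index + 500 * (alpha == lasso) + chunk
    "phenotypes": 7_001,
    "derangement": 9_002,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "run"
    seed: int = 1
    n_samples: int = 160
    sim: dict = field(default_factory=dict)  # SimParams overrides
    alphas: tuple[str, ...] = ("ridge", "lasso")
    n_folds: int = 5
    n_lambda: int = 50
    cpm_threshold: float = 0.836
    min_samples: int = 96
    min_total: int = 15
    fdr_obs: float = 0.05
    batch_covariate: bool = True
    train_sizes: tuple[int, ...] | None = None  # sweep; None = full training half
    clip_at_zero: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("alphas", "train_sizes"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("alphas", "train_sizes"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


ALPHA_CODE = {"lasso": 1, "ridge": 0}


def _manifest_update(out: Path, stage: str, info: dict) -> None:
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = info
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, force: bool = False) -> pb.PseudobulkDataset:
    out = Path(cfg.out_dir) / "sim"
    params = pb.SimParams(seed=cfg.seed + SEED_OFFSETS["simulate"], **cfg.sim)
    if not force and (out / "bulk_counts.tsv").exists():
        logger.info("simulate: outputs exist, skipping")
        return _load_dataset(out)
    dataset = pb.simulate_dataset(params, n_samples=cfg.n_samples)
    dataset.write(out)
    _manifest_update(Path(cfg.out_dir), "simulate",
                     {"seed": params.seed, "n_samples": cfg.n_samples,
                      "n_genes": params.n_genes, "out": str(out)})
    return dataset


def _load_dataset(simdir: Path) -> pb.PseudobulkDataset:
    bulk = eio.read_counts(simdir / "bulk_counts.tsv")
    design = pd.read_csv(simdir / "design.tsv", sep="\t")
    frac_df = pd.read_csv(simdir / "fractions.tsv", sep="\t", index_col=0)
    fractions = pb.FractionMatrix(
        list(frac_df.index.astype(str)), list(frac_df.columns), frac_df.to_numpy()
    )
    truth = {}
    for ct in fractions.cell_types:
        truth[ct] = eio.read_counts(simdir / f"truth_counts_{ct}.tsv")
    de_path = simdir / "truth_de_genes.tsv"
    truth_de: dict[str, dict[str, float]] = {}
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t")
        for ct, sub in de.groupby("cell_type"):
            truth_de[str(ct)] = dict(zip(sub["gene_id"].astype(str), sub["log2fc"]))
    annot_path = simdir / "gene_annotation.tsv"
    annot = eio.GeneAnnotation.read_tsv(annot_path) if annot_path.exists() else None
    return pb.PseudobulkDataset(
        gene_ids=list(bulk.gene_ids),
        sample_ids=list(bulk.sample_ids),
        cell_types=list(fractions.cell_types),
        bulk=bulk,
        truth=truth,
        fractions=fractions,
        design=design,
        truth_de_genes=truth_de,
        annotation=annot,
    )


def stage_normalise(cfg: RunConfig, dataset: pb.PseudobulkDataset):
    """Filter low-expressed genes on raw counts, then TPM -> log2(TPM+1).

    Filtering sees all matrices (bulk + per-cell-type truth) side by side,
    with the matrix of origin as the group label.
    """
    combined = np.concatenate(
        [dataset.bulk.counts] + [dataset.truth[ct].counts for ct in dataset.cell_types],
        axis=1,
    )
    col_ids = [f"bulk:{s}" for s in dataset.sample_ids] + [
        f"{ct}:{s}" for ct in dataset.cell_types for s in dataset.sample_ids
    ]
    group = {c: c.split(":")[0] for c in col_ids}
    cm = eio.CountMatrix(list(dataset.gene_ids), col_ids, combined)
    keep = eio.filter_low_expressed(
        cm, cpm_threshold=cfg.cpm_threshold,
        min_samples=min(cfg.min_samples, len(col_ids)),
        min_total=cfg.min_total, group=group,
    )
    genes = [g for g, k in zip(dataset.gene_ids, keep) if k]

    annot = dataset.annotation
    if annot is None:
        raise ValueError("dataset has no gene annotation; cannot compute TPM")

    def _log2tpm(counts: eio.CountMatrix) -> eio.ExpressionMatrix:
        return eio.log_transform(eio.compute_tpm(counts.subset_genes(genes), annot))

    bulk_expr = _log2tpm(dataset.bulk)
    truth_expr = {ct: _log2tpm(dataset.truth[ct]) for ct in dataset.cell_types}
    return genes, bulk_expr, truth_expr


def stage_chunk(cfg: RunConfig, truth_expr, train_ids, force: bool = False):
    out = Path(cfg.out_dir) / "chunks"
    out.mkdir(parents=True, exist_ok=True)
    assignments = {}
    for ct, expr in truth_expr.items():
        path = out / f"chunks_{ct}.tsv"
        if not force and path.exists():
            assignments[ct] = ChunkAssignment.read_tsv(path)
            continue
        sub = expr.subset_samples(train_ids)
        assignments[ct] = chunk_genes(sub.gene_ids, sub.values, cell_type=ct)
        assignments[ct].write_tsv(path)
    _manifest_update(Path(cfg.out_dir), "chunk",
                     {ct: a.sizes for ct, a in assignments.items()})
    return assignments


def stage_train(cfg: RunConfig, bulk_expr, truth_expr, assignments, train_ids,
                force: bool = False) -> dict[tuple[str, str], ImputerBundle]:
    bundles = {}
    out = Path(cfg.out_dir) / "models"
    bulk_tr = bulk_expr.subset_samples(train_ids)
    for c, ct in enumerate(truth_expr):
        truth_tr = truth_expr[ct].subset_samples(train_ids)
        for alpha_name in cfg.alphas:
            bdir = out / f"{ct}_{alpha_name}"
            if not force and (bdir / "bundle.json").exists():
                bundles[(ct, alpha_name)] = load_bundle(bdir)
                continue
            seed = (cfg.seed + SEED_OFFSETS["train"] + 1000 * c
                    + 500 * (alpha_name == "lasso"))
            bundle = train_imputer(
                bulk_tr.values, bulk_tr.gene_ids,
                truth_tr.values, truth_tr.gene_ids,
                assignments[ct], ALPHA_CODE[alpha_name],
                seed=seed, n_folds=cfg.n_folds, n_lambda=cfg.n_lambda,
            )
            save_bundle(bundle, bdir)
            bundles[(ct, alpha_name)] = bundle
    _manifest_update(Path(cfg.out_dir), "train",
                     {f"{ct}_{a}": [m.lambda_selected for m in b.chunk_models]
                      for (ct, a), b in bundles.items()})
    return bundles


def stage_impute(cfg: RunConfig, bundles, bulk_expr, test_ids):
    out = Path(cfg.out_dir) / "imputed"
    out.mkdir(parents=True, exist_ok=True)
    bulk_te = bulk_expr.subset_samples(test_ids)
    imputed = {}
    for (ct, alpha_name), bundle in bundles.items():
        tensor = impute(bundle, bulk_te.values, bulk_te.gene_ids, test_ids,
                        clip_at_zero=cfg.clip_at_zero)
        imputed[(ct, alpha_name)] = tensor
        df = pd.DataFrame(tensor.slab(ct), index=tensor.gene_ids, columns=test_ids)
        df.index.name = "gene_id"
        df.to_csv(out / f"imputed_{ct}_{alpha_name}.tsv", sep="\t",
                  lineterminator="\n")
    return imputed


def evaluate_method(
    cfg: RunConfig,
    dataset: pb.PseudobulkDataset,
    truth_expr,
    ct: str,
    tensor,
    train_ids,
    test_ids,
) -> dict:
    """Metrics + condition-phenotype DGE recovery for one imputed slab."""
    obs = truth_expr[ct]
    imp_slab = tensor.slab(ct)
    gene_df = per_gene_metrics(obs.values, obs.gene_ids, obs.sample_ids,
                               imp_slab, tensor.gene_ids, tensor.sample_ids,
                               test_ids)
    subj_df = per_subject_metrics(obs.values, obs.gene_ids, obs.sample_ids,
                                  imp_slab, tensor.gene_ids, tensor.sample_ids,
                                  test_ids)
    design = dataset.design.set_index("sample_id")
    ordered = train_ids + test_ids
    condition = (design.loc[ordered, "condition"] == "3hCA").astype(float).to_numpy()
    covs = {}
    if cfg.batch_covariate:
        covs["batch"] = (design.loc[ordered, "batch"] == "V3").astype(float).to_numpy()
    obs_res, imp_res = run_paired_dge(
        obs.values, obs.gene_ids, imp_slab, tensor.gene_ids,
        ordered, train_ids, test_ids,
        phenotype=condition, covariates=covs,
    )
    try:
        curve = recovery_curve(obs_res, imp_res, fdr_obs=cfg.fdr_obs)
        auc = curve.auc
    except ValueError:
        logger.warning("evaluate: no observed-significant genes for %s; "
                       "recovery AUC undefined", ct)
        curve, auc = None, float("nan")
    slope, r2 = attenuation_slope(obs_res.logfc, imp_res.logfc)
    with np.errstate(invalid="ignore"):
        median_r_gene = float(np.nanmedian(gene_df["r"])) if gene_df["r"].notna().any() else float("nan")
    return {
        "cell_type": ct,
        "median_r_gene": median_r_gene,
        "median_rmse_std_gene": float(np.nanmedian(gene_df["rmse_std"])),
        "median_r_subject": float(np.nanmedian(subj_df["r"])),
        "auc": auc,
        "lfc_slope": slope,
        "lfc_r2": r2,
        "curve": curve,
    }


def run_pipeline(cfg: RunConfig, force: bool = False) -> pd.DataFrame:
    """Run all stages; returns (and writes) the summary table.

    With ``cfg.train_sizes`` set, the train/impute/evaluate cycle repeats
    per training size, always against the same fixed test half.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    dataset = stage_simulate(cfg, force=force)
    genes, bulk_expr, truth_expr = stage_normalise(cfg, dataset)
    train_superset, test_ids = pb.split_train_test(dataset.sample_ids)
    assignments = stage_chunk(cfg, truth_expr, train_superset, force=force)

    sizes = cfg.train_sizes or (len(train_superset),)
    rows = []
    base_out = cfg.out_dir
    for size in sizes:
        train_ids, _ = pb.split_train_test(dataset.sample_ids, train_size=size)
        if len(sizes) > 1:
            cfg = dataclasses.replace(cfg, out_dir=str(Path(base_out) / f"n{size}"))
        bundles = stage_train(cfg, bulk_expr, truth_expr, assignments, train_ids,
                              force=force)
        imputed = stage_impute(cfg, bundles, bulk_expr, test_ids)
        for ct in dataset.cell_types:
            truth_tr = truth_expr[ct].subset_samples(train_ids)
            base = baseline_mean_predictor(truth_tr.values, truth_tr.gene_ids, ct)
            imputed[(ct, "baseline")] = base.predict(test_ids)
        for (ct, method), tensor in imputed.items():
            res = evaluate_method(cfg, dataset, truth_expr, ct, tensor,
                                  train_ids, test_ids)
            curve = res.pop("curve")
            if curve is not None:
                curve.to_frame().to_csv(
                    Path(cfg.out_dir) / f"recovery_{ct}_{method}.tsv",
                    sep="\t", index=False, lineterminator="\n")
            rows.append({"train_size": len(train_ids), "method": method, **res})
    cfg = dataclasses.replace(cfg, out_dir=base_out)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, lineterminator="\n",
                   float_format="%.6g")
    _manifest_update(out, "evaluate", {"rows": len(summary)})
    return summary
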