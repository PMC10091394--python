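"""End-to-end orchestration: simulate/load -> preprocess -> fuse -> cluster
-> survival models -> classifiers, from a single flat configuration.

Every stage derives its own seed from the master seed by a fixed counter
(stage_seed = (master * 1009 + stage_index) mod 2^31 - 1) so a completed run
is reproducible bit-for-bit from the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import gini_select, roc_auc, train_rf
from .cluster import ClusterConfig, consensus_cluster
from .fusion import build_gdtec, screen_gdtec_proportion
from .omics_io import (
    ClinicalTable,
    GdtecError,
    align_layers,
    read_clinical,
    read_matrix,
    read_mutation_table,
    write_matrix,
)
from .preprocess import (
    DiscretizationScheme,
    binarize_mutations,
    collapse_cnv,
    compute_lfc,
    discretize_lfc,
)
from .simulate import SyntheticSpec, generate, truth_ari
from .survival import cox_fit, count_group, km_logrank, risk_stratify

logger = logging.getLogger("gdtec")

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "snv", "cnv", "expr_tumor", "expr_normal", "clinical",
    "simulate", "n_samples", "n_genes", "n_subtypes",
    "p_driven_in", "p_driven_out", "lfc_effect", "expression_noise_sd",
    "censoring_rate",
    "lfc_low", "lfc_high", "pseudocount", "cnv_mode", "nonsilent_only",
    "max_zero_fraction",
    "base_method", "distance", "k_min", "k_max", "reps", "subsample_fraction",
    "elbow_threshold",
    "screen_hi", "screen_lo", "n_cox_features",
    "train_fraction", "n_trees", "gini_top_n",
    "outdir", "seed",
}


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run. Unknown keys are errors."""

    # inputs: either file paths or simulate=True
    snv: str | None = None
    cnv: str | None = None
    expr_tumor: str | None = None
    expr_normal: str | None = None
    clinical: str | None = None
    simulate: bool = False
    n_samples: int = 200
    n_genes: int = 80
    n_subtypes: int = 4
    p_driven_in: float = 0.8
    p_driven_out: float = 0.05
    lfc_effect: float = 2.0
    expression_noise_sd: float = 0.3
    censoring_rate: float = 0.2
    # preprocess
    lfc_low: float = -1.0
    lfc_high: float = 1.0
    pseudocount: float = 1.0
    cnv_mode: str = "sign"
    nonsilent_only: bool = True
    # fusion
    max_zero_fraction: float = 0.6
    # clustering
    base_method: str = "pam"
    distance: str = "binary"
    k_min: int = 2
    k_max: int = 6
    reps: int = 250
    subsample_fraction: float = 0.8
    elbow_threshold: float = 0.08
    # screening / survival / classification
    screen_hi: float = 0.7
    screen_lo: float = 0.3
    n_cox_features: int = 2
    train_fraction: float = 0.7
    n_trees: int = 500
    gini_top_n: int = 18
    # run
    outdir: str = "gdtec_run"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise GdtecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if not self.simulate:
            for key in ("snv", "cnv", "expr_tumor", "expr_normal", "clinical"):
                path = getattr(self, key)
                if path is None:
                    raise GdtecError(f"config must set {key!r} or simulate=true")
                if not Path(path).exists():
                    raise GdtecError(f"input file for {key!r} not found: {path}")
        if self.k_max >= self.n_samples and self.simulate:
            raise GdtecError("k_max must be below the number of samples")
        if self.k_min < 2 or self.k_min > self.k_max:
            raise GdtecError("invalid k range")


def _stage_seed(master: int, index: int) -> int:
    return (master * 1009 + index) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write outputs plus a run manifest.

    Returns the manifest.  A stage failure is recorded in the manifest and
    downstream stages are skipped.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    state: dict = {}

    stages = [
        ("inputs", _stage_inputs),
        ("preprocess", _stage_preprocess),
        ("fuse", _stage_fuse),
        ("cluster", _stage_cluster),
        ("survival", _stage_survival),
        ("classify", _stage_classify),
    ]
    for i, (name, fn) in enumerate(stages):
        try:
            info = fn(config, state, outdir, _stage_seed(config.seed, i))
            manifest["stages"].append({"name": name, "status": "completed", **info})
        except Exception as exc:
            logger.exception("stage %s failed", name)
            manifest["stages"].append(
                {"name": name, "status": "failed", "error": str(exc)}
            )
            break
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _stage_inputs(config: RunConfig, state: dict, outdir: Path, seed: int) -> dict:
    if config.simulate:
        spec = SyntheticSpec(
            n_samples=config.n_samples,
            n_genes=config.n_genes,
            n_subtypes=config.n_subtypes,
            p_driven_in=config.p_driven_in,
            p_driven_out=config.p_driven_out,
            lfc_effect=config.lfc_effect,
            expression_noise_sd=config.expression_noise_sd,
            censoring_rate=config.censoring_rate,
            seed=seed,
        )
        cohort = generate(spec)
        state["cohort"] = cohort
        state["mutations"] = cohort.mutations
        state["cnv"] = cohort.cnv
        state["expr_tumor"] = cohort.expr_tumor
        state["expr_normal"] = cohort.expr_normal
        state["clinical"] = cohort.clinical
        return {"source": "simulated", "n_samples": spec.n_samples, "n_genes": spec.n_genes}
    state["mutations"] = read_mutation_table(config.snv)
    state["cnv"] = read_matrix(config.cnv, "integer-calls")
    state["expr_tumor"] = read_matrix(config.expr_tumor, "real")
    state["expr_normal"] = read_matrix(config.expr_normal, "real")
    state["clinical"] = read_clinical(config.clinical)
    (layers, clin, report) = align_layers(
        [state["cnv"], state["expr_tumor"]], state["clinical"]
    )
    state["cnv"], state["expr_tumor"] = layers
    state["clinical"] = clin
    return {"source": "files", "alignment": {k: report[k] for k in ("n_genes", "n_samples")}}


def _stage_preprocess(config: RunConfig, state: dict, outdir: Path, seed: int) -> dict:
    scheme = DiscretizationScheme(low=config.lfc_low, high=config.lfc_high)
    lfc = compute_lfc(state["expr_tumor"], state["expr_normal"], config.pseudocount)
    post_rnaseq = discretize_lfc(lfc, scheme)
    post_cnv = collapse_cnv(state["cnv"], config.cnv_mode)
    post_snv, drop_report = binarize_mutations(
        state["mutations"],
        post_rnaseq.gene_ids,
        post_rnaseq.sample_ids,
        config.nonsilent_only,
    )
    state.update(lfc=lfc, post_rnaseq=post_rnaseq, post_cnv=post_cnv, post_snv=post_snv)
    for name in ("post_rnaseq", "post_cnv", "post_snv"):
        write_matrix(state[name], outdir / f"{name}.tsv")
    return {"lfc_band": [config.lfc_low, config.lfc_high], "drops": drop_report}


def _stage_fuse(config: RunConfig, state: dict, outdir: Path, seed: int) -> dict:
    result = build_gdtec(
        state["post_snv"], state["post_cnv"], state["post_rnaseq"],
        config.max_zero_fraction,
    )
    if result.matrix.shape[0] < 2:
        raise GdtecError("fewer than two genes retained after the sparsity filter")
    state["gdtec"] = result
    write_matrix(result.matrix, outdir / "gdtec.tsv")
    return {
        "n_retained_genes": len(result.retained_genes),
        "n_removed_genes": len(result.removed_genes),
    }


def _stage_cluster(config: RunConfig, state: dict, outdir: Path, seed: int) -> dict:
    cc = ClusterConfig(
        base_method=config.base_method,
        distance=config.distance,
        k_range=(config.k_min, config.k_max),
        reps=config.reps,
        subsample_fraction=config.subsample_fraction,
        seed=seed,
        elbow_threshold=config.elbow_threshold,
    )
    run = consensus_cluster(state["gdtec"].matrix, cc)
    state["run"] = run
    run.final_partition.to_csv(outdir / "partition.tsv", sep="\t", index_label="sample_id")
    summary = {
        "chosen_k": run.chosen_k,
        "areas": run.areas,
        "deltas": run.deltas,
        "degenerate_k": run.degenerate_k,
    }
    info: dict = dict(summary)
    if "cohort" in state:
        info["ari_vs_truth"] = truth_ari(run.final_partition, state["cohort"])
    with open(outdir / "cluster_summary.json", "w") as fh:
        json.dump(info, fh, indent=1, sort_keys=True)
    return info


def _worst_cluster(state: dict) -> int:
    """The cluster with the worst outcome: highest event rate, ties broken by
    mean GDTEC burden (most genome-driven genes)."""
    part = state["run"].final_partition
    clin = state["clinical"].records
    burden = state["gdtec"].matrix.values.sum(axis=0)
    best, key = None, None
    for c in sorted(part.unique()):
        ids = part.index[part == c]
        ev = clin.loc[ids, "os_event"].mean()
        bu = burden[ids].mean()
        if key is None or (ev, bu) > key:
            best, key = c, (ev, bu)
    return int(best)


def _stage_survival(config: RunConfig, state: dict, outdir: Path, seed: int) -> dict:
    part = state["run"].final_partition
    clin: ClinicalTable = state["clinical"]
    lr = km_logrank(clin, part)
    gdtec = state["gdtec"].matrix

    # univariate screen over retained genes, then a multivariate risk model
    feats = gdtec.values.T  # samples x genes
    variable = [g for g in feats.columns if feats[g].nunique() > 1]
    uni = cox_fit(clin, feats[variable], mode="univariate-per-feature")
    ranked = uni.summary.reindex(uni.summary["pvalue"].sort_values().index)
    top = list(ranked.index[: config.n_cox_features])
    info: dict = {
        "logrank_statistic": lr["statistic"],
        "logrank_pvalue": lr["pvalue"],
        "n_screened": len(variable),
        "risk_genes": top,
    }
    if len(top) >= 1:
        multi = cox_fit(clin, feats[top], mode="multivariate")
        state["cox"] = multi
        multi.summary.to_csv(outdir / "cox_summary.tsv", sep="\t", index_label="feature")
        multi.risk_scores.rename("risk_score").to_csv(
            outdir / "risk_scores.tsv", sep="\t", index_label="sample_id"
        )
        try:
            groups = risk_stratify(multi)
            groups.to_csv(outdir / "risk_groups.tsv", sep="\t", index_label="sample_id")
            lr_risk = km_logrank(clin, groups)
            info["risk_logrank_pvalue"] = lr_risk["pvalue"]
        except GdtecError as exc:
            info["risk_stratify_flag"] = str(exc)
        if len(top) == 2:
            counts = count_group(gdtec, top)
            counts.to_csv(outdir / "count_groups.tsv", sep="\t", index_label="sample_id")
            if counts.nunique() > 1:
                info["count_logrank_pvalue"] = km_logrank(clin, counts)["pvalue"]
        info["cox_summary"] = {
            g: {k: float(v) for k, v in row.items()}
            for g, row in multi.summary.iterrows()
        }
    return info


def _stage_classify(config: RunConfig, state: dict, outdir: Path, seed: int) -> dict:
    part = state["run"].final_partition
    worst = _worst_cluster(state)
    labels = pd.Series(
        np.where(part == worst, "Mix_Sub", "other"), index=part.index
    )
    gdtec = state["gdtec"].matrix
    screen = screen_gdtec_proportion(
        gdtec, labels, hi=config.screen_hi, lo=config.screen_lo,
        positive_group="Mix_Sub",
    )
    markers = list(screen.index[screen["selected"]])
    if len(markers) < 2:
        markers = list(gdtec.gene_ids)
    feats = gdtec.values.loc[markers].T
    fit = train_rf(
        feats, labels, positive_class="Mix_Sub",
        train_fraction=config.train_fraction, n_trees=config.n_trees, seed=seed,
    )
    roc = roc_auc(fit.test_scores, (fit.test_labels == "Mix_Sub").astype(int))
    acc = float((fit.predicted == fit.test_labels).mean())

    # expression-level classifier on the LFC of the top-importance genes
    top_genes = gini_select(fit, mode="top_n", value=min(config.gini_top_n, len(markers)))
    lfc_feats = state["lfc"].values.loc[top_genes].T
    fit_expr = train_rf(
        lfc_feats, labels, positive_class="Mix_Sub",
        train_fraction=config.train_fraction, n_trees=config.n_trees, seed=seed + 1,
    )
    roc_expr = roc_auc(fit_expr.test_scores, (fit_expr.test_labels == "Mix_Sub").astype(int))

    fit.test_scores.rename("score").to_csv(
        outdir / "classifier_scores.tsv", sep="\t", index_label="sample_id"
    )
    info = {
        "positive_cluster": worst,
        "n_markers": len(markers),
        "gdtec_auc": roc.auc,
        "gdtec_accuracy": acc,
        "n_expression_features": len(top_genes),
        "expression_auc": roc_expr.auc,
    }
    with open(outdir / "classifier_summary.json", "w") as fh:
        json.dump(info, fh, indent=1, sort_keys=True)
    return info
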