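"""Synthetic multi-omics cohorts with planted subtype structure.

Generates aligned mutation / copy-number / tumor-expression / normal-
expression layers plus a clinical table, with known ground truth: subtype
labels, per-subtype driven-gene sets, and true log-hazards.  Driven events
are planted per cell as either CNV-type (a copy-number call whose sign
matches a ±lfc_effect expression shift) or SNV-type (a somatic mutation
plus an expression shift of random sign), mutually exclusive by default so
the fusion XOR rule has a clean noiseless limit.

Default design: four equally sized subtypes over 80 genes, with each gene
driven in exactly two cyclically adjacent subtypes (gene block i is driven
in subtypes i and i+1 mod 4).  This keeps the four GDTEC signatures
distinct while leaving each informative gene GDTEC-positive in roughly 43%
of samples, so the 60% sparsity filter retains the planted structure —
mirroring real cohorts, where retained genes are the GDTEC-rich ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .omics_io import (
    ClinicalTable,
    GdtecError,
    GeneSampleMatrix,
    MutationTable,
    write_clinical,
    write_matrix,
    write_mutation_table,
)

__all__ = ["SyntheticSpec", "SyntheticCohort", "generate", "truth_ari", "write_cohort"]


def _default_subtype_hazards() -> list[float]:
    return [0.0, 0.3, 0.6, 1.0]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Probabilities are per gene x sample cell; ``p_driven_in`` applies where
    the gene belongs to the sample's subtype driven set, ``p_driven_out``
    elsewhere.  Expression is baseline x 2^(shift + N(0, noise_sd));
    survival is exponential with log-hazard = subtype baseline + sum of
    per-gene effects over planted events; censoring is independent
    exponential calibrated to the target rate.
    """

    n_samples: int = 200
    n_genes: int = 80
    n_subtypes: int = 4
    subtype_proportions: list[float] | None = None
    driven_gene_sets: list[list[int]] | None = None  # gene indices per subtype
    p_driven_in: float = 0.8
    p_driven_out: float = 0.05
    cnv_vs_snv_mix: float = 0.5
    expression_noise_sd: float = 0.3  # log2 scale
    lfc_effect: float = 2.0
    n_normal: int = 50
    baseline_log_mean: float = 5.0  # natural-log scale of the lognormal baseline
    baseline_log_sd: float = 1.0
    subtype_log_hazards: list[float] = field(default_factory=_default_subtype_hazards)
    gene_log_hazards: dict[int, float] = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.2
    p_cooccurrence: float = 0.0  # probability a driven event is both CNV and SNV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_proportions is None:
            self.subtype_proportions = [1.0 / self.n_subtypes] * self.n_subtypes
        if len(self.subtype_proportions) != self.n_subtypes:
            raise GdtecError("one proportion per subtype required")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise GdtecError("subtype proportions must sum to 1")
        for p in (self.p_driven_in, self.p_driven_out, self.cnv_vs_snv_mix,
                  self.p_cooccurrence):
            if not 0 <= p <= 1:
                raise GdtecError("probabilities must lie in [0, 1]")
        if not self.p_driven_in > self.p_driven_out:
            raise GdtecError("p_driven_in must exceed p_driven_out")
        if not 0 <= self.censoring_rate < 1:
            raise GdtecError("censoring_rate must lie in [0, 1)")
        if len(self.subtype_log_hazards) != self.n_subtypes:
            raise GdtecError("one baseline log-hazard per subtype required")
        if self.driven_gene_sets is None:
            self.driven_gene_sets = _cyclic_driven_sets(self.n_genes, self.n_subtypes)
        if len(self.driven_gene_sets) != self.n_subtypes:
            raise GdtecError("one driven-gene set per subtype required")
        for s in self.driven_gene_sets:
            if any(g < 0 or g >= self.n_genes for g in s):
                raise GdtecError("driven gene index outside the gene universe")


def _cyclic_driven_sets(n_genes: int, n_subtypes: int) -> list[list[int]]:
    """Gene block i is driven in subtypes i and (i+1) mod n_subtypes."""
    blocks = np.array_split(np.arange(n_genes), n_subtypes)
    sets: list[list[int]] = [[] for _ in range(n_subtypes)]
    for i, block in enumerate(blocks):
        for t in (i, (i + 1) % n_subtypes):
            sets[t].extend(int(g) for g in block)
    return [sorted(s) for s in sets]


@dataclass
class SyntheticCohort:
    mutations: MutationTable
    cnv: GeneSampleMatrix  # integer calls
    expr_tumor: GeneSampleMatrix
    expr_normal: GeneSampleMatrix
    clinical: ClinicalTable
    truth_labels: pd.Series  # sample -> subtype index
    driven_gene_sets: list[list[str]]  # gene IDs per subtype
    true_log_hazards: pd.Series
    events: dict  # planted event masks, for oracles
    spec: SyntheticSpec


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a cohort; bit-reproducible for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    normals = [f"N{i:04d}" for i in range(spec.n_normal)]

    # subtype labels: largest-remainder sizes, then a random permutation
    raw = np.array(spec.subtype_proportions) * spec.n_samples
    sizes = np.floor(raw).astype(int)
    rem = spec.n_samples - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:rem]] += 1
    labels = np.repeat(np.arange(spec.n_subtypes), sizes)
    labels = labels[rng.permutation(spec.n_samples)]

    driven = np.zeros((spec.n_genes, spec.n_samples), dtype=bool)
    for t, gene_set in enumerate(spec.driven_gene_sets):
        driven[np.ix_(gene_set, np.flatnonzero(labels == t))] = True
    p = np.where(driven, spec.p_driven_in, spec.p_driven_out)
    event = rng.random((spec.n_genes, spec.n_samples)) < p

    both = event & (rng.random(event.shape) < spec.p_cooccurrence)
    is_cnv = event & (rng.random(event.shape) < spec.cnv_vs_snv_mix)
    is_snv = event & ~is_cnv
    is_cnv |= both
    is_snv |= both

    sign = np.where(rng.random(event.shape) < 0.5, 1.0, -1.0)
    magnitude = np.where(rng.random(event.shape) < 0.5, 1.0, 2.0)
    cnv_calls = np.where(is_cnv, sign * magnitude, 0.0)

    # expression shift: CNV events shift with the CNV sign; SNV-only events
    # shift with an independent random sign
    shift_sign = np.where(is_cnv, sign, np.where(rng.random(event.shape) < 0.5, 1.0, -1.0))
    shift = np.where(event, shift_sign * spec.lfc_effect, 0.0)

    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    tum_noise = rng.normal(0.0, spec.expression_noise_sd, (spec.n_genes, spec.n_samples))
    nor_noise = rng.normal(0.0, spec.expression_noise_sd, (spec.n_genes, spec.n_normal))
    expr_tumor = base[:, None] * np.power(2.0, shift + tum_noise)
    expr_normal = base[:, None] * np.power(2.0, nor_noise)

    gi, si = np.nonzero(is_snv)
    mut_df = pd.DataFrame(
        {
            "sample_id": [samples[j] for j in si],
            "gene_id": [genes[i] for i in gi],
            "variant_classification": "Missense_Mutation",
        }
    )

    gene_eff = np.zeros(spec.n_genes)
    for g, eff in spec.gene_log_hazards.items():
        gene_eff[g] = eff
    log_hazard = np.array([spec.subtype_log_hazards[t] for t in labels])
    log_hazard = log_hazard + gene_eff @ event
    rate = spec.baseline_hazard * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        # Exp censoring at rate * c/(1-c) gives P(censored) = c per sample
        c = spec.censoring_rate
        t_cens = rng.exponential(1.0 / (rate * c / (1.0 - c)))
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time, os_event = t_event, np.ones(spec.n_samples, dtype=int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {"os_time": os_time, "os_event": os_event},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return SyntheticCohort(
        mutations=MutationTable(mut_df),
        cnv=GeneSampleMatrix(
            pd.DataFrame(cnv_calls, index=genes, columns=samples), "integer-calls"
        ),
        expr_tumor=GeneSampleMatrix(
            pd.DataFrame(expr_tumor, index=genes, columns=samples), "real"
        ),
        expr_normal=GeneSampleMatrix(
            pd.DataFrame(expr_normal, index=genes, columns=normals), "real"
        ),
        clinical=clinical,
        truth_labels=pd.Series(labels, index=samples, name="subtype"),
        driven_gene_sets=[[genes[g] for g in s] for s in spec.driven_gene_sets],
        true_log_hazards=pd.Series(log_hazard, index=samples, name="log_hazard"),
        events={"event": event, "is_cnv": is_cnv, "is_snv": is_snv, "shift": shift},
        spec=spec,
    )


def truth_ari(partition: pd.Series | dict, cohort: SyntheticCohort) -> float:
    """Adjusted Rand index between a partition and the planted subtype labels."""
    part = pd.Series(partition)
    if set(part.index) != set(cohort.truth_labels.index):
        raise GdtecError("partition does not cover the cohort samples")
    part = part.reindex(cohort.truth_labels.index)
    return float(adjusted_rand_score(cohort.truth_labels.to_numpy(), part.to_numpy()))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write the five input files (formats omics_io reads) plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mutation_table(cohort.mutations, outdir / "mutations.maf")
    write_matrix(cohort.cnv, outdir / "cnv_calls.tsv")
    cohort.expr_tumor.values.to_csv(outdir / "expr_tumor.tsv", sep="\t", index_label="gene_id")
    cohort.expr_normal.values.to_csv(outdir / "expr_normal.tsv", sep="\t", index_label="gene_id")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    truth = {
        "subtype_labels": {s: int(t) for s, t in cohort.truth_labels.items()},
        "driven_gene_sets": cohort.driven_gene_sets,
        "true_log_hazards": {s: float(h) for s, h in cohort.true_log_hazards.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {"outdir": str(outdir), "files": sorted(p.name for p in outdir.iterdir())}
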