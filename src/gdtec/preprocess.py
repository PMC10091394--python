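"""Discretization of the three omics layers.

Builds the binary mutation layer (post-SNV), the ternary copy-number layer
(post-CNV), and the ternary expression-change layer (post-RNAseq, via log2
fold change of each tumor sample against the mean normal reference), plus
the multi-level scoring variant and the absolute-value transform
(post2-RNAseq) consumed by the fusion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omics_io import (
    AlignmentError,
    DomainError,
    GdtecError,
    GeneSampleMatrix,
    MutationTable,
    SILENT_CLASSES,
)

__all__ = [
    "LFCMatrix",
    "DiscretizationScheme",
    "compute_lfc",
    "discretize_lfc",
    "discretize_lfc_multilevel",
    "binarize_mutations",
    "collapse_cnv",
    "absolutize",
]


@dataclass
class LFCMatrix:
    """Per-gene, per-tumor-sample log2 fold change against a normal reference."""

    values: pd.DataFrame
    pseudocount: float = 1.0
    reference: str = "per-gene mean over normal samples"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DiscretizationScheme:
    """How an LFC matrix is turned into discrete expression-change calls.

    ``binary-threshold`` maps LFC >= high to 1, <= low to -1, else 0 — the
    band (low, high) is "normal expression" and threshold-equal values count
    as abnormal.  ``multi-level`` assigns sign(LFC) times the score of the
    highest band whose lower bound <= |LFC|.
    """

    kind: str = "binary-threshold"
    low: float = -1.0
    high: float = 1.0
    level_bands: list[tuple[float, int]] = field(
        default_factory=lambda: [(1.0, 1), (2.0, 2), (3.0, 3)]
    )

    def __post_init__(self) -> None:
        if self.kind not in ("binary-threshold", "multi-level"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError("scheme requires low < high")
        if self.kind == "multi-level":
            if not self.level_bands:
                raise GdtecError("multi-level scheme requires at least one band")
            bounds = [b for b, _ in self.level_bands]
            scores = [s for _, s in self.level_bands]
            if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
                raise ValueError("band lower bounds must be strictly increasing")
            if any(s <= 0 or int(s) != s for s in scores):
                raise ValueError("band scores must be positive integers")


def compute_lfc(
    tumor: GeneSampleMatrix,
    normal: GeneSampleMatrix,
    pseudocount: float = 1.0,
) -> LFCMatrix:
    """log2((tumor + p) / (mean over normal samples + p)), per gene per sample.

    The reference is the per-gene mean abundance over all normal samples;
    the pseudocount is added to both numerator and reference on the
    abundance scale before the log.
    """
    missing = set(tumor.gene_ids) - set(normal.gene_ids)
    if missing:
        raise AlignmentError(
            f"genes present in tumor but absent in normal: {sorted(missing)[:5]}"
        )
    if normal.shape[1] < 1:
        raise AlignmentError("normal matrix has no samples")
    ref = normal.values.loc[tumor.gene_ids].mean(axis=1) + pseudocount
    if (ref <= 0).any():
        bad = ref.index[ref <= 0][0]
        raise ZeroDivisionError(
            f"non-positive reference mean for gene {bad!r} with pseudocount {pseudocount}"
        )
    lfc = np.log2(tumor.values.add(pseudocount).div(ref, axis=0))
    return LFCMatrix(lfc, pseudocount=pseudocount)


def discretize_lfc(
    lfc: LFCMatrix, scheme: DiscretizationScheme | None = None
) -> GeneSampleMatrix:
    """Ternary expression-change calls: 1 if LFC >= high, -1 if <= low, else 0."""
    scheme = scheme or DiscretizationScheme()
    arr = lfc.values.to_numpy()
    out = np.where(arr >= scheme.high, 1.0, np.where(arr <= scheme.low, -1.0, 0.0))
    return GeneSampleMatrix(
        pd.DataFrame(out, index=lfc.values.index, columns=lfc.values.columns),
        "ternary",
    )


def discretize_lfc_multilevel(
    lfc: LFCMatrix, scheme: DiscretizationScheme | None = None
) -> GeneSampleMatrix:
    """Signed multi-level scores: sign(LFC) x score of the highest band reached."""
    if scheme is None:
        scheme = DiscretizationScheme(kind="multi-level")
    if not scheme.level_bands:
        raise GdtecError("multi-level scheme requires at least one band")
    arr = lfc.values.to_numpy()
    mag = np.abs(arr)
    score = np.zeros_like(arr)
    for bound, s in scheme.level_bands:  # bounds increasing; later bands overwrite
        score = np.where(mag >= bound, float(s), score)
    out = np.sign(arr) * score
    return GeneSampleMatrix(
        pd.DataFrame(out, index=lfc.values.index, columns=lfc.values.columns),
        "integer-calls",
    )


def binarize_mutations(
    muts: MutationTable,
    genes: list[str],
    samples: list[str],
    nonsilent_only: bool = True,
) -> tuple[GeneSampleMatrix, dict]:
    """Gene x sample 0/1 mutation matrix over the given ID universes.

    A cell is 1 iff at least one qualifying record exists for that
    (gene, sample).  With ``nonsilent_only``, records in the silent set
    (Silent, Intron, UTRs, Flanks, IGR, RNA) do not qualify.  Records for
    IDs outside the universes are dropped and counted in the report.
    """
    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(genes), len(samples)))
    rec = muts.records
    if nonsilent_only:
        rec = rec[~rec["variant_classification"].isin(SILENT_CLASSES)]
    n_silent_skipped = len(muts.records) - len(rec)
    dropped = 0
    for g, s in zip(rec["gene_id"], rec["sample_id"]):
        gi = gene_idx.get(g)
        sj = sample_idx.get(s)
        if gi is None or sj is None:
            dropped += 1
            continue
        mat[gi, sj] = 1.0
    report = {"records_outside_universe": dropped, "silent_records_skipped": n_silent_skipped}
    return (
        GeneSampleMatrix(pd.DataFrame(mat, index=genes, columns=samples), "binary"),
        report,
    )


def collapse_cnv(calls: GeneSampleMatrix, mode: str = "sign") -> GeneSampleMatrix:
    """Collapse GISTIC-style integer calls to ternary gain/neutral/loss.

    ``sign`` keeps any amplification/deletion (entry = sign of the call);
    ``deep-only`` keeps only |call| = 2 events.
    """
    arr = calls.to_numpy()
    if not np.all(np.isfinite(arr) & (arr == np.round(arr))):
        raise DomainError("CNV calls must be integers")
    if mode == "sign":
        out = np.sign(arr)
    elif mode == "deep-only":
        out = np.where(np.abs(arr) >= 2, np.sign(arr), 0.0)
    else:
        raise ValueError(f"unknown collapse mode {mode!r}")
    return GeneSampleMatrix(
        pd.DataFrame(out, index=calls.values.index, columns=calls.values.columns),
        "ternary",
    )


def absolutize(post_rnaseq: GeneSampleMatrix) -> GeneSampleMatrix:
    """|x| of a ternary matrix: marks any expression change (either sign) as 1."""
    arr = post_rnaseq.to_numpy()
    if not np.isin(arr, (-1.0, 0.0, 1.0)).all():
        raise DomainError("absolutize expects a ternary matrix")
    return GeneSampleMatrix(
        pd.DataFrame(
            np.abs(arr), index=post_rnaseq.values.index, columns=post_rnaseq.values.columns
        ),
        "binary",
    )
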