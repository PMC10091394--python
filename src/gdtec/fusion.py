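"""GDTEC fusion arithmetic and feature-screening rules.

The core of the method: per gene per patient, an expression change that is
concordant with a copy-number change (same sign) or co-occurs with a
somatic mutation marks the cell as genome-driven transcriptome expression
(GDTEC = 1).  Cells where both genomic mechanisms fire are set back to 0 —
simultaneous CNV- and mutation-driven expression of the same gene in the
same patient is treated as too rare to be a real signal.  Genes that are
GDTEC in too few samples are then removed (sparsity filter, default: drop
a gene if more than 60% of samples are 0).

Screening helpers select subtype-specific features: by GDTEC proportion in
two patient groups, by differential expression (Welch t / Wilcoxon on log2
values with Benjamini-Hochberg correction), or by Spearman correlation of
paired genes (ligand-receptor style lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .omics_io import AlignmentError, GdtecError, GeneSampleMatrix
from .preprocess import absolutize

__all__ = [
    "GDTECResult",
    "cnv_rna_consistency",
    "snv_rna_consistency",
    "fuse_gdtec",
    "filter_sparse_genes",
    "build_gdtec",
    "screen_gdtec_proportion",
    "differential_genes",
    "correlate_pairs",
]


def _require_same_shape(a: GeneSampleMatrix, b: GeneSampleMatrix) -> None:
    if a.shape != b.shape or a.gene_ids != b.gene_ids or a.sample_ids != b.sample_ids:
        raise AlignmentError(
            f"matrices not aligned: shapes {a.shape} vs {b.shape} or differing IDs"
        )


def _binary(df_values: np.ndarray, template: GeneSampleMatrix) -> GeneSampleMatrix:
    return GeneSampleMatrix(
        pd.DataFrame(
            df_values, index=template.values.index, columns=template.values.columns
        ),
        "binary",
    )


def cnv_rna_consistency(
    post_cnv: GeneSampleMatrix, post_rnaseq: GeneSampleMatrix
) -> GeneSampleMatrix:
    """CNV-RNAseq consistency: 1 iff copy-number and expression change agree in sign.

    The ternary layers are summed; sums of +-2 (both +1 or both -1) mark
    CNV-driven expression (1), sums of +-1 mark expression not driven by
    CNV (0).
    """
    _require_same_shape(post_cnv, post_rnaseq)
    total = post_cnv.to_numpy() + post_rnaseq.to_numpy()
    return _binary(np.where(np.abs(total) == 2, 1.0, 0.0), post_cnv)


def snv_rna_consistency(
    post_snv: GeneSampleMatrix, post2_rnaseq: GeneSampleMatrix
) -> GeneSampleMatrix:
    """SNV-RNAseq consistency: 1 iff a mutation co-occurs with any expression change.

    Sum of the two binary layers; 2 marks mutation-driven expression (1),
    1 marks expression not driven by mutation (0).
    """
    _require_same_shape(post_snv, post2_rnaseq)
    total = post_snv.to_numpy() + post2_rnaseq.to_numpy()
    return _binary(np.where(total == 2, 1.0, 0.0), post_snv)


def fuse_gdtec(
    cnv_rna: GeneSampleMatrix, snv_rna: GeneSampleMatrix
) -> GeneSampleMatrix:
    """Fuse the two consistency matrices: XOR.

    The matrices are summed and 2s are marked 0 — a cell driven by both
    mechanisms at once is discarded as implausibly rare — so GDTEC is 1 iff
    exactly one of the consistency matrices is 1.
    """
    _require_same_shape(cnv_rna, snv_rna)
    total = cnv_rna.to_numpy() + snv_rna.to_numpy()
    return _binary(np.where(total == 1, 1.0, 0.0), cnv_rna)


@dataclass
class GDTECResult:
    """GDTEC matrix after the sparsity filter, with provenance."""

    matrix: GeneSampleMatrix
    cnv_rna: GeneSampleMatrix
    snv_rna: GeneSampleMatrix
    retained_genes: list[str]
    removed_genes: list[str]
    filter_fraction: float
    provenance: dict = field(default_factory=dict)


def filter_sparse_genes(
    gdtec: GeneSampleMatrix,
    max_zero_fraction: float = 0.6,
    cnv_rna: GeneSampleMatrix | None = None,
    snv_rna: GeneSampleMatrix | None = None,
) -> GDTECResult:
    """Remove genes whose GDTEC row is 0 in MORE than ``max_zero_fraction`` of samples.

    The inequality is strict: a gene with exactly 60% zeros is retained.
    """
    if not 0 < max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    n_samples = gdtec.shape[1]
    if n_samples == 0:
        raise GdtecError("cannot filter a matrix with zero samples")
    zero_frac = (gdtec.to_numpy() == 0).sum(axis=1) / n_samples
    keep = zero_frac <= max_zero_fraction
    retained = [g for g, k in zip(gdtec.gene_ids, keep) if k]
    removed = [g for g, k in zip(gdtec.gene_ids, keep) if not k]
    if not retained:
        filtered = GeneSampleMatrix(
            gdtec.values.iloc[:0], "binary"
        )
    else:
        filtered = GeneSampleMatrix(gdtec.values.loc[retained], "binary")
    return GDTECResult(
        matrix=filtered,
        cnv_rna=cnv_rna if cnv_rna is not None else gdtec,
        snv_rna=snv_rna if snv_rna is not None else gdtec,
        retained_genes=retained,
        removed_genes=removed,
        filter_fraction=max_zero_fraction,
        provenance={"n_input_genes": gdtec.shape[0], "n_samples": n_samples},
    )


def build_gdtec(
    post_snv: GeneSampleMatrix,
    post_cnv: GeneSampleMatrix,
    post_rnaseq: GeneSampleMatrix,
    max_zero_fraction: float = 0.6,
) -> GDTECResult:
    """Full fusion: consistency matrices -> XOR -> sparsity filter."""
    post2 = absolutize(post_rnaseq)
    cnv_rna = cnv_rna_consistency(post_cnv, post_rnaseq)
    snv_rna = snv_rna_consistency(post_snv, post2)
    fused = fuse_gdtec(cnv_rna, snv_rna)
    return filter_sparse_genes(
        fused, max_zero_fraction, cnv_rna=cnv_rna, snv_rna=snv_rna
    )


def _split_groups(sample_ids: list[str], groups: pd.Series | dict) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(groups).reindex(sample_ids)
    if labels.isna().any():
        raise AlignmentError("group labels missing for some samples")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise GdtecError(f"expected exactly two groups, found {uniq}")
    in_a = (labels == uniq[0]).to_numpy()
    return in_a, ~in_a


def screen_gdtec_proportion(
    gdtec: GeneSampleMatrix,
    groups: pd.Series | dict,
    hi: float = 0.7,
    lo: float = 0.3,
    positive_group=None,
) -> pd.DataFrame:
    """Select genes GDTEC-rich in one group and GDTEC-poor in the other.

    A gene is selected iff its proportion of 1s is >= ``hi`` in the positive
    group and <= ``lo`` in the other.  ``positive_group`` names the label of
    the enriched group (default: lexicographically larger label, matching
    "Mix_Sub" > "non" orderings is the caller's concern).
    """
    labels = pd.Series(groups).reindex(gdtec.sample_ids)
    if labels.isna().any():
        raise AlignmentError("group labels missing for some samples")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise GdtecError(f"expected exactly two groups, found {uniq}")
    pos = positive_group if positive_group is not None else uniq[0]
    if pos not in uniq:
        raise GdtecError(f"positive_group {pos!r} not among labels {uniq}")
    in_pos = (labels == pos).to_numpy()
    if in_pos.sum() == 0 or (~in_pos).sum() == 0:
        raise GdtecError("both groups must be non-empty")
    arr = gdtec.to_numpy()
    prop_pos = arr[:, in_pos].mean(axis=1)
    prop_neg = arr[:, ~in_pos].mean(axis=1)
    selected = (prop_pos >= hi) & (prop_neg <= lo)
    return pd.DataFrame(
        {
            "proportion_positive": prop_pos,
            "proportion_negative": prop_neg,
            "selected": selected,
        },
        index=gdtec.gene_ids,
    )


def differential_genes(
    values: GeneSampleMatrix,
    groups: pd.Series | dict,
    min_abs_logfc: float = 0.58,
    max_fdr: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Two-group differential screen on log2-scale values.

    Effect size is the difference of group means; p-values from Welch's t
    (default) or Wilcoxon rank-sum; BH adjustment across genes.  A gene is
    selected iff |effect| >= ``min_abs_logfc`` and adjusted p < ``max_fdr``.
    Genes constant in both groups get p = 1 and are never selected.
    """
    in_a, in_b = _split_groups(values.sample_ids, groups)
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise GdtecError("each group needs at least two samples")
    arr = values.to_numpy()
    a, b = arr[:, in_a], arr[:, in_b]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    constant = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pvals = np.ones(arr.shape[0])
    nonconst = ~constant
    if nonconst.any():
        if test == "welch":
            _, p = stats.ttest_ind(
                a[nonconst], b[nonconst], axis=1, equal_var=False
            )
        elif test == "wilcoxon":
            _, p = stats.mannwhitneyu(
                a[nonconst], b[nonconst], axis=1, alternative="two-sided"
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        pvals[nonconst] = np.nan_to_num(p, nan=1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    selected = (np.abs(logfc) >= min_abs_logfc) & (fdr < max_fdr) & ~constant
    return pd.DataFrame(
        {"logfc": logfc, "pvalue": pvals, "fdr": fdr, "selected": selected},
        index=values.gene_ids,
    )


def correlate_pairs(
    expr: GeneSampleMatrix,
    pairs: list[tuple[str, str]],
    min_rho: float = 0.2,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation screen over gene pairs (e.g. ligand-receptor lists).

    A pair is selected iff rho >= ``min_rho`` and p < ``max_p``.  Pairs with
    a constant gene have undefined rho and are reported unselected with a
    ``degenerate`` flag.
    """
    if expr.shape[1] < 3:
        raise GdtecError("correlation needs at least three samples")
    rows = []
    for ga, gb in pairs:
        for g in (ga, gb):
            if g not in expr.values.index:
                raise KeyError(f"gene {g!r} not in expression matrix")
        xa = expr.values.loc[ga].to_numpy()
        xb = expr.values.loc[gb].to_numpy()
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            rows.append((ga, gb, np.nan, np.nan, False, True))
            continue
        rho, p = stats.spearmanr(xa, xb)
        rows.append((ga, gb, rho, p, bool(rho >= min_rho and p < max_p), False))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rho", "pvalue", "selected", "degenerate"]
    )
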