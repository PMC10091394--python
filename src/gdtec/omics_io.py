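"""Tabular I/O and cross-layer alignment for the GDTEC pipeline.

All matrices travel as :class:`GeneSampleMatrix` — a pandas DataFrame with
gene rows and sample columns plus a declared value domain that is enforced
on read and on construction.  Mutations travel as a long-format record
table (:class:`MutationTable`), clinical data as :class:`ClinicalTable`.

The canonical on-disk matrix format is TSV: gene IDs in the first column,
one column per sample, header row of sample IDs (UCSC Xena / GEO
series-matrix convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GdtecError",
    "FormatError",
    "DomainError",
    "AlignmentError",
    "MutationTable",
    "GeneSampleMatrix",
    "ClinicalTable",
    "read_mutation_table",
    "write_mutation_table",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "align_layers",
]


class GdtecError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GdtecError):
    """A file does not conform to its declared format."""


class DomainError(GdtecError):
    """A matrix value falls outside its declared value domain."""


class AlignmentError(GdtecError):
    """Layers cannot be aligned on shared gene/sample IDs."""


# Controlled vocabulary for MAF variant classifications.  Unknown values are
# preserved but flagged on the table.
VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
    }
)

#: Variant classes that do not alter the protein product; excluded when
#: binarizing mutations with ``nonsilent_only=True``.
SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)

VALUE_DOMAINS = ("real", "ternary", "binary", "integer-calls")

_MAF_COLUMNS = {
    "gene_id": "Hugo_Symbol",
    "sample_id": "Tumor_Sample_Barcode",
    "variant_classification": "Variant_Classification",
}


@dataclass
class MutationTable:
    """Long-format somatic mutation records (one row per call)."""

    records: pd.DataFrame  # columns: sample_id, gene_id, variant_classification
    unknown_classes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = ["sample_id", "gene_id", "variant_classification"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise FormatError(f"mutation table missing columns: {missing}")
        rec = self.records[required].astype(str)
        if (rec["sample_id"].str.len() == 0).any() or (rec["gene_id"].str.len() == 0).any():
            raise FormatError("mutation table contains empty sample or gene IDs")
        self.records = rec.reset_index(drop=True)
        unknown = set(rec["variant_classification"]) - VARIANT_CLASSES
        self.unknown_classes = frozenset(unknown)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSampleMatrix:
    """Gene x sample numeric matrix with a declared value domain."""

    values: pd.DataFrame  # index = gene IDs, columns = sample IDs
    value_domain: str = "real"

    def __post_init__(self) -> None:
        if self.value_domain not in VALUE_DOMAINS:
            raise DomainError(
                f"unknown value domain {self.value_domain!r}; expected one of {VALUE_DOMAINS}"
            )
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        self.values = df.astype(float)
        self.values.index.name = None
        self.values.columns.name = None
        _check_domain(self.values, self.value_domain)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def _check_domain(df: pd.DataFrame, domain: str) -> None:
    arr = df.to_numpy()
    if domain == "real":
        return
    if domain == "integer-calls":
        bad = np.isfinite(arr) & (arr != np.round(arr))
    elif domain == "ternary":
        bad = ~np.isin(arr, (-1.0, 0.0, 1.0))
    elif domain == "binary":
        bad = ~np.isin(arr, (0.0, 1.0))
    else:  # pragma: no cover - guarded in __post_init__
        raise DomainError(f"unknown domain {domain!r}")
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise DomainError(
            f"value {arr[g, s]!r} at gene {df.index[g]!r}, sample {df.columns[s]!r} "
            f"outside declared domain {domain!r}"
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical data: overall-survival time, event, covariates."""

    records: pd.DataFrame  # index = sample_id; columns os_time, os_event, ...

    def __post_init__(self) -> None:
        df = self.records
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if df.index.duplicated().any():
            raise FormatError("clinical table has duplicate sample IDs")
        if (df["os_time"].astype(float) < 0).any():
            raise DomainError("os_time must be non-negative")
        if not df["os_event"].astype(float).isin([0.0, 1.0]).all():
            raise DomainError("os_event must be 0 or 1")
        self.records = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)

    def __len__(self) -> int:
        return len(self.records)


def read_mutation_table(path: str | Path, format: str = "maf") -> MutationTable:
    """Read somatic mutation calls from a MAF or long-format TSV file.

    ``maf`` expects at least Hugo_Symbol / Tumor_Sample_Barcode /
    Variant_Classification; ``long-tsv`` expects gene_id / sample_id /
    variant_classification.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty mutation file: {path}") from None
    if df.empty:
        raise FormatError(f"mutation file has no records: {path}")
    if format == "maf":
        rename = {v: k for k, v in _MAF_COLUMNS.items()}
    elif format == "long-tsv":
        rename = {c: c for c in ("gene_id", "sample_id", "variant_classification")}
    else:
        raise ValueError(f"unknown mutation format {format!r}")
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise FormatError(f"mutation file {path} missing required column(s): {missing}")
    df = df[list(rename)].rename(columns=rename)
    return MutationTable(df)


def write_mutation_table(table: MutationTable, path: str | Path, format: str = "maf") -> None:
    df = table.records
    if format == "maf":
        df = df.rename(columns=_MAF_COLUMNS)[list(_MAF_COLUMNS.values())]
    elif format != "long-tsv":
        raise ValueError(f"unknown mutation format {format!r}")
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, value_domain: str = "real") -> GeneSampleMatrix:
    """Read a gene x sample TSV matrix, validating against ``value_domain``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return GeneSampleMatrix(df, value_domain)


def write_matrix(matrix: GeneSampleMatrix, path: str | Path) -> None:
    df = matrix.values
    if matrix.value_domain != "real":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"clinical file {path} missing 'sample_id' column")
    return ClinicalTable(df.set_index("sample_id"))


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.records.to_csv(path, sep="\t", index_label="sample_id")


def align_layers(
    layers: Sequence[GeneSampleMatrix],
    clinical: ClinicalTable | None = None,
) -> tuple[list[GeneSampleMatrix], ClinicalTable | None, dict]:
    """Restrict all layers (and clinical table) to shared genes and samples.

    Output layers use the lexicographically sorted intersection of gene IDs
    and of sample IDs, so alignment is canonical and idempotent.  Returns
    the aligned layers, the aligned clinical table (or None), and a report
    listing the IDs dropped from each input.
    """
    if len(layers) < 2 and clinical is None:
        raise AlignmentError("align_layers needs at least two layers")
    genes: set[str] | None = None
    samples: set[str] | None = None
    for layer in layers:
        genes = set(layer.gene_ids) if genes is None else genes & set(layer.gene_ids)
        samples = set(layer.sample_ids) if samples is None else samples & set(layer.sample_ids)
    if clinical is not None:
        samples = set(clinical.sample_ids) if samples is None else samples & set(clinical.sample_ids)
    if not genes or not samples:
        raise AlignmentError("empty gene or sample intersection across layers")
    gene_order = sorted(genes)
    sample_order = sorted(samples)
    report: dict = {"n_genes": len(gene_order), "n_samples": len(sample_order), "dropped": []}
    aligned = []
    for i, layer in enumerate(layers):
        dropped_g = sorted(set(layer.gene_ids) - genes)
        dropped_s = sorted(set(layer.sample_ids) - samples)
        report["dropped"].append(
            {"layer": i, "genes": dropped_g, "samples": dropped_s}
        )
        aligned.append(
            GeneSampleMatrix(
                layer.values.loc[gene_order, sample_order], layer.value_domain
            )
        )
    aligned_clin = None
    if clinical is not None:
        dropped_s = sorted(set(clinical.sample_ids) - samples)
        report["dropped"].append({"layer": "clinical", "genes": [], "samples": dropped_s})
        aligned_clin = ClinicalTable(clinical.records.loc[sample_order])
    return aligned, aligned_clin, report
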