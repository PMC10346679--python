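"""Plain-TSV readers and writers for the pipeline's artifacts."""

from __future__ import annotations

import pandas as pd

from .expression import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "read_phenotypes",
    "write_table",
]


def read_count_matrix(counts_path, lengths_path) -> CountMatrix:
    """Counts TSV (gene rows, sample-id header) + gene-length TSV (gene, length)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, lengths=lengths)


def write_count_matrix(cm: CountMatrix, counts_path, lengths_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.lengths.rename("length").to_frame().to_csv(lengths_path, sep="\t")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "environment", "timepoint", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    return design


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    required = {"trait", "environment", "timepoint", "genotype", "value"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table {path} missing columns: {sorted(missing)}")
    return pheno


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
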