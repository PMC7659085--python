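"""TSV readers/writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .expression import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_count_matrix",
    "write_count_matrix",
    "read_homology",
    "write_table",
]


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    counts = read_counts(counts_path)
    samples = pd.read_csv(samples_path, sep="\t")
    if "sample_id" not in samples.columns:
        raise SchemaError("sample sheet is missing required column 'sample_id'")
    return CountMatrix(counts, samples)


def write_count_matrix(cm: CountMatrix, out_dir, prefix: str = "") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_path = out_dir / f"{prefix}counts.tsv"
    samples_path = out_dir / f"{prefix}samples.tsv"
    write_counts(cm.counts, counts_path)
    cm.samples.reset_index().to_csv(samples_path, sep="\t", index=False)
    return counts_path, samples_path


def read_homology(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
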