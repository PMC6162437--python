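"""Plain-text readers and writers for the pipeline's tabular formats.

Everything is tab-separated UTF-8: expression matrices (first column gene id,
header row of sample ids), two-column label tables (sample, label), taxon
count tables (taxon id, phylum, family, species, then one column per sample),
enrichment-score matrices (set × sample) and protein FASTA (via Biopython).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_taxon_tsv",
    "write_taxon_tsv",
    "read_scores_tsv",
    "write_scores_tsv",
    "read_fasta",
    "write_fasta",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.isna().to_numpy().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene"
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t", float_format="%.6g")


def read_labels_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0].astype(str).rename("label")


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("sample").to_csv(path, sep="\t")


def read_taxon_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "taxon"
    return table


def write_taxon_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("taxon").to_csv(path, sep="\t")


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    scores = pd.read_csv(path, sep="\t", index_col=0)
    scores.index.name = "set"
    return scores


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.rename_axis("set").to_csv(path, sep="\t", float_format="%.8g")


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
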