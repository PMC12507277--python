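"""File format helpers: FASTA/FASTQ streaming, cluster membership tables,
truth sidecars, hit tables, and assignment tables.

All tabular formats are TSV with headers; sequence input is gz-transparent.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

PathLike = Union[str, Path]

CLUSTER_TSV_COLUMNS = ["cluster_id", "protein_id", "is_representative", "annotation"]
TRUTH_TSV_COLUMNS = ["read_id", "true_cluster", "true_protein", "n_mutations", "start", "length"]
ASSIGNMENT_TSV_COLUMNS = ["read_id", "cluster_id", "score", "classified", "annotation"]
HIT_TABLE_COLUMNS = ["qseqid", "sseqid", "pident", "evalue"]

# blast/diamond -outfmt 6 default column order (headerless)
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _open_text(path: PathLike) -> IO[str]:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def sniff_format(path: PathLike) -> str:
    """Return 'fasta' or 'fastq' from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(
                f"{path}: not FASTA or FASTQ (first record starts with {line[0]!r})"
            )
    return "fasta"  # empty file: treat as empty FASTA


def iter_reads(path: PathLike, fmt: Optional[str] = None) -> Iterator[Tuple[str, str]]:
    """Stream ``(id, sequence)`` pairs from a FASTA/FASTQ file.

    Single pass, constant memory in the number of records. Malformed
    records raise ``ValueError`` naming the record number.
    """
    fmt = fmt or sniff_format(path)
    n = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                n += 1
                if not rec.id:
                    raise ValueError(f"{path}: record {n} has an empty identifier")
                yield rec.id, str(rec.seq)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} near record {n + 1}: {exc}") from exc


def write_fasta(records: Sequence[Tuple[str, str]], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_cluster_tsv(path: PathLike) -> pd.DataFrame:
    """Cluster membership table: cluster_id, protein_id, is_representative, annotation."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "protein_id": str})
    missing = set(CLUSTER_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cluster table column(s) {sorted(missing)}")
    df["annotation"] = df["annotation"].fillna("")
    return df


def write_cluster_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CLUSTER_TSV_COLUMNS)


def read_truth_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "true_cluster": str, "true_protein": str})
    if "read_id" not in df.columns or "true_cluster" not in df.columns:
        raise ValueError(f"{path}: truth table needs at least read_id and true_cluster columns")
    return df


def read_assignments_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"read_id": str, "annotation": str}, keep_default_na=False,
        na_values=[""],
    )
    missing = set(ASSIGNMENT_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing assignment column(s) {sorted(missing)}")
    df["classified"] = df["classified"].astype(bool)
    return df


def read_hit_table(
    path: PathLike,
    columns: Optional[Sequence[str]] = None,
    has_header: bool = True,
) -> pd.DataFrame:
    """Load an aligner hit table into (qseqid, sseqid, pident, evalue) rows.

    ``columns`` remaps arbitrary dialects: a sequence of column names for
    headerless files (e.g. :data:`OUTFMT6_COLUMNS`) or, with a header, the
    four source column names corresponding to qseqid/sseqid/pident/evalue.
    """
    if has_header:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if columns is not None:
            if len(columns) != 4:
                raise ValueError("columns must name the qseqid, sseqid, pident, evalue sources")
            df = df.rename(columns=dict(zip(columns, HIT_TABLE_COLUMNS)))
    else:
        names = list(columns) if columns is not None else OUTFMT6_COLUMNS
        df = pd.read_csv(path, sep="\t", header=None, names=names)
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hit table missing column(s) {sorted(missing)}")
    df = df[list(HIT_TABLE_COLUMNS)].copy()
    df["qseqid"] = df["qseqid"].astype(str)
    df["sseqid"] = df["sseqid"].astype(str)
    bad = df[(df["pident"] < 0) | (df["pident"] > 100)]
    if len(bad):
        raise ValueError(f"{path}: percent identity outside [0,100] in {len(bad)} row(s)")
    return df
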