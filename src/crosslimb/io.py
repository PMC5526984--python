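"""Readers/writers for the pipeline's plain-text table formats.

Counts are TSV with the feature ID in the first column; cluster maps are
headerless two-column TSV (contig TAB locus, Corset dialect); similarity hits
are BLAST tabular ``-outfmt 6`` (12 columns); sample sheets are CSV with
columns ``sample,species,tissue,replicate[,sex]``.
"""

from __future__ import annotations

import pandas as pd

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

SAMPLE_SHEET_COLUMNS = ["sample", "species", "tissue", "replicate"]


def read_counts(path) -> pd.DataFrame:
    """Read a feature x sample integer count matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature IDs in count matrix: {dups[:5]}")
    return df


def write_counts(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_cluster_map(path) -> pd.Series:
    """Read a Corset-style contig->locus map; returns Series indexed by contig."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig_id", "locus_id"])
    if df["contig_id"].duplicated().any():
        raise ValueError("cluster map assigns some contig to more than one locus")
    return df.set_index("contig_id")["locus_id"]


def write_cluster_map(cluster_map: pd.Series, path) -> None:
    cluster_map.rename_axis("contig_id").rename("locus_id").reset_index().to_csv(
        path, sep="\t", header=False, index=False
    )


def read_blast6(path) -> pd.DataFrame:
    """Read BLAST tabular outfmt-6 hits (qseqid, sseqid, ..., evalue, bitscore)."""
    return pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)


def write_blast6(hits: pd.DataFrame, path) -> None:
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("sample",) if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
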