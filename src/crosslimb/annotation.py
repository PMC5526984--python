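"""Annotation transfer from de-novo assembly loci to reference gene IDs.

Contigs from a de-novo transcriptome are matched against a reference
species' transcripts (BLAST tabular hits); hits with e-value at or above the
cutoff (default 1e-5) are discarded, each contig is annotated with the gene
of its best surviving hit, and the annotation is lifted to Corset-style
loci: a locus whose contigs name exactly one gene is annotated with it, a
locus naming two or more genes is discarded as ambiguous, and a locus with
no surviving hits stays unannotated. Counts of loci annotated to the same
gene are then aggregated into a gene-level matrix comparable with the
reference species' own counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

DEFAULT_EVALUE_THRESHOLD = 1e-5

HIT_COLUMNS = {"contig": "qseqid", "gene": "sseqid"}


@dataclass
class AnnotationMap:
    """Outcome of annotation transfer for every input locus.

    Exactly one of three fates per locus: ``annotated`` (locus -> gene ID),
    ``discarded_multigene`` (locus -> set of >= 2 distinct gene IDs), or
    ``unannotated``.
    """

    annotated: dict[str, str] = field(default_factory=dict)
    discarded_multigene: dict[str, frozenset[str]] = field(default_factory=dict)
    unannotated: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for locus, gset in self.discarded_multigene.items():
            if len(gset) < 2:
                raise ValueError(f"multi-gene locus {locus!r} lists fewer than 2 genes")
        groups = [set(self.annotated), set(self.discarded_multigene), self.unannotated]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise ValueError(f"locus statuses overlap: {sorted(overlap)[:5]}")

    @property
    def n_loci(self) -> int:
        return len(self.annotated) + len(self.discarded_multigene) + len(self.unannotated)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-locus report: locus_id, status, genes (';'-joined)."""
        rows = [(l, "annotated", g) for l, g in self.annotated.items()]
        rows += [
            (l, "discarded_multigene", ";".join(sorted(gs)))
            for l, gs in self.discarded_multigene.items()
        ]
        rows += [(l, "unannotated", "") for l in sorted(self.unannotated)]
        return (
            pd.DataFrame(rows, columns=["locus_id", "status", "genes"])
            .sort_values("locus_id", kind="stable")
            .reset_index(drop=True)
        )


def _as_hit_frame(hits: pd.DataFrame) -> pd.DataFrame:
    """Normalize a hit table to columns contig_id, gene_id, evalue, bitscore."""
    if {"contig_id", "gene_id"}.issubset(hits.columns):
        df = hits
    else:
        df = hits.rename(columns={"qseqid": "contig_id", "sseqid": "gene_id"})
    need = ["contig_id", "gene_id", "evalue", "bitscore"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return df[need]


def resolve_transcripts(hits: pd.DataFrame, transcript_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Map hit subject IDs from transcripts to genes before annotation.

    Subjects absent from the map are dropped (no gene identity can be
    transferred through them).
    """
    col = "sseqid" if "sseqid" in hits.columns else "gene_id"
    mapped = hits[col].map(dict(transcript_to_gene))
    out = hits[mapped.notna()].copy()
    out[col] = mapped[mapped.notna()]
    return out


def filter_hits(
    hits: pd.DataFrame, threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> pd.DataFrame:
    """Keep hits with e-value strictly below ``threshold``.

    Hits at or above the threshold are discarded; input row order is
    preserved. Negative e-values are rejected.
    """
    if threshold <= 0:
        raise ValueError("e-value threshold must be > 0")
    df = _as_hit_frame(hits)
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-values in hit table")
    return df[df["evalue"] < threshold]


def best_hit_per_contig(hits: pd.DataFrame) -> dict[str, str]:
    """Gene of each contig's best hit: minimum e-value, ties broken by
    maximum bitscore then lexicographically smallest gene ID.

    Contigs with no hits are absent from the result. Expects e-value-filtered
    input (``filter_hits``); the rule itself does not re-filter.
    """
    df = _as_hit_frame(hits)
    if df.empty:
        return {}
    ordered = df.sort_values(
        ["contig_id", "evalue", "bitscore", "gene_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    best = ordered.drop_duplicates("contig_id", keep="first")
    return dict(zip(best["contig_id"], best["gene_id"]))


def annotate_loci(
    cluster_map: Mapping[str, str] | pd.Series, contig_genes: Mapping[str, str]
) -> AnnotationMap:
    """Lift contig-level gene annotations to loci.

    A locus whose annotated contigs name exactly one distinct gene becomes
    ``annotated``; two or more distinct genes make it ``discarded_multigene``
    (count assignment would be ambiguous); no annotated contigs leave it
    ``unannotated``. Every locus in ``cluster_map`` receives exactly one
    status.
    """
    if isinstance(cluster_map, pd.Series):
        cluster_map = cluster_map.to_dict()
    missing = [c for c in contig_genes if c not in cluster_map]
    if missing:
        raise ValueError(
            f"contigs annotated but absent from the cluster map: {sorted(missing)[:5]}"
        )

    genes_per_locus: dict[str, set[str]] = {}
    for contig, locus in cluster_map.items():
        genes_per_locus.setdefault(locus, set())
        gene = contig_genes.get(contig)
        if gene is not None:
            genes_per_locus[locus].add(gene)

    result = AnnotationMap()
    for locus, genes in genes_per_locus.items():
        if len(genes) == 0:
            result.unannotated.add(locus)
        elif len(genes) == 1:
            result.annotated[locus] = next(iter(genes))
        else:
            result.discarded_multigene[locus] = frozenset(genes)
    return result


def aggregate_counts(locus_counts: pd.DataFrame, annotation: AnnotationMap) -> pd.DataFrame:
    """Sum counts of loci annotated to the same gene into a gene x sample matrix.

    Discarded (multi-gene) and unannotated loci contribute nothing. Rows are
    the distinct annotated genes, sorted; raises if an annotated locus is
    missing from the count matrix.
    """
    missing = [l for l in annotation.annotated if l not in locus_counts.index]
    if missing:
        raise ValueError(f"annotated loci absent from count matrix: {sorted(missing)[:5]}")
    if not annotation.annotated:
        return pd.DataFrame(
            columns=locus_counts.columns, index=pd.Index([], name="gene_id")
        ).astype(locus_counts.dtypes.to_dict() if len(locus_counts.columns) else "int64")
    keep = locus_counts.loc[list(annotation.annotated)]
    gene_of = pd.Series(annotation.annotated)
    out = keep.groupby(gene_of.reindex(keep.index)).sum()
    out.index.name = "gene_id"
    return out.sort_index()


def intersect_species(
    gene_counts_a: pd.DataFrame, gene_counts_b: pd.DataFrame
) -> tuple[pd.DataFrame, list[str], dict[str, list[str]]]:
    """Join two gene-level matrices on their common genes.

    Returns ``(joined, genes, dropped)`` where ``joined`` has species A's
    columns followed by species B's, ``genes`` is the sorted intersection and
    ``dropped`` records genes private to each input.
    """
    for name, df in (("A", gene_counts_a), ("B", gene_counts_b)):
        if df.index.has_duplicates:
            raise ValueError(f"duplicated gene IDs in matrix {name}")
    common = sorted(gene_counts_a.index.intersection(gene_counts_b.index))
    dropped = {
        "only_in_a": sorted(gene_counts_a.index.difference(gene_counts_b.index)),
        "only_in_b": sorted(gene_counts_b.index.difference(gene_counts_a.index)),
    }
    joined = pd.concat(
        [gene_counts_a.loc[common], gene_counts_b.loc[common]], axis=1
    )
    joined.index.name = "gene_id"
    return joined, common, dropped
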