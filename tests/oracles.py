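"""Independent brute-force oracles used to validate the pipeline.

These deliberately restate the rules in the plainest possible form (loops
and dicts, no pandas) so that agreement with the vectorized implementation
is meaningful.
"""

from __future__ import annotations

import math


def brute_force_annotation(hits, cluster_map, locus_counts, threshold=1e-5):
    """Filter -> best hit -> locus gene sets -> aggregate, by exhaustive loops.

    ``hits``: iterable of (contig, gene, evalue, bitscore) tuples;
    ``cluster_map``: dict contig -> locus; ``locus_counts``: dict locus ->
    tuple of per-sample counts. Returns (annotated, discarded, unannotated,
    gene_totals).
    """
    kept = [h for h in hits if h[2] < threshold]

    best = {}
    for contig, gene, ev, bits in kept:
        key = (ev, -bits, gene)
        if contig not in best or key < best[contig][0]:
            best[contig] = (key, gene)
    contig_gene = {c: g for c, (_, g) in best.items()}

    locus_genes = {locus: set() for locus in cluster_map.values()}
    for contig, locus in cluster_map.items():
        if contig in contig_gene:
            locus_genes[locus].add(contig_gene[contig])

    annotated, discarded, unannotated = {}, {}, set()
    for locus, genes in locus_genes.items():
        if len(genes) == 1:
            annotated[locus] = next(iter(genes))
        elif len(genes) >= 2:
            discarded[locus] = frozenset(genes)
        else:
            unannotated.add(locus)

    gene_totals = {}
    for locus, gene in annotated.items():
        row = locus_counts[locus]
        if gene not in gene_totals:
            gene_totals[gene] = [0] * len(row)
        for j, c in enumerate(row):
            gene_totals[gene][j] += c
    return annotated, discarded, unannotated, gene_totals


def classical_contrast_t(y_rows, X, L):
    """Ordinary (unmoderated, unit-weight) contrast t-tests, one per row.

    Direct dense-algebra evaluation: beta = (X'X)^-1 X'y, s^2 = RSS/(n-p),
    t = L'beta / (s * sqrt(L'(X'X)^-1 L)). Pure-python loops over genes.
    """
    import numpy as np

    X = np.asarray(X, float)
    L = np.asarray(L, float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    lvl = float(L @ xtx_inv @ L)
    out = []
    for y in y_rows:
        y = np.asarray(y, float)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        s2 = float(resid @ resid) / (n - p)
        out.append(float(L @ beta) / math.sqrt(s2 * lvl))
    return out


def bh_step_up(pvals):
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
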