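"""Region-to-gene annotation and hypergeometric gene-set enrichment.

Differential regions become gene lists by TSS proximity (a gene is
associated with a region when its TSS lies within 1 kb of the region by
default); gene lists are then tested for over-representation of curated
gene sets (GMT format) with a one-sided hypergeometric test,
BH-corrected across sets. The universe is the set of genes associated
with any feature that survived QC, restricting the null to assayable
genes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust
from .errors import ValidationError
from .features import ALLOWED_BIOTYPES, FeatureSet, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "merge_close_intervals",
    "associate_genes",
    "hypergeometric_overrep",
    "enrich_gene_sets",
    "read_gmt",
    "read_gene_annotation",
]


def merge_close_intervals(
    intervals: list[GenomicInterval], gap: int = 5000
) -> list[GenomicInterval]:
    """Merge successive same-chromosome intervals separated by < gap bp.

    Intervals are sorted by (chrom, start); a merged interval spans the
    minimum start to the maximum end. Typical use: stitching peak-caller
    output into contiguous domains (default merge distance 5 kb).
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start - last.end < gap:
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged


def associate_genes(
    features: FeatureSet, annotation: pd.DataFrame, max_dist: int = 1000
) -> dict[int, list[str]]:
    """Map each feature index to genes whose TSS lies near it.

    Gene g is associated with feature f iff tss(g) is in
    [start_f - max_dist, end_f + max_dist); strand is ignored for the
    distance. Genes on chromosomes absent from the feature set are
    skipped with a log message.
    """
    if max_dist < 0:
        raise ValidationError("max_dist must be >= 0")
    feature_chroms = {iv.chrom for iv in features.intervals}
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    n_skipped = 0
    for row in annotation.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in feature_chroms:
            n_skipped += 1
            continue
        by_chrom.setdefault(chrom, []).append((int(row.tss), str(row.gene)))
    if n_skipped:
        logger.info("%d genes on chromosomes absent from the feature set", n_skipped)
    for lst in by_chrom.values():
        lst.sort()

    assoc: dict[int, list[str]] = {}
    for i, iv in enumerate(features.intervals):
        genes = [
            g
            for tss, g in by_chrom.get(iv.chrom, [])
            if max(0, iv.start - max_dist) <= tss < iv.end + max_dist
        ]
        if genes:
            assoc[i] = genes
    return assoc


def hypergeometric_overrep(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValidationError(f"inconsistent hypergeometric sizes k={k} K={K} n={n} N={N}")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich_gene_sets(
    query_genes,
    universe_genes,
    sets: dict[str, list[str]],
    q_display: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Gene symbols are matched case-insensitively. The query is
    intersected with the universe (logged when genes fall outside).
    Sets with no gene in the universe are skipped. Output columns:
    set, N, K, n, k, p, q, significant (q < q_display), genes; sorted by
    (q, p).
    """
    universe = {str(g).upper() for g in universe_genes}
    if not universe:
        raise ValidationError("empty gene universe")
    query = {str(g).upper() for g in query_genes}
    outside = query - universe
    if outside:
        logger.info("%d query genes outside the universe; intersected", len(outside))
    query &= universe

    rows = []
    for name, members in sets.items():
        in_universe = {str(g).upper() for g in members} & universe
        if not in_universe:
            continue
        overlap = in_universe & query
        p = hypergeometric_overrep(len(overlap), len(in_universe), len(query), len(universe))
        rows.append(
            {
                "set": name,
                "N": len(universe),
                "K": len(in_universe),
                "n": len(query),
                "k": len(overlap),
                "p": p,
                "genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p", "genes"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < q_display
        table = table.sort_values(["q", "p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
    return table[["set", "N", "K", "n", "k", "p", "q", "significant", "genes"]]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, then member gene symbols."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs name, description, genes")
            genes = [g.upper() for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: empty gene set {parts[0]!r}")
            sets[parts[0]] = genes
    return sets


def read_gene_annotation(path: str | Path, biotype_filter: bool = True) -> pd.DataFrame:
    """Read a gene annotation TSV (gene, chrom, tss, strand, biotype).

    By default only protein_coding, antisense and lncRNA genes are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    required = {"gene", "chrom", "tss", "strand", "biotype"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: annotation needs columns {sorted(required)}")
    if biotype_filter:
        df = df[df["biotype"].isin(ALLOWED_BIOTYPES)].reset_index(drop=True)
    return df
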