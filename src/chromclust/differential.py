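"""Differential enrichment of normalized signal between cell clusters.

Per cluster and per feature, normalized counts of the cluster's cells
are compared with all other cells (or one chosen cluster) by a
two-sided Wilcoxon rank-sum test; p-values are Benjamini-Hochberg
corrected across features within each cluster's comparison. A region is
called *enriched* when q < 0.01 and log2FC > 1, *depleted* when
q < 0.01 and log2FC < -1 (defaults). For a repressive mark such as
H3K27me3, depleted regions are the ones permissive for transcription.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .consensus import ClusterAssignment
from .errors import ValidationError
from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log2_fold_change",
    "differential_table",
]

#: largest pooled sample size using the exact null distribution
EXACT_MAX_N = 30


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the pooled size is <= 30 with no ties;
    otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, original order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_a: float, mean_b: float) -> float:
    """log2((mean_a + 1) / (mean_b + 1)) on normalized values.

    The pseudocount of 1 (on the RPKM scale) bounds fold changes when a
    group mean is zero.
    """
    return float(np.log2((mean_a + 1.0) / (mean_b + 1.0)))


def _group_pvalues(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Row-wise Wilcoxon p for feature x cells blocks of the two groups."""
    n = xa.shape[1] + xb.shape[1]
    if n > EXACT_MAX_N:
        return mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic", axis=1).pvalue
    return np.array([wilcoxon_rank_sum(a, b) for a, b in zip(xa, xb)])


def differential_table(
    x: NormalizedMatrix,
    assignment: ClusterAssignment,
    mode: str = "one_vs_rest",
    target: int | None = None,
    q_threshold: float = 0.01,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cluster, per-feature differential table.

    mode="one_vs_rest" compares each cluster against all other cells;
    mode="one_vs_cluster" compares against cells of cluster ``target``.
    Features with zero signal in both groups are skipped (p and q NaN,
    call "skipped"). Clusters with fewer than 2 cells are skipped with a
    warning.
    """
    if mode not in {"one_vs_rest", "one_vs_cluster"}:
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "one_vs_cluster" and target is None:
        raise ValidationError("one_vs_cluster mode requires a target cluster")
    labels = assignment.labels
    clusters = sorted(np.unique(labels))
    if len(clusters) < 2:
        raise ValidationError("differential analysis needs >= 2 clusters")

    dense = x.dense()
    feats = x.feature_set.to_frame()
    frames = []
    for c in clusters:
        if mode == "one_vs_cluster" and c == target:
            continue
        in_c = labels == c
        other = (labels == target) if mode == "one_vs_cluster" else ~in_c
        if in_c.sum() < 2 or other.sum() < 2:
            logger.warning("cluster %s skipped: fewer than 2 cells in a group", c)
            continue
        xa, xb = dense[:, in_c], dense[:, other]
        mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
        lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
        testable = ~((xa.sum(axis=1) == 0) & (xb.sum(axis=1) == 0))
        p = np.full(dense.shape[0], np.nan)
        q = np.full(dense.shape[0], np.nan)
        if testable.any():
            p[testable] = _group_pvalues(xa[testable], xb[testable])
            q[testable] = bh_adjust(p[testable])
        call = np.where(
            ~testable,
            "skipped",
            np.where(
                (q < q_threshold) & (lfc > fc_threshold),
                "enriched",
                np.where((q < q_threshold) & (lfc < -fc_threshold), "depleted", "ns"),
            ),
        )
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "feature": feats["name"],
                    "chrom": feats["chrom"],
                    "start": feats["start"],
                    "end": feats["end"],
                    "n_in": int(in_c.sum()),
                    "n_out": int(other.sum()),
                    "mean_in": mean_a,
                    "mean_out": mean_b,
                    "log2fc": lfc,
                    "p": p,
                    "q": q,
                    "call": call,
                }
            )
        )
    if not frames:
        raise ValidationError("no cluster had enough cells to test")
    return pd.concat(frames, ignore_index=True)
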