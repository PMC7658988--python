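"""Resampled consensus clustering with CDF-area statistics.

For each candidate k in [2, k_max], cells are repeatedly subsampled
(default 1000 iterations, 80% of cells each) and hierarchically
clustered on the PC scores with Pearson dissimilarity (1 - r) and Ward
linkage. The consensus matrix entry m_ij is the fraction of iterations
in which cells i and j co-clustered, among iterations where both were
sampled. Stable structure shows as near-binary m; the area A(k) under
the CDF of consensus values and its relative change Delta(k) guide the
user's choice of k (a plateau in Delta(k) marks the knee). The final
partition at the chosen k clusters the consensus matrix itself
(distance 1 - m, Ward), not a single data clustering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .reduce import Embedding, pairwise_pearson

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ConsensusResult",
    "hclust_partition",
    "consensus_matrix",
    "cdf_area",
    "relative_area_change",
    "item_consensus",
    "final_partition",
    "run_consensus",
]


@dataclass
class ClusterAssignment:
    """Cell id -> cluster label (1..k) at a chosen k."""

    cell_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cell_ids) != self.labels.size:
            raise ValidationError("labels must cover every cell")
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValidationError(f"labels must be contiguous 1..{self.k}, got {sorted(present)}")

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, partitions and CDF-area statistics."""

    ks: list[int]
    matrices: dict[int, np.ndarray]
    partitions: dict[int, np.ndarray]
    item_scores: dict[int, np.ndarray]
    areas: dict[int, float] = field(default_factory=dict)
    deltas: dict[int, float] = field(default_factory=dict)
    n_iter: int = 1000
    frac: float = 0.8
    seed: int = 0


def _ward_cut(dist: np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage agglomeration of a square distance matrix, cut at k."""
    dist = np.asarray(dist, dtype=float)
    dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    z = linkage(condensed, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel contiguously in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        labels[i] = remap.setdefault(lab, len(remap) + 1)
    return labels


def hclust_partition(e: Embedding, k: int) -> np.ndarray:
    """Hierarchical clustering of cells: 1 - Pearson distance, Ward linkage."""
    n = e.n_cells
    if not (2 <= k <= n):
        raise ValidationError(f"k must be in [2, {n}]")
    corr = pairwise_pearson(e.scores)
    labels = _ward_cut(1.0 - corr, k)
    if len(np.unique(labels)) < k:
        logger.warning("requested k=%d but only %d distinct clusters formed", k, len(np.unique(labels)))
    return labels


def consensus_matrix(
    e: Embedding, k: int, n_iter: int = 1000, frac: float = 0.8, seed: int = 0
) -> np.ndarray:
    """Co-clustering frequency across subsampled hierarchical clusterings.

    Each iteration samples ceil(frac * n) cells without replacement and
    partitions them with :func:`hclust_partition`. m_ij = co-clustered
    count / co-sampled count; pairs never co-sampled get 0 with a
    warning. The diagonal is 1.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    n = e.n_cells
    size = math.ceil(frac * n)
    if size < k:
        raise ValidationError(f"subsample size {size} smaller than k={k}")
    co_sampled = np.zeros((n, n))
    co_clustered = np.zeros((n, n))
    children = np.random.SeedSequence(seed).spawn(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        idx = np.sort(rng.choice(n, size=size, replace=False))
        labels = hclust_partition(e.subset_cells(idx), k)
        co_sampled[np.ix_(idx, idx)] += 1
        for lab in np.unique(labels):
            members = idx[labels == lab]
            co_clustered[np.ix_(members, members)] += 1
    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning("%d cell pairs never co-sampled; consensus set to 0", int(never.sum()) // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(m, 1.0)
    return m


def cdf_area(matrices: dict[int, np.ndarray]) -> tuple[dict[int, float], dict[int, float]]:
    """Area under the consensus-value CDF per k, and its relative change.

    A(k) integrates the empirical CDF of the upper-triangle consensus
    values: A = sum_i (x_{i+1} - x_i) * CDF(x_i) over sorted unique
    values x. Delta(2) = A(2); Delta(k) = (A(k) - A(k-1)) / A(k-1). When
    A(k-1) = 0, Delta(k) is reported as NaN.
    """
    ks = sorted(matrices)
    if len(ks) < 2:
        raise ValidationError("cdf_area needs consensus matrices for >= 2 values of k")
    areas: dict[int, float] = {}
    for k in ks:
        m = matrices[k]
        iu = np.triu_indices(m.shape[0], k=1)
        vals = np.sort(m[iu])
        xs, counts = np.unique(vals, return_counts=True)
        cdf = np.cumsum(counts) / vals.size
        areas[k] = float(np.sum(np.diff(xs) * cdf[:-1])) if xs.size > 1 else 0.0
    return areas, relative_area_change(areas)


def relative_area_change(areas: dict[int, float]) -> dict[int, float]:
    """Delta(k) table: Delta at the smallest k is A itself, then relative change."""
    ks = sorted(areas)
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (
            (areas[k] - areas[prev]) / areas[prev] if areas[prev] != 0 else float("nan")
        )
    return deltas


def item_consensus(m: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean consensus of each cell with the other members of its cluster.

    Singleton clusters score 1 by convention (logged).
    """
    labels = np.asarray(labels)
    if labels.size != m.shape[0]:
        raise ValidationError("labels must cover the consensus matrix")
    scores = np.empty(labels.size)
    for i in range(labels.size):
        mates = np.flatnonzero(labels == labels[i])
        mates = mates[mates != i]
        if mates.size == 0:
            logger.info("cell %d is a singleton cluster; item consensus set to 1", i)
            scores[i] = 1.0
        else:
            scores[i] = m[i, mates].mean()
    return scores


def final_partition(m: np.ndarray, k: int, cell_ids: list[str]) -> ClusterAssignment:
    """Partition cells by clustering the consensus matrix (1 - m, Ward)."""
    n = m.shape[0]
    if not (2 <= k <= n):
        raise ValidationError(f"k must be in [2, {n}]")
    labels = _ward_cut(1.0 - m, k)
    return ClusterAssignment(list(cell_ids), labels, k=int(labels.max()))


def run_consensus(
    e: Embedding,
    k_max: int = 10,
    n_iter: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering for every k in [2, k_max] plus A/Delta table."""
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    ks = list(range(2, min(k_max, e.n_cells - 1) + 1))
    matrices: dict[int, np.ndarray] = {}
    partitions: dict[int, np.ndarray] = {}
    item_scores: dict[int, np.ndarray] = {}
    for k in ks:
        m = consensus_matrix(e, k, n_iter=n_iter, frac=frac, seed=seed)
        matrices[k] = m
        partitions[k] = final_partition(m, k, e.cell_ids).labels
        item_scores[k] = item_consensus(m, partitions[k])
    areas, deltas = cdf_area(matrices) if len(ks) >= 2 else ({}, {})
    return ConsensusResult(
        ks, matrices, partitions, item_scores, areas, deltas, n_iter, frac, seed
    )
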