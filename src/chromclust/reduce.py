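"""PCA reduction and correlation-based cell filtering.

After normalization, cells are embedded into the first 50 principal
components (centered, not scaled). Isolated cells that do not correlate
with any subgroup destabilize clustering and are removed: the
correlation threshold t is the chosen percentile (99th by default) of
pairwise cell-cell Pearson correlations measured on a *randomized*
dataset — each feature independently permuted across cells — which
preserves per-feature marginals while destroying cell structure. A cell
is kept iff it correlates at >= t with at least p% of the other cells.

All correlations (threshold, filtering, and downstream clustering) are
computed on the PC score rows, not on raw features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "CorrelationFilterParams",
    "run_pca",
    "correlation_threshold",
    "filter_uncorrelated",
]


@dataclass
class Embedding:
    """Cells x n_pcs PC scores, ordered by decreasing explained variance."""

    scores: np.ndarray
    explained_variance: np.ndarray
    cell_ids: list[str]
    sample_labels: list[str]

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def subset_cells(self, indices) -> "Embedding":
        indices = list(indices)
        return Embedding(
            self.scores[indices],
            self.explained_variance,
            [self.cell_ids[j] for j in indices],
            [self.sample_labels[j] for j in indices],
        )


@dataclass
class CorrelationFilterParams:
    percentile: float = 99.0
    min_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.percentile <= 100):
            raise ValidationError("percentile must be in (0, 100]")
        if not (0 <= self.min_fraction <= 100):
            raise ValidationError("min_fraction must be in [0, 100]")


def run_pca(x: NormalizedMatrix, n_pcs: int = 50) -> Embedding:
    """Truncated SVD of the centered cells x features matrix.

    Each feature is centered to zero mean across cells; no unit-variance
    scaling. If n_pcs exceeds the matrix rank it is silently reduced
    with a warning. Sign convention: the largest-magnitude loading of
    each component is positive, so scores are reproducible across runs.
    """
    if x.n_cells < 2 or x.n_features < 2:
        raise ValidationError("PCA needs at least 2 cells and 2 features")
    mat = x.dense().T.astype(float)  # cells x features
    mat -= mat.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    tol = s.max(initial=0.0) * max(mat.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_pcs, rank)
    if k < n_pcs:
        logger.warning("n_pcs=%d exceeds rank %d; reduced", n_pcs, rank)
    if k == 0:
        raise ValidationError("matrix has rank 0 after centering")
    # fix sign so each component's largest-|loading| is positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt[:k]), axis=1)])
    flip[flip == 0] = 1.0
    scores = u[:, :k] * s[:k] * flip
    explained = s[:k] ** 2 / (x.n_cells - 1)
    return Embedding(scores, explained, list(x.cell_ids), list(x.sample_labels))


def pairwise_pearson(scores: np.ndarray) -> np.ndarray:
    """Pearson correlation between cell score rows; errors on constant rows."""
    sd = scores.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"cell at index {bad} has a constant score row")
    return np.corrcoef(scores)


def _nearest_rank(values: np.ndarray, percentile: float) -> float:
    vals = np.sort(values)
    idx = max(1, math.ceil(percentile / 100.0 * vals.size)) - 1
    return float(vals[idx])


def correlation_threshold(
    e: Embedding, params: CorrelationFilterParams, source: NormalizedMatrix
) -> float:
    """Percentile of null cell-cell correlations from a randomized dataset.

    Each feature (row) of the normalized matrix is independently
    permuted across cells (seeded), PCA is re-run with the embedding's
    dimensionality, and the requested nearest-rank percentile of the
    upper-triangle pairwise Pearson correlations is returned.
    """
    if e.n_cells < 3:
        raise ValidationError("correlation threshold needs at least 3 cells")
    rng = np.random.default_rng(params.seed)
    dense = source.dense()
    shuffled = np.empty_like(dense)
    for i in range(dense.shape[0]):
        shuffled[i] = dense[i, rng.permutation(dense.shape[1])]
    randomized = NormalizedMatrix(
        sp.csr_matrix(shuffled),
        source.cell_ids,
        source.sample_labels,
        source.feature_set,
    )
    null_embedding = run_pca(randomized, n_pcs=e.n_pcs)
    corr = pairwise_pearson(null_embedding.scores)
    iu = np.triu_indices(corr.shape[0], k=1)
    return _nearest_rank(corr[iu], params.percentile)


def filter_uncorrelated(
    e: Embedding, t: float, p: float
) -> tuple[list[str], np.ndarray]:
    """Keep cells correlating at >= t with >= p% of the other cells.

    Returns retained cell ids and the full correlation matrix for
    reporting.
    """
    if not np.isfinite(t):
        raise ValidationError("threshold t must be finite")
    corr = pairwise_pearson(e.scores)
    n = corr.shape[0]
    if n == 1:
        return list(e.cell_ids), corr
    off = corr.copy()
    np.fill_diagonal(off, np.nan)
    frac = np.nansum(off >= t, axis=1) / (n - 1)
    kept = np.flatnonzero(frac >= p / 100.0)
    logger.info("correlation filter: %d/%d cells kept (t=%.4f)", kept.size, n, t)
    return [e.cell_ids[j] for j in kept], corr
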