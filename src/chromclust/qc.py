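"""Cell and region quality control, exclusion regions, normalization.

Sparse single-cell chromatin data demands two-sided cell filtering:
lowly covered barcodes are uninformative (or ligation artifacts), while
the very highest-coverage barcodes likely correspond to doublets. Region
filtering then drops features supported by too few well-covered cells.
Defaults follow practice on droplet scChIP-seq: minimum 1600 unique
reads per cell, top 5% of coverage removed, regions detected in at
least 1% of cells with > 1000 reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptyResultError, ValidationError
from .features import GenomicInterval
from .matrix import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "filter_cells",
    "filter_features",
    "exclude_regions",
    "normalize",
    "read_exclusion_bed",
]


@dataclass
class QCParams:
    min_reads_per_cell: int = 1600
    top_coverage_percentile: float = 5.0
    min_cells_fraction: float = 1.0
    coverage_floor: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.top_coverage_percentile <= 100):
            raise ValidationError("top_coverage_percentile must be in [0, 100]")
        if not (0 <= self.min_cells_fraction <= 100):
            raise ValidationError("min_cells_fraction must be in [0, 100]")
        if self.min_reads_per_cell < 0 or self.coverage_floor < 0:
            raise ValidationError("count thresholds must be >= 0")


def filter_cells(m: CountMatrix, qc: QCParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop low-coverage cells, then the top-percentile coverage cells.

    Step 1 removes cells with T_j < min_reads_per_cell. Step 2 removes
    the ceil(q/100 * n_remaining) highest-coverage remaining cells
    (ties broken by cell index). Returns the filtered matrix and a
    per-cell report (total, kept, removal reason).
    """
    if m.n_cells == 0:
        raise ValidationError("empty count matrix")
    totals = m.totals
    reason = np.array([""] * m.n_cells, dtype=object)

    low = totals < qc.min_reads_per_cell
    reason[low] = "below_min_reads"
    remaining = np.flatnonzero(~low)

    q = qc.top_coverage_percentile
    if q > 0 and remaining.size:
        n_remove = math.ceil(q / 100.0 * remaining.size)
        # highest coverage first; equal totals resolved by lower cell index
        order = remaining[np.lexsort((remaining, -totals[remaining]))]
        top = order[:n_remove]
        reason[top] = "top_coverage"

    kept = np.flatnonzero(reason == "")
    report = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "total_reads": totals,
            "kept": reason == "",
            "removal_reason": reason,
        }
    )
    if kept.size == 0:
        raise EmptyResultError("no cells remain after QC; lower min_reads_per_cell")
    logger.info(
        "cell QC: %d/%d kept (%d below min reads, %d top coverage)",
        kept.size, m.n_cells, int(low.sum()), int((reason == "top_coverage").sum()),
    )
    return m.subset_cells(kept), report


def filter_features(m: CountMatrix, qc: QCParams) -> CountMatrix:
    """Keep features detected (count >= 1) in enough well-covered cells.

    The supporting set S is the cells with total > coverage_floor; a
    feature is kept iff it is detected in >= (min_cells_fraction/100)*|S|
    of those cells.
    """
    totals = m.totals
    support = totals > qc.coverage_floor
    if not support.any():
        raise EmptyResultError(
            f"no cells exceed coverage_floor={qc.coverage_floor}; lower it"
        )
    detected = np.asarray((m.counts[:, np.flatnonzero(support)] > 0).sum(axis=1)).ravel()
    threshold = qc.min_cells_fraction / 100.0 * int(support.sum())
    kept = np.flatnonzero(detected >= threshold)
    logger.info("feature QC: %d/%d features kept", kept.size, m.n_features)
    if kept.size == 0:
        raise EmptyResultError("no features remain after QC")
    return m.subset_features(kept)


def exclude_regions(m: CountMatrix, exclusion: list[GenomicInterval]) -> CountMatrix:
    """Drop features overlapping any exclusion interval by >= 1 bp.

    Used e.g. to mask known copy-number-variable segments whose signal
    reflects DNA content rather than the chromatin mark.
    """
    if not exclusion:
        return m
    kept = [
        i
        for i, iv in enumerate(m.feature_set.intervals)
        if not any(iv.overlaps(ex) for ex in exclusion)
    ]
    if len(kept) == m.n_features:
        return m
    if not kept:
        raise EmptyResultError("exclusion regions removed every feature")
    return m.subset_features(kept)


def read_exclusion_bed(path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: malformed BED line")
            try:
                intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
    return intervals


def normalize(m: CountMatrix) -> NormalizedMatrix:
    """Normalize by per-cell total and feature length (RPKM convention).

    x_ij = c_ij / (T_j / 1e6) / (L_i / 1e3). All cells must have
    positive totals (guaranteed after QC).
    """
    totals = m.totals
    if (totals == 0).any():
        raise ValidationError("cells with zero total reads; run cell QC first")
    lengths = np.asarray(m.feature_set.lengths, dtype=float)
    inv_cells = sp.diags(1e6 / totals.astype(float))
    inv_lengths = sp.diags(1e3 / lengths)
    values = (inv_lengths @ m.counts.astype(float) @ inv_cells).tocsr()
    return NormalizedMatrix(values, m.cell_ids, m.sample_labels, m.feature_set)
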