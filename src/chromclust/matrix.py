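"""Sparse count and normalized matrices (features x cells) with metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ValidationError
from .features import FeatureSet, GenomicInterval

__all__ = ["CountMatrix", "NormalizedMatrix", "write_count_matrix", "read_count_matrix"]


@dataclass
class CountMatrix:
    """Nonnegative integer counts c_ij over features i x cells j.

    ``sample_labels`` track which input sample each cell/barcode came
    from (set via an explicit manifest, never inferred from file names).
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    sample_labels: list[str]
    feature_set: FeatureSet

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_feat, n_cells = self.counts.shape
        if n_feat != len(self.feature_set):
            raise ValidationError(
                f"{n_feat} matrix rows but {len(self.feature_set)} features"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"{n_cells} matrix columns but {len(self.cell_ids)} cell ids"
            )
        if len(self.sample_labels) != len(self.cell_ids):
            raise ValidationError("sample_labels must cover all cells")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-cell totals T_j = sum_i c_ij."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, indices) -> "CountMatrix":
        indices = list(indices)
        return CountMatrix(
            self.counts[:, indices],
            [self.cell_ids[j] for j in indices],
            [self.sample_labels[j] for j in indices],
            self.feature_set,
        )

    def subset_features(self, indices) -> "CountMatrix":
        indices = list(indices)
        return CountMatrix(
            self.counts[indices, :],
            self.cell_ids,
            self.sample_labels,
            self.feature_set.subset(indices),
        )


@dataclass
class NormalizedMatrix:
    """Counts normalized by per-cell total and feature length (RPKM scale).

    x_ij = c_ij / (T_j / 1e6) / (L_i / 1e3); zeros stay zeros.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    sample_labels: list[str]
    feature_set: FeatureSet = field(repr=False)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def write_count_matrix(m: CountMatrix, outdir: str | Path, prefix: str = "") -> None:
    """Write MTX + features BED + barcodes TSV (with sample labels)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / f"{prefix}matrix.mtx"), m.counts)
    feats = m.feature_set.to_frame()
    feats.to_csv(outdir / f"{prefix}features.bed", sep="\t", header=False, index=False)
    pd.DataFrame({"cell_id": m.cell_ids, "sample": m.sample_labels}).to_csv(
        outdir / f"{prefix}barcodes.tsv", sep="\t", index=False
    )


def read_count_matrix(outdir: str | Path, prefix: str = "", mode: str = "peaks") -> CountMatrix:
    """Read a matrix written by :func:`write_count_matrix`."""
    outdir = Path(outdir)
    counts = sp.csr_matrix(scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx")))
    feats = pd.read_csv(
        outdir / f"{prefix}features.bed",
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
    )
    barcodes = pd.read_csv(outdir / f"{prefix}barcodes.tsv", sep="\t")
    intervals = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end), name=str(r.name))
        for r in feats.itertuples(index=False)
    ]
    return CountMatrix(
        counts,
        barcodes["cell_id"].astype(str).tolist(),
        barcodes["sample"].astype(str).tolist(),
        FeatureSet(intervals, mode=mode),
    )
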