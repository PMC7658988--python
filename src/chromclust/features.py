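"""Genomic feature definitions: genomes, intervals, bins and TSS windows.

Count-matrix rows are genomic intervals in one of three modes:

``bins``
    Fixed-width, non-overlapping tiles spanning every chromosome
    (50 kb by default, suited to broad repressive marks such as H3K27me3).
``peaks``
    User-supplied intervals, e.g. from an external peak caller.
``tss``
    Windows of +/- ``flank`` bp around gene transcription start sites
    (suited to sharp active marks such as H3K4me3); windows may overlap
    and are kept as distinct features.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: biotypes retained when loading gene annotations
ALLOWED_BIOTYPES = frozenset({"protein_coding", "antisense", "lncRNA"})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths (a chrom.sizes table in memory)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths differ in length")
        if len(self.chrom_names) == 0:
            raise ValidationError("genome must contain at least one chromosome")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chromosome names must be unique")
        if any(ln < 1 for ln in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be >= 1")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeSpec":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)


@dataclass
class FeatureSet:
    """Ordered genomic intervals defining the rows of a count matrix."""

    intervals: list[GenomicInterval]
    mode: str = "bins"
    genome: GenomeSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in {"bins", "peaks", "tss"}:
            raise ValidationError(f"unknown feature mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def lengths(self) -> list[int]:
        """Per-feature lengths L_i in bp."""
        return [iv.length for iv in self.intervals]

    @property
    def names(self) -> list[str]:
        return [
            iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in self.intervals
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": self.names,
            }
        )

    def subset(self, indices) -> "FeatureSet":
        mode = self.mode if self.mode != "bins" else "peaks"
        # a subset of bins no longer tiles the genome, so it is demoted
        return FeatureSet(
            [self.intervals[i] for i in indices], mode=mode, genome=self.genome
        )


def make_bins(genome: GenomeSpec, width: int) -> FeatureSet:
    """Tile each chromosome with non-overlapping ``width``-bp bins.

    The final partial bin ``[floor(L/w)*w, L)`` is kept when non-empty, so
    the bins cover every base exactly once. Order: chromosomes in genome
    order, then position.
    """
    if width < 1:
        raise ValidationError("bin width must be >= 1")
    intervals: list[GenomicInterval] = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        start = 0
        while start < length:
            intervals.append(GenomicInterval(chrom, start, min(start + width, length)))
            start += width
    return FeatureSet(intervals, mode="bins", genome=genome)


def make_tss_windows(
    annotation: pd.DataFrame, flank: int, genome: GenomeSpec | None = None
) -> FeatureSet:
    """One window ``[max(0, tss-flank), tss+flank)`` per gene.

    Overlapping windows are retained as distinct features. When a genome
    is supplied, windows extending past a chromosome end are clipped with
    a warning, and genes on unknown chromosomes are skipped.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    intervals: list[GenomicInterval] = []
    n_clipped = 0
    for row in annotation.itertuples(index=False):
        chrom, tss = str(row.chrom), int(row.tss)
        start = max(0, tss - flank)
        end = tss + flank
        if genome is not None:
            if chrom not in genome:
                logger.warning("gene %s on unknown chromosome %s: skipped", row.gene, chrom)
                continue
            chrom_len = genome.length_of(chrom)
            if end > chrom_len:
                end = chrom_len
                n_clipped += 1
        if end <= start:
            continue
        intervals.append(GenomicInterval(chrom, start, end, name=str(row.gene)))
    if n_clipped:
        logger.warning("%d TSS windows clipped at chromosome ends", n_clipped)
    return FeatureSet(intervals, mode="tss", genome=genome)
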