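"""Synthetic genomes, reads and count matrices with known cluster structure.

The generator emulates a multi-sample mixture of cell populations that
differ in which genomic bins carry chromatin signal: each population has
a set of "signal" bins where read density is ``enrichment_ratio`` times
the background. Per-cell totals are drawn log-normally to mimic the
strongly heterogeneous coverage of droplet single-cell chromatin data
(defaults give a median of ~3000 reads per cell, comfortably straddling
the 1600-read QC threshold). Everything is driven by an explicit seed
and is byte-for-byte reproducible.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .features import GenomeSpec, make_bins
from .matrix import CountMatrix

__all__ = [
    "PopulationProfile",
    "generate_toy_genome",
    "simulate_cells",
    "simulate_count_matrix",
    "four_population_profiles",
    "planted_benchmark",
    "write_cell_beds",
    "write_chrom_sizes",
    "write_labels",
]

BIOTYPES = ("protein_coding", "antisense", "lncRNA")


@dataclass
class PopulationProfile:
    """One cell population: which bins carry signal, and how strongly."""

    population_id: str
    signal_bins: frozenset[int]
    enrichment_ratio: float
    n_cells: int
    coverage_log_mean: float = 8.0   # ln-scale; exp(8) ~ 3000 reads median
    coverage_log_sd: float = 0.4
    sample_label: str = "sample1"

    def __post_init__(self) -> None:
        self.signal_bins = frozenset(int(b) for b in self.signal_bins)
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.enrichment_ratio < 1:
            raise ValidationError("enrichment_ratio must be >= 1")
        if any(b < 0 for b in self.signal_bins):
            raise ValidationError("signal bins must be nonnegative indices")


def _check_profiles(profiles: list[PopulationProfile]) -> None:
    if not profiles:
        raise ValidationError("at least one population profile required")
    ids = [p.population_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("population ids must be unique")


def generate_toy_genome(
    n_chroms: int, chrom_length: int, n_genes: int, seed: int
) -> tuple[GenomeSpec, pd.DataFrame]:
    """A small genome plus a gene annotation table at pseudo-random TSSs.

    Genes get deterministic names (G0001, ...), uniform TSS positions in
    [0, chrom_length), random strand and one of the retained biotypes.
    """
    if n_chroms < 1 or chrom_length < 1:
        raise ValidationError("n_chroms and chrom_length must be >= 1")
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    genome = GenomeSpec(
        tuple(f"chr{i + 1}" for i in range(n_chroms)),
        tuple(chrom_length for _ in range(n_chroms)),
    )
    rng = np.random.default_rng(seed)
    ann = pd.DataFrame(
        {
            "gene": [f"G{i + 1:04d}" for i in range(n_genes)],
            "chrom": rng.choice(genome.chrom_names, size=n_genes),
            "tss": rng.integers(0, chrom_length, size=n_genes),
            "strand": rng.choice(["+", "-"], size=n_genes),
            "biotype": rng.choice(BIOTYPES, size=n_genes),
        }
    )
    ann = ann.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    return genome, ann


def simulate_cells(
    genome: GenomeSpec,
    profiles: list[PopulationProfile],
    bin_width: int,
    seed: int,
    fragment_length: int = 100,
) -> tuple[dict[str, list[tuple[str, int, int]]], pd.DataFrame]:
    """Per-cell read records (BED-style tuples) plus ground-truth labels.

    Each cell's total read count is log-normal; each read's bin is drawn
    multinomially with weight ``enrichment_ratio`` on the population's
    signal bins and 1 elsewhere; the read start is uniform within the
    bin. Returns {cell_id: [(chrom, start, end), ...]} and a labels
    table (cell_id, population, sample).
    """
    _check_profiles(profiles)
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    bins = make_bins(genome, bin_width)
    n_bins = len(bins)
    for p in profiles:
        if p.signal_bins and max(p.signal_bins) >= n_bins:
            raise ValidationError(
                f"population {p.population_id}: signal bin beyond the {n_bins} genome bins"
            )
    rng = np.random.default_rng(seed)
    cells: dict[str, list[tuple[str, int, int]]] = {}
    labels = []
    for prof in profiles:
        weights = np.ones(n_bins)
        if prof.signal_bins:
            weights[sorted(prof.signal_bins)] = prof.enrichment_ratio
        probs = weights / weights.sum()
        for c in range(prof.n_cells):
            cell_id = f"{prof.population_id}_c{c + 1:04d}"
            total = max(1, int(round(rng.lognormal(prof.coverage_log_mean, prof.coverage_log_sd))))
            bin_idx = rng.choice(n_bins, size=total, p=probs)
            reads = []
            for b in bin_idx:
                iv = bins[int(b)]
                start = int(rng.integers(iv.start, iv.end))
                chrom_len = genome.length_of(iv.chrom)
                reads.append((iv.chrom, start, min(start + fragment_length, chrom_len)))
            reads.sort()
            cells[cell_id] = reads
            labels.append((cell_id, prof.population_id, prof.sample_label))
    return cells, pd.DataFrame(labels, columns=["cell_id", "population", "sample"])


def simulate_count_matrix(
    profiles: list[PopulationProfile],
    n_features: int,
    seed: int,
    dispersion: float = 2.0,
    bin_width: int = 50_000,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial count matrix shortcut (no read simulation).

    Per cell, a log-normal total is spread over features in proportion
    to the population's bin weights, then each count is drawn from a
    negative binomial with that mean and shape ``dispersion`` (smaller =
    more overdispersed). Features are ``bin_width`` bins on one
    synthetic chromosome, so region lengths exist for normalization.
    """
    _check_profiles(profiles)
    if n_features < 1:
        raise ValidationError("n_features must be >= 1")
    for p in profiles:
        if p.signal_bins and max(p.signal_bins) >= n_features:
            raise ValidationError(
                f"population {p.population_id}: signal bin beyond n_features={n_features}"
            )
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    genome = GenomeSpec(("chr1",), (n_features * bin_width,))
    features = make_bins(genome, bin_width)

    rng = np.random.default_rng(seed)
    columns = []
    labels = []
    for prof in profiles:
        weights = np.ones(n_features)
        if prof.signal_bins:
            weights[sorted(prof.signal_bins)] = prof.enrichment_ratio
        probs = weights / weights.sum()
        for c in range(prof.n_cells):
            cell_id = f"{prof.population_id}_c{c + 1:04d}"
            total = max(1, int(round(rng.lognormal(prof.coverage_log_mean, prof.coverage_log_sd))))
            mean = total * probs
            p_nb = dispersion / (dispersion + mean)
            counts = rng.negative_binomial(dispersion, p_nb)
            columns.append(sp.csc_matrix(counts[:, None]))
            labels.append((cell_id, prof.population_id, prof.sample_label))
    counts = sp.hstack(columns).tocsr()
    label_df = pd.DataFrame(labels, columns=["cell_id", "population", "sample"])
    matrix = CountMatrix(
        counts,
        label_df["cell_id"].tolist(),
        label_df["sample"].tolist(),
        features,
    )
    return matrix, label_df


def four_population_profiles(
    n_cells: int = 100,
    n_features: int = 2000,
    n_signal: int = 100,
    enrichment_ratio: float = 20.0,
    n_samples: int = 2,
) -> list[PopulationProfile]:
    """Four populations with disjoint signal-bin blocks, split over samples.

    Population i gets the contiguous block of ``n_signal`` bins starting
    at i * n_signal; populations are assigned round-robin to
    ``n_samples`` sample labels so sample-of-origin is informative but
    not identical to population.
    """
    if 4 * n_signal > n_features:
        raise ValidationError("need n_features >= 4 * n_signal for disjoint blocks")
    return [
        PopulationProfile(
            population_id=f"pop{i + 1}",
            signal_bins=frozenset(range(i * n_signal, (i + 1) * n_signal)),
            enrichment_ratio=enrichment_ratio,
            n_cells=n_cells,
            sample_label=f"sample{i % n_samples + 1}",
        )
        for i in range(4)
    ]


def planted_benchmark(
    seed: int,
    n_cells: int = 100,
    n_features: int = 2000,
    n_signal: int = 100,
    enrichment_ratio: float = 20.0,
    genes_per_set: int = 20,
    n_decoy_sets: int = 10,
):
    """Full ground-truth fixture: counts, labels, annotation and gene sets.

    One gene is placed at the midpoint of each of the first
    ``4 * n_signal + n_decoy`` bins. The planted gene set for each
    population is a sample of ``genes_per_set`` genes from its signal
    bins; decoy sets draw uniformly from all placed genes. Returns
    (CountMatrix, labels, annotation, {set name: genes}, profiles).
    """
    profiles = four_population_profiles(
        n_cells=n_cells,
        n_features=n_features,
        n_signal=n_signal,
        enrichment_ratio=enrichment_ratio,
    )
    matrix, labels = simulate_count_matrix(profiles, n_features, seed=seed)

    rng = np.random.default_rng(seed + 1)
    bin_width = matrix.feature_set[0].length
    n_genes = n_features  # one gene per bin, at the bin midpoint
    ann = pd.DataFrame(
        {
            "gene": [f"G{i + 1:04d}" for i in range(n_genes)],
            "chrom": "chr1",
            "tss": [i * bin_width + bin_width // 2 for i in range(n_genes)],
            "strand": rng.choice(["+", "-"], size=n_genes),
            "biotype": "protein_coding",
        }
    )
    gene_of_bin = ann["gene"].tolist()
    sets: dict[str, list[str]] = {}
    for prof in profiles:
        bins = sorted(prof.signal_bins)
        chosen = rng.choice(bins, size=min(genes_per_set, len(bins)), replace=False)
        sets[f"PLANTED_{prof.population_id.upper()}"] = [gene_of_bin[b] for b in sorted(chosen)]
    for d in range(n_decoy_sets):
        chosen = rng.choice(n_genes, size=genes_per_set, replace=False)
        sets[f"DECOY_{d + 1:02d}"] = [gene_of_bin[b] for b in sorted(chosen)]
    return matrix, labels, ann, sets, profiles


def write_cell_beds(
    cells: dict[str, list[tuple[str, int, int]]], outdir: str | Path, gzipped: bool = True
) -> dict[str, Path]:
    """Write one 3-column BED per cell; returns {cell_id: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cell_id, reads in cells.items():
        path = outdir / (f"{cell_id}.bed.gz" if gzipped else f"{cell_id}.bed")
        opener = gzip.open if gzipped else open
        with opener(path, "wt") as fh:
            for chrom, start, end in reads:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        paths[cell_id] = path
    return paths


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False)
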