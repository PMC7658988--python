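"""Stage-by-stage pipeline with on-disk checkpoints and resume.

Stages run in a fixed order — counts, qc, pca, corrfilter, consensus,
partition, differential, enrichment, metrics — and each writes its
outputs under its own subdirectory of the run directory. A stage whose
outputs already exist is skipped on re-run, so a run can be resumed (or
a single stage recomputed by deleting its checkpoint). Deterministic
stages are pure functions of (config, seed, inputs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import differential as diff
from . import enrichment as enr
from . import metrics as met
from . import qc as qcmod
from . import reads as readsmod
from . import reduce as red
from .errors import ValidationError
from .features import GenomeSpec, make_bins, make_tss_windows, GenomicInterval, FeatureSet
from .matrix import CountMatrix, read_count_matrix, write_count_matrix

logger = logging.getLogger(__name__)

STAGES = [
    "counts",
    "qc",
    "pca",
    "corrfilter",
    "consensus",
    "partition",
    "differential",
    "enrichment",
    "metrics",
]


@dataclass
class PipelineConfig:
    """All parameters of a run; defaults follow field practice."""

    outdir: str = "chromclust_run"
    seed: int = 0

    # input
    input_mode: str = "matrix"          # "beds" | "matrix"
    matrix_dir: str | None = None
    beds_dir: str | None = None
    manifest: str | None = None
    chrom_sizes: str | None = None
    deduplicate: bool = False           # optional for BED inputs
    dedup_window: int = 50

    # features
    feature_mode: str = "bins"          # "bins" | "peaks" | "tss"
    bin_width: int = 50_000
    peaks_path: str | None = None
    tss_flank: int = 2500
    annotation: str | None = None

    # QC
    min_reads_per_cell: int = 1600
    top_coverage_percentile: float = 5.0
    min_cells_fraction: float = 1.0
    coverage_floor: int = 1000
    exclusion_bed: str | None = None

    # reduction & correlation filter
    n_pcs: int = 50
    corr_percentile: float = 99.0
    corr_min_fraction: float = 1.0
    batch_correct: bool = False

    # consensus clustering
    k_max: int = 10
    n_iter: int = 1000
    subsample_frac: float = 0.8
    chosen_k: int = 2

    # differential
    q_threshold: float = 0.01
    fc_threshold: float = 1.0

    # enrichment
    gmt: str | None = None
    tss_max_dist: int = 1000
    merge_gap: int = 5000
    q_display: float = 0.1

    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        return cfg

    def validate(self) -> None:
        if self.input_mode not in {"beds", "matrix"}:
            raise ValidationError(f"input_mode must be 'beds' or 'matrix', got {self.input_mode!r}")
        if self.input_mode == "matrix" and not self.matrix_dir:
            raise ValidationError("matrix_dir required in matrix input mode")
        if self.input_mode == "beds":
            for key in ("beds_dir", "manifest", "chrom_sizes"):
                if not getattr(self, key):
                    raise ValidationError(f"{key} required in beds input mode")
        if self.feature_mode not in {"bins", "peaks", "tss"}:
            raise ValidationError(f"unknown feature_mode {self.feature_mode!r}")
        if self.feature_mode == "peaks" and self.input_mode == "beds" and not self.peaks_path:
            raise ValidationError("peaks_path required in peaks feature mode")
        if self.feature_mode == "tss" and not self.annotation:
            raise ValidationError("annotation required in tss feature mode")
        if self.chosen_k < 2:
            raise ValidationError("chosen_k must be >= 2")
        if self.batch_correct:
            raise ValidationError(
                "--batch-correct is not implemented; batch integration is a "
                "reserved hook delegated to external correction methods"
            )
        for key in ("matrix_dir", "beds_dir", "manifest", "chrom_sizes",
                    "peaks_path", "annotation", "exclusion_bed", "gmt"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise ValidationError(f"{key}: path does not exist: {value}")


def read_chrom_sizes(path: str | Path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeSpec(tuple(df["chrom"].astype(str)), tuple(int(v) for v in df["length"]))


def read_peaks_bed(path: str | Path) -> FeatureSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    intervals = [
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]
    return FeatureSet(intervals, mode="peaks")


class Pipeline:
    """Executes the configured stages against a run directory."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.summary: dict = {"stages": {}}

    # -- helpers -----------------------------------------------------------
    def _dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def _done(self, stage: str) -> bool:
        return (self.outdir / stage / ".done").exists()

    def _mark(self, stage: str) -> None:
        (self.outdir / stage / ".done").touch()

    def _load_matrix(self, stage: str) -> CountMatrix:
        return read_count_matrix(self.outdir / stage)

    def _load_embedding(self, stage: str = "pca") -> red.Embedding:
        df = pd.read_csv(self.outdir / stage / "embedding.tsv", sep="\t")
        ev = pd.read_csv(self.outdir / stage / "explained_variance.tsv", sep="\t")
        pcs = [c for c in df.columns if c.startswith("PC")]
        return red.Embedding(
            df[pcs].to_numpy(),
            ev["explained_variance"].to_numpy(),
            df["cell_id"].astype(str).tolist(),
            df["sample"].astype(str).tolist(),
        )

    def _write_embedding(self, e: red.Embedding, stage: str) -> None:
        d = self._dir(stage)
        cols = {"cell_id": e.cell_ids, "sample": e.sample_labels}
        for i in range(e.n_pcs):
            cols[f"PC{i + 1}"] = e.scores[:, i]
        pd.DataFrame(cols).to_csv(d / "embedding.tsv", sep="\t", index=False)
        pd.DataFrame({"explained_variance": e.explained_variance}).to_csv(
            d / "explained_variance.tsv", sep="\t", index=False
        )

    # -- stages ------------------------------------------------------------
    def stage_counts(self) -> None:
        cfg = self.cfg
        d = self._dir("counts")
        if cfg.input_mode == "matrix":
            m = read_count_matrix(cfg.matrix_dir)
        else:
            genome = read_chrom_sizes(cfg.chrom_sizes)
            manifest = readsmod.read_manifest(cfg.manifest)
            paths = {}
            for cell_id in manifest["cell_id"]:
                for suffix in (".bed", ".bed.gz"):
                    p = Path(cfg.beds_dir) / f"{cell_id}{suffix}"
                    if p.exists():
                        paths[cell_id] = p
                        break
                else:
                    raise ValidationError(f"no BED file for cell {cell_id} in {cfg.beds_dir}")
            reads = readsmod.read_cell_beds(paths)
            if cfg.deduplicate:
                reads, report = readsmod.deduplicate_reads(reads, window=cfg.dedup_window)
                pd.DataFrame([report]).to_csv(d / "dedup_report.tsv", sep="\t", index=False)
            if cfg.feature_mode == "bins":
                features = make_bins(genome, cfg.bin_width)
            elif cfg.feature_mode == "peaks":
                features = read_peaks_bed(cfg.peaks_path)
            else:
                ann = enr.read_gene_annotation(cfg.annotation)
                features = make_tss_windows(ann, cfg.tss_flank, genome=genome)
            m = readsmod.count_reads(reads, features, manifest)
        write_count_matrix(m, d)
        self.summary["stages"]["counts"] = {"n_cells": m.n_cells, "n_features": m.n_features}

    def stage_qc(self) -> None:
        cfg = self.cfg
        d = self._dir("qc")
        m = self._load_matrix("counts")
        params = qcmod.QCParams(
            cfg.min_reads_per_cell,
            cfg.top_coverage_percentile,
            cfg.min_cells_fraction,
            cfg.coverage_floor,
        )
        m, report = qcmod.filter_cells(m, params)
        report.to_csv(d / "cell_report.tsv", sep="\t", index=False)
        m = qcmod.filter_features(m, params)
        if cfg.exclusion_bed:
            m = qcmod.exclude_regions(m, qcmod.read_exclusion_bed(cfg.exclusion_bed))
        write_count_matrix(m, d)
        self.summary["stages"]["qc"] = {"n_cells": m.n_cells, "n_features": m.n_features}

    def stage_pca(self) -> None:
        m = self._load_matrix("qc")
        x = qcmod.normalize(m)
        e = red.run_pca(x, n_pcs=self.cfg.n_pcs)
        self._write_embedding(e, "pca")
        self.summary["stages"]["pca"] = {"n_cells": e.n_cells, "n_pcs": e.n_pcs}

    def stage_corrfilter(self) -> None:
        cfg = self.cfg
        d = self._dir("corrfilter")
        m = self._load_matrix("qc")
        x = qcmod.normalize(m)
        e = self._load_embedding("pca")
        params = red.CorrelationFilterParams(
            cfg.corr_percentile, cfg.corr_min_fraction, seed=cfg.seed
        )
        t = red.correlation_threshold(e, params, x)
        kept_ids, corr = red.filter_uncorrelated(e, t, cfg.corr_min_fraction)
        kept = [e.cell_ids.index(c) for c in kept_ids]
        self._write_embedding(e.subset_cells(kept), "corrfilter")
        pd.DataFrame({"cell_id": kept_ids}).to_csv(d / "kept_cells.tsv", sep="\t", index=False)
        (d / "threshold.txt").write_text(f"{t}\n")
        self.summary["stages"]["corrfilter"] = {"n_cells": len(kept_ids), "threshold": t}

    def stage_consensus(self) -> None:
        cfg = self.cfg
        d = self._dir("consensus")
        e = self._load_embedding("corrfilter")
        result = cons.run_consensus(
            e, k_max=cfg.k_max, n_iter=cfg.n_iter, frac=cfg.subsample_frac, seed=cfg.seed
        )
        for k in result.ks:
            np.savetxt(d / f"consensus_k{k}.tsv", result.matrices[k], delimiter="\t")
            pd.DataFrame(
                {
                    "cell_id": e.cell_ids,
                    "cluster": result.partitions[k],
                    "item_consensus": result.item_scores[k],
                }
            ).to_csv(d / f"labels_k{k}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "k": result.ks,
                "cdf_area": [result.areas[k] for k in result.ks],
                "delta": [result.deltas[k] for k in result.ks],
            }
        ).to_csv(d / "cdf_areas.tsv", sep="\t", index=False)
        self.summary["stages"]["consensus"] = {"ks": result.ks}

    def stage_partition(self) -> None:
        cfg = self.cfg
        d = self._dir("partition")
        e = self._load_embedding("corrfilter")
        m = np.loadtxt(self.outdir / "consensus" / f"consensus_k{cfg.chosen_k}.tsv", delimiter="\t")
        assignment = cons.final_partition(m, cfg.chosen_k, e.cell_ids)
        pd.DataFrame({"cell_id": assignment.cell_ids, "cluster": assignment.labels}).to_csv(
            d / "labels.tsv", sep="\t", index=False
        )
        self.summary["stages"]["partition"] = {
            "k": assignment.k,
            "sizes": {int(c): int((assignment.labels == c).sum()) for c in np.unique(assignment.labels)},
        }

    def _load_assignment(self) -> cons.ClusterAssignment:
        df = pd.read_csv(self.outdir / "partition" / "labels.tsv", sep="\t")
        return cons.ClusterAssignment(
            df["cell_id"].astype(str).tolist(),
            df["cluster"].to_numpy(),
            int(df["cluster"].max()),
        )

    def _filtered_normalized(self):
        m = self._load_matrix("qc")
        kept = pd.read_csv(self.outdir / "corrfilter" / "kept_cells.tsv", sep="\t")
        idx = [m.cell_ids.index(c) for c in kept["cell_id"].astype(str)]
        return qcmod.normalize(m.subset_cells(idx))

    def stage_differential(self) -> None:
        cfg = self.cfg
        d = self._dir("differential")
        x = self._filtered_normalized()
        table = diff.differential_table(
            x,
            self._load_assignment(),
            q_threshold=cfg.q_threshold,
            fc_threshold=cfg.fc_threshold,
        )
        table.to_csv(d / "table.tsv", sep="\t", index=False)
        calls = table[table["call"].isin(["enriched", "depleted"])]
        self.summary["stages"]["differential"] = {
            "n_calls": int(len(calls)),
            "per_cluster": calls.groupby("cluster")["call"].count().to_dict(),
        }

    def stage_enrichment(self) -> None:
        cfg = self.cfg
        d = self._dir("enrichment")
        if not cfg.gmt or not cfg.annotation:
            logger.info("enrichment skipped: gmt and/or annotation not configured")
            self.summary["stages"]["enrichment"] = {"skipped": True}
            return
        ann = enr.read_gene_annotation(cfg.annotation)
        sets = enr.read_gmt(cfg.gmt)
        x = self._filtered_normalized()
        assoc = enr.associate_genes(x.feature_set, ann, max_dist=cfg.tss_max_dist)
        universe = sorted({g for genes in assoc.values() for g in genes})
        table = pd.read_csv(self.outdir / "differential" / "table.tsv", sep="\t")
        feat_index = {name: i for i, name in enumerate(x.feature_set.names)}
        n_written = 0
        for cluster, sub in table.groupby("cluster"):
            for direction in ("enriched", "depleted"):
                regions = sub[sub["call"] == direction]["feature"]
                genes = sorted(
                    {g for f in regions for g in assoc.get(feat_index.get(f, -1), [])}
                )
                if not genes:
                    continue
                result = enr.enrich_gene_sets(genes, universe, sets, q_display=cfg.q_display)
                result.to_csv(
                    d / f"cluster{cluster}_{direction}.tsv", sep="\t", index=False
                )
                n_written += 1
        self.summary["stages"]["enrichment"] = {"n_tables": n_written}

    def stage_metrics(self) -> None:
        d = self._dir("metrics")
        assignment = self._load_assignment()
        e = self._load_embedding("corrfilter")
        samples = e.sample_labels
        ari = met.adjusted_rand_index(samples, assignment.labels)
        scores = met.assignment_scores(samples, assignment.labels)
        scores.to_csv(d / "assignment_scores.tsv", sep="\t")
        sample_names = sorted(set(samples))
        overall = np.array([samples.count(s) for s in sample_names], dtype=float)
        overall /= overall.sum()
        composition = {}
        for c in np.unique(assignment.labels):
            obs = np.array(
                [sum(1 for s, l in zip(samples, assignment.labels) if s == sn and l == c)
                 for sn in sample_names]
            )
            composition[int(c)] = met.composition_chisq(obs, overall)
        report = {"ari_vs_sample": ari, "composition_chisq_p": composition}
        (d / "metrics.json").write_text(json.dumps(report, indent=2))
        self.summary["stages"]["metrics"] = report

    # -- driver ------------------------------------------------------------
    def run(self) -> dict:
        handlers = {
            "counts": self.stage_counts,
            "qc": self.stage_qc,
            "pca": self.stage_pca,
            "corrfilter": self.stage_corrfilter,
            "consensus": self.stage_consensus,
            "partition": self.stage_partition,
            "differential": self.stage_differential,
            "enrichment": self.stage_enrichment,
            "metrics": self.stage_metrics,
        }
        for stage in STAGES:
            if self._done(stage):
                logger.info("stage %s: checkpoint exists, skipping", stage)
                continue
            logger.info("stage %s: running", stage)
            try:
                handlers[stage]()
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed: {exc} "
                    f"(delete {self.outdir / stage} to recompute after fixing)"
                ) from exc
            self._mark(stage)
        self.summary["config"] = dataclasses.asdict(self.cfg)
        (self.outdir / "summary.json").write_text(json.dumps(self.summary, indent=2, default=str))
        return self.summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run (or resume) every stage; returns the summary report."""
    return Pipeline(config).run()
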