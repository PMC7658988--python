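"""Barcode-resolved read records: BED input, duplicate removal, counting.

Droplet single-cell chromatin protocols produce three classes of
duplicate beyond what bulk dedup handles, removed here per barcode in a
fixed order:

(i)   PCR duplicates — read 1 *and* read 2 map at the same positions;
(ii)  RT duplicates — read 1 maps at the same position (linear
      amplification re-copies the same fragment with a different mate);
(iii) window duplicates — surviving reads whose read-1 position falls in
      the same non-overlapping 50 bp genomic window are stacked into
      one, as reads likely originating from the same nucleosome.

Counting assigns each read to features by the 5' position of read 1, a
single point, so in ``bins`` mode every retained read counts exactly
once; overlapping TSS windows each receive the read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .errors import ValidationError
from .features import FeatureSet
from .matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "deduplicate_reads",
    "count_reads",
    "read_cell_beds",
    "read_barcoded_bed",
    "read_manifest",
]


@dataclass(frozen=True)
class ReadRecord:
    """One aligned fragment: barcode plus the 5' positions of its reads."""

    barcode: str
    chrom: str
    pos_r1: int
    pos_r2: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.pos_r1 < 0 or (self.pos_r2 is not None and self.pos_r2 < 0):
            raise ValidationError("read positions must be >= 0")


def _survivor_key(item: tuple[int, ReadRecord]) -> tuple[int, int, int]:
    idx, r = item
    return (r.pos_r1, -1 if r.pos_r2 is None else r.pos_r2, idx)


def deduplicate_reads(
    reads: list[ReadRecord], window: int = 50
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Remove PCR, RT and window duplicates per barcode.

    Returns the surviving reads and a report with counts removed per
    rule. Within each duplicate group the survivor is the record with
    the smallest (pos_r1, pos_r2, input index), so the surviving
    multiset does not depend on input order. Single-end records (no
    pos_r2) skip the PCR rule and enter the RT rule directly.
    """
    if window < 1:
        raise ValidationError("dedup window must be >= 1")
    report = {"pcr_duplicates": 0, "rt_duplicates": 0, "window_duplicates": 0}
    survivors: list[ReadRecord] = []

    by_barcode: dict[str, list[tuple[int, ReadRecord]]] = {}
    for idx, r in enumerate(reads):
        by_barcode.setdefault(r.barcode, []).append((idx, r))

    for _, items in sorted(by_barcode.items()):
        # rule (i): collapse identical (chrom, pos_r1, pos_r2); single-end pass through
        groups: dict[tuple, list[tuple[int, ReadRecord]]] = {}
        passthrough: list[tuple[int, ReadRecord]] = []
        for idx, r in items:
            if r.pos_r2 is None:
                passthrough.append((idx, r))
            else:
                groups.setdefault((r.chrom, r.pos_r1, r.pos_r2), []).append((idx, r))
        stage1 = list(passthrough)
        for members in groups.values():
            report["pcr_duplicates"] += len(members) - 1
            stage1.append(min(members, key=_survivor_key))

        # rule (ii): collapse identical (chrom, pos_r1)
        groups2: dict[tuple, list[tuple[int, ReadRecord]]] = {}
        for idx, r in stage1:
            groups2.setdefault((r.chrom, r.pos_r1), []).append((idx, r))
        stage2 = []
        for members in groups2.values():
            report["rt_duplicates"] += len(members) - 1
            stage2.append(min(members, key=_survivor_key))

        # rule (iii): collapse reads in the same genome-anchored window tile
        groups3: dict[tuple, list[tuple[int, ReadRecord]]] = {}
        for idx, r in stage2:
            groups3.setdefault((r.chrom, r.pos_r1 // window), []).append((idx, r))
        for members in groups3.values():
            report["window_duplicates"] += len(members) - 1
            survivors.append(min(members, key=_survivor_key)[1])

    survivors.sort(key=lambda r: (r.barcode, r.chrom, r.pos_r1))
    return survivors, report


def count_reads(
    reads: list[ReadRecord],
    features: FeatureSet,
    manifest: pd.DataFrame,
    on_unknown_barcode: str = "drop",
) -> CountMatrix:
    """Aggregate reads into a features x cells count matrix.

    A read increments feature i for its barcode iff pos_r1 lies in
    [start_i, end_i); with overlapping features every containing feature
    is incremented. Cells listed in the manifest with zero reads appear
    as all-zero columns. Barcodes absent from the manifest are dropped
    with a warning (or raise, with ``on_unknown_barcode="error"``).
    """
    if on_unknown_barcode not in {"drop", "error"}:
        raise ValidationError("on_unknown_barcode must be 'drop' or 'error'")
    if not {"cell_id", "sample"} <= set(manifest.columns):
        raise ValidationError("manifest needs columns: cell_id, sample")

    cell_ids = manifest["cell_id"].astype(str).tolist()
    if len(set(cell_ids)) != len(cell_ids):
        raise ValidationError("duplicate cell ids in manifest")
    samples = manifest["sample"].astype(str).tolist()
    col_of = {c: j for j, c in enumerate(cell_ids)}

    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(features.intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    rows, cols = [], []
    n_unknown_barcode = 0
    n_unknown_chrom = 0
    for r in reads:
        j = col_of.get(r.barcode)
        if j is None:
            if on_unknown_barcode == "error":
                raise ValidationError(f"barcode {r.barcode!r} absent from manifest")
            n_unknown_barcode += 1
            continue
        tree = trees.get(r.chrom)
        if tree is None:
            n_unknown_chrom += 1
            continue
        for hit in tree.at(r.pos_r1):
            rows.append(hit.data)
            cols.append(j)
    if n_unknown_barcode:
        logger.warning("%d reads dropped: barcode not in manifest", n_unknown_barcode)
    if n_unknown_chrom:
        logger.warning("%d reads dropped: chromosome not in feature set", n_unknown_chrom)

    counts = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(features), len(cell_ids)),
    ).tocsr()
    return CountMatrix(counts, cell_ids, samples, features)


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_bed_line(line: str, path: Path, lineno: int):
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise ValidationError(f"{path}:{lineno}: malformed BED line (need >= 3 columns)")
    try:
        return parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else None
    except ValueError as exc:
        raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc


def read_cell_beds(paths: dict[str, str | Path]) -> list[ReadRecord]:
    """Read one BED file per cell; keys are cell ids, values file paths.

    Each record's start becomes pos_r1; pos_r2 is left unset (public
    single-cell BED files are fragment/point records).
    """
    reads: list[ReadRecord] = []
    for barcode, path in paths.items():
        path = Path(path)
        with _open_maybe_gzip(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, _end, _name = _parse_bed_line(line, path, lineno)
                reads.append(ReadRecord(barcode=str(barcode), chrom=chrom, pos_r1=start))
    return reads


def read_barcoded_bed(path: str | Path) -> list[ReadRecord]:
    """Read a single BED file carrying the barcode in column 4."""
    path = Path(path)
    reads: list[ReadRecord] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, _end, name = _parse_bed_line(line, path, lineno)
            if not name:
                raise ValidationError(f"{path}:{lineno}: missing barcode in column 4")
            reads.append(ReadRecord(barcode=name, chrom=chrom, pos_r1=start))
    return reads


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cell manifest TSV with columns cell_id and sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "sample"} <= set(df.columns):
        raise ValidationError(f"{path}: manifest needs columns cell_id and sample")
    return df
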