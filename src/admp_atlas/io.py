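"""TSV/BED dialects used across the pipeline.

Matrices are TSV with probe ids in the first column and sample ids in the
header; missing betas are encoded ``NA``.  BED inputs are 0-based half-open;
probe-manifest positions are 1-based (array-manifest convention) and
converted to the internal 0-based convention on ingestion.  Gzip is handled
transparently via the ``.gz`` suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import STATE_VOCABULARY, GenomicInterval
from .calling import MethylationDataset
from .synthetic import EffectMap, SyntheticGenome


class FormatError(ValueError):
    """Malformed input file; the message names the offending record."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# beta matrices and sample metadata
# ---------------------------------------------------------------------------

def write_matrix(dataset: MethylationDataset, path: str | Path) -> None:
    """Write a beta matrix TSV (rows = probes, columns = samples, NA missing)."""
    dataset.betas.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_matrix(path: str | Path, meta_path: str | Path | None = None,
                tissue: str = "") -> pd.DataFrame | MethylationDataset:
    """Read a beta matrix TSV; optionally join metadata into a dataset.

    Validates: rectangular rows, unique probe ids, numeric cells (``NA``
    allowed), betas in [0, 1].  Errors name the probe and sample involved.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_cols:
                raise FormatError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            raise FormatError(
                f"{path}: non-numeric beta for probe {bad[0]!r}, sample {col!r}")
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: beta {vals[i, j]} outside [0, 1] for probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}")
    if meta_path is None:
        return df
    meta = read_metadata(meta_path)
    return MethylationDataset(betas=df, samples=meta.loc[list(df.columns)],
                              tissue=tissue)


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "age" not in meta.columns:
        raise FormatError(f"{path}: metadata must contain an 'age' column")
    return meta


# ---------------------------------------------------------------------------
# BED intervals, probe manifests, gene models
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, merge: bool = False) -> list[GenomicInterval]:
    """Read a BED file (>= 3 columns, optional name column).

    Intervals are validated (0 <= start < end) and returned sorted per
    chromosome (stable); malformed lines are reported with their number.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            intervals.append(GenomicInterval(chrom, start, end, name))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    if merge:
        from .annotation import merge_intervals
        merged = merge_intervals(intervals)
        intervals = [GenomicInterval(c, int(s), int(e))
                     for c in sorted(merged)
                     for s, e in zip(*merged[c])]
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Probe manifest TSV (probe_id, chrom, pos) with 1-based positions.

    Positions are converted to the internal 0-based convention.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids in manifest")
    df = df.set_index("probe_id")
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: manifest positions must be >= 1 (1-based)")
    return df[["chrom", "pos"]]


def write_manifest(probes: pd.DataFrame, path: str | Path) -> None:
    """Write internal 0-based probe positions as a 1-based manifest TSV."""
    out = probes[["chrom", "pos"]].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_genes(path: str | Path) -> pd.DataFrame:
    """Gene models TSV/BED-like: gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene models need columns {sorted(required)}")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
        raise FormatError(f"{path}: gene {bad!r} has start >= end")
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ground truth and genome export
# ---------------------------------------------------------------------------

def write_effect_map(effects: EffectMap, path: str | Path) -> None:
    """Ground-truth TSV: per planted probe, direction/sharing/tissues/slope."""
    effects.info.to_csv(path, sep="\t", index_label="probe_id")


def write_genome(genome: SyntheticGenome, outdir: str | Path) -> dict[str, Path]:
    """Export a synthetic genome as plain-text BED/TSV files.

    Writes the probe manifest (1-based), CGI and EZH2 BEDs, one segmentation
    BED per tissue (state label in the name column) and the gene models.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["manifest"] = outdir / "probes.tsv"
    write_manifest(genome.probes, paths["manifest"])
    paths["cgi"] = outdir / "cgi.bed"
    write_bed(genome.cgi, paths["cgi"])
    paths["ezh2"] = outdir / "ezh2.bed"
    write_bed(genome.ezh2, paths["ezh2"])
    for tissue, seg in genome.segmentations.items():
        p = outdir / f"segmentation_{tissue}.bed"
        write_bed(seg, p)
        paths[f"segmentation_{tissue}"] = p
    paths["genes"] = outdir / "genes.tsv"
    write_genes(genome.genes, paths["genes"])
    return paths


def read_segmentation(path: str | Path) -> list[GenomicInterval]:
    """Segmentation BED: the name column must hold a 15-state label."""
    ivs = read_bed(path)
    for iv in ivs:
        if iv.name not in STATE_VOCABULARY:
            raise FormatError(
                f"{path}: state {iv.name!r} not in the 15-state vocabulary")
    return ivs


def write_admp_table(table, path: str | Path) -> None:
    """Per-tissue aDMP results TSV."""
    table.table.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_admp_table(path: str | Path, tissue: str):
    from .calling import ADMPTable
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    m_tested = int((df["class"] != "untested").sum())
    return ADMPTable(tissue=tissue, table=df, m_tested=m_tested)
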