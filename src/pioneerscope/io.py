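"""Plain-text I/O: BED, bedGraph, FASTA and TSV tables.

Everything is written 0-based half-open, UTF-8, LF line endings. Malformed
lines raise :class:`ParseError` carrying the offending line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import BindingSite, GenomicInterval, RegionSignal, ValidationError


class ParseError(ValueError):
    """A malformed record in a text format, with its line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------- BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (columns beyond strand are ignored)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >= 3 BED columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValidationError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return out


def write_bed(path, intervals: Sequence[GenomicInterval], names=None, scores=None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = "." if names is None else str(names[i])
                score = 0 if scores is None else scores[i]
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ------------------------------------------------------------- binding sites


SITE_COLUMNS = ["chrom", "start", "end", "summit", "score", "fdr"]


def read_sites(path) -> list[BindingSite]:
    """Read binding sites from a headered TSV (chrom start end summit score fdr)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing site columns {missing}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            fdr = getattr(row, "fdr", None)
            if fdr is not None and np.isnan(fdr):
                fdr = None
            sites.append(
                BindingSite(
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    summit=int(row.summit),
                    score=float(row.score),
                    fdr=None if fdr is None else float(fdr),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(path, i, str(exc)) from None
    return sites


def write_sites(path, sites: Sequence[BindingSite]) -> None:
    from .core import sites_to_frame

    sites_to_frame(sites).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------------ bedGraph


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-base float arrays, one per chromosome.

    Overlapping lines are a dialect violation and are rejected; gaps are
    zero-filled. Lines must be sorted within each chromosome.
    """
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    last_end: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 bedGraph columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if chrom not in cov:
                raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise ParseError(path, lineno, f"bad interval {start}-{end} on {chrom}")
            if start < last_end.get(chrom, 0):
                raise ParseError(path, lineno, "overlapping or unsorted bedGraph lines")
            last_end[chrom] = end
            cov[chrom][start:end] = value
    return cov


def write_bedgraph(path, coverage: Mapping[str, np.ndarray], decimals: int = 4) -> None:
    """Write per-base coverage as run-length-encoded bedGraph, skipping zeros."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom in sorted(coverage):
            arr = np.round(np.asarray(coverage[chrom], dtype=float), decimals)
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# --------------------------------------------------------------------- FASTA


def read_fasta(path, upper: bool = True) -> dict[str, str]:
    """Read FASTA sequences; lowercase (soft-masked) bases upper-cased by default."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        seqs[rec.id] = s.upper() if upper else s
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


# ----------------------------------------------------------------- TSV / misc


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_library_sizes(path) -> dict[str, int]:
    """Two-column TSV (sample, library_size) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "library_size"} <= set(df.columns):
        raise ParseError(path, 1, "expected columns: sample, library_size")
    return {str(r["sample"]): int(r["library_size"]) for _, r in df.iterrows()}


def read_counts(path, library_sizes: Mapping[str, int]) -> RegionSignal:
    """Read a region x sample count matrix (chrom, start, end, then samples)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    regions = [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    return RegionSignal(
        regions=regions,
        samples=samples,
        raw_counts=df[samples].to_numpy(dtype=float),
        library_sizes={s: int(library_sizes[s]) for s in samples},
    )


def write_counts(path, signal: RegionSignal, matrix: str = "raw") -> None:
    arr = signal.raw_counts if matrix == "raw" else signal.rpkm
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in signal.regions],
            "start": [r.start for r in signal.regions],
            "end": [r.end for r in signal.regions],
        }
    )
    for j, s in enumerate(signal.samples):
        df[s] = arr[:, j]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
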