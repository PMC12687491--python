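"""Genomic coordinate conventions and interval algebra shared by all stages.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Any 1-based input must be converted at the I/O boundary. The "centre" of an
interval is ``floor((start + end) / 2)``, which is deterministic for odd
lengths and is the reference point for every distance computed downstream
(peak spacing, capture radii, summit windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an input record violates the coordinate contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Ordering is (chrom, start, end, strand), which is the tie-break order
    used for every deterministic sort in the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"empty chrom in interval {self!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"bad strand {self.strand!r} in {self!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        """True iff the intersection spans at least ``min_overlap`` bases."""
        return self.overlap_length(other) >= min_overlap


@dataclass(frozen=True)
class BindingSite:
    """A TF-bound genomic region with a summit, score and optional FDR.

    The summit is the single-base position of maximal enrichment and must
    lie inside the interval. ``fdr`` carries the peak-caller significance
    used to filter sites (the classifier keeps sites with fdr < 0.1).
    """

    interval: GenomicInterval
    summit: int
    score: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        iv = self.interval
        if not (iv.start <= self.summit < iv.end):
            raise ValidationError(
                f"summit {self.summit} outside {iv.chrom}:{iv.start}-{iv.end}"
            )
        if self.score < 0:
            raise ValidationError(f"negative score {self.score} at {iv}")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"fdr {self.fdr} outside [0, 1] at {iv}")

    @property
    def centre(self) -> int:
        return self.interval.centre

    def key(self) -> tuple[str, int, int]:
        iv = self.interval
        return (iv.chrom, iv.start, iv.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a stranded interval; TSS is the 5' end per strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class RegionSignal:
    """A region x sample matrix of raw counts with RPKM normalisation.

    RPKM is reads per kilobase of region per million mapped reads:
    ``rpkm[r, s] = raw[r, s] / (len_kb(r) * lib[s] / 1e6)``.
    """

    regions: list[GenomicInterval]
    samples: list[str]
    raw_counts: np.ndarray
    library_sizes: dict[str, int]
    rpkm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        if self.raw_counts.shape != (len(self.regions), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.raw_counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if (self.raw_counts < 0).any():
            raise ValidationError("negative raw counts")
        for s in self.samples:
            if s not in self.library_sizes:
                raise ValidationError(f"missing library size for sample {s!r}")

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)


def rpkm_normalise(signal: RegionSignal, pseudocount: float = 0.0) -> RegionSignal:
    """Populate the RPKM matrix of a RegionSignal; raw counts are untouched.

    ``pseudocount`` (in reads) is added to every count before normalising;
    the default of 0 gives the exact RPKM formula.
    """
    lib = np.array([signal.library_sizes[s] for s in signal.samples], dtype=float)
    if (lib <= 0).any():
        bad = [s for s in signal.samples if signal.library_sizes[s] <= 0]
        raise ValidationError(f"non-positive library size for sample(s) {bad}")
    length_kb = np.array([len(r) for r in signal.regions], dtype=float) / 1000.0
    rpkm = (signal.raw_counts + pseudocount) / (length_kb[:, None] * lib[None, :] / 1e6)
    return RegionSignal(
        regions=list(signal.regions),
        samples=list(signal.samples),
        raw_counts=signal.raw_counts.copy(),
        library_sizes=dict(signal.library_sizes),
        rpkm=rpkm,
    )


def merge_overlapping(
    intervals: Iterable[GenomicInterval], min_overlap: int = 1
) -> list[GenomicInterval]:
    """Merge intervals that overlap by at least ``min_overlap`` bases.

    Half-open intervals that merely abut share zero bases and are kept
    separate. Output is sorted by (chrom, start, end); strand is dropped
    (merged regions are unstranded).
    """
    if min_overlap < 1:
        raise ValidationError(f"min_overlap must be >= 1, got {min_overlap}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and min(merged[-1].end, iv.end) - iv.start >= min_overlap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def gene_window(gene: GeneModel, upstream: int = 3000, downstream: int = 1000) -> GenomicInterval:
    """Strand-oriented association window: TSS - upstream to TES + downstream.

    Upstream/downstream are measured 5'->3' along the gene's strand, the
    universal promoter convention. The window is clipped at base 0.
    """
    iv = gene.interval
    if gene.strand == "+":
        start, end = iv.start - upstream, iv.end + downstream
    else:
        start, end = iv.start - downstream, iv.end + upstream
    return GenomicInterval(iv.chrom, max(0, start), end)


def associate_genes(
    sites: Sequence[BindingSite],
    genes: Sequence[GeneModel],
    upstream: int = 3000,
    downstream: int = 1000,
) -> dict[str, list[BindingSite]]:
    """Link binding sites to genes whose vicinity window they overlap.

    A site links to a gene iff its interval overlaps, by >= 1 bp, the
    window from ``upstream`` bp 5' of the TSS to ``downstream`` bp 3' of
    the TES (strand-oriented). A site may link to several genes. Genes with
    no linked site are present with an empty list; the result is invariant
    under permutation of the gene list (keys sorted by gene_id).
    """
    out: dict[str, list[BindingSite]] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        win = gene_window(gene, upstream, downstream)
        linked = [s for s in sites if s.interval.overlaps(win)]
        linked.sort(key=lambda s: s.key())
        out[gene.gene_id] = linked
    return out


def sites_to_frame(sites: Sequence[BindingSite]) -> pd.DataFrame:
    """Tabular view of binding sites (chrom, start, end, summit, score, fdr)."""
    return pd.DataFrame(
        {
            "chrom": [s.interval.chrom for s in sites],
            "start": [s.interval.start for s in sites],
            "end": [s.interval.end for s in sites],
            "summit": [s.summit for s in sites],
            "score": [s.score for s in sites],
            "fdr": [np.nan if s.fdr is None else s.fdr for s in sites],
        }
    )


def frame_to_sites(df: pd.DataFrame) -> list[BindingSite]:
    sites = []
    for row in df.itertuples(index=False):
        fdr = getattr(row, "fdr", None)
        if fdr is not None and (isinstance(fdr, float) and np.isnan(fdr)):
            fdr = None
        sites.append(
            BindingSite(
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                summit=int(row.summit),
                score=float(row.score),
                fdr=None if fdr is None else float(fdr),
            )
        )
    return sites
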