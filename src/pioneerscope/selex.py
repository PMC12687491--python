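"""Map SELEX-derived k-mer relative affinities onto a genome and call peaks.

The in-vitro selection experiment yields a table of 12-mers with relative
binding affinities. Every exact occurrence of a table k-mer in the genome
(either strand) becomes an affinity "hit" at the forward-strand window it
occupies. Candidate peaks are runs of above-median-affinity hits: the
threshold is the median affinity over *all table entries* (whether or not
they match the genome), hits above it are unioned, candidate regions
separated by less than ``merge_gap`` bases are merged, and only regions
supported by at least two mapped k-mers are kept. A peak's score is the
arithmetic mean affinity of its contributing hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerAffinityTable:
    """k-mer -> relative binding affinity (positive reals).

    ``min_count`` records the minimum k-mer count filter applied upstream
    when the table was estimated; it is metadata only.
    """

    k: int
    entries: dict[str, float]
    min_count: int = 10

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("empty k-mer affinity table")
        for kmer, aff in self.entries.items():
            if len(kmer) != self.k or set(kmer) - set("ACGT"):
                raise ValidationError(f"bad k-mer {kmer!r} for k={self.k}")
            if aff <= 0:
                raise ValidationError(f"non-positive affinity {aff} for {kmer}")

    def median_affinity(self) -> float:
        """Median over the full table — the peak-calling threshold."""
        return float(np.median(list(self.entries.values())))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_count: int = 10) -> "KmerAffinityTable":
        if not {"kmer", "affinity"} <= set(df.columns):
            raise ValidationError("affinity table needs columns: kmer, affinity")
        entries = {str(r.kmer): float(r.affinity) for r in df.itertuples(index=False)}
        k = len(next(iter(entries)))
        return cls(k=k, entries=entries, min_count=min_count)

    def to_frame(self) -> pd.DataFrame:
        kmers = sorted(self.entries)
        return pd.DataFrame({"kmer": kmers, "affinity": [self.entries[k] for k in kmers]})


@dataclass(frozen=True)
class KmerHit:
    """One exact match of a table entry, at forward-strand coordinates."""

    chrom: str
    start: int
    kmer: str  # the table entry (not necessarily the forward-strand sequence)
    affinity: float


@dataclass(frozen=True)
class SelexPeak:
    interval: GenomicInterval
    score: float
    n_kmers: int

    def __post_init__(self) -> None:
        if self.n_kmers < 2:
            raise ValidationError(f"peak {self.interval} with n_kmers={self.n_kmers} < 2")
        if self.score <= 0:
            raise ValidationError(f"non-positive peak score {self.score}")

    @property
    def centre(self) -> int:
        return self.interval.centre


def map_kmers(genome: dict[str, str], table: KmerAffinityTable) -> list[KmerHit]:
    """All exact matches of table k-mers in the genome, both strands.

    Reverse-complement matches are reported at the forward-strand window.
    A window matching both a table entry and the reverse complement of a
    *different* entry yields two hits; a palindromic entry matching its own
    reverse complement yields one (one piece of evidence, counted once).
    Windows containing N never match.
    """
    k = table.k
    # seq variant -> list of (entry kmer, affinity); forward and revcomp forms
    lookup: dict[str, list[tuple[str, float]]] = {}
    for kmer, aff in table.entries.items():
        lookup.setdefault(kmer, []).append((kmer, aff))
        rc = revcomp(kmer)
        if rc != kmer:
            lookup.setdefault(rc, []).append((kmer, aff))
    hits: list[KmerHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            matched = lookup.get(window)
            if matched is None:
                continue
            seen: set[str] = set()
            for entry, aff in matched:
                if entry not in seen:
                    seen.add(entry)
                    hits.append(KmerHit(chrom, i, entry, aff))
    return hits


def call_selex_peaks(
    hits: list[KmerHit],
    table: KmerAffinityTable,
    merge_gap: int = 3,
    min_kmers: int = 2,
) -> list[SelexPeak]:
    """Call affinity peaks from mapped k-mer hits.

    1. threshold = median affinity over all table entries;
    2. keep hits with affinity strictly above the threshold;
    3. union the retained hit windows into candidate regions;
    4. merge candidate regions whose gap is < ``merge_gap`` bp;
    5. keep regions with >= ``min_kmers`` contributing hits;
    score = mean affinity of the region's contributing hits.
    """
    k = table.k
    threshold = table.median_affinity()
    retained = [h for h in hits if h.affinity > threshold]
    retained.sort(key=lambda h: (h.chrom, h.start, h.kmer))
    peaks: list[SelexPeak] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_affs: list[float] = []

    def flush() -> None:
        if cur_chrom is not None and len(cur_affs) >= min_kmers:
            peaks.append(
                SelexPeak(
                    GenomicInterval(cur_chrom, cur_start, cur_end),
                    score=float(np.mean(cur_affs)),
                    n_kmers=len(cur_affs),
                )
            )

    for h in retained:
        h_end = h.start + k
        # gap < merge_gap between candidate regions joins them; overlapping
        # or abutting windows (gap <= 0) always join.
        if cur_chrom == h.chrom and h.start - cur_end < merge_gap:
            cur_end = max(cur_end, h_end)
            cur_affs.append(h.affinity)
        else:
            flush()
            cur_chrom, cur_start, cur_end = h.chrom, h.start, h_end
            cur_affs = [h.affinity]
    flush()
    return peaks


def peaks_to_frame(peaks: list[SelexPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "n_kmers": [p.n_kmers for p in peaks],
            "score": [p.score for p in peaks],
        }
    )


def frame_to_peaks(df: pd.DataFrame) -> list[SelexPeak]:
    return [
        SelexPeak(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            score=float(r.score),
            n_kmers=int(r.n_kmers),
        )
        for r in df.itertuples(index=False)
    ]


def write_peaks_bed(path, peaks: list[SelexPeak]) -> None:
    """BED6 export: name = n_kmers, score = mean affinity x1000 clamped to 1000."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in peaks:
            bed_score = min(1000, int(round(p.score * 1000)))
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.n_kmers}\t{bed_score}\t.\n"
            )
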