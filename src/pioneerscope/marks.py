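"""Histone-mark x binding-site-category contingency analysis.

Cell (m, c) counts the category-c sites overlapping at least one region of
mark m by >= 1 bp (a site may count toward several marks, as drawn in the
source heatmaps). Enrichment/depletion is reported as Pearson residuals
(O - E)/sqrt(E) under row-column independence, with the Pearson chi-square
statistic and its p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import BindingSite, GenomicInterval, ValidationError


@dataclass
class OverlapContingency:
    marks: list[str]
    categories: list[str]
    counts: np.ndarray  # marks x categories

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.marks), len(self.categories)):
            raise ValidationError("contingency shape mismatch")
        if (self.counts < 0).any():
            raise ValidationError("negative contingency counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.marks, columns=self.categories)


def build_contingency(
    sites: Sequence[BindingSite],
    labels: Sequence[str],
    mark_beds: Mapping[str, Sequence[GenomicInterval]],
) -> OverlapContingency:
    """Count, per mark and category, the sites overlapping the mark >= 1 bp."""
    if len(sites) != len(labels):
        raise ValidationError("labels must cover sites")
    categories = sorted(set(labels))
    marks = sorted(mark_beds)
    counts = np.zeros((len(marks), len(categories)), dtype=float)
    cat_idx = {c: j for j, c in enumerate(categories)}
    for i, mark in enumerate(marks):
        regions = list(mark_beds[mark])
        if not regions:
            warnings.warn(f"mark {mark!r} has no regions; zero row retained",
                          stacklevel=2)
            continue
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for site, label in zip(sites, labels):
            iv = site.interval
            if any(iv.overlaps(r) for r in by_chrom.get(iv.chrom, ())):
                counts[i, cat_idx[label]] += 1
    return OverlapContingency(marks=marks, categories=categories, counts=counts)


def pearson_residuals(
    table: OverlapContingency,
) -> tuple[pd.DataFrame, float, float, int]:
    """Pearson residual matrix, chi-square statistic, p-value and df.

    Expected counts come from the margins (E_ij = row_i * col_j / total),
    residual_ij = (O_ij - E_ij)/sqrt(E_ij), chi2 = sum of squared
    residuals, df = (r - 1)(c - 1). No continuity correction. Zero rows or
    columns are dropped (with a warning) before testing.
    """
    counts = table.counts
    marks, cats = list(table.marks), list(table.categories)
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        dropped = [m for m, ok in zip(marks, row_ok) if not ok] + [
            c for c, ok in zip(cats, col_ok) if not ok
        ]
        warnings.warn(f"dropping all-zero rows/columns: {dropped}", stacklevel=2)
        counts = counts[row_ok][:, col_ok]
        marks = [m for m, ok in zip(marks, row_ok) if ok]
        cats = [c for c, ok in zip(cats, col_ok) if ok]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need at least a 2x2 table after dropping zeros")
    total = counts.sum()
    expected = counts.sum(axis=1, keepdims=True) * counts.sum(axis=0, keepdims=True) / total
    residuals = (counts - expected) / np.sqrt(expected)
    stat = float((residuals**2).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(chi2.sf(stat, df))
    return pd.DataFrame(residuals, index=marks, columns=cats), stat, p, df
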