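"""Accessibility thresholding and 9-way binding-site classification.

Significant binding sites (FDR < 0.1) are split into closed vs open
chromatin by comparing their baseline ATAC RPKM to a threshold derived as
the midpoint between the median accessibility of regions overlapping
nucleosome-free regions and of regions overlapping nucleosome-containing
regions. Each class is then subdivided by accessibility dynamics after
induction, using the differential-accessibility fold change and p-value:

    increasing:  FC > 1.2  and p < 0.1
    decreasing:  FC < 0.8  and p < 0.1
    steady:      0.8 <= FC <= 1.2 and p > 0.1

Sites matching none of the three dynamics rules fall into a residual
"other" category, split by accessibility (other_closed / other_open); a
catch-all "other" label remains for sites that cannot be placed on the
accessibility axis. Fold changes are linear (not log2) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BindingSite,
    GeneModel,
    GenomicInterval,
    RegionSignal,
    ValidationError,
    associate_genes,
    rpkm_normalise,
)

CATEGORY_LABELS = (
    "wt_closed_incr",
    "wt_closed_steady",
    "wt_closed_decr",
    "wt_open_incr",
    "wt_open_steady",
    "wt_open_decr",
    "other_closed",
    "other_open",
    "other",
)


@dataclass(frozen=True)
class AccessibilityThreshold:
    median_nfr: float
    median_nuc: float

    @property
    def threshold(self) -> float:
        return (self.median_nfr + self.median_nuc) / 2.0


@dataclass(frozen=True)
class DifferentialRecord:
    """Linear fold change (induced over baseline accessibility) and p-value."""

    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError(f"fold_change must be > 0, got {self.fold_change}")


def derive_threshold(
    signal: RegionSignal,
    nfr: Sequence[GenomicInterval],
    nuc: Sequence[GenomicInterval],
    samples: str | Sequence[str],
) -> AccessibilityThreshold:
    """Midpoint-of-medians accessibility threshold.

    ``samples`` names the baseline sample(s); with several, each region's
    accessibility is their mean RPKM. A signal region contributes to a
    median iff it overlaps (>= 1 bp) at least one region of the set.
    """
    if signal.rpkm is None:
        signal = rpkm_normalise(signal)
    if isinstance(samples, str):
        samples = [samples]
    cols = [signal.sample_index(s) for s in samples]
    acc = signal.rpkm[:, cols].mean(axis=1)

    def overlapping_median(regions: Sequence[GenomicInterval], name: str) -> float:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        vals = [
            acc[i]
            for i, reg in enumerate(signal.regions)
            if any(reg.overlaps(o) for o in by_chrom.get(reg.chrom, ()))
        ]
        if not vals:
            raise ValidationError(f"no signal regions overlap the {name} set")
        return float(np.median(vals))

    return AccessibilityThreshold(
        median_nfr=overlapping_median(nfr, "nucleosome-free"),
        median_nuc=overlapping_median(nuc, "nucleosome-containing"),
    )


def midpoint_threshold(median_nfr: float, median_nuc: float) -> float:
    """The threshold arithmetic on already-known medians."""
    return AccessibilityThreshold(median_nfr, median_nuc).threshold


def _dynamics(fc: float, p: float, fc_low: float = 0.8, fc_high: float = 1.2,
              p_max: float = 0.1) -> str:
    if fc > fc_high and p < p_max:
        return "incr"
    if fc < fc_low and p < p_max:
        return "decr"
    if fc_low <= fc <= fc_high and p > p_max:
        return "steady"
    return "other"


def classify_sites(
    sites: Sequence[BindingSite],
    baseline_rpkm: Sequence[float],
    diffs: Sequence[DifferentialRecord],
    threshold: float,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Assign each FDR-significant site one of the 9 chromatin categories.

    Returns a frame over the significant sites with columns chrom, start,
    end, baseline_rpkm, fc, p, accessibility (closed/open) and category.
    Accessibility ties (RPKM exactly equal to the threshold) go to closed.
    """
    if len(sites) != len(baseline_rpkm) or len(sites) != len(diffs):
        raise ValidationError(
            f"sites ({len(sites)}), baseline ({len(baseline_rpkm)}) and diffs "
            f"({len(diffs)}) must align"
        )
    rows = []
    for site, rpkm, rec in zip(sites, baseline_rpkm, diffs):
        if rec is None:
            raise ValidationError(f"missing differential record for site {site.key()}")
        if site.fdr is None or site.fdr >= fdr_max:
            continue
        if rpkm is None or (isinstance(rpkm, float) and math.isnan(rpkm)):
            access, category = "na", "other"
        else:
            access = "closed" if rpkm <= threshold else "open"
            dyn = _dynamics(rec.fold_change, rec.p_value)
            if dyn == "other":
                category = f"other_{access}"
            else:
                category = f"wt_{access}_{dyn}"
        rows.append(
            {
                "chrom": site.interval.chrom,
                "start": site.interval.start,
                "end": site.interval.end,
                "baseline_rpkm": rpkm,
                "fc": rec.fold_change,
                "p": rec.p_value,
                "accessibility": access,
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "baseline_rpkm",
            "fc",
            "p",
            "accessibility",
            "category",
        ],
    )


def category_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = {label: 0 for label in CATEGORY_LABELS}
    for label, n in classified["category"].value_counts().items():
        counts[str(label)] = int(n)
    return counts


def rank_specific_sites(
    signal_a: RegionSignal,
    signal_b: RegionSignal,
    top_n: int,
    pseudocount: float = 0.5,
) -> tuple[list[int], list[int], np.ndarray]:
    """Rank shared regions by log2 RPKM ratio of condition A over B.

    Returns (a_specific, b_specific, log2fc): the indices of the top_n
    regions with the highest and lowest log2(RPKM_A / RPKM_B). RPKM values
    are recomputed with ``pseudocount`` reads added to every raw count so
    zero-count regions stay rankable; per-region RPKM is the mean across
    each signal's samples. Ties break by region coordinate.
    """
    if [r for r in signal_a.regions] != [r for r in signal_b.regions]:
        raise ValidationError("signals must cover an identical region list")
    if top_n > len(signal_a.regions):
        raise ValidationError(
            f"top_n={top_n} exceeds {len(signal_a.regions)} regions"
        )
    a = rpkm_normalise(signal_a, pseudocount=pseudocount).rpkm.mean(axis=1)
    b = rpkm_normalise(signal_b, pseudocount=pseudocount).rpkm.mean(axis=1)
    log2fc = np.log2(a / b)
    keys = [(r.chrom, r.start, r.end) for r in signal_a.regions]
    order_desc = sorted(range(len(keys)), key=lambda i: (-log2fc[i], keys[i]))
    order_asc = sorted(range(len(keys)), key=lambda i: (log2fc[i], keys[i]))
    return order_desc[:top_n], order_asc[:top_n], log2fc


def random_regions(
    chrom_sizes: Mapping[str, int],
    n: int = 1000,
    length: int = 400,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """n random fixed-length regions, uniform over all valid start positions.

    Chromosomes are sampled proportionally to their number of valid starts,
    so the draw is uniform over the whole genome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    valid = np.array([chrom_sizes[c] - length + 1 for c in chroms], dtype=float)
    if (valid <= 0).any():
        short = [c for c, v in zip(chroms, valid) if v <= 0]
        raise ValidationError(f"chromosome(s) shorter than {length} bp: {short}")
    probs = valid / valid.sum()
    picks = rng.choice(len(chroms), size=n, p=probs)
    out = []
    for idx in picks:
        start = int(rng.integers(0, int(valid[idx])))
        out.append(GenomicInterval(chroms[idx], start, start + length))
    return out


def link_de_genes(
    de_table: pd.DataFrame,
    sites: Sequence[BindingSite],
    genes: Sequence[GeneModel],
    log2fc_min: float = 1.0,
    fdr_max: float = 0.05,
    upstream: int = 3000,
    downstream: int = 1000,
) -> dict[str, float]:
    """Differential-expression bookkeeping around binding sites.

    DE genes have |log2FC| > ``log2fc_min`` and FDR < ``fdr_max``; activated
    genes additionally have positive log2FC. A gene is "direct" if at least
    one binding site overlaps its vicinity window (3 kb upstream to 1 kb
    downstream by default). Returns counts plus the fractions the study
    style reports (fraction of DE genes activated, fraction of DE and of
    activated genes with a site in the vicinity).
    """
    for col in ("gene", "log2fc", "fdr"):
        if col not in de_table.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    de = de_table[(de_table["log2fc"].abs() > log2fc_min) & (de_table["fdr"] < fdr_max)]
    activated = de[de["log2fc"] > log2fc_min]
    gene_map = {g.gene_id: g for g in genes}
    linked = associate_genes(
        sites,
        [gene_map[g] for g in de["gene"] if g in gene_map],
        upstream=upstream,
        downstream=downstream,
    )
    with_site = {g for g, ss in linked.items() if ss}
    de_with_site = [g for g in de["gene"] if g in with_site]
    act_with_site = [g for g in activated["gene"] if g in with_site]
    n_de, n_act = len(de), len(activated)
    return {
        "n_de": n_de,
        "n_activated": n_act,
        "n_de_with_site": len(de_with_site),
        "n_activated_with_site": len(act_with_site),
        "frac_activated": n_act / n_de if n_de else float("nan"),
        "frac_de_with_site": len(de_with_site) / n_de if n_de else float("nan"),
        "frac_activated_with_site": len(act_with_site) / n_act if n_act else float("nan"),
    }


def welch_differential(
    signal: RegionSignal,
    baseline_samples: Sequence[str],
    induced_samples: Sequence[str],
    pseudocount: float = 0.5,
) -> list[DifferentialRecord]:
    """Simple per-region differential-accessibility estimator for synthetic
    pipelines: linear FC of mean RPKM (induced over baseline, pseudocounted)
    and a Welch t-test on log2 RPKM across replicates.

    This is a deliberately plain estimator for generated data; analyses of
    real count data should consume an externally computed differential
    table (e.g. from a negative-binomial GLM framework).
    """
    from scipy.stats import ttest_ind

    if signal.rpkm is None:
        signal = rpkm_normalise(signal)
    b_cols = [signal.sample_index(s) for s in baseline_samples]
    i_cols = [signal.sample_index(s) for s in induced_samples]
    base = signal.rpkm[:, b_cols]
    ind = signal.rpkm[:, i_cols]
    fc = (ind.mean(axis=1) + pseudocount) / (base.mean(axis=1) + pseudocount)
    log_b = np.log2(base + pseudocount)
    log_i = np.log2(ind + pseudocount)
    out = []
    for r in range(len(signal.regions)):
        t = ttest_ind(log_i[r], log_b[r], equal_var=False)
        p = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
        out.append(DifferentialRecord(fold_change=float(fc[r]), p_value=p))
    return out
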