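"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the deposited datasets the analysis
was designed for: a small genome with CArG boxes (CC[W]5-7GG, W = A/T)
planted singly and in pairs at a controlled ~50 bp centre-to-centre
spacing, a 12-mer affinity table whose CArG-containing entries carry high
relative affinity, negative-binomial replicate count matrices with planted
closed/open accessibility classes and accessibility dynamics, MNase
coverage with planted nucleosome depletion after induction, and
histone-mark interval sets with planted category biases.

Every generated object comes with a machine-readable truth table, and
every stage draws from its own child generator of the master seed, so the
same config + seed reproduces byte-identical outputs and individual stages
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BindingSite, GenomicInterval, RegionSignal, ValidationError, rpkm_normalise
from .classify import DifferentialRecord, welch_differential
from .selex import KmerAffinityTable, SelexPeak

BASES = np.array(list("ACGT"))

# stage tags -> child-seed stream indices
_STAGES = {
    "genome": 1,
    "affinity": 2,
    "counts": 3,
    "mnase": 4,
    "marks": 5,
    "kd": 6,
    "chip": 8,
}


def _default_mark_bias() -> dict[str, dict[str, float]]:
    # odds multipliers on the base overlap probability, keyed by accessibility
    # class; repressive H3K27me3 is biased toward closed chromatin, active
    # promoter/acetylation marks toward open chromatin.
    return {
        "H3K27me3": {"closed": 3.0, "open": 0.4},
        "H3K4me3": {"closed": 0.5, "open": 3.0},
        "H3K9ac": {"closed": 0.7, "open": 2.5},
        "H3K36me3": {},
    }


@dataclass
class SimulationConfig:
    """The study conditions the generator emulates (all sizes desk scale)."""

    seed: int = 0
    # genome geometry
    n_chroms: int = 2
    genome_length: int = 350_000
    site_length: int = 400
    min_site_gap: int = 100
    # binding sites and planted CArG boxes
    n_sites: int = 1200
    n_paired_boxes: int = 100          # tetramer sites: one pair at pair_spacing
    n_uniform_pairs: int = 150         # pair sites at uniform spacing
    n_single_boxes: int = 250          # single-box sites
    pair_spacing: int = 50             # centre-to-centre, bp
    spacing_jitter: int = 3
    uniform_spacing_range: tuple[int, int] = (24, 280)
    # affinity table (relative affinities, dimensionless)
    high_affinity_mean: float = 10.0
    high_affinity_sigma: float = 0.25
    low_affinity_mean: float = 0.5
    low_affinity_sigma: float = 0.35
    low_kmer_factor: int = 3           # low entries per high entry
    # replicate ATAC counts
    frac_closed: float = 0.35
    closed_rpkm_mean: float = 15.0
    open_rpkm_mean: float = 70.0
    rpkm_region_sigma: float = 0.2     # log-sd of per-region mean around class mean
    dispersion: float = 0.02           # NB: var = mu + dispersion * mu^2
    frac_increasing: float = 0.30
    frac_decreasing: float = 0.15
    planted_fc: float = 2.0
    n_replicates: int = 3
    library_size: int = 20_000_000
    library_size_jitter: float = 0.1
    # MNase coverage
    n_depleted: int = 500
    mnase_depletion_factor: float = 0.3
    mnase_background_mean: float = 10.0
    mnase_noise_cv: float = 0.1
    mnase_track_noise: float = 0.05    # log-sd of DEX-vs-MOCK bin wobble
    mnase_bin: int = 10
    depletion_halfwidth: int = 73      # one nucleosome half-footprint around summit
    # paired ChIP (WT vs tetramerisation mutant)
    n_wt_specific: int = 50
    specific_ratio: float = 8.0
    chip_rpkm_mean: float = 30.0
    # histone marks
    mark_base_prob: float = 0.25
    mark_bias: dict[str, dict[str, float]] = field(default_factory=_default_mark_bias)
    # EMSA series
    kd_true: float = 2.0               # nM
    bmax_true: float = 1.0             # nM
    kd_n_points: int = 10
    kd_total_max: float = 12.38        # nM, titration top
    kd_total_min: float = 0.02         # nM, titration bottom
    kd_noise_frac: float = 0.02        # noise sd as fraction of Bmax

    def __post_init__(self) -> None:
        for name in ("frac_closed", "frac_increasing", "frac_decreasing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.frac_increasing + self.frac_decreasing > 1.0:
            raise ValidationError("dynamics fractions exceed 1")
        if self.pair_spacing <= 0:
            raise ValidationError("pair_spacing must be positive")
        if self.n_paired_boxes + self.n_uniform_pairs + self.n_single_boxes > self.n_sites:
            raise ValidationError("more planted elements than sites")

    def rng(self, stage: str) -> np.random.Generator:
        """A child generator dedicated to one output stage."""
        return np.random.default_rng([_STAGES[stage], self.seed])


# ------------------------------------------------------------------- genome


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    """Non-overlapping fixed-length site intervals, roughly uniform."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per = np.full(config.n_chroms, config.n_sites // config.n_chroms)
    per[: config.n_sites % config.n_chroms] += 1
    sites = []
    for chrom, n_c in zip(chroms, per):
        n_c = int(n_c)
        need = n_c * config.site_length + (n_c + 1) * config.min_site_gap
        if need > config.genome_length:
            raise ValidationError(
                f"cannot place {n_c} sites of {config.site_length} bp on a "
                f"{config.genome_length} bp chromosome"
            )
        slack = config.genome_length - n_c * config.site_length - n_c * config.min_site_gap
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = 0
        for i in range(n_c):
            pos += int(extra[i]) + config.min_site_gap
            sites.append(GenomicInterval(chrom, pos, pos + config.site_length))
            pos += config.site_length
    return sites


def _carg_box(rng: np.random.Generator) -> str:
    w_len = int(rng.integers(5, 8))  # uniform over {5, 6, 7}
    run = "".join(rng.choice(["A", "T"], size=w_len))
    return f"CC{run}GG"


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    sites: list[BindingSite]
    truth_sites: pd.DataFrame   # one row per site: kind, spacing, score, ...
    truth_boxes: pd.DataFrame   # one row per planted box


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """I.i.d.-uniform background with CArG boxes planted at binding sites.

    Site kinds: ``tetramer`` (a box pair at ~pair_spacing, high site score),
    ``uniform_pair`` (a pair at uniform spacing), ``single`` (one box) and
    ``empty`` (no box, indirect binding). Box pairs are centred on the site
    centre; the truth tables record every planted box and pair spacing.
    """
    rng = config.rng("genome")
    intervals = _place_sites(config, rng)
    seqs = {
        f"chr{i + 1}": rng.choice(BASES, size=config.genome_length)
        for i in range(config.n_chroms)
    }
    kinds = (
        ["tetramer"] * config.n_paired_boxes
        + ["uniform_pair"] * config.n_uniform_pairs
        + ["single"] * config.n_single_boxes
    )
    kinds += ["empty"] * (config.n_sites - len(kinds))
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]

    site_rows, box_rows, sites = [], [], []
    lo, hi = config.uniform_spacing_range
    for idx, (iv, kind) in enumerate(zip(intervals, kinds)):
        centre = iv.centre
        spacing = np.nan
        boxes: list[tuple[int, str]] = []
        if kind == "tetramer":
            spacing = config.pair_spacing + int(
                rng.integers(-config.spacing_jitter, config.spacing_jitter + 1)
            )
        elif kind == "uniform_pair":
            spacing = int(rng.integers(lo, hi + 1))
        if kind in ("tetramer", "uniform_pair"):
            c1 = centre - int(spacing) // 2
            c2 = c1 + int(spacing)
            for c in (c1, c2):
                box = _carg_box(rng)
                boxes.append((c - len(box) // 2, box))
        elif kind == "single":
            box = _carg_box(rng)
            boxes.append((centre - len(box) // 2, box))
        for start, box in boxes:
            seqs[iv.chrom][start : start + len(box)] = list(box)
            box_rows.append(
                {
                    "site_index": idx,
                    "chrom": iv.chrom,
                    "start": start,
                    "end": start + len(box),
                    "box": box,
                    "kind": kind,
                }
            )
        # tetramer sites carry the top ChIP scores; others score lower
        if kind == "tetramer":
            score = float(rng.uniform(8.0, 10.0))
        elif kind == "empty":
            score = float(rng.uniform(0.5, 3.0))
        else:
            score = float(rng.uniform(1.0, 6.0))
        fdr = float(rng.uniform(0.0, 0.09))
        sites.append(BindingSite(iv, summit=centre, score=score, fdr=fdr))
        site_rows.append(
            {
                "site_index": idx,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "summit": centre,
                "kind": kind,
                "spacing": spacing,
                "score": score,
            }
        )
    genome = {c: "".join(a) for c, a in seqs.items()}
    return SimulatedGenome(
        genome=genome,
        sites=sites,
        truth_sites=pd.DataFrame(site_rows),
        truth_boxes=pd.DataFrame(box_rows),
    )


# ----------------------------------------------------------- affinity table


def simulate_affinity_table(
    config: SimulationConfig, sim_genome: SimulatedGenome, k: int = 12
) -> KmerAffinityTable:
    """Affinity table with a high log-normal component for CArG 12-mers.

    High entries are the genomic k-mer windows fully containing a planted
    box (so mapping them back recovers the box, with 2-4 supporting k-mers
    per locus); low entries are random k-mers from a separated low
    component. With the default separation the table median falls inside
    the low component, below every high entry.
    """
    rng = config.rng("affinity")
    entries: dict[str, float] = {}
    for row in sim_genome.truth_boxes.itertuples(index=False):
        seq = sim_genome.genome[row.chrom]
        box_len = row.end - row.start
        for w in range(row.end - k, row.start + 1):
            if w < 0 or w + k > len(seq):
                continue
            kmer = seq[w : w + k]
            if kmer not in entries:
                entries[kmer] = float(
                    rng.lognormal(np.log(config.high_affinity_mean), config.high_affinity_sigma)
                )
    n_low = config.low_kmer_factor * max(1, len(entries))
    while n_low > 0:
        kmer = "".join(rng.choice(BASES, size=k))
        if kmer in entries:
            continue
        entries[kmer] = float(
            rng.lognormal(np.log(config.low_affinity_mean), config.low_affinity_sigma)
        )
        n_low -= 1
    return KmerAffinityTable(k=k, entries=entries, min_count=10)


# ------------------------------------------------------------------- counts


@dataclass
class SimulatedCounts:
    signal: RegionSignal              # baseline + induced samples, RPKM filled
    baseline_samples: list[str]
    induced_samples: list[str]
    diffs: list[DifferentialRecord]
    nfr: list[GenomicInterval]
    nuc: list[GenomicInterval]
    truth: pd.DataFrame               # access + dynamics truth per region


def simulate_counts(
    config: SimulationConfig, regions: Sequence[GenomicInterval]
) -> SimulatedCounts:
    """Negative-binomial replicate ATAC counts with planted classes.

    Closed regions draw a low per-region mean accessibility, open regions a
    high one (log-normal around the class mean); "increasing"/"decreasing"
    regions have their induced-sample mean multiplied by the planted fold
    change (or its inverse). Nucleosome-free truth regions are sampled from
    open sites and nucleosome-containing ones from closed sites, so the
    midpoint-of-medians threshold separates the classes.
    """
    rng = config.rng("counts")
    n = len(regions)
    access = np.where(rng.random(n) < config.frac_closed, "closed", "open")
    u = rng.random(n)
    dynamics = np.where(
        u < config.frac_increasing,
        "incr",
        np.where(u < config.frac_increasing + config.frac_decreasing, "decr", "steady"),
    )
    class_mean = np.where(
        access == "closed", config.closed_rpkm_mean, config.open_rpkm_mean
    )
    region_mean = class_mean * rng.lognormal(
        -0.5 * config.rpkm_region_sigma**2, config.rpkm_region_sigma, size=n
    )
    fc = np.where(
        dynamics == "incr",
        config.planted_fc,
        np.where(dynamics == "decr", 1.0 / config.planted_fc, 1.0),
    )
    baseline_samples = [f"atac_uninduced_rep{i + 1}" for i in range(config.n_replicates)]
    induced_samples = [f"atac_induced48_rep{i + 1}" for i in range(config.n_replicates)]
    samples = baseline_samples + induced_samples
    lib = {
        s: int(
            config.library_size
            * (1.0 + config.library_size_jitter * float(rng.uniform(-1.0, 1.0)))
        )
        for s in samples
    }
    length_kb = np.array([len(r) for r in regions]) / 1000.0
    counts = np.zeros((n, len(samples)))
    r_nb = 1.0 / config.dispersion
    for j, s in enumerate(samples):
        mean_rpkm = region_mean * (fc if s in induced_samples else 1.0)
        mu = mean_rpkm * length_kb * lib[s] / 1e6
        counts[:, j] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    signal = rpkm_normalise(
        RegionSignal(list(regions), samples, counts, lib)
    )
    diffs = welch_differential(signal, baseline_samples, induced_samples)

    open_idx = np.flatnonzero(access == "open")
    closed_idx = np.flatnonzero(access == "closed")
    n_pick = max(1, min(150, open_idx.size, closed_idx.size))
    nfr_idx = rng.choice(open_idx, size=n_pick, replace=False)
    nuc_idx = rng.choice(closed_idx, size=n_pick, replace=False)

    def shrink(iv: GenomicInterval) -> GenomicInterval:
        c = iv.centre
        return GenomicInterval(iv.chrom, max(iv.start, c - 100), min(iv.end, c + 100))

    truth = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "access": access,
            "dynamics": dynamics,
            "category": [f"wt_{a}_{d}" for a, d in zip(access, dynamics)],
            "region_mean_rpkm": region_mean,
            "planted_fc": fc,
        }
    )
    return SimulatedCounts(
        signal=signal,
        baseline_samples=baseline_samples,
        induced_samples=induced_samples,
        diffs=diffs,
        nfr=[shrink(regions[i]) for i in sorted(nfr_idx)],
        nuc=[shrink(regions[i]) for i in sorted(nuc_idx)],
        truth=truth,
    )


# -------------------------------------------------------------------- MNase


@dataclass
class SimulatedMnase:
    mock: dict[str, np.ndarray]
    dex: dict[str, np.ndarray]
    depleted_index: np.ndarray  # indices into the site list


def simulate_mnase(
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    sites: Sequence[BindingSite],
) -> SimulatedMnase:
    """Piecewise-constant MNase coverage; DEX depleted at designated sites.

    Coverage is gamma noise around a common mean in fixed-width bins; the
    DEX track is the MOCK track with small multiplicative noise, scaled by
    the depletion factor over summit ± depletion_halfwidth at the depleted
    sites (nucleosome loss after induction). Coverage is nonnegative
    everywhere by construction.
    """
    rng = config.rng("mnase")
    cv = config.mnase_noise_cv
    shape = 1.0 / (cv * cv)
    mock, dex = {}, {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = (size + config.mnase_bin - 1) // config.mnase_bin
        bins = rng.gamma(shape, config.mnase_background_mean / shape, size=n_bins)
        s = config.mnase_track_noise
        wobble = rng.lognormal(-0.5 * s * s, s, size=n_bins) if s > 0 else np.ones(n_bins)
        mock[chrom] = np.repeat(bins, config.mnase_bin)[:size]
        dex[chrom] = np.repeat(bins * wobble, config.mnase_bin)[:size]
    depleted = np.sort(
        rng.choice(len(sites), size=min(config.n_depleted, len(sites)), replace=False)
    )
    for i in depleted:
        site = sites[i]
        arr = dex[site.interval.chrom]
        lo = max(0, site.summit - config.depletion_halfwidth)
        hi = min(arr.size, site.summit + config.depletion_halfwidth + 1)
        arr[lo:hi] *= config.mnase_depletion_factor
    return SimulatedMnase(mock=mock, dex=dex, depleted_index=depleted)


# -------------------------------------------------------------------- marks


def simulate_marks(
    config: SimulationConfig,
    sites: Sequence[BindingSite],
    labels: Sequence[str],
    access: Sequence[str],
) -> tuple[dict[str, list[GenomicInterval]], pd.DataFrame]:
    """Mark interval sets with planted accessibility-class biases.

    Each (site, mark) overlap is Bernoulli with probability
    base_prob * odds, where the odds come from mark_bias keyed by the full
    category label or, failing that, by the accessibility class; missing
    keys mean odds 1 (no bias). Returns the BED-ready interval sets and a
    truth table of realised overlaps.
    """
    rng = config.rng("marks")
    beds: dict[str, list[GenomicInterval]] = {}
    rows = []
    for mark in sorted(config.mark_bias):
        bias = config.mark_bias[mark]
        regions = []
        for site, label, acc in zip(sites, labels, access):
            odds = bias.get(label, bias.get(acc, 1.0))
            p = min(0.95, config.mark_base_prob * odds)
            hit = bool(rng.random() < p)
            if hit:
                c = site.centre
                regions.append(GenomicInterval(site.interval.chrom, max(0, c - 100), c + 100))
            rows.append({"mark": mark, "site_key": site.key(), "overlap": hit})
        beds[mark] = regions
    return beds, pd.DataFrame(rows)


# ----------------------------------------------------------- ChIP WT vs mut


@dataclass
class SimulatedChipPair:
    signal_wt: RegionSignal
    signal_mut: RegionSignal
    specific_index: np.ndarray  # regions planted WT-specific


def simulate_chip_pair(
    config: SimulationConfig, regions: Sequence[GenomicInterval]
) -> SimulatedChipPair:
    """Paired ChIP count matrices with planted WT-specific regions.

    ``n_wt_specific`` regions have their WT mean multiplied by
    ``specific_ratio``; elsewhere WT and mutant share the same mean, so the
    log2 RPKM ratio ranks the planted regions on top.
    """
    rng = config.rng("chip")
    n = len(regions)
    base = config.chip_rpkm_mean * rng.lognormal(
        -0.5 * config.rpkm_region_sigma**2, config.rpkm_region_sigma, size=n
    )
    specific = np.sort(rng.choice(n, size=min(config.n_wt_specific, n), replace=False))
    wt_mean = base.copy()
    wt_mean[specific] *= config.specific_ratio
    length_kb = np.array([len(r) for r in regions]) / 1000.0
    r_nb = 1.0 / config.dispersion

    def draw(mean_rpkm: np.ndarray, prefix: str) -> RegionSignal:
        samples = [f"{prefix}_rep{i + 1}" for i in range(config.n_replicates)]
        lib = {
            s: int(
                config.library_size
                * (1.0 + config.library_size_jitter * float(rng.uniform(-1.0, 1.0)))
            )
            for s in samples
        }
        counts = np.zeros((n, len(samples)))
        for j, s in enumerate(samples):
            mu = mean_rpkm * length_kb * lib[s] / 1e6
            counts[:, j] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        return rpkm_normalise(RegionSignal(list(regions), samples, counts, lib))

    return SimulatedChipPair(
        signal_wt=draw(wt_mean, "chip_wt"),
        signal_mut=draw(base, "chip_mut"),
        specific_index=specific,
    )


# ------------------------------------------------------- peak-level geometry


def simulate_peak_geometry(
    seed: int,
    n_tetramer: int = 100,
    n_uniform: int = 150,
    n_single: int = 250,
    pair_spacing: int | None = 50,
    spacing_jitter: int = 3,
    uniform_spacing_range: tuple[int, int] = (24, 280),
    site_length: int = 400,
    spacing_bp: int = 600,
) -> tuple[list[BindingSite], list[SelexPeak]]:
    """Sites and affinity peaks drawn directly at the geometry level.

    Bypasses sequence simulation and k-mer mapping: peak centres are placed
    at the positions the sequence-level generator would plant boxes. With
    ``pair_spacing=None`` the tetramer sites draw their spacing uniformly —
    the spacing-test null. Used for replicate-heavy null experiments where
    only peak geometry matters.
    """
    rng = np.random.default_rng([7, seed])
    kinds = ["tetramer"] * n_tetramer + ["uniform_pair"] * n_uniform + ["single"] * n_single
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]
    lo, hi = uniform_spacing_range
    sites, peaks = [], []
    pos = spacing_bp
    for kind in kinds:
        centre = pos + site_length // 2
        iv = GenomicInterval("chr1", pos, pos + site_length)
        if kind == "tetramer":
            if pair_spacing is None:
                d = int(rng.integers(lo, hi + 1))
            else:
                d = pair_spacing + int(rng.integers(-spacing_jitter, spacing_jitter + 1))
            centres = [centre - d // 2, centre - d // 2 + d]
            score = float(rng.uniform(8.0, 10.0))
        elif kind == "uniform_pair":
            d = int(rng.integers(lo, hi + 1))
            centres = [centre - d // 2, centre - d // 2 + d]
            score = float(rng.uniform(1.0, 6.0))
        else:
            centres = [centre]
            score = float(rng.uniform(1.0, 6.0))
        sites.append(BindingSite(iv, summit=centre, score=score, fdr=0.01))
        for c in centres:
            peaks.append(
                SelexPeak(GenomicInterval("chr1", c - 8, c + 9), score=2.0, n_kmers=2)
            )
        pos += site_length + spacing_bp
    return sites, peaks


# ---------------------------------------------------------------- EMSA data


def simulate_kd_series(config: SimulationConfig):
    """A titration series on the configured concentration range with 2% noise."""
    from .kdfit import simulate_series

    rng = config.rng("kd")
    totals = np.geomspace(config.kd_total_min, config.kd_total_max, config.kd_n_points)
    return simulate_series(
        kd=config.kd_true,
        bmax=config.bmax_true,
        totals=totals,
        noise_sd=config.kd_noise_frac * config.bmax_true,
        rng=rng,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["uniform_spacing_range"] = list(d["uniform_spacing_range"])
    return d
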