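"""Accessibility threshold, 9-way classification, specific-site ranking."""

import numpy as np
import pandas as pd
import pytest

from pioneerscope.classify import (
    AccessibilityThreshold,
    DifferentialRecord,
    classify_sites,
    category_counts,
    derive_threshold,
    link_de_genes,
    midpoint_threshold,
    random_regions,
    rank_specific_sites,
    welch_differential,
)
from pioneerscope.core import (
    BindingSite,
    GeneModel,
    GenomicInterval,
    RegionSignal,
    ValidationError,
    rpkm_normalise,
)
from pioneerscope.simulate import SimulationConfig, simulate_chip_pair


def make_site(i, fdr=0.01):
    iv = GenomicInterval("chr1", i * 1000, i * 1000 + 400)
    return BindingSite(iv, summit=iv.centre, score=1.0, fdr=fdr)


class TestThreshold:
    def test_midpoint_of_published_medians(self):
        thr = midpoint_threshold(30.17, 51.79)
        assert thr == (30.17 + 51.79) / 2
        assert round(thr, 2) == 40.98

    def test_identical_medians(self):
        assert AccessibilityThreshold(7.5, 7.5).threshold == 7.5

    def test_symmetric_in_region_sets(self):
        a = AccessibilityThreshold(10.0, 30.0)
        b = AccessibilityThreshold(30.0, 10.0)
        assert a.threshold == b.threshold

    def test_recovers_planted_medians(self, rng):
        """Bimodal synthetic signal: regions overlapping the NFR set carry
        one planted median, the nucleosome set the other."""
        n = 101
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(2 * n)]
        low = np.sort(rng.uniform(5, 25, n))
        high = np.sort(rng.uniform(40, 90, n))
        rpkm = np.concatenate([high, low])  # first n regions are accessible
        lib = 10**6
        counts = rpkm * 0.5 * lib / 1e6
        sig = rpkm_normalise(
            RegionSignal(regions, ["s"], counts[:, None], {"s": lib})
        )
        nfr = [regions[i] for i in range(n)]
        nuc = [regions[i] for i in range(n, 2 * n)]
        thr = derive_threshold(sig, nfr, nuc, "s")
        assert thr.median_nfr == pytest.approx(np.median(high), abs=1e-9)
        assert thr.median_nuc == pytest.approx(np.median(low), abs=1e-9)
        assert thr.threshold == pytest.approx((np.median(high) + np.median(low)) / 2,
                                              abs=1e-9)

    def test_empty_overlap_set_named_in_error(self, rng):
        regions = [GenomicInterval("chr1", 0, 500)]
        sig = rpkm_normalise(
            RegionSignal(regions, ["s"], np.array([[10.0]]), {"s": 10**6})
        )
        with pytest.raises(ValidationError, match="nucleosome-free"):
            derive_threshold(sig, [GenomicInterval("chr2", 0, 100)], regions, "s")


def rule_table_oracle(fc, p, rpkm, threshold):
    """Straight transcription of the classification rules."""
    access = "closed" if rpkm <= threshold else "open"
    if fc > 1.2 and p < 0.1:
        return f"wt_{access}_incr"
    if fc < 0.8 and p < 0.1:
        return f"wt_{access}_decr"
    if 0.8 <= fc <= 1.2 and p > 0.1:
        return f"wt_{access}_steady"
    return f"other_{access}"


class TestClassifySites:
    def test_closed_increasing_example(self):
        df = classify_sites(
            [make_site(0)], [10.0], [DifferentialRecord(1.5, 0.05)], threshold=40.98
        )
        assert list(df["category"]) == ["wt_closed_incr"]

    def test_steady_in_each_accessibility_class(self):
        df = classify_sites(
            [make_site(0), make_site(1)],
            [10.0, 80.0],
            [DifferentialRecord(1.0, 0.5)] * 2,
            threshold=40.98,
        )
        assert list(df["category"]) == ["wt_closed_steady", "wt_open_steady"]

    def test_boundary_grid_matches_rule_table(self):
        eps = 1e-9
        fcs = [0.5, 0.8 - eps, 0.8, 0.8 + eps, 1.0, 1.2 - eps, 1.2, 1.2 + eps, 1.5]
        ps = [0.05, 0.1 - eps, 0.1, 0.1 + eps, 0.5]
        thr = 40.98
        for rpkm in (thr - 1, thr, thr + 1):  # exact tie goes to closed
            for fc in fcs:
                for p in ps:
                    df = classify_sites(
                        [make_site(0)], [rpkm], [DifferentialRecord(fc, p)], thr
                    )
                    assert df["category"].iloc[0] == rule_table_oracle(fc, p, rpkm, thr), (
                        fc, p, rpkm
                    )

    def test_p_exactly_point_one_is_other(self):
        df = classify_sites(
            [make_site(0)], [10.0], [DifferentialRecord(1.0, 0.1)], threshold=40.0
        )
        assert df["category"].iloc[0] == "other_closed"

    def test_fdr_filter_and_partition(self, rng):
        n = 200
        sites = [make_site(i, fdr=float(rng.uniform(0, 0.2))) for i in range(n)]
        rpkm = rng.uniform(0, 100, n)
        diffs = [
            DifferentialRecord(float(rng.lognormal(0, 0.5)), float(rng.uniform(0, 1)))
            for _ in range(n)
        ]
        df = classify_sites(sites, rpkm, diffs, threshold=41.0)
        n_sig = sum(1 for s in sites if s.fdr < 0.1)
        assert len(df) == n_sig
        counts = category_counts(df)
        assert sum(counts.values()) == n_sig
        closed = (df["accessibility"] == "closed").sum()
        opened = (df["accessibility"] == "open").sum()
        assert closed + opened == n_sig

    def test_scale_invariance(self, rng):
        n = 50
        sites = [make_site(i) for i in range(n)]
        rpkm = rng.uniform(0, 100, n)
        diffs = [
            DifferentialRecord(float(rng.lognormal(0, 0.5)), float(rng.uniform(0, 1)))
            for _ in range(n)
        ]
        a = classify_sites(sites, rpkm, diffs, threshold=40.0)
        b = classify_sites(sites, rpkm * 3.0, diffs, threshold=120.0)
        assert list(a["category"]) == list(b["category"])

    def test_missing_record_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_sites([make_site(0)], [10.0], [None], threshold=40.0)


class TestRankSpecific:
    def _signal(self, counts, prefix):
        n = np.asarray(counts).shape[0]
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(n)]
        samples = [f"{prefix}1"]
        return RegionSignal(regions, samples, np.asarray(counts, float),
                            {samples[0]: 10**6})

    def test_highest_ratio_ranks_first(self):
        wt = self._signal([[8], [4], [4]], "wt")
        mut = self._signal([[1], [4], [4]], "mut")
        wt_idx, mut_idx, _ = rank_specific_sites(wt, mut, top_n=1)
        assert wt_idx == [0]

    def test_swapping_signals_swaps_lists(self, rng):
        counts_a = rng.integers(1, 100, size=(20, 2)).astype(float)
        counts_b = rng.integers(1, 100, size=(20, 2)).astype(float)
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(20)]
        lib = {"x1": 10**6, "x2": 10**6}
        a = RegionSignal(regions, ["x1", "x2"], counts_a, lib)
        b = RegionSignal(regions, ["x1", "x2"], counts_b, lib)
        fwd = rank_specific_sites(a, b, top_n=5)
        rev = rank_specific_sites(b, a, top_n=5)
        assert fwd[0] == rev[1] and fwd[1] == rev[0]

    def test_top_n_exceeding_regions_is_an_error(self):
        wt = self._signal([[1], [2]], "wt")
        with pytest.raises(ValidationError):
            rank_specific_sites(wt, wt, top_n=3)

    def test_planted_high_ratio_regions_recovered(self):
        """50 planted WT-specific regions among 1,000: at least 48 land in
        the top 50 by log2 RPKM ratio under default generator noise."""
        cfg = SimulationConfig(seed=5)
        regions = [
            GenomicInterval("chr1", i * 1000, i * 1000 + 400) for i in range(1000)
        ]
        chip = simulate_chip_pair(cfg, regions)
        wt_idx, _, _ = rank_specific_sites(chip.signal_wt, chip.signal_mut, top_n=50)
        assert len(set(wt_idx) & set(chip.specific_index.tolist())) >= 48


class TestRandomRegions:
    def test_fixed_length_and_determinism(self):
        sizes = {"chr1": 10_000, "chr2": 30_000}
        a = random_regions(sizes, n=100, length=400, seed=3)
        b = random_regions(sizes, n=100, length=400, seed=3)
        assert all(len(r) == 400 for r in a)
        assert a == b
        assert a != random_regions(sizes, n=100, length=400, seed=4)

    def test_allocation_proportional_to_valid_starts(self):
        sizes = {"chr1": 10_000, "chr2": 30_000}
        draws = random_regions(sizes, n=10_000, length=400, seed=9)
        n1 = sum(1 for r in draws if r.chrom == "chr1")
        p1 = (10_000 - 399) / ((10_000 - 399) + (30_000 - 399))
        se = np.sqrt(p1 * (1 - p1) / 10_000)
        assert abs(n1 / 10_000 - p1) < 2.576 * se  # 99% binomial CI

    def test_chrom_shorter_than_length_rejected(self):
        with pytest.raises(ValidationError):
            random_regions({"chr1": 300}, n=10, length=400, seed=0)


class TestLinkDeGenes:
    def _genes(self):
        return [
            GeneModel("g_up", GenomicInterval("chr1", 10_000, 12_000), "+"),
            GeneModel("g_down", GenomicInterval("chr1", 30_000, 32_000), "+"),
            GeneModel("g_far", GenomicInterval("chr1", 60_000, 62_000), "+"),
        ]

    def test_activated_and_repressed_bookkeeping(self):
        de = pd.DataFrame(
            {
                "gene": ["g_up", "g_down", "g_far"],
                "log2fc": [1.2, -1.2, 2.0],
                "fdr": [0.01, 0.01, 0.5],  # g_far fails the FDR filter
            }
        )
        sites = [
            BindingSite(GenomicInterval("chr1", 8_000, 8_200), 8_100, 1.0),  # promoter
        ]
        out = link_de_genes(de, sites, self._genes())
        assert out["n_de"] == 2 and out["n_activated"] == 1
        assert out["n_de_with_site"] == 1 and out["n_activated_with_site"] == 1
        assert out["frac_activated"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        genes = [
            GeneModel(f"g{i}", GenomicInterval("chr1", int(s), int(s) + 1500), "+")
            for i, s in enumerate(rng.integers(5_000, 90_000, 30))
        ]
        de = pd.DataFrame(
            {
                "gene": [g.gene_id for g in genes],
                "log2fc": rng.normal(0, 1.5, 30),
                "fdr": rng.uniform(0, 0.2, 30),
            }
        )
        sites = [
            BindingSite(GenomicInterval("chr1", int(s), int(s) + 200), int(s) + 100, 1.0)
            for s in rng.integers(0, 95_000, 40)
        ]
        out = link_de_genes(de, sites, genes)
        de_mask = (de["log2fc"].abs() > 1) & (de["fdr"] < 0.05)
        exp_de = set(de["gene"][de_mask])
        exp_act = set(de["gene"][(de["log2fc"] > 1) & (de["fdr"] < 0.05)])
        gmap = {g.gene_id: g for g in genes}

        def has_site(gid):
            g = gmap[gid]
            ws, we = g.interval.start - 3000, g.interval.end + 1000
            return any(
                min(s.interval.end, we) - max(s.interval.start, ws) >= 1 for s in sites
            )

        assert out["n_de"] == len(exp_de)
        assert out["n_activated"] == len(exp_act)
        assert out["n_de_with_site"] == sum(1 for g in exp_de if has_site(g))
        assert out["n_activated_with_site"] == sum(1 for g in exp_act if has_site(g))


class TestWelchDifferential:
    def test_null_false_positive_rate_calibrated(self):
        """With no planted fold change the stand-in test's p < 0.05 fraction
        sits near (and, being a small-sample Welch test, slightly below) the
        nominal rate."""
        cfg = SimulationConfig(
            seed=3,
            frac_increasing=0.0,
            frac_decreasing=0.0,
            planted_fc=1.0,
            n_paired_boxes=0,
            n_uniform_pairs=0,
            n_single_boxes=0,
            n_sites=1000,
        )
        from pioneerscope.simulate import simulate_counts

        regions = [
            GenomicInterval("chr1", i * 500, i * 500 + 400) for i in range(1000)
        ]
        sc = simulate_counts(cfg, regions)
        frac = np.mean([d.p_value < 0.05 for d in sc.diffs])
        assert 0.01 <= frac <= 0.08
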