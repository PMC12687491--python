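"""End-to-end driver: simulate -> selex -> spacing -> classify -> rank ->
mnase-rank -> mark-enrich -> kd, with a run manifest.

The driver chains every analysis stage on one synthetic dataset and writes
all stage products plus a JSON manifest (tool version, seed, config, and a
SHA-256 digest per output). With a fixed seed the stage products are
byte-identical across reruns; the manifest's wall-clock timestamps are the
one deliberately non-reproducible field.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as psio
from .classify import (
    category_counts,
    classify_sites,
    derive_threshold,
    rank_specific_sites,
)
from .core import sites_to_frame
from .kdfit import fit_both
from .marks import build_contingency, pearson_residuals
from .mnase import category_overlap, records_to_frame, summit_ratio, top_bottom_groups
from .selex import call_selex_peaks, map_kmers, peaks_to_frame, write_peaks_bed
from .simulate import (
    SimulationConfig,
    config_to_dict,
    simulate_affinity_table,
    simulate_chip_pair,
    simulate_counts,
    simulate_genome,
    simulate_kd_series,
    simulate_marks,
    simulate_mnase,
)
from .spacing import min_p_window, results_to_frame, spacing_test, top_sites


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: SimulationConfig,
    outdir,
    top_n: int | None = None,
    mnase_group_n: int | None = None,
    write_timestamps: bool = True,
) -> dict:
    """Run every stage on one synthetic dataset; returns the manifest dict.

    ``top_n`` is the foreground size for the spacing test (defaults to the
    number of tetramer sites); ``mnase_group_n`` the top/bottom group size
    (defaults to min(500, n_sites // 2)).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    if top_n is None:
        top_n = config.n_paired_boxes
    if mnase_group_n is None:
        mnase_group_n = min(500, config.n_sites // 2)

    # --- simulate genome, sites, affinity table
    sim = simulate_genome(config)
    chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
    table = simulate_affinity_table(config, sim)
    psio.write_fasta(outdir / "genome.fa", sim.genome)
    psio.write_table(outdir / "affinity.tsv", table.to_frame())
    psio.write_sites(outdir / "sites.tsv", sim.sites)
    psio.write_table(truth_dir / "sites.tsv", sim.truth_sites)
    psio.write_table(truth_dir / "boxes.tsv", sim.truth_boxes)

    # --- selex mapping and peak calling
    hits = map_kmers(sim.genome, table)
    peaks = call_selex_peaks(hits, table)
    psio.write_table(outdir / "selex_peaks.tsv", peaks_to_frame(peaks))
    write_peaks_bed(outdir / "selex_peaks.bed", peaks)

    # --- spacing enrichment in top-scoring sites
    fg = top_sites(sim.sites, top_n)
    spacing = spacing_test(fg, peaks, window=20, radius=200, max_distance=300)
    psio.write_table(outdir / "spacing.tsv", results_to_frame(spacing))
    best = min_p_window(spacing)

    # --- accessibility classification
    counts = simulate_counts(config, [s.interval for s in sim.sites])
    psio.write_counts(outdir / "counts.tsv", counts.signal)
    psio.write_table(
        outdir / "library_sizes.tsv",
        pd.DataFrame(
            {
                "sample": counts.signal.samples,
                "library_size": [
                    counts.signal.library_sizes[s] for s in counts.signal.samples
                ],
            }
        ),
    )
    psio.write_bed(outdir / "nfr.bed", counts.nfr)
    psio.write_bed(outdir / "nuc.bed", counts.nuc)
    psio.write_table(truth_dir / "counts.tsv", counts.truth)
    thr = derive_threshold(counts.signal, counts.nfr, counts.nuc, counts.baseline_samples)
    psio.write_table(
        outdir / "threshold.tsv",
        pd.DataFrame(
            [
                {
                    "median_nfr": thr.median_nfr,
                    "median_nuc": thr.median_nuc,
                    "threshold": thr.threshold,
                }
            ]
        ),
    )
    base_cols = [counts.signal.sample_index(s) for s in counts.baseline_samples]
    baseline = counts.signal.rpkm[:, base_cols].mean(axis=1)
    diff_df = pd.DataFrame(
        {
            "chrom": [s.interval.chrom for s in sim.sites],
            "start": [s.interval.start for s in sim.sites],
            "end": [s.interval.end for s in sim.sites],
            "fold_change": [d.fold_change for d in counts.diffs],
            "p_value": [d.p_value for d in counts.diffs],
        }
    )
    psio.write_table(outdir / "diff.tsv", diff_df)
    classified = classify_sites(sim.sites, baseline, counts.diffs, thr.threshold)
    psio.write_table(outdir / "categories.tsv", classified)

    # --- WT vs mutant specific-site ranking
    chip = simulate_chip_pair(config, [s.interval for s in sim.sites])
    wt_idx, mut_idx, log2fc = rank_specific_sites(
        chip.signal_wt, chip.signal_mut, top_n=config.n_wt_specific
    )
    sites_df = sites_to_frame(sim.sites)
    rank_df = sites_df[["chrom", "start", "end"]].copy()
    rank_df["log2fc_wt_vs_mut"] = log2fc
    rank_df["wt_specific"] = [i in set(wt_idx) for i in range(len(sim.sites))]
    rank_df["mut_specific"] = [i in set(mut_idx) for i in range(len(sim.sites))]
    psio.write_table(outdir / "specific_sites.tsv", rank_df)
    psio.write_table(
        truth_dir / "wt_specific.tsv",
        sites_df.iloc[chip.specific_index][["chrom", "start", "end"]],
    )

    # --- MNase ratio ranking and category overlap
    mn = simulate_mnase(config, chrom_sizes, sim.sites)
    psio.write_bedgraph(outdir / "mnase_mock.bedgraph", mn.mock)
    psio.write_bedgraph(outdir / "mnase_dex.bedgraph", mn.dex)
    psio.write_table(
        truth_dir / "mnase_depleted.tsv",
        sites_df.iloc[mn.depleted_index][["chrom", "start", "end", "summit"]],
    )
    records = summit_ratio(sim.sites, mn.mock, mn.dex)
    psio.write_table(outdir / "mnase_ratios.tsv", records_to_frame(records))
    group1, group2 = top_bottom_groups(records, n=mnase_group_n)
    labels = {
        (str(r.chrom), int(r.start), int(r.end)): str(r.category)
        for r in classified.itertuples(index=False)
    }
    overlap_df = category_overlap(group1, group2, labels)
    psio.write_table(outdir / "mnase_category_overlap.tsv", overlap_df)

    # --- histone-mark contingency
    label_list = [labels[s.key()] for s in sim.sites]
    access_list = list(counts.truth["access"])
    mark_beds, mark_truth = simulate_marks(config, sim.sites, label_list, access_list)
    for mark, regions in mark_beds.items():
        psio.write_bed(outdir / f"mark_{mark}.bed", regions)
    table_mc = build_contingency(sim.sites, label_list, mark_beds)
    residuals, chi2_stat, chi2_p, chi2_df = pearson_residuals(table_mc)
    residuals.to_csv(outdir / "mark_residuals.tsv", sep="\t", lineterminator="\n")
    table_mc.to_frame().to_csv(outdir / "mark_counts.tsv", sep="\t", lineterminator="\n")
    psio.write_table(
        outdir / "mark_chi2.tsv",
        pd.DataFrame([{"chi2": chi2_stat, "df": chi2_df, "p_value": chi2_p}]),
    )

    # --- EMSA Kd estimation
    series = simulate_kd_series(config)
    psio.write_table(
        outdir / "kd_series.tsv",
        pd.DataFrame({"total": series.total, "bound": series.bound}),
    )
    kd_df = fit_both(series)
    psio.write_table(outdir / "kd_fits.tsv", kd_df)

    # --- manifest
    outputs = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "tool": "pioneerscope",
        "version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "parameters": {
            "top_n": top_n,
            "mnase_group_n": mnase_group_n,
            "spacing_window": 20,
            "spacing_radius": 200,
            "spacing_max_distance": 300,
        },
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        "summary": {
            "n_selex_peaks": len(peaks),
            "min_p_window": [best.window_start, best.window_end],
            "min_p_value": best.p_value,
            "threshold_rpkm": thr.threshold,
            "category_counts": category_counts(classified),
            "chi2": chi2_stat,
            "chi2_p": chi2_p,
            "kd": {r["model"]: r["kd"] for _, r in kd_df.iterrows()},
        },
    }
    if write_timestamps:
        manifest["timestamps"] = {
            "finished": datetime.datetime.now(datetime.timezone.utc).isoformat()
        }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
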