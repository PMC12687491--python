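import numpy as np
import pytest

from pioneerscope.classify import classify_sites, derive_threshold
from pioneerscope.selex import call_selex_peaks, map_kmers
from pioneerscope.simulate import (
    SimulationConfig,
    simulate_affinity_table,
    simulate_counts,
    simulate_genome,
    simulate_mnase,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for fast per-test simulations."""
    return SimulationConfig(
        seed=7,
        n_chroms=1,
        genome_length=40_000,
        n_sites=60,
        n_paired_boxes=12,
        n_uniform_pairs=15,
        n_single_boxes=20,
        n_depleted=20,
        n_wt_specific=10,
    )


@pytest.fixture(scope="session")
def study(default_config):
    """One full synthetic study at default conditions, shared across tests.

    Runs the sequence-level generator, SELEX mapping/peak calling, the
    accessibility classification and the MNase simulation once.
    """
    cfg = default_config
    sim = simulate_genome(cfg)
    table = simulate_affinity_table(cfg, sim)
    peaks = call_selex_peaks(map_kmers(sim.genome, table), table)
    counts = simulate_counts(cfg, [s.interval for s in sim.sites])
    thr = derive_threshold(
        counts.signal, counts.nfr, counts.nuc, counts.baseline_samples
    )
    base_cols = [counts.signal.sample_index(s) for s in counts.baseline_samples]
    baseline = counts.signal.rpkm[:, base_cols].mean(axis=1)
    classified = classify_sites(sim.sites, baseline, counts.diffs, thr.threshold)
    chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
    mn = simulate_mnase(cfg, chrom_sizes, sim.sites)
    return {
        "config": cfg,
        "sim": sim,
        "table": table,
        "peaks": peaks,
        "counts": counts,
        "threshold": thr,
        "classified": classified,
        "mnase": mn,
        "chrom_sizes": chrom_sizes,
    }
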