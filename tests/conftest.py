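import numpy as np
import pandas as pd
import pytest

from scnova.fragments import FRAGMENT_COLUMNS, fragments_from_frame
from scnova.simulate import CloneSpec, SimulationConfig, simulate_cells, simulate_genome


def make_fragments(rows):
    """Build a FragmentSet from (chrom, start, end, cell, strand, hap, mapq, dup, suppl) rows."""
    return fragments_from_frame(pd.DataFrame(rows, columns=FRAGMENT_COLUMNS))


@pytest.fixture(scope="session")
def sim_default():
    """A small default simulation shared by track/feature tests."""
    cfg = SimulationConfig(
        n_chroms=1,
        chrom_length=1_000_000,
        n_genes=40,
        gene_length_range=(6_000, 12_000),
        n_cells=40,
        fragments_per_cell=4_000,
        seed=3,
    )
    genome = simulate_genome(cfg)
    frags, truth = simulate_cells(genome, cfg)
    return cfg, genome, frags, truth


@pytest.fixture(scope="session")
def sim_haplo_effect():
    """Simulation with a 2x H1 occupancy effect on a third of the genes."""
    eff_genes = [f"g{i:05d}" for i in range(0, 60, 3)]
    clones = [CloneSpec("c1", 1.0, haplotype_effects={g: {"H1": 2.0} for g in eff_genes})]
    cfg = SimulationConfig(
        n_chroms=1,
        chrom_length=1_500_000,
        n_genes=60,
        gene_length_range=(8_000, 15_000),
        n_cells=80,
        fragments_per_cell=6_000,
        clones=clones,
        seed=11,
    )
    genome = simulate_genome(cfg)
    frags, truth = simulate_cells(genome, cfg)
    return cfg, genome, frags, truth, eff_genes


@pytest.fixture(scope="session")
def sim_two_clones():
    """Two equal clones, 20 of 200 genes carry a 2-fold NO shift in the SV clone."""
    shift_genes = [f"g{i:05d}" for i in range(0, 200, 10)]
    clones = [
        CloneSpec("ref", 0.5),
        CloneSpec("sv", 0.5, activity_shifts={g: 2.0 for g in shift_genes}),
    ]
    cfg = SimulationConfig(
        n_chroms=2,
        chrom_length=2_000_000,
        n_genes=200,
        gene_length_range=(5_000, 12_000),
        n_cells=100,
        fragments_per_cell=8_000,
        clones=clones,
        seed=7,
    )
    genome = simulate_genome(cfg)
    frags, truth = simulate_cells(genome, cfg)
    return cfg, genome, frags, truth, shift_genes
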