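import numpy as np
import pytest

from baculoannot.synthetic import (
    PanelConfig,
    SimulationConfig,
    simulate_genome,
    simulate_panel,
)

BALANCED_8_TAXON_TREE = (
    "(((A:0.08,B:0.08):0.08,(C:0.08,D:0.08):0.08):0.04,"
    "((E:0.08,F:0.08):0.08,(G:0.08,H:0.08):0.08):0.04);"
)


@pytest.fixture(scope="session")
def sim_genome():
    """Mid-sized planted-truth circular genome used across modules."""
    cfg = SimulationConfig(genome_length=24_000, n_orfs=22, seed=11)
    record, truth = simulate_genome(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def sim_panel():
    """Four-genome panel with one inversion per non-focal genome."""
    tree = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);"
    cfg = PanelConfig(
        n_genes=8,
        gene_length_aa=(80, 120),
        subst_rate=1.0,
        inversions_per_genome=1,
        seed=3,
    )
    return cfg, simulate_panel(tree, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


def orf_key(f):
    return (f.start, f.strand, f.length_nt)


def orf_keys(orfs):
    return {orf_key(f) for f in orfs}
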