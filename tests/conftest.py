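import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paleostack.genio import Dataset, assign_blocks
from paleostack.simdata import (DriftGraphSpec, default_map,
                                sample_pseudohaploid, simulate_freq_graph)


@pytest.fixture(scope="session")
def clade_panel():
    """Two populations forming a clade (P1, P2 from C) plus outgroups."""
    spec = DriftGraphSpec(
        nodes=["root", "C", "P1", "P2", "O1", "O2", "O3", "O4", "O5"],
        edges=[("root", "C", 0.05), ("C", "P1", 0.02), ("C", "P2", 0.02),
               ("root", "O1", 0.10), ("root", "O2", 0.15), ("root", "O3", 0.20),
               ("root", "O4", 0.12), ("root", "O5", 0.18)],
    )
    snp = default_map(10_000, n_chrom=10, seed=42)
    return simulate_freq_graph(spec, 10_000, seed=42, snp=snp)


def build_dataset(panel, sampling, missing=0.0, seed=0):
    """Stack pseudohaploid samples from several populations into one Dataset."""
    parts = [sample_pseudohaploid(panel, pop, n, missing, seed) for pop, n in sampling]
    return Dataset(np.vstack([p.geno for p in parts]), panel.snp.copy(),
                   pd.concat([p.ind for p in parts], ignore_index=True))


@pytest.fixture(scope="session")
def clade_dataset(clade_panel):
    ds = build_dataset(clade_panel,
                       [(p, 10) for p in ["P1", "P2", "O1", "O2", "O3", "O4", "O5"]],
                       missing=0.05, seed=7)
    return ds, assign_blocks(ds.snp)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fully observed 3-population dataset small enough for brute-force oracles."""
    spec = DriftGraphSpec(nodes=["root", "A", "B", "C"],
                          edges=[("root", "A", 0.05), ("root", "B", 0.10),
                                 ("root", "C", 0.20)])
    snp = default_map(200, n_chrom=2, seed=3)
    panel = simulate_freq_graph(spec, 200, seed=3, snp=snp)
    ds = build_dataset(panel, [("A", 5), ("B", 4), ("C", 6)], missing=0.0, seed=5)
    return ds, assign_blocks(ds.snp)
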