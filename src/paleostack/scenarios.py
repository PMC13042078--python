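"""Study scenarios: synthetic cohorts emulating the Altiplano Cundiboyacense
analyses, with published point estimates used as simulation ground truth.

Two scenarios are packaged because they are exercised by several drivers and
by the reproduction script:

* the two-way Chibchan-related / Amazonian-North admixture model for the
  Herrera-Muisca gene pool (weight recovery with a qpAdm-style fit), and
* the admixture-date scenario (ancestry-covariance decay over mosaic
  chromosomes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datefit import DateFit, covariance_curve, fit_decay, snp_weights
from .genio import BlockAssignment, Dataset, assign_blocks
from .simdata import (AdmixtureTruth, DriftGraphSpec, default_map,
                      sample_pseudohaploid, simulate_admixed_cohort,
                      simulate_freq_graph)
from .wave_adm import AdmixtureModel, qpadm_fit

#: fitted Chibchan-related ancestry proportion for the Colombia_Cundinamarca
#: group, used as simulation ground truth (fraction)
CUNDINAMARCA_CHIBCHAN_W = 0.539
#: inferred admixture depth of the Herrera-Muisca gene pool, generations
HERRERA_ADMIX_GENERATIONS = 137
REFERENCES = [f"Ref{i}" for i in range(1, 9)]


def admixture_graph(w: float = CUNDINAMARCA_CHIBCHAN_W) -> DriftGraphSpec:
    """Drift graph: two diverged sources, 8 differentially related references,
    and a target admixed with weight ``w`` plus post-admixture drift F=0.01."""
    nodes = ["root", "X", "YA", "YB", "Chibchan", "AmazonianNorth",
             "T0", "Target"] + REFERENCES
    edges = [
        ("root", "X", 0.10), ("X", "YA", 0.05), ("X", "YB", 0.05),
        ("YA", "Chibchan", 0.05), ("YB", "AmazonianNorth", 0.05),
        ("YA", "Ref3", 0.08), ("YA", "Ref4", 0.12),
        ("YB", "Ref5", 0.08), ("YB", "Ref6", 0.12),
        ("X", "Ref7", 0.15),
        ("root", "Ref1", 0.20), ("root", "Ref2", 0.15), ("root", "Ref8", 0.25),
        ("T0", "Target", 0.01),
    ]
    adm = [("T0", "Chibchan", "AmazonianNorth", w)]
    return DriftGraphSpec(nodes=nodes, edges=edges, admixture_events=adm)


def simulate_admixture_cohort_dataset(
        seed: int, w: float = CUNDINAMARCA_CHIBCHAN_W, n_snps: int = 200_000,
        n_target: int = 30, n_source: int = 15, n_ref: int = 10,
        missing_rate: float = 0.10) -> tuple[Dataset, BlockAssignment]:
    """Pseudohaploid cohort for the two-source weight-recovery scenario."""
    spec = admixture_graph(w)
    snp = default_map(n_snps, n_chrom=20, seed=seed)
    panel = simulate_freq_graph(spec, n_snps, seed=seed, snp=snp)
    parts = [sample_pseudohaploid(panel, "Target", n_target, missing_rate, seed)]
    for pop in ["Chibchan", "AmazonianNorth"]:
        parts.append(sample_pseudohaploid(panel, pop, n_source, missing_rate, seed))
    for pop in REFERENCES:
        parts.append(sample_pseudohaploid(panel, pop, n_ref, missing_rate, seed))
    ds = Dataset(np.vstack([p.geno for p in parts]), snp,
                 pd.concat([p.ind for p in parts], ignore_index=True))
    return ds, assign_blocks(ds.snp)


def fit_admixture_weights(ds: Dataset, blocks: BlockAssignment) -> AdmixtureModel:
    return qpadm_fit(ds, "Target", ["Chibchan", "AmazonianNorth"],
                     REFERENCES, blocks)


def simulate_dating_cohort(seed: int, t_gens: int = HERRERA_ADMIX_GENERATIONS,
                           w: float = 0.6, n_snps: int = 100_000,
                           n_ind: int = 100, n_chrom: int = 20,
                           source_f: float = 0.025
                           ) -> tuple[Dataset, np.ndarray]:
    """Mosaic diploid cohort plus decay weights for the dating scenario.

    The two source panels diverge by F = ``source_f`` on each branch
    (Fst ~ 0.05 between them).
    """
    spec = DriftGraphSpec(nodes=["root", "SrcA", "SrcB"],
                          edges=[("root", "SrcA", source_f),
                                 ("root", "SrcB", source_f)])
    snp = default_map(n_snps, n_chrom=n_chrom, seed=seed)
    panel = simulate_freq_graph(spec, n_snps, seed=seed, snp=snp)
    truth = AdmixtureTruth(w=w, t_gens=t_gens, source_a="SrcA", source_b="SrcB")
    ds = simulate_admixed_cohort(panel["SrcA"], panel["SrcB"], truth, snp,
                                 n_ind=n_ind, seed=seed)
    weights = snp_weights(panel["SrcA"], panel["SrcB"])
    return ds, weights


def fit_admixture_date(ds: Dataset, weights: np.ndarray) -> DateFit:
    curve = covariance_curve(ds, weights, binsize=0.001, maxdis=0.20)
    return fit_decay(curve, fit_min=0.005, fit_max=0.20)
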