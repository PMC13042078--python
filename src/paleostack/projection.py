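"""PCA on reference individuals with least-squares projection of ancients.

The basis is fit on complete-data reference individuals only: genotypes are
normalized per SNP by subtracting the mean and dividing by sqrt(p(1-p))
with p the reference allele frequency, and the top-k eigenvectors of the
normalized covariance are extracted.  Low-coverage samples are then placed
by ordinary least squares of their normalized non-missing entries on the
eigenvector rows restricted to those SNPs — the standard remedy for the
shrinkage-toward-zero that plain inner products suffer under missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import Dataset

__all__ = ["PCABasis", "fit_pca", "lsq_project"]


@dataclass
class PCABasis:
    snp_indices: np.ndarray       # columns of the Dataset used (reference-complete)
    means: np.ndarray             # per-SNP genotype mean over references
    norms: np.ndarray             # per-SNP sqrt(p(1-p)) scale
    eigvecs: np.ndarray           # (n_used_snps, k), orthonormal columns
    eigvals: np.ndarray
    ref_scores: np.ndarray        # (n_ref, k)
    ref_ids: list[str]


def fit_pca(ds: Dataset, reference_ids: list[str], k: int) -> PCABasis:
    """Eigenbasis of the normalized reference genotype matrix.

    SNPs with any reference missingness, and SNPs monomorphic in the
    references (normalization undefined), are dropped.  The sign of each
    eigenvector is fixed by making its largest-magnitude entry positive.
    """
    ref = ds.subset_ind(reference_ids)
    if k > ref.n_ind - 1:
        raise ValueError(f"k={k} too large for {ref.n_ind} reference individuals")
    g = ref.geno.astype(float)
    complete = ~(g == 9).any(axis=0)
    p = g[:, complete].mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    used = np.flatnonzero(complete)[poly]
    g = ds.geno[:, used].astype(float)[ds.ind.set_index("id").index.get_indexer(reference_ids)]
    means = g.mean(axis=0)
    norms = np.sqrt(p[poly] * (1 - p[poly]))
    Z = (g - means) / norms
    # eigen-decomposition via SVD of the normalized matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvecs = Vt[:k].T
    eigvals = (s[:k] ** 2) / (len(reference_ids) - 1)
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1
    ref_scores = Z @ eigvecs
    return PCABasis(used, means, norms, eigvecs, eigvals, ref_scores,
                    list(reference_ids))


def lsq_project(basis: PCABasis, genotype_row: np.ndarray) -> np.ndarray:
    """Least-squares PCA coordinates for one (possibly missing-ridden) sample."""
    g = np.asarray(genotype_row, float)[basis.snp_indices]
    obs = g != 9
    k = basis.eigvecs.shape[1]
    if obs.sum() < k:
        raise ValueError(f"only {int(obs.sum())} non-missing SNPs for a k={k} projection")
    z = (g[obs] - basis.means[obs]) / basis.norms[obs]
    V = basis.eigvecs[obs]
    coords, *_ = np.linalg.lstsq(V, z, rcond=None)
    return coords
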