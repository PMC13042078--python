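"""Unbiased f2/f3/f4 estimators for pseudohaploid data with block jackknife.

Per-SNP contributions use haploid allele counts: a pseudohaploid individual
contributes one haploid observation per non-missing site, a diploid
individual two.  With sample frequency p̂ = x/n the sampling-heterozygosity
correction is h = x(n-x)/(n²(n-1)); it debiases squared frequency
differences involving the same sample ("inbreed" mode, the correct mode for
pseudohaploid data) and is skipped where n = 1.

Standard errors come from a weighted delete-one-block jackknife over
contiguous genetic-map blocks (default 5 cM), with block weights equal to
valid SNP counts (Busing's delete-m_j formulas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import BlockAssignment, Dataset

__all__ = [
    "pop_counts", "per_snp_contributions", "jackknife", "JackknifeEstimate",
    "FStatResult", "f_stat", "run_battery",
]


def pop_counts(ds: Dataset, pops: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Haploid alt-allele counts x and haploid sample sizes n per (pop, SNP)."""
    pseudo = ds.is_pseudohaploid()
    groups = ds.ind["group"].to_numpy()
    x = np.zeros((len(pops), ds.n_snp))
    n = np.zeros((len(pops), ds.n_snp))
    ids = ds.ind["id"].to_numpy()
    for k, pop in enumerate(pops):
        idx = np.flatnonzero(groups == pop)
        if idx.size == 0:  # a bare individual id acts as a singleton population
            idx = np.flatnonzero(ids == pop)
        if idx.size == 0:
            raise KeyError(f"unresolvable population label {pop!r}")
        g = ds.geno[idx].astype(np.int64)
        miss = g == 9
        ps = pseudo[idx][:, None]
        # haploid units: pseudohaploid 0/2 -> 0/1 allele of 1; diploid 0/1/2 of 2
        alt = np.where(miss, 0, np.where(ps, g // 2, g))
        tot = np.where(miss, 0, np.where(ps, 1, 2))
        x[k] = alt.sum(axis=0)
        n[k] = tot.sum(axis=0)
    return x, n


def _het_correction(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """h = x(n-x)/(n²(n-1)); zero where n <= 1 (correction skipped)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        h = x * (n - x) / (n ** 2 * (n - 1.0))
    h[n <= 1] = 0.0
    return h


def per_snp_contributions(ds: Dataset, kind: str, pops: list[str],
                          inbreed: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP terms and validity mask for one f-statistic.

    kind: 'f2' (A,B), 'f3' (X;A,B with X first), or 'f4' (A,B;C,D).
    The mask is per-statistic: a SNP is valid when every required population
    has at least one haploid observation ("allsnps" semantics — no global
    intersection across a battery).  With inbreed=False the finite-sample
    corrections are computed from observed heterozygote fractions instead of
    haploid counts (only meaningful for diploid samples).
    """
    arity = {"f2": 2, "f3": 3, "f4": 4}
    if kind not in arity:
        raise ValueError(f"unknown statistic kind {kind!r}")
    if len(pops) != arity[kind]:
        raise ValueError(f"{kind} takes {arity[kind]} populations, got {len(pops)}")
    x, n = pop_counts(ds, pops)
    mask = (n > 0).all(axis=0)
    if not mask.any():
        raise ValueError("no SNP has data in every required population")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, x / np.maximum(n, 1), np.nan)

    if inbreed:
        h = _het_correction(x, n)
    else:
        h = _observed_het_correction(ds, pops)

    if kind == "f4":
        terms = (p[0] - p[1]) * (p[2] - p[3])
    elif kind == "f3":
        terms = (p[0] - p[1]) * (p[0] - p[2]) - h[0]
    else:  # f2
        terms = (p[0] - p[1]) ** 2 - h[0] - h[1]
    terms = np.where(mask, terms, 0.0)
    return terms, mask


def _observed_het_correction(ds: Dataset, pops: list[str]) -> np.ndarray:
    """Correction from observed heterozygote fractions (diploid, outbred samples)."""
    groups = ds.ind["group"].to_numpy()
    out = np.zeros((len(pops), ds.n_snp))
    for k, pop in enumerate(pops):
        idx = np.flatnonzero(groups == pop)
        g = ds.geno[idx]
        nonmiss = (g != 9).sum(axis=0)
        het = (g == 1).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[k] = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), 0.0) / (
                4.0 * np.maximum(nonmiss, 1))
    return out


@dataclass
class JackknifeEstimate:
    """Weighted delete-one-block jackknife summary of a per-SNP statistic."""

    estimate: float
    loo: np.ndarray        # leave-one-out estimates, one per non-empty block
    weights: np.ndarray    # valid-SNP counts per non-empty block
    se: float

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.inf * np.sign(self.estimate)


def jackknife(values: np.ndarray, mask: np.ndarray,
              blocks: BlockAssignment) -> JackknifeEstimate:
    """Point estimate and weighted block-jackknife SE of a per-SNP statistic.

    The point estimate is the mean of ``values`` over valid SNPs; the SE uses
    Busing's delete-m_j weighted jackknife with block weights m_j = valid SNP
    counts.
    """
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    bi = blocks.block_index
    nb = blocks.n_blocks
    w = np.bincount(bi, weights=mask.astype(float), minlength=nb)
    s = np.bincount(bi, weights=np.where(mask, values, 0.0), minlength=nb)
    nonempty = w > 0
    if nonempty.sum() < 2:
        raise ValueError("need at least 2 non-empty blocks for the jackknife")
    w, s = w[nonempty], s[nonempty]
    W = w.sum()
    theta = s.sum() / W
    loo = (s.sum() - s) / (W - w)          # delete-one-block estimates
    g = len(w)
    h = W / w                               # Busing h_j
    # Busing et al. (1999) delete-m_j jackknife variance
    theta_j = g * theta - np.sum((1.0 - w / W) * loo)
    tau = h * theta - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return JackknifeEstimate(theta, loo, w, float(np.sqrt(max(var, 0.0))))


@dataclass
class FStatResult:
    kind: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        """|Z| > 3, the conventional cutoff for calling an f4 asymmetry real."""
        return abs(self.z) > 3.0


def f_stat(ds: Dataset, kind: str, pops: list[str], blocks: BlockAssignment,
           inbreed: bool = True) -> FStatResult:
    terms, mask = per_snp_contributions(ds, kind, pops, inbreed=inbreed)
    jk = jackknife(terms, mask, blocks)
    return FStatResult(kind, tuple(pops), jk.estimate, jk.se, jk.z,
                       int(mask.sum()), len(jk.weights))


def run_battery(ds: Dataset, spec: list[tuple[str, list[str]]],
                blocks: BlockAssignment, inbreed: bool = True) -> pd.DataFrame:
    """One row per configured statistic (kind, pops); flags |Z| > 3."""
    rows = []
    for kind, pops in spec:
        r = f_stat(ds, kind, pops, blocks, inbreed=inbreed)
        rows.append((r.kind, ",".join(r.pops), r.estimate, r.se, r.z,
                     r.n_snps, r.n_blocks, r.significant))
    return pd.DataFrame(rows, columns=["kind", "pops", "est", "se", "z",
                                       "nsnps", "nblocks", "significant"])
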