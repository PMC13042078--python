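"""Runs of homozygosity and effective population size.

ROH segments in an individual arise where its two chromosomes coalesce t
generations back: the segment length is approximately exponential with rate
2t per Morgan, and under a constant population of 2Ne haploid genomes the
coalescence time is geometric with success probability 1/2Ne.  The expected
number of segments with length in (l1, l2) Morgans over a genome of total
map length L is

    E[count] = sum_t P(T=t) * integral_{l1}^{l2} 4 t^2 L exp(-2 t l) dl
             = sum_t P(T=t) * 2 t L [exp(-2 t l1) - exp(-2 t l2)],

truncated at t_max generations.  Observed per-individual counts in length
bins are modelled as independent Poisson draws with these means; 2Ne is
estimated by maximum composite likelihood over a log grid with a golden-
section refinement, the 95% CI from the likelihood profile (drop of 1.92),
and the reported Ne is 2Ne / 2.

The segment caller here is a windowed heterozygosity scan intended for the
synthetic diploid genomes produced by the simulator; it is not a
haplotype-copying HMM and is not meant for sparse real aDNA data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import Dataset

__all__ = [
    "call_roh", "summarize_roh", "ROHProfile", "expected_roh_counts",
    "segment_density", "fit_ne", "NeFit", "DEFAULT_BINS_CM",
]

T_MAX = 3000
#: length-class bin edges in cM used by the Ne likelihood
DEFAULT_BINS_CM = np.array([4.0, 8.0, 12.0, 20.0, 300.0])
#: length classes reported in per-individual summaries (lower bounds, cM)
SUMMARY_CLASSES_CM = (4.0, 8.0, 12.0, 20.0)
#: an individual with more than this much ROH > 20 cM (in cM) is flagged as
#: the product of a close-kin union and excluded from Ne fitting
CLOSE_KIN_SUM_CM = 50.0
#: minimum SNPs covered for ROH-based analyses
MIN_SNPS_COVERED = 300_000


def call_roh(genotypes: np.ndarray, snp: pd.DataFrame, window_snps: int = 50,
             max_het: int = 1, min_cm: float = 4.0) -> pd.DataFrame:
    """Windowed ROH caller for one diploid genotype row.

    Non-overlapping windows of ``window_snps`` SNPs with at most ``max_het``
    heterozygous calls are marked; adjacent marked windows merge; each merged
    run's boundaries are then refined SNP-by-SNP outward to the nearest
    heterozygous call (window grids shave segment ends by up to a window,
    which would systematically push short segments below ``min_cm``); runs
    shorter than ``min_cm`` are discarded.  Returns a segment table with
    chromosome, start/end (Morgans) and length (cM).  A fully homozygous
    genome yields one segment per chromosome (callers should treat that as
    degenerate input).
    """
    g = np.asarray(genotypes)
    if g.ndim != 1 or g.size != len(snp):
        raise ValueError("genotype row does not match SNP table")
    if (g == 9).all():
        return pd.DataFrame(columns=["chrom", "start", "end", "length_cm"])
    chrom = snp["chrom"].to_numpy()
    gpos = snp["gpos"].to_numpy(float)
    segs = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        gc, xc = g[idx], gpos[idx]
        n_win = len(idx) // window_snps
        if n_win == 0:
            continue
        het = (gc[: n_win * window_snps] == 1).reshape(n_win, window_snps).sum(axis=1)
        marked = het <= max_het
        het_pos = np.flatnonzero(gc == 1)
        # background het rate from unmarked windows; sets the expected
        # overshoot (1-h)/h SNPs of the extend-to-next-het refinement
        n_un = (~marked).sum()
        if n_un > 0:
            h_bg = het[~marked].sum() / (n_un * window_snps)
            shrink = int(round((1.0 - h_bg) / h_bg)) if h_bg > 0 else 0
        else:
            shrink = 0
        # merge adjacent marked windows into runs, then refine boundaries
        start = None
        for w in range(n_win + 1):
            if w < n_win and marked[w]:
                if start is None:
                    start = w
            elif start is not None:
                a = start * window_snps
                b = min(w * window_snps, len(idx)) - 1
                # extend to the nearest flanking heterozygote (exclusive),
                # then pull back by the expected geometric overshoot
                kl = np.searchsorted(het_pos, a) - 1
                if kl < 0:
                    a = 0
                else:
                    a = min(het_pos[kl] + 1 + shrink, a)
                kr = np.searchsorted(het_pos, b, side="right")
                if kr >= het_pos.size:
                    b = len(idx) - 1
                else:
                    b = max(het_pos[kr] - 1 - shrink, b)
                lo, hi = xc[a], xc[b]
                if (hi - lo) * 100.0 >= min_cm:
                    segs.append((c, lo, hi, (hi - lo) * 100.0))
                start = None
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "length_cm"])


@dataclass
class ROHProfile:
    """Per-individual ROH summary: class sums (cM) and eligibility flags."""

    ind: str
    segments: pd.DataFrame
    class_sums: dict[float, float] = field(init=False)
    close_kin: bool = field(init=False)
    eligible: bool = True            # meets the SNP-coverage gate

    def __post_init__(self) -> None:
        lens = self.segments["length_cm"].to_numpy(float) if len(self.segments) else np.zeros(0)
        self.class_sums = {c: float(lens[lens > c].sum()) for c in SUMMARY_CLASSES_CM}
        self.close_kin = self.class_sums[20.0] > CLOSE_KIN_SUM_CM

    def bin_counts(self, edges_cm: np.ndarray = DEFAULT_BINS_CM) -> np.ndarray:
        lens = self.segments["length_cm"].to_numpy(float) if len(self.segments) else np.zeros(0)
        return np.histogram(lens, bins=edges_cm)[0]


def summarize_roh(ind: str, segments: pd.DataFrame,
                  snps_covered: int | None = None,
                  min_snps_covered: int = MIN_SNPS_COVERED) -> ROHProfile:
    """Class sums, close-kin flag, and the SNP-coverage eligibility gate."""
    prof = ROHProfile(ind, segments)
    if snps_covered is not None and snps_covered < min_snps_covered:
        prof.eligible = False
    return prof


# ---------------------------------------------------------------------------
# The geometric-coalescent segment model
# ---------------------------------------------------------------------------

def _geom_pmf(two_ne: float, t: np.ndarray) -> np.ndarray:
    q = 1.0 / two_ne
    return q * (1.0 - q) ** (t - 1.0)


def expected_roh_counts(two_ne: float, genome_morgans: float,
                        bins_cm: np.ndarray, t_max: int = T_MAX) -> np.ndarray:
    """Expected ROH count per length bin for one individual.

    bins_cm are ordered bin edges in cM; returns len(bins_cm)-1 expectations.
    """
    if two_ne <= 2:
        raise ValueError("two_ne must be > 2")
    bins_cm = np.asarray(bins_cm, float)
    if np.any(np.diff(bins_cm) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    t = np.arange(1, t_max + 1, dtype=float)
    pt = _geom_pmf(two_ne, t)
    l_edges = bins_cm / 100.0                       # Morgans
    # closed form: integral of 4 t^2 L e^{-2tl} over (l1, l2) = 2 t L (e^{-2t l1} - e^{-2t l2})
    ex = np.exp(-2.0 * np.outer(t, l_edges))        # (t, edges)
    per_t = 2.0 * t[:, None] * genome_morgans * (ex[:, :-1] - ex[:, 1:])
    return pt @ per_t


def segment_density(two_ne: float, lengths_morgans: np.ndarray,
                    t_max: int = T_MAX) -> np.ndarray:
    """Unnormalized density of segment length (per Morgan) under the model."""
    t = np.arange(1, t_max + 1, dtype=float)
    pt = _geom_pmf(two_ne, t)
    l = np.asarray(lengths_morgans, float)
    return (pt[:, None] * 4.0 * t[:, None] ** 2 * np.exp(-2.0 * np.outer(t, l))).sum(axis=0)


@dataclass
class NeFit:
    grid_two_ne: np.ndarray
    loglik: np.ndarray
    two_ne_mle: float
    ci_two_ne: tuple[float, float | None]
    n_individuals: int

    @property
    def ne(self) -> float:
        return self.two_ne_mle / 2.0

    @property
    def ci_ne(self) -> tuple[float, float | None]:
        lo, hi = self.ci_two_ne
        return lo / 2.0, (hi / 2.0 if hi is not None else None)


def fit_ne(profiles: list[ROHProfile], genome_morgans: float,
           bins_cm: np.ndarray = DEFAULT_BINS_CM,
           grid: tuple[float, float, int] = (20.0, 20000.0, 400)) -> NeFit:
    """Composite Poisson likelihood fit of 2Ne from ROH length-bin counts.

    Close-kin-flagged and coverage-ineligible individuals are excluded.  The
    MLE maximizes the summed Poisson log-likelihood over a log-spaced 2Ne
    grid with golden-section refinement; the 95% CI is the likelihood-profile
    set {2Ne : logL >= logL_max - 1.92}.  With zero observed segments the
    upper CI bound is unbounded (None).
    """
    from scipy.optimize import minimize_scalar
    from scipy.stats import poisson

    use = [p for p in profiles if p.eligible and not p.close_kin]
    if not use:
        raise ValueError("no eligible individuals for the Ne fit")
    counts = np.array([p.bin_counts(bins_cm) for p in use])  # (n_ind, n_bins)
    tot = counts.sum(axis=0)
    n = len(use)

    def negll(log_two_ne: float) -> float:
        lam = expected_roh_counts(np.exp(log_two_ne), genome_morgans, bins_cm)
        lam = np.maximum(lam, 1e-300)
        # n individuals with identical expectations: Poisson(n * lam) on totals
        return -float(np.sum(poisson.logpmf(tot, n * lam)))

    lo, hi, npts = grid
    g = np.exp(np.linspace(np.log(lo), np.log(hi), int(npts)))
    ll = np.array([-negll(np.log(v)) for v in g])
    k = int(np.argmax(ll))
    a = np.log(g[max(k - 1, 0)])
    b = np.log(g[min(k + 1, len(g) - 1)])
    res = minimize_scalar(negll, bounds=(a, b), method="bounded")
    two_ne_mle = float(np.exp(res.x))
    ll_max = -float(res.fun)

    inside = ll >= ll_max - 1.92
    ci_lo = float(g[inside][0]) if inside.any() else two_ne_mle
    if tot.sum() == 0 or inside[-1]:
        ci_hi: float | None = None                   # open interval
    else:
        ci_hi = float(g[inside][-1]) if inside.any() else two_ne_mle
    return NeFit(g, ll, two_ne_mle, (ci_lo, ci_hi), n)
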