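"""Admixture dating from the decay of weighted ancestry covariance.

After an admixture pulse t generations ago, the covariance between
ancestry-informative alleles at two loci separated by d Morgans decays as
exp(-t*d).  The statistic binned here is, for every intra-chromosome SNP
pair (i, j) with distance d <= maxdis,

    weight_i * weight_j * cov_across_individuals(residual_i, residual_j)

with weight_i the signed source frequency difference a_i - b_i and
residual = genotype - 2 * pooled sample frequency.  Pairs accumulate into
distance bins of width ``binsize``; the binned curve is fit with
y(d) = A * exp(-t * d) + c and t converted to years with a configurable
generation time.  Uncertainty comes from a delete-one-chromosome jackknife
weighted by pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import curve_fit

from .genio import Dataset

__all__ = ["DecayCurve", "DateFit", "snp_weights", "covariance_curve", "fit_decay",
           "GENERATION_YEARS"]

#: default generation time, years
GENERATION_YEARS = 28.9


def snp_weights(freq_a: np.ndarray, freq_b: np.ndarray) -> np.ndarray:
    """Signed source frequency differences a - b; NaN where both missing."""
    freq_a = np.asarray(freq_a, float)
    freq_b = np.asarray(freq_b, float)
    if freq_a.shape != freq_b.shape:
        raise ValueError("source frequency vectors must share the SNP set")
    w = freq_a - freq_b
    if np.isnan(w).all():
        raise ValueError("no SNP with data in both sources")
    return w


@dataclass
class DecayCurve:
    midpoints: np.ndarray           # bin midpoints, Morgans
    values: np.ndarray              # per-bin weighted covariance
    counts: np.ndarray              # per-bin pair counts
    chrom_sums: np.ndarray          # (n_chrom, n_bins) per-chromosome numerators
    chrom_counts: np.ndarray        # (n_chrom, n_bins)
    chromosomes: list
    binsize: float
    maxdis: float


@njit(cache=True, fastmath=True)
def _accumulate_pairs(gpos, wts, C, start, stop, jmax, binsize, maxdis,
                      n_bins, sums, counts):
    """Accumulate pairs (i, j) with start <= i < stop, i < j < jmax.

    C holds the pair covariances for rows [start, stop) x columns [start, jmax).
    """
    for i in range(start, stop):
        wi = wts[i]
        if wi == 0.0 or not np.isfinite(wi):
            continue
        for j in range(i + 1, jmax):
            d = gpos[j] - gpos[i]
            if d > maxdis:
                break
            wj = wts[j]
            if wj == 0.0 or not np.isfinite(wj):
                continue
            # bin ceil(d/binsize); zero-distance pairs go to the first bin
            b = int(np.ceil(d / binsize)) - 1
            if b < 0:
                b = 0
            if b >= n_bins:
                continue
            sums[b] += wi * wj * C[i - start, j - start]
            counts[b] += 1.0


def covariance_curve(ds: Dataset, weights: np.ndarray, binsize: float = 0.001,
                     maxdis: float = 0.20, block_snps: int = 4096) -> DecayCurve:
    """Binned weighted ancestry-covariance versus genetic distance.

    The across-individual covariance for every SNP pair is computed per
    chromosome as a blocked matrix product of mean-centred residual rows,
    then pairs are binned exactly by distance.  Missing genotypes (code 9)
    are mean-imputed for the residual product, which leaves the expected
    covariance unchanged.
    """
    if ds.n_ind < 2:
        raise ValueError("ancestry covariance needs at least 2 individuals")
    weights = np.asarray(weights, float)
    n_bins = int(round(maxdis / binsize))
    chroms = list(pd.unique(ds.snp["chrom"]))
    chrom_sums = np.zeros((len(chroms), n_bins))
    chrom_counts = np.zeros((len(chroms), n_bins))

    chrom_arr = ds.snp["chrom"].to_numpy()
    gpos_all = ds.snp["gpos"].to_numpy(float)
    for ci, c in enumerate(chroms):
        idx = np.flatnonzero(chrom_arr == c)
        g = ds.geno[:, idx].astype(float)
        miss = g == 9
        g[miss] = np.nan
        p = np.nanmean(g, axis=0) / 2.0             # pooled sample frequency
        resid = g - 2.0 * p[None, :]
        resid[miss] = 0.0                           # mean imputation
        nonmiss = (~miss).sum(axis=0).astype(float)
        wts = np.where(np.isfinite(weights[idx]) & (nonmiss > 1), weights[idx], 0.0)
        gpos = gpos_all[idx]
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        # blocked pair covariance: C[i, j] = sum_k resid_ki resid_kj / (n-1)
        R = np.ascontiguousarray(resid.T)           # (n_snp_c, n_ind)
        denom = ds.n_ind - 1.0
        n_c = R.shape[0]
        for start in range(0, n_c, block_snps):
            stop = min(start + block_snps, n_c)
            jmax = int(np.searchsorted(gpos, gpos[stop - 1] + maxdis, side="right"))
            Cblk = (R[start:stop] @ R[start:jmax].T) / denom
            _accumulate_pairs(gpos, wts, Cblk, start, stop, jmax,
                              binsize, maxdis, n_bins, sums, counts)
        chrom_sums[ci] = sums
        chrom_counts[ci] = counts

    tot_sum = chrom_sums.sum(axis=0)
    tot_cnt = chrom_counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(tot_cnt > 0, tot_sum / np.maximum(tot_cnt, 1), np.nan)
    mids = (np.arange(n_bins) + 0.5) * binsize
    return DecayCurve(mids, values, tot_cnt, chrom_sums, chrom_counts,
                      chroms, binsize, maxdis)


@dataclass
class DateFit:
    amplitude: float
    t_gens: float
    offset: float
    se: float
    fit_min: float
    fit_max: float
    generation_years: float = GENERATION_YEARS
    converged: bool = True
    loo_t: np.ndarray | None = None

    @property
    def z(self) -> float:
        return self.t_gens / self.se if self.se > 0 else np.inf

    @property
    def years(self) -> float:
        return self.t_gens * self.generation_years

    @property
    def years_se(self) -> float:
        return self.se * self.generation_years


def _fit_exp(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Least-squares fit of y = A exp(-t d) + c; returns (A, t, c, converged)."""
    c0 = float(np.mean(y[-max(3, len(y) // 10):]))
    a0 = float(y[0] - c0)
    span = d[-1] - d[0]
    # initial slope from the log-linear regression of the positive part
    pos = (y - c0) > 0
    if pos.sum() >= 3 and a0 > 0:
        sl = np.polyfit(d[pos], np.log(y[pos] - c0 + 1e-300), 1)[0]
        t0 = max(1.0, -sl)
    else:
        t0 = 2.0 / max(span, 1e-9)
    try:
        popt, _ = curve_fit(lambda x, A, t, c: A * np.exp(-t * x) + c, d, y,
                            p0=[a0 if a0 != 0 else 1e-6, t0, c0], maxfev=20000)
        return float(popt[0]), float(popt[1]), float(popt[2]), True
    except RuntimeError:
        return a0, t0, c0, False


def fit_decay(curve: DecayCurve, fit_min: float = 0.005, fit_max: float = 0.20,
              generation_years: float = GENERATION_YEARS) -> DateFit:
    """Exponential fit of the decay curve with delete-one-chromosome jackknife.

    Bins with midpoints in [fit_min, fit_max] enter the fit.  An essentially
    flat curve returns a "no signal" fit (A ~ 0) rather than raising.  The
    jackknife refits the curve with each chromosome's pair contributions
    removed and weights chromosomes by their pair counts.
    """
    sel = (curve.midpoints >= fit_min) & (curve.midpoints <= fit_max) & \
          np.isfinite(curve.values) & (curve.counts > 0)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 usable bins in the fit range")
    d = curve.midpoints[sel]
    y = curve.values[sel]

    scale = float(np.nanmax(np.abs(y)))
    if scale == 0 or not np.isfinite(scale):
        return DateFit(0.0, 0.0, 0.0, np.nan, fit_min, fit_max,
                       generation_years, converged=False)
    A, t, c, ok = _fit_exp(d, y)

    # delete-one-chromosome jackknife on t
    nch = len(curve.chromosomes)
    loo_t = np.full(nch, np.nan)
    bw = curve.chrom_counts.sum(axis=1)
    tot_sum = curve.chrom_sums.sum(axis=0)
    tot_cnt = curve.chrom_counts.sum(axis=0)
    for k in range(nch):
        s = tot_sum - curve.chrom_sums[k]
        n = tot_cnt - curve.chrom_counts[k]
        with np.errstate(invalid="ignore", divide="ignore"):
            yk = np.where(n > 0, s / np.maximum(n, 1), np.nan)[sel]
        good = np.isfinite(yk)
        if good.sum() < 10:
            continue
        _, loo_t[k], _, _ = _fit_exp(d[good], yk[good])
    good = np.isfinite(loo_t) & (bw > 0)
    if good.sum() >= 2:
        w = bw[good]
        loo = loo_t[good]
        W = w.sum()
        g = good.sum()
        h = W / w
        theta_j = g * t - np.sum((1 - 1 / h) * loo)
        tau = h * t - (h - 1) * loo
        se = float(np.sqrt(max(np.sum((tau - theta_j) ** 2 / (h - 1)) / g, 0.0)))
    else:
        se = np.nan
    return DateFit(A, t, c, se, fit_min, fit_max, generation_years,
                   converged=ok, loo_t=loo_t)
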