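"""Pairwise kinship from pseudohaploid mismatch rates.

For two pseudohaploid individuals the mismatch rate pmr (fraction of
disagreeing sites among jointly covered sites) decreases linearly with
relatedness: an unrelated pair has pmr = b (the population baseline), a
same-individual/twin pair b/2, a parent-offspring or sibling pair 3b/4, and
in general pmr = b (1 - r/2) where r is the expected genome-shared fraction.
Inverting, r_hat = 2 (1 - pmr / b), and degree classes are cut at the
midpoints of the expected r values 1, 1/2, 1/4, 1/8, 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fstats import jackknife
from .genio import BlockAssignment

__all__ = ["KinshipEstimate", "pairwise_mismatch", "classify_pair", "baseline_pmr"]

#: class boundaries on r_hat: midpoints of expected r in {1, .5, .25, .125, 0}
DEGREE_BOUNDS = [(0.75, "identical"), (0.375, "1st"), (0.1875, "2nd"),
                 (0.0625, "3rd"), (-np.inf, "unrelated")]
MIN_OVERLAP = 3000


@dataclass
class KinshipEstimate:
    id_a: str
    id_b: str
    pmr: float
    overlap: int
    se: float
    baseline: float | None = None
    r_hat: float | None = None
    degree: str | None = None


def pairwise_mismatch(g1: np.ndarray, g2: np.ndarray,
                      blocks: BlockAssignment) -> tuple[float, int, float]:
    """Mismatch rate between two pseudohaploid rows with block-jackknife SE.

    Returns (pmr, overlap, se); raises on zero overlap.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    for g in (g1, g2):
        if not np.isin(g, [0, 2, 9]).all():
            raise ValueError("rows must be pseudohaploid (codes {0,2,9})")
    both = (g1 != 9) & (g2 != 9)
    overlap = int(both.sum())
    if overlap == 0:
        raise ValueError("zero overlapping SNPs; pair excluded")
    mismatch = both & (g1 != g2)
    jk = jackknife(mismatch.astype(float), both, blocks)
    return jk.estimate, overlap, jk.se


def baseline_pmr(pmrs: list[float], overlaps: list[int],
                 min_overlap: int = 10_000) -> float:
    """Baseline b: median pmr of (within-group) pairs with enough overlap."""
    vals = [p for p, o in zip(pmrs, overlaps) if o >= min_overlap]
    if not vals:
        raise ValueError("no pair with sufficient overlap for the baseline")
    return float(np.median(vals))


def classify_pair(est: KinshipEstimate, baseline: float,
                  min_overlap: int = MIN_OVERLAP) -> KinshipEstimate:
    """Attach r_hat = 2(1 - pmr/b) and a degree class to a mismatch estimate.

    "insufficient" when the overlap is too small or when the +-1 SE interval
    of r_hat straddles a class boundary.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    est.baseline = baseline
    r = 2.0 * (1.0 - est.pmr / baseline)
    est.r_hat = r
    if est.overlap < min_overlap:
        est.degree = "insufficient"
        return est
    r_se = 2.0 * est.se / baseline
    lo_cls = _degree_of(r - r_se)
    hi_cls = _degree_of(r + r_se)
    est.degree = _degree_of(r) if lo_cls == hi_cls else "insufficient"
    return est


def _degree_of(r: float) -> str:
    for bound, name in DEGREE_BOUNDS:
        if r >= bound:
            return name
    return "unrelated"
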