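"""Radiocarbon combination and calibration.

Replicate measurements of the same event are pooled with the inverse-
variance-weighted mean; their consistency is judged by the Ward-Wilson
chi-square statistic T = sum((x_i - pooled)/sigma_i)^2 with n-1 degrees of
freedom.  Calibration places a Normal likelihood for the measured age over
a 1-year calendar grid through the calibration curve mean mu(theta) with
variance sigma_m^2 + sigma_curve(theta)^2, normalizes, and reports the
95.4% highest-posterior-density set as maximal contiguous calBP intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["C14Measurement", "CalCurve", "read_14c", "ward_wilson_combine",
           "calibrate", "calbp_to_calendar", "format_calendar"]


@dataclass
class C14Measurement:
    lab_code: str
    age_bp: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("measurement error must be positive")


@dataclass
class CalCurve:
    """Calibration curve on a calendar grid (cal BP): mean and 1-sigma."""

    cal_bp: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        d = np.diff(self.cal_bp)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("calendar grid must be strictly monotone")
        if (self.sigma < 0).any():
            raise ValueError("curve sigma must be non-negative")
        if self.cal_bp[0] > self.cal_bp[-1]:       # store ascending
            self.cal_bp = self.cal_bp[::-1].copy()
            self.mu = self.mu[::-1].copy()
            self.sigma = self.sigma[::-1].copy()


def read_14c(path: str | Path) -> CalCurve:
    """Read a standard .14c curve file (comment lines '#'; comma or whitespace
    separated columns: cal BP, 14C age BP, 1-sigma; extra columns ignored)."""
    cal, mu, sig = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            cal.append(float(parts[0]))
            mu.append(float(parts[1]))
            sig.append(float(parts[2]))
    return CalCurve(np.array(cal), np.array(mu), np.array(sig))


def ward_wilson_combine(measurements: list[C14Measurement]
                        ) -> tuple[float, float, float, int, bool]:
    """Pool replicate measurements; returns (pooled, pooled_sigma, T, df, consistent).

    consistent is True when T is below the upper 5% chi-square critical value.
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 measurements to combine")
    x = np.array([m.age_bp for m in measurements], float)
    s = np.array([m.sigma for m in measurements], float)
    w = 1.0 / s ** 2
    pooled = float(np.sum(w * x) / np.sum(w))
    pooled_sigma = float(np.sum(w) ** -0.5)
    T = float(np.sum(((x - pooled) / s) ** 2))
    df = len(measurements) - 1
    crit = float(stats.chi2.ppf(0.95, df))
    return pooled, pooled_sigma, T, df, T < crit


def calibrate(m: C14Measurement, curve: CalCurve, level: float = 0.954
              ) -> tuple[list[tuple[int, int]], float]:
    """Calibrate a measurement; returns (HPD intervals in calBP, total mass).

    The posterior is computed on a 1-year grid spanning the curve (linear
    interpolation between curve knots); intervals are (older, younger) calBP
    pairs, sorted oldest first, whose total mass is the smallest set of grid
    years reaching ``level``.
    """
    lo, hi = float(curve.cal_bp[0]), float(curve.cal_bp[-1])
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    mu = np.interp(grid, curve.cal_bp, curve.mu)
    sig = np.interp(grid, curve.cal_bp, curve.sigma)
    var = m.sigma ** 2 + sig ** 2
    dens = np.exp(-0.5 * (m.age_bp - mu) ** 2 / var) / np.sqrt(var)
    total = dens.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("measurement lies outside the calibration curve support")
    post = dens / total
    # guard: mass piling at the grid edge means the curve does not cover the age
    if post[0] > 1e-4 or post[-1] > 1e-4:
        raise ValueError("measurement is at the edge of the calibration curve span")
    order = np.argsort(post)[::-1]
    csum = np.cumsum(post[order])
    k = int(np.searchsorted(csum, level)) + 1
    members = np.zeros(post.size, dtype=bool)
    members[order[:k]] = True
    mass = float(post[members].sum())
    # contiguous runs -> (older, younger) intervals
    intervals = []
    idx = np.flatnonzero(members)
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((int(grid[prev]), int(grid[start])))
            start = i
        prev = i
    intervals.append((int(grid[prev]), int(grid[start])))
    intervals.sort(reverse=True)      # oldest first
    return intervals, mass


def calbp_to_calendar(cal_bp: int) -> tuple[int, str]:
    """Convert calBP to a calendar year with era tag (no year zero)."""
    year = 1950 - int(cal_bp)
    if year > 0:
        return year, "CE"
    return 1 - year, "BCE"            # e.g. calBP 1950 -> 1 BCE


def format_calendar(interval: tuple[int, int]) -> str:
    older, younger = interval
    (y1, e1), (y2, e2) = calbp_to_calendar(older), calbp_to_calendar(younger)
    if e1 == e2:
        return f"{y1}–{y2} cal{e1}"
    return f"{y1} cal{e1}–{y2} cal{e2}"
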