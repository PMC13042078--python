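"""Adaptive pseudohaploid calling with an empirical aDNA error model, plus QC.

The caller estimates substitution error rates empirically from reads at sites
known to be monomorphic, stratified by library, substitution pair, read
position (terminal = within 10 bp of either read end, else central), strand,
and mapping/base-quality bins.  Because the two directions of a substitution
pair can have very different rates (C->T deamination damage vs T->C), read
reliability uses the symmetric score S = max[E(a->b), E(b->a)] for the site's
allele pair; reads in strata with S at or above the threshold (default 0.02)
are excluded, and one base is drawn uniformly at random from the surviving
pileup.  The achieved per-base error is therefore bounded above by the
threshold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import PileupSet

__all__ = [
    "ErrorModel", "fit_error_model", "reliability_S", "call_site",
    "call_dataset", "library_metrics", "apply_qc", "qc_failures", "QC_THRESHOLDS",
]

#: quality bin edges (MQ and BQ): bin 0 = quality < 30, bin 1 = quality >= 30
QUALITY_BIN_EDGE = 30


def stratum_key(lib: str, pair: tuple[str, str], position: str, strand: str,
                mq_bin: int, bq_bin: int) -> tuple:
    return (lib, pair, position, strand, int(mq_bin), int(bq_bin))


@dataclass
class ErrorModel:
    """Per-stratum substitution error estimates.

    rates maps (lib, (a, b), position, strand, mq_bin, bq_bin) -> (rate, count)
    where (a, b) is the *ordered* substitution a->b.  Strata never observed
    fall back to ``prior`` with count 0 — unseen strata are not certified as
    reliable.
    """

    rates: dict[tuple, tuple[float, int]] = field(default_factory=dict)
    prior: float = 0.001

    def rate(self, key: tuple) -> float:
        return self.rates.get(key, (self.prior, 0))[0]

    def count(self, key: tuple) -> int:
        return self.rates.get(key, (self.prior, 0))[1]


def fit_error_model(pileups: PileupSet, prior: float = 0.001) -> ErrorModel:
    """Estimate stratified error rates from reads at monomorphic-flagged sites.

    For each stratum and ordered pair (true base a -> observed b), the rate is
    the fraction of reads at monomorphic sites whose true base is a that were
    read as b.
    """
    sites = pileups.sites
    mono = sites[sites["monomorphic"]]
    if mono.empty:
        raise ValueError("no monomorphic-flagged sites in pileup set")
    reads = pileups.reads.merge(mono[["site_id", "true_base", "ref", "alt"]], on="site_id")
    if reads.empty:
        raise ValueError("no reads at monomorphic sites")

    # the substitution partner at a monomorphic training site is the site's
    # other allele, so E(a -> b) is estimated from {a, b}-type sites whose
    # true base is a — the same quantity the caller queries at an (a, b) SNP
    reads["other"] = np.where(reads["true_base"] == reads["ref"],
                              reads["alt"], reads["ref"])
    model = ErrorModel(prior=prior)
    grouped = reads.groupby(
        ["lib", "true_base", "other", "terminal", "strand", "mq_bin", "bq_bin"],
        sort=False,
    )
    for (lib, tb, ob, pos, strand, mq, bq), grp in grouped:
        total = len(grp)
        n_mis = int((grp["base"] == ob).sum())
        key = stratum_key(lib, (tb, ob), pos, strand, mq, bq)
        model.rates[key] = (n_mis / total, total)
    return model


def reliability_S(model: ErrorModel, allele_pair: tuple[str, str],
                  lib: str, position: str, strand: str, mq_bin: int, bq_bin: int) -> float:
    """Symmetric reliability score S = max of the two directional error rates."""
    a, b = allele_pair
    e_ab = model.rate(stratum_key(lib, (a, b), position, strand, mq_bin, bq_bin))
    e_ba = model.rate(stratum_key(lib, (b, a), position, strand, mq_bin, bq_bin))
    return max(e_ab, e_ba)


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    """Per-site random stream keyed by SNP id, independent of iteration order."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(site_id.encode())])


def call_site(reads: pd.DataFrame, ref: str, alt: str, model: ErrorModel,
              threshold: float = 0.02, seed: int = 0, site_id: str = "") -> int:
    """Pseudohaploid call at one SNP: 0 (ref), 2 (alt) or 9 (no reliable base).

    Reads whose stratum reliability S >= threshold are discarded; bases
    matching neither allele are discarded; one surviving base is drawn
    uniformly at random from a stream keyed by the SNP id.
    """
    if reads is None or len(reads) == 0:
        return 9
    keep = []
    for row in reads.itertuples(index=False):
        if row.base not in (ref, alt):
            continue
        s = reliability_S(model, (ref, alt), row.lib, row.terminal, row.strand,
                          row.mq_bin, row.bq_bin)
        if s < threshold:
            keep.append(row.base)
    if not keep:
        return 9
    rng = _site_rng(seed, site_id or "site")
    base = keep[int(rng.integers(len(keep)))]
    return 0 if base == ref else 2


def call_dataset(pileups: PileupSet, model: ErrorModel, threshold: float = 0.02,
                 seed: int = 0) -> pd.DataFrame:
    """Call every site of a pileup set; returns site_id -> genotype code table."""
    by_site = dict(tuple(pileups.reads.groupby("site_id", sort=False)))
    out = []
    for row in pileups.sites.itertuples(index=False):
        reads = by_site.get(row.site_id)
        code = call_site(reads, row.ref, row.alt, model, threshold, seed, row.site_id)
        out.append((row.site_id, code))
    return pd.DataFrame(out, columns=["site_id", "code"])


def library_metrics(pileups: PileupSet, x_reads: int, y_reads: int
                    ) -> tuple[float, float | None]:
    """Library damage rate and sex ratio.

    damage_rate: terminal C->T mismatch fraction at monomorphic C sites.
    sex_ratio: Y/(X+Y) aligned-read counts; None (undefined) when X+Y = 0.
    """
    sites = pileups.sites
    mono_c = sites[(sites["monomorphic"]) & (sites["true_base"] == "C")
                   & (sites["alt"] == "T")]
    reads = pileups.reads.merge(mono_c[["site_id"]], on="site_id")
    term = reads[reads["terminal"] == "terminal"]
    damage = float((term["base"] == "T").mean()) if len(term) else 0.0
    sex_ratio = None if (x_reads + y_reads) == 0 else y_reads / (x_reads + y_reads)
    return damage, sex_ratio


# ---------------------------------------------------------------------------
# Authenticity / QC filtering
# ---------------------------------------------------------------------------

QC_THRESHOLDS = dict(
    min_snps=15_000,          # fail if snps_covered < 15,000
    min_damage_udg=0.03,      # fail if damage < 3% (UDG-treated)
    min_damage_noudg=0.10,    # fail if damage < 10% (non-UDG)
    max_contam_lower=0.01,    # fail if contamination lower bound > 0.01
    min_mt_match=0.90,        # fail if mtDNA consensus match upper bound < 0.90
    sex_ratio_window=(0.05, 0.3),  # fail if strictly between (ambiguous sex)
)

_QC_METRICS = ("snps_covered", "damage_rate", "udg_flag", "contam_lower_bound",
               "mt_match_upper_bound", "sex_ratio")


def qc_failures(row: dict, thresholds: dict = QC_THRESHOLDS) -> list[str]:
    """Reason codes for one individual's metrics; empty list means pass.

    All comparisons are strict, so exact-threshold values pass.
    """
    for m in _QC_METRICS:
        if m not in row or row[m] is None or (isinstance(row[m], float) and np.isnan(row[m])):
            return ["incomplete"]
    reasons = []
    if row["snps_covered"] < thresholds["min_snps"]:
        reasons.append("low_coverage")
    dmg_min = thresholds["min_damage_udg"] if row["udg_flag"] else thresholds["min_damage_noudg"]
    if row["damage_rate"] < dmg_min:
        reasons.append("low_damage")
    if row["contam_lower_bound"] > thresholds["max_contam_lower"]:
        reasons.append("contamination")
    if row["mt_match_upper_bound"] < thresholds["min_mt_match"]:
        reasons.append("mt_mismatch")
    lo, hi = thresholds["sex_ratio_window"]
    if lo < row["sex_ratio"] < hi:
        reasons.append("ambiguous_sex_ratio")
    return reasons


def apply_qc(table: pd.DataFrame,
             relatives: list[tuple[str, str]] | None = None,
             date_excluded: list[str] | None = None,
             thresholds: dict = QC_THRESHOLDS) -> tuple[list[str], pd.DataFrame]:
    """Apply authenticity thresholds, date-based exclusions, and relative pruning.

    relatives: 1st-degree pairs (id_a, id_b); among passers the lower-coverage
    member of each pair is dropped with reason "first_degree_relative" (this
    exclusion applies to grouped analyses only and is distinguished by its
    reason code).

    Returns (passing ids, fail records with all triggered reason codes).
    """
    date_excluded = set(date_excluded or [])
    fail_rows = []
    passed: dict[str, float] = {}
    for _, row in table.iterrows():
        reasons = qc_failures(dict(row), thresholds)
        if row["id"] in date_excluded:
            reasons = reasons + ["date_inconsistent"]
        if reasons:
            fail_rows.append((row["id"], ";".join(reasons)))
        else:
            passed[row["id"]] = row["snps_covered"]
    for a, b in relatives or []:
        if a in passed and b in passed:
            drop = a if passed[a] <= passed[b] else b
            del passed[drop]
            fail_rows.append((drop, "first_degree_relative"))
    fails = pd.DataFrame(fail_rows, columns=["id", "reasons"])
    return list(passed), fails
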