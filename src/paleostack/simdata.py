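"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (pseudohaploid calling, f-statistics,
qpWave/qpAdm, admixture-LD dating, ROH/Ne, kinship, QC filtering) is
exercised on data produced here, so each generator records the truth it
embeds.  All generators are pure functions of (parameters, seed).

Drift is modelled per branch with Balding-Nichols Beta sampling: a child
population's allele frequency given parent frequency p and branch drift F
is Beta(p(1-F)/F, (1-p)(1-F)/F), which preserves the mean and has variance
F p(1-p).  Admixture events mix parental frequencies linearly before any
child drift is applied.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import Dataset, MISSING

__all__ = [
    "DriftGraphSpec",
    "PanelFreqs",
    "AdmixtureTruth",
    "simulate_freq_graph",
    "sample_pseudohaploid",
    "simulate_pileups",
    "simulate_admixed_cohort",
    "simulate_roh_genome",
    "simulate_qc_table",
    "default_map",
]


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child RNG keyed by seed plus string/int keys."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Drift graphs and allele-frequency panels
# ---------------------------------------------------------------------------

@dataclass
class DriftGraphSpec:
    """Admixture-graph specification for allele-frequency simulation.

    edges: (parent, child, F) with drift F strictly in (0, 1).
    admixture_events: (child, parentA, parentB, w) — the child's
        pre-drift frequency is w*pA + (1-w)*pB.  A node appearing as an
        admixture child must not also have a parent edge.
    root_freq_law: (low, high) of the uniform law for root frequencies.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    admixture_events: list[tuple[str, str, str, float]] = field(default_factory=list)
    root_freq_law: tuple[float, float] = (0.05, 0.95)

    def validate(self) -> None:
        parents: dict[str, list] = {n: [] for n in self.nodes}
        for p, c, f in self.edges:
            if not (0.0 < f < 1.0):
                raise ValueError(f"drift F must be in (0,1); edge {p}->{c} has F={f}")
            if p not in parents or c not in parents:
                raise ValueError(f"edge {p}->{c} references unknown node")
            parents[c].append(p)
        for c, a, b, w in self.admixture_events:
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"admixture weight must be in [0,1]; got {w} for {c}")
            for n in (c, a, b):
                if n not in parents:
                    raise ValueError(f"admixture event references unknown node {n}")
            parents[c].append((a, b))
        roots = [n for n in self.nodes if not parents[n]]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root; found {roots}")
        multi = [n for n in self.nodes if len(parents[n]) > 1]
        if multi:
            raise ValueError(f"nodes with more than one incoming edge/event: {multi}")
        # topological order exists iff acyclic
        self.topological_order()

    def topological_order(self) -> list[str]:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for p, c, _ in self.edges:
            children[p].append(c)
            indeg[c] += 1
        for c, a, b, _ in self.admixture_events:
            children[a].append(c)
            children[b].append(c)
            indeg[c] += 2
        order, stack = [], sorted(n for n in self.nodes if indeg[n] == 0)
        while stack:
            n = stack.pop()
            order.append(n)
            for ch in children[n]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    stack.append(ch)
        if len(order) != len(self.nodes):
            raise ValueError("drift graph contains a cycle")
        return order


@dataclass
class PanelFreqs:
    """Per-population allele frequencies (populations x SNPs) plus SNP metadata."""

    freqs: dict[str, np.ndarray]
    snp: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.snp)
        for pop, f in self.freqs.items():
            if f.shape != (n,):
                raise ValueError(f"frequency vector for {pop} has wrong length")
            if (f < 0).any() or (f > 1).any():
                raise ValueError(f"frequencies for {pop} outside [0,1]")

    def __getitem__(self, pop: str) -> np.ndarray:
        try:
            return self.freqs[pop]
        except KeyError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass
class AdmixtureTruth:
    """Ground truth of a simulated admixture pulse."""

    w: float
    t_gens: int
    source_a: str = "A"
    source_b: str = "B"

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("w must be in [0,1]")
        if int(self.t_gens) < 1 or self.t_gens != int(self.t_gens):
            raise ValueError("t_gens must be a positive integer")
        self.t_gens = int(self.t_gens)


def default_map(n_snps: int, n_chrom: int = 20, chrom_morgans: float = 1.0,
                seed: int = 0, monomorphic_frac: float = 0.0) -> pd.DataFrame:
    """SNP metadata table: n_snps sites spread uniformly over n_chrom chromosomes.

    Genetic positions are sorted uniform draws per chromosome (Morgans);
    physical positions are 1-based at 1 Mb per cM.  A ``monomorphic`` flag
    column marks error-training sites.
    """
    rng = _rng(seed, "map")
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    rows = []
    bases = ["A", "C", "G", "T"]
    k = 0
    for c in range(1, n_chrom + 1):
        g = np.sort(rng.uniform(0.0, chrom_morgans, per[c - 1]))
        for x in g:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((f"snp{k}", str(c), float(x), int(round(x * 1e8)) + 1,
                         bases[ref], bases[alt]))
            k += 1
    snp = pd.DataFrame(rows, columns=["id", "chrom", "gpos", "ppos", "ref", "alt"])
    mono = np.zeros(len(snp), dtype=bool)
    if monomorphic_frac > 0:
        mono[rng.random(len(snp)) < monomorphic_frac] = True
    snp["monomorphic"] = mono
    return snp


def simulate_freq_graph(spec: DriftGraphSpec, n_snps: int, seed: int,
                        snp: pd.DataFrame | None = None) -> PanelFreqs:
    """Simulate per-population allele frequencies down a drift/admixture graph."""
    spec.validate()
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if snp is None:
        snp = default_map(n_snps, seed=seed)
    if len(snp) != n_snps:
        raise ValueError("snp table length does not match n_snps")

    edge_by_child = {c: (p, f) for p, c, f in spec.edges}
    adm_by_child = {c: (a, b, w) for c, a, b, w in spec.admixture_events}
    lo, hi = spec.root_freq_law
    freqs: dict[str, np.ndarray] = {}
    for node in spec.topological_order():
        rng = _rng(seed, "freq", node)
        if node in edge_by_child:
            parent, f = edge_by_child[node]
            p = freqs[parent]
            a = np.clip(p, 1e-12, 1 - 1e-12) * (1 - f) / f
            b = np.clip(1 - p, 1e-12, 1 - 1e-12) * (1 - f) / f
            freqs[node] = np.clip(rng.beta(a, b), 0.0, 1.0)
        elif node in adm_by_child:
            a, b, w = adm_by_child[node]
            freqs[node] = w * freqs[a] + (1 - w) * freqs[b]
        else:  # root
            freqs[node] = rng.uniform(lo, hi, n_snps)
    panel = PanelFreqs(freqs, snp.reset_index(drop=True))
    if "monomorphic" in snp.columns:
        mono = snp["monomorphic"].to_numpy(bool)
        for f in panel.freqs.values():
            f[mono] = 0.0  # error-training sites are fixed for the reference base
    return panel


def sample_pseudohaploid(panel: PanelFreqs, pop: str, n_ind: int,
                         missing_rate: float, seed: int,
                         group: str | None = None) -> Dataset:
    """Draw pseudohaploid individuals (codes {0,2,9}) from panel frequencies."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0,1)")
    p = panel[pop]
    rng = _rng(seed, "pseudohap", pop)
    allele = rng.random((n_ind, p.size)) < p[None, :]
    geno = np.where(allele, 2, 0).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    ind = pd.DataFrame({
        "id": [f"{pop}_{i}" for i in range(n_ind)],
        "sex": "U",
        "group": group or pop,
        "pseudohaploid": True,
    })
    return Dataset(geno, panel.snp.copy(), ind)


def sample_diploid(panel: PanelFreqs, pop: str, n_ind: int, seed: int,
                   group: str | None = None) -> Dataset:
    """Draw diploid Hardy-Weinberg individuals (codes {0,1,2}) from panel frequencies."""
    p = panel[pop]
    rng = _rng(seed, "diploid", pop)
    geno = (rng.random((n_ind, p.size)) < p).astype(np.int8)
    geno += (rng.random((n_ind, p.size)) < p).astype(np.int8)
    ind = pd.DataFrame({
        "id": [f"{pop}_{i}" for i in range(n_ind)],
        "sex": "U",
        "group": group or pop,
        "pseudohaploid": False,
    })
    return Dataset(geno, panel.snp.copy(), ind)


# ---------------------------------------------------------------------------
# Pileups with an aDNA damage/error model
# ---------------------------------------------------------------------------

#: stratum key order used throughout: (lib, pair, position, strand, mq_bin, bq_bin)
PILEUP_COLUMNS = ["site_id", "base", "strand", "terminal", "qbin", "lib", "udg"]


@dataclass
class PileupSet:
    """Per-read pileup records plus the site truth they were generated from."""

    reads: pd.DataFrame            # columns PILEUP_COLUMNS (+ mq_bin, bq_bin ints)
    sites: pd.DataFrame            # site_id, ref, alt, true_base, monomorphic

    def to_tsv(self, path) -> None:
        self.reads[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def simulate_pileups(truth: Dataset, depth_mean: float,
                     damage: dict | float, seed: int,
                     individual: int = 0, lib: str = "lib1",
                     udg: bool = True, terminal_frac: float = 0.25) -> PileupSet:
    """Simulate per-read pileups for one individual of ``truth``.

    ``damage`` is either a scalar error rate applied to every stratum or a
    dict mapping (position, strand, mq_bin, bq_bin) -> rate, where position
    is "terminal" or "central", strand is "+"/"-", and the quality bins are
    0 (<30) / 1 (>=30).  Missing keys default to 0.  Errors flip the true
    base to the other allele of the site (ref<->alt), which is the substitution
    class the caller's reliability score is built from.

    Sites flagged ``monomorphic`` in the SNP table have their true base fixed
    to the reference allele regardless of genotype.
    """
    snp = truth.snp
    g = truth.geno[individual]
    rng = _rng(seed, "pileup", lib, individual)
    depth = rng.poisson(depth_mean, truth.n_snp)
    mono = snp["monomorphic"].to_numpy(bool) if "monomorphic" in snp.columns else np.zeros(truth.n_snp, bool)

    site_ids = snp["id"].to_numpy()
    refs = snp["ref"].to_numpy()
    alts = snp["alt"].to_numpy()

    rows = []
    for j in range(truth.n_snp):
        d = int(depth[j])
        if d == 0:
            continue
        if mono[j]:
            true_base = refs[j]
        elif g[j] == MISSING:
            continue
        else:
            # pseudohaploid: 0 -> ref, 2 -> alt; diploid het draws per read
            true_base = None
        strands = np.where(rng.random(d) < 0.5, "+", "-")
        terminal = rng.random(d) < terminal_frac
        mq_bin = (rng.random(d) < 0.7).astype(int)   # 70% of reads MQ>=30
        bq_bin = (rng.random(d) < 0.7).astype(int)
        for r in range(d):
            if true_base is None:
                tb = alts[j] if rng.random() < g[j] / 2.0 else refs[j]
            else:
                tb = true_base
            pos = "terminal" if terminal[r] else "central"
            if isinstance(damage, dict):
                rate = damage.get((pos, strands[r], int(mq_bin[r]), int(bq_bin[r])), 0.0)
            else:
                rate = float(damage)
            base = tb
            if rate > 0 and rng.random() < rate:
                base = alts[j] if tb == refs[j] else refs[j]
            rows.append((site_ids[j], base, strands[r], pos,
                         f"m{mq_bin[r]}b{bq_bin[r]}", lib, "UDG" if udg else "noUDG",
                         int(mq_bin[r]), int(bq_bin[r])))
    reads = pd.DataFrame(rows, columns=PILEUP_COLUMNS + ["mq_bin", "bq_bin"])
    sites = pd.DataFrame({
        "site_id": site_ids, "ref": refs, "alt": alts,
        "true_base": np.where(mono, refs, np.where(g == 2, alts, np.where(g == 0, refs, "N"))),
        "monomorphic": mono,
    })
    return PileupSet(reads, sites)


# ---------------------------------------------------------------------------
# Mosaic admixed chromosomes (ground truth for admixture-LD dating)
# ---------------------------------------------------------------------------

def simulate_admixed_cohort(pA: np.ndarray, pB: np.ndarray, truth: AdmixtureTruth,
                            snp: pd.DataFrame, n_ind: int, seed: int,
                            group: str = "admixed") -> Dataset:
    """Diploid admixed individuals as two independent ancestry-mosaic haplotypes.

    Along each chromosome a haplotype's local ancestry is a two-state Markov
    chain started at Bernoulli(w) (state 1 = source A) with switch points laid
    down as a Poisson process of rate ``t_gens`` per Morgan; at each switch
    point the state is redrawn Bernoulli(w) (the large-t limit of recombining
    against the whole admixed pool).  Alleles are drawn Bernoulli from the
    local ancestry's source frequency; the diploid genotype is the haplotype
    sum.
    """
    if pA.shape != pB.shape or len(snp) != pA.size:
        raise ValueError("source frequency vectors and SNP table must align")
    t = truth.t_gens
    w = truth.w
    rng = _rng(seed, "admixed")
    chrom = snp["chrom"].to_numpy()
    gpos = snp["gpos"].to_numpy(float)
    geno = np.zeros((n_ind, len(snp)), dtype=np.int8)

    chrom_slices = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        chrom_slices.append((idx, gpos[idx]))

    for i in range(n_ind):
        for _hap in range(2):
            for idx, g in chrom_slices:
                L = g[-1] if g.size else 0.0
                n_sw = rng.poisson(t * L)
                cuts = np.sort(rng.uniform(0.0, L, n_sw)) if n_sw else np.empty(0)
                states = rng.random(n_sw + 1) < w        # True = ancestry A
                seg = np.searchsorted(cuts, g, side="right")
                anc = states[seg]
                p = np.where(anc, pA[idx], pB[idx])
                geno[i, idx] += (rng.random(idx.size) < p).astype(np.int8)
    ind = pd.DataFrame({
        "id": [f"{group}_{i}" for i in range(n_ind)],
        "sex": "U", "group": group, "pseudohaploid": False,
    })
    return Dataset(geno, snp.reset_index(drop=True), ind)


# ---------------------------------------------------------------------------
# ROH genomes from the geometric-coalescent segment model
# ---------------------------------------------------------------------------

def simulate_roh_genome(two_ne: float, genome: dict[str, float], het_rate: float,
                        n_ind: int, seed: int, snp_per_morgan: int = 5000,
                        min_cm: float = 2.0, max_retries: int = 200):
    """Diploid genomes whose ROH content follows the geometric-coalescent model.

    Segment counts per length bin are Poisson with the expectations of
    :func:`paleostack.rohne.expected_roh_counts` (the generative twin of the
    Ne likelihood); lengths are drawn from the within-bin density, positions
    uniform without overlap.  Heterozygous sites occur at ``het_rate`` per SNP
    outside ROH and never inside.  Returns (Dataset, true_segments DataFrame).
    """
    from .rohne import expected_roh_counts, segment_density

    if two_ne <= 2:
        raise ValueError("two_ne must be > 2")
    L_total = float(sum(genome.values()))
    # fine simulation bins (cM), from min_cm up to 300
    edges = np.concatenate([np.arange(min_cm, 30.0, 1.0), np.arange(30.0, 100.0, 5.0), [300.0]])
    lam = expected_roh_counts(two_ne, L_total, edges)

    rng = _rng(seed, "roh")
    chroms = list(genome)
    chrom_len = np.array([genome[c] for c in chroms])

    # SNP map: regular grid per chromosome keeps window-based calling simple
    snp_rows = []
    for c in chroms:
        n = max(2, int(round(genome[c] * snp_per_morgan)))
        g = np.linspace(0.0, genome[c], n, endpoint=False)
        for x in g:
            snp_rows.append((f"{c}_{len(snp_rows)}", c, float(x), int(round(x * 1e8)) + 1, "A", "G"))
    snp = pd.DataFrame(snp_rows, columns=["id", "chrom", "gpos", "ppos", "ref", "alt"])
    chrom_arr = snp["chrom"].to_numpy()
    gpos = snp["gpos"].to_numpy(float)

    geno = np.ones((n_ind, len(snp)), dtype=np.int8)  # het=1 baseline, overwritten below
    seg_records = []
    for i in range(n_ind):
        # draw segments genome-wide, then place without overlap
        segs = []
        for k in range(len(edges) - 1):
            cnt = rng.poisson(lam[k])
            for _ in range(cnt):
                segs.append(segment_density_sample(two_ne, edges[k], edges[k + 1], rng))
        placed = []  # (chrom_idx, start, end) Morgans
        for length_cm in sorted(segs, reverse=True):
            # segments are placed wholly within a chromosome (uniform among
            # feasible positions) so that realized lengths keep the drawn
            # distribution — the likelihood model the generator twins ignores
            # chromosome edges; a draw longer than every chromosome (vanishing
            # probability for sensible two_ne) is clipped to the longest one
            length = min(length_cm / 100.0, chrom_len.max())
            feasible = np.maximum(chrom_len - length, 0.0)
            if feasible.sum() <= 0:     # segment exactly fills the longest chromosome
                feasible = (chrom_len >= length).astype(float)
            ok = False
            for _try in range(max_retries):
                ci = rng.choice(len(chroms), p=feasible / feasible.sum())
                start = rng.uniform(0.0, chrom_len[ci] - length) \
                    if chrom_len[ci] > length else 0.0
                end = start + length
                if all(not (ci == cj and start < e and end > s) for cj, s, e in placed):
                    placed.append((ci, start, end))
                    ok = True
                    break
            if not ok:
                raise RuntimeError("could not place ROH segment without overlap")
        in_roh = np.zeros(len(snp), dtype=bool)
        for ci, s, e in placed:
            m = (chrom_arr == chroms[ci]) & (gpos >= s) & (gpos < e)
            in_roh |= m
            seg_records.append((f"ind{i}", chroms[ci], s, e, (e - s) * 100.0))
        het = (rng.random(len(snp)) < het_rate) & ~in_roh
        geno[i] = np.where(het, 1, np.where(rng.random(len(snp)) < 0.5, 0, 2))
    ind = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n_ind)],
        "sex": "U", "group": "sim", "pseudohaploid": False,
    })
    truth = pd.DataFrame(seg_records, columns=["ind", "chrom", "start", "end", "length_cm"])
    return Dataset(geno, snp, ind), truth


def segment_density_sample(two_ne: float, l1_cm: float, l2_cm: float,
                           rng: np.random.Generator) -> float:
    """Draw one segment length (cM) from the model density restricted to [l1, l2)."""
    from .rohne import segment_density

    grid = np.linspace(l1_cm, l2_cm, 64)
    dens = segment_density(two_ne, grid / 100.0)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, grid))


# ---------------------------------------------------------------------------
# QC metric tables with constructed pass/fail truth
# ---------------------------------------------------------------------------

QC_COLUMNS = ["id", "snps_covered", "damage_rate", "udg_flag",
              "contam_lower_bound", "mt_match_upper_bound", "sex_ratio"]

#: metric values comfortably inside every pass region
_PASS_TEMPLATE = dict(snps_covered=500_000, damage_rate=0.06, udg_flag=True,
                      contam_lower_bound=0.003, mt_match_upper_bound=0.98,
                      sex_ratio=0.45)


def simulate_qc_table(n_pass: int, fail_specs: list[tuple[str, object]],
                      seed: int) -> pd.DataFrame:
    """Per-individual QC metrics: exactly ``n_pass`` rows pass all thresholds.

    Each fail_spec (metric, value) yields one row identical to a passing row
    except for that metric, which is set to ``value``; the value must actually
    violate the corresponding rule (checked), so each fail row fails for
    exactly one stated reason.
    """
    from .pullcall import qc_failures

    rng = _rng(seed, "qc")
    rows = []
    for i in range(n_pass):
        row = dict(_PASS_TEMPLATE)
        row["id"] = f"pass{i}"
        row["snps_covered"] = int(rng.integers(100_000, 1_000_000))
        row["damage_rate"] = float(rng.uniform(0.04, 0.12))
        row["sex_ratio"] = float(rng.choice([rng.uniform(0.0, 0.04), rng.uniform(0.35, 1.0)]))
        rows.append(row)
    for k, (metric, value) in enumerate(fail_specs):
        if metric not in _PASS_TEMPLATE:
            raise ValueError(f"unknown QC metric {metric!r}")
        row = dict(_PASS_TEMPLATE)
        row["id"] = f"fail{k}"
        row[metric] = value
        reasons = qc_failures(row)
        if not reasons:
            raise ValueError(f"fail_spec ({metric}, {value}) does not violate any threshold")
        rows.append(row)
    table = pd.DataFrame(rows, columns=QC_COLUMNS)
    # constructed passers must actually pass
    for row in rows[:n_pass]:
        if qc_failures(row):
            raise AssertionError("internal error: constructed passing row fails QC")
    return table
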