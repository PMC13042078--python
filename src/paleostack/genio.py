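"""EIGENSTRAT genotype I/O and jackknife block assignment.

The in-memory container is :class:`Dataset`: a dense genotype matrix
(individuals x SNPs, codes 0/1/2 = alternative-allele count, 9 = missing)
together with a SNP table and an individual table.  Genetic positions are
carried in Morgans everywhere inside the package; centimorgans appear only
at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = frozenset({0, 1, 2, 9})
MISSING = 9

SNP_COLUMNS = ["id", "chrom", "gpos", "ppos", "ref", "alt"]
IND_COLUMNS = ["id", "sex", "group"]


class FormatError(ValueError):
    """Malformed EIGENSTRAT input; message carries the offending line number."""


@dataclass
class Dataset:
    """Genotype matrix plus SNP and individual metadata.

    Attributes
    ----------
    geno : (n_ind, n_snp) int8 array with codes in {0, 1, 2, 9}.
    snp  : DataFrame with columns id, chrom, gpos (Morgans), ppos, ref, alt,
           and optional boolean flag columns (e.g. ``monomorphic``).
    ind  : DataFrame with columns id, sex ('M'/'F'/'U'), group, and an
           optional boolean ``pseudohaploid`` column.
    """

    geno: np.ndarray
    snp: pd.DataFrame
    ind: pd.DataFrame

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.validate()

    # -- basic protocol ------------------------------------------------
    @property
    def n_ind(self) -> int:
        return self.geno.shape[0]

    @property
    def n_snp(self) -> int:
        return self.geno.shape[1]

    def validate(self) -> None:
        if self.geno.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
        if self.geno.shape != (len(self.ind), len(self.snp)):
            raise ValueError(
                f"genotype matrix {self.geno.shape} does not match tables "
                f"({len(self.ind)} individuals, {len(self.snp)} SNPs)"
            )
        bad = ~np.isin(self.geno, [0, 1, 2, 9])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"illegal genotype code {self.geno[i, j]} at individual {i}, SNP {j}")
        for col in SNP_COLUMNS:
            if col not in self.snp.columns:
                raise ValueError(f"SNP table missing column {col!r}")
        for col in IND_COLUMNS:
            if col not in self.ind.columns:
                raise ValueError(f"individual table missing column {col!r}")
        # genetic positions must be sorted within each chromosome
        gpos = self.snp["gpos"].to_numpy(float)
        chrom = self.snp["chrom"].to_numpy()
        for c in pd.unique(chrom):
            g = gpos[chrom == c]
            if np.any(np.diff(g) < 0):
                raise ValueError(f"genetic positions not sorted on chromosome {c}")

    def is_pseudohaploid(self) -> np.ndarray:
        """Boolean per individual: pseudohaploid (one haploid draw coded as hom).

        Uses the explicit ``pseudohaploid`` column when present, otherwise
        infers from the absence of heterozygous calls.
        """
        if "pseudohaploid" in self.ind.columns:
            return self.ind["pseudohaploid"].to_numpy(bool)
        return ~(self.geno == 1).any(axis=1)

    def subset_ind(self, ids: list[str]) -> "Dataset":
        idx = self.ind.set_index("id").index.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, k in zip(ids, idx) if k < 0]
            raise KeyError(f"unknown individual id(s): {missing}")
        return Dataset(self.geno[idx], self.snp.copy(), self.ind.iloc[idx].reset_index(drop=True))

    def group_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.ind["group"].to_numpy() == label)
        if idx.size == 0:
            raise KeyError(f"no individuals with group label {label!r}")
        return idx


@dataclass
class BlockAssignment:
    """Per-SNP jackknife block index; blocks are contiguous within chromosomes."""

    block_index: np.ndarray          # (n_snp,) int
    block_sizes: np.ndarray = field(init=False)  # SNP count per block

    def __post_init__(self) -> None:
        self.block_index = np.asarray(self.block_index, dtype=np.int64)
        if self.block_index.size:
            self.block_sizes = np.bincount(self.block_index)
        else:
            self.block_sizes = np.zeros(0, dtype=np.int64)

    @property
    def n_blocks(self) -> int:
        return int(self.block_index.max()) + 1 if self.block_index.size else 0


def assign_blocks(snp: pd.DataFrame, block_cm: float = 5.0) -> BlockAssignment:
    """Greedy segmentation of the genome into ~block_cm jackknife blocks.

    A new block starts at each chromosome start and whenever a SNP lies at
    least ``block_cm``/100 Morgans beyond the first SNP of the current block.
    """
    if len(snp) == 0:
        return BlockAssignment(np.zeros(0, dtype=np.int64))
    width = block_cm / 100.0
    chrom = snp["chrom"].to_numpy()
    gpos = snp["gpos"].to_numpy(float)
    out = np.empty(len(snp), dtype=np.int64)
    block = -1
    cur_chrom = None
    start = 0.0
    for i in range(len(snp)):
        if chrom[i] != cur_chrom or gpos[i] - start >= width:
            block += 1
            cur_chrom = chrom[i]
            start = gpos[i]
        out[i] = block
    return BlockAssignment(out)


# ---------------------------------------------------------------------------
# EIGENSTRAT plain-text dialect
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix: str | Path) -> Dataset:
    """Read a plain-text EIGENSTRAT triplet ``prefix``.{geno,snp,ind}.

    Genetic positions are accepted in Morgans; if every per-chromosome span
    exceeds 4 (i.e. the file is in centimorgans) they are divided by 100
    with a logged warning.
    """
    prefix = Path(prefix)
    snp_rows = []
    with open(prefix.with_suffix(".snp")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise FormatError(f"{prefix}.snp line {ln}: expected 6 columns, got {len(parts)}")
            sid, chrom, gpos, ppos, ref, alt = parts
            try:
                snp_rows.append((sid, chrom, float(gpos), int(ppos), ref, alt))
            except ValueError as exc:
                raise FormatError(f"{prefix}.snp line {ln}: {exc}") from None
    snp = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)

    ind_rows = []
    with open(prefix.with_suffix(".ind")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise FormatError(f"{prefix}.ind line {ln}: expected 3 columns, got {len(parts)}")
            iid, sex, group = parts
            if sex not in ("M", "F", "U"):
                raise FormatError(f"{prefix}.ind line {ln}: illegal sex code {sex!r}")
            ind_rows.append((iid, sex, group))
    ind = pd.DataFrame(ind_rows, columns=IND_COLUMNS)

    geno = np.empty((len(ind), len(snp)), dtype=np.int8)
    with open(prefix.with_suffix(".geno")) as fh:
        nline = 0
        for ln, line in enumerate(fh, 1):
            row = line.strip()
            if not row:
                continue
            if nline >= len(snp):
                raise FormatError(f"{prefix}.geno line {ln}: more lines than SNPs")
            if len(row) != len(ind):
                raise FormatError(
                    f"{prefix}.geno line {ln}: {len(row)} genotypes for {len(ind)} individuals"
                )
            codes = np.frombuffer(row.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = ~np.isin(codes, [0, 1, 2, 9])
            if bad.any():
                raise FormatError(
                    f"{prefix}.geno line {ln}: illegal genotype character {row[int(np.argmax(bad))]!r}"
                )
            geno[:, nline] = codes
            nline += 1
    if nline != len(snp):
        raise FormatError(f"{prefix}.geno: {nline} lines for {len(snp)} SNPs")

    # auto-detect centimorgan input: per-chromosome spans all far beyond 4 Morgans
    spans = snp.groupby("chrom", sort=False)["gpos"].agg(lambda g: g.max())
    if len(snp) and (spans > 4.0).any():
        logger.warning("genetic positions in %s.snp look like centimorgans; dividing by 100", prefix)
        snp["gpos"] = snp["gpos"] / 100.0

    try:
        return Dataset(geno, snp, ind)
    except ValueError as exc:
        raise FormatError(str(exc)) from None


def write_eigenstrat(ds: Dataset, prefix: str | Path) -> None:
    """Write ``ds`` as a plain-text EIGENSTRAT triplet readable by read_eigenstrat."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for row in ds.snp.itertuples(index=False):
            fh.write(f"{row.id}\t{row.chrom}\t{row.gpos:.8f}\t{int(row.ppos)}\t{row.ref}\t{row.alt}\n")
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for row in ds.ind.itertuples(index=False):
            fh.write(f"{row.id}\t{row.sex}\t{row.group}\n")
    digits = np.char.mod("%d", ds.geno.T)
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for j in range(ds.n_snp):
            fh.write("".join(digits[j]) + "\n")
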