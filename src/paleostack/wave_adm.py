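"""qpWave-style rank/cladality tests and qpAdm-style admixture-weight fits.

Both operate on an F4Matrix: with left populations L (first is the base) and
right/reference populations R (first is the base), entry X[i-1, j-1] is
f4(L_i, L_0; R_j, R_0), with a block-jackknife covariance of the stacked
entries.  A clade between two left populations relative to R means every
entry is zero (rank 0); a target that is a mixture of s sources means the
full left set spans only s independent drift directions (rank s-1 after
differencing against the target).

The rank test fits the best rank-r approximation under the covariance-
weighted quadratic form by alternating generalized least squares on the two
factors; the minimized form is chi-square with (|L|-1-r)(|R|-1-r) degrees of
freedom under the rank-r null.

The admixture fit takes the target as the left base, so the model
f4(T - sum_i w_i S_i, .) = 0 becomes sum_i w_i X[i, :] = 0 with sum w = 1;
weights minimize the covariance-weighted norm of that combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fstats import jackknife, per_snp_contributions
from .genio import BlockAssignment, Dataset

logger = logging.getLogger(__name__)

__all__ = ["F4Matrix", "AdmixtureModel", "build_f4_matrix", "rank_test",
           "group_by_cladality", "qpadm_fit"]

#: relative ridge added to near-singular jackknife covariances
RIDGE = 1e-6
COND_MAX = 1e12


@dataclass
class F4Matrix:
    left: list[str]
    right: list[str]
    X: np.ndarray                 # (|L|-1, |R|-1)
    cov: np.ndarray               # covariance of X.flatten() (row-major)
    loo: np.ndarray               # (n_blocks, |L|-1, |R|-1) leave-one-block-out entries
    block_weights: np.ndarray     # (n_blocks,) mean valid-SNP count across entries

    @property
    def n_left(self) -> int:
        return len(self.left) - 1

    @property
    def n_right(self) -> int:
        return len(self.right) - 1


def build_f4_matrix(ds: Dataset, left: list[str], right: list[str],
                    blocks: BlockAssignment, inbreed: bool = False) -> F4Matrix:
    """f4 entries, leave-one-block-out entries and jackknife covariance.

    Masks are per entry ("allsnps" semantics).  Entries with zero variance
    across blocks are flagged with a logged warning (degenerate, e.g. a right
    population duplicated in the left set).
    """
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 left and 2 right populations")
    nL, nR = len(left) - 1, len(right) - 1
    nb = blocks.n_blocks
    ent_sum = np.zeros((nL, nR, nb))
    ent_w = np.zeros((nL, nR, nb))
    for i in range(1, len(left)):
        for j in range(1, len(right)):
            terms, mask = per_snp_contributions(
                ds, "f4", [left[i], left[0], right[j], right[0]], inbreed=inbreed)
            ent_sum[i - 1, j - 1] = np.bincount(
                blocks.block_index, weights=np.where(mask, terms, 0.0), minlength=nb)
            ent_w[i - 1, j - 1] = np.bincount(
                blocks.block_index, weights=mask.astype(float), minlength=nb)

    W = ent_w.sum(axis=2)
    if (W == 0).any():
        raise ValueError("an f4 entry has no valid SNPs")
    X = ent_sum.sum(axis=2) / W

    # leave-one-block-out entry matrices (per-entry weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = (ent_sum.sum(axis=2, keepdims=True) - ent_sum) / (
            W[:, :, None] - ent_w)
    loo = np.where(np.isfinite(loo), loo, X[:, :, None])
    loo = np.moveaxis(loo, 2, 0)                     # (nb, nL, nR)

    # Busing-style jackknife covariance of the stacked entries; per-entry
    # h factors, cross terms symmetrized through sqrt((h_e-1)(h_f-1))
    h = (W[None, :, :] / np.where(ent_w.transpose(2, 0, 1) > 0,
                                  ent_w.transpose(2, 0, 1), np.nan))
    g_eff = np.isfinite(h).sum(axis=0)               # non-empty block count per entry
    theta_j = (g_eff * X) - np.nansum((1.0 - 1.0 / h) * loo, axis=0)
    tau = h * X[None] - (h - 1.0) * loo
    dev = (tau - theta_j[None]) / np.sqrt(np.where(h > 1, h - 1.0, np.nan))
    devf = dev.reshape(nb, nL * nR)
    devf = np.where(np.isfinite(devf), devf, 0.0)
    g_flat = g_eff.reshape(-1).astype(float)
    cov = devf.T @ devf / np.sqrt(np.outer(g_flat, g_flat))
    cov = (cov + cov.T) / 2.0
    var = np.diag(cov)
    if (var <= 0).any():
        logger.warning("degenerate (zero-variance) f4 entries: %s",
                       np.flatnonzero(var <= 0).tolist())
    bw = np.where(ent_w.transpose(2, 0, 1) > 0, ent_w.transpose(2, 0, 1), 0.0)
    return F4Matrix(list(left), list(right), X, cov, loo,
                    bw.reshape(nb, -1).mean(axis=1))


def _safe_inverse(cov: np.ndarray) -> np.ndarray:
    """Inverse with a relative ridge when the condition number is extreme."""
    c = np.linalg.cond(cov)
    if not np.isfinite(c) or c > COND_MAX:
        logger.warning("near-singular covariance (cond=%.3g); applying ridge", c)
        cov = cov + RIDGE * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    return np.linalg.inv(cov)


def rank_test(m: F4Matrix, r: int) -> tuple[float, int, float]:
    """Chi-square test that the f4 matrix has rank <= r.

    Returns (chi2, df, p) with df = (|L|-1-r)(|R|-1-r).  r = 0 reduces to the
    quadratic form x' Sigma^-1 x on the stacked entries.
    """
    nL, nR = m.n_left, m.n_right
    if r < 0 or r >= min(nL, nR) + 1:
        raise ValueError(f"rank {r} out of range for a {nL}x{nR} matrix")
    v = m.X.reshape(-1)
    P = _safe_inverse(m.cov)
    df = (nL - r) * (nR - r)
    if r == 0:
        chi2 = float(v @ P @ v)
    elif df <= 0:
        chi2 = 0.0
    else:
        chi2 = _als_rank_fit(m.X, P, r)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def _als_rank_fit(X: np.ndarray, P: np.ndarray, r: int,
                  n_iter: int = 200, tol: float = 1e-12) -> float:
    """Minimize (v - vec(AB))' P (v - vec(AB)) over A (nLxr), B (rxnR)."""
    nL, nR = X.shape
    v = X.reshape(-1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    A = U[:, :r] * s[:r]
    B = Vt[:r]
    prev = np.inf
    for _ in range(n_iter):
        # solve for A given B: columns of design indexed by (i,k)
        MA = np.zeros((nL * nR, nL * r))
        for i in range(nL):
            MA[i * nR:(i + 1) * nR, i * r:(i + 1) * r] = B.T
        A = np.linalg.solve(MA.T @ P @ MA, MA.T @ P @ v).reshape(nL, r)
        # solve for B given A
        MB = np.kron(A, np.eye(nR))      # vec_row(AB) = (A kron I) vec_row(B)
        B = np.linalg.solve(MB.T @ P @ MB, MB.T @ P @ v).reshape(r, nR)
        resid = v - (A @ B).reshape(-1)
        chi2 = float(resid @ P @ resid)
        if abs(prev - chi2) < tol * (1.0 + abs(chi2)):
            break
        prev = chi2
    return chi2


def group_by_cladality(ds: Dataset, individuals: list[str], right: list[str],
                       blocks: BlockAssignment, alpha: float = 0.05,
                       inbreed: bool = False) -> tuple[list[list[str]], list[str]]:
    """Partition individuals into clades by pairwise rank-0 qpWave tests.

    An edge joins each pair whose rank-0 p exceeds ``alpha``; groups are the
    connected components.  An individual whose neighbours fall into more than
    one component of the graph with that individual removed is flagged
    ambiguous and left ungrouped.

    Returns (groups, ambiguous ids).
    """
    n = len(individuals)
    if n < 2:
        return [list(individuals)], []
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            m = build_f4_matrix(ds, [individuals[a], individuals[b]], right,
                                blocks, inbreed=inbreed)
            _, _, p = rank_test(m, 0)
            adj[a, b] = adj[b, a] = p > alpha

    def components(mask_nodes: list[int]) -> list[set[int]]:
        seen, comps = set(), []
        for s0 in mask_nodes:
            if s0 in seen:
                continue
            comp, stack = set(), [s0]
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(w for w in mask_nodes if adj[u, w] and w not in comp)
            seen |= comp
            comps.append(comp)
        return comps

    ambiguous = []
    for v in range(n):
        others = [u for u in range(n) if u != v]
        comps = components(others)
        touched = {k for k, comp in enumerate(comps) if any(adj[v, u] for u in comp)}
        if len(touched) > 1:
            ambiguous.append(v)
    keep = [u for u in range(n) if u not in ambiguous]
    groups = [sorted(individuals[u] for u in comp) for comp in components(keep)]
    return groups, [individuals[v] for v in ambiguous]


@dataclass
class AdmixtureModel:
    target: str
    sources: list[str]
    references: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    chi2: float
    df: int
    p: float
    infeasible: bool = field(default=False)

    def __post_init__(self) -> None:
        self.infeasible = bool((self.weights < 0).any() or (self.weights > 1).any())


def _solve_weights(X: np.ndarray, cov: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """min_w (X'w)' C(w)^-1 (X'w) s.t. sum w = 1, by GLS fixed-point iteration.

    C(w) is the covariance of y = X'w contracted from the full jackknife
    covariance of vec(X); with C fixed the constrained minimizer is
    w = Q^-1 1 / (1' Q^-1 1) with Q = X C^-1 X'.
    """
    S, nR = X.shape
    ones = np.ones(S)
    cov4 = cov.reshape(S, nR, S, nR)
    w = ones / S
    for _ in range(n_iter):
        C = np.einsum("i,ijkl,k->jl", w, cov4, w)
        C = (C + C.T) / 2.0
        Ci = _safe_inverse(C)
        Q = X @ Ci @ X.T
        try:
            qi1 = np.linalg.solve(Q, ones)
        except np.linalg.LinAlgError:
            raise ValueError("collinear sources: the weight system is singular") from None
        w_new = qi1 / (ones @ qi1)
        if np.allclose(w_new, w, atol=1e-12):
            w = w_new
            break
        w = w_new
    return w


def qpadm_fit(ds: Dataset, target: str, sources: list[str], references: list[str],
              blocks: BlockAssignment, inbreed: bool = False) -> AdmixtureModel:
    """Admixture weights for ``target`` as a mixture of ``sources``.

    Needs |references| >= |sources| + 1.  The model p-value is the rank test
    at r = |sources| - 1 on the full left set {target} + sources.  Weight
    standard errors come from re-solving the weight system on each
    leave-one-block-out f4 matrix (weighted block jackknife).  Weights
    outside [0,1] are flagged infeasible, not clipped.
    """
    if len(references) < len(sources) + 1:
        raise ValueError("need at least |sources|+1 reference populations")
    left = [target] + list(sources)
    m = build_f4_matrix(ds, left, references, blocks, inbreed=inbreed)
    # sanity: collinear sources give (near) linearly dependent rows
    if len(sources) >= 2:
        Xn = m.X / np.linalg.norm(m.X, axis=1, keepdims=True)
        gram = Xn @ Xn.T
        for i in range(len(sources)):
            for j in range(i + 1, len(sources)):
                if abs(gram[i, j]) > 1.0 - 1e-10:
                    raise ValueError(
                        f"collinear sources: {sources[i]} and {sources[j]}")
    w = _solve_weights(m.X, m.cov)
    C = np.einsum("i,ijkl,k->jl", w, m.cov.reshape(m.n_left, m.n_right,
                                                   m.n_left, m.n_right), w)
    y = m.X.T @ w
    chi2_fit = float(y @ _safe_inverse((C + C.T) / 2) @ y)

    # model fit: can the full left set be explained by rank |sources|-1?
    chi2, df, p = rank_test(m, len(sources) - 1)

    # block jackknife of the whole fit
    loo_w = np.array([_solve_weights(m.loo[b], m.cov) for b in range(m.loo.shape[0])])
    se = np.empty(len(sources))
    for k in range(len(sources)):
        bw = m.block_weights
        Wtot = bw.sum()
        gb = len(bw)
        h = Wtot / np.where(bw > 0, bw, np.nan)
        theta_j = gb * w[k] - np.nansum((1 - 1 / h) * loo_w[:, k])
        tau = h * w[k] - (h - 1) * loo_w[:, k]
        var = np.nansum((tau - theta_j) ** 2 / (h - 1)) / gb
        se[k] = np.sqrt(max(var, 0.0))
    del chi2_fit
    return AdmixtureModel(target, list(sources), list(references), w, se, chi2, df, p)
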