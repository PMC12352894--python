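"""Covarying-neighborhood differential abundance (NDA).

A kNN graph over cells is turned into a random-walk transition matrix; each
sample's neighborhood abundance row starts as the uniform distribution over
its own cells and diffuses for a fixed number of steps, yielding a samples x
cells neighborhood abundance matrix (NAM).  A sample-level phenotype is then
tested against the NAM after residualizing both on covariates: a global
permutation test on the squared multiple correlation with the top NAM
principal components, plus per-cell association coefficients with a
permutation-derived FDR threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .preprocess import EventMatrix, build_knn_adjacency

logger = logging.getLogger("cytostrat")


# ---------------------------------------------------------------------------
# graph + NAM
# ---------------------------------------------------------------------------

@dataclass
class KnnGraph:
    """Symmetrized kNN graph over cells, with the sample of each cell."""

    adjacency: sparse.csr_matrix
    cell_sample: np.ndarray  # per-cell sample id (object array)
    k: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


def build_graph_from_events(
    samples: dict[str, EventMatrix], *, k: int = 15, markers: list[str] | None = None,
) -> KnnGraph:
    """Pooled kNN graph on z-scored transformed marker intensities."""
    sids = list(samples)
    mk = markers or samples[sids[0]].markers
    cols = [samples[sids[0]].markers.index(m) for m in mk]
    X = np.vstack([samples[s].values[:, cols] for s in sids])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    A = build_knn_adjacency((X - mu) / sd, k)
    cell_sample = np.concatenate(
        [np.full(samples[s].n_cells, s, dtype=object) for s in sids])
    return KnnGraph(adjacency=A, cell_sample=cell_sample, k=k)


@dataclass
class NeighborhoodAbundanceMatrix:
    """Samples x cells matrix of random-walk-smoothed per-sample neighborhood
    fractions; every row sums to 1."""

    matrix: pd.DataFrame  # index: sample ids, columns: cell indices
    n_steps: int


def build_nam(graph: KnnGraph, n_steps: int = 3) -> NeighborhoodAbundanceMatrix:
    """Diffuse each sample's uniform cell distribution ``n_steps`` times
    through the row-normalized symmetrized transition matrix."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    sids = list(dict.fromkeys(graph.cell_sample))
    n = graph.n_cells
    M = np.zeros((len(sids), n))
    for i, s in enumerate(sids):
        mask = graph.cell_sample == s
        cnt = int(mask.sum())
        if cnt == 0:
            raise ValueError(f"sample {s} has no cells")
        M[i, mask] = 1.0 / cnt
    if n_steps:
        A = graph.adjacency.astype(float)
        deg = np.asarray(A.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        T = sparse.diags(1.0 / deg) @ A  # row-stochastic
        for _ in range(n_steps):
            M = M @ T
    M /= M.sum(axis=1, keepdims=True)
    return NeighborhoodAbundanceMatrix(pd.DataFrame(M, index=sids), n_steps)


def auto_n_steps(graph: KnnGraph, max_steps: int = 10, stop_rho: float = 0.99) -> int:
    """Smallest step count at which consecutive steps' per-cell total
    abundance rank-correlate above ``stop_rho`` (default walk length 3 is
    used by the pipeline; this is the documented auto rule)."""
    from scipy.stats import spearmanr

    prev = build_nam(graph, 0).matrix.to_numpy().sum(axis=0)
    for s in range(1, max_steps + 1):
        cur = build_nam(graph, s).matrix.to_numpy().sum(axis=0)
        rho = spearmanr(prev, cur).statistic
        if rho > stop_rho:
            return s
        prev = cur
    return max_steps


# ---------------------------------------------------------------------------
# association testing
# ---------------------------------------------------------------------------

@dataclass
class NdaResult:
    global_p: float
    coefficients: np.ndarray       # per-cell correlation with residual phenotype
    fdr_threshold: float           # |coefficient| cutoff (inf if none passes)
    passing_mask: np.ndarray       # |coef| >= threshold
    n_pcs: int
    n_perms: int
    seed: int
    fdr_q: float


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """OLS residual of y (vector or matrix columns) on C (with intercept)."""
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta


def associate(
    nam: NeighborhoodAbundanceMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    n_pcs: int | str = "auto",
    n_perms: int = 1000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> NdaResult:
    """Test a sample-level phenotype against neighborhood abundances.

    Phenotype and NAM columns are residualized on the covariates (OLS with
    intercept); the global statistic is the squared multiple correlation of
    the residual phenotype with the top ``n_pcs`` NAM principal components,
    with the p-value from ``n_perms`` permutations of the residual phenotype
    (add-one rule, so p is never 0).  Per-cell coefficients are correlations
    of the residual phenotype with the top-``n_pcs`` reconstruction of the
    residual NAM columns (truncation denoises single-cell neighborhood
    fractions before localization); the FDR threshold
    is the smallest |coefficient| cutoff at which the mean permuted
    exceedance count over the observed exceedance count is <= ``fdr_q``.

    Binary phenotypes are coded 0/1 and treated numerically.
    """
    sids = list(nam.matrix.index)
    if len(sids) < 8:
        raise ValueError("need at least 8 samples")
    y = phenotype.loc[sids].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    n = len(sids)

    if covariates is not None and len(covariates.columns):
        cov = covariates.loc[sids]
        dropped = cov.index[cov.isna().any(axis=1)]
        if len(dropped):
            logger.warning("associate: dropping %d samples with missing covariates",
                           len(dropped))
            keep = [s for s in sids if s not in set(dropped)]
            return associate(
                NeighborhoodAbundanceMatrix(nam.matrix.loc[keep], nam.n_steps),
                phenotype, covariates.dropna(), n_pcs=n_pcs, n_perms=n_perms,
                seed=seed, fdr_q=fdr_q)
        C = pd.get_dummies(cov, drop_first=True).to_numpy(dtype=float)
        C = np.column_stack([np.ones(n), C])
    else:
        C = np.ones((n, 1))

    M = nam.matrix.to_numpy()
    y_r = _residualize(y, C)
    if np.allclose(y_r, 0):
        raise ValueError("phenotype fully explained by covariates")
    M_r = _residualize(M, C)
    M_r = M_r - M_r.mean(axis=0)

    # PCA of residualized NAM via SVD (samples x cells, samples small)
    U, S, Vt = np.linalg.svd(M_r, full_matrices=False)
    y_std = (y_r - y_r.mean()) / y_r.std()
    k_max = max(1, min(10, n - 2))
    if n_pcs != "auto":
        if int(n_pcs) >= n:
            raise ValueError("n_pcs must be < n_samples")
        k_max = max(k_max, max(1, int(n_pcs)))

    # cumulative R^2 of y on the leading PCs (PC subspace = span of U cols)
    def r2_path(Y: np.ndarray) -> np.ndarray:
        proj = (Y @ U[:, :k_max]) ** 2 / n  # rows: vectors, cols: PC index
        return np.cumsum(np.atleast_2d(proj), axis=1)

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perms)])
    perm_y = y_std[perm_idx]

    if n_pcs == "auto":
        # BIC-selected walk dimension; the selection is repeated inside every
        # permutation so the global test stays calibrated
        ks = np.arange(1, k_max + 1)

        def bic_stat(R2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            bic = n * np.log(np.clip(1.0 - R2, 1e-12, None)) + ks * np.log(n)
            return -bic.min(axis=1), ks[np.argmin(bic, axis=1)]

        obs_stat, obs_k = bic_stat(r2_path(y_std))
        perm_stat, _ = bic_stat(r2_path(perm_y))
        k = int(obs_k[0])
        obs_val = float(obs_stat[0])
    else:
        k = int(n_pcs)
        if k >= n:
            raise ValueError("n_pcs must be < n_samples")
        k = max(k, 1)
        obs_val = float(r2_path(y_std)[0, k - 1])
        perm_stat = r2_path(perm_y)[:, k - 1]
    global_p = float((1 + (perm_stat >= obs_val).sum()) / (1 + n_perms))

    # per-cell coefficients: correlation of the residual phenotype with the
    # rank-k (top-PC) reconstruction of the NAM columns; the truncation
    # denoises single-cell neighborhood fractions before localization
    Vk = Vt[:k]                       # (k, n_cells)
    proj = (y_std @ U[:, :k]) * S[:k] / n     # phenotype in PC space
    col_num = proj @ Vk               # covariance with reconstructed columns
    col_sd = np.sqrt(((S[:k, None] * Vk) ** 2).sum(axis=0) / n)
    safe = col_sd > 1e-12
    coef = np.zeros(M.shape[1])
    coef[safe] = col_num[safe] / col_sd[safe]
    coef = np.clip(coef, -1.0, 1.0)

    # permutation FDR over a threshold grid (streamed to bound memory)
    abs_coef = np.abs(coef)
    grid = np.unique(np.quantile(abs_coef, np.linspace(0.5, 1.0, 201)))
    obs_exceed = (abs_coef[None, :] >= grid[:, None]).sum(axis=1)
    perm_exceed = np.zeros(len(grid))
    chunk = max(1, int(2e7 // max(M.shape[1], 1)))
    for start in range(0, n_perms, chunk):
        P = y_std[perm_idx[start:start + chunk]]  # (b, n)
        pproj = (P @ U[:, :k]) * S[:k] / n
        pc = np.zeros((P.shape[0], M.shape[1]))
        pc[:, safe] = (pproj @ Vk)[:, safe] / col_sd[safe]
        a = np.abs(np.clip(pc, -1.0, 1.0))
        for gi, t in enumerate(grid):
            perm_exceed[gi] += (a >= t).sum()
    # add-one numerator keeps the estimator conservative when observed
    # exceedance counts are small
    mean_perm_exceed = (perm_exceed + 1.0) / n_perms
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_curve = np.where(obs_exceed > 0, mean_perm_exceed / obs_exceed, 1.0)
    passing = np.where((fdr_curve <= fdr_q) & (obs_exceed > 0))[0]
    # local discoveries are only reported when the global association is
    # significant; the per-cell FDR estimate is not reliable on its own
    # under correlated null columns
    if len(passing) and global_p < 0.05:
        thr = float(grid[passing[0]])
        # inclusive, matching the exceedance counts the threshold was chosen by
        mask = abs_coef >= thr
    else:
        thr = float("inf")
        mask = np.zeros_like(abs_coef, dtype=bool)

    return NdaResult(
        global_p=global_p, coefficients=coef, fdr_threshold=thr,
        passing_mask=mask, n_pcs=k, n_perms=n_perms, seed=seed, fdr_q=fdr_q)
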